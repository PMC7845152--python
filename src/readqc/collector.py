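"""Single-pass statistics collection.

The design centralizes file reading: one streaming pass over the reads
updates every sufficient statistic (positional base/quality counts, per-read
GC and mean-quality histograms, read lengths, per-tile quality sums, a
bounded duplication tracker and cumulative adapter-match counters).  All
analysis modules are then computed from the accumulator after the pass, so
memory is bounded by the longest read, not the number of reads.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional

import numpy as np

from .config import AdapterSet
from .seqio import FastqRecord

__all__ = [
    "BaseGroup",
    "make_base_groups",
    "DuplicationTracker",
    "track_duplication",
    "corrected_count",
    "scan_adapters",
    "tile_from_name",
    "TileStats",
    "StreamStats",
    "update_stats",
]

#: quality histogram dimension: printable ASCII 33..126 stored offset-33
QUAL_RANGE = 94

#: number of distinct sequences retained by the duplication tracker
DEFAULT_TRACKER_CAPACITY = 100_000

#: reads longer than this have their duplication key truncated to 50 bp
_DUP_TRUNCATE_ABOVE = 75
_DUP_KEY_LEN = 50

#: minimum number of adapter bases that must match at a read's 3' end
MIN_ADAPTER_MATCH = 12

# base -> column index; everything outside A,C,G,T counts as N (column 4)
_BASE_IDX = np.full(256, 4, dtype=np.intp)
for _i, _b in enumerate(b"ACGT"):
    _BASE_IDX[_b] = _i


# --------------------------------------------------------------------------
# position grouping
# --------------------------------------------------------------------------

@dataclass(frozen=True, slots=True)
class BaseGroup:
    """Contiguous 1-based position range pooled into one table row."""

    start: int
    end: int

    @property
    def label(self) -> str:
        return str(self.start) if self.start == self.end else f"{self.start}-{self.end}"


def make_base_groups(max_len: int, nogroup: bool = False) -> List[BaseGroup]:
    """Tile positions 1..max_len into display groups.

    Reads up to 75 bp get one group per position.  Longer reads keep
    singleton groups for positions 1-9 and then switch to progressively
    wider bins (5, then 10, 50, 100, 500 as the read length grows), matching
    the reference tool's "Base" column.  ``nogroup`` forces singletons.
    """
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    if nogroup or max_len <= 75:
        return [BaseGroup(i, i) for i in range(1, max_len + 1)]
    groups: List[BaseGroup] = []
    start, interval = 1, 1
    while start <= max_len:
        end = min(start + interval - 1, max_len)
        groups.append(BaseGroup(start, end))
        start += interval
        if start == 10 and max_len > 75:
            interval = 5
        if start == 50 and max_len > 200:
            interval = 10
        if start == 100 and max_len > 300:
            interval = 50
        if start == 500 and max_len > 1000:
            interval = 100
        if start == 1000 and max_len > 2000:
            interval = 500
    return groups


# --------------------------------------------------------------------------
# duplication tracking
# --------------------------------------------------------------------------

class DuplicationTracker:
    """Bounded map of the first ``capacity`` distinct (truncated) sequences.

    Sequences longer than 75 bp are keyed by their first 50 bases.  Once the
    map is full no new keys are admitted, but counts of stored keys keep
    accumulating through the whole file.  ``count_at_limit`` records how many
    reads had been seen when the tracker last accepted a new key; it feeds
    the extrapolation in :func:`corrected_count`.
    """

    __slots__ = ("counts", "capacity", "count_at_limit", "total_reads")

    def __init__(self, capacity: int = DEFAULT_TRACKER_CAPACITY):
        self.counts: Dict[str, int] = {}
        self.capacity = capacity
        self.count_at_limit = 0
        self.total_reads = 0

    @staticmethod
    def key_for(bases: str) -> str:
        if len(bases) > _DUP_TRUNCATE_ABOVE:
            return bases[:_DUP_KEY_LEN]
        return bases

    def add(self, bases: str, reads_seen: int) -> None:
        self.total_reads = reads_seen
        key = self.key_for(bases)
        cur = self.counts.get(key)
        if cur is not None:
            self.counts[key] = cur + 1
        elif len(self.counts) < self.capacity:
            self.counts[key] = 1
            self.count_at_limit = reads_seen

    @property
    def at_capacity(self) -> bool:
        return len(self.counts) >= self.capacity


def track_duplication(
    tracker: DuplicationTracker, bases: str, reads_seen: int
) -> DuplicationTracker:
    tracker.add(bases, reads_seen)
    return tracker


def corrected_count(observed: int, count_at_limit: int, total: int) -> float:
    """Extrapolate a tracked sequence's count to the whole library.

    A sequence seen ``observed`` times in the full file entered the tracker
    only if one of its copies fell within the first ``count_at_limit`` reads.
    Dividing by that probability corrects for sequences that never entered:

        observed / (1 - prod_{i=0}^{count_at_limit-1} (total-observed-i)/(total-i))

    When the tracker saw the whole file, or the sequence could not have been
    missed, the observed count is already exact.
    """
    if total == 0:
        raise ValueError("total must be positive")
    if count_at_limit == total:
        return float(observed)
    if total - observed < count_at_limit:
        return float(observed)
    p_not_seen = 1.0
    for i in range(count_at_limit):
        p_not_seen *= (total - observed - i) / (total - i)
    return observed / (1.0 - p_not_seen)


# --------------------------------------------------------------------------
# adapter scanning and tile parsing
# --------------------------------------------------------------------------

def scan_adapters(bases: str, adapters: AdapterSet) -> Dict[str, Optional[int]]:
    """Earliest 1-based match position of each adapter in a read.

    A match is the full adapter sequence anywhere in the read, or an adapter
    prefix of at least MIN_ADAPTER_MATCH bases flush with the read's 3' end
    (the adapter ran off the read).  Only the earliest position per adapter
    is reported.
    """
    out: Dict[str, Optional[int]] = {}
    n = len(bases)
    for name, seq in adapters:
        pos = bases.find(seq)
        best = pos + 1 if pos >= 0 else None
        # partial adapter hanging off the end of the read
        max_k = min(len(seq) - 1, n)
        for k in range(max_k, MIN_ADAPTER_MATCH - 1, -1):
            start = n - k
            if best is not None and start + 1 >= best:
                break
            if bases.startswith(seq[:k], start):
                best = start + 1
                break
        out[name] = best
    return out


def tile_from_name(name: str) -> Optional[int]:
    """Extract the flowcell tile id from an Illumina-style read header.

    Casava 1.8+ headers (>= 7 ':' fields) carry the tile in field 5;
    legacy headers (5-6 fields) in field 3.  Anything else yields None.
    """
    parts = name.split(":")
    if len(parts) >= 7:
        candidate = parts[4]
    elif len(parts) >= 5:
        candidate = parts[2]
    else:
        return None
    try:
        return int(candidate)
    except ValueError:
        return None


class TileStats:
    """Per-tile, per-position quality sums and counts."""

    __slots__ = ("tiles", "max_len")

    def __init__(self):
        self.tiles: Dict[int, list] = {}  # tile -> [qual_sum array, count array]
        self.max_len = 0

    def add(self, tile: int, quals: np.ndarray) -> None:
        length = quals.shape[0]
        entry = self.tiles.get(tile)
        if entry is None:
            entry = [np.zeros(length, dtype=np.float64),
                     np.zeros(length, dtype=np.int64)]
            self.tiles[tile] = entry
        elif entry[0].shape[0] < length:
            grow = length - entry[0].shape[0]
            entry[0] = np.pad(entry[0], (0, grow))
            entry[1] = np.pad(entry[1], (0, grow))
        entry[0][:length] += quals
        entry[1][:length] += 1
        if length > self.max_len:
            self.max_len = length

    def __bool__(self) -> bool:
        return bool(self.tiles)


# --------------------------------------------------------------------------
# the accumulator
# --------------------------------------------------------------------------

class StreamStats:
    """Every sufficient statistic needed by the analysis modules.

    Quality values are stored on the raw (offset-33) scale; the detected
    Phred offset is applied at postprocessing time.  Positional arrays grow
    to the longest read seen so far.
    """

    def __init__(self, adapters: Optional[AdapterSet] = None,
                 tracker_capacity: int = DEFAULT_TRACKER_CAPACITY,
                 count_kmers: bool = False, kmer_length: int = 7):
        self.adapters = adapters if adapters is not None else AdapterSet([])
        self.max_len = 0
        self.min_len: Optional[int] = None
        self.total_reads = 0
        self.min_qual_code: Optional[int] = None

        self.base_counts = np.zeros((0, 5), dtype=np.int64)  # A C G T N
        self.qual_counts = np.zeros((0, QUAL_RANGE), dtype=np.int64)
        self.seq_qual_hist = np.zeros(QUAL_RANGE, dtype=np.int64)
        self.gc_hist = np.zeros(101, dtype=np.int64)
        self.length_hist = np.zeros(1, dtype=np.int64)  # index = read length

        self.tracker = DuplicationTracker(tracker_capacity)
        self.tiles = TileStats()

        # adapter name -> (match-start histogram, matched-read length histogram)
        self.adapter_starts = {name: np.zeros(0, dtype=np.int64)
                               for name, _ in self.adapters}
        self.adapter_lengths = {name: np.zeros(0, dtype=np.int64)
                                for name, _ in self.adapters}

        self.count_kmers = count_kmers
        self.kmer_length = kmer_length
        # kmer -> {position -> count}; populated only when count_kmers is set
        self.kmer_pos_counts: Dict[str, Dict[int, int]] = {}

    # -- growth helpers ---------------------------------------------------
    def _grow(self, length: int) -> None:
        if length > self.base_counts.shape[0]:
            extra = length - self.base_counts.shape[0]
            self.base_counts = np.pad(self.base_counts, ((0, extra), (0, 0)))
            self.qual_counts = np.pad(self.qual_counts, ((0, extra), (0, 0)))
        if length >= self.length_hist.shape[0]:
            self.length_hist = np.pad(
                self.length_hist, (0, length + 1 - self.length_hist.shape[0])
            )

    # -- per-read update --------------------------------------------------
    def update(self, rec: FastqRecord) -> None:
        self.total_reads += 1
        length = len(rec.bases)
        self._grow(length)
        self.length_hist[length] += 1
        if self.min_len is None or length < self.min_len:
            self.min_len = length
        if length > self.max_len:
            self.max_len = length
        if length == 0:
            return  # zero-length reads contribute only to the length histogram

        codes = np.frombuffer(rec.bases.encode("ascii"), dtype=np.uint8)
        qcodes = np.frombuffer(rec.quality.encode("ascii"), dtype=np.uint8)
        positions = np.arange(length)

        idx = _BASE_IDX[codes]
        # each (position, base) pair is unique within a read
        self.base_counts[positions, idx] += 1

        qmin = int(qcodes.min())
        if self.min_qual_code is None or qmin < self.min_qual_code:
            self.min_qual_code = qmin
        quals = qcodes.astype(np.int64) - 33
        self.qual_counts[positions, quals] += 1

        # per-read summaries: GC% rounded half-up over the full read length,
        # mean quality truncated toward zero
        gc = int(np.count_nonzero((idx == 1) | (idx == 2)))
        self.gc_hist[int(100.0 * gc / length + 0.5)] += 1
        self.seq_qual_hist[int(quals.mean())] += 1

        tile = tile_from_name(rec.name)
        if tile is not None:
            self.tiles.add(tile, quals.astype(np.float64))

        self.tracker.add(rec.bases, self.total_reads)

        if self.adapters.entries:
            hits = scan_adapters(rec.bases, self.adapters)
            for name, pos in hits.items():
                if pos is None:
                    continue
                starts = self.adapter_starts[name]
                if pos > starts.shape[0]:
                    starts = np.pad(starts, (0, pos - starts.shape[0]))
                    self.adapter_starts[name] = starts
                starts[pos - 1] += 1
                lens = self.adapter_lengths[name]
                if length >= lens.shape[0]:
                    lens = np.pad(lens, (0, length + 1 - lens.shape[0]))
                    self.adapter_lengths[name] = lens
                lens[length] += 1

        if self.count_kmers and length >= self.kmer_length:
            k = self.kmer_length
            bases = rec.bases
            for p in range(length - k + 1):
                kmer = bases[p:p + k]
                if "N" in kmer:
                    continue
                slots = self.kmer_pos_counts.setdefault(kmer, {})
                slots[p + 1] = slots.get(p + 1, 0) + 1

    # -- derived views ----------------------------------------------------
    def reads_at_least(self) -> np.ndarray:
        """reads_at_least()[p-1] = number of reads with length >= p."""
        if self.max_len == 0:
            return np.zeros(0, dtype=np.int64)
        per_len = self.length_hist[: self.max_len + 1]
        # suffix sum over lengths, evaluated at 1..max_len
        return np.cumsum(per_len[::-1])[::-1][1:]

    def adapter_cumulative(self, name: str) -> np.ndarray:
        """Reads with a match at or before each position 1..max_len.

        A read contributes to positions from its earliest match through its
        own length (it cannot be counted past its end).
        """
        cum = np.zeros(self.max_len, dtype=np.int64)
        if self.max_len == 0:
            return cum
        starts = np.zeros(self.max_len, dtype=np.int64)
        s = self.adapter_starts.get(name)
        if s is not None and s.shape[0]:
            starts[: s.shape[0]] = s[: self.max_len]
        ended = np.zeros(self.max_len + 1, dtype=np.int64)
        e = self.adapter_lengths.get(name)
        if e is not None and e.shape[0]:
            ended[: e.shape[0]] = e
        started_by = np.cumsum(starts)
        # matched reads whose length < p no longer cover position p
        ended_before = np.cumsum(ended)[:-1]
        return started_by - ended_before

    def base_groups(self, nogroup: bool = False) -> List[BaseGroup]:
        return make_base_groups(max(self.max_len, 1), nogroup)


def update_stats(stats: StreamStats, rec: FastqRecord) -> StreamStats:
    stats.update(rec)
    return stats


def collect(stream, adapters: Optional[AdapterSet] = None, **kwargs) -> StreamStats:
    """Run the single pass over a read stream and return the accumulator."""
    stats = StreamStats(adapters, **kwargs)
    for rec in stream:
        stats.update(rec)
    return stats
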
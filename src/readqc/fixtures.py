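"""Deterministic synthetic FASTQ generation with planted structure.

Every QC module is testable without downloads: the generator plants known
duplicates, adapter insertions, tile-specific quality offsets and N calls,
and returns a manifest of the exact planted truths.  A naive two-pass
oracle recomputes every accumulator statistic by definition (loading all
reads) for equivalence checks against the streaming pass, and
``compare_reports`` diffs two data files in the report dialect.
"""

from __future__ import annotations

import gzip
import json
import os
from collections import Counter
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .collector import MIN_ADAPTER_MATCH, DEFAULT_TRACKER_CAPACITY
from .config import AdapterSet
from .report import parse_data_txt
from .seqio import open_reads

__all__ = ["FixtureSpec", "generate_fastq", "two_pass_oracle", "compare_reports"]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class FixtureSpec:
    """Recipe for a synthetic FASTQ file.

    quality: a constant Phred value, or a (start, end) pair interpolated
    linearly along the read.  tile_offsets shifts quality per tile id (tiles
    are cycled across reads when ``tiles`` is set).  duplicates is a list of
    (sequence-or-None, multiplicity) blocks prepended to the file; adapter
    is (sequence, 1-based start, fraction of reads).  All randomness comes
    from one generator seeded by ``seed``.
    """

    n_reads: int = 100
    length: Union[int, Tuple[int, int]] = 50
    quality: Union[int, Tuple[int, int]] = 35
    quality_jitter: float = 0.0
    base_probs: Tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    duplicates: List[Tuple[Optional[str], int]] = field(default_factory=list)
    adapter: Optional[Tuple[str, int, float]] = None
    tiles: Optional[List[int]] = None
    tile_offsets: Optional[Dict[int, float]] = None
    n_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.length_range()
        if lo < 1 or hi < lo:
            raise ValueError("invalid length range")
        if not 0 <= self.n_rate <= 1:
            raise ValueError("n_rate must be in [0,1]")
        if self.adapter is not None:
            seq, start, frac = self.adapter
            if not 0 <= frac <= 1:
                raise ValueError("adapter fraction must be in [0,1]")
            if start < 1 or start - 1 + min(len(seq), MIN_ADAPTER_MATCH) > lo:
                raise ValueError(
                    "planted adapter does not fit the shortest read"
                )
        for seq, mult in self.duplicates:
            if mult < 1:
                raise ValueError("duplicate multiplicity must be >= 1")
            if seq is not None and len(seq) != lo and lo != hi:
                raise ValueError("explicit duplicate must match fixed length")

    def length_range(self) -> Tuple[int, int]:
        if isinstance(self.length, int):
            return self.length, self.length
        lo, hi = self.length
        return int(lo), int(hi)


def _quality_profile(spec: FixtureSpec, length: int) -> np.ndarray:
    if isinstance(spec.quality, int):
        return np.full(length, spec.quality, dtype=np.float64)
    q0, q1 = spec.quality
    if length == 1:
        return np.array([float(q0)])
    return np.linspace(q0, q1, length)


def generate_fastq(spec: FixtureSpec, path: str, gzipped: bool = False) -> dict:
    """Write the fixture to ``path`` and return the manifest of planted truths.

    The manifest is also written next to the file as ``<path>.manifest.json``.
    Identical specs produce byte-identical files.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.length_range()
    probs = np.asarray(spec.base_probs, dtype=np.float64)
    probs = probs / probs.sum()

    # which reads carry the planted adapter (exact count, deterministic)
    adapter_idx: set = set()
    if spec.adapter is not None:
        _, _, frac = spec.adapter
        k = int(round(frac * spec.n_reads))
        adapter_idx = set(
            rng.choice(spec.n_reads, size=k, replace=False).tolist()
        )

    # planted duplicate blocks occupy the first reads of the file
    dup_blocks: List[Tuple[str, int]] = []
    for seq, mult in spec.duplicates:
        if seq is None:
            codes = rng.choice(4, size=lo, p=probs)
            seq = bytes(_BASES[codes]).decode()
        dup_blocks.append((seq.upper(), mult))
    n_dup_reads = sum(m for _, m in dup_blocks)
    if n_dup_reads > spec.n_reads:
        raise ValueError("duplicate blocks exceed n_reads")

    tiles = spec.tiles or []
    tile_offsets = spec.tile_offsets or {}
    n_per_position: Counter = Counter()
    adapter_count = 0
    tile_of_read: List[Optional[int]] = []

    def make_bases(i: int) -> str:
        length = lo if lo == hi else int(rng.integers(lo, hi + 1))
        codes = rng.choice(4, size=length, p=probs)
        bases = _BASES[codes].copy()
        if i in adapter_idx:
            aseq, astart, _ = spec.adapter
            ins = np.frombuffer(aseq.encode(), dtype=np.uint8)
            end = min(astart - 1 + len(ins), length)
            bases[astart - 1:end] = ins[: end - (astart - 1)]
        if spec.n_rate > 0:
            mask = rng.random(length) < spec.n_rate
            bases[mask] = ord("N")
            for p in np.nonzero(mask)[0]:
                n_per_position[int(p) + 1] += 1
        return bytes(bases).decode()

    def make_qual(i: int, length: int, tile: Optional[int]) -> str:
        q = _quality_profile(spec, length).copy()
        if tile is not None and tile in tile_offsets:
            q += tile_offsets[tile]
        if spec.quality_jitter > 0:
            q += rng.normal(0.0, spec.quality_jitter, size=length)
        q = np.clip(np.rint(q), 0, 40).astype(np.int64)
        return bytes((q + 33).astype(np.uint8)).decode()

    records: List[str] = []
    dup_iter = [seq for seq, mult in dup_blocks for _ in range(mult)]
    for i in range(spec.n_reads):
        tile = tiles[i % len(tiles)] if tiles else None
        tile_of_read.append(tile)
        if i < len(dup_iter):
            bases = dup_iter[i]
        else:
            bases = make_bases(i)
        if i in adapter_idx and i < len(dup_iter):
            adapter_idx.discard(i)  # planted duplicates stay verbatim
        if i in adapter_idx:
            adapter_count += 1
        if tile is not None:
            name = f"SIM:1:FCX:1:{tile}:{i + 1}:1"
        else:
            name = f"read_{i + 1}"
        qual = make_qual(i, len(bases), tile)
        records.append(f"@{name}\n{bases}\n+\n{qual}\n")

    payload = "".join(records).encode("ascii")
    if gzipped:
        # fixed mtime and empty stored filename keep gzip output byte-identical
        with open(path, "wb") as raw:
            with gzip.GzipFile(filename="", fileobj=raw, mode="wb",
                               mtime=0) as gz:
                gz.write(payload)
    else:
        with open(path, "wb") as fh:
            fh.write(payload)

    manifest = {
        "spec": {k: v for k, v in asdict(spec).items()},
        "n_reads": spec.n_reads,
        "length_min": lo,
        "length_max": hi,
        "adapter_read_count": adapter_count,
        "duplicate_blocks": [[seq, mult] for seq, mult in dup_blocks],
        "n_per_position": dict(sorted(n_per_position.items())),
        "tiles_used": sorted({t for t in tile_of_read if t is not None}),
    }
    with open(path + ".manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=list)
    return manifest


# --------------------------------------------------------------------------
# naive two-pass oracle
# --------------------------------------------------------------------------

def two_pass_oracle(path: str, adapters: Optional[AdapterSet] = None,
                    tracker_capacity: int = DEFAULT_TRACKER_CAPACITY) -> dict:
    """Recompute every accumulator statistic by definition, loading all reads.

    Returns plain dicts/lists (no numpy) so tests can compare it field-wise
    with the streaming accumulator.  Implemented independently of the
    streaming code path: per-read loops over characters, no shortcuts.
    """
    records = list(open_reads(path))
    adapters = adapters if adapters is not None else AdapterSet([])
    max_len = max((len(r.bases) for r in records), default=0)

    base_counts = [[0] * 5 for _ in range(max_len)]
    qual_counts = [[0] * 94 for _ in range(max_len)]
    seq_qual_hist = [0] * 94
    gc_hist = [0] * 101
    length_hist: Counter = Counter()
    min_qual_code = None
    tile_sum: Dict[int, List[float]] = {}
    tile_cnt: Dict[int, List[int]] = {}
    dup_counts: Dict[str, int] = {}
    dup_count_at_limit = 0
    adapter_cum = {name: [0] * max_len for name, _ in adapters}

    for ridx, rec in enumerate(records, start=1):
        L = len(rec.bases)
        length_hist[L] += 1
        if L == 0:
            continue
        gc = 0
        for p, ch in enumerate(rec.bases):
            col = {"A": 0, "C": 1, "G": 2, "T": 3}.get(ch, 4)
            base_counts[p][col] += 1
            if ch in "GC":
                gc += 1
        gc_hist[int(100.0 * gc / L + 0.5)] += 1
        qsum = 0
        for p, ch in enumerate(rec.quality):
            code = ord(ch)
            if min_qual_code is None or code < min_qual_code:
                min_qual_code = code
            qual_counts[p][code - 33] += 1
            qsum += code - 33
        seq_qual_hist[int(qsum / L)] += 1

        parts = rec.name.split(":")
        tile = None
        if len(parts) >= 7:
            cand = parts[4]
        elif len(parts) >= 5:
            cand = parts[2]
        else:
            cand = None
        if cand is not None:
            try:
                tile = int(cand)
            except ValueError:
                tile = None
        if tile is not None:
            if tile not in tile_sum:
                tile_sum[tile] = [0.0] * max_len
                tile_cnt[tile] = [0] * max_len
            for p, ch in enumerate(rec.quality):
                tile_sum[tile][p] += ord(ch) - 33
                tile_cnt[tile][p] += 1

        key = rec.bases[:50] if L > 75 else rec.bases
        if key in dup_counts:
            dup_counts[key] += 1
        elif len(dup_counts) < tracker_capacity:
            dup_counts[key] = 1
            dup_count_at_limit = ridx

        for name, aseq in adapters:
            hit = None
            for start in range(L):
                k = min(len(aseq), L - start)
                if k < min(len(aseq), MIN_ADAPTER_MATCH):
                    break
                if k < len(aseq) and start + k != L:
                    continue
                if rec.bases[start:start + k] == aseq[:k]:
                    hit = start
                    break
            if hit is not None:
                for p in range(hit, L):
                    adapter_cum[name][p] += 1

    return {
        "total_reads": len(records),
        "max_len": max_len,
        "min_len": min((len(r.bases) for r in records), default=None),
        "base_counts": base_counts,
        "qual_counts": qual_counts,
        "seq_qual_hist": seq_qual_hist,
        "gc_hist": gc_hist,
        "length_hist": dict(length_hist),
        "min_qual_code": min_qual_code,
        "tile_sum": tile_sum,
        "tile_cnt": tile_cnt,
        "dup_counts": dup_counts,
        "dup_count_at_limit": dup_count_at_limit,
        "adapter_cumulative": adapter_cum,
    }


# --------------------------------------------------------------------------
# report diffing
# --------------------------------------------------------------------------

def compare_reports(path_a: str, path_b: str, tol: float = 1e-2) -> List[str]:
    """Diff two data files in the report dialect.

    Reports grade mismatches, missing modules and numeric cells differing
    beyond the relative tolerance.  Empty list means equivalent.
    """
    with open(path_a) as fh:
        blocks_a = {b["name"]: b for b in parse_data_txt(fh.read())}
    with open(path_b) as fh:
        blocks_b = {b["name"]: b for b in parse_data_txt(fh.read())}
    diffs: List[str] = []
    for name in blocks_a.keys() | blocks_b.keys():
        if name not in blocks_a or name not in blocks_b:
            missing_in = "first" if name not in blocks_a else "second"
            diffs.append(f"{name}: missing in {missing_in} report")
            continue
        a, b = blocks_a[name], blocks_b[name]
        if a["grade"] != b["grade"]:
            diffs.append(f"{name}: grade {a['grade']} != {b['grade']}")
        if len(a["rows"]) != len(b["rows"]):
            diffs.append(
                f"{name}: row count {len(a['rows'])} != {len(b['rows'])}"
            )
            continue
        for i, (ra, rb) in enumerate(zip(a["rows"], b["rows"])):
            if len(ra) != len(rb):
                diffs.append(f"{name} row {i}: arity differs")
                continue
            for j, (va, vb) in enumerate(zip(ra, rb)):
                if isinstance(va, (int, float)) and isinstance(vb, (int, float)):
                    scale = max(abs(va), abs(vb), 1e-12)
                    if abs(va - vb) / scale > tol and abs(va - vb) > 1e-9:
                        diffs.append(
                            f"{name} row {i} col {j}: {va} vs {vb}"
                        )
                elif va != vb:
                    diffs.append(f"{name} row {i} col {j}: {va!r} != {vb!r}")
    return sorted(diffs)
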
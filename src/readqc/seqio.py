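"""Streaming read input: FASTQ (plain/gzip), SAM and BAM.

Reads are delivered strictly in file order, one record buffered at a time,
so memory use is bounded by the longest single read rather than file size.
FASTQ parsing is strict four-line parsing with precise error locations;
SAM/BAM go through pysam.
"""

from __future__ import annotations

import gzip
import io
import os
from dataclasses import dataclass
from typing import Iterator, Optional

__all__ = [
    "FastqRecord",
    "PhredEncoding",
    "ReadStream",
    "SeqIOError",
    "open_reads",
    "detect_encoding",
    "write_fastq",
]


class SeqIOError(ValueError):
    """Fatal input problem (missing file, malformed record, bad format)."""


@dataclass(slots=True)
class FastqRecord:
    """One sequencing read: header name (without '@'), bases, quality string.

    Bases are uppercased on input; characters outside {A,C,G,T} are treated
    as N by downstream counting.  Zero-length reads are permitted (they drive
    a fail grade in the length-distribution module).
    """

    name: str
    bases: str
    quality: str


@dataclass(frozen=True, slots=True)
class PhredEncoding:
    label: str
    offset: int  # 33 or 64


SANGER = PhredEncoding("Sanger / Illumina 1.9", 33)
ILLUMINA_LEGACY = PhredEncoding("Illumina 1.5", 64)


def detect_encoding(min_quality_char_code: int) -> PhredEncoding:
    """Resolve the Phred offset from the lowest quality character in a file.

    Codes 33-63 imply the modern offset-33 encoding; codes >= 64 imply a
    legacy offset-64 encoding.  Codes below 33 are not printable Phred
    characters and are fatal.
    """
    if min_quality_char_code < 33:
        raise SeqIOError(
            f"invalid quality character (ASCII {min_quality_char_code} < 33)"
        )
    if min_quality_char_code <= 63:
        return SANGER
    return ILLUMINA_LEGACY


_FASTQ_EXTS = (".fastq", ".fq", ".txt")


def _sniff_gzip(path: str) -> bool:
    with open(path, "rb") as fh:
        return fh.read(2) == b"\x1f\x8b"


def _resolve_format(path: str, format_override: Optional[str]) -> str:
    if format_override:
        fmt = format_override.lower()
        if fmt not in {"fastq", "fastq.gz", "sam", "bam"}:
            raise SeqIOError(f"unrecognized format {format_override!r}")
        if fmt == "fastq" and _sniff_gzip(path):
            return "fastq.gz"
        return fmt
    lower = path.lower()
    if lower.endswith(".sam"):
        return "sam"
    if lower.endswith(".bam"):
        return "bam"
    if lower.endswith(".gz") or _sniff_gzip(path):
        return "fastq.gz"
    return "fastq"


class ReadStream:
    """Iterator of FastqRecord from a FASTQ/SAM/BAM file, in file order."""

    def __init__(self, path: str, format: str):
        self.path = path
        self.format = format
        if format in ("fastq", "fastq.gz"):
            raw = gzip.open(path, "rb") if format == "fastq.gz" else open(path, "rb")
            self._fh = io.TextIOWrapper(io.BufferedReader(raw), encoding="ascii",
                                        errors="strict")
            self._lineno = 0
            self._iter = self._iter_fastq()
        elif format == "sam":
            self._iter = self._iter_sam_text()
        else:
            self._iter = self._iter_bam()

    # -- FASTQ ------------------------------------------------------------
    def _readline(self) -> str:
        line = self._fh.readline()
        if line:
            self._lineno += 1
        return line

    def _iter_fastq(self) -> Iterator[FastqRecord]:
        while True:
            header = self._readline()
            if header == "":
                return
            header = header.rstrip("\n").rstrip("\r")
            if not header:
                # trailing blank line(s) at EOF are tolerated
                rest = self._fh.read(1)
                if rest == "":
                    return
                raise SeqIOError(f"{self.path}:{self._lineno}: blank line inside FASTQ")
            if not header.startswith("@"):
                raise SeqIOError(
                    f"{self.path}:{self._lineno}: expected '@' header, got {header[:20]!r}"
                )
            bases = self._readline()
            plus = self._readline()
            qual = self._readline()
            if qual == "" and plus == "":
                raise SeqIOError(
                    f"{self.path}:{self._lineno}: truncated final FASTQ record"
                )
            bases = bases.rstrip("\n").rstrip("\r")
            plus = plus.rstrip("\n").rstrip("\r")
            qual = qual.rstrip("\n").rstrip("\r") if qual else ""
            if not plus.startswith("+"):
                raise SeqIOError(
                    f"{self.path}:{self._lineno - 1}: expected '+' separator "
                    "(multi-line records are not supported)"
                )
            if len(bases) != len(qual):
                raise SeqIOError(
                    f"{self.path}:{self._lineno}: sequence and quality lengths "
                    f"differ ({len(bases)} vs {len(qual)})"
                )
            yield FastqRecord(header[1:], bases.upper(), qual)

    # -- SAM --------------------------------------------------------------
    def _iter_sam_text(self) -> Iterator[FastqRecord]:
        # Parsed directly: headerless unaligned SAM is legal input for QC,
        # and reads are taken as stored (no reverse-complementing by flag).
        with open(self.path, encoding="ascii") as fh:
            for lineno, line in enumerate(fh, start=1):
                if line.startswith("@"):
                    continue
                line = line.rstrip("\n").rstrip("\r")
                if not line:
                    continue
                fields = line.split("\t")
                if len(fields) < 11:
                    raise SeqIOError(
                        f"{self.path}:{lineno}: SAM record has "
                        f"{len(fields)} fields, expected >= 11"
                    )
                name, seq, qual = fields[0], fields[9], fields[10]
                if seq == "*":
                    continue
                if qual == "*":
                    raise SeqIOError(
                        f"{self.path}:{lineno}: read {name!r} has bases but "
                        "no quality string"
                    )
                if len(seq) != len(qual):
                    raise SeqIOError(
                        f"{self.path}:{lineno}: sequence and quality lengths "
                        f"differ ({len(seq)} vs {len(qual)})"
                    )
                yield FastqRecord(name, seq.upper(), qual)

    # -- BAM --------------------------------------------------------------
    def _iter_bam(self) -> Iterator[FastqRecord]:
        try:
            import pysam
        except ImportError as exc:
            raise SeqIOError(
                "BAM input requires the 'pysam' package; install it with "
                "'pip install pysam', or convert to SAM/FASTQ first"
            ) from exc
        try:
            afile = pysam.AlignmentFile(self.path, "rb", check_sq=False)
        except (ValueError, OSError) as exc:
            raise SeqIOError(f"cannot open {self.path} as BAM: {exc}")

        def gen() -> Iterator[FastqRecord]:
            with afile:
                for aln in afile:
                    seq = aln.query_sequence
                    if seq is None:  # SEQ field '*'
                        continue
                    quals = aln.query_qualities
                    if quals is None:
                        raise SeqIOError(
                            f"{self.path}: read {aln.query_name!r} has bases "
                            "but no quality string"
                        )
                    qual = pysam.qualities_to_qualitystring(quals)
                    yield FastqRecord(aln.query_name, seq.upper(), qual)

        return gen()

    def __iter__(self) -> Iterator[FastqRecord]:
        return self._iter

    def __next__(self) -> FastqRecord:
        return next(self._iter)


def open_reads(path: str, format_override: Optional[str] = None) -> ReadStream:
    """Open a reads file, resolving format from override, extension and magic.

    ``.gz`` extensions and the gzip magic bytes ``1f 8b`` both select
    gzip-compressed FASTQ; ``.sam``/``.bam`` select pysam-backed parsing;
    anything else is plain FASTQ.
    """
    if not os.path.exists(path):
        raise SeqIOError(f"input file not found: {path}")
    if not os.path.isfile(path):
        raise SeqIOError(f"not a regular file: {path}")
    fmt = _resolve_format(path, format_override)
    return ReadStream(path, fmt)


def next_record(stream: ReadStream) -> Optional[FastqRecord]:
    """Return the next record or None at end of input."""
    return next(iter(stream), None)


def write_fastq(records, handle) -> None:
    """Write records as strict 4-line FASTQ (LF line endings)."""
    for rec in records:
        handle.write(f"@{rec.name}\n{rec.bases}\n+\n{rec.quality}\n")
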
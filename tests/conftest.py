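import numpy as np
import pytest

from readqc.collector import StreamStats
from readqc.config import AdapterSet
from readqc.seqio import FastqRecord


def records_from(pairs):
    """Build FastqRecords from (bases, quality[, name]) tuples."""
    recs = []
    for i, item in enumerate(pairs):
        if len(item) == 3:
            bases, qual, name = item
        else:
            bases, qual = item
            name = f"read_{i + 1}"
        recs.append(FastqRecord(name, bases.upper(), qual))
    return recs


def stats_from(pairs, adapters=None, **kwargs):
    """Run the streaming accumulator over in-memory reads."""
    stats = StreamStats(adapters if adapters is not None else AdapterSet([]),
                        **kwargs)
    for rec in records_from(pairs):
        stats.update(rec)
    return stats


@pytest.fixture
def make_fastq(tmp_path):
    """Write literal FASTQ text to a temp file and return its path."""

    def _make(text, name="reads.fq"):
        path = tmp_path / name
        path.write_text(text)
        return str(path)

    return _make


def qstr(values):
    """Quality string from Phred values (offset 33)."""
    return "".join(chr(v + 33) for v in np.atleast_1d(values))
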
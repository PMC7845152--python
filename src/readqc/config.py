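"""Configuration parsing in FastQC's plain-text dialects.

Three files control the analysis: ``limits.txt`` (per-module warn/error
thresholds and ignore switches), ``adapter_list.txt`` and
``contaminant_list.txt``.  Packaged defaults matching the reference tool's
Configuration directory are used when no user file is supplied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, List, Optional, Tuple

log = logging.getLogger("readqc.config")

__all__ = [
    "ConfigError",
    "Limits",
    "SequenceSet",
    "AdapterSet",
    "ContaminantSet",
    "load_limits",
    "load_adapters",
    "load_contaminants",
]


class ConfigError(ValueError):
    """Malformed configuration file."""


#: module keys recognized in limits files (unknown keys warn, not fail)
KNOWN_LIMIT_KEYS = {
    "duplication",
    "kmer",
    "n_content",
    "overrepresented",
    "quality_base",
    "quality_base_lower",
    "quality_base_median",
    "sequence",
    "gc_sequence",
    "quality_sequence",
    "tile",
    "sequence_length",
    "adapter",
}

_FIELDS = {"warn", "error", "ignore"}


@dataclass
class Limits:
    """Map of (module-key, field) -> numeric threshold.

    ``field`` is one of ``warn``, ``error``, ``ignore``; ignore values are
    interpreted as booleans (module disabled when 1).
    """

    values: Dict[Tuple[str, str], float] = field(default_factory=dict)

    def get(self, key: str, fld: str, default: float = 0.0) -> float:
        return self.values.get((key, fld), default)

    def warn(self, key: str) -> float:
        return self.get(key, "warn")

    def error(self, key: str) -> float:
        return self.get(key, "error")

    def ignored(self, key: str) -> bool:
        return self.get(key, "ignore", 0.0) == 1


@dataclass
class SequenceSet:
    """Ordered list of named sequences (adapters or contaminants)."""

    entries: List[Tuple[str, str]] = field(default_factory=list)

    def __iter__(self):
        return iter(self.entries)

    def __len__(self):
        return len(self.entries)

    @property
    def names(self) -> List[str]:
        return [name for name, _ in self.entries]


# The two set types share a format; distinct classes keep signatures honest.
class AdapterSet(SequenceSet):
    pass


class ContaminantSet(SequenceSet):
    pass


def _default_text(filename: str) -> str:
    return (
        resources.files("readqc").joinpath("configuration", filename).read_text()
    )


def _iter_content_lines(text: str):
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip("\r\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        yield lineno, line


def load_limits(path: Optional[str] = None) -> Limits:
    """Parse a limits file (whitespace-separated ``key field value`` triples).

    With no path, the packaged defaults are returned.  Unknown module keys
    are kept but logged; malformed lines are fatal with their line number.
    """
    if path is None:
        text, origin = _default_text("limits.txt"), "<packaged limits>"
    else:
        with open(path) as fh:
            text, origin = fh.read(), path
    limits = Limits()
    for lineno, line in _iter_content_lines(text):
        tokens = line.split()
        if len(tokens) != 3:
            raise ConfigError(
                f"{origin}:{lineno}: expected 'key field value', got {line!r}"
            )
        key, fld, value = tokens
        if fld not in _FIELDS:
            raise ConfigError(
                f"{origin}:{lineno}: field must be warn/error/ignore, got {fld!r}"
            )
        try:
            num = float(value)
        except ValueError:
            raise ConfigError(f"{origin}:{lineno}: non-numeric value {value!r}")
        if key not in KNOWN_LIMIT_KEYS:
            log.warning("%s:%d: unknown limits key %r (kept)", origin, lineno, key)
        limits.values[(key, fld)] = num
    return limits


def _load_sequences(path: Optional[str], default_file: str, cls):
    if path is None:
        text, origin = _default_text(default_file), f"<packaged {default_file}>"
    else:
        with open(path) as fh:
            text, origin = fh.read(), path
    entries: List[Tuple[str, str]] = []
    for lineno, line in _iter_content_lines(text):
        if "\t" in line:
            name, _, seq = line.rpartition("\t")
            name = name.strip("\t").strip()
        else:  # tolerate runs of spaces as the separator
            parts = line.rsplit(None, 1)
            if len(parts) != 2:
                raise ConfigError(f"{origin}:{lineno}: expected 'name<TAB>sequence'")
            name, seq = parts
        seq = seq.strip().upper()
        if not name or not seq:
            raise ConfigError(f"{origin}:{lineno}: expected 'name<TAB>sequence'")
        if set(seq) - set("ACGT"):
            bad = sorted(set(seq) - set("ACGT"))
            raise ConfigError(
                f"{origin}:{lineno}: sequence contains non-ACGT characters {bad}"
            )
        entries.append((name, seq))
    return cls(entries)


def load_adapters(path: Optional[str] = None) -> AdapterSet:
    """Parse an adapter list (``name<TAB>sequence``); packaged defaults if None."""
    adapters = _load_sequences(path, "adapter_list.txt", AdapterSet)
    seen = set()
    for name, _ in adapters:
        if name in seen:
            raise ConfigError(f"duplicate adapter name {name!r}")
        seen.add(name)
    return adapters


def load_contaminants(path: Optional[str] = None) -> ContaminantSet:
    """Parse a contaminant list (``name<TAB>sequence``); packaged defaults if None."""
    return _load_sequences(path, "contaminant_list.txt", ContaminantSet)
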
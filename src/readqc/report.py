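"""Report emission: fastqc_data.txt, summary.txt and an interactive HTML page.

The text outputs use the fastqc_data dialect (``##FastQC`` magic line,
``>>Title<TAB>grade`` blocks terminated by ``>>END_MODULE``) so existing
downstream consumers (MultiQC-style aggregators, fastqcr-style parsers)
ingest them unchanged.  Output is deterministic: no timestamps, LF endings.
"""

from __future__ import annotations

import json
import numbers
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np

from .qc_modules import ModuleResult

__all__ = [
    "QCReport",
    "write_data_txt",
    "write_summary_txt",
    "write_html",
    "write_all",
    "parse_data_txt",
]

#: dialect marker: downstream parsers dispatch on this first line
DIALECT_NAME = "FastQC"
DIALECT_VERSION = "0.11.8"

PLOTLY_CDN = "https://cdn.plot.ly/plotly-2.27.0.min.js"


@dataclass
class QCReport:
    """Ordered module results plus file metadata; input to all three writers."""

    filename: str
    modules: List[ModuleResult]
    extra: Dict[str, object] = field(default_factory=dict)


def format_number(value) -> str:
    """Up to 10 significant digits, trailing zeros trimmed."""
    if isinstance(value, (bool,)):
        return str(int(value))
    if isinstance(value, numbers.Integral):
        return str(int(value))
    if isinstance(value, numbers.Real):
        v = float(value)
        if v != v or v in (float("inf"), float("-inf")):
            return str(v)
        if v == int(v) and abs(v) < 1e15:
            return f"{v:.1f}"  # keep one decimal so floats read as floats
        return f"{v:.10g}"
    return str(value)


def write_data_txt(report: QCReport) -> str:
    lines = [f"##{DIALECT_NAME}\t{DIALECT_VERSION}"]
    for mod in report.modules:
        lines.append(f">>{mod.name}\t{mod.grade}")
        if "Total Deduplicated Percentage" in mod.extra:
            lines.append(
                "#Total Deduplicated Percentage\t"
                + format_number(mod.extra["Total Deduplicated Percentage"])
            )
        if mod.header:
            lines.append("#" + "\t".join(mod.header))
        for row in mod.rows:
            lines.append("\t".join(format_number(v) for v in row))
        lines.append(">>END_MODULE")
    return "\n".join(lines) + "\n"


def write_summary_txt(report: QCReport) -> str:
    base = os.path.basename(report.filename)
    return "".join(
        f"{mod.grade.upper()}\t{mod.name}\t{base}\n" for mod in report.modules
    )


def parse_data_txt(text: str) -> List[dict]:
    """Parse a fastqc_data dialect file back into module blocks.

    Returns a list of dicts with keys name, grade, header, rows, extras.
    Raises ValueError on structural problems (missing magic line, unterminated
    module).  Numeric cells are converted to int/float where possible.
    """
    lines = text.splitlines()
    if not lines or not lines[0].startswith("##"):
        raise ValueError("missing '##' dialect marker on first line")
    blocks: List[dict] = []
    i = 1
    while i < len(lines):
        line = lines[i]
        if not line.strip():
            i += 1
            continue
        if not line.startswith(">>"):
            raise ValueError(f"line {i + 1}: expected '>>' module start")
        head = line[2:].split("\t")
        if len(head) != 2:
            raise ValueError(f"line {i + 1}: expected '>>Title<TAB>grade'")
        name, grade = head
        block = {"name": name, "grade": grade, "header": None,
                 "rows": [], "extras": {}}
        i += 1
        terminated = False
        while i < len(lines):
            line = lines[i]
            if line == ">>END_MODULE":
                terminated = True
                i += 1
                break
            if line.startswith("#"):
                body = line[1:]
                if "\t" in body and body.split("\t")[0] in (
                    "Total Deduplicated Percentage",
                ):
                    key, val = body.split("\t", 1)
                    block["extras"][key] = _coerce(val)
                else:
                    block["header"] = body.split("\t")
            else:
                block["rows"].append(tuple(_coerce(v) for v in line.split("\t")))
            i += 1
        if not terminated:
            raise ValueError(f"module {name!r} not terminated by >>END_MODULE")
        blocks.append(block)
    return blocks


def _coerce(token: str):
    try:
        return int(token)
    except ValueError:
        pass
    try:
        return float(token)
    except ValueError:
        return token


# --------------------------------------------------------------------------
# HTML
# --------------------------------------------------------------------------

_GRADE_COLOR = {"pass": "#2e7d32", "warn": "#f9a825", "fail": "#c62828"}


def _get(report: QCReport, name: str) -> Optional[ModuleResult]:
    for mod in report.modules:
        if mod.name == name:
            return mod
    return None


def _plot(div_id: str, traces: list, layout: dict) -> str:
    payload = json.dumps({"data": traces, "layout": layout})
    return (
        f'<div id="{div_id}" class="plot"></div>\n'
        f"<script>(function(s){{Plotly.newPlot('{div_id}', s.data, s.layout, "
        f"{{responsive:true}});}})({payload});</script>"
    )


def _module_plots(report: QCReport) -> Dict[str, str]:
    plots: Dict[str, str] = {}

    mod = _get(report, "Per base sequence quality")
    if mod and mod.rows:
        x = [r[0] for r in mod.rows]
        names = ["Mean", "Median", "Lower Quartile", "Upper Quartile",
                 "10th Percentile", "90th Percentile"]
        traces = [{"x": x, "y": [r[i + 1] for r in mod.rows],
                   "name": n, "mode": "lines"} for i, n in enumerate(names)]
        plots[mod.name] = _plot("plot-pbq", traces,
                                {"title": mod.name,
                                 "yaxis": {"title": "Phred score"},
                                 "xaxis": {"title": "Position in read (bp)"}})

    mod = _get(report, "Per tile sequence quality")
    if mod and mod.rows:
        tiles = sorted({r[0] for r in mod.rows})
        bases = []
        for r in mod.rows:
            if r[1] not in bases:
                bases.append(r[1])
        lookup = {(r[0], r[1]): r[2] for r in mod.rows}
        z = [[lookup.get((t, b)) for b in bases] for t in tiles]
        plots[mod.name] = _plot(
            "plot-tile",
            [{"type": "heatmap", "z": z, "x": bases,
              "y": [str(t) for t in tiles], "colorscale": "RdBu"}],
            {"title": mod.name, "xaxis": {"title": "Position in read (bp)"},
             "yaxis": {"title": "Tile", "type": "category"}})

    mod = _get(report, "Per sequence quality scores")
    if mod and mod.rows:
        plots[mod.name] = _plot(
            "plot-psq",
            [{"x": [r[0] for r in mod.rows], "y": [r[1] for r in mod.rows],
              "mode": "lines", "name": "Count"}],
            {"title": mod.name, "xaxis": {"title": "Mean Phred score"},
             "yaxis": {"title": "Reads"}})

    mod = _get(report, "Per base sequence content")
    if mod and mod.rows:
        x = [r[0] for r in mod.rows]
        traces = [{"x": x, "y": [r[i + 1] for r in mod.rows],
                   "mode": "lines", "name": base}
                  for i, base in enumerate("GATC")]
        plots[mod.name] = _plot("plot-pbc", traces,
                                {"title": mod.name,
                                 "yaxis": {"title": "%", "range": [0, 100]},
                                 "xaxis": {"title": "Position in read (bp)"}})

    mod = _get(report, "Per sequence GC content")
    if mod and mod.rows:
        traces = [{"x": [r[0] for r in mod.rows],
                   "y": [r[1] for r in mod.rows],
                   "mode": "lines", "name": "GC count per read"}]
        theo = mod.extra.get("theoretical")
        if theo is not None:
            theo_list = list(np.asarray(theo, dtype=float))
            traces.append({"x": list(range(101)), "y": theo_list,
                           "mode": "lines", "name": "Theoretical distribution"})
        plots[mod.name] = _plot("plot-gc", traces,
                                {"title": mod.name,
                                 "xaxis": {"title": "Mean GC content (%)"},
                                 "yaxis": {"title": "Reads"}})

    mod = _get(report, "Per base N content")
    if mod and mod.rows:
        plots[mod.name] = _plot(
            "plot-n",
            [{"x": [r[0] for r in mod.rows], "y": [r[1] for r in mod.rows],
              "mode": "lines", "name": "%N"}],
            {"title": mod.name, "yaxis": {"title": "%N", "range": [0, 100]},
             "xaxis": {"title": "Position in read (bp)"}})

    mod = _get(report, "Sequence Length Distribution")
    if mod and mod.rows:
        plots[mod.name] = _plot(
            "plot-len",
            [{"x": [r[0] for r in mod.rows], "y": [r[1] for r in mod.rows],
              "mode": "lines", "name": "Reads"}],
            {"title": mod.name, "xaxis": {"title": "Sequence length (bp)"},
             "yaxis": {"title": "Reads"}})

    mod = _get(report, "Sequence Duplication Levels")
    if mod and mod.rows:
        x = [r[0] for r in mod.rows]
        plots[mod.name] = _plot(
            "plot-dup",
            [{"type": "bar", "x": x, "y": [r[1] for r in mod.rows],
              "name": "% Deduplicated"},
             {"type": "bar", "x": x, "y": [r[2] for r in mod.rows],
              "name": "% Total"}],
            {"title": mod.name, "xaxis": {"title": "Duplication level",
                                          "type": "category"},
             "yaxis": {"title": "%", "range": [0, 100]}})

    mod = _get(report, "Adapter Content")
    if mod and mod.rows and mod.header:
        x = [r[0] for r in mod.rows]
        traces = [{"x": x, "y": [r[i + 1] for r in mod.rows],
                   "mode": "lines", "name": name}
                  for i, name in enumerate(mod.header[1:])]
        plots[mod.name] = _plot("plot-adapter", traces,
                                {"title": mod.name,
                                 "yaxis": {"title": "% of reads",
                                           "range": [0, 100]},
                                 "xaxis": {"title": "Position in read (bp)"}})
    return plots


def _table_html(mod: ModuleResult, max_rows: int = 25) -> str:
    if not mod.rows:
        return "<p class='empty'>No entries.</p>"
    head = ""
    if mod.header:
        head = ("<tr>" + "".join(f"<th>{h}</th>" for h in mod.header) + "</tr>")
    body_rows = mod.rows[:max_rows]
    body = "".join(
        "<tr>" + "".join(f"<td>{format_number(v)}</td>" for v in row) + "</tr>"
        for row in body_rows
    )
    note = ""
    if len(mod.rows) > max_rows:
        note = (f"<p class='empty'>showing {max_rows} of {len(mod.rows)} rows; "
                "see fastqc_data.txt for the full table</p>")
    return f"<table>{head}{body}</table>{note}"


def write_html(report: QCReport) -> str:
    """Self-contained report page; the plot library is loaded from a CDN URL."""
    plots = _module_plots(report)
    sections = []
    toc = []
    for i, mod in enumerate(report.modules):
        color = _GRADE_COLOR.get(mod.grade, "#555")
        anchor = f"M{i}"
        toc.append(
            f'<li><a href="#{anchor}"><span class="badge" '
            f'style="background:{color}">{mod.grade.upper()}</span> '
            f"{mod.name}</a></li>"
        )
        body = plots.get(mod.name, "")
        if mod.name in ("Basic Statistics", "Overrepresented sequences",
                        "Kmer Content") or not body:
            body += _table_html(mod)
        sections.append(
            f'<section id="{anchor}"><h2><span class="badge" '
            f'style="background:{color}">{mod.grade.upper()}</span> '
            f"{mod.name}</h2>{body}</section>"
        )
    base = os.path.basename(report.filename)
    return f"""<!DOCTYPE html>
<html lang="en">
<head>
<meta charset="utf-8">
<title>readqc report: {base}</title>
<script src="{PLOTLY_CDN}"></script>
<style>
body {{ font-family: sans-serif; margin: 0 auto; max-width: 960px; padding: 1em; }}
.badge {{ color: #fff; border-radius: 3px; padding: 2px 6px; font-size: 0.8em; }}
table {{ border-collapse: collapse; margin: 0.5em 0; }}
td, th {{ border: 1px solid #ccc; padding: 2px 8px; text-align: left; }}
.plot {{ min-height: 380px; }}
.empty {{ color: #777; font-style: italic; }}
nav ul {{ list-style: none; padding-left: 0; }}
</style>
</head>
<body>
<h1>readqc report &mdash; {base}</h1>
<nav><ul>
{os.linesep.join(toc)}
</ul></nav>
{os.linesep.join(sections)}
</body>
</html>
"""


def write_all(report: QCReport, outdir: str) -> Dict[str, str]:
    """Write the three output files into outdir; returns name -> path."""
    os.makedirs(outdir, exist_ok=True)
    paths = {}
    for fname, text in (
        ("fastqc_data.txt", write_data_txt(report)),
        ("summary.txt", write_summary_txt(report)),
        ("fastqc_report.html", write_html(report)),
    ):
        path = os.path.join(outdir, fname)
        with open(path, "w", newline="\n") as fh:
            fh.write(text)
        paths[fname] = path
    return paths
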
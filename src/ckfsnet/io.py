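"""Readers and writers for time-series, network, and edge-list files.

Formats are deliberately plain text:

* time series — tab-separated, header row of gene names, one row per time
  point.  The DREAM4-style dialect adds a leading ``Time`` column and holds
  several perturbation series in one file, delimited either by blank lines
  or by the time value resetting (decreasing) between consecutive rows.
* networks — tab-separated weight matrix with a header of gene names and a
  leading row-label column (rows = target genes).
* edge lists — ``source<TAB>target<TAB>{0|1}`` gold-standard lines, and
  ranked predictions ``source<TAB>target<TAB>score<TAB>sign``.
* run configuration — a YAML mapping onto :class:`RunConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .exceptions import FormatError
from .model import GeneNetwork, TimeSeriesData

__all__ = [
    "read_timeseries",
    "write_timeseries",
    "read_edge_list",
    "write_edge_list",
    "write_ranked_edges",
    "read_ranked_edges",
    "read_network",
    "write_network",
    "RunConfig",
    "load_config",
]


def _lines(path):
    path = Path(path)
    if not path.exists():
        raise FormatError("file not found", path=path)
    return path.read_text().splitlines()


def _parse_floats(cells, path, lineno):
    try:
        return [float(c) for c in cells]
    except ValueError:
        raise FormatError("non-numeric cell", path=path, line=lineno) from None


def read_timeseries(path, dialect: str = "generic") -> TimeSeriesData:
    """Parse a tab-separated time-series file.

    ``dialect="generic"``: header of gene names, one matrix, one series.
    ``dialect="dream4"``: leading time column; blank lines or a time reset
    start a new perturbation series.
    """
    if dialect not in ("generic", "dream4"):
        raise ValueError(f"unknown dialect {dialect!r}")
    lines = _lines(path)
    rows = [(i + 1, ln) for i, ln in enumerate(lines)]
    # locate header: first non-blank line
    while rows and not rows[0][1].strip():
        rows.pop(0)
    if not rows:
        raise FormatError("empty file", path=path)
    header_no, header = rows.pop(0)
    names = header.rstrip("\n").split("\t")
    if dialect == "dream4":
        if not names or names[0].strip().lower() not in ("time", "t", '"time"'):
            raise FormatError("dream4 dialect expects a leading Time column",
                              path=path, line=header_no)
        names = names[1:]
    names = [c.strip().strip('"') for c in names]
    if not names or any(not c for c in names):
        raise FormatError("bad header", path=path, line=header_no)
    n = len(names)
    width = n + (1 if dialect == "dream4" else 0)

    series: list[np.ndarray] = []
    block: list[list[float]] = []
    last_time = None

    def flush():
        nonlocal block, last_time
        if block:
            series.append(np.asarray(block))
        block, last_time = [], None

    for lineno, ln in rows:
        if not ln.strip():
            flush()
            continue
        cells = ln.split("\t")
        if len(cells) != width:
            raise FormatError(
                f"expected {width} columns, found {len(cells)}", path=path, line=lineno
            )
        values = _parse_floats(cells, path, lineno)
        if dialect == "dream4":
            t, values = values[0], values[1:]
            if last_time is not None and t < last_time:
                flush()
            last_time = t
        block.append(values)
    flush()
    if not series:
        raise FormatError("no data rows", path=path)
    return TimeSeriesData(series=series, gene_names=names,
                          series_ids=[f"P{i + 1}" for i in range(len(series))])


def write_timeseries(path, data: TimeSeriesData, dialect: str = "generic") -> None:
    path = Path(path)
    out = []
    if dialect == "generic":
        out.append("\t".join(data.gene_names))
        for row in data.series[0]:
            out.append("\t".join(repr(float(v)) for v in row))
    elif dialect == "dream4":
        out.append("\t".join(["Time"] + list(data.gene_names)))
        for si, mat in enumerate(data.series):
            if si:
                out.append("")
            for t, row in enumerate(mat):
                out.append("\t".join([str(t)] + [repr(float(v)) for v in row]))
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    path.write_text("\n".join(out) + "\n")


def read_edge_list(path):
    """Parse a gold-standard edge list; returns (edges, genes).

    ``edges`` is a set of (source, target) gene-name pairs with label 1;
    ``genes`` lists every gene seen, in order of first appearance.
    """
    edges: set[tuple[str, str]] = set()
    genes: list[str] = []
    seen: set[str] = set()
    for lineno, ln in enumerate(_lines(path), start=1):
        if not ln.strip():
            continue
        cells = ln.split("\t")
        if len(cells) != 3:
            raise FormatError("expected 3 tab-separated columns", path=path, line=lineno)
        src, tgt, label = (c.strip() for c in cells)
        if label not in ("0", "1"):
            raise FormatError(f"bad label {label!r} (expected 0 or 1)", path=path, line=lineno)
        for g in (src, tgt):
            if g not in seen:
                seen.add(g)
                genes.append(g)
        if label == "1":
            edges.add((src, tgt))
    return edges, genes


def write_edge_list(path, network_or_edges, gene_names=None) -> None:
    """Write a gold-standard edge list (``source  target  1`` lines)."""
    if isinstance(network_or_edges, GeneNetwork):
        names = network_or_edges.gene_names
        edges = sorted(network_or_edges.edge_set())
        lines = [f"{names[m]}\t{names[t]}\t1" for m, t in edges]
    else:
        edges = network_or_edges
        if gene_names is not None:
            edges = [(gene_names[m], gene_names[t]) for m, t in edges]
        lines = [f"{m}\t{t}\t1" for m, t in sorted(edges)]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def write_ranked_edges(path, estimate, include_self_loops: bool = False) -> None:
    """Write the scored candidate edges of a NetworkEstimate, best first."""
    names = estimate.gene_names
    lines = [
        f"{names[src]}\t{names[tgt]}\t{float(score)!r}\t{sign:+d}"
        for src, tgt, score, sign in estimate.ranked_edges(include_self_loops)
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_ranked_edges(path):
    """Read a ranked-edge file back into (scores matrix, gene names).

    The score of edge (m, n) lands in ``scores[n, m]`` with its sign.
    """
    rows = []
    genes: list[str] = []
    seen: set[str] = set()
    for lineno, ln in enumerate(_lines(path), start=1):
        if not ln.strip():
            continue
        cells = ln.split("\t")
        if len(cells) != 4:
            raise FormatError("expected 4 tab-separated columns", path=path, line=lineno)
        src, tgt = cells[0].strip(), cells[1].strip()
        score = _parse_floats(cells[2:3], path, lineno)[0]
        sign = cells[3].strip()
        if sign not in ("+1", "-1", "1"):
            raise FormatError(f"bad sign {sign!r}", path=path, line=lineno)
        rows.append((src, tgt, score, 1.0 if sign in ("+1", "1") else -1.0))
        for g in (src, tgt):
            if g not in seen:
                seen.add(g)
                genes.append(g)
    genes_sorted = sorted(genes)
    idx = {g: i for i, g in enumerate(genes_sorted)}
    scores = np.zeros((len(genes_sorted), len(genes_sorted)))
    for src, tgt, score, sign in rows:
        scores[idx[tgt], idx[src]] = sign * score
    return scores, genes_sorted


def read_network(path) -> GeneNetwork:
    """Read a weight-matrix TSV (header gene names, leading row-label column)."""
    lines = [ln for ln in _lines(path) if ln.strip()]
    if not lines:
        raise FormatError("empty file", path=path)
    names = [c.strip() for c in lines[0].split("\t")[1:]]
    n = len(names)
    weights = np.zeros((n, n))
    if len(lines) - 1 != n:
        raise FormatError(f"expected {n} data rows, found {len(lines) - 1}", path=path)
    for i, ln in enumerate(lines[1:], start=2):
        cells = ln.split("\t")
        if len(cells) != n + 1:
            raise FormatError(f"expected {n + 1} columns", path=path, line=i)
        weights[i - 2] = _parse_floats(cells[1:], path, i)
    return GeneNetwork(weights, gene_names=names)


def write_network(path, network: GeneNetwork) -> None:
    names = network.gene_names
    lines = ["\t".join([""] + names)]
    for i, row in enumerate(network.weights):
        lines.append("\t".join([names[i]] + [repr(float(v)) for v in row]))
    Path(path).write_text("\n".join(lines) + "\n")


_KNOWN_KEYS = {
    "sigma_w2", "sigma_v2", "k_tau", "pm_variance", "walk_variance",
    "pm_schedule", "decouple", "standardize", "seed", "method", "dialect",
}


@dataclass
class RunConfig:
    """Parsed YAML run configuration for the command-line pipeline."""

    sigma_w2: float = 1e-5
    sigma_v2: float = 1e-5
    k_tau: int | str = "auto"
    pm_variance: float = 100.0
    walk_variance: float = 0.0
    pm_schedule: str = "per_step"
    decouple: bool | str = "auto"
    standardize: bool = False
    seed: int | None = None
    method: str = "ckfs"
    dialect: str = "generic"


def load_config(path) -> RunConfig:
    path = Path(path)
    if not path.exists():
        raise FormatError("file not found", path=path)
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise FormatError("config must be a YAML mapping", path=path)
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        raise FormatError(f"unknown config keys: {sorted(unknown)}", path=path)
    return RunConfig(**raw)
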
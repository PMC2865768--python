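"""Degree tables, the eight regulatory patterns, and degree-asymmetry tests.

Activators are genes upregulated in tumor, suppressors genes downregulated
in tumor.  Crossing node class, edge sign, and edge direction gives eight
regulatory patterns; with the display convention that a positive edge links
same-class genes and a negative edge links opposite classes, the patterns
partition a node's out-edges (patterns 1–4) and in-edges (patterns 5–8):

    suppressor out: negative → 1 (suppresses activators),
                    positive → 2 (activates suppressors)
    activator  out: negative → 3 (suppresses suppressors),
                    positive → 4 (activates activators)
    suppressor in:  negative → 5 (suppressed by activators),
                    positive → 6 (activated by suppressors)
    activator  in:  negative → 7 (suppressed by suppressors),
                    positive → 8 (activated by activators)

so per gene the pattern 1–4 counts sum to its out-degree and the 5–8 counts
to its in-degree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .inference import GeneNetwork

__all__ = [
    "DegreeRecord",
    "PatternCounts",
    "degree_table",
    "degrees_frame",
    "pattern_counts",
    "patterns_frame",
    "paired_t_one_tailed",
    "welch_t_one_tailed",
    "asymmetry_report",
]


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


@dataclass(frozen=True)
class DegreeRecord:
    """Per-gene connection degrees across the α sweep."""

    gene: str
    total: dict[float, int]
    indegree: dict[float, int]

    def outdegree(self, alpha: float) -> int:
        return self.total[alpha] - self.indegree[alpha]

    @property
    def avg_total(self) -> float:
        return float(np.mean(list(self.total.values())))

    @property
    def avg_indegree(self) -> float:
        return float(np.mean(list(self.indegree.values())))

    @property
    def avg_outdegree(self) -> float:
        return self.avg_total - self.avg_indegree

    @property
    def avg_total_rounded(self) -> int:
        return _round_half_up(self.avg_total)

    @property
    def avg_indegree_rounded(self) -> int:
        return _round_half_up(self.avg_indegree)


@dataclass(frozen=True)
class PatternCounts:
    """Counts n₁…n₈ of the eight regulatory patterns for one gene."""

    gene: str
    n: tuple[int, int, int, int, int, int, int, int]

    @property
    def out_sum(self) -> int:
        return sum(self.n[:4])

    @property
    def in_sum(self) -> int:
        return sum(self.n[4:])


def degree_table(networks: Sequence[GeneNetwork], genes: Iterable[str] | None = None) -> list[DegreeRecord]:
    """Total and in-degrees of each gene in each network of the sweep."""
    if genes is None:
        genes = sorted(set().union(*(set(n.nodes) for n in networks)))
    genes = list(genes)
    records = []
    for g in genes:
        total: dict[float, int] = {}
        ind: dict[float, int] = {}
        for net in networks:
            i = sum(1 for e in net.edges if e.target == g)
            o = sum(1 for e in net.edges if e.regulator == g)
            total[net.alpha] = i + o
            ind[net.alpha] = i
        records.append(DegreeRecord(gene=g, total=total, indegree=ind))
    return records


def degrees_frame(records: Sequence[DegreeRecord]) -> pd.DataFrame:
    """Printed-table layout: one row per gene, ``total (indegree)`` per α."""
    alphas = sorted(records[0].total, reverse=True) if records else []
    rows = []
    for r in records:
        row: dict = {"gene": r.gene}
        for a in alphas:
            row[f"alpha={a:g}"] = f"{r.total[a]} ({r.indegree[a]})"
        row["average"] = f"{r.avg_total_rounded} ({r.avg_indegree_rounded})"
        row["average_total_exact"] = r.avg_total
        row["average_indegree_exact"] = r.avg_indegree
        rows.append(row)
    return pd.DataFrame(rows)


_OUT_PATTERN = {("down", -1): 0, ("down", 1): 1, ("up", -1): 2, ("up", 1): 3}
_IN_PATTERN = {("down", -1): 4, ("down", 1): 5, ("up", -1): 6, ("up", 1): 7}


def pattern_counts(network: GeneNetwork) -> list[PatternCounts]:
    """Tally the eight patterns for every annotated node of one network."""
    for gene, ann in network.nodes.items():
        if ann not in ("up", "down"):
            raise ValueError(f"node {gene!r} is not annotated up or down")
    counts = {g: [0] * 8 for g in network.nodes}
    for e in network.edges:
        if e.sign not in (-1, 1):
            raise ValueError(f"edge {e.regulator}->{e.target} is unsigned")
        if e.regulator in counts:
            counts[e.regulator][_OUT_PATTERN[(network.nodes[e.regulator], e.sign)]] += 1
        if e.target in counts:
            counts[e.target][_IN_PATTERN[(network.nodes[e.target], e.sign)]] += 1
    return [PatternCounts(gene=g, n=tuple(c)) for g, c in counts.items()]


def patterns_frame(counts: Sequence[PatternCounts]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"gene": c.gene, **{f"pattern{i+1}": c.n[i] for i in range(8)}} for c in counts]
    )


def paired_t_one_tailed(x, y):
    """Paired one-tailed t-test of mean(x) > mean(y); returns (t, df, p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 2:
        raise ValueError("paired test needs two aligned samples of size >= 2")
    d = x - y
    if np.allclose(d.std(ddof=1), 0.0):
        raise ValueError("degenerate paired test: zero-variance differences")
    res = stats.ttest_rel(x, y, alternative="greater")
    return float(res.statistic), int(len(x) - 1), float(res.pvalue)


def welch_t_one_tailed(x, y):
    """Welch one-tailed t-test of mean(x) > mean(y); returns (t, df, p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("welch test needs two samples of size >= 2")
    if np.allclose(x.std(ddof=1), 0.0) and np.allclose(y.std(ddof=1), 0.0):
        raise ValueError("degenerate welch test: both groups constant")
    res = stats.ttest_ind(x, y, equal_var=False, alternative="greater")
    return float(res.statistic), float(res.df), float(res.pvalue)


def _safe(testfn, x, y):
    try:
        t, df, p = testfn(x, y)
        return {"t": t, "df": df, "p": p}
    except ValueError as exc:
        return {"skipped": str(exc)}


def asymmetry_report(
    records: Sequence[DegreeRecord],
    annotations: Mapping[str, str],
    rounded_average: bool = True,
) -> dict:
    """Degree-asymmetry summary between up- and down-regulated genes.

    Per α: group means of in- and out-degrees, paired one-tailed tests
    within each group (down genes: out > in; up genes: in > out), and a
    Welch one-tailed test of up-gene indegrees exceeding down-gene
    indegrees.  The ``'average'`` entry repeats the between-group test on
    the per-gene sweep averages — on the rounded integers of the printed
    table layout when ``rounded_average`` (the default), else exact.
    """
    up = [r for r in records if annotations.get(r.gene) == "up"]
    down = [r for r in records if annotations.get(r.gene) == "down"]
    alphas = sorted(records[0].total, reverse=True) if records else []
    report: dict = {"alphas": [float(a) for a in alphas], "per_alpha": {}}
    for a in alphas:
        up_in = [r.indegree[a] for r in up]
        up_out = [r.outdegree(a) for r in up]
        down_in = [r.indegree[a] for r in down]
        down_out = [r.outdegree(a) for r in down]
        report["per_alpha"][f"{a:g}"] = {
            "mean_indegree_up": float(np.mean(up_in)) if up_in else 0.0,
            "mean_indegree_down": float(np.mean(down_in)) if down_in else 0.0,
            "mean_outdegree_up": float(np.mean(up_out)) if up_out else 0.0,
            "mean_outdegree_down": float(np.mean(down_out)) if down_out else 0.0,
            "paired_down_out_gt_in": _safe(paired_t_one_tailed, down_out, down_in),
            "paired_up_in_gt_out": _safe(paired_t_one_tailed, up_in, up_out),
            "welch_up_in_gt_down_in": _safe(welch_t_one_tailed, up_in, down_in),
        }
    if rounded_average:
        up_avg = [r.avg_indegree_rounded for r in up]
        down_avg = [r.avg_indegree_rounded for r in down]
    else:
        up_avg = [r.avg_indegree for r in up]
        down_avg = [r.avg_indegree for r in down]
    report["average"] = {
        "mean_indegree_up": float(np.mean(up_avg)) if up_avg else 0.0,
        "mean_indegree_down": float(np.mean(down_avg)) if down_avg else 0.0,
        "welch_up_in_gt_down_in": _safe(welch_t_one_tailed, up_avg, down_avg),
    }
    return report
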
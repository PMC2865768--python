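"""Supervised entropy discretization with the MDL stopping rule.

Each continuous attribute is split recursively at the midpoint between
adjacent distinct values that minimizes the class-entropy of the induced
two-way partition; a split is kept only when its information gain clears the
minimum-description-length criterion

    gain > log2(N - 1)/N + Δ/N,
    Δ = log2(3^k − 2) − [k·E(S) − k₁·E(S₁) − k₂·E(S₂)],

where ``k`` counts the classes present in the segment and ``E`` is Shannon
entropy in bits.  Attributes that accept no cut are labeled ``'All'``;
otherwise values map to interval labels in the ``'(-inf-x)'`` / ``'(x-y)'`` /
``'(x-inf)'`` dialect, where ``'(-inf-x)'`` means ``<= x`` (left interval
closed at the cut) and ``'(x-inf)'`` means ``> x``.
"""

from __future__ import annotations

import math
from bisect import bisect_left
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .decision_table import DecisionTable

__all__ = [
    "class_entropy",
    "find_cuts",
    "DiscretizationScheme",
    "MDLPDiscretizer",
    "discretize_table",
]


def class_entropy(labels) -> float:
    """Shannon entropy (bits) of a multiset of decision values."""
    labels = list(labels)
    if not labels:
        raise ValueError("class_entropy of an empty label set is undefined")
    counts = np.asarray(list(Counter(labels).values()), dtype=float)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def _entropy_from_counts(counts: np.ndarray) -> float:
    total = counts.sum()
    if total == 0:
        return 0.0
    nz = counts[counts > 0]
    p = nz / total
    return float(-(p * np.log2(p)).sum())


def _best_cut(values: np.ndarray, codes: np.ndarray, n_classes: int):
    """Lowest-weighted-entropy boundary cut; smallest cut wins ties.

    ``values`` must be sorted ascending with ``codes`` aligned.  Returns
    ``(cut, split_index, e1, e2)`` or ``None`` when no boundary exists.
    Candidate cuts are midpoints between adjacent distinct values, skipping
    pairs where both values carry the same single class (no information
    there, per the boundary-point theorem).
    """
    n = len(values)
    # prefix class counts: counts[i] = class histogram of values[:i]
    onehot = np.zeros((n, n_classes))
    onehot[np.arange(n), codes] = 1.0
    prefix = np.cumsum(onehot, axis=0)
    total = prefix[-1]

    best = None
    i = 0
    # group boundaries between runs of equal values
    distinct_ends = np.flatnonzero(np.diff(values) > 0) + 1  # split indices
    for idx in distinct_ends:
        left_val, right_val = values[idx - 1], values[idx]
        # classes present at the two adjacent distinct values
        run_start = idx - 1
        while run_start > 0 and values[run_start - 1] == left_val:
            run_start -= 1
        run_end = idx
        while run_end < n and values[run_end] == right_val:
            run_end += 1
        left_codes = set(codes[run_start:idx])
        right_codes = set(codes[idx:run_end])
        if len(left_codes) == 1 and left_codes == right_codes:
            continue
        c1 = prefix[idx - 1]
        c2 = total - c1
        e1 = _entropy_from_counts(c1)
        e2 = _entropy_from_counts(c2)
        w = (idx * e1 + (n - idx) * e2) / n
        cut = (left_val + right_val) / 2.0
        if best is None or w < best[0] - 1e-12:
            best = (w, cut, idx, e1, e2)
    if best is None:
        return None
    return best[1], best[2], best[3], best[4]


def _mdlp_accept(n, ent, e1, e2, n1, n2, k, k1, k2) -> bool:
    gain = ent - (n1 * e1 + n2 * e2) / n
    delta = math.log2(3**k - 2) - (k * ent - k1 * e1 - k2 * e2)
    return gain > (math.log2(n - 1) + delta) / n


def _recurse(values: np.ndarray, codes: np.ndarray, n_classes: int, out: list) -> None:
    n = len(values)
    if n < 2:
        return
    counts = np.bincount(codes, minlength=n_classes).astype(float)
    k = int((counts > 0).sum())
    if k < 2:
        return
    ent = _entropy_from_counts(counts)
    found = _best_cut(values, codes, n_classes)
    if found is None:
        return
    cut, idx, e1, e2 = found
    c1 = np.bincount(codes[:idx], minlength=n_classes)
    c2 = np.bincount(codes[idx:], minlength=n_classes)
    k1, k2 = int((c1 > 0).sum()), int((c2 > 0).sum())
    if not _mdlp_accept(n, ent, e1, e2, idx, n - idx, k, k1, k2):
        return
    out.append(cut)
    _recurse(values[:idx], codes[:idx], n_classes, out)
    _recurse(values[idx:], codes[idx:], n_classes, out)


def find_cuts(values, labels) -> list[float]:
    """Recursive MDL-pruned cut points for one attribute (sorted ascending)."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if len(values) != len(labels):
        raise ValueError("values and labels must be aligned")
    if len(values) == 0:
        raise ValueError("find_cuts needs at least one sample")
    order = np.argsort(values, kind="stable")
    values = values[order]
    _, codes = np.unique(labels[order], return_inverse=True)
    n_classes = codes.max() + 1 if len(codes) else 1
    out: list[float] = []
    _recurse(values, codes, int(n_classes), out)
    return sorted(out)


def _fmt(x: float) -> str:
    """Shortest decimal that round-trips to the same float."""
    s = repr(float(x))
    return s[:-2] if s.endswith(".0") else s


@dataclass(frozen=True)
class DiscretizationScheme:
    """Per-attribute ordered cut points plus the supervising decision attribute.

    ``primary_cuts`` records, for attributes with multiple accepted cuts, the
    single highest-gain (top-level) cut — the one used when the attribute
    must be binarized to act as a decision attribute.
    """

    cuts: dict[str, list[float]]
    decision_attribute: str = ""
    primary_cuts: dict[str, float] = field(default_factory=dict)

    def labels(self, attribute: str) -> list[str]:
        c = self.cuts.get(attribute, [])
        if not c:
            return ["All"]
        labs = [f"(-inf-{_fmt(c[0])})"]
        labs += [f"({_fmt(a)}-{_fmt(b)})" for a, b in zip(c, c[1:])]
        labs.append(f"({_fmt(c[-1])}-inf)")
        return labs

    def interval_index(self, attribute: str, value: float) -> int:
        """Index of the interval holding ``value`` (left-closed at each cut)."""
        return bisect_left(self.cuts.get(attribute, []), float(value))

    def interval_label(self, attribute: str, value: float) -> str:
        return self.labels(attribute)[self.interval_index(attribute, value)]

    def apply(self, attribute: str, values) -> pd.Series:
        values = pd.to_numeric(pd.Series(values))
        cuts = self.cuts.get(attribute, [])
        labs = self.labels(attribute)
        if not cuts:
            out = pd.Series("All", index=values.index)
        else:
            idx = np.searchsorted(np.asarray(cuts), values.to_numpy(), side="left")
            out = pd.Series(np.asarray(labs, dtype=object)[idx], index=values.index)
        out.name = getattr(values, "name", attribute)
        return out

    def binarizing_cut(self, attribute: str) -> float:
        """The single cut used to binarize ``attribute`` into Down/Up."""
        c = self.cuts.get(attribute, [])
        if not c:
            raise ValueError(f"attribute {attribute!r} has no cut")
        if len(c) == 1:
            return c[0]
        if attribute in self.primary_cuts:
            return self.primary_cuts[attribute]
        raise ValueError(
            f"attribute {attribute!r} has {len(c)} cuts and no recorded primary cut"
        )

    # -- serialization -----------------------------------------------------

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"#decision\t{self.decision_attribute}\n")
            for attr, c in self.cuts.items():
                primary = self.primary_cuts.get(attr)
                pcol = _fmt(primary) if primary is not None else ""
                fh.write(f"{attr}\t{','.join(_fmt(x) for x in c)}\t{pcol}\n")

    @classmethod
    def from_tsv(cls, path) -> "DiscretizationScheme":
        cuts: dict[str, list[float]] = {}
        primary: dict[str, float] = {}
        decision = ""
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                if line.startswith("#decision\t"):
                    decision = line.split("\t", 1)[1]
                    continue
                parts = line.split("\t")
                attr = parts[0]
                cuts[attr] = [float(x) for x in parts[1].split(",")] if parts[1] else []
                if len(parts) > 2 and parts[2]:
                    primary[attr] = float(parts[2])
        return cls(cuts=cuts, decision_attribute=decision, primary_cuts=primary)


class MDLPDiscretizer(TransformerMixin, BaseEstimator):
    """Sklearn-style supervised discretizer (Fayyad–Irani MDLP stopping).

    ``fit(X, y)`` learns per-column cut points against the labels ``y``;
    ``transform(X)`` replaces values by interval labels.  ``X`` may be a
    DataFrame (column names become attribute IDs) or a 2-D array (columns
    named positionally ``"0"``, ``"1"``, …).

    Attributes
    ----------
    cuts_ : dict[str, list[float]]
        Accepted cut points per attribute, ascending.
    scheme_ : DiscretizationScheme
        The cuts plus interval-label dialect, serializable to TSV.
    """

    def fit(self, X, y):
        X = self._as_frame(X)
        y = np.asarray(y)
        if len(y) != len(X):
            raise ValueError("X and y are not aligned")
        cuts: dict[str, list[float]] = {}
        primary: dict[str, float] = {}
        for col in X.columns:
            vals = X[col].to_numpy(dtype=float)
            c = find_cuts(vals, y)
            cuts[col] = c
            if len(c) > 1:
                primary[col] = self._top_level_cut(vals, y)
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.cuts_ = cuts
        self.scheme_ = DiscretizationScheme(
            cuts=cuts, decision_attribute="y", primary_cuts=primary
        )
        return self

    def transform(self, X) -> pd.DataFrame:
        X = self._as_frame(X)
        out = {col: self.scheme_.apply(col, X[col]) for col in X.columns}
        return pd.DataFrame(out, index=X.index)

    @staticmethod
    def _as_frame(X) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            return X
        X = np.asarray(X)
        return pd.DataFrame(X, columns=[str(i) for i in range(X.shape[1])])

    @staticmethod
    def _top_level_cut(values: np.ndarray, labels: np.ndarray) -> float:
        order = np.argsort(values, kind="stable")
        v = values[order]
        _, codes = np.unique(np.asarray(labels)[order], return_inverse=True)
        found = _best_cut(v, codes, int(codes.max()) + 1)
        assert found is not None
        return found[0]


def discretize_table(table: DecisionTable):
    """Discretize every condition attribute against the decision attribute.

    Supervision is by the table's *current* decision attribute, so promoting
    a gene to decision and re-discretizing generally yields different cuts
    than class-supervised discretization of the same genes.

    Returns ``(discretized_table, scheme)``.
    """
    if not table.is_discrete(table.decision_attribute):
        raise ValueError("decision attribute must be categorical before discretizing")
    cond = table.condition_attributes
    disc = MDLPDiscretizer().fit(table.data[cond], table.decision_values.to_numpy())
    labeled = disc.transform(table.data[cond])
    labeled[table.decision_attribute] = table.decision_values
    scheme = DiscretizationScheme(
        cuts=disc.cuts_,
        decision_attribute=table.decision_attribute,
        primary_cuts=disc.scheme_.primary_cuts,
    )
    return table.with_data(labeled), scheme
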
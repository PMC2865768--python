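"""Expression decision tables and equivalence-class partitioning.

A *decision table* ``S = (U, A = C ∪ D)`` is the rough-set view of an
expression matrix: ``U`` is the sample set, ``C`` the condition attributes
(genes), and ``D`` a single designated decision attribute — the tumor/normal
class label, or, when inferring regulation, a binarized target gene.  The
information function ``I_a`` maps a sample to its value on attribute ``a``;
the equivalence relation ``R(A')`` groups samples agreeing on every attribute
of ``A'``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DecisionTable",
    "EquivalencePartition",
    "read_expression_table",
    "write_expression_table",
    "set_decision_attribute",
    "partition",
]


@dataclass(frozen=True)
class DecisionTable:
    """Samples × attributes with one designated decision attribute.

    Parameters
    ----------
    data : pandas.DataFrame
        Rows are samples (index = sample IDs), columns are attributes.
        Condition columns hold continuous expression values or categorical
        interval labels; the decision column holds categorical values.
    decision_attribute : str
        Column currently playing the role of ``D``.
    metadata : pandas.DataFrame
        Per-sample columns carried along but excluded from ``C`` (e.g. the
        original class labels after a gene has been promoted to decision).
    """

    data: pd.DataFrame
    decision_attribute: str
    metadata: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if self.decision_attribute not in self.data.columns:
            raise ValueError(
                f"decision attribute {self.decision_attribute!r} not among attributes"
            )
        if len(self.data) < 2:
            raise ValueError("a decision table needs at least 2 samples")
        if self.data.index.duplicated().any():
            dupes = self.data.index[self.data.index.duplicated()].tolist()
            raise ValueError(f"duplicate sample IDs: {dupes}")
        if self.data.columns.duplicated().any():
            dupes = self.data.columns[self.data.columns.duplicated()].tolist()
            raise ValueError(f"duplicate attribute IDs: {dupes}")
        na = self.data.isna()
        if na.to_numpy().any():
            sample = self.data.index[na.any(axis=1)][0]
            attr = self.data.columns[na.loc[sample]][0]
            raise ValueError(f"missing value at sample {sample!r}, attribute {attr!r}")

    # -- accessors ---------------------------------------------------------

    @property
    def samples(self) -> list:
        return list(self.data.index)

    @property
    def attributes(self) -> list[str]:
        return list(self.data.columns)

    @property
    def condition_attributes(self) -> list[str]:
        return [a for a in self.data.columns if a != self.decision_attribute]

    @property
    def n_samples(self) -> int:
        return len(self.data)

    def values(self, attribute: str) -> pd.Series:
        return self.data[attribute]

    @property
    def decision_values(self) -> pd.Series:
        return self.data[self.decision_attribute]

    def is_discrete(self, attribute: str) -> bool:
        return not pd.api.types.is_numeric_dtype(self.data[attribute])

    def with_data(self, data: pd.DataFrame) -> "DecisionTable":
        return replace(self, data=data)


@dataclass(frozen=True)
class EquivalencePartition:
    """The quotient ``U / R(A')``: blocks of samples agreeing on ``A'``."""

    blocks: tuple[frozenset, ...]
    inducing_attributes: tuple[str, ...]

    @property
    def universe(self) -> frozenset:
        return frozenset().union(*self.blocks) if self.blocks else frozenset()

    def __len__(self) -> int:
        return len(self.blocks)


def read_expression_table(
    path,
    label_column: str = "Class",
    orientation: str = "rows-are-samples",
    sep: str | None = None,
) -> DecisionTable:
    """Read a delimited expression matrix with a class-label column.

    The canonical layout has rows = samples, columns = genes, and a final
    categorical label column; ``orientation='rows-are-genes'`` transposes a
    gene-major file (the label column is then a label *row*).  The delimiter
    is sniffed from the extension (``.csv`` → comma, else tab) unless given.
    """
    if orientation not in ("rows-are-samples", "rows-are-genes"):
        raise ValueError(f"unknown orientation {orientation!r}")
    if sep is None:
        sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    if orientation == "rows-are-genes":
        df = df.T
    if label_column not in df.columns:
        raise ValueError(f"label column {label_column!r} not found in {path}")
    labels = df[label_column].astype(str)
    expr = df.drop(columns=[label_column])
    for col in expr.columns:
        try:
            expr[col] = pd.to_numeric(expr[col])
        except (ValueError, TypeError) as exc:
            raise ValueError(f"non-numeric expression value in column {col!r}: {exc}")
    expr[label_column] = labels
    return DecisionTable(data=expr, decision_attribute=label_column)


def write_expression_table(table: DecisionTable, path, sep: str | None = None) -> None:
    """Write back in the canonical rows-are-samples layout (decision last)."""
    if sep is None:
        sep = "," if str(path).endswith(".csv") else "\t"
    cols = table.condition_attributes + [table.decision_attribute]
    table.data[cols].to_csv(path, sep=sep)


def set_decision_attribute(table: DecisionTable, gene: str, binarizer) -> DecisionTable:
    """Promote a gene to decision attribute, binarized at its supervised cut.

    The gene's continuous values are mapped to ``Down`` (≤ cut) / ``Up``
    (> cut) using the single cut the ``binarizer`` scheme holds for it; the
    gene leaves the condition set and the previous decision column is parked
    in ``metadata``.  A gene whose scheme is the single interval ``'All'``
    carries no class information and cannot serve as a decision attribute.
    """
    if gene not in table.condition_attributes:
        raise ValueError(f"{gene!r} is not a condition attribute")
    cuts = binarizer.cuts.get(gene, [])
    if not cuts:
        raise ValueError(
            f"gene {gene!r} cannot serve as decision attribute: "
            "its discretization scheme is the single interval 'All'"
        )
    cut = binarizer.binarizing_cut(gene)
    values = pd.to_numeric(table.values(gene))
    levels = pd.Series(
        np.where(values <= cut, "Down", "Up"), index=table.data.index, name=gene
    )
    meta = table.metadata.copy()
    meta[table.decision_attribute] = table.decision_values
    data = table.data.drop(columns=[gene, table.decision_attribute]).copy()
    data[gene] = levels
    return DecisionTable(data=data, decision_attribute=gene, metadata=meta)


def partition(table: DecisionTable, attrs: Iterable[str]) -> EquivalencePartition:
    """Compute ``U / R(attrs)`` for a set of discretized attributes."""
    attrs = list(attrs)
    if not attrs:
        raise ValueError("attrs must be nonempty")
    for a in attrs:
        if a not in table.data.columns:
            raise ValueError(f"unknown attribute {a!r}")
        if not table.is_discrete(a):
            raise ValueError(
                f"partition requires discretized values; attribute {a!r} is continuous"
            )
    grouped = table.data.groupby(attrs, sort=False, observed=True).groups
    blocks = tuple(frozenset(idx) for idx in grouped.values())
    return EquivalencePartition(blocks=blocks, inducing_attributes=tuple(attrs))
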
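"""α-depended degree, positive regions, decision rules, and a rule classifier.

The α-depended degree of a condition subset ``P`` on decision ``D`` is

    γ_P(D, α) = |POS_P(D, α)| / |U|,
    POS_P(D, α) = ∪_{X ∈ U/R(D)} pos(P, X, α),
    pos(P, X, α) = ∪ { Y ∈ U/R(P) : |Y ∩ X| / |Y| ≥ α },

i.e. the fraction of samples lying in P-blocks whose majority decision class
reaches purity α.  γ = 1 means P determines D at tolerance α; the classical
rough-set depended degree is the α = 1 case.  Each qualifying block yields a
decision rule ``A(c_i(g)) ⇒ B(d_j(D))`` whose confidence is the conditional
support ``support(A ∧ B) / support(A)``.

α is restricted to (0.5, 1] throughout: above one half the qualifying
decision value of a block is unique, so rules are unambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from .decision_table import DecisionTable, EquivalencePartition, partition
from .discretize import MDLPDiscretizer, discretize_table, find_cuts, DiscretizationScheme

__all__ = [
    "DecisionRule",
    "DependencyResult",
    "alpha_positive_region",
    "alpha_depended_degree",
    "induce_rules",
    "select_genes",
    "classify",
    "loocv",
    "AlphaRuleClassifier",
    "rules_to_tsv",
    "rule_text",
]


def _check_alpha(alpha: float) -> float:
    if not 0.5 < alpha <= 1.0:
        raise ValueError(f"alpha must lie in (0.5, 1], got {alpha}")
    return float(alpha)


@dataclass(frozen=True)
class DecisionRule:
    """Single-attribute rule ``(attribute = interval) ⇒ (decision = consequent)``."""

    attribute: str
    interval: str
    consequent: str
    support_antecedent: float
    confidence: float

    def __post_init__(self) -> None:
        if not 0.0 < self.support_antecedent <= 1.0:
            raise ValueError("antecedent support must lie in (0, 1]")
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError("confidence must lie in [0, 1]")


@dataclass(frozen=True)
class DependencyResult:
    gamma: float
    positive_region: frozenset
    alpha: float


def alpha_positive_region(
    P_partition: EquivalencePartition,
    D_partition: EquivalencePartition,
    alpha: float,
) -> frozenset:
    """Union of P-blocks whose best decision-class overlap ratio reaches α."""
    _check_alpha(alpha)
    if P_partition.universe != D_partition.universe:
        raise ValueError("partitions are over different sample universes")
    pos: set = set()
    for Y in P_partition.blocks:
        best = max(len(Y & X) for X in D_partition.blocks)
        if best / len(Y) >= alpha:
            pos |= Y
    return frozenset(pos)


def alpha_depended_degree(
    table: DecisionTable, P: Iterable[str], alpha: float
) -> DependencyResult:
    """γ_P(D, α) of the attribute subset P on the table's decision attribute."""
    alpha = _check_alpha(alpha)
    P = list(P)
    P_part = partition(table, P)
    D_part = partition(table, [table.decision_attribute])
    pos = alpha_positive_region(P_part, D_part, alpha)
    return DependencyResult(
        gamma=len(pos) / table.n_samples, positive_region=pos, alpha=alpha
    )


def induce_rules(table: DecisionTable, g: str, alpha: float) -> list[DecisionRule]:
    """Decision rules of a single discretized attribute at confidence ≥ α.

    One rule per equivalence class of g whose majority decision value reaches
    purity α; blocks failing the test yield no rule.
    """
    alpha = _check_alpha(alpha)
    if g not in table.condition_attributes:
        raise ValueError(f"{g!r} is not a condition attribute")
    n = table.n_samples
    rules = []
    grouped = table.data.groupby(g, sort=True, observed=True)[table.decision_attribute]
    for interval, decisions in grouped:
        counts = decisions.value_counts()
        best_value = counts.idxmax()
        conf = counts.max() / len(decisions)
        if conf >= alpha:
            rules.append(
                DecisionRule(
                    attribute=g,
                    interval=str(interval),
                    consequent=str(best_value),
                    support_antecedent=len(decisions) / n,
                    confidence=float(conf),
                )
            )
    return rules


def select_genes(table: DecisionTable, alpha: float, with_flags: bool = False):
    """Condition attributes fully determining the decision: γ_g(D, α) = 1.

    A gene discretized to the single interval ``'All'`` is one block = U; it
    passes only when one decision class already has frequency ≥ α, in which
    case it is flagged degenerate (it carries no per-sample information).

    Returns the list of selected attribute IDs, or (gene, degenerate) pairs
    when ``with_flags`` is set.
    """
    alpha = _check_alpha(alpha)
    selected = []
    for g in table.condition_attributes:
        res = alpha_depended_degree(table, [g], alpha)
        if res.gamma == 1.0:
            degenerate = table.values(g).nunique() == 1
            selected.append((g, degenerate))
    return selected if with_flags else [g for g, _ in selected]


def classify(rules: Sequence[DecisionRule], sample_values: Mapping[str, str]):
    """Apply rules to one discretized sample; ``None`` means abstain.

    Conflicts resolve by highest confidence, then larger antecedent support,
    then lexicographically smallest consequent.
    """
    firing = [
        r
        for r in rules
        if sample_values.get(r.attribute) == r.interval
    ]
    if not firing:
        return None
    best = max(
        firing,
        key=lambda r: (r.confidence, r.support_antecedent, _NegStr(r.consequent)),
    )
    return best.consequent


class _NegStr:
    """Orders strings descending so that max() picks the lexicographic min."""

    __slots__ = ("s",)

    def __init__(self, s: str) -> None:
        self.s = s

    def __lt__(self, other: "_NegStr") -> bool:
        return self.s > other.s

    def __eq__(self, other) -> bool:
        return self.s == other.s


def loocv(table: DecisionTable, gene: str, alpha: float) -> float:
    """Leave-one-out accuracy of the single-gene rule classifier.

    Each fold re-discretizes the gene and re-induces rules on the n−1
    training samples to avoid information leakage, then classifies the
    held-out sample; abstentions and degenerate single-class training folds
    count as errors.
    """
    alpha = _check_alpha(alpha)
    if table.n_samples < 3:
        raise ValueError("LOOCV needs at least 3 samples")
    values = pd.to_numeric(table.values(gene))
    labels = table.decision_values.astype(str)
    correct = 0
    for held in table.samples:
        train_mask = table.data.index != held
        v_train = values[train_mask].to_numpy()
        y_train = labels[train_mask].to_numpy()
        if len(set(y_train)) < 2:
            continue  # degenerate fold counts as error
        cuts = find_cuts(v_train, y_train)
        scheme = DiscretizationScheme(cuts={gene: cuts})
        disc = scheme.apply(gene, pd.Series(v_train))
        fold = pd.DataFrame({gene: disc.to_numpy(), "y": y_train})
        fold.index = [f"s{i}" for i in range(len(fold))]
        fold_table = DecisionTable(data=fold, decision_attribute="y")
        rules = induce_rules(fold_table, gene, alpha)
        pred = classify(rules, {gene: scheme.interval_label(gene, values[held])})
        if pred is not None and pred == labels[held]:
            correct += 1
    return correct / table.n_samples


class AlphaRuleClassifier(ClassifierMixin, BaseEstimator):
    """Rule-based classifier over MDLP-discretized expression values.

    ``fit(X, y)`` discretizes every feature against ``y``, keeps the
    features with γ(D, α) = 1 (or the explicit ``attributes``), and induces
    their decision rules.  ``predict`` fires the matching rules per sample;
    with ``on_abstain='majority'`` (default) unmatched samples get the
    training majority class, with ``'none'`` they get ``None``.

    Parameters
    ----------
    alpha : float, default 0.8
        Rule-confidence threshold in (0.5, 1].
    attributes : sequence of str, optional
        Fixed antecedent attributes; bypasses γ-based selection.
    on_abstain : {'majority', 'none'}, default 'majority'
    """

    def __init__(self, alpha: float = 0.8, attributes=None, on_abstain: str = "majority"):
        self.alpha = alpha
        self.attributes = attributes
        self.on_abstain = on_abstain

    def fit(self, X, y):
        _check_alpha(self.alpha)
        X = MDLPDiscretizer._as_frame(X)
        y = np.asarray(y).astype(str)
        self.classes_ = np.unique(y)
        self.discretizer_ = MDLPDiscretizer().fit(X, y)
        labeled = self.discretizer_.transform(X)
        labeled["__decision__"] = y
        table = DecisionTable(data=labeled, decision_attribute="__decision__")
        if self.attributes is not None:
            selected = [str(a) for a in self.attributes]
        else:
            selected = [
                g
                for g, degen in select_genes(table, self.alpha, with_flags=True)
                if not degen
            ]
        self.selected_attributes_ = selected
        self.rules_ = [
            r for g in selected for r in induce_rules(table, g, self.alpha)
        ]
        counts = pd.Series(y).value_counts()
        self.majority_class_ = str(counts.idxmax())
        return self

    def predict(self, X):
        X = MDLPDiscretizer._as_frame(X)
        labeled = self.discretizer_.transform(X)
        fallback = self.majority_class_ if self.on_abstain == "majority" else None
        preds = [
            classify(self.rules_, row) or fallback
            for row in labeled.to_dict(orient="records")
        ]
        return np.asarray(preds, dtype=object)


def rule_text(rule: DecisionRule, decision_attribute: str = "class") -> str:
    """Human-readable form: ``if g in (-inf-x) then class = v (96% confidence)``."""
    pct = round(rule.confidence * 100)
    return (
        f"if {rule.attribute} in '{rule.interval}' then "
        f"{decision_attribute} = {rule.consequent} ({pct}% confidence)"
    )


def rules_to_tsv(rules: Sequence[DecisionRule], path) -> None:
    pd.DataFrame(
        [
            {
                "attribute": r.attribute,
                "interval": r.interval,
                "consequent": r.consequent,
                "support": r.support_antecedent,
                "confidence": r.confidence,
            }
            for r in rules
        ]
    ).to_csv(path, sep="\t", index=False)
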
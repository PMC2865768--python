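"""Directed, signed regulatory-edge inference via gene-as-decision tables.

To test whether gene *g* regulates a target gene *t*, the target is promoted
to decision attribute — binarized Down/Up at its class-supervised cut — and
every candidate is re-discretized supervised by the binarized target.  An
edge ``g → t`` is drawn at level α when g splits into at least two intervals
and *every* equivalence class of g determines a target level with confidence
≥ α (γ_g(t, α) = 1), with the two blocks mapping to different levels so a
sign is defined: low⇒Down plus high⇒Up is positive regulation, the mirror
mapping negative.  Candidates discretized to the single interval ``'All'``
are barred: a one-block attribute reaches γ = 1 trivially whenever the
target distribution is α-skewed, which asserts nothing about regulation.

Because the per-target discretization is computed once and reused across the
α sweep, the networks nest: for α₁ < α₂ every edge of G(α₂) appears in
G(α₁) with the same sign.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .decision_table import DecisionTable, set_decision_attribute
from .discretize import DiscretizationScheme, MDLPDiscretizer, discretize_table
from .rules import DecisionRule, _check_alpha, induce_rules

logger = logging.getLogger(__name__)

__all__ = [
    "SignedEdge",
    "GeneNetwork",
    "edge_sign",
    "infer_regulators",
    "build_network",
    "annotate_genes",
    "GRNInferencer",
    "edges_to_tsv",
    "edges_from_tsv",
    "to_sif",
    "to_graphml",
    "networks_from_edges",
]

LOW_PREFIX = "(-inf"


@dataclass(frozen=True)
class SignedEdge:
    """Directed regulatory relation with its sign and survival level.

    ``alpha_level`` is the largest sweep α at which the edge holds (well
    defined by nesting); ``rule_confidences`` lists the per-block rule
    confidences, whose minimum governs survival.
    """

    regulator: str
    target: str
    sign: int
    alpha_level: float | None = None
    rule_confidences: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.regulator == self.target:
            raise ValueError("self-regulation edges are not drawn")
        if self.sign not in (-1, 1):
            raise ValueError("sign must be +1 or -1")

    @property
    def key(self) -> tuple[str, str]:
        return (self.regulator, self.target)


@dataclass(frozen=True)
class GeneNetwork:
    """Edge set at one α with node regulation-class annotations."""

    nodes: Mapping[str, str]  # gene -> 'up' | 'down' | 'unclassified'
    edges: tuple[SignedEdge, ...]
    alpha: float | None
    network_type: int = 1

    @property
    def edge_keys(self) -> set[tuple[str, str]]:
        return {e.key for e in self.edges}

    def __len__(self) -> int:
        return len(self.edges)


def _interval_is_low(label: str) -> bool:
    return label.startswith(LOW_PREFIX)


def edge_sign(rules: Sequence[DecisionRule]):
    """Sign of a binary regulator's block→level mapping onto a binary target.

    +1 when the low interval implies Down and the high interval implies Up;
    −1 for the mirror mapping; ``None`` when both blocks imply the same
    level (no discrimination) or the regulator is not binary.
    """
    if len(rules) != 2:
        return None
    low = next((r for r in rules if _interval_is_low(r.interval)), None)
    high = next((r for r in rules if not _interval_is_low(r.interval)), None)
    if low is None or high is None:
        return None
    if low.consequent == high.consequent:
        return None
    if low.consequent == "Down" and high.consequent == "Up":
        return 1
    if low.consequent == "Up" and high.consequent == "Down":
        return -1
    return None


@dataclass(frozen=True)
class _CandidateProfile:
    """Block→level mapping of one candidate against one binarized target."""

    sign: int
    min_confidence: float
    confidences: tuple[float, ...]


def _profile_candidates(
    table: DecisionTable,
    target: str,
    candidates: Sequence[str],
    class_scheme: DiscretizationScheme,
    multi_interval: str = "suppress",
) -> dict[str, _CandidateProfile]:
    """Re-discretize candidates against the binarized target and map blocks.

    Returns, per candidate with a defined sign, the mapping profile whose
    ``min_confidence`` decides the α levels at which the edge holds.
    """
    bin_table = set_decision_attribute(table, target, class_scheme)
    keep = [c for c in candidates if c != target]
    sub = bin_table.data[keep + [target]]
    sub_table = DecisionTable(data=sub, decision_attribute=target)
    disc_table, disc_scheme = discretize_table(sub_table)
    profiles: dict[str, _CandidateProfile] = {}
    n_all = n_sign_undefined = 0
    levels = disc_table.decision_values
    for g in keep:
        labels = disc_table.values(g)
        n_intervals = labels.nunique()
        if n_intervals < 2:
            n_all += 1
            continue
        if n_intervals > 2 and multi_interval == "suppress":
            n_sign_undefined += 1
            logger.warning(
                "candidate %s has %d intervals for target %s; edge suppressed",
                g, n_intervals, target,
            )
            continue
        # per-block majority level and purity, blocks in interval order
        tab = pd.crosstab(labels, levels)
        majority = tab.idxmax(axis=1)
        purity = tab.max(axis=1) / tab.sum(axis=1)
        order = [lab for lab in disc_scheme.labels(g) if lab in tab.index]
        mapped = [majority[lab] for lab in order]
        conf = np.asarray([purity[lab] for lab in order])
        if len(set(mapped)) < 2:
            n_sign_undefined += 1
            continue
        # sign defined only for a monotone interval-order -> level mapping
        runs = tuple(k for i, k in enumerate(mapped) if i == 0 or mapped[i - 1] != k)
        sign = {("Down", "Up"): 1, ("Up", "Down"): -1}.get(runs)
        if sign is None:
            n_sign_undefined += 1
            logger.warning("candidate %s maps non-monotonically onto %s", g, target)
            continue
        profiles[g] = _CandidateProfile(
            sign=sign,
            min_confidence=float(conf.min()),
            confidences=tuple(float(c) for c in conf),
        )
    if n_all or n_sign_undefined:
        logger.info(
            "target %s: %d candidates barred ('All'), %d sign-undefined",
            target, n_all, n_sign_undefined,
        )
    return profiles


def infer_regulators(
    table: DecisionTable,
    target: str,
    alpha: float,
    candidates: Sequence[str],
    class_scheme: DiscretizationScheme | None = None,
    multi_interval: str = "suppress",
) -> list[SignedEdge]:
    """Regulators of one target at a single α threshold."""
    alpha = _check_alpha(alpha)
    if class_scheme is None:
        _, class_scheme = discretize_table(table)
    if not class_scheme.cuts.get(target):
        raise ValueError(f"target {target!r} has no class-supervised cut; cannot binarize")
    profiles = _profile_candidates(table, target, candidates, class_scheme, multi_interval)
    return [
        SignedEdge(
            regulator=g,
            target=target,
            sign=p.sign,
            alpha_level=alpha,
            rule_confidences=p.confidences,
        )
        for g, p in sorted(profiles.items())
        if p.min_confidence >= alpha
    ]


def annotate_genes(
    table: DecisionTable,
    genes: Iterable[str],
    class_scheme: DiscretizationScheme,
    positive_class: str | None = None,
) -> dict[str, str]:
    """Regulation class of each gene from its class-supervised rule direction.

    A gene whose below-cut samples are mostly ``positive_class`` (the tumor
    label) is low in tumor, hence ``'down'``; the mirror case is ``'up'``;
    genes with no cut or no majority signal are ``'unclassified'``.
    """
    classes = sorted(set(table.decision_values.astype(str)))
    if positive_class is None:
        tumorish = [c for c in classes if c.lower() in ("tumor", "tumour", "cancer", "case")]
        if len(tumorish) == 1:
            positive_class = tumorish[0]
        else:
            raise ValueError(
                "positive_class (the tumor/case label) must be given; "
                f"classes are {classes}"
            )
    out: dict[str, str] = {}
    for g in genes:
        cuts = class_scheme.cuts.get(g, [])
        if not cuts:
            out[g] = "unclassified"
            continue
        cut = class_scheme.binarizing_cut(g)
        low_mask = pd.to_numeric(table.values(g)) <= cut
        if low_mask.sum() == 0 or (~low_mask).sum() == 0:
            out[g] = "unclassified"
            continue
        low_pos = (table.decision_values[low_mask].astype(str) == positive_class).mean()
        high_pos = (table.decision_values[~low_mask].astype(str) == positive_class).mean()
        if low_pos > high_pos:
            out[g] = "down"
        elif high_pos > low_pos:
            out[g] = "up"
        else:
            out[g] = "unclassified"
    return out


def build_network(
    table: DecisionTable,
    targets: Sequence[str],
    candidates: Sequence[str] | None = None,
    alphas: Sequence[float] = (1.0, 0.95, 0.9, 0.85, 0.8, 0.75, 0.7),
    network_type: int = 1,
    positive_class: str | None = None,
    strict_direction: bool = False,
    multi_interval: str = "suppress",
    on_unbinarizable: str = "raise",
) -> list[GeneNetwork]:
    """One network per sweep α, sharing a fixed per-target discretization.

    Type 1 restricts candidates to the target list itself (regulation among
    the identified genes); Type 2 admits every condition attribute as a
    candidate regulator while targets stay the identified genes.  Node
    annotations come from each gene's class-supervised rule direction.
    """
    targets = list(targets)
    if not targets:
        raise ValueError("targets must be nonempty")
    alphas = sorted({_check_alpha(a) for a in alphas}, reverse=True)
    if candidates is None:
        candidates = targets if network_type == 1 else table.condition_attributes
    candidates = list(candidates)
    _, class_scheme = discretize_table(table)
    annotations = annotate_genes(table, set(targets) | set(candidates), class_scheme, positive_class)

    profiles: dict[str, dict[str, _CandidateProfile]] = {}
    for t in targets:
        if not class_scheme.cuts.get(t):
            if on_unbinarizable == "skip":
                logger.warning("target %s has no class-supervised cut; skipped", t)
                continue
            raise ValueError(f"target {t!r} has no class-supervised cut; cannot binarize")
        profiles[t] = _profile_candidates(table, t, candidates, class_scheme, multi_interval)

    if strict_direction:
        for t, profs in profiles.items():
            for g in list(profs):
                if not class_scheme.cuts.get(g):
                    continue  # g not binarizable: no reverse test possible
                reverse = _profile_candidates(table, g, [t], class_scheme, multi_interval)
                if t in reverse and reverse[t].min_confidence >= profs[g].min_confidence:
                    logger.info("symmetric pair %s <-> %s dropped (strict mode)", g, t)
                    del profs[g]

    networks = []
    for alpha in alphas:
        edges = []
        for t in sorted(profiles):
            for g, p in sorted(profiles[t].items()):
                if p.min_confidence >= alpha:
                    level = max(a for a in alphas if a <= p.min_confidence)
                    edges.append(
                        SignedEdge(
                            regulator=g,
                            target=t,
                            sign=p.sign,
                            alpha_level=level,
                            rule_confidences=p.confidences,
                        )
                    )
        if network_type == 1:
            node_set = set(targets)
        else:
            node_set = set(targets) | {e.regulator for e in edges}
        nodes = {g: annotations.get(g, "unclassified") for g in sorted(node_set)}
        networks.append(
            GeneNetwork(nodes=nodes, edges=tuple(edges), alpha=alpha, network_type=network_type)
        )
    return networks


class GRNInferencer(BaseEstimator):
    """Sklearn-style estimator inferring signed regulatory networks.

    ``fit(X, y)`` takes a samples × genes expression frame and binary class
    labels, picks the identified genes (explicit ``targets`` or the genes
    with γ(class, selection_alpha) = 1), and builds one network per sweep α.

    Attributes
    ----------
    networks_ : list[GeneNetwork]
        One per α, descending.
    targets_ : list[str]
        The identified genes used as decision attributes.
    annotations_ : dict[str, str]
        Gene → 'up' / 'down' / 'unclassified' in the positive class.
    """

    def __init__(
        self,
        alphas: Sequence[float] = (1.0, 0.95, 0.9, 0.85, 0.8, 0.75, 0.7),
        network_type: int = 1,
        targets: Sequence[str] | None = None,
        positive_class: str | None = None,
        selection_alpha: float = 0.9,
        strict_direction: bool = False,
        multi_interval: str = "suppress",
        on_unbinarizable: str = "raise",
    ):
        self.alphas = alphas
        self.network_type = network_type
        self.targets = targets
        self.positive_class = positive_class
        self.selection_alpha = selection_alpha
        self.strict_direction = strict_direction
        self.multi_interval = multi_interval
        self.on_unbinarizable = on_unbinarizable

    def fit(self, X, y):
        from .rules import select_genes

        X = MDLPDiscretizer._as_frame(X)
        y = np.asarray(y).astype(str)
        data = X.copy()
        data["__class__"] = y
        table = DecisionTable(data=data, decision_attribute="__class__")
        if self.targets is not None:
            targets = [str(t) for t in self.targets]
        else:
            disc, _ = discretize_table(table)
            targets = [
                g
                for g, degen in select_genes(disc, self.selection_alpha, with_flags=True)
                if not degen
            ]
            if not targets:
                raise ValueError(
                    f"no gene reaches gamma=1 at selection_alpha={self.selection_alpha}; "
                    "lower selection_alpha or pass targets explicitly"
                )
        self.targets_ = targets
        self.networks_ = build_network(
            table,
            targets=targets,
            candidates=None,
            alphas=self.alphas,
            network_type=self.network_type,
            positive_class=self.positive_class,
            strict_direction=self.strict_direction,
            multi_interval=self.multi_interval,
            on_unbinarizable=self.on_unbinarizable,
        )
        self.annotations_ = dict(self.networks_[0].nodes) if self.networks_ else {}
        return self

    def predict(self, X=None) -> list[GeneNetwork]:
        return self.networks_


# -- exporters -------------------------------------------------------------


def edges_to_tsv(edges: Iterable[SignedEdge], path) -> None:
    pd.DataFrame(
        [
            {
                "regulator": e.regulator,
                "target": e.target,
                "sign": e.sign,
                "alpha_level": e.alpha_level,
                "confidences": ";".join(f"{c:g}" for c in e.rule_confidences),
            }
            for e in edges
        ],
        columns=["regulator", "target", "sign", "alpha_level", "confidences"],
    ).to_csv(path, sep="\t", index=False)


def edges_from_tsv(path) -> list[SignedEdge]:
    df = pd.read_csv(path, sep="\t", dtype={"regulator": str, "target": str})
    out = []
    for row in df.itertuples(index=False):
        confs = tuple(
            float(c) for c in str(row.confidences).split(";") if c and c != "nan"
        )
        out.append(
            SignedEdge(
                regulator=row.regulator,
                target=row.target,
                sign=int(row.sign),
                alpha_level=float(row.alpha_level) if pd.notna(row.alpha_level) else None,
                rule_confidences=confs,
            )
        )
    return out


def networks_from_edges(
    edges: Iterable[SignedEdge],
    nodes: Mapping[str, str],
    alphas: Sequence[float],
    network_type: int = 1,
) -> list[GeneNetwork]:
    """Rebuild the per-α nested networks from a flat alpha-leveled edge list."""
    edges = list(edges)
    out = []
    for alpha in sorted(alphas, reverse=True):
        sub = tuple(e for e in edges if e.alpha_level is not None and e.alpha_level >= alpha)
        out.append(GeneNetwork(nodes=dict(nodes), edges=sub, alpha=alpha, network_type=network_type))
    return out


def to_sif(network: GeneNetwork, path) -> None:
    """Cytoscape SIF: ``regulator activates|represses target`` per line."""
    with open(path, "w") as fh:
        for e in network.edges:
            verb = "activates" if e.sign > 0 else "represses"
            fh.write(f"{e.regulator}\t{verb}\t{e.target}\n")


def to_graphml(network: GeneNetwork, path) -> None:
    g = nx.DiGraph()
    for node, ann in network.nodes.items():
        g.add_node(node, regulation=ann)
    for e in network.edges:
        g.add_edge(
            e.regulator,
            e.target,
            sign=e.sign,
            alpha_level=float(e.alpha_level) if e.alpha_level is not None else float("nan"),
        )
    nx.write_graphml(g, path)
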
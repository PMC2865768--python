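from collections import defaultdict

import numpy as np
import pandas as pd
import pytest

from conftest import random_discrete_table
from grnrules.decision_table import DecisionTable, partition
from grnrules.rules import (
    AlphaRuleClassifier,
    DecisionRule,
    alpha_depended_degree,
    alpha_positive_region,
    classify,
    induce_rules,
    loocv,
    select_genes,
)

ALPHAS = (0.7, 0.75, 0.8, 0.85, 0.9, 0.95, 1.0)


# -- brute-force oracle straight from the set-theoretic definitions


def oracle_gamma(table, attrs, alpha):
    blocks = defaultdict(set)
    for s in table.samples:
        blocks[tuple(table.data.loc[s, a] for a in attrs)].add(s)
    dblocks = defaultdict(set)
    for s in table.samples:
        dblocks[table.data.loc[s, table.decision_attribute]].add(s)
    pos = set()
    for Y in blocks.values():
        for X in dblocks.values():
            if len(Y & X) / len(Y) >= alpha:
                pos |= Y
    return len(pos) / table.n_samples, frozenset(pos)


def oracle_rules(table, g, alpha):
    blocks = defaultdict(set)
    for s in table.samples:
        blocks[table.data.loc[s, g]].add(s)
    out = set()
    for interval, Y in blocks.items():
        for d in set(table.decision_values):
            X = {s for s in Y if table.data.loc[s, table.decision_attribute] == d}
            if len(X) / len(Y) >= alpha:
                out.add((str(interval), str(d), len(Y), len(X)))
    return out


class TestPositiveRegionAndGamma:
    def test_worked_two_block_example(self, two_block_table):
        t = two_block_table
        res = alpha_depended_degree(t, ["g"], 0.8)
        assert res.gamma == pytest.approx(0.6)  # only the 5/6 block passes
        assert res.positive_region == frozenset(f"s{i}" for i in range(6))
        assert alpha_depended_degree(t, ["g"], 0.75).gamma == pytest.approx(1.0)

    def test_alpha_one_is_classical_set_inclusion(self, two_block_table):
        res = alpha_depended_degree(two_block_table, ["g"], 1.0)
        assert res.gamma == 0.0
        # a pure table reaches gamma 1 at alpha 1
        df = pd.DataFrame({"g": list("llhh"), "D": list("aabb")}, index=list("wxyz"))
        t = DecisionTable(data=df, decision_attribute="D")
        assert alpha_depended_degree(t, ["g"], 1.0).gamma == 1.0

    def test_single_balanced_block_is_empty_at_high_alpha(self):
        df = pd.DataFrame(
            {"g": ["All"] * 10, "D": ["T"] * 5 + ["N"] * 5},
            index=[f"s{i}" for i in range(10)],
        )
        t = DecisionTable(data=df, decision_attribute="D")
        part = partition(t, ["g"])
        dpart = partition(t, ["D"])
        assert alpha_positive_region(part, dpart, 0.8) == frozenset()

    def test_mismatched_universes_rejected(self, two_block_table):
        part = partition(two_block_table, ["g"])
        df = pd.DataFrame({"D": ["a", "b"]}, index=["u1", "u2"])
        other = partition(DecisionTable(data=df, decision_attribute="D"), ["D"])
        with pytest.raises(ValueError, match="universes"):
            alpha_positive_region(part, other, 0.8)

    def test_alpha_outside_half_one_rejected(self, two_block_table):
        for bad in (0.5, 0.4, 1.01, 0.0):
            with pytest.raises(ValueError, match="alpha"):
                alpha_depended_degree(two_block_table, ["g"], bad)

    def test_gamma_matches_bruteforce_oracle_on_random_tables(self, rng):
        for _ in range(500):
            t = random_discrete_table(rng)
            attrs = list(
                rng.choice(t.condition_attributes,
                           size=int(rng.integers(1, len(t.condition_attributes) + 1)),
                           replace=False)
            )
            for alpha in ALPHAS:
                expect_gamma, expect_pos = oracle_gamma(t, attrs, alpha)
                res = alpha_depended_degree(t, attrs, alpha)
                assert res.gamma == pytest.approx(expect_gamma)
                assert res.positive_region == expect_pos

    def test_gamma_monotone_in_alpha(self, rng):
        for _ in range(100):
            t = random_discrete_table(rng)
            g = [t.condition_attributes[0]]
            gammas = [alpha_depended_degree(t, g, a).gamma for a in ALPHAS]
            assert all(x >= y for x, y in zip(gammas, gammas[1:]))


class TestRuleInduction:
    def test_two_rules_with_confidences(self):
        # low block 96% Down, high block 100% Up
        df = pd.DataFrame(
            {
                "g245": ["(-inf-1048.3779)"] * 25 + ["(1048.3779-inf)"] * 10,
                "g249": ["Down"] * 24 + ["Up"] + ["Up"] * 10,
            },
            index=[f"s{i}" for i in range(35)],
        )
        t = DecisionTable(data=df, decision_attribute="g249")
        rules = induce_rules(t, "g245", 0.95)
        by_interval = {r.interval: r for r in rules}
        assert by_interval["(-inf-1048.3779)"].consequent == "Down"
        assert by_interval["(-inf-1048.3779)"].confidence == pytest.approx(0.96)
        assert by_interval["(1048.3779-inf)"].confidence == pytest.approx(1.0)

    def test_block_below_alpha_yields_no_rule(self, two_block_table):
        rules = induce_rules(two_block_table, "g", 0.8)
        assert [r.interval for r in rules] == ["low"]  # 3/4 block fails at 0.8

    def test_all_attribute_yields_single_majority_rule(self):
        df = pd.DataFrame(
            {"g": ["All"] * 10, "D": ["Tumor"] * 9 + ["Normal"]},
            index=[f"s{i}" for i in range(10)],
        )
        t = DecisionTable(data=df, decision_attribute="D")
        rules = induce_rules(t, "g", 0.8)
        assert len(rules) == 1
        assert rules[0].consequent == "Tumor"
        assert rules[0].confidence == pytest.approx(0.9)

    def test_matches_bruteforce_oracle_on_random_tables(self, rng):
        for _ in range(200):
            t = random_discrete_table(rng)
            g = t.condition_attributes[0]
            for alpha in ALPHAS:
                got = {
                    (r.interval, r.consequent,
                     round(r.support_antecedent * t.n_samples),
                     round(r.confidence * r.support_antecedent * t.n_samples))
                    for r in induce_rules(t, g, alpha)
                }
                assert got == oracle_rules(t, g, alpha)

    def test_rule_confidence_at_least_alpha_and_disjoint_antecedents(self, rng):
        for _ in range(100):
            t = random_discrete_table(rng)
            g = t.condition_attributes[0]
            rules = induce_rules(t, g, 0.7)
            assert all(r.confidence >= 0.7 for r in rules)
            assert len({r.interval for r in rules}) == len(rules)


class TestSelectGenes:
    def test_perfect_marker_selected_at_alpha_one(self):
        df = pd.DataFrame(
            {"m": ["low"] * 5 + ["high"] * 5, "b": ["All"] * 10,
             "D": ["T"] * 5 + ["N"] * 5},
            index=[f"s{i}" for i in range(10)],
        )
        t = DecisionTable(data=df, decision_attribute="D")
        assert select_genes(t, 1.0) == ["m"]

    def test_selection_threshold_between_085_and_095(self):
        # blocks 85% and 90% pure: selected at 0.85, not at 0.95
        g = ["low"] * 20 + ["high"] * 20
        d = (["T"] * 17 + ["N"] * 3) + (["N"] * 18 + ["T"] * 2)
        df = pd.DataFrame({"g": g, "D": d}, index=[f"s{i}" for i in range(40)])
        t = DecisionTable(data=df, decision_attribute="D")
        assert select_genes(t, 0.85) == ["g"]
        assert select_genes(t, 0.95) == []

    def test_degenerate_all_gene_flagged(self):
        df = pd.DataFrame(
            {"g": ["All"] * 10, "D": ["T"] * 9 + ["N"]},
            index=[f"s{i}" for i in range(10)],
        )
        t = DecisionTable(data=df, decision_attribute="D")
        assert select_genes(t, 0.9, with_flags=True) == [("g", True)]
        assert select_genes(t, 0.95) == []


class TestClassifierAndLoocv:
    def test_classify_fires_matching_rule_and_abstains(self):
        rules = [
            DecisionRule("g249", "(-inf-1696.2275)", "Tumor", 0.6, 0.89),
            DecisionRule("g249", "(1696.2275-inf)", "Normal", 0.4, 0.86),
        ]
        assert classify(rules, {"g249": "(-inf-1696.2275)"}) == "Tumor"
        assert classify(rules, {"g249": "(1696.2275-inf)"}) == "Normal"
        assert classify(rules, {"other": "All"}) is None

    def test_conflicts_resolved_by_confidence(self):
        rules = [
            DecisionRule("a", "x", "N", 0.5, 0.8),
            DecisionRule("b", "y", "T", 0.5, 0.9),
        ]
        assert classify(rules, {"a": "x", "b": "y"}) == "T"

    def test_separable_marker_has_perfect_loocv(self):
        rng = np.random.default_rng(0)
        cls = np.array(["T"] * 10 + ["N"] * 10)
        vals = np.where(cls == "T", 100.0, 900.0) + rng.normal(0, 10, 20)
        df = pd.DataFrame({"m": vals, "Class": cls}, index=[f"s{i}" for i in range(20)])
        t = DecisionTable(data=df, decision_attribute="Class")
        assert loocv(t, "m", 0.8) == pytest.approx(1.0)

    def test_class_independent_gene_mostly_abstains(self, rng):
        # with abstentions counted as errors an uninformative gene scores near 0
        accs = []
        for seed in range(10):
            r = np.random.default_rng(seed)
            df = pd.DataFrame(
                {"g": r.uniform(0, 1, 20), "Class": ["T", "N"] * 10},
                index=[f"s{i}" for i in range(20)],
            )
            t = DecisionTable(data=df, decision_attribute="Class")
            accs.append(loocv(t, "g", 0.8))
        assert np.mean(accs) <= 0.15

    def test_three_sample_fold_accounting(self):
        # holding out the singleton class leaves a one-class training fold,
        # which counts as an error; the two remaining folds classify correctly
        df = pd.DataFrame(
            {"g": [1.0, 1.0, 9.0], "Class": ["T", "T", "N"]},
            index=["a", "b", "c"],
        )
        t = DecisionTable(data=df, decision_attribute="Class")
        assert loocv(t, "g", 0.8) == pytest.approx(2 / 3)

    def test_estimator_selects_informative_gene_and_predicts(self):
        rng = np.random.default_rng(1)
        cls = np.array(["T"] * 15 + ["N"] * 15)
        X = pd.DataFrame(
            {
                "m": np.where(cls == "T", 100.0, 900.0) + rng.normal(0, 20, 30),
                "junk": rng.uniform(0, 1, 30),
            }
        )
        clf = AlphaRuleClassifier(alpha=0.9).fit(X, cls)
        assert clf.selected_attributes_ == ["m"]
        assert (clf.predict(X) == cls).mean() >= 0.95
        # sklearn param plumbing
        assert clf.get_params()["alpha"] == 0.9
        clf.set_params(alpha=0.8)
        assert clf.alpha == 0.8
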
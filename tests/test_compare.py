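"""Module comparison: Jaccard matrix, On/conserved labels, Add-modules,
gene-set over-representation."""

import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from dims.compare import (
    classify_modules,
    enrich_gene_sets,
    identify_add_modules,
    module_similarity_matrix,
    on_module_ids,
    read_gmt,
    set_jaccard,
)
from dims.modules import ModulePartition


def partition(assignments: dict[str, int]) -> ModulePartition:
    genes = list(assignments)
    return ModulePartition(genes, np.array(list(assignments.values())),
                           cut_height=0.5, min_module_size=3)


class TestJaccard:
    def test_published_worked_example(self):
        """79 module genes, 336 reference genes, 47 shared -> 47/368 = 0.128."""
        a = {f"m{i}" for i in range(79)}
        b = {f"m{i}" for i in range(47)} | {f"d{i}" for i in range(289)}
        assert len(b) == 336 and len(a & b) == 47
        assert round(set_jaccard(a, b), 3) == 0.128

    def test_identity_disjoint_and_empty(self):
        assert set_jaccard({"a", "b"}, {"a", "b"}) == 1.0
        assert set_jaccard({"a"}, {"b"}) == 0.0
        assert set_jaccard(set(), set()) == 0.0

    @settings(derandomize=True, max_examples=100)
    @given(
        a=st.sets(st.integers(0, 30)),
        b=st.sets(st.integers(0, 30)),
    )
    def test_jaccard_properties(self, a, b):
        j = set_jaccard(a, b)
        assert 0.0 <= j <= 1.0
        assert j == set_jaccard(b, a)
        assert (j == 1.0) == (bool(a) and a == b)
        assert (j == 0.0) == (not a & b)


class TestSimilarityMatrix:
    def test_self_comparison_has_unit_match_per_row(self):
        p = partition({"g1": 1, "g2": 1, "g3": 2, "g4": 2, "g5": 0})
        sim = module_similarity_matrix(p, p)
        assert (sim.s == 1.0).all()
        assert sim.b.loc[1, 1] == 1.0 and sim.b.loc[1, 2] == 0.0

    def test_hand_set_arithmetic(self):
        p1 = partition({f"g{i}": 1 for i in range(1, 5)})
        p2 = partition({f"g{i}": 1 for i in range(3, 7)})
        sim = module_similarity_matrix(p1, p2)
        assert sim.b.loc[1, 1] == pytest.approx(2 / 6)

    def test_matches_brute_force_and_transposes(self):
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(30)]
        p1 = partition(dict(zip(genes, rng.integers(0, 4, 30))))
        p2 = partition(dict(zip(genes, rng.integers(0, 3, 30))))
        sim = module_similarity_matrix(p1, p2)
        back = module_similarity_matrix(p2, p1)
        pd.testing.assert_frame_equal(sim.b, back.b.T)
        for i in p1.module_ids:
            for j in p2.module_ids:
                mi, mj = p1.members(i), p2.members(j)
                assert sim.b.loc[i, j] == len(mi & mj) / len(mi | mj)

    def test_empty_partition_rejected(self):
        good = partition({"g1": 1, "g2": 1, "g3": 1})
        empty = partition({"g1": 0, "g2": 0, "g3": 0})
        with pytest.raises(ValueError, match="proper module"):
            module_similarity_matrix(good, empty)


class FakeSim:
    """Similarity matrix stub with a fixed score vector."""

    def __init__(self, s):
        self.b = pd.DataFrame({1: list(s)}, index=range(1, len(s) + 1)).astype(float)
        self.s = pd.Series(list(s), index=range(1, len(s) + 1), dtype=float)


class TestClassification:
    def test_threshold_arithmetic_at_published_theta(self):
        cls = classify_modules(FakeSim([0.05, 0.50, 0.95]), 0.1, 0.1)
        labels = {c.module_id: c.label for c in cls}
        assert labels == {1: "on-module", 2: "intermediate", 3: "conserved"}

    def test_equal_scores_are_all_ambiguous_with_warning(self):
        with pytest.warns(UserWarning, match="ambiguous"):
            cls = classify_modules(FakeSim([0.4, 0.4, 0.4]), 0.1, 0.1)
        assert all(c.label == "ambiguous" for c in cls)

    def test_strict_inequalities_at_zero_theta(self):
        cls = classify_modules(FakeSim([0.2, 0.8]), 0.0, 0.0)
        assert all(c.label == "intermediate" for c in cls)

    def test_each_module_gets_exactly_one_label(self):
        rng = np.random.default_rng(5)
        cls = classify_modules(FakeSim(rng.uniform(size=12)), 0.1, 0.1)
        assert len(cls) == 12
        on = {c.module_id for c in cls if c.label == "on-module"}
        cm = {c.module_id for c in cls if c.label == "conserved"}
        assert not on & cm


class TestAddModules:
    @staticmethod
    def cls_with_on(part, on: set[int]):
        sim = FakeSim([0.05 if m in on else 0.9 for m in part.module_ids])
        sim.s.index = part.module_ids
        sim.b.index = part.module_ids
        return classify_modules(sim, 0.1, 0.1)

    def make_partition(self):
        return partition({f"g{i}": 1 + i // 5 for i in range(40)})  # modules 1..8

    def test_intersection_of_on_labels(self):
        part = self.make_partition()
        cls_a = self.cls_with_on(part, {4, 7})
        cls_b = self.cls_with_on(part, {4})
        res = identify_add_modules({1, 4}, cls_a, cls_b, part)
        assert res.add_modules == {4}
        assert res.gene_lists[4] == sorted(part.members(4))

    def test_empty_when_one_side_has_no_on_modules(self):
        part = self.make_partition()
        res = identify_add_modules(
            {1, 4}, self.cls_with_on(part, set()), self.cls_with_on(part, {4}), part
        )
        assert res.add_modules == set()

    def test_unknown_module_id_rejected(self):
        part = self.make_partition()
        cls = self.cls_with_on(part, {4})
        with pytest.raises(ValueError, match="unknown module ids"):
            identify_add_modules({99}, cls, cls, part)

    def test_deg_overlap_statistics(self):
        """79 Add-module genes with 47 in the DEG list -> 59% overlap."""
        part = partition(
            {f"g{i}": 1 for i in range(79)} | {f"h{i}": 2 for i in range(10)}
        )
        cls = classify_modules(FakeSim([0.0, 0.9]), 0.1, 0.1)
        degs = {f"g{i}" for i in range(47)} | {f"x{i}" for i in range(289)}
        res = identify_add_modules({1}, cls, cls, part, degs)
        ov = res.deg_overlap
        assert ov["overlap"] == 47
        assert ov["overlap_pct_of_add_genes"] == 59
        assert round(ov["jaccard"], 3) == 0.128


class TestEnrichment:
    def test_full_overlap_matches_hypergeometric_closed_form(self):
        universe = {f"g{i}" for i in range(100)}
        module = {f"g{i}" for i in range(10)}
        table = enrich_gene_sets(module, universe, {"set": set(module)})
        assert table["p"].iloc[0] == pytest.approx(1 / comb(100, 10), rel=1e-9)

    def test_independent_overlap_is_not_significant(self):
        universe = {f"g{i}" for i in range(200)}
        module = {f"g{i}" for i in range(100)}
        geneset = {f"g{i}" for i in range(50, 150)}  # overlap 50 = expectation
        table = enrich_gene_sets(module, universe, {"s": geneset})
        assert table["p"].iloc[0] > 0.4
        assert not table["significant"].iloc[0]

    def test_bh_adjustment_matches_direct_step_up(self):
        """Adjusted p equals an independently coded BH step-up."""
        universe = {f"g{i}" for i in range(1000)}
        module = set(itertools.islice(universe, 40))
        # three sets engineered to give increasing p; check BH against a
        # direct step-up computation rather than fixed constants
        rng = np.random.default_rng(1)
        sets = {
            f"s{j}": set(rng.choice(sorted(universe), size=60, replace=False))
            for j in range(3)
        }
        table = enrich_gene_sets(module, universe, sets)
        p = table["p"].to_numpy()
        m = len(p)
        stepup = np.minimum.accumulate((p * m / np.arange(1, m + 1))[::-1])[::-1]
        np.testing.assert_allclose(table["p_adjusted"], np.minimum(stepup, 1.0))
        assert (table["p_adjusted"] >= table["p"] - 1e-15).all()

    def test_fisher_equals_exact_hypergeometric_enumeration(self):
        """One-sided Fisher p equals the hypergeometric tail for all tables
        with small margins."""
        universe = [f"g{i}" for i in range(25)]
        for m_size in (5, 10):
            for s_size in (4, 12):
                for k in range(0, min(m_size, s_size) + 1):
                    module = set(universe[:m_size])
                    geneset = set(universe[m_size - k : m_size - k + s_size])
                    assert len(module & geneset) == k
                    table = enrich_gene_sets(module, set(universe), {"s": geneset})
                    contingency = [
                        [k, s_size - k],
                        [m_size - k, 25 - m_size - s_size + k],
                    ]
                    _, p_fisher = stats.fisher_exact(contingency, alternative="greater")
                    assert table["p"].iloc[0] == pytest.approx(p_fisher, rel=1e-9)

    def test_module_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="subset"):
            enrich_gene_sets({"x"}, {"a", "b"}, {})
        with pytest.raises(ValueError, match="empty"):
            enrich_gene_sets(set(), set(), {})


def test_gmt_parsing(tmp_path):
    path = tmp_path / "sets.gmt"
    path.write_text("pathway_a\tdesc\tg1\tg2\tg3\npathway_b\t\tg2\tg4\n\n")
    collection = read_gmt(path)
    assert collection == {"pathway_a": {"g1", "g2", "g3"}, "pathway_b": {"g2", "g4"}}
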
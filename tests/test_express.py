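"""Expression layer: FPKM, activity threshold, exact DE test, statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from lncwheat import express as E

from oracles import binom_exact_two_sided, n50_oracle


def toy_matrix(counts_dict, lengths, reps=("CK_1", "DS_1")):
    counts = pd.DataFrame(counts_dict, index=list(lengths))
    conditions = {s: ("control" if s.startswith("CK") else "drought")
                  for s in counts.columns}
    return E.ExpressionMatrix(counts=counts, lengths=pd.Series(lengths),
                              conditions=conditions)


class TestFpkm:
    def test_textbook_value(self):
        m = toy_matrix({"CK_1": [10], "DS_1": [0]}, {"t1": 1000})
        m.library_sizes = pd.Series({"CK_1": 1e6, "DS_1": 1e6})
        fpkm = E.compute_fpkm(m)
        assert fpkm.loc["t1", "CK_1"] == pytest.approx(10.0)
        assert fpkm.loc["t1", "DS_1"] == 0.0

    def test_scale_invariance(self, rng):
        counts = pd.DataFrame(rng.integers(0, 500, size=(30, 4)),
                              columns=["CK_1", "CK_2", "DS_1", "DS_2"],
                              index=[f"t{i}" for i in range(30)])
        lengths = pd.Series(rng.integers(200, 3000, size=30),
                            index=counts.index)
        conds = {s: "control" if s.startswith("CK") else "drought" for s in counts}
        m1 = E.ExpressionMatrix(counts=counts, lengths=lengths, conditions=conds)
        m2 = E.ExpressionMatrix(counts=counts * 7, lengths=lengths, conditions=conds)
        pd.testing.assert_frame_equal(E.compute_fpkm(m1), E.compute_fpkm(m2) * 7 / 7,
                                      check_exact=False)
        assert np.allclose(E.compute_fpkm(m1), E.compute_fpkm(m2))

    def test_zero_library_size_rejected(self):
        m = toy_matrix({"CK_1": [0], "DS_1": [1]}, {"t1": 500})
        with pytest.raises(ValueError):
            E.compute_fpkm(m)


class TestThresholdSelection:
    @staticmethod
    def curve_to_fpkm(curve, grid=E.DEFAULT_FPKM_GRID):
        """Build per-condition FPKM values whose failing-percent curve over
        the grid equals ``curve`` (percent, len == len(grid))."""
        n = 100
        vals = []
        prev = 0.0
        # place curve[k]-curve[k-1] transcripts just below grid[k]
        for k, target in enumerate(curve):
            add = int(round(target - prev))
            vals.extend([grid[k] - 0.05] * add)
            prev = target
        vals.extend([grid[-1] + 1.0] * (n - len(vals)))
        arr = np.array(vals)
        return pd.DataFrame({"control": arr, "drought": arr})

    def test_inflection_found_by_second_difference(self):
        curve = [5, 5, 5, 5, 6, 9, 14, 21, 30, 41, 54, 69, 86,
                 100, 100, 100, 100, 100, 100, 100]
        cond = self.curve_to_fpkm(curve)
        # hand check: second differences peak first at index 4 (0.5 FPKM)
        assert E.select_fpkm_threshold(cond) == pytest.approx(0.5)

    def test_linear_curve_falls_back_to_half(self):
        curve = list(range(5, 105, 5))
        cond = self.curve_to_fpkm(curve)
        assert E.select_fpkm_threshold(cond) == 0.5

    def test_failing_curve_is_monotone(self, rng):
        cond = pd.DataFrame({"control": rng.exponential(1.0, 500),
                             "drought": rng.exponential(1.0, 500)})
        grid = E.DEFAULT_FPKM_GRID
        failing = [np.mean((cond.to_numpy() < t).all(axis=1)) for t in grid]
        assert all(a <= b + 1e-12 for a, b in zip(failing, failing[1:]))

    def test_small_grid_rejected(self):
        with pytest.raises(ValueError):
            E.select_fpkm_threshold(pd.DataFrame({"control": [1.0], "drought": [1.0]}),
                                    grid=np.array([0.1, 0.2]))


class TestActiveSets:
    def test_zero_threshold_keeps_everything(self, rng):
        cond = toy_matrix({"CK_1": [5, 0, 3], "DS_1": [0, 2, 3]},
                          {"a": 300, "b": 400, "c": 500})
        sets = E.active_sets(cond, threshold=0.0)
        assert all(len(s) == 3 for s in sets["per_sample"].values())

    def test_partition_covers_all_transcripts(self):
        m = toy_matrix({"CK_1": [50, 0, 30, 0], "DS_1": [0, 40, 30, 0]},
                       {"a": 300, "b": 300, "c": 300, "d": 300})
        spec = E.active_sets(m, threshold=1.0)["specificity"]
        assert spec.value_counts().sum() == 4
        assert spec["a"] == "control_only"
        assert spec["b"] == "drought_only"
        assert spec["c"] == "common"
        assert spec["d"] == "absent"


class TestExactTest:
    def test_balanced_counts_give_null_result(self):
        m = toy_matrix({"CK_1": [50, 1000], "DS_1": [50, 1000]},
                       {"a": 300, "b": 300})
        de = E.exact_de_test(m, dispersion=0.0)
        assert de.loc["a", "log2fc"] == pytest.approx(0.0)
        assert de.loc["a", "p_value"] == pytest.approx(1.0)

    def test_label_swap_negates_log2fc_keeps_p(self):
        m1 = toy_matrix({"CK_1": [80, 100], "DS_1": [20, 100]}, {"a": 300, "b": 300})
        m2 = toy_matrix({"CK_1": [20, 100], "DS_1": [80, 100]}, {"a": 300, "b": 300})
        d1 = E.exact_de_test(m1, dispersion=0.1)
        d2 = E.exact_de_test(m2, dispersion=0.1)
        assert d1.loc["a", "log2fc"] == pytest.approx(-d2.loc["a", "log2fc"])
        assert d1.loc["a", "p_value"] == pytest.approx(d2.loc["a", "p_value"])

    def test_dispersion_zero_matches_binomial_enumeration(self):
        # all (k, n-k) splits for n <= 30, equal library sizes forced
        for n in (1, 2, 5, 11, 17, 30):
            for k in range(n + 1):
                m = toy_matrix({"CK_1": [k, 500], "DS_1": [n - k, 500]},
                               {"a": 300, "pad": 300})
                m.library_sizes = pd.Series({"CK_1": 1000.0, "DS_1": 1000.0})
                de = E.exact_de_test(m, dispersion=0.0)
                expected = binom_exact_two_sided(k, n, 0.5)
                assert de.loc["a", "p_value"] == pytest.approx(expected, rel=1e-9)

    def test_three_conditions_rejected(self):
        counts = pd.DataFrame({"CK_1": [1], "DS_1": [1]}, index=["a"])
        m = E.ExpressionMatrix(counts=counts, lengths=pd.Series({"a": 300}),
                               conditions={"CK_1": "control", "DS_1": "heat"})
        with pytest.raises(ValueError):
            E.exact_de_test(m)

    def test_status_requires_both_cutoffs(self):
        # strong p but tiny fold change (just above/below lfc boundary)
        m = toy_matrix({"CK_1": [4000, 1000], "DS_1": [6000, 1000]},
                       {"a": 300, "b": 300})
        de = E.exact_de_test(m, dispersion=0.0, alpha=0.001, lfc_min=2)
        assert de.loc["a", "p_value"] < 0.001
        assert de.loc["a", "status"] == "ns"  # |log2fc| < 2


class TestBH:
    def test_single_p_unchanged(self):
        assert E.bh_adjust([0.04])[0] == pytest.approx(0.04)

    def test_hand_computed_example(self):
        np.testing.assert_allclose(E.bh_adjust([0.01, 0.02, 0.03]),
                                   [0.03, 0.03, 0.03])

    @given(st.lists(st.floats(min_value=1e-9, max_value=1.0), min_size=1, max_size=40))
    def test_q_at_least_p_and_capped(self, ps):
        q = E.bh_adjust(ps)
        assert (q >= np.asarray(ps) - 1e-12).all()
        assert (q <= 1.0).all()


class TestGenotypeComparison:
    def test_identical_sequence_is_common(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=300))
        labels = E.common_across_genotypes({"q": seq}, {"s": seq})
        assert labels["q"] == "common"

    def test_diverged_sequence_is_specific(self, rng):
        seq = list("".join(rng.choice(list("ACGT"), size=300)))
        other = list(seq)
        for pos in rng.choice(300, size=75, replace=False):  # ~75% identity
            other[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[other[pos]]
        labels = E.common_across_genotypes({"q": "".join(seq)}, {"s": "".join(other)},
                                           min_identity=80, min_coverage=80)
        assert labels["q"] == "specific"

    def test_empty_reference_set(self):
        labels = E.common_across_genotypes({"q": "ACGTACGT"}, {})
        assert (labels == "specific").all()


class TestAssemblyStats:
    def test_sorted_cumulative_example(self):
        seqs = {f"c{i}": "A" * L for i, L in enumerate([4, 3, 3, 2, 2, 2])}
        st_ = E.assembly_stats(seqs)
        assert st_.n50 == 3
        assert st_.n_transcripts == 6

    def test_single_contig(self):
        st_ = E.assembly_stats({"c": "A" * 777})
        assert st_.n50 == 777 and st_.median_len == 777

    def test_gc_percent(self):
        assert E.assembly_stats({"c": "GGCCATAT"}).gc_percent == pytest.approx(50.0)

    def test_n50_matches_oracle_on_random_multisets(self, rng):
        for _ in range(20):
            lens = rng.integers(100, 5000, size=int(rng.integers(3, 60)))
            seqs = {f"c{i}": "A" * L for i, L in enumerate(lens)}
            assert E.assembly_stats(seqs).n50 == n50_oracle(lens)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            E.assembly_stats({})

    def test_n50_weighted_half_invariant(self, rng):
        lens = rng.integers(100, 5000, size=40)
        seqs = {f"c{i}": "A" * L for i, L in enumerate(lens)}
        n50 = E.assembly_stats(seqs).n50
        assert sum(L for L in lens if L >= n50) >= lens.sum() / 2


class TestCharacterize:
    def test_gc_extremes(self):
        seqs = {"a": "ATAT", "b": "GGCC"}
        classes = pd.Series({"a": "lncRNA", "b": "lncRNA"})
        out = E.characterize(seqs, classes)
        assert out.loc["lncRNA", "min_gc"] == 0.0
        assert out.loc["lncRNA", "max_gc"] == 100.0

    def test_class_means_match_direct_loop(self, small_dataset):
        transcripts, truth = small_dataset
        seqs = {t.id: t.sequence for t in transcripts}
        out = E.characterize(seqs, truth.transcripts["true_class"])
        for cls in out.index:
            ids = truth.transcripts.index[truth.transcripts["true_class"] == cls]
            manual = np.mean([len(seqs[i]) for i in ids])
            assert out.loc[cls, "mean_len"] == pytest.approx(manual)


@pytest.mark.parametrize("dct,expected", [(0.0, 1.0), (1.0, 0.5), (-2.0, 4.0)])
def test_relative_expression(dct, expected):
    assert E.relative_expression(20.0 + dct, 20.0) == pytest.approx(expected)
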
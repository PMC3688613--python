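"""Cross-criterion congruence and the neighborhood effect test."""

import numpy as np
import pandas as pd
import pytest

from matenet.congruence import (allospecific_fraction, congruence_glm,
                                congruence_summary, harmonize_labels)


def table(rows, criteria=("interfertility", "genotype", "morphology")):
    return pd.DataFrame(rows, columns=list(criteria),
                        index=[f"t{i}" for i in range(len(rows))])


class TestHarmonize:
    def test_identity_when_already_aligned(self):
        t = table([["S1", "S1", "S1"], ["S2", "S2", "S2"]])
        pd.testing.assert_frame_equal(harmonize_labels(t, reference="genotype"), t)

    def test_swapped_criterion_restored(self):
        t = table([["S2", "S1", "S1"], ["S1", "S2", "S2"], ["intermediate", "S1", "S1"]])
        h = harmonize_labels(t, reference="genotype")
        assert list(h["interfertility"]) == ["S1", "S2", "intermediate"]

    def test_optimal_pairing_at_least_half_agreement(self, rng):
        ref = pd.Series(rng.choice(["S1", "S2"], size=200))
        other = pd.Series(rng.choice(["S1", "S2"], size=200))
        t = pd.DataFrame({"genotype": ref, "other": other})
        h = harmonize_labels(t, reference="genotype")
        assert (h["genotype"] == h["other"]).mean() >= 0.5

    def test_degenerate_overlap_errors(self):
        t = table([["intermediate", "S1", "S1"]])
        with pytest.raises(ValueError, match="overlap"):
            harmonize_labels(t, reference="genotype")


class TestSummary:
    def test_all_consistent(self):
        t = table([["S1"] * 3, ["S2"] * 3, ["S1"] * 3])
        rep = congruence_summary(t)
        assert rep.consistent_counts == {"S1": 2, "S2": 1}
        assert rep.n_inversions == 0 and rep.n_discrepant == 0

    def test_single_inversion_row(self):
        rep = congruence_summary(table([["S1", "S2", "S1"]]))
        assert rep.n_inversions == 1
        assert rep.frac_discrepancies_from_intermediates == 0.0

    def test_intermediate_driven_discrepancies(self):
        t = table([
            ["S1", "S1", "S1"],
            ["intermediate", "S1", "S1"],
            ["S2", "S1", "intermediate"],  # pure conflict AND intermediate
        ])
        rep = congruence_summary(t)
        assert rep.n_discrepant == 2
        assert rep.n_inversions == 1
        assert rep.n_intermediate_any == 2
        assert rep.frac_discrepancies_from_intermediates == pytest.approx(0.5)

    def test_counts_partition_complete_rows(self, rng):
        labels = rng.choice(["S1", "S2", "intermediate"], size=(100, 3), p=[0.4, 0.4, 0.2])
        rep = congruence_summary(table(labels.tolist()))
        n_consistent = sum(rep.consistent_counts.values())
        assert n_consistent + rep.n_discrepant == rep.n_complete == 100


class TestAllospecificFraction:
    def test_hand_example_radius_cut(self):
        coords = pd.DataFrame({"x": [0.0, 10.0, 50.0, 100.0], "y": [0.0] * 4},
                              index=["f", "n1", "n2", "n3"])
        labels = pd.Series({"f": "S1", "n1": "S2", "n2": "S1", "n3": "S2"})
        frac = allospecific_fraction(coords, labels, radius=69.0)
        assert frac["f"] == pytest.approx(0.5)

    def test_isolated_focal_undefined(self):
        coords = pd.DataFrame({"x": [0.0, 500.0], "y": [0.0, 0.0]}, index=["a", "b"])
        labels = pd.Series({"a": "S1", "b": "S2"})
        frac = allospecific_fraction(coords, labels, radius=69.0)
        assert np.isnan(frac["a"]) and np.isnan(frac["b"])

    def test_balanced_random_stand_mean_half(self, rng):
        n = 300
        coords = pd.DataFrame({"x": rng.uniform(0, 100, n), "y": rng.uniform(0, 100, n)},
                              index=[f"i{k}" for k in range(n)])
        labels = pd.Series(["S1", "S2"] * (n // 2), index=coords.index)
        frac = allospecific_fraction(coords, labels, radius=1000.0)
        assert frac.mean() == pytest.approx(0.5, abs=0.02)

    def test_invariant_under_species_relabeling(self, rng):
        n = 40
        coords = pd.DataFrame({"x": rng.uniform(0, 50, n), "y": rng.uniform(0, 50, n)},
                              index=[f"i{k}" for k in range(n)])
        labels = pd.Series(rng.choice(["S1", "S2"], n), index=coords.index)
        swapped = labels.map({"S1": "S2", "S2": "S1"})
        a = allospecific_fraction(coords, labels, radius=20.0)
        b = allospecific_fraction(coords, swapped, radius=20.0)
        pd.testing.assert_series_equal(a, b)

    def test_intermediates_excluded(self):
        coords = pd.DataFrame({"x": [0.0, 1.0, 2.0], "y": [0.0] * 3}, index=list("abc"))
        labels = pd.Series({"a": "S1", "b": "intermediate", "c": "S2"})
        frac = allospecific_fraction(coords, labels, radius=10.0)
        assert "b" not in frac.index
        assert frac["a"] == pytest.approx(1.0)


class TestGlm:
    def test_constant_fraction_null_result(self):
        y = pd.Series([0, 1] * 20)
        x = pd.Series([0.3] * 40)
        r = congruence_glm(y, x)
        assert r.lr_chi2 == 0.0 and r.p_value == 1.0

    def test_single_class_outcome_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            congruence_glm(pd.Series([1] * 10), pd.Series(np.linspace(0, 1, 10)))

    def test_strong_effect_detected_with_direction(self, rng):
        n = 300
        x = rng.random(n)
        p = 1 / (1 + np.exp(-(2 - 6 * x)))  # congruence falls with fraction
        y = (rng.random(n) < p).astype(int)
        r = congruence_glm(pd.Series(y), pd.Series(x))
        assert r.slope < 0
        assert r.p_value < 0.01
        assert r.mean_fraction_incongruent > r.mean_fraction_congruent
        assert r.df == 1 and r.reliable

    def test_complete_separation_flagged(self):
        x = pd.Series(np.r_[np.zeros(20), np.ones(20)])
        y = pd.Series(np.r_[np.zeros(20), np.ones(20)].astype(int))
        r = congruence_glm(y, x)
        assert not r.reliable
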
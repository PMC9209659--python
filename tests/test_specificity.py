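import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methsub import specificity as sp
from methsub.types import BetaMatrix, SubtypeAssignment

EPS = sp.EPS


def oracle_entropy(m):
    """Independent H_Q recomputation via scipy's entropy."""
    m = np.asarray(m, float)

    def h(v):
        return stats.entropy(v + EPS, base=2) / np.log2(v.size)

    return min(h(m), h(m.max() + m.min() - m))


class TestSubgroupProfile:
    def test_mean_and_shape(self):
        b = BetaMatrix(pd.DataFrame([[0.2, 0.4, 0.8, 0.6]], index=["cg1"],
                                    columns=["a", "b", "c", "d"]))
        labels = SubtypeAssignment({"a": 1, "b": 1, "c": 2, "d": 2})
        prof = sp.subgroup_mean_profile(b, labels)
        assert prof.shape == (1, 2)
        assert prof.loc["cg1", 1] == pytest.approx(0.3)
        assert prof.loc["cg1", 2] == pytest.approx(0.7)

    def test_sample_order_invariance(self, imputed_cohort, true_labels):
        b = imputed_cohort.beta
        shuffled = BetaMatrix(b.values[list(reversed(b.samples))])
        p1 = sp.subgroup_mean_profile(b, true_labels)
        p2 = sp.subgroup_mean_profile(shuffled, true_labels)
        pd.testing.assert_frame_equal(p1, p2)

    def test_empty_cluster_errors(self):
        b = BetaMatrix(pd.DataFrame([[0.5, 0.5]], index=["cg1"], columns=["a", "b"]))
        with pytest.raises(ValueError):
            sp.subgroup_mean_profile(b, SubtypeAssignment({"a": 1, "b": 3, "c": 2}))


class TestEntropyQ:
    def test_uniform_vector_maximal(self):
        assert sp.entropy_q([0.5, 0.5, 0.5, 0.5]) == pytest.approx(1.0, abs=1e-12)
        assert sp.entropy_q([0.0, 0.0, 0.0]) == pytest.approx(1.0, abs=1e-9)

    def test_reflected_branch_attains_minimum_for_hypo_outlier(self):
        m = np.array([0.9, 0.9, 0.9, 0.1])
        got = sp.entropy_q(m)
        assert got == pytest.approx(oracle_entropy(m), abs=1e-12)
        assert got < 1.0
        assert got == pytest.approx(0.6037, abs=2e-3)

    def test_permutation_invariance(self):
        m = [0.2, 0.5, 0.7, 0.9]
        vals = {round(sp.entropy_q(p), 14) for p in itertools.permutations(m)}
        assert len(vals) == 1

    def test_reflection_symmetry(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            m = rng.uniform(0, 1, 4)
            refl = m.max() + m.min() - m
            assert sp.entropy_q(m) == pytest.approx(sp.entropy_q(refl), abs=1e-12)

    def test_monotone_decrease_as_outlier_grows(self):
        hs = [sp.entropy_q([0.5, 0.5, 0.5, 0.5 + d]) for d in np.arange(0, 0.45, 0.05)]
        assert all(a > b for a, b in zip(hs, hs[1:]))

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            sp.entropy_q([0.5, 1.2, 0.3])


class TestCategoricalSpecificity:
    def test_uniform_gives_all_zero(self):
        _, _, _, cs = sp.categorical_specificity([0.4, 0.4, 0.4, 0.4])
        np.testing.assert_array_equal(cs, 0.0)

    def test_hyper_outlier_flags_only_its_subgroup(self):
        _, _, _, cs = sp.categorical_specificity([0.1, 0.1, 0.1, 0.9])
        assert np.flatnonzero(cs != 0).tolist() == [3]
        assert cs[3] > 0

    def test_hypo_outlier_flips_sign(self):
        _, _, _, cs = sp.categorical_specificity([0.9, 0.9, 0.9, 0.1])
        assert np.flatnonzero(cs != 0).tolist() == [3]
        assert cs[3] < 0

    def test_hyper_hypo_mirror_magnitudes(self):
        _, _, _, hyper = sp.categorical_specificity([0.1, 0.1, 0.1, 0.9])
        _, _, _, hypo = sp.categorical_specificity([0.9, 0.9, 0.9, 0.1])
        assert abs(hyper[3]) == pytest.approx(abs(hypo[3]), abs=1e-12)

    def test_zero_wherever_delta_h_nonpositive(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            m = rng.uniform(0, 1, 4)
            _, _, dh, cs = sp.categorical_specificity(m)
            assert np.all(cs[dh <= 0] == 0)

    def test_needs_three_subgroups(self):
        with pytest.raises(ValueError):
            sp.categorical_specificity([0.1, 0.9])


class TestMarkerCalling:
    def test_planted_profile_recovered(self):
        rows = {"null1": [0.50, 0.52, 0.49, 0.51],
                "hyper3": [0.40, 0.40, 0.80, 0.40],
                "hypo2": [0.60, 0.20, 0.60, 0.60]}
        prof = pd.DataFrame.from_dict(rows, orient="index", columns=[1, 2, 3, 4])
        scores = {s.probe: s for s in sp.call_specific_markers(prof, h_max=0.99)}
        assert scores["null1"].assigned is None
        assert (scores["hyper3"].assigned, scores["hyper3"].direction) == (3, "hyper")
        assert (scores["hypo2"].assigned, scores["hypo2"].direction) == (2, "hypo")

    def test_uniform_profile_yields_no_markers(self):
        prof = pd.DataFrame(0.5, index=[f"cg{i}" for i in range(5)], columns=[1, 2, 3, 4])
        assert all(s.assigned is None
                   for s in sp.call_specific_markers(prof, h_max=0.99))

    def test_calibration_threshold_separates_null_from_planted(self, imputed_cohort, true_labels):
        h_max = sp.calibrate_h_max(imputed_cohort.beta, true_labels, seed=0)
        prof = sp.subgroup_mean_profile(imputed_cohort.beta, true_labels)
        planted = [sp.entropy_q(prof.loc[p].to_numpy())
                   for p in imputed_cohort.truth.specific_probes]
        assert max(planted) < h_max < 1.0

    def test_requires_calibration_inputs_when_no_threshold(self):
        prof = pd.DataFrame(0.5, index=["cg0"], columns=[1, 2, 3, 4])
        with pytest.raises(ValueError, match="calibration"):
            sp.call_specific_markers(prof)
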
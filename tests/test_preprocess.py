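import numpy as np
import pandas as pd
import pytest

from methsub import preprocess as pp
from methsub.types import BetaMatrix, ExprMatrix, ProbeAnnotation


def _beta(arr, probes=None, samples=None):
    arr = np.asarray(arr, dtype=float)
    probes = probes or [f"cg{i}" for i in range(arr.shape[0])]
    samples = samples or [f"S{j}" for j in range(arr.shape[1])]
    return BetaMatrix(pd.DataFrame(arr, index=probes, columns=samples))


class TestNormalizeExpression:
    def test_zero_replacement_then_log2(self):
        m = ExprMatrix(pd.DataFrame([[0.0, 4.0], [2.0, 8.0]],
                                    index=["g1", "g2"], columns=["S1", "S2"]))
        out = pp.normalize_expression(m)
        # min positive value is 2, so the zero becomes 2 -> log2 gives 1
        np.testing.assert_allclose(out.values.to_numpy(), [[1, 2], [1, 3]])
        assert out.log2

    def test_all_ones_maps_to_zero(self):
        m = ExprMatrix(pd.DataFrame(np.ones((3, 2))))
        assert (pp.normalize_expression(m).values.to_numpy() == 0).all()

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="minimum positive"):
            pp.normalize_expression(ExprMatrix(pd.DataFrame(np.zeros((2, 2)))))

    def test_idempotent_on_normalized(self):
        m = pp.normalize_expression(ExprMatrix(pd.DataFrame([[1.0, 4.0]])))
        assert pp.normalize_expression(m) is m


class TestMissingFilter:
    def test_strict_greater_than_boundary(self):
        row_8 = [np.nan] * 8 + [0.5, 0.5]   # 0.8 missing -> removed
        row_7 = [np.nan] * 7 + [0.5, 0.5, 0.5]  # exactly 0.7 -> retained
        full = [0.5] * 10
        m = _beta([row_8, row_7, full])
        out = pp.filter_missing_probes(m, 0.70)
        assert out.probes == ["cg1", "cg2"]
        assert out.samples == m.samples


class TestKnnImpute:
    def test_hand_example_mean_of_two_nearest(self):
        m = _beta([[np.nan, 0.5, 0.5],
                   [0.2, 0.5, 0.5],
                   [0.4, 0.5, 0.5],
                   [0.9, 0.9, 0.9]])
        out = pp.knn_impute(m, k=2)
        assert out.values.iloc[0, 0] == pytest.approx(0.3, abs=1e-12)

    def test_no_missing_is_identity(self):
        m = _beta([[0.1, 0.2], [0.3, 0.4]])
        assert pp.knn_impute(m, k=1) is m

    def test_imputed_values_bounded_by_donors(self):
        rng = np.random.default_rng(5)
        arr = rng.random((40, 12))
        mask = rng.random((40, 12)) < 0.1
        arr2 = arr.copy()
        arr2[mask] = np.nan
        out = pp.knn_impute(_beta(arr2), k=5).values.to_numpy()
        assert not np.isnan(out).any()
        assert out.min() >= 0 and out.max() <= 1
        # observed entries untouched
        np.testing.assert_array_equal(out[~mask], arr[~mask])

    def test_no_shared_sample_errors(self):
        m = _beta([[0.1, np.nan], [np.nan, 0.2]])
        with pytest.raises(ValueError, match="lower k|no donor"):
            pp.knn_impute(m, k=1)

    def test_idempotent(self):
        m = _beta([[np.nan, 0.5], [0.2, 0.5], [0.4, 0.6]])
        once = pp.knn_impute(m, k=2)
        assert pp.knn_impute(once, k=2) is once


class TestBlacklistAndPromoter:
    ANN = [
        ProbeAnnotation("cgA", "chrX", 9500, "+", "G1", 10000),
        ProbeAnnotation("cgB", "chr2", 9500, "+", "G2", 10000),
        ProbeAnnotation("cgC", "chr3", 9500, "+", "G3", 10000, blacklisted=True),
    ]

    def test_sex_chromosome_and_flagged_removed(self):
        m = _beta(np.full((3, 2), 0.5), probes=["cgA", "cgB", "cgC"])
        out = pp.remove_blacklisted(m, self.ANN)
        assert out.probes == ["cgB"]

    def test_unannotated_probe_errors(self):
        m = _beta([[0.5]], probes=["cgZ"])
        with pytest.raises(ValueError, match="cgZ"):
            pp.remove_blacklisted(m, self.ANN)

    @pytest.mark.parametrize("strand,pos,kept", [
        ("+", 9500, True),    # 500 bp upstream
        ("+", 10600, False),  # 600 bp downstream, window is 500
        ("+", 8000, True),    # upstream boundary, closed
        ("+", 10500, False),  # downstream boundary, half-open
        ("-", 11500, True),   # 1500 bp upstream on - strand
        ("-", 9400, False),   # 600 bp downstream on - strand
        ("-", 12000, True),   # upstream boundary, closed
        ("-", 9500, False),   # downstream boundary, half-open
    ])
    def test_promoter_window_strand_relative(self, strand, pos, kept):
        ann = [ProbeAnnotation("cg1", "chr1", pos, strand, "G", 10000)]
        m = _beta([[0.5]], probes=["cg1"])
        out = pp.filter_promoter_probes(m, ann, up=2000, down=500)
        assert (out.probes == ["cg1"]) == kept
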
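import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from methsub import integrate as mi
from methsub.types import BetaMatrix, DiffResult, ExprMatrix, ProbeAnnotation


class TestPearson:
    def test_perfect_correlations(self):
        assert mi.pearson([1, 2, 3], [3, 2, 1])[0] == pytest.approx(-1.0)
        assert mi.pearson([1, 2, 3], [1, 2, 3])[0] == pytest.approx(1.0)

    def test_four_point_example_exact(self):
        # sum dx*dy = -2.15, sum dx^2 = 0.25, sum dy^2 = 18.75
        x = [0.1, 0.4, 0.5, 0.8]
        y = [8.0, 6.0, 5.0, 2.0]
        r, p = mi.pearson(x, y)
        assert r == pytest.approx(-2.15 / np.sqrt(0.25 * 18.75), abs=1e-12)
        assert r == pytest.approx(-0.993, abs=5e-4)
        # independent route: scipy's implementation
        r_sp, p_sp = stats.pearsonr(x, y)
        assert r == pytest.approx(r_sp, abs=1e-12)
        assert p == pytest.approx(p_sp, rel=1e-9)

    @given(st.lists(st.floats(-50, 50), min_size=4, max_size=12),
           st.floats(0.1, 5), st.floats(-10, 10))
    @settings(max_examples=50, deadline=None)
    def test_affine_invariance_and_sign_flip(self, xs, a, b):
        x = np.asarray(xs)
        rng = np.random.default_rng(0)
        y = x + rng.normal(0, 1, size=x.size)
        if x.std(ddof=1) == 0 or y.std(ddof=1) == 0:
            return
        r0, _ = mi.pearson(x, y)
        assert mi.pearson(a * x + b, y)[0] == pytest.approx(r0, abs=1e-9)
        assert mi.pearson(-a * x + b, y)[0] == pytest.approx(-r0, abs=1e-9)
        assert mi.pearson(y, x)[0] == pytest.approx(r0, abs=1e-12)

    def test_errors(self):
        with pytest.raises(ValueError, match="zero-variance"):
            mi.pearson([1, 1, 1], [1, 2, 3])
        with pytest.raises(ValueError, match="mismatch"):
            mi.pearson([1, 2, 3], [1, 2])
        with pytest.raises(ValueError, match="n >= 3"):
            mi.pearson([1, 2], [3, 4])


def _tiny_setup():
    """Two probes on two genes; probe cg1 anti-correlates with g1."""
    samples = [f"S{i}" for i in range(12)]
    rng = np.random.default_rng(4)
    beta1 = rng.uniform(0.1, 0.9, 12)
    beta2 = rng.uniform(0.1, 0.9, 12)
    e1 = 8 - 4 * beta1 + rng.normal(0, 0.1, 12)
    e2 = rng.normal(8, 1, 12)
    b = BetaMatrix(pd.DataFrame([beta1, beta2], index=["cg1", "cg2"], columns=samples))
    e = ExprMatrix(pd.DataFrame([e1, e2], index=["g1", "g2"], columns=samples), log2=True)
    ann = [ProbeAnnotation("cg1", "chr1", 100, "+", "g1", 100),
           ProbeAnnotation("cg2", "chr1", 200, "+", "g2", 200)]
    dm = [DiffResult("cg1", 0.3, 0.001, 0.01, True),
          DiffResult("cg2", 0.3, 0.001, 0.01, True)]
    de = [DiffResult("g1", 2.0, 0.001, 0.01, True),
          DiffResult("g2", 2.0, 0.001, 0.01, True)]
    return b, e, ann, dm, de


def test_selects_planted_negative_pair_only():
    b, e, ann, dm, de = _tiny_setup()
    pairs = mi.select_regulatory_cpgs(b, e, ann, dm, de)
    assert [(c.probe, c.gene) for c in pairs] == [("cg1", "g1")]
    assert pairs[0].r < 0 and pairs[0].p < 0.05 and pairs[0].n == 12


def test_probe_with_uncalled_gene_never_tested():
    b, e, ann, dm, de = _tiny_setup()
    de = [DiffResult("g1", 2.0, 0.001, 0.01, True),
          DiffResult("g2", 2.0, 0.001, 0.01, False)]
    # make cg2 perfectly anti-correlated with g2: still excluded by the gate
    e.values.loc["g2"] = 8 - 4 * b.values.loc["cg2"]
    pairs = mi.select_regulatory_cpgs(b, e, ann, dm, de)
    assert {c.probe for c in pairs} == {"cg1"}


def test_selection_shrinks_with_stricter_p():
    rng = np.random.default_rng(8)
    n, m = 40, 60
    samples = [f"S{i}" for i in range(n)]
    betas = rng.uniform(0.1, 0.9, (m, n))
    exprs = 8 - 1.0 * betas + rng.normal(0, 1.0, (m, n))
    b = BetaMatrix(pd.DataFrame(betas, index=[f"cg{i}" for i in range(m)], columns=samples))
    e = ExprMatrix(pd.DataFrame(exprs, index=[f"g{i}" for i in range(m)], columns=samples), log2=True)
    ann = [ProbeAnnotation(f"cg{i}", "chr1", i, "+", f"g{i}", i) for i in range(m)]
    dm = [DiffResult(f"cg{i}", 0.3, 0.001, 0.01, True) for i in range(m)]
    de = [DiffResult(f"g{i}", 2.0, 0.001, 0.01, True) for i in range(m)]
    loose = mi.select_regulatory_cpgs(b, e, ann, dm, de, p_max=0.2)
    strict = mi.select_regulatory_cpgs(b, e, ann, dm, de, p_max=0.01)
    assert {c.probe for c in strict} <= {c.probe for c in loose}
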
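"""Tumor-vs-normal differential screens for expression and methylation.

Both screens are a Welch (unequal-variance) two-sample t test with
Benjamini-Hochberg adjustment across all features, combined with an
effect-size gate: |log2 fold change| > log2(fc_min) for genes,
|mean beta difference| > delta_min for probes.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import BetaMatrix, DiffResult, ExprMatrix, SampleMetadata

__all__ = ["diff_expression", "diff_methylation", "results_frame", "called"]


def _split_samples(samples: Sequence[str], meta: Sequence[SampleMetadata]):
    cond = {m.sample: m.condition for m in meta}
    tumor = [s for s in samples if cond.get(s) == "tumor"]
    normal = [s for s in samples if cond.get(s) == "normal"]
    if len(tumor) < 2 or len(normal) < 2:
        raise ValueError(
            f"each condition needs >= 2 samples (tumor={len(tumor)}, normal={len(normal)})"
        )
    return tumor, normal


def _welch_screen(values: pd.DataFrame, tumor, normal,
                  effect_min: float, p_max: float) -> list[DiffResult]:
    t_arr = values[tumor].to_numpy(dtype=float)
    n_arr = values[normal].to_numpy(dtype=float)
    effect = t_arr.mean(axis=1) - n_arr.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        _, p_raw = stats.ttest_ind(t_arr, n_arr, axis=1, equal_var=False)
    p_raw = np.where(np.isnan(p_raw), 1.0, p_raw)  # zero-variance degenerate rows
    _, p_adj, _, _ = multipletests(p_raw, method="fdr_bh")
    passes = (np.abs(effect) > effect_min) & (p_adj < p_max)
    return [
        DiffResult(feature=f, effect=float(e), p_raw=float(pr),
                   p_adj=float(pa), passes=bool(ok))
        for f, e, pr, pa, ok in zip(values.index, effect, p_raw, p_adj, passes)
    ]


def diff_expression(e: ExprMatrix, meta: Sequence[SampleMetadata],
                    fc_min: float = 2.0, q_max: float = 0.05) -> list[DiffResult]:
    """Screen differentially expressed genes on the log2 matrix.

    Effect is the difference of log2 means (log2 of the geometric-mean
    fold change); a gene is called when |effect| > log2(fc_min) and the
    BH-adjusted p is below ``q_max``.
    """
    if not e.log2:
        raise ValueError("diff_expression expects a normalized (log2) matrix")
    tumor, normal = _split_samples(e.samples, meta)
    return _welch_screen(e.values, tumor, normal, np.log2(fc_min), q_max)


def diff_methylation(b: BetaMatrix, meta: Sequence[SampleMetadata],
                     delta_min: float = 0.20, p_max: float = 0.05) -> list[DiffResult]:
    """Screen differentially methylated probes (|mean beta difference| > delta_min,
    BH-adjusted p < p_max). Requires a fully imputed matrix."""
    if b.n_missing:
        raise ValueError("diff_methylation requires an imputed matrix (missing entries present)")
    tumor, normal = _split_samples(b.samples, meta)
    return _welch_screen(b.values, tumor, normal, delta_min, p_max)


def results_frame(results: Sequence[DiffResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.feature, r.effect, r.p_raw, r.p_adj, r.passes) for r in results],
        columns=["feature", "effect", "p_raw", "p_adj", "passes"],
    ).set_index("feature")


def called(results: Sequence[DiffResult]) -> set:
    return {r.feature for r in results if r.passes}
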
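"""Methylation-expression integration.

Promoter methylation typically represses transcription, so the
classification features are the differentially methylated promoter CpGs
whose beta-values correlate *negatively* (r < 0, p < 0.05) with their
gene's log2 expression.

The Pearson coefficient is computed from sample moments,

    r = (1/(n-1)) * sum_i ((x_i - xbar)/s_x) * ((y_i - ybar)/s_y),

with sample standard deviations (n-1 denominator); its p-value uses the
exact transform t = r*sqrt((n-2)/(1-r^2)) against Student's t with n-2
degrees of freedom, two-sided.
"""

from __future__ import annotations

import logging
from typing import Sequence

from scipy import stats

from .types import BetaMatrix, CorrelationPair, DiffResult, ExprMatrix, ProbeAnnotation

logger = logging.getLogger(__name__)

__all__ = ["pearson", "select_regulatory_cpgs"]


def pearson(x, y) -> tuple[float, float]:
    """Sample Pearson correlation and its two-sided t-test p-value."""
    import numpy as np

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    n = x.size
    if n < 3:
        raise ValueError(f"need n >= 3 paired observations, got {n}")
    sx = x.std(ddof=1)
    sy = y.std(ddof=1)
    if sx == 0 or sy == 0:
        raise ValueError("zero-variance vector: correlation undefined")
    r = float(((x - x.mean()) / sx * (y - y.mean()) / sy).sum() / (n - 1))
    r = min(1.0, max(-1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * ((n - 2) / (1.0 - r * r)) ** 0.5
    p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return r, p


def select_regulatory_cpgs(b: BetaMatrix, e: ExprMatrix,
                           ann: Sequence[ProbeAnnotation],
                           dm: Sequence[DiffResult], de: Sequence[DiffResult],
                           r_max: float = 0.0, p_max: float = 0.05,
                           tumor_only: bool = False,
                           meta=None) -> list[CorrelationPair]:
    """Select regulatory CpG features.

    For each called differentially methylated probe whose annotated gene
    is a called differentially expressed gene, correlate beta with log2
    expression over the shared samples and keep pairs with r < ``r_max``
    and p < ``p_max``. With ``tumor_only`` the correlation uses tumor
    samples only (requires ``meta``).
    """
    if not e.log2:
        raise ValueError("select_regulatory_cpgs expects normalized (log2) expression")
    dm_called = {r.feature for r in dm if r.passes}
    de_called = {r.feature for r in de if r.passes}
    gene_of = {a.probe: a.gene for a in ann}

    shared = [s for s in b.samples if s in set(e.samples)]
    if tumor_only:
        if meta is None:
            raise ValueError("tumor_only requires sample metadata")
        tumors = {m.sample for m in meta if m.condition == "tumor"}
        shared = [s for s in shared if s in tumors]

    out: list[CorrelationPair] = []
    for probe in b.values.index:
        if probe not in dm_called:
            continue
        gene = gene_of.get(probe)
        if gene is None:
            logger.warning("probe %s has no annotated gene; skipped", probe)
            continue
        if gene not in de_called or gene not in e.values.index:
            continue
        r, p = pearson(b.values.loc[probe, shared], e.values.loc[gene, shared])
        if r < r_max and p < p_max:
            out.append(CorrelationPair(probe=probe, gene=gene, r=r, p=p, n=len(shared)))
    return out
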
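"""Cleaning stages for beta and expression matrices.

Stage order in the pipeline: expression normalization; probe missingness
filter (removed when missing in *more than* ``max_frac`` of samples, the
70% boundary retained); KNN imputation across probes; blacklist / sex
chromosome removal; promoter windowing (2 kb upstream to 0.5 kb
downstream of the TSS, strand-relative). Each stage is idempotent on its
own output.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .types import BetaMatrix, ExprMatrix, ProbeAnnotation

__all__ = [
    "normalize_expression",
    "filter_missing_probes",
    "knn_impute",
    "remove_blacklisted",
    "filter_promoter_probes",
]


def normalize_expression(m: ExprMatrix) -> ExprMatrix:
    """Replace zeros by the matrix-wide minimum positive value, then log2.

    Already-normalized matrices (``log2=True``) are returned unchanged.
    """
    if m.log2:
        return m
    arr = m.values.to_numpy(dtype=float)
    if np.any(arr < 0):
        raise ValueError("raw expression contains negative values")
    pos = arr[arr > 0]
    if pos.size == 0:
        raise ValueError("all-zero expression matrix: no minimum positive value")
    minpos = pos.min()
    out = np.where(arr == 0, minpos, arr)
    return ExprMatrix(pd.DataFrame(np.log2(out), index=m.values.index,
                                   columns=m.values.columns), log2=True)


def filter_missing_probes(m: BetaMatrix, max_frac: float = 0.70) -> BetaMatrix:
    """Drop probes missing in more than ``max_frac`` of samples (strict >)."""
    if not 0.0 <= max_frac <= 1.0:
        raise ValueError(f"max_frac must be in [0, 1], got {max_frac}")
    frac = m.values.isna().mean(axis=1)
    return BetaMatrix(m.values.loc[frac <= max_frac])


def knn_impute(m: BetaMatrix, k: int = 10) -> BetaMatrix:
    """Impute missing beta-values from the k nearest probes.

    Distance between two probes is the Euclidean distance over samples
    where both are observed. A missing entry (probe p, sample s) becomes
    the mean beta at s of the k nearest probes that are observed at s
    (fewer donors are used, with a warning, when not enough exist).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    X = m.values.to_numpy(dtype=float)
    obs = ~np.isnan(X)
    if obs.all():
        return m
    Xf = np.where(obs, X, 0.0)
    W = obs.astype(float)
    sq = Xf ** 2
    # shared-sample squared distance via three matmuls
    shared = W @ W.T
    D2 = (sq * W) @ W.T + W @ (sq * W).T - 2.0 * (Xf @ Xf.T)
    D2 = np.maximum(D2, 0.0)
    D2[shared == 0] = np.inf
    np.fill_diagonal(D2, np.inf)

    n_probes = X.shape[0]
    out = X.copy()
    short = False
    for i in np.flatnonzero(~obs.all(axis=1)):
        if np.all(np.isinf(D2[i])):
            raise ValueError(
                f"probe {m.values.index[i]!r} shares no observed sample with "
                f"any other probe; lower k or filter it out"
            )
        order = np.argsort(D2[i], kind="stable")
        for j in np.flatnonzero(~obs[i]):
            donors = order[obs[order, j] & np.isfinite(D2[i, order])][:k]
            if donors.size == 0:
                raise ValueError(
                    f"no donor probe observed at sample {m.values.columns[j]!r} "
                    f"for probe {m.values.index[i]!r}; lower k"
                )
            if donors.size < k:
                short = True
            out[i, j] = X[donors, j].mean()
    if short:
        warnings.warn("fewer than k donors available for some entries; "
                      "used all available donors", stacklevel=2)
    assert not np.isnan(out).any()
    return BetaMatrix(pd.DataFrame(out, index=m.values.index, columns=m.values.columns))


def _ann_map(ann: Sequence[ProbeAnnotation]) -> dict:
    return {a.probe: a for a in ann}


def remove_blacklisted(m: BetaMatrix, ann: Sequence[ProbeAnnotation]) -> BetaMatrix:
    """Drop flagged probes and probes on chrX/chrY."""
    amap = _ann_map(ann)
    keep = []
    for probe in m.values.index:
        a = amap.get(probe)
        if a is None:
            raise ValueError(f"probe {probe!r} absent from annotation")
        if not a.blacklisted and a.chrom not in {"chrX", "chrY", "X", "Y"}:
            keep.append(probe)
    return BetaMatrix(m.values.loc[keep])


def in_promoter(a: ProbeAnnotation, up: int = 2000, down: int = 500) -> bool:
    """Strand-relative promoter window membership.

    '+' strand: pos in [tss-up, tss+down); '-' strand is the reflection
    around the TSS (upstream = higher coordinates): pos in (tss-down, tss+up].
    """
    if a.strand == "+":
        return a.tss - up <= a.pos < a.tss + down
    return a.tss - down < a.pos <= a.tss + up


def filter_promoter_probes(m: BetaMatrix, ann: Sequence[ProbeAnnotation],
                           up: int = 2000, down: int = 500) -> BetaMatrix:
    """Keep probes lying in their gene's promoter window."""
    amap = _ann_map(ann)
    keep = []
    for probe in m.values.index:
        a = amap.get(probe)
        if a is None:
            raise ValueError(f"probe {probe!r} absent from annotation")
        if in_promoter(a, up, down):
            keep.append(probe)
    return BetaMatrix(m.values.loc[keep])
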
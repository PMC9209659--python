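"""Entropy-based subtype-specific methylation markers.

Given the probe x subgroup matrix of mean beta-values, each probe's
cross-subgroup methylation difference is quantified by a normalized
Shannon entropy, and the contribution of each subgroup by a leave-one-out
entropy change:

* the subgroup means are turned into a probability vector with a small
  pseudocount, ``p_s = (m_s + eps) / sum_t (m_t + eps)``, and the entropy
  ``-sum p log2 p`` is normalized by log2(n) to [0, 1];
* because a raw entropy on the means cannot flag a *hypo*methylated
  outlier (a small coordinate barely perturbs the distribution), the same
  entropy is also computed on the reflected vector ``max + min - m``, and
  the profile entropy is ``H_Q = min(direct, reflected)``. A constant
  vector scores 1; a single extreme subgroup, high or low, scores low and
  symmetrically so;
* for each subgroup S, ``H_loo(S)`` is the same entropy of the vector
  with S removed (normalized by log2(n-1) so entropies are comparable),
  and ``delta_H(S) = H_loo(S) - H_Q`` measures how much of the difference
  S explains;
* the categorical specificity is ``CS(S) = delta_H(S) * sign(m_S -
  median(m))`` when ``delta_H(S) > 0`` and 0 otherwise, so CS > 0 marks a
  subgroup-specific hypermethylated probe and CS < 0 a hypomethylated one.

A probe is called a marker when ``H_Q`` falls at or below a threshold;
the default threshold is calibrated as a low quantile of H_Q under a
label-permutation null: cluster labels are permuted across samples and
the subgroup-mean vectors recomputed, which destroys the subgroup
structure while preserving each probe's baseline methylation level (a
pooled-value null would mix baselines across probes and grossly inflate
the null entropy spread).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .types import BetaMatrix, SpecificityScore, SubtypeAssignment

__all__ = [
    "subgroup_mean_profile",
    "entropy_q",
    "categorical_specificity",
    "calibrate_h_max",
    "call_specific_markers",
    "scores_frame",
]

EPS = 1e-6


def subgroup_mean_profile(b: BetaMatrix, labels: SubtypeAssignment) -> pd.DataFrame:
    """Probe x subgroup matrix of mean beta-values over each cluster's samples."""
    if b.n_missing:
        raise ValueError("profile requires an imputed matrix")
    missing = [s for s in labels.samples if s not in set(b.samples)]
    if missing:
        raise ValueError(f"clustered samples absent from beta matrix: {missing[:3]}")
    cols = {}
    for c in range(1, labels.k + 1):
        members = [s for s, l in labels.of.items() if l == c]
        if not members:
            raise ValueError(f"cluster {c} is empty")
        cols[c] = b.values[members].mean(axis=1)
    return pd.DataFrame(cols)


def _norm_entropy(m: np.ndarray) -> float:
    w = m + EPS
    p = w / w.sum()
    return float(-(p * np.log2(p)).sum() / np.log2(m.size))


def _entropy_q_rows(M: np.ndarray) -> np.ndarray:
    """Vectorized H_Q over the rows of a probe x subgroup matrix."""
    def h(rows):
        w = rows + EPS
        p = w / w.sum(axis=1, keepdims=True)
        return -(p * np.log2(p)).sum(axis=1) / np.log2(rows.shape[1])
    reflected = M.max(axis=1, keepdims=True) + M.min(axis=1, keepdims=True) - M
    return np.minimum(h(M), h(reflected))


def entropy_q(m) -> float:
    """Normalized min(direct, reflected) Shannon entropy of a mean vector."""
    m = np.asarray(m, dtype=float)
    if m.size < 2:
        raise ValueError("entropy needs >= 2 subgroups")
    if np.any((m < 0) | (m > 1)) or np.any(np.isnan(m)):
        raise ValueError("subgroup means must lie in [0, 1]")
    direct = _norm_entropy(m)
    reflected = _norm_entropy(m.max() + m.min() - m)
    return min(direct, reflected)


def categorical_specificity(m):
    """Leave-one-out entropy changes and signed categorical specificity.

    Returns ``(h_q, h_loo, delta_h, cs)`` as float / arrays of length n.
    """
    m = np.asarray(m, dtype=float)
    n = m.size
    if n < 3:
        raise ValueError("categorical specificity needs >= 3 subgroups")
    h_q = entropy_q(m)
    h_loo = np.empty(n)
    for s in range(n):
        h_loo[s] = entropy_q(np.delete(m, s))
    delta_h = h_loo - h_q
    sign = np.sign(m - np.median(m))
    cs = np.where(delta_h > 0, delta_h * sign, 0.0)
    return h_q, h_loo, delta_h, cs


def calibrate_h_max(b: BetaMatrix, labels: SubtypeAssignment,
                    quantile: float = 0.01, n_perm: int = 50,
                    seed: int = 0) -> float:
    """Entropy threshold from a per-probe label-permutation null.

    Cluster labels are permuted across samples ``n_perm`` times, the
    subgroup-mean profile recomputed each time, and the threshold is the
    ``quantile`` of the pooled null H_Q distribution. Calling probes at
    ``H_Q <= threshold`` then yields a false-call fraction of about
    ``quantile`` among structureless probes.
    """
    if b.n_missing:
        raise ValueError("calibration requires an imputed matrix")
    samples = [s for s in b.samples if s in labels.of]
    X = b.values[samples].to_numpy(dtype=float)
    y = labels.labels(samples)
    k = labels.k
    rng = np.random.default_rng(seed)
    null_h = []
    for _ in range(n_perm):
        perm = rng.permutation(y)
        means = np.column_stack([X[:, perm == c].mean(axis=1)
                                 for c in range(1, k + 1)])
        null_h.append(_entropy_q_rows(means))
    return float(np.quantile(np.concatenate(null_h), quantile))


def call_specific_markers(profile: pd.DataFrame, h_max: float | None = None,
                          cs_min: float = 0.0, beta: BetaMatrix | None = None,
                          labels: SubtypeAssignment | None = None,
                          null_quantile: float = 0.01, n_perm: int = 50,
                          seed: int = 0) -> list[SpecificityScore]:
    """Score every probe and call subtype-specific markers.

    A probe with ``H_Q <= h_max`` is assigned to the subgroup with
    maximal |CS| provided that magnitude exceeds ``cs_min``; direction is
    hyper for CS > 0 and hypo for CS < 0. When ``h_max`` is None it is
    calibrated from the permutation null, which requires the underlying
    ``beta`` matrix and ``labels``. Argmax ties (possible by reflection
    symmetry) are broken toward the lower subgroup index and flagged.
    """
    if h_max is None:
        if beta is None or labels is None:
            raise ValueError("h_max calibration needs the beta matrix and labels")
        h_max = calibrate_h_max(beta, labels, quantile=null_quantile,
                                n_perm=n_perm, seed=seed)
    out = []
    for probe, row in zip(profile.index, profile.to_numpy(dtype=float)):
        h_q, h_loo, delta_h, cs = categorical_specificity(row)
        assigned: int | None = None
        direction = "none"
        tied = False
        mag = np.abs(cs)
        if h_q <= h_max and mag.max() > cs_min:
            best = int(np.argmax(mag))
            tied = bool(np.sum(np.isclose(mag, mag[best], rtol=0, atol=1e-12)) > 1)
            assigned = int(profile.columns[best])
            direction = "hyper" if cs[best] > 0 else "hypo"
        out.append(SpecificityScore(probe=probe, h_q=h_q, h_loo=h_loo,
                                    delta_h=delta_h, cs=cs, assigned=assigned,
                                    direction=direction, tied=tied))
    return out


def scores_frame(scores: Sequence[SpecificityScore], columns=None) -> pd.DataFrame:
    """Flat marker table: probe, H_Q, assigned subgroup, direction, CS values."""
    rows = []
    for s in scores:
        row = {"probe": s.probe, "h_q": s.h_q,
               "assigned": 0 if s.assigned is None else s.assigned,
               "direction": s.direction, "tied": s.tied}
        names = columns if columns is not None else range(1, len(s.cs) + 1)
        for c, v in zip(names, s.cs):
            row[f"cs_{c}"] = v
        rows.append(row)
    return pd.DataFrame(rows).set_index("probe")
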
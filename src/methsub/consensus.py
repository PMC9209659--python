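"""Resampling consensus clustering with CDF / delta-area / CV model selection.

For each candidate cluster number k, the data are repeatedly subsampled
(80% of samples without replacement by default), each subsample is
partitioned by k-means (squared-Euclidean Lloyd iterations, random
centers drawn from the data, one start per repetition), and the
consensus value of a sample pair is the fraction of runs containing both
in which they were co-clustered. The final per-k call is agglomerative
hierarchical clustering (average linkage by default) on the distance
1 - consensus, cut to k groups.

Model selection evidence per k:

* the empirical CDF of off-diagonal consensus values and its area
  (trapezoid rule); ``delta_area`` is area(k=2) for the first k and the
  relative increase (area(k) - area(k-1)) / area(k-1) thereafter;
* ``cluster_consensus``: mean within-cluster consensus per final cluster,
  and ``item_consensus``: per sample, mean consensus with its co-members;
* ``cv``: coefficient of variation of cluster consensus,
  100 * SD / mean with sample (n-1) standard deviation.

``select_k`` codifies the usual reading of these plots: among k whose
mean cluster consensus ranks in the top half of the evaluated range and
whose CV ranks in the bottom half, pick the k with maximal delta area
(ties toward smaller k). The full evidence table is always reported so a
user can override the automatic choice.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans

from .types import SubtypeAssignment

__all__ = ["ConsensusResult", "kmeans_partition", "consensus_cluster", "select_k"]


def kmeans_partition(data: np.ndarray, k: int, seed: int) -> np.ndarray:
    """One k-means partition (Lloyd, squared Euclidean), labels 0..k-1.

    Initial centers are random data points drawn by the distance-weighted
    k-means++ rule; a single start per call (the consensus resampling
    provides the averaging), 300-iteration cap, tol 1e-6. Uniformly
    random centers frequently seed two centers inside one tight cluster
    and freeze a split/merge even on well-separated data, which would
    break the consensus-to-indicator convergence the pipeline relies on.
    """
    data = np.asarray(data, dtype=float)
    if not np.all(np.isfinite(data)):
        raise ValueError("k-means input must be finite")
    if k > data.shape[0]:
        raise ValueError(f"k={k} exceeds number of samples {data.shape[0]}")
    km = KMeans(n_clusters=k, init="k-means++", n_init=1, max_iter=300,
                tol=1e-6, random_state=seed)
    return km.fit_predict(data)


@dataclass
class ConsensusResult:
    """Per-k consensus matrices, final labels and model-selection evidence."""

    k_range: list
    samples: list
    consensus: dict                 # k -> (n, n) consensus matrix
    labels: dict                    # k -> SubtypeAssignment
    item_consensus: dict            # k -> (n,) mean consensus with co-members
    cluster_consensus: dict         # k -> (k,) mean within-cluster consensus
    cdf: dict                       # k -> (grid, F) arrays of the empirical CDF
    area: dict                      # k -> area under the CDF
    delta_area: dict                # k -> relative change in area
    cv: dict                        # k -> coefficient of variation (%)
    chosen_k: int | None = None
    stable: bool = True
    seed: int | None = None

    def evidence(self) -> pd.DataFrame:
        """Per-k model-selection table (area, delta area, consensus, CV)."""
        rows = [
            (k, self.area[k], self.delta_area[k],
             float(np.mean(self.cluster_consensus[k])), self.cv[k])
            for k in self.k_range
        ]
        return pd.DataFrame(rows, columns=["k", "area", "delta_area",
                                           "mean_cluster_consensus", "cv_pct"]
                            ).set_index("k")


def _ecdf(values: np.ndarray):
    """Empirical CDF of consensus values on a grid covering [0, 1]."""
    xs = np.concatenate(([0.0], np.unique(values), [1.0]))
    xs = np.unique(xs)
    F = np.searchsorted(np.sort(values), xs, side="right") / values.size
    return xs, F


def _cdf_area(xs: np.ndarray, F: np.ndarray) -> float:
    return float(np.trapezoid(F, xs))


def consensus_cluster(data, k_range: Sequence[int] = range(2, 11),
                      reps: int = 100, subsample_frac: float = 0.80,
                      seed: int = 0, linkage_method: str = "average",
                      feature_frac: float | None = None,
                      sample_ids: Sequence | None = None) -> ConsensusResult:
    """Run resampling consensus clustering over ``k_range``.

    ``data`` is sample x feature (a DataFrame's index supplies sample
    ids). ``feature_frac`` optionally subsamples features as well
    (default: samples only).
    """
    if isinstance(data, pd.DataFrame):
        sample_ids = list(data.index) if sample_ids is None else list(sample_ids)
        X = data.to_numpy(dtype=float)
    else:
        X = np.asarray(data, dtype=float)
        sample_ids = list(range(X.shape[0])) if sample_ids is None else list(sample_ids)
    n, n_feat = X.shape
    k_range = list(k_range)
    if n < max(k_range):
        raise ValueError(f"max k {max(k_range)} exceeds number of samples {n}")
    if not np.all(np.isfinite(X)):
        raise ValueError("consensus input must be finite")
    n_sub = int(np.floor(subsample_frac * n))
    if n_sub < max(k_range):
        raise ValueError("subsample too small for the largest k; raise subsample_frac")

    consensus, labels, item_c, cluster_c = {}, {}, {}, {}
    cdf, area, delta_area, cv = {}, {}, {}, {}

    for ki, k in enumerate(k_range):
        # per-k substream keyed on (seed, k-index) for reproducibility
        rng = np.random.default_rng(np.random.SeedSequence([seed, ki]))
        together = np.zeros((n, n))
        both = np.zeros((n, n))
        for rep in range(reps):
            idx = rng.choice(n, size=n_sub, replace=False)
            if feature_frac:
                feat = rng.choice(n_feat, size=int(np.floor(feature_frac * n_feat)),
                                  replace=False)
                sub = X[np.ix_(idx, feat)]
            else:
                sub = X[idx]
            part = kmeans_partition(sub, k, seed=int(rng.integers(2**31 - 1)))
            same = (part[:, None] == part[None, :]).astype(float)
            together[np.ix_(idx, idx)] += same
            both[np.ix_(idx, idx)] += 1.0
        off = ~np.eye(n, dtype=bool)
        if np.any(both[off] == 0):
            raise ValueError(
                "some sample pair was never co-subsampled; increase reps")
        M = np.ones((n, n))
        M[off] = together[off] / both[off]
        M = (M + M.T) / 2.0
        consensus[k] = M

        # final agglomerative call on 1 - consensus
        D = 1.0 - M
        np.fill_diagonal(D, 0.0)
        Z = linkage(squareform(D, checks=False), method=linkage_method)
        lab = fcluster(Z, t=k, criterion="maxclust")
        # relabel to contiguous 1..k in order of first appearance
        remap = {}
        for l in lab:
            if l not in remap:
                remap[l] = len(remap) + 1
        lab = np.array([remap[l] for l in lab], dtype=int)
        labels[k] = SubtypeAssignment({sample_ids[i]: int(lab[i]) for i in range(n)})

        cc = []
        ic = np.zeros(n)
        for c in range(1, lab.max() + 1):
            members = np.flatnonzero(lab == c)
            if members.size > 1:
                sub = M[np.ix_(members, members)]
                vals = sub[~np.eye(members.size, dtype=bool)]
                cc.append(float(vals.mean()))
                ic[members] = sub.sum(axis=1) - 1.0
                ic[members] /= members.size - 1
            else:
                cc.append(1.0)
                ic[members] = 1.0
        cluster_c[k] = np.array(cc)
        item_c[k] = ic

        vals = M[np.triu_indices(n, 1)]
        xs, F = _ecdf(vals)
        cdf[k] = (xs, F)
        area[k] = _cdf_area(xs, F)
        mean_cc = float(np.mean(cc))
        sd_cc = float(np.std(cc, ddof=1)) if len(cc) > 1 else 0.0
        cv[k] = 100.0 * sd_cc / mean_cc if mean_cc > 0 else np.inf

    for i, k in enumerate(k_range):
        if i == 0:
            delta_area[k] = area[k]
        else:
            prev = k_range[i - 1]
            delta_area[k] = (area[k] - area[prev]) / area[prev] if area[prev] > 0 else np.inf

    res = ConsensusResult(k_range=k_range, samples=sample_ids, consensus=consensus,
                          labels=labels, item_consensus=item_c,
                          cluster_consensus=cluster_c, cdf=cdf, area=area,
                          delta_area=delta_area, cv=cv, seed=seed)
    select_k(res)
    return res


def select_k(res: ConsensusResult, stability_floor: float = 0.8) -> int:
    """Choose k: maximal delta area among k ranking in the top half by mean
    cluster consensus and the bottom half by CV; ties toward smaller k.

    Falls back to the overall delta-area maximum (flagging ``stable=False``)
    when no k satisfies both rank filters, and flags instability whenever
    the chosen k's mean cluster consensus is below ``stability_floor``.
    """
    ks = res.k_range
    mcc = np.array([float(np.mean(res.cluster_consensus[k])) for k in ks])
    cvs = np.array([res.cv[k] for k in ks])
    das = np.array([res.delta_area[k] for k in ks])

    half = int(np.ceil(len(ks) / 2))
    top_mcc = set(np.argsort(-mcc, kind="stable")[:half])
    low_cv = set(np.argsort(cvs, kind="stable")[:half])
    eligible = sorted(top_mcc & low_cv)
    pool = eligible if eligible else list(range(len(ks)))
    best = max(pool, key=lambda i: (das[i], -ks[i]))
    res.chosen_k = ks[best]
    res.stable = bool(eligible) and mcc[best] >= stability_floor
    return res.chosen_k
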
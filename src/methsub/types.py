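"""Shared domain types for the methylation-subtyping pipeline.

Matrices are thin wrappers around :class:`pandas.DataFrame` (features on
rows, samples on columns) that enforce the invariants the pipeline relies
on: beta-values in [0, 1], unique identifiers, finite log2 expression.
Record types (annotation, metadata, screen results) are plain dataclasses.

All genomic coordinates are 0-based; promoter intervals are half-open on
the downstream side.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BetaMatrix",
    "ExprMatrix",
    "ProbeAnnotation",
    "SampleMetadata",
    "DiffResult",
    "CorrelationPair",
    "SubtypeAssignment",
    "KMCurve",
    "SurvivalComparison",
    "SpecificityScore",
    "ClassifierReport",
]


def _check_unique(ids: Sequence, what: str) -> None:
    seen = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {what} id: {i!r}")
        seen.add(i)


@dataclass
class BetaMatrix:
    """Probe x sample methylation fractions (beta-values).

    Missing entries (NaN) are permitted before imputation; every observed
    value must lie in [0, 1].
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(list(self.values.index), "probe")
        _check_unique(list(self.values.columns), "sample")
        arr = self.values.to_numpy(dtype=float)
        bad = (arr < 0) | (arr > 1)
        if np.any(bad & ~np.isnan(arr)):
            r, c = np.argwhere(bad & ~np.isnan(arr))[0]
            raise ValueError(
                f"beta value {arr[r, c]!r} outside [0, 1] at probe "
                f"{self.values.index[r]!r}, sample {self.values.columns[c]!r}"
            )

    @property
    def probes(self) -> list:
        return list(self.values.index)

    @property
    def samples(self) -> list:
        return list(self.values.columns)

    @property
    def n_missing(self) -> int:
        return int(self.values.isna().to_numpy().sum())

    def copy(self) -> "BetaMatrix":
        return BetaMatrix(self.values.copy())


@dataclass
class ExprMatrix:
    """Gene x sample expression matrix.

    ``log2=True`` marks a normalized matrix (finite values required);
    raw matrices hold non-negative counts/FPKM-like values.
    """

    values: pd.DataFrame
    log2: bool = False

    def __post_init__(self) -> None:
        _check_unique(list(self.values.index), "gene")
        _check_unique(list(self.values.columns), "sample")
        arr = self.values.to_numpy(dtype=float)
        if self.log2:
            if not np.all(np.isfinite(arr)):
                raise ValueError("normalized expression matrix contains non-finite values")
        else:
            if np.any(np.isnan(arr)) or np.any(arr < 0):
                raise ValueError("raw expression values must be non-negative and present")

    @property
    def genes(self) -> list:
        return list(self.values.index)

    @property
    def samples(self) -> list:
        return list(self.values.columns)


@dataclass(frozen=True)
class ProbeAnnotation:
    """One 450K probe: genomic location plus its promoter gene and TSS."""

    probe: str
    chrom: str
    pos: int
    strand: str
    gene: str
    tss: int
    blacklisted: bool = False

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"probe {self.probe!r}: strand must be '+' or '-', got {self.strand!r}")
        if self.pos < 0 or self.tss < 0:
            raise ValueError(f"probe {self.probe!r}: negative coordinate")


@dataclass(frozen=True)
class SampleMetadata:
    """Condition label and (right-censored) survival record for one sample."""

    sample: str
    condition: str
    time: float
    event: int

    def __post_init__(self) -> None:
        if self.condition not in {"tumor", "normal"}:
            raise ValueError(f"sample {self.sample!r}: condition must be tumor/normal, got {self.condition!r}")
        if self.time < 0:
            raise ValueError(f"sample {self.sample!r}: negative survival time {self.time}")
        if self.event not in (0, 1):
            raise ValueError(f"sample {self.sample!r}: event must be 0 or 1, got {self.event!r}")


@dataclass(frozen=True)
class DiffResult:
    """Per-feature two-group screen result.

    ``effect`` is the log2 fold change for genes, or the mean beta
    difference (tumor minus normal) for probes.
    """

    feature: str
    effect: float
    p_raw: float
    p_adj: float
    passes: bool


@dataclass(frozen=True)
class CorrelationPair:
    """Pearson correlation between a promoter probe's beta and its gene's expression."""

    probe: str
    gene: str
    r: float
    p: float
    n: int


@dataclass
class SubtypeAssignment:
    """Sample -> cluster label mapping; labels form a contiguous 1..k set."""

    of: dict

    def __post_init__(self) -> None:
        labels = set(self.of.values())
        if labels and labels != set(range(1, max(labels) + 1)):
            raise ValueError(f"cluster labels must be contiguous 1..k, got {sorted(labels)}")

    @property
    def k(self) -> int:
        return max(self.of.values()) if self.of else 0

    @property
    def samples(self) -> list:
        return list(self.of)

    def labels(self, samples: Iterable | None = None) -> np.ndarray:
        samples = self.samples if samples is None else list(samples)
        return np.array([self.of[s] for s in samples], dtype=int)


@dataclass
class KMCurve:
    """Kaplan-Meier product-limit estimate as a right-continuous step function."""

    times: np.ndarray      # distinct event times, ascending
    survival: np.ndarray   # S(t) just after each event time
    n: int

    def at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class SurvivalComparison:
    """Per-group KM curves plus the g-group log-rank test."""

    curves: Mapping[int, KMCurve]
    chi2: float
    df: int
    p: float


@dataclass
class SpecificityScore:
    """Entropy-based subtype specificity of one probe.

    ``cs`` holds the signed categorical specificity per subgroup
    (positive = hypermethylated in that subgroup, negative = hypo);
    ``assigned`` is the subgroup with maximal |CS|, or None for probes
    whose overall entropy exceeds the calling threshold.
    """

    probe: str
    h_q: float
    h_loo: np.ndarray
    delta_h: np.ndarray
    cs: np.ndarray
    assigned: int | None
    direction: str  # hyper / hypo / none
    tied: bool = False


@dataclass
class ClassifierReport:
    """Pooled cross-validation metrics for the subtype classifier."""

    confusion: np.ndarray
    accuracy: float
    sensitivity: float   # macro-averaged recall
    precision: float     # macro-averaged precision
    auc: float           # macro one-vs-rest AUC from decision scores
    classes: list = field(default_factory=list)
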
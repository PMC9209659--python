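"""Synthetic methylation/expression cohorts with planted ground truth.

The generator emulates the statistical structure the pipeline assumes in a
450K tumor/normal cohort:

* beta-values drawn from Beta distributions parameterized by a per-group
  mean and a shared concentration (``a = mu*nu``, ``b = (1-mu)*nu``), so
  values stay strictly inside (0, 1);
* a planted set of tumor-vs-normal differential probes shifted by
  ``delta_beta`` (alternating hyper/hypo);
* within the differential set, subtype-specific probes whose mean in
  exactly one of ``k_subtypes`` latent tumor subtypes is separated from
  the other subtypes by ``specific_shift`` (alternating hyper/hypo);
* log2 expression of regulated genes linearly and negatively coupled to
  their promoter probe's beta (``baseline - neg_slope*beta + noise``);
  the matrix is emitted on the raw scale (2**log2) so the normalization
  stage is exercised;
* exponential survival with a per-subtype hazard, censored at an
  independent exponential time;
* a fraction of beta entries masked at random.

Group means are laid out around 0.5 so every planted shift keeps means
inside (0, 1); the config validator rejects combinations that do not.
All randomness flows from one root seed via spawned substreams, so a
fixed seed gives bit-identical cohorts.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from . import io as msio
from .types import BetaMatrix, ExprMatrix, ProbeAnnotation, SampleMetadata

__all__ = ["SynthConfig", "SynthTruth", "Cohort", "generate_cohort",
           "write_cohort", "simulate_survival"]

_MEAN_LO, _MEAN_HI = 0.02, 0.98


@dataclass(frozen=True)
class SynthConfig:
    """Cohort layout and planted effect sizes.

    Defaults mirror a TCGA-like bladder cohort at array-subsampled scale:
    4 latent subtypes, 102 tumors per subtype and 14 normals, a 0.3
    tumor-vs-normal beta shift on differential probes and a 0.4
    subtype-specific shift, with ~2% missing entries.
    """

    k_subtypes: int = 4
    n_per_subtype: int = 102
    n_normal: int = 14
    n_probes: int = 2000
    n_diff_probes: int = 200
    n_specific_per_subtype: int = 10
    n_genes: int = 500
    frac_regulated: float = 0.7
    delta_beta: float = 0.3
    specific_shift: float = 0.4
    beta_concentration: float = 50.0
    neg_slope: float = 4.0
    expr_sd: float = 0.5
    hazards: tuple = (0.002, 0.002, 0.004, 0.008)  # events/day per subtype
    censor_rate: float = 0.002                      # 1/days
    missing_frac: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        counts = dict(k_subtypes=self.k_subtypes, n_per_subtype=self.n_per_subtype,
                      n_normal=self.n_normal, n_probes=self.n_probes, n_genes=self.n_genes)
        for name, v in counts.items():
            if v <= 0:
                raise ValueError(f"{name} must be positive, got {v}")
        if self.k_subtypes < 2:
            raise ValueError("k_subtypes must be >= 2")
        for name, v in dict(frac_regulated=self.frac_regulated,
                            missing_frac=self.missing_frac).items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_diff_probes > self.n_probes:
            raise ValueError("n_diff_probes exceeds n_probes")
        if self.n_specific_per_subtype * self.k_subtypes > self.n_diff_probes:
            raise ValueError("specific probes exceed the planted differential set")
        if len(self.hazards) != self.k_subtypes:
            raise ValueError(f"need {self.k_subtypes} hazards, got {len(self.hazards)}")
        for mu in self._planted_means():
            if not (_MEAN_LO <= mu <= _MEAN_HI):
                raise ValueError(
                    f"planted shifts push a group mean to {mu:.3f}, outside "
                    f"({_MEAN_LO}, {_MEAN_HI}); reduce delta_beta/specific_shift"
                )

    def _planted_means(self) -> list[float]:
        d, s, k = self.delta_beta, self.specific_shift, self.k_subtypes
        means = [0.5 - d / 2, 0.5 + d / 2]                      # plain diff probes
        for e in (+1, -1):                                      # specific probes
            mu_n = 0.5 - e * 0.3
            mu_other = mu_n + e * (d - s / k)
            means += [mu_n, mu_other, mu_other + e * s]
        return means


class SynthTruth(NamedTuple):
    """Planted ground truth emitted alongside a cohort."""

    subtype_of: dict            # tumor sample -> 1..k
    regulated_pairs: set        # {(probe, gene)} negatively coupled
    diff_probes: set            # tumor-vs-normal shifted probes
    diff_genes: set             # genes coupled to diff probes
    specific_probes: dict       # probe -> (subtype, "hyper"/"hypo")
    hazards: tuple


class Cohort(NamedTuple):
    beta: BetaMatrix
    expr: ExprMatrix
    annotation: list
    metadata: list
    truth: SynthTruth


def _group_means(cfg: SynthConfig, rng: np.random.Generator):
    """Per-probe mean beta for normals and for each tumor subtype.

    Returns (mu_normal[p], mu_subtype[p, k], diff_idx, specific: idx -> (subtype, dir)).
    """
    p, k = cfg.n_probes, cfg.k_subtypes
    d, s = cfg.delta_beta, cfg.specific_shift
    mu_n = rng.uniform(0.15, 0.85, size=p)
    mu_t = np.tile(mu_n[:, None], (1, k))

    diff_idx = np.arange(cfg.n_diff_probes)
    n_spec = cfg.n_specific_per_subtype * k
    specific: dict[int, tuple[int, str]] = {}
    # subtype-specific probes come first within the differential set
    for j, idx in enumerate(diff_idx[:n_spec]):
        subtype = j % k + 1
        e = +1 if (j // k) % 2 == 0 else -1
        mu_norm = 0.5 - e * 0.3
        mu_other = mu_norm + e * (d - s / k)
        mu_n[idx] = mu_norm
        mu_t[idx, :] = mu_other
        mu_t[idx, subtype - 1] = mu_other + e * s
        specific[idx] = (subtype, "hyper" if e > 0 else "hypo")
    # remaining differential probes: plain tumor-vs-normal shift, alternating sign
    for j, idx in enumerate(diff_idx[n_spec:]):
        e = +1 if j % 2 == 0 else -1
        mu_n[idx] = 0.5 - e * d / 2
        mu_t[idx, :] = 0.5 + e * d / 2
    return mu_n, mu_t, diff_idx, specific


def _beta_draw(mu: np.ndarray, nu: float, rng: np.random.Generator) -> np.ndarray:
    a = mu * nu
    b = (1.0 - mu) * nu
    x = rng.beta(a, b)
    # guard against denormal endpoint draws
    return np.clip(x, 1e-9, 1.0 - 1e-9)


def simulate_survival(hazards: Sequence[float], n_per_group: int, censor_rate: float,
                      rng: np.random.Generator):
    """Exponential event times per group with independent exponential censoring.

    Returns (times, events, groups) with groups labeled 1..len(hazards).
    """
    times, events, groups = [], [], []
    for g, lam in enumerate(hazards, start=1):
        t_event = rng.exponential(1.0 / lam, size=n_per_group)
        t_cens = (rng.exponential(1.0 / censor_rate, size=n_per_group)
                  if censor_rate > 0 else np.full(n_per_group, np.inf))
        t = np.minimum(t_event, t_cens)
        times.append(t)
        events.append((t_event <= t_cens).astype(int))
        groups.append(np.full(n_per_group, g))
    return np.concatenate(times), np.concatenate(events), np.concatenate(groups)


def generate_cohort(cfg: SynthConfig) -> Cohort:
    """Draw one cohort (beta, expression, annotation, metadata, truth) from ``cfg``."""
    cfg.validate()
    streams = np.random.SeedSequence(cfg.seed).spawn(5)
    rng_beta, rng_expr, rng_surv, rng_miss, rng_layout = (
        np.random.default_rng(s) for s in streams)

    k, npt, nn, p = cfg.k_subtypes, cfg.n_per_subtype, cfg.n_normal, cfg.n_probes
    n_tumor = k * npt
    probes = [f"cg{i:06d}" for i in range(p)]
    genes = [f"GENE{i:04d}" for i in range(cfg.n_genes)]
    tumor_ids = [f"T{i:03d}" for i in range(n_tumor)]
    normal_ids = [f"N{i:03d}" for i in range(nn)]
    subtype = np.repeat(np.arange(1, k + 1), npt)

    mu_n, mu_t, diff_idx, specific_idx = _group_means(cfg, rng_layout)

    mu = np.empty((p, n_tumor + nn))
    mu[:, :n_tumor] = mu_t[:, subtype - 1]
    mu[:, n_tumor:] = mu_n[:, None]
    beta = _beta_draw(mu, cfg.beta_concentration, rng_beta)

    # probe -> gene assignment: round-robin so every gene has >= 1 probe
    probe_gene = np.arange(p) % cfg.n_genes
    ann = []
    for i, pr in enumerate(probes):
        strand = "+" if i % 2 == 0 else "-"
        tss = 100_000 + 10_000 * i
        off = int(rng_layout.integers(-499, 2000))   # within the 2kb/0.5kb window
        pos = tss - off if strand == "+" else tss + off
        ann.append(ProbeAnnotation(probe=pr, chrom=f"chr{i % 22 + 1}", pos=pos,
                                   strand=strand, gene=genes[probe_gene[i]], tss=tss))

    # expression: regulated genes coupled to the first regulated diff probe
    n_reg = int(round(cfg.frac_regulated * len(diff_idx)))
    reg_probe_idx = diff_idx[:n_reg]
    baseline = rng_expr.uniform(4.0, 10.0, size=cfg.n_genes)
    log2e = baseline[:, None] + rng_expr.normal(0.0, cfg.expr_sd,
                                                size=(cfg.n_genes, n_tumor + nn))
    regulated_pairs = set()
    seen_genes: set[int] = set()
    for idx in reg_probe_idx:
        g = probe_gene[idx]
        if g in seen_genes:
            continue
        seen_genes.add(g)
        log2e[g, :] += cfg.neg_slope * (0.5 - beta[idx, :])  # centred negative coupling
        regulated_pairs.add((probes[idx], genes[g]))
    expr_raw = np.power(2.0, log2e)

    # survival for tumors; normals carry time 0 / censored
    t_surv, e_surv, _ = simulate_survival(cfg.hazards, npt, cfg.censor_rate, rng_surv)
    order = np.argsort(np.repeat(np.arange(k), npt), kind="stable")
    meta = [SampleMetadata(sample=tumor_ids[i], condition="tumor",
                           time=float(t_surv[order][i]), event=int(e_surv[order][i]))
            for i in range(n_tumor)]
    meta += [SampleMetadata(sample=s, condition="normal", time=0.0, event=0)
             for s in normal_ids]

    if cfg.missing_frac > 0:
        mask = rng_miss.random(beta.shape) < cfg.missing_frac
        beta = beta.copy()
        beta[mask] = np.nan

    beta_df = pd.DataFrame(beta, index=probes, columns=tumor_ids + normal_ids)
    expr_df = pd.DataFrame(expr_raw, index=genes, columns=tumor_ids + normal_ids)

    truth = SynthTruth(
        subtype_of={tumor_ids[i]: int(subtype[i]) for i in range(n_tumor)},
        regulated_pairs=regulated_pairs,
        diff_probes={probes[i] for i in diff_idx},
        diff_genes={g for _, g in regulated_pairs},
        specific_probes={probes[i]: v for i, v in specific_idx.items()},
        hazards=tuple(cfg.hazards),
    )
    return Cohort(BetaMatrix(beta_df), ExprMatrix(expr_df, log2=False), ann, meta, truth)


def write_cohort(outdir, cohort: Cohort) -> dict:
    """Write the cohort as the TSV files the io module reads, plus truth tables.

    Returns a name -> path mapping of everything written.
    """
    os.makedirs(outdir, exist_ok=True)
    paths = {name: os.path.join(outdir, fname) for name, fname in [
        ("beta", "beta.tsv"), ("expression", "expression.tsv"),
        ("annotation", "annotation.tsv"), ("metadata", "metadata.tsv"),
        ("truth_subtypes", "truth_subtypes.tsv"),
        ("truth_probes", "truth_probes.tsv"),
        ("truth_pairs", "truth_pairs.tsv"),
    ]}
    msio.write_matrix(cohort.beta, paths["beta"])
    msio.write_matrix(cohort.expr, paths["expression"])
    msio.write_annotation(cohort.annotation, paths["annotation"])
    msio.write_metadata(cohort.metadata, paths["metadata"])

    t = cohort.truth
    pd.DataFrame(sorted(t.subtype_of.items()), columns=["sample", "subtype"]) \
        .to_csv(paths["truth_subtypes"], sep="\t", index=False)
    rows = []
    for probe in sorted(t.diff_probes):
        sub, direction = t.specific_probes.get(probe, (0, "none"))
        rows.append((probe, "diff", sub, direction))
    pd.DataFrame(rows, columns=["probe", "role", "specific_subtype", "direction"]) \
        .to_csv(paths["truth_probes"], sep="\t", index=False)
    pd.DataFrame(sorted(t.regulated_pairs), columns=["probe", "gene"]) \
        .to_csv(paths["truth_pairs"], sep="\t", index=False)
    return paths
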
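"""End-to-end orchestration: one config, fixed seed, delimited artifacts.

Stage order: preprocess -> diff -> integrate -> cluster -> survival ->
markers -> classify. Inputs come either from files or from the synthetic
cohort generator. Every stage writes a self-describing delimited artifact
to the output directory, and a JSON manifest records the seed, a config
hash, library versions and per-stage record counts. A stage failure
aborts the run but preserves the partial manifest with the failing stage
named.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import classify as mclassify
from . import consensus as mconsensus
from . import differential as mdiff
from . import integrate as mintegrate
from . import io as msio
from . import preprocess as mprep
from . import simulate as msim
from . import specificity as mspec
from . import survival as msurv


__all__ = ["PipelineConfig", "run_all"]

STAGES = ["preprocess", "diff", "integrate", "cluster", "survival", "markers", "classify"]


@dataclass
class PipelineConfig:
    """All stage thresholds plus either input paths or a synthetic config."""

    # inputs: file paths, or synthetic=True with synth settings
    synthetic: bool = True
    synth: msim.SynthConfig = field(default_factory=msim.SynthConfig)
    beta_path: str | None = None
    expr_path: str | None = None
    annotation_path: str | None = None
    metadata_path: str | None = None

    # preprocess
    max_missing: float = 0.70
    knn_k: int = 10
    promoter_up: int = 2000
    promoter_down: int = 500
    # differential
    fc_min: float = 2.0
    q_max: float = 0.05
    delta_min: float = 0.20
    p_max: float = 0.05
    # integration
    corr_p_max: float = 0.05
    tumor_only_corr: bool = False
    # consensus
    k_min: int = 2
    k_max: int = 10
    reps: int = 100
    subsample: float = 0.80
    # markers
    h_max: float | None = None
    null_quantile: float = 0.01
    # classifier
    folds: int = 10
    kernel: str = "linear"
    svm_c: float = 1.0

    seed: int = 0
    outdir: str = "results/pipeline"

    def validate(self) -> None:
        for name, v, lo, hi in [("max_missing", self.max_missing, 0, 1),
                                ("subsample", self.subsample, 0, 1),
                                ("q_max", self.q_max, 0, 1),
                                ("p_max", self.p_max, 0, 1),
                                ("corr_p_max", self.corr_p_max, 0, 1)]:
            if not lo <= v <= hi:
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")
        if self.k_min < 2 or self.k_max < self.k_min:
            raise ValueError("need 2 <= k_min <= k_max")
        if not self.synthetic:
            missing = [n for n in ("beta_path", "expr_path", "annotation_path",
                                   "metadata_path") if getattr(self, n) is None]
            if missing:
                raise ValueError(f"file-based run needs paths: {missing}")

    # --- YAML round-trip -------------------------------------------------
    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["synth"]["hazards"] = list(d["synth"]["hazards"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        synth = d.pop("synth", None)
        cfg = cls(**d)
        if synth is not None:
            synth["hazards"] = tuple(synth["hazards"])
            cfg.synth = msim.SynthConfig(**synth)
        return cfg

    def digest(self) -> str:
        d = asdict(self)
        d["synth"]["hazards"] = list(d["synth"]["hazards"])
        return hashlib.sha256(json.dumps(d, sort_keys=True).encode()).hexdigest()[:16]


def _load_inputs(cfg: PipelineConfig):
    if cfg.synthetic:
        synth = dataclasses.replace(cfg.synth, seed=cfg.seed)
        cohort = msim.generate_cohort(synth)
        return cohort.beta, cohort.expr, cohort.annotation, cohort.metadata, cohort.truth
    beta = msio.read_matrix(cfg.beta_path, "beta")
    expr = msio.read_matrix(cfg.expr_path, "expression")
    ann = msio.read_annotation(cfg.annotation_path)
    meta = msio.read_metadata(cfg.metadata_path)
    return beta, expr, ann, meta, None


def run_all(cfg: PipelineConfig) -> dict:
    """Execute every stage; returns (and writes) the run manifest."""
    cfg.validate()
    os.makedirs(cfg.outdir, exist_ok=True)
    manifest: dict = {
        "seed": cfg.seed,
        "config_hash": cfg.digest(),
        "versions": {m.__name__: m.__version__ for m in (np, pd)},
        "stages": [],
        "counts": {},
        "thresholds": {k: v for k, v in asdict(cfg).items()
                       if k not in {"synth", "outdir"}},
    }
    manifest_path = os.path.join(cfg.outdir, "manifest.json")

    def _save_manifest():
        with open(manifest_path, "w") as fh:
            json.dump(manifest, fh, indent=1, default=str)

    stage = "load"
    try:
        beta, expr, ann, meta, truth = _load_inputs(cfg)

        stage = "preprocess"
        expr_n = mprep.normalize_expression(expr)
        beta_f = mprep.filter_missing_probes(beta, cfg.max_missing)
        beta_i = mprep.knn_impute(beta_f, cfg.knn_k)
        beta_b = mprep.remove_blacklisted(beta_i, ann)
        beta_p = mprep.filter_promoter_probes(beta_b, ann, cfg.promoter_up,
                                              cfg.promoter_down)
        msio.write_matrix(beta_p, os.path.join(cfg.outdir, "beta_clean.tsv"))
        msio.write_matrix(expr_n, os.path.join(cfg.outdir, "expression_log2.tsv"))
        manifest["counts"][stage] = {"probes": len(beta_p.probes),
                                     "genes": len(expr_n.genes)}
        manifest["stages"].append(stage)

        stage = "diff"
        de = mdiff.diff_expression(expr_n, meta, cfg.fc_min, cfg.q_max)
        dm = mdiff.diff_methylation(beta_p, meta, cfg.delta_min, cfg.p_max)
        mdiff.results_frame(de).to_csv(os.path.join(cfg.outdir, "diff_genes.tsv"), sep="\t")
        mdiff.results_frame(dm).to_csv(os.path.join(cfg.outdir, "diff_probes.tsv"), sep="\t")
        manifest["counts"][stage] = {"de_genes": len(mdiff.called(de)),
                                     "dm_probes": len(mdiff.called(dm))}
        manifest["stages"].append(stage)

        stage = "integrate"
        pairs = mintegrate.select_regulatory_cpgs(
            beta_p, expr_n, ann, dm, de, p_max=cfg.corr_p_max,
            tumor_only=cfg.tumor_only_corr, meta=meta)
        pd.DataFrame([(c.probe, c.gene, c.r, c.p, c.n) for c in pairs],
                     columns=["probe", "gene", "r", "p", "n"]) \
            .to_csv(os.path.join(cfg.outdir, "features.tsv"), sep="\t", index=False)
        features = [c.probe for c in pairs]
        if not features:
            raise ValueError("no regulatory CpG features selected")
        manifest["counts"][stage] = {"feature_cpgs": len(features)}
        manifest["stages"].append(stage)

        stage = "cluster"
        tumors = [m.sample for m in meta if m.condition == "tumor"
                  and m.sample in set(beta_p.samples)]
        feat_mat = beta_p.values.loc[features, tumors].T  # samples x features
        res = mconsensus.consensus_cluster(
            feat_mat, k_range=range(cfg.k_min, cfg.k_max + 1), reps=cfg.reps,
            subsample_frac=cfg.subsample, seed=cfg.seed)
        labels = res.labels[res.chosen_k]
        res.evidence().to_csv(os.path.join(cfg.outdir, "consensus_evidence.tsv"), sep="\t")
        pd.DataFrame(res.consensus[res.chosen_k], index=tumors, columns=tumors) \
            .to_csv(os.path.join(cfg.outdir, "consensus_matrix.tsv"), sep="\t",
                    float_format="%.6g")
        pd.DataFrame(sorted(labels.of.items()), columns=["sample", "cluster"]) \
            .to_csv(os.path.join(cfg.outdir, "subtype_labels.tsv"), sep="\t", index=False)
        manifest["counts"][stage] = {"chosen_k": res.chosen_k, "stable": res.stable}
        manifest["stages"].append(stage)

        stage = "survival"
        surv_meta = {m.sample: m for m in meta}
        times = np.array([surv_meta[s].time for s in labels.samples])
        events = np.array([surv_meta[s].event for s in labels.samples])
        comp = msurv.logrank(times, events, labels.labels())
        with open(os.path.join(cfg.outdir, "survival_test.json"), "w") as fh:
            json.dump({"chi2": comp.chi2, "df": comp.df, "p": comp.p}, fh, indent=1)
        curve_rows = [(g, t, s) for g, c in comp.curves.items()
                      for t, s in zip(c.times, c.survival)]
        pd.DataFrame(curve_rows, columns=["cluster", "time", "survival"]) \
            .to_csv(os.path.join(cfg.outdir, "km_curves.tsv"), sep="\t", index=False)
        manifest["counts"][stage] = {"chi2": comp.chi2, "p": comp.p, "df": comp.df}
        manifest["stages"].append(stage)

        stage = "markers"
        profile = mspec.subgroup_mean_profile(
            type(beta_p)(beta_p.values.loc[features]), labels)
        scores = mspec.call_specific_markers(
            profile, h_max=cfg.h_max, beta=beta_p, labels=labels,
            null_quantile=cfg.null_quantile, seed=cfg.seed)
        mspec.scores_frame(scores, columns=profile.columns) \
            .to_csv(os.path.join(cfg.outdir, "markers.tsv"), sep="\t")
        n_called = sum(1 for s in scores if s.assigned is not None)
        manifest["counts"][stage] = {"markers": n_called}
        manifest["stages"].append(stage)

        stage = "classify"
        report = mclassify.crossval_report(feat_mat, labels, folds=cfg.folds,
                                           seed=cfg.seed, kernel=cfg.kernel,
                                           C=cfg.svm_c)
        clf = mclassify.SubtypeClassifier(kernel=cfg.kernel, C=cfg.svm_c,
                                          seed=cfg.seed).fit(feat_mat, labels)
        if cfg.kernel == "linear":
            clf.save(os.path.join(cfg.outdir, "model.json"))
        with open(os.path.join(cfg.outdir, "classifier_report.json"), "w") as fh:
            json.dump({"accuracy": report.accuracy, "sensitivity": report.sensitivity,
                       "precision": report.precision, "auc": report.auc,
                       "confusion": report.confusion.tolist(),
                       "classes": report.classes}, fh, indent=1)
        manifest["counts"][stage] = {"accuracy": report.accuracy, "auc": report.auc}
        manifest["stages"].append(stage)

        manifest["status"] = "completed"
        _save_manifest()
        return manifest
    except Exception as exc:
        manifest["status"] = "failed"
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        _save_manifest()
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
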
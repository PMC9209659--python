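"""Generate the synthetic tumor/normal methylation cohort used downstream.

Emulates a TCGA-like bladder cohort: 4 latent subtypes x 102 tumors plus
14 normals, 2000 promoter CpGs (200 shifted in tumors, 40 of those
subtype-specific), expression negatively coupled to methylation for
regulated genes, subtype-dependent survival, 2% missing entries.
Writes the cohort and its planted truth under results/cohort/.
"""

from methsub.simulate import SynthConfig, generate_cohort, write_cohort

SEED = 1

cfg = SynthConfig(seed=SEED)
cohort = generate_cohort(cfg)
paths = write_cohort("results/cohort", cohort)

n_tumor = cfg.k_subtypes * cfg.n_per_subtype
print(f"cohort: {len(cohort.beta.probes)} probes x {len(cohort.beta.samples)} samples "
      f"({n_tumor} tumors in {cfg.k_subtypes} subtypes, {cfg.n_normal} normals)")
print(f"planted: {len(cohort.truth.diff_probes)} differential probes, "
      f"{len(cohort.truth.specific_probes)} subtype-specific, "
      f"{len(cohort.truth.regulated_pairs)} regulated probe-gene pairs")
print(f"missing beta entries: {cohort.beta.n_missing}")
for name, p in paths.items():
    print(f"  wrote {name}: {p}")
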
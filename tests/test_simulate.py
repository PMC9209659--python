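import dataclasses

import numpy as np
import pytest

from methsub import io as msio
from methsub.simulate import SynthConfig, generate_cohort, simulate_survival, write_cohort


def test_seeded_determinism(small_cfg):
    a = generate_cohort(small_cfg)
    b = generate_cohort(small_cfg)
    assert a.beta.values.equals(b.beta.values)
    assert a.expr.values.equals(b.expr.values)
    assert a.truth == b.truth
    c = generate_cohort(dataclasses.replace(small_cfg, seed=small_cfg.seed + 1))
    assert not a.beta.values.equals(c.beta.values)


def test_beta_strictly_inside_unit_interval(imputed_cohort):
    arr = imputed_cohort.beta.values.to_numpy()
    assert np.all(arr > 0) and np.all(arr < 1)


def test_group_means_match_planted_shifts(imputed_cohort, small_cfg):
    """Planted specific probes differ from the other subtypes by ~specific_shift,
    and empirical group means sit within 3 SE of their targets."""
    c = imputed_cohort
    cfg = dataclasses.replace(small_cfg, missing_frac=0.0)
    by_subtype = {k: [s for s, v in c.truth.subtype_of.items() if v == k]
                  for k in range(1, 5)}
    nu = cfg.beta_concentration
    n = cfg.n_per_subtype
    for probe, (subtype, direction) in c.truth.specific_probes.items():
        row = c.beta.values.loc[probe]
        own = row[by_subtype[subtype]].mean()
        others = np.mean([row[by_subtype[k]].mean() for k in range(1, 5) if k != subtype])
        gap = own - others
        expected = cfg.specific_shift if direction == "hyper" else -cfg.specific_shift
        se = np.sqrt(0.25 / (nu + 1) / n)  # upper bound on SE of a group mean
        assert abs(gap - expected) < 3 * se * 2


def test_missingness_fraction(small_cohort, small_cfg):
    frac = small_cohort.beta.values.isna().to_numpy().mean()
    n = small_cohort.beta.values.size
    se = np.sqrt(small_cfg.missing_frac * (1 - small_cfg.missing_frac) / n)
    assert abs(frac - small_cfg.missing_frac) < 4 * se


def test_survival_event_rate_matches_hazard():
    """With exponential events (rate h) and censoring (rate c), the expected
    event fraction is h/(h+c); check within binomial error at n=1000."""
    rng = np.random.default_rng(9)
    hazards, censor = (0.002, 0.008), 0.002
    times, events, groups = simulate_survival(hazards, 1000, censor, rng)
    for g, h in enumerate(hazards, start=1):
        expected = h / (h + censor)
        observed = events[groups == g].mean()
        se = np.sqrt(expected * (1 - expected) / 1000)
        assert abs(observed - expected) < 4 * se


def test_regulated_pairs_negative_coupling(imputed_cohort):
    """Planted probe-gene couplings show negative sample correlation."""
    c = imputed_cohort
    log2e = np.log2(c.expr.values)
    neg = 0
    pairs = sorted(c.truth.regulated_pairs)
    for probe, gene in pairs:
        r = np.corrcoef(c.beta.values.loc[probe], log2e.loc[gene])[0, 1]
        neg += r < 0
    assert neg / len(pairs) > 0.95


def test_annotation_covers_all_probes_in_promoters(imputed_cohort):
    from methsub.preprocess import in_promoter
    ann = {a.probe: a for a in imputed_cohort.annotation}
    assert set(ann) == set(imputed_cohort.beta.probes)
    assert all(in_promoter(a) for a in ann.values())


def test_config_validation_rejects_out_of_range_means():
    with pytest.raises(ValueError, match="group mean"):
        SynthConfig(delta_beta=0.8, specific_shift=0.8).validate()
    with pytest.raises(ValueError, match="hazards"):
        SynthConfig(k_subtypes=3).validate()
    with pytest.raises(ValueError, match="positive"):
        SynthConfig(n_probes=0).validate()


def test_write_cohort_round_trip_and_truth_bookkeeping(tmp_path, small_cohort, small_cfg):
    paths = write_cohort(tmp_path, small_cohort)
    beta = msio.read_matrix(paths["beta"], "beta")
    np.testing.assert_allclose(beta.values.to_numpy(),
                               small_cohort.beta.values.to_numpy(),
                               rtol=1e-12, equal_nan=True)
    meta = msio.read_metadata(paths["metadata"])
    assert meta == small_cohort.metadata
    import pandas as pd
    probes = pd.read_csv(paths["truth_probes"], sep="\t")
    n_spec = (probes["direction"] != "none").sum()
    assert n_spec == small_cfg.n_specific_per_subtype * small_cfg.k_subtypes
    assert len(probes) == small_cfg.n_diff_probes
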
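"""Call subtype-specific hyper/hypo-methylated marker CpGs among the
feature set with the entropy-based specificity score, at a threshold
calibrated from a label-permutation null over all cleaned probes."""

import pandas as pd

from methsub import io as msio
from methsub import specificity as sp
from methsub.types import SubtypeAssignment

SEED = 1

beta = msio.read_matrix("results/analysis/beta_clean.tsv", "beta")
lab_df = pd.read_csv("results/analysis/subtype_labels.tsv", sep="\t")
labels = SubtypeAssignment(dict(zip(lab_df["sample"], lab_df["cluster"])))
features = pd.read_csv("results/analysis/features.tsv", sep="\t")["probe"].tolist()

h_max = sp.calibrate_h_max(beta, labels, quantile=0.01, seed=SEED)
profile = sp.subgroup_mean_profile(
    type(beta)(beta.values.loc[features]), labels)
scores = sp.call_specific_markers(profile, h_max=h_max)
table = sp.scores_frame(scores, columns=profile.columns)
table.to_csv("results/analysis/markers.tsv", sep="\t")

called = table[table["assigned"] != 0]
print(f"entropy threshold (1% permutation null): H_Q <= {h_max:.4f}")
print(f"subtype-specific markers: {len(called)} of {len(table)} candidate CpGs")
print(called.groupby(["assigned", "direction"]).size())
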
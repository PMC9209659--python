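"""Discover methylation subtypes by resampling consensus clustering over
the feature CpGs (k = 2..10, 100 subsamples of 80% of tumors) and pick k
from the delta-area / cluster-consensus / CV evidence. Writes the
evidence table, consensus matrix at the chosen k, and final labels."""

import pandas as pd

from methsub import io as msio
from methsub.consensus import consensus_cluster

SEED = 1

beta = msio.read_matrix("results/analysis/beta_clean.tsv", "beta")
meta = msio.read_metadata("results/cohort/metadata.tsv")
features = pd.read_csv("results/analysis/features.tsv", sep="\t")["probe"].tolist()

tumors = [m.sample for m in meta if m.condition == "tumor"]
X = beta.values.loc[features, tumors].T  # samples x features

res = consensus_cluster(X, k_range=range(2, 11), reps=100,
                        subsample_frac=0.80, seed=SEED)
labels = res.labels[res.chosen_k]

res.evidence().to_csv("results/analysis/consensus_evidence.tsv", sep="\t")
pd.DataFrame(res.consensus[res.chosen_k], index=tumors, columns=tumors) \
    .to_csv("results/analysis/consensus_matrix.tsv", sep="\t", float_format="%.6g")
pd.DataFrame(sorted(labels.of.items()), columns=["sample", "cluster"]) \
    .to_csv("results/analysis/subtype_labels.tsv", sep="\t", index=False)

print(res.evidence().round(4))
sizes = pd.Series(list(labels.of.values())).value_counts().sort_index()
print(f"chosen k = {res.chosen_k} (stable={res.stable}); "
      f"cluster sizes: {sizes.to_dict()}")
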
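"""Compare overall survival across the discovered subtypes: Kaplan-Meier
curves per cluster and the g-group log-rank test."""

import json

import pandas as pd

from methsub import io as msio
from methsub.survival import logrank

meta = {m.sample: m for m in msio.read_metadata("results/cohort/metadata.tsv")}
labels = pd.read_csv("results/analysis/subtype_labels.tsv", sep="\t")

times = [meta[s].time for s in labels["sample"]]
events = [meta[s].event for s in labels["sample"]]
comp = logrank(times, events, labels["cluster"].to_numpy())

rows = [(g, t, s) for g, c in comp.curves.items() for t, s in zip(c.times, c.survival)]
pd.DataFrame(rows, columns=["cluster", "time", "survival"]) \
    .to_csv("results/analysis/km_curves.tsv", sep="\t", index=False)
with open("results/analysis/survival_test.json", "w") as fh:
    json.dump({"chi2": comp.chi2, "df": comp.df, "p": comp.p}, fh, indent=1)

for g, c in sorted(comp.curves.items()):
    median = next((t for t, s in zip(c.times, c.survival) if s <= 0.5), None)
    print(f"cluster {g}: n={c.n}, median survival "
          f"{'%.0f days' % median if median else 'not reached'}")
print(f"log-rank: chi2={comp.chi2:.2f}, df={comp.df}, p={comp.p:.3g}")
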
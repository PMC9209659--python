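"""Train the linear SVM subtype classifier on the feature CpGs, evaluate
it by stratified ten-fold cross-validation, and predict subtypes for an
independent cohort drawn from the same generator (external-validation
stand-in)."""

import dataclasses
import json

import pandas as pd

from methsub import classify as cl
from methsub import io as msio
from methsub import preprocess as pp
from methsub.simulate import SynthConfig, generate_cohort
from methsub.types import SubtypeAssignment

SEED = 1

beta = msio.read_matrix("results/analysis/beta_clean.tsv", "beta")
meta = msio.read_metadata("results/cohort/metadata.tsv")
lab_df = pd.read_csv("results/analysis/subtype_labels.tsv", sep="\t")
labels = SubtypeAssignment(dict(zip(lab_df["sample"], lab_df["cluster"])))
features = pd.read_csv("results/analysis/features.tsv", sep="\t")["probe"].tolist()

tumors = [m.sample for m in meta if m.condition == "tumor"]
X = beta.values.loc[features, tumors].T

rep = cl.crossval_report(X, labels, folds=10, seed=SEED)
with open("results/analysis/classifier_report.json", "w") as fh:
    json.dump({"accuracy": rep.accuracy, "sensitivity": rep.sensitivity,
               "precision": rep.precision, "auc": rep.auc,
               "confusion": rep.confusion.tolist(), "classes": rep.classes},
              fh, indent=1)
print(f"10-fold CV: accuracy {rep.accuracy:.3f}, sensitivity {rep.sensitivity:.3f}, "
      f"precision {rep.precision:.3f}, macro OvR AUC {rep.auc:.3f}")
print("confusion matrix (rows true, cols predicted):")
print(pd.DataFrame(rep.confusion, index=rep.classes, columns=rep.classes))

# external-cohort stand-in from the same generative process, new seed
ext = generate_cohort(dataclasses.replace(SynthConfig(), seed=SEED + 7919))
ext_beta = pp.knn_impute(pp.filter_missing_probes(ext.beta))
ext_tumors = sorted(ext.truth.subtype_of)
pred = cl.fit_and_predict(X, labels, ext_beta.values.loc[features, ext_tumors].T)
counts = pd.Series(list(pred.of.values())).value_counts().sort_index()
pd.DataFrame(sorted(pred.of.items()), columns=["sample", "cluster"]) \
    .to_csv("results/analysis/external_predictions.tsv", sep="\t", index=False)
print(f"external cohort predictions per cluster: {counts.to_dict()}")
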
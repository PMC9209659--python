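"""Clean the cohort: log2-normalize expression, filter/impute beta-values,
drop blacklisted and non-promoter probes. Writes cleaned matrices under
results/analysis/."""

import os

from methsub import io as msio
from methsub import preprocess as pp

os.makedirs("results/analysis", exist_ok=True)

beta = msio.read_matrix("results/cohort/beta.tsv", "beta")
expr = msio.read_matrix("results/cohort/expression.tsv", "expression")
ann = msio.read_annotation("results/cohort/annotation.tsv")

expr_n = pp.normalize_expression(expr)
beta_f = pp.filter_missing_probes(beta, max_frac=0.70)
beta_i = pp.knn_impute(beta_f, k=10)
beta_b = pp.remove_blacklisted(beta_i, ann)
beta_p = pp.filter_promoter_probes(beta_b, ann, up=2000, down=500)

msio.write_matrix(expr_n, "results/analysis/expression_log2.tsv")
msio.write_matrix(beta_p, "results/analysis/beta_clean.tsv")

print(f"expression: {len(expr_n.genes)} genes log2-normalized")
print(f"probes: {len(beta.probes)} -> missingness filter {len(beta_f.probes)} "
      f"-> imputed ({beta_f.n_missing} entries) -> blacklist {len(beta_b.probes)} "
      f"-> promoter {len(beta_p.probes)}")
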
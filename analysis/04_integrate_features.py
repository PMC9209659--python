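"""Select classification features: differentially methylated promoter CpGs
whose beta-value correlates negatively (r < 0, p < 0.05) with their
gene's log2 expression. Writes the feature table under results/analysis/."""

import pandas as pd

from methsub import differential as md
from methsub import integrate as mi
from methsub import io as msio
from methsub.types import DiffResult

beta = msio.read_matrix("results/analysis/beta_clean.tsv", "beta")
expr = msio.read_matrix("results/analysis/expression_log2.tsv", "expression_log2")
ann = msio.read_annotation("results/cohort/annotation.tsv")


def load_results(path):
    df = pd.read_csv(path, sep="\t")
    return [DiffResult(r.feature, r.effect, r.p_raw, r.p_adj, bool(r.passes))
            for r in df.itertuples(index=False)]


dm = load_results("results/analysis/diff_probes.tsv")
de = load_results("results/analysis/diff_genes.tsv")

pairs = mi.select_regulatory_cpgs(beta, expr, ann, dm, de, r_max=0.0, p_max=0.05)
pd.DataFrame([(c.probe, c.gene, c.r, c.p, c.n) for c in pairs],
             columns=["probe", "gene", "r", "p", "n"]) \
    .to_csv("results/analysis/features.tsv", sep="\t", index=False)

rs = [c.r for c in pairs]
print(f"regulatory CpG features: {len(pairs)} "
      f"(r range {min(rs):.3f} .. {max(rs):.3f})")
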
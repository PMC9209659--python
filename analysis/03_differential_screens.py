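"""Screen tumor-vs-normal differentially expressed genes (|log2 FC| > 1,
BH q < 0.05) and differentially methylated CpGs (|delta beta| > 0.20,
BH p < 0.05). Writes result tables under results/analysis/."""

from methsub import differential as md
from methsub import io as msio

expr = msio.read_matrix("results/analysis/expression_log2.tsv", "expression_log2")
beta = msio.read_matrix("results/analysis/beta_clean.tsv", "beta")
meta = msio.read_metadata("results/cohort/metadata.tsv")

de = md.diff_expression(expr, meta, fc_min=2.0, q_max=0.05)
dm = md.diff_methylation(beta, meta, delta_min=0.20, p_max=0.05)

md.results_frame(de).to_csv("results/analysis/diff_genes.tsv", sep="\t")
md.results_frame(dm).to_csv("results/analysis/diff_probes.tsv", sep="\t")

print(f"differentially expressed genes: {len(md.called(de))} of {len(de)}")
print(f"differentially methylated CpGs: {len(md.called(dm))} of {len(dm)}")
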
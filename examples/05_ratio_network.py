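"""Interpret a fitted model as a ratio network with gene importance.

Significant positively-oriented ratios form a directed graph; a gene's
positivity (fraction of its ratios where it is the numerator) separates
putative positive regulators of response (positivity near 1) from negative
ones (near 0).  Leave-one-gene-out cross-validation measures each gene's
contribution to prediction.
"""

from genratio.expression import filter_genes
from genratio.model import GrepConfig, fit_grep
from genratio.network import build_ratio_network, gene_elimination_importance, network_node_table
from genratio.ratios import compute_log_ratios, permutation_significance, select_significant
from genratio.simulate import SyntheticConfig, generate_expression

data = generate_expression(
    SyntheticConfig(
        n_samples=300, n_genes=150, hypothesis_set_size=20, n_true_ratios=2,
        effect_size=2.0, seed=4,
    )
)
cfg = GrepConfig(seed=4)

Xf = filter_genes(data.X)
genes = [g for g in data.hypothesis_genes if g in Xf.index]
ratios = compute_log_ratios(Xf, genes, cfg.pseudocount)
permutation_significance(ratios, data.labels, cfg.ratio_config())
significant = select_significant(ratios, cfg.fdr_cutoff)

model = fit_grep(data.X, data.labels, data.hypothesis_genes, cfg)
G = build_ratio_network(significant.pairs, model.ratios, significant.t_stat)
print("top genes by ratio degree (positivity 1 = numerator in all its ratios):")
print(network_node_table(G).head(6).to_string(index=False))
print("planted pairs:", data.true_ratios)

planted = [g for p in data.true_ratios for g in p]
scan = planted + [g for g in data.hypothesis_genes if g not in planted][:3]
imp = gene_elimination_importance(
    data.X, data.labels, data.hypothesis_genes, cfg, genes_to_test=scan
)
print("\nleave-one-gene-out AUC cost (planted genes first):")
for gi in imp:
    print(f"  {gi.gene}: delta AUC {gi.delta:+.3f}")
print("\nplanted numerators sit at positivity ~1, denominators ~0, and their")
print("removal costs AUC; bystander genes cost nothing.")
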
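"""Gene-set overrepresentation and transcription-factor impact ranking.

Builds gene sets correlated with the planted DPG blocks (plus decoys), runs
per-DPG hypergeometric enrichment, tests a two-DPG union against a regulon
with Fisher's exact test, and ranks TF regulons by their GRN impact score.
"""

import dipackit as dk

design = dk.SyntheticDesign(
    n_genes=3000, dpg_block_sizes={7: 120, 8: 200}, dispersion=0.05, seed=2
)
cm, truth = dk.generate_counts(design)
deg_a = dk.test_differential_expression(cm, "PHH", "WT-HLC")
deg_b = dk.test_differential_expression(cm, "PHH", "KO-HLC")
deg_ba = dk.test_differential_expression(cm, "WT-HLC", "KO-HLC")
cfg = dk.DipacConfig()
result = dk.classify_all(dk.build_coordinates(deg_a, deg_b, deg_ba, cfg), cfg)

# tissue-style sets: one enriched set per planted block + uniform decoys
sets = dk.generate_gene_sets(truth, n_decoy_sets=10, set_size=60, seed=2)
table = dk.enrich_collection(result, sets, dpgs=[7, 8], alpha=0.001)
best = table.sort_values("pvalue").head(4)
print("top enriched (set, DPG) pairs — planted signatures should lead:")
print(best[["set", "dpg", "overlap", "odds_ratio", "pvalue", "padj"]].to_string(index=False))

# union enrichment: are "TF targets" (here the DPG8 signature) overrepresented
# among all downregulated-toward-reference genes (DPG7 u DPG8)?
union = set(result.genes_in_dpg(7)) | set(result.genes_in_dpg(8))
targets = sets.members("DPG8_signature")
odds, p = dk.fisher_union_test(union, targets, result.universe)
print(f"\nunion DPG7+8 vs DPG8 signature: OR = {odds:.2f}, Fisher p = {p:.3g}")

# GRN impact: per-target score = regulon weight x |transition log2FC|,
# TF summary = median target score, gated by regulon overrepresentation
regulons = dk.GeneSetCollection(sets=dict(sets.sets), category="TF")
impact = dk.tf_impact_summary(result, deg_ba, regulons, dpg=8, alpha=0.05)
print("\nranked TFs for DPG8 (higher summary = stronger influence):")
print(impact.ranked()[["n_targets", "summary", "enrich_p", "padj", "rank"]].to_string())
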
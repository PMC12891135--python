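"""Benign-vs-malignant differential feature analysis.

Runs feature-wise Wilcoxon rank-sum tests with Benjamini-Hochberg correction
and shows the direction of the Alu-subfamily contrast (higher in benign under
the generator's defaults) plus the top differential features.
"""

import plasmafrag as pf

spec = pf.CohortSpec(
    n_benign=15, n_malignant=15, fragments_per_sample=6000, seed=21, chrom_length=300_000
)
cohort = pf.simulate_cohort(spec)
bins = pf.build_bins(cohort.genome, 100_000)
feats = pf.extract_cohort_features(
    cohort.fragment_sets, cohort.genome, bins=bins,
    annotation=cohort.annotation, sites=cohort.dip_sites,
)
matrix = pf.assemble_features(feats, cohort.metadata)

table = pf.wilcoxon_differential(matrix)
print("Alu subfamily contrast (expected direction: benign):")
print(table.loc[["REP_AluY", "REP_AluS", "REP_AluJ"],
                ["median_benign", "median_malignant", "direction", "q_value"]]
      .round(5).to_string())

features, z = pf.top_k(table, matrix, k=10)
print(f"\ntop 10 differential features: {features}")
print(f"z-scored heatmap matrix: {z.shape[0]} samples x {z.shape[1]} features")
n_sig = int((table["q_value"] < 0.05).sum())
print(f"{n_sig} of {len(table)} features significant at q < 0.05")
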
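"""Expression profiling: FPKM, clustering and 2^-ddCt.

Simulates RNA-seq counts with a planted stress-responsive block, computes
FPKM and log10 values, clusters genes for a heatmap, and checks the
qRT-PCR calculator against planted fold changes.
"""
from sklearn.metrics import rand_score

from legfam import (
    SyntheticConfig, cut_clusters, ddct_fold_change, fpkm,
    generate_ct_table, generate_expression, generate_genomes,
    hierarchical_cluster, log_transform,
)

fixture = generate_genomes(
    SyntheticConfig(species_count=1, genes_per_species=60, seed=7,
                    planted_tandem_pairs=0, planted_segmental_pairs=0)
)
expr = generate_expression(fixture.truth, seed=7, dispersion=0.05,
                           fold_separation=8.0)
matrix = log_transform(fpkm(expr.counts, expr.lengths_kb, expr.totals))
clustering = hierarchical_cluster(matrix, linkage="average")
members = cut_clusters(clustering, 2)
truth_blocks = [fixture.truth.genes[g].expression_block
                for g in matrix.index]
predicted = [members[g] for g in matrix.index]
print(f"log10 FPKM matrix: {matrix.shape[0]} genes x "
      f"{matrix.shape[1]} samples")
print(f"Rand index of 2-cluster cut vs planted blocks: "
      f"{rand_score(truth_blocks, predicted):.3f}")

genes = sorted(fixture.truth.genes)[:3]
folds = dict(zip(genes, (4.0, 0.5, 1.0)))
ct = generate_ct_table(fixture.truth, folds, seed=7, noise_sd=0.0)
result = ddct_fold_change(ct).set_index("gene")
for gene, fold in folds.items():
    print(f"{gene}: planted fold {fold} -> "
          f"2^-ddCt recovers {result.loc[gene, 'fold_change']:.2f} "
          f"(ddCt {result.loc[gene, 'ddct']:+.2f})")
# Fold 0.5 gives ddCt +1 and fold 4 gives ddCt -2, matching the
# relative-quantification arithmetic exactly at zero noise.
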
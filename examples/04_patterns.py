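"""Pattern discovery: variable-gene PCA, clustering, and overlap counts.

Builds the gene x condition methylation matrix from the contrast example's
study, runs PCA on the most variable genes, clusters conditions over the
commonly hypermethylated genes, and decomposes the methylated-gene sets.
"""

from methkit.genes import aggregate_genes
from methkit.patterns import build_matrix, cluster_common_hyper, overlap_counts, pca, top_k_variable
from methkit.simulate import SimConfig, simulate_genome, simulate_methylome
from methkit.sites import classify_sites

cfg = SimConfig(
    genome_length=200_000,
    n_genes=120,
    depth_mean=20.0,
    affected_fraction=1.0,
    condition_effects={"control": 0.0, "intermediate": 2.0, "drought": 4.0},
    seed=42,
)
sequences, genes = simulate_genome(cfg)
tables = {}
for condition in ("control", "intermediate", "drought"):
    report, _ = simulate_methylome(cfg, sequences, genes, condition)
    tables[condition] = aggregate_genes(classify_sites(report, genes), condition)

matrix = top_k_variable(build_matrix(tables), 50)
res = pca(matrix)
print("PCA variance explained:", [f"{v:.1%}" for v in res.explained_variance_ratio])
print(res.scores.round(2).to_string())

clus = cluster_common_hyper(tables)
if clus is not None:
    print(f"\n{clus.n_features} genes hypermethylated in every condition; dendrogram:")
    print(clus.newick)

rep = overlap_counts(
    {c: set(t.loc[t["is_methylated_gene"], "gene_id"]) for c, t in tables.items()}
)
print(f"\nmethylated genes common to all conditions: {rep.common_to_all}")
print(
    "PC1 separates the shifted conditions from control; the Newick tree "
    "records average-linkage clustering of conditions over the common "
    "hypermethylated gene set."
)
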
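"""Classify cytosine sites and print a genome-wide summary table.

Every site passing the depth filter (total reads >= 5) gets three labels:
sequence context (CpG/CHG/CHH, from the reference), genomic region
(exonic/intronic/intergenic, from the gene models) and intensity
(hypomethylated <= 30%, hypermethylated >= 70%, intermediate between).
The summary reports the composition of methylated sites in each dimension.
"""

from methkit.simulate import SimConfig, simulate_genome, simulate_methylome
from methkit.sites import FilterConfig, classify_sites, summarize

cfg = SimConfig(seed=42)
sequences, genes = simulate_genome(cfg)
report, _ = simulate_methylome(cfg, sequences, genes, "control")

classified = classify_sites(report, genes, FilterConfig(min_depth=5))
stats = summarize(classified)

print(stats.to_frame().to_string(index=False))
print(
    f"\nOf {stats.n_total} depth-passing sites, {stats.n_methylated} carry at "
    "least one methylated read; each percentage triple (context, intensity, "
    "region) is computed over those methylated sites and sums to 100."
)
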
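"""Gene-level drought contrast: median shift, Wilcoxon + BH, DMG calling.

Simulates control / intermediate / drought methylomes with imposed exonic
shifts of 0 / +2 / +4 percentage points, aggregates each to gene-level
exonic methylation, and contrasts every condition against the control.
"""

from methkit.contrasts import contrast_family
from methkit.genes import aggregate_genes
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

for res in contrast_family(tables, "control"):
    print(
        f"{res.spec.test_condition:>12} vs control: "
        f"median_diff={res.median_diff:+.2f} points over {res.n_genes} genes, "
        f"sd_loci={res.sd_loci:.2f}, q={res.q_value:.2e}, DMGs(|delta|>=10)={res.n_dmg}"
    )
print(
    "\nThe median of per-gene level differences is the genome-wide effect "
    "size; it recovers the imposed +2/+4-point shifts up to sampling noise, "
    "and the BH-adjusted Wilcoxon q-values flag both shifts as significant."
)
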
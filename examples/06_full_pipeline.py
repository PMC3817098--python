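"""Run the whole pipeline from one configuration object.

Stages: load/align -> both scans x both treatments -> thresholds -> peak
calling and cis/trans classification -> hotspot counting/enrichment ->
two-locus epistasis screen. Outputs (peak TSV/BED, count tables, manifest)
land under the output directory.
"""

import vqtlscan as v

sim = v.SimConfig(
    n_segregants=109,
    chrom_lengths={"chr1": 410_000, "chr2": 410_000},
    seed=17,
    architectures=[
        v.Architecture("cis_additive", [10], effect=2.0),
        v.Architecture("trans_additive", [150], effect=2.0),
        v.Architecture("and_epistasis", [20, 160], effect=2.0),
        v.Architecture("direct_vqtl", [60], effect=2.0),
    ],
    n_null_phenotypes=6,
)
g = v.simulate_genotypes(sim)
panels, truth = v.simulate_expression(g, sim)

cfg = v.PipelineConfig(
    threshold_mode="fixed",
    fixed_threshold=1e-5,
    perm_phenotypes=5,
    perm_rounds=10,
    seed=7,
)
result = v.run_pipeline(cfg, "scratch/example_run", genotypes=g, expression=panels)

print("peak counts by test x treatment:")
print(result.count_table.to_string(index=False))
print(f"\nthresholds: { {f'{t}:{tr}': v_ for (t, tr), v_ in result.thresholds.items()} }")
print(f"interaction screens run: {len(result.interactions)}")
print("outputs written under scratch/example_run/ (see manifest.json)")
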
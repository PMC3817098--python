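"""Run both genome scans — mean effects and variance heterogeneity.

The Wilcoxon rank-sum scan finds loci that shift a phenotype's mean between
the two allele classes (classic eQTL). The Brown-Forsythe scan finds loci
whose allele classes differ in *variance* — the vQTL signal that marks
unmodeled interactions or direct variance control.
"""

import numpy as np

import vqtlscan as v

cfg = v.SimConfig(
    n_segregants=109,
    chrom_lengths={"chr1": 410_000, "chr2": 410_000},
    seed=17,
    architectures=[
        v.Architecture("trans_additive", [150], effect=2.0, phenotype_id="additive_gene"),
        # SD ratio 3: variance effects need to be large to clear n=109 power
        v.Architecture("direct_vqtl", [60], effect=3.0, phenotype_id="variance_gene"),
    ],
    n_null_phenotypes=3,
)
g = v.simulate_genotypes(cfg)
panels, truth = v.simulate_expression(g, cfg)
e = panels["glucose"]

for test in ("wilcoxon", "brown_forsythe"):
    scan = v.genome_scan(e, g, test)
    print(f"\n{test} scan ({scan.p_value.shape[0]} phenotypes x {scan.p_value.shape[1]} markers)")
    for j, pid in enumerate(scan.phenotype_ids):
        best = int(np.nanargmin(scan.p_value[j]))
        print(f"  {pid:16s} best marker {scan.marker_ids[best]:14s} p={scan.p_value[j, best]:.3g}")
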
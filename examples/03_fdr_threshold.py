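"""Calibrate a genome-wide p-value threshold by permutation FDR.

A subset of phenotypes has its values permuted across segregants (breaking
genotype-phenotype links while keeping each phenotype's distribution); the
resulting null p-values give, for any threshold t, the expected number of
false positives. FDR(t) = expected false / observed positives; the
threshold is the loosest t with FDR at or below the target.
"""

import vqtlscan as v

cfg = v.SimConfig(
    n_segregants=109,
    chrom_lengths={"chr1": 410_000, "chr2": 410_000},
    seed=5,
    architectures=[v.Architecture("trans_additive", [i * 30], effect=2.0) for i in range(5)],
    n_null_phenotypes=20,
)
g = v.simulate_genotypes(cfg)
panels, _ = v.simulate_expression(g, cfg)
e = panels["glucose"]

scan = v.genome_scan(e, g, "wilcoxon")
null = v.build_null(e, g, "wilcoxon", n_phenotypes=10, n_permutations=20, seed=1)

for target in (0.01, 0.05):
    t = v.threshold_for_fdr(null, scan, target)
    est = v.estimate_fdr(null, scan, t)
    print(
        f"target FDR {target:4.2f}: threshold p <= {t:.3g}, "
        f"{est.observed} positives, {est.expected_false:.2f} expected false "
        f"(FDR {est.fdr:.3f})"
    )
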
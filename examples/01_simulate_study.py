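"""Generate a synthetic segregant study and write it to disk.

The simulator emulates a two-parent haploid cross: per-chromosome Markov
chains of parental origin (Haldane map function), plus expression
phenotypes with planted genetic architectures — additive loci, AND-model
epistasis, direct variance-control loci, a shared-marker hotspot, and
pure-noise phenotypes.
"""

import vqtlscan as v

cfg = v.default_study(seed=0)
g = v.simulate_genotypes(cfg)
panels, truth = v.simulate_expression(g, cfg)

print(f"segregants: {g.n_segregants}")
print(f"markers:    {g.n_markers} on {len(cfg.chrom_lengths)} chromosomes")
print(f"phenotypes: {panels['glucose'].n_phenotypes} per treatment, "
      f"treatments: {list(panels)}")
print("\nplanted truth (first rows):")
print(truth.to_frame().head(8).to_string(index=False))

paths = v.write_study(panels, truth, g, "scratch/example_study")
print("\nwritten:")
for name, p in paths.items():
    print(f"  {name}: {p}")
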
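"""Collapse significant markers into peaks, classify cis/trans, and test
hotspot enrichment.

Greedy peak calling: the lowest-p significant marker seeds a peak and
absorbs all significant markers within 25 kb; repeat. A peak is *cis* when
it lies within 150 kb of the gene it regulates, *trans* otherwise. Trans
peaks piling into a few genomic intervals mark regulatory hotspots; a
chi-square compares their in-hotspot count against uniform expectation.
"""

import vqtlscan as v

cfg = v.SimConfig(
    n_segregants=109,
    chrom_lengths={"chr1": 410_000, "chr2": 410_000},
    seed=11,
    architectures=(
        [v.Architecture("cis_additive", [10], effect=2.0)]
        + [v.Architecture("hotspot_member", [150], effect=2.0) for _ in range(6)]
    ),
    n_null_phenotypes=4,
)
g = v.simulate_genotypes(cfg)
panels, _ = v.simulate_expression(g, cfg)
e = panels["glucose"]

scan = v.genome_scan(e, g, "wilcoxon")
all_peaks = []
for pid in scan.phenotype_ids:
    all_peaks.extend(v.call_peaks(scan, pid, 1e-5).peaks)
pset = v.PeakSet(peaks=all_peaks, threshold=1e-5)
v.classify_peaks(pset, e)
print(v.summarize_counts([pset]).to_string(index=False))

# the hotspot-member phenotypes share a causal marker near chr2:205 kb
hotspot_marker = g.marker_pos[150]
hs = v.HotspotSet(
    intervals=[("chr2", int(hotspot_marker) - 25_000, int(hotspot_marker) + 25_000, "h1")],
    genome_size={"chr1": 410_000, "chr2": 410_000},
)
trans = v.PeakSet(peaks=[pk for pk in pset if pk.cis_trans == "trans"])
from vqtlscan.hotspots import in_out_totals

totals = in_out_totals(v.count_in_hotspots(trans, hs))
frac = hs.covered_fraction()
cnt = totals["QTL"]
res = v.uniformity_chisq(cnt["in"], cnt["out"], frac)
print(
    f"\ntrans peaks in hotspot: {cnt['in']}/{cnt['in'] + cnt['out']} "
    f"(covered fraction {frac:.3f}): chi2={res.chi2:.1f}, p={res.p:.3g}, {res.direction}"
)
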
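"""vQTL-anchored epistasis screen: genotype-phenotype maps, interaction
contrasts, conditional scans within an anchor genotype, and candidate genes
near peaks.

The rationale: a non-additive interaction between two loci shows up as
variance heterogeneity at each locus in a one-dimensional scan, so detected
vQTL are promising anchors for a cheap epistasis screen — build the
multi-locus genotype-phenotype (GP) map for each (vQTL, other peak) pair of
the same phenotype, quantify non-additivity with the interaction contrast

    delta = (m11 - m10) - (m01 - m00)

(or its three-way alternating-sum analogue), and, where a genotype class
looks heterogeneous, re-scan for mean effects inside that class only.
This avoids the multiple-testing cost of an exhaustive two-dimensional scan.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
from intervaltree import IntervalTree

from .association import ScanResult, genome_scan
from .io_formats import ExpressionPanel, GenotypePanel
from .permutation import build_null, threshold_for_fdr

logger = logging.getLogger(__name__)

CANDIDATE_WINDOW_BP = 10_000


@dataclass
class GPMap:
    """Per genotype-class summary statistics for 2 or 3 loci.

    ``classes`` maps a genotype tuple like (0,1) (BY=0, RM=1 per locus, in
    ``loci`` order) to a dict with n, mean, sd, se. Classes with no data get
    n=0 and missing statistics; single-observation classes get n=1 with a
    mean but missing sd/se.
    """

    phenotype_id: str
    treatment: str
    loci: list[str]
    classes: dict[tuple[int, ...], dict[str, float]]

    def n_total(self) -> int:
        return int(sum(c["n"] for c in self.classes.values()))


@dataclass
class InteractionSummary:
    phenotype_id: str
    loci: list[str]
    delta: float
    se_delta: float
    marginal_variance_ratio: dict[str, float]
    flagged: bool


def gp_map(
    e: ExpressionPanel, g: GenotypePanel, phenotype_id: str, loci: list[str]
) -> GPMap:
    """Class-wise n/mean/SD/SE of one phenotype over 2- or 3-locus genotypes.

    Uses pairwise-complete observations (segregants with the phenotype and
    all loci observed).
    """
    if not 2 <= len(loci) <= 3:
        raise ValueError("gp_map supports 2 or 3 loci")
    if e.segregant_ids != g.segregant_ids:
        raise ValueError("panels are not sample-aligned")
    j = e.phenotype_index(phenotype_id)
    y = e.values[:, j]
    geno = np.column_stack([g.calls[:, g.marker_index(m)] for m in loci])
    keep = ~np.isnan(y) & ~np.isnan(geno).any(axis=1)
    y = y[keep]
    geno = geno[keep].astype(int)
    classes: dict[tuple[int, ...], dict[str, float]] = {}
    for combo in itertools.product((0, 1), repeat=len(loci)):
        mask = (geno == np.array(combo)).all(axis=1)
        n = int(mask.sum())
        if n == 0:
            classes[combo] = {"n": 0, "mean": np.nan, "sd": np.nan, "se": np.nan}
        elif n == 1:
            classes[combo] = {"n": 1, "mean": float(y[mask][0]), "sd": np.nan, "se": np.nan}
        else:
            sd = float(np.std(y[mask], ddof=1))
            classes[combo] = {
                "n": n,
                "mean": float(y[mask].mean()),
                "sd": sd,
                "se": sd / np.sqrt(n),
            }
    return GPMap(phenotype_id=phenotype_id, treatment=e.treatment, loci=list(loci), classes=classes)


def interaction_contrast(gpm: GPMap, flag_se_multiple: float = 2.0) -> InteractionSummary:
    """Non-additivity contrast on a GP map, with its standard error.

    Two loci: delta = (m11 - m10) - (m01 - m00). Three loci: the alternating
    sum over the genotype cube, sign = (-1)^(number of BY alleles). Missing
    whenever any class has n < 2. The marginal variance ratio per locus is
    var(allele 1 class) / var(allele 0 class) of the phenotype.
    """
    k = len(gpm.loci)
    if any(c["n"] < 2 for c in gpm.classes.values()):
        delta = np.nan
        se = np.nan
    else:
        delta = 0.0
        var = 0.0
        for combo, c in gpm.classes.items():
            sign = (-1) ** (k - sum(combo))
            delta += sign * c["mean"]
            var += c["se"] ** 2
        se = float(np.sqrt(var))
    # marginal variance ratios from the class-level moments
    ratios: dict[str, float] = {}
    for axis, locus in enumerate(gpm.loci):
        stats_by_allele = {}
        for allele in (0, 1):
            groups = [c for combo, c in gpm.classes.items() if combo[axis] == allele and c["n"] >= 1]
            n = sum(c["n"] for c in groups)
            if n < 2:
                stats_by_allele[allele] = np.nan
                continue
            mean = sum(c["n"] * c["mean"] for c in groups) / n
            # pooled second moment: within-class var + between-class spread
            ss = 0.0
            for c in groups:
                within = (c["n"] - 1) * c["sd"] ** 2 if c["n"] > 1 else 0.0
                ss += within + c["n"] * (c["mean"] - mean) ** 2
            stats_by_allele[allele] = ss / (n - 1)
        v0 = stats_by_allele.get(0, np.nan)
        v1 = stats_by_allele.get(1, np.nan)
        ratios[locus] = v1 / v0 if np.isfinite(v0) and v0 > 0 and np.isfinite(v1) else np.nan
    flagged = bool(np.isfinite(delta) and np.isfinite(se) and abs(delta) > flag_se_multiple * se)
    return InteractionSummary(
        phenotype_id=gpm.phenotype_id,
        loci=list(gpm.loci),
        delta=float(delta),
        se_delta=float(se),
        marginal_variance_ratio=ratios,
        flagged=flagged,
    )


def conditional_scan(
    e: ExpressionPanel,
    g: GenotypePanel,
    phenotype_id: str,
    anchor_marker: str,
    anchor_genotype: int,
    test: str = "wilcoxon",
    n_permutations: int = 500,
    target_fdr: float = 0.05,
    seed: int = 0,
    min_class_size: int = 2,
) -> tuple[ScanResult, float]:
    """Mean-effect scan restricted to segregants carrying one anchor allele.

    Only segregants with ``anchor_genotype`` (0=BY, 1=RM) at ``anchor_marker``
    enter the scan; the permutation threshold at ``target_fdr`` comes from
    ``n_permutations`` value-permutations of the subset phenotype. Returns
    (subset ScanResult, threshold); the threshold is NaN when no observed
    p-value achieves the target FDR.
    """
    if e.segregant_ids != g.segregant_ids:
        raise ValueError("panels are not sample-aligned")
    m = g.marker_index(anchor_marker)
    carriers = np.flatnonzero(g.calls[:, m] == anchor_genotype)
    if carriers.size == 0:
        raise ValueError(f"no segregants carry genotype {anchor_genotype} at {anchor_marker}")
    if carriers.size < 2 * min_class_size:
        raise ValueError(
            f"anchor subset of {carriers.size} segregants is below 2 x min class size"
        )
    g_sub = g.subset_segregants(carriers)
    j = e.phenotype_index(phenotype_id)
    e_sub = ExpressionPanel(
        segregant_ids=[e.segregant_ids[i] for i in carriers],
        phenotype_ids=[phenotype_id],
        treatment=e.treatment,
        values=e.values[carriers][:, [j]],
        gene_chrom=e.gene_chrom[[j]],
        gene_pos=e.gene_pos[[j]],
    )
    scan = genome_scan(e_sub, g_sub, test, min_class_size=min_class_size)
    null = build_null(
        e_sub, g_sub, test, n_phenotypes=1, n_permutations=n_permutations, seed=seed,
        min_class_size=min_class_size,
    )
    thr = threshold_for_fdr(null, scan, target_fdr)
    return scan, thr


def read_gff_genes(path) -> dict[str, IntervalTree]:
    """Index gene spans from a GFF3 file: chromosome -> IntervalTree.

    Only ``gene`` features are kept; the tree stores (start, end+1) in
    1-based inclusive converted to half-open, with the gene name (Name or ID
    attribute) as data.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True, merge_strategy="merge"
    )
    trees: dict[str, IntervalTree] = {}
    for feat in db.features_of_type("gene"):
        name = (feat.attributes.get("Name") or feat.attributes.get("ID") or ["?"])[0]
        trees.setdefault(feat.seqid, IntervalTree()).addi(feat.start, feat.end + 1, name)
    return trees


def candidate_genes(
    peak, annotation: dict[str, IntervalTree], window_bp: int = CANDIDATE_WINDOW_BP
) -> list[str]:
    """Genes whose annotated span intersects [center - window, center + window].

    Intersection, not containment; the window is measured from the peak's
    center SNP. An unannotated chromosome yields an empty list with a warning.
    """
    tree = annotation.get(str(peak.chrom))
    if tree is None:
        logger.warning("chromosome %s absent from annotation", peak.chrom)
        return []
    lo = peak.center_pos - window_bp
    hi = peak.center_pos + window_bp + 1  # inclusive right edge in half-open coords
    return sorted({iv.data for iv in tree.overlap(lo, hi)})


def screen_phenotype(
    e: ExpressionPanel,
    g: GenotypePanel,
    phenotype_id: str,
    vqtl_markers: list[str],
    other_markers: list[str],
    flag_se_multiple: float = 2.0,
) -> list[InteractionSummary]:
    """GP maps + contrasts for all (vQTL x {QTL or vQTL}) marker pairs.

    Mirrors a manual inspection of pairwise GP maps, with the numeric
    contrast replacing the visual call: a pair is flagged when
    |delta| > ``flag_se_multiple`` x SE(delta).
    """
    summaries = []
    seen = set()
    pool = list(dict.fromkeys(other_markers + vqtl_markers))
    for anchor in vqtl_markers:
        for other in pool:
            if other == anchor:
                continue
            key = frozenset((anchor, other))
            if key in seen:
                continue
            seen.add(key)
            gpm = gp_map(e, g, phenotype_id, [anchor, other])
            summaries.append(interaction_contrast(gpm, flag_se_multiple=flag_se_multiple))
    return summaries
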
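"""Per-marker two-group association tests and whole-matrix genome scans.

Two tests are implemented:

* Wilcoxon rank-sum (Mann-Whitney) for a shift in *mean* expression between
  the two parental genotype classes (GWAS). The default p-value is the
  tie-corrected normal approximation with a 0.5 continuity correction;
  an exact-enumeration mode exists for small groups and is used as a test
  oracle only.
* Brown-Forsythe (Levene with group medians) for *variance heterogeneity*
  between genotype classes (vGWAS): a one-way ANOVA F on the absolute
  deviations z_ij = |y_ij - median_j| with k = 2 groups,

      F = [(N - k)/(k - 1)] * sum_j n_j (zbar_j - zbar)^2
                             / sum_j sum_i (z_ij - zbar_j)^2,

  referred to F(k - 1, N - k).

Degenerate cells (a genotype class with fewer than ``min_class_size``
observations after pairwise-complete filtering) yield a missing (NaN)
p-value, never 0 or 1. Complete ties in the Wilcoxon test (zero tie-corrected
variance) are defined to return p = 1: uninformative, not invalid.

The genome scan loops over markers and vectorizes over phenotypes, so the
per-marker genotype split is computed once and medians/ranks are taken
column-wise over the whole expression matrix.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io_formats import ExpressionPanel, GenotypePanel

logger = logging.getLogger(__name__)

TESTS = ("wilcoxon", "brown_forsythe")

#: smallest positive double; reported when the Brown-Forsythe F is infinite
TINY_P = np.nextafter(0.0, 1.0)


@dataclass
class ScanResult:
    """Per-phenotype, per-marker statistics for one test and treatment.

    Matrices are (n_phenotypes, n_markers); NaN marks degenerate cells.
    ``n0``/``n1`` hold genotype-class sizes after missing-data removal.
    """

    phenotype_ids: list[str]
    marker_ids: list[str]
    marker_chrom: np.ndarray
    marker_pos: np.ndarray
    test: str
    treatment: str
    statistic: np.ndarray
    p_value: np.ndarray
    n0: np.ndarray
    n1: np.ndarray

    def __post_init__(self) -> None:
        shape = (len(self.phenotype_ids), len(self.marker_ids))
        for name in ("statistic", "p_value", "n0", "n1"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != shape:
                raise ValueError(f"{name} has shape {arr.shape}, expected {shape}")
            setattr(self, name, arr)
        p = self.p_value
        ok = np.isnan(p) | ((p > 0) & (p <= 1))
        if not ok.all():
            raise ValueError("p-values must lie in (0,1] or be missing")

    def row(self, phenotype_id: str) -> np.ndarray:
        return self.p_value[self.phenotype_ids.index(phenotype_id)]


def _clean_pair(values, groups):
    """Pairwise-complete observations: drop entries missing in either vector."""
    v = np.asarray(values, dtype=float)
    g = np.asarray(groups, dtype=float)
    keep = ~np.isnan(v) & ~np.isnan(g)
    return v[keep], g[keep]


def wilcoxon_test(values, groups, min_class_size: int = 2) -> tuple[float, float]:
    """Two-sided rank-sum test of a location shift between two genotype classes.

    Returns (U statistic of the group-1 class, p). Tie-corrected normal
    approximation with 0.5 continuity correction. A class below
    ``min_class_size`` gives (nan, nan); complete ties give p = 1.
    """
    v, g = _clean_pair(values, groups)
    n1 = int((g == 1).sum())
    n0 = int((g == 0).sum())
    if min(n0, n1) < min_class_size:
        return (np.nan, np.nan)
    ranks = stats.rankdata(v)
    r1 = ranks[g == 1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    n = n0 + n1
    _, counts = np.unique(v, return_counts=True)
    tie_term = float((counts**3 - counts).sum())
    var = n0 * n1 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return (float(u1), 1.0)
    mean = n0 * n1 / 2.0
    z = (u1 - mean - 0.5 * np.sign(u1 - mean)) / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return (float(u1), float(np.clip(p, TINY_P, 1.0)))


def wilcoxon_exact(values, groups) -> tuple[float, float]:
    """Exact two-sided rank-sum p by full enumeration of label assignments.

    Enumerates all C(n, n1) relabelings and counts assignments whose U is at
    least as far from the null mean as the observed one. Oracle mode for
    small samples; O(C(n, n1)).
    """
    v, g = _clean_pair(values, groups)
    n1 = int((g == 1).sum())
    n = len(v)
    ranks = stats.rankdata(v)
    mean = n1 * (n - n1) / 2.0

    def u_of(idx) -> float:
        return ranks[list(idx)].sum() - n1 * (n1 + 1) / 2.0

    obs = abs(u_of(np.flatnonzero(g == 1)) - mean)
    total = 0
    extreme = 0
    for combo in itertools.combinations(range(n), n1):
        total += 1
        if abs(u_of(combo) - mean) >= obs - 1e-12:
            extreme += 1
    u1 = u_of(np.flatnonzero(g == 1))
    return (float(u1), extreme / total)


def brown_forsythe_test(values, groups, min_class_size: int = 2) -> tuple[float, float]:
    """Brown-Forsythe equality-of-variances test between two genotype classes.

    ANOVA F on absolute deviations from the group medians, referred to
    F(1, N-2). Returns (F, p). Degenerate classes give (nan, nan); an
    infinite F (zero within-group spread of the deviations but a nonzero
    between-group difference) is reported as p = smallest positive double;
    all-zero deviations everywhere give (nan, nan).
    """
    v, g = _clean_pair(values, groups)
    z0 = np.abs(v[g == 0] - np.median(v[g == 0])) if (g == 0).sum() else np.array([])
    z1 = np.abs(v[g == 1] - np.median(v[g == 1])) if (g == 1).sum() else np.array([])
    n0, n1 = len(z0), len(z1)
    if min(n0, n1) < min_class_size:
        return (np.nan, np.nan)
    n = n0 + n1
    zbar0, zbar1 = z0.mean(), z1.mean()
    zbar = (n0 * zbar0 + n1 * zbar1) / n
    between = n0 * (zbar0 - zbar) ** 2 + n1 * (zbar1 - zbar) ** 2
    within = ((z0 - zbar0) ** 2).sum() + ((z1 - zbar1) ** 2).sum()
    if within == 0.0:
        if between == 0.0:
            return (np.nan, np.nan)  # phenotype constant within classes
        logger.debug("infinite Brown-Forsythe F; reporting smallest positive p")
        return (np.inf, TINY_P)
    f = (n - 2) * between / within
    return (float(f), float(stats.f.sf(f, 1, n - 2)))


def _rank_and_ties(values):
    """Column-wise ranks and tie-correction terms, computed once per scan."""
    ranks = stats.rankdata(values, axis=0)
    n_ph = values.shape[1]
    srt = np.sort(values, axis=0)
    any_tie = (srt[1:] == srt[:-1]).any(axis=0)
    tie_term = np.zeros(n_ph)
    for j in np.flatnonzero(any_tie):
        _, counts = np.unique(srt[:, j], return_counts=True)
        tie_term[j] = float((counts.astype(np.int64) ** 3 - counts).sum())
    return ranks, tie_term


def _scan_marker_wilcoxon(values, g_col, min_class_size, precomp=None):
    """Vectorized Wilcoxon over all phenotype columns for one marker.

    ``values``: (n_segregants, n_phenotypes) with no NaN; ``g_col``: genotype
    vector with no NaN. ``precomp`` holds (ranks, tie_term) from
    :func:`_rank_and_ties` when the value matrix is shared across markers.
    Returns (stat, p, n0, n1) arrays of length n_phenotypes.
    """
    n_ph = values.shape[1]
    n1 = int((g_col == 1).sum())
    n0 = int((g_col == 0).sum())
    if min(n0, n1) < min_class_size:
        nanrow = np.full(n_ph, np.nan)
        return nanrow, nanrow.copy(), np.full(n_ph, n0, float), np.full(n_ph, n1, float)
    n = n0 + n1
    ranks, tie_term = precomp if precomp is not None else _rank_and_ties(values)
    r1 = ranks[g_col == 1].sum(axis=0)
    u1 = r1 - n1 * (n1 + 1) / 2.0
    var = n0 * n1 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    mean = n0 * n1 / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (u1 - mean - 0.5 * np.sign(u1 - mean)) / np.sqrt(var)
        p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.clip(p, TINY_P, 1.0)
    p[var <= 0] = 1.0  # complete ties
    return u1, p, np.full(n_ph, n0, float), np.full(n_ph, n1, float)


def _scan_marker_bf(values, g_col, min_class_size, precomp=None):
    """Vectorized Brown-Forsythe over all phenotype columns for one marker."""
    n_ph = values.shape[1]
    m0 = g_col == 0
    m1 = g_col == 1
    n0 = int(m0.sum())
    n1 = int(m1.sum())
    if min(n0, n1) < min_class_size:
        nanrow = np.full(n_ph, np.nan)
        return nanrow, nanrow.copy(), np.full(n_ph, n0, float), np.full(n_ph, n1, float)
    n = n0 + n1
    z0 = np.abs(values[m0] - np.median(values[m0], axis=0))
    z1 = np.abs(values[m1] - np.median(values[m1], axis=0))
    zbar0 = z0.mean(axis=0)
    zbar1 = z1.mean(axis=0)
    zbar = (n0 * zbar0 + n1 * zbar1) / n
    between = n0 * (zbar0 - zbar) ** 2 + n1 * (zbar1 - zbar) ** 2
    within = ((z0 - zbar0) ** 2).sum(axis=0) + ((z1 - zbar1) ** 2).sum(axis=0)
    f = np.full(n_ph, np.nan)
    p = np.full(n_ph, np.nan)
    ok = within > 0
    f[ok] = (n - 2) * between[ok] / within[ok]
    p[ok] = stats.f.sf(f[ok], 1, n - 2)
    p[ok] = np.maximum(p[ok], TINY_P)
    inf_f = (~ok) & (between > 0)
    f[inf_f] = np.inf
    p[inf_f] = TINY_P
    return f, p, np.full(n_ph, n0, float), np.full(n_ph, n1, float)


def genome_scan(
    e: ExpressionPanel,
    g: GenotypePanel,
    test: str,
    min_class_size: int = 2,
) -> ScanResult:
    """Apply one two-group test to every phenotype x marker cell.

    Panels must be sample-aligned. Each cell uses pairwise-complete
    observations; the result equals looping the single-test function over
    cells. Vectorized over phenotypes within each marker when the marker has
    no missing calls (the common case); cells touched by missing data fall
    back to the scalar path.
    """
    if test not in TESTS:
        raise ValueError(f"unknown test {test!r}; expected one of {TESTS}")
    if e.segregant_ids != g.segregant_ids:
        raise ValueError("panels are not sample-aligned; call align_samples first")
    scalar = wilcoxon_test if test == "wilcoxon" else brown_forsythe_test
    vector = _scan_marker_wilcoxon if test == "wilcoxon" else _scan_marker_bf

    n_ph, n_mk = e.n_phenotypes, g.n_markers
    stat = np.full((n_ph, n_mk), np.nan)
    pval = np.full((n_ph, n_mk), np.nan)
    n0 = np.zeros((n_ph, n_mk))
    n1 = np.zeros((n_ph, n_mk))
    values = e.values
    pheno_missing = np.isnan(values).any(axis=0)
    precomp_clean = None
    if test == "wilcoxon" and not pheno_missing.any():
        precomp_clean = _rank_and_ties(values)
    for m in range(n_mk):
        g_col = g.calls[:, m]
        g_missing = np.isnan(g_col)
        if not g_missing.any() and not pheno_missing.any():
            stat[:, m], pval[:, m], n0[:, m], n1[:, m] = vector(
                values, g_col, min_class_size, precomp=precomp_clean
            )
            continue
        keep = ~g_missing
        clean_cols = ~pheno_missing
        if keep.any() and clean_cols.any():
            s, p, c0, c1 = vector(values[keep][:, clean_cols], g_col[keep], min_class_size)
            stat[clean_cols, m] = s
            pval[clean_cols, m] = p
            n0[clean_cols, m] = c0
            n1[clean_cols, m] = c1
        for j in np.flatnonzero(pheno_missing):
            s, p = scalar(values[:, j], g_col, min_class_size)
            stat[j, m], pval[j, m] = s, p
            v, gg = _clean_pair(values[:, j], g_col)
            n0[j, m] = (gg == 0).sum()
            n1[j, m] = (gg == 1).sum()
    return ScanResult(
        phenotype_ids=list(e.phenotype_ids),
        marker_ids=list(g.marker_ids),
        marker_chrom=g.marker_chrom.copy(),
        marker_pos=g.marker_pos.copy(),
        test=test,
        treatment=e.treatment,
        statistic=stat,
        p_value=pval,
        n0=n0,
        n1=n1,
    )
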
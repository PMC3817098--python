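"""Permutation null distribution and false-discovery-rate estimation.

The genome-wide significance threshold is calibrated by scanning permuted
copies of randomly sampled phenotypes: P_s phenotypes are drawn without
replacement, each is value-permuted R times (preserving the multiset of
values), and every permuted copy is scanned against all markers. Assuming
the permuted phenotypes carry no true signal, the p-values collected this
way estimate the study-wide null distribution of false-positive signals.

For a candidate threshold t the expected number of false positives in the
full study is

    E(t) = (P_total / P_s) * (1/R) * #(null p <= t)

and FDR(t) = E(t) / #(observed p <= t). The counting unit is significant
SNP tests. ``scale_to_study`` controls whether the P_total/P_s factor is
applied (default) or the estimate is left per-sampled-phenotype.

Null p-values are stored as counts on a fixed -log10 grid of resolution
0.01 to bound memory (``store="grid"``); queries snap an arbitrary
threshold down to the nearest grid point (conservative), and are exact at
grid points. ``store="full"`` keeps the raw null p-values for small
problems.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .association import ScanResult, genome_scan
from .io_formats import ExpressionPanel, GenotypePanel

logger = logging.getLogger(__name__)

GRID_RESOLUTION = 0.01
GRID_MAX_NEGLOG10 = 320.0  # beyond the smallest positive double


def _grid_index(t: float) -> int:
    """Index of the largest grid threshold <= t (grid_i = 10^(-0.01*i))."""
    neglog = -np.log10(t)
    return int(np.ceil(np.round(neglog / GRID_RESOLUTION, 9)))


@dataclass
class PermutationNull:
    """Null p-value distribution from permuted phenotype scans."""

    test: str
    treatment: str
    sampled_phenotypes: list[str]
    n_permutations: int  # R, per phenotype
    n_markers: int
    seed: int
    store: str = "grid"
    #: counts[i] = number of null p-values <= 10^(-GRID_RESOLUTION * i)
    grid_counts: np.ndarray = field(default=None)  # type: ignore[assignment]
    null_p: np.ndarray | None = None

    @property
    def n_scans(self) -> int:
        return len(self.sampled_phenotypes) * self.n_permutations

    def count_leq(self, t: float) -> float:
        """Number of null p-values <= t (snapped down to the grid if gridded)."""
        if self.store == "full":
            return float((self.null_p <= t).sum())
        i = _grid_index(t)
        if i >= len(self.grid_counts):
            return 0.0
        return float(self.grid_counts[i])


@dataclass
class FdrEstimate:
    """FDR at one threshold: expected false positives over observed positives."""

    threshold: float
    expected_false: float
    observed: int
    fdr: float


def build_null(
    e: ExpressionPanel,
    g: GenotypePanel,
    test: str,
    n_phenotypes: int,
    n_permutations: int,
    seed: int,
    store: str = "grid",
    min_class_size: int = 2,
) -> PermutationNull:
    """Scan permuted copies of randomly sampled phenotypes against all markers.

    ``n_phenotypes`` (P_s) phenotypes are sampled without replacement;
    each is permuted ``n_permutations`` (R) times. Reproducible given seed.
    """
    if n_phenotypes < 1 or n_permutations < 1:
        raise ValueError("n_phenotypes and n_permutations must be >= 1")
    if n_phenotypes > e.n_phenotypes:
        raise ValueError(
            f"cannot sample {n_phenotypes} phenotypes from a panel of {e.n_phenotypes}"
        )
    rng = np.random.default_rng(seed)
    sampled_idx = rng.choice(e.n_phenotypes, size=n_phenotypes, replace=False)
    sampled_ids = [e.phenotype_ids[i] for i in sampled_idx]
    n_seg = e.n_segregants

    # build one wide panel of all R permutations of each sampled phenotype
    # and scan it in blocks to reuse the vectorized per-marker path
    grid_len = int(GRID_MAX_NEGLOG10 / GRID_RESOLUTION) + 1
    grid_counts = np.zeros(grid_len, dtype=np.int64)
    all_null: list[np.ndarray] = []
    block = max(1, min(n_phenotypes, 4000 // max(1, n_permutations)))
    for start in range(0, n_phenotypes, block):
        ids = sampled_idx[start : start + block]
        cols = []
        for i in ids:
            base = e.values[:, i]
            for _ in range(n_permutations):
                cols.append(base[rng.permutation(n_seg)])
        perm_panel = ExpressionPanel(
            segregant_ids=list(e.segregant_ids),
            phenotype_ids=[f"perm{k}" for k in range(len(cols))],
            treatment=e.treatment,
            values=np.column_stack(cols),
        )
        scan = genome_scan(perm_panel, g, test, min_class_size=min_class_size)
        p = scan.p_value[~np.isnan(scan.p_value)]
        if store == "full":
            all_null.append(p)
        else:
            neglog = -np.log10(p)
            idx = np.floor(np.round(neglog / GRID_RESOLUTION, 9)).astype(int)
            idx = np.clip(idx, 0, grid_len - 1)
            # p <= grid_i for all i <= floor(neglog/res): cumulative from top
            hist = np.bincount(idx, minlength=grid_len)
            grid_counts += np.cumsum(hist[::-1])[::-1]
    return PermutationNull(
        test=test,
        treatment=e.treatment,
        sampled_phenotypes=sampled_ids,
        n_permutations=n_permutations,
        n_markers=g.n_markers,
        seed=seed,
        store=store,
        grid_counts=grid_counts if store == "grid" else None,
        null_p=np.concatenate(all_null) if store == "full" else None,
    )


def estimate_fdr(
    null: PermutationNull,
    observed: ScanResult,
    threshold: float,
    total_phenotypes: int | None = None,
    scale_to_study: bool = True,
) -> FdrEstimate:
    """Estimate the FDR at a p-value threshold from the permutation null.

    ``total_phenotypes`` defaults to the observed scan's phenotype count
    (P_total). The expected false-positive count is scaled from the P_s
    sampled phenotypes to the full study unless ``scale_to_study=False``.
    """
    if null.test != observed.test or null.treatment != observed.treatment:
        raise ValueError("null and observed scans disagree on test or treatment")
    if null.n_markers != len(observed.marker_ids):
        raise ValueError("null and observed scans disagree on the marker set")
    p_total = total_phenotypes if total_phenotypes is not None else len(observed.phenotype_ids)
    p_s = len(null.sampled_phenotypes)
    factor = (p_total / p_s) if scale_to_study else 1.0
    expected = factor * null.count_leq(threshold) / null.n_permutations
    obs_count = int((observed.p_value <= threshold).sum())
    if obs_count == 0:
        logger.warning("no observed positives at t=%g; FDR reported as +inf", threshold)
        fdr = np.inf if expected > 0 else 0.0
    else:
        fdr = expected / obs_count
    return FdrEstimate(threshold=threshold, expected_false=expected, observed=obs_count, fdr=fdr)


def threshold_for_fdr(
    null: PermutationNull,
    observed: ScanResult,
    target_fdr: float,
    total_phenotypes: int | None = None,
    scale_to_study: bool = True,
) -> float:
    """Largest observed p-value threshold whose estimated FDR is <= target.

    Candidate thresholds are the distinct observed p-values (the FDR
    estimate only changes there). Returns NaN when no threshold qualifies.
    """
    if not 0.0 < target_fdr < 1.0:
        raise ValueError("target_fdr must be in (0,1)")
    obs_p = observed.p_value[~np.isnan(observed.p_value)]
    if obs_p.size == 0:
        raise ValueError("observed scan has no valid p-values")
    for t in np.unique(obs_p)[::-1]:
        est = estimate_fdr(null, observed, float(t), total_phenotypes, scale_to_study)
        if est.fdr <= target_fdr:
            return float(t)
    return float("nan")
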
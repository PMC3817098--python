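"""Synthetic segregant panels and expression phenotypes with planted truth.

Emulates a two-parent haploid cross: each segregant's chromosome is a
two-state Markov chain of parental origins along the marker map. The first
marker is Bernoulli(0.5); the recombination probability between adjacent
markers follows the Haldane map function (no interference),

    r = 0.5 * (1 - exp(-2 d / 100)),   d [cM] = spacing_kb * cM_per_kb.

Expression phenotypes are Gaussian on the log2 scale around an architecture-
determined mean:

    y = mu + sum additive e * x
           + sum AND-epistasis e * x_A * x_B
           - sum duplicate-factor d * prod_j (1 - x_j)
           + eps,   eps ~ N(0, sigma_class^2)

where x is the RM-allele indicator and sigma_class may depend on genotype
for a direct variance-control locus. Hotspot-member phenotypes share one
causal marker. Treatments draw independent noise (and, optionally,
treatment-specific effect scaling).

Defaults follow the study design the pipeline targets: 109 segregants,
16 yeast-length chromosomes, one marker every 4.1 kb (~2950 markers),
0.35 cM/kb.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import (
    ExpressionPanel,
    GenotypePanel,
    write_expression,
    write_genotypes,
)

#: S. cerevisiae chromosome lengths (bp), chrI..chrXVI
YEAST_CHROM_LENGTHS = {
    "chrI": 230_218,
    "chrII": 813_184,
    "chrIII": 316_620,
    "chrIV": 1_531_933,
    "chrV": 576_874,
    "chrVI": 270_161,
    "chrVII": 1_090_940,
    "chrVIII": 562_643,
    "chrIX": 439_888,
    "chrX": 745_751,
    "chrXI": 666_816,
    "chrXII": 1_078_177,
    "chrXIII": 924_431,
    "chrXIV": 784_333,
    "chrXV": 1_091_291,
    "chrXVI": 948_066,
}

ARCHITECTURES = (
    "cis_additive",
    "trans_additive",
    "hotspot_member",
    "and_epistasis",
    "duplicate_factor_3locus",
    "direct_vqtl",
)


@dataclass
class Architecture:
    """One planted phenotype architecture.

    ``kind`` is one of ``ARCHITECTURES``; ``loci`` holds marker ids (filled
    by index when given as ints); ``effect`` is the effect size on the log2
    scale (for direct_vqtl, the SD ratio sigma_RM / sigma_BY at the locus).
    """

    kind: str
    loci: list
    effect: float
    phenotype_id: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ARCHITECTURES:
            raise ValueError(f"unknown architecture {self.kind!r}")


@dataclass
class SimConfig:
    n_segregants: int = 109
    chrom_lengths: dict[str, int] = field(default_factory=lambda: dict(YEAST_CHROM_LENGTHS))
    marker_spacing_bp: int = 4_100
    cm_per_kb: float = 0.35
    noise_sd: float = 1.0
    baseline: float = 8.0  # mean log2 expression level
    architectures: list[Architecture] = field(default_factory=list)
    n_null_phenotypes: int = 0  # pure-noise phenotypes appended after planted ones
    treatments: tuple[str, ...] = ("glucose", "ethanol")
    seed: int = 0

    def __post_init__(self) -> None:
        if any(length <= 0 for length in self.chrom_lengths.values()):
            raise ValueError("chromosome lengths must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def recomb_prob(self) -> float:
        """Adjacent-marker recombination fraction under the Haldane map."""
        d_cm = (self.marker_spacing_bp / 1000.0) * self.cm_per_kb
        return 0.5 * (1.0 - np.exp(-2.0 * d_cm / 100.0))


@dataclass
class SimTruth:
    """Planted architecture per phenotype, for recovery tests."""

    records: list[dict]

    def causal_markers(self, phenotype_id: str) -> list[str]:
        return [r["marker_id"] for r in self.records if r["phenotype_id"] == phenotype_id]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.records,
            columns=["phenotype_id", "architecture", "marker_id", "effect"],
        )


def simulate_genotypes(cfg: SimConfig, rng: np.random.Generator | None = None) -> GenotypePanel:
    """Haploid segregant panel as per-chromosome parental-origin Markov chains."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    marker_ids: list[str] = []
    chroms: list[str] = []
    pos: list[int] = []
    for chrom, length in cfg.chrom_lengths.items():
        p = cfg.marker_spacing_bp // 2
        while p <= length:
            marker_ids.append(f"{chrom}_{p}")
            chroms.append(chrom)
            pos.append(p)
            p += cfg.marker_spacing_bp
    n_mk = len(marker_ids)
    r = cfg.recomb_prob
    calls = np.empty((cfg.n_segregants, n_mk))
    chrom_arr = np.array(chroms, dtype=object)
    for chrom in cfg.chrom_lengths:
        idx = np.flatnonzero(chrom_arr == chrom)
        m = len(idx)
        if m == 0:
            continue
        state = rng.random(cfg.n_segregants) < 0.5
        block = np.empty((cfg.n_segregants, m), dtype=bool)
        block[:, 0] = state
        if m > 1:
            flips = rng.random((cfg.n_segregants, m - 1)) < r
            block[:, 1:] = flips
            np.logical_xor.accumulate(block, axis=1, out=block)
        calls[:, idx] = block.astype(float)
    return GenotypePanel(
        segregant_ids=[f"seg{i:03d}" for i in range(cfg.n_segregants)],
        marker_ids=marker_ids,
        marker_chrom=chrom_arr,
        marker_pos=np.array(pos, dtype=np.int64),
        calls=calls,
    )


def _resolve_loci(arch: Architecture, g: GenotypePanel, rng: np.random.Generator) -> list[str]:
    loci = []
    for loc in arch.loci:
        if isinstance(loc, (int, np.integer)):
            loci.append(g.marker_ids[int(loc)])
        elif loc is None:
            loci.append(g.marker_ids[int(rng.integers(g.n_markers))])
        else:
            if loc not in g.marker_ids:
                raise ValueError(f"architecture locus {loc!r} is not a marker in the panel")
            loci.append(loc)
    return loci


def simulate_expression(
    g: GenotypePanel, cfg: SimConfig, rng: np.random.Generator | None = None
) -> tuple[dict[str, ExpressionPanel], SimTruth]:
    """Per-treatment expression panels with the planted architectures + truth.

    Every architecture produces one phenotype (shared across treatments with
    independent noise); ``n_null_phenotypes`` pure-noise phenotypes are
    appended. Phenotype gene positions are drawn uniformly on the genome;
    a cis_additive phenotype is positioned at its causal marker.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 1)
    n_seg = g.n_segregants
    records: list[dict] = []
    pheno_ids: list[str] = []
    gene_chrom: list = []
    gene_pos: list[float] = []
    mean_parts: list[np.ndarray] = []
    sd_parts: list[np.ndarray] = []

    chrom_names = list(cfg.chrom_lengths)

    def random_position() -> tuple[str, int]:
        c = chrom_names[int(rng.integers(len(chrom_names)))]
        return c, int(rng.integers(1, cfg.chrom_lengths[c] + 1))

    for k, arch in enumerate(cfg.architectures):
        pid = arch.phenotype_id or f"ph_{arch.kind}_{k:04d}"
        loci = _resolve_loci(arch, g, rng)
        x = np.column_stack([g.calls[:, g.marker_index(m)] for m in loci])
        mu = np.full(n_seg, cfg.baseline)
        sd = np.full(n_seg, cfg.noise_sd)
        if arch.kind in ("cis_additive", "trans_additive", "hotspot_member"):
            mu = mu + arch.effect * x[:, 0]
        elif arch.kind == "and_epistasis":
            mu = mu + arch.effect * x[:, 0] * x[:, 1]
        elif arch.kind == "duplicate_factor_3locus":
            mu = mu - arch.effect * np.prod(1 - x, axis=1)
        elif arch.kind == "direct_vqtl":
            sd = np.where(x[:, 0] == 1, cfg.noise_sd * arch.effect, cfg.noise_sd)
        pheno_ids.append(pid)
        if arch.kind == "cis_additive":
            m = g.marker_index(loci[0])
            gene_chrom.append(str(g.marker_chrom[m]))
            gene_pos.append(float(g.marker_pos[m]))
        else:
            c, p = random_position()
            gene_chrom.append(c)
            gene_pos.append(float(p))
        mean_parts.append(mu)
        sd_parts.append(sd)
        for m in loci:
            records.append(
                {"phenotype_id": pid, "architecture": arch.kind, "marker_id": m, "effect": arch.effect}
            )

    for k in range(cfg.n_null_phenotypes):
        pheno_ids.append(f"ph_null_{k:04d}")
        c, p = random_position()
        gene_chrom.append(c)
        gene_pos.append(float(p))
        mean_parts.append(np.full(n_seg, cfg.baseline))
        sd_parts.append(np.full(n_seg, cfg.noise_sd))

    means = np.column_stack(mean_parts) if mean_parts else np.empty((n_seg, 0))
    sds = np.column_stack(sd_parts) if sd_parts else np.empty((n_seg, 0))
    panels = {}
    for treatment in cfg.treatments:
        noise = rng.standard_normal(means.shape) * sds
        panels[treatment] = ExpressionPanel(
            segregant_ids=list(g.segregant_ids),
            phenotype_ids=list(pheno_ids),
            treatment=treatment,
            values=means + noise,
            gene_chrom=np.array(gene_chrom, dtype=object),
            gene_pos=np.array(gene_pos, dtype=float),
        )
    return panels, SimTruth(records=records)


def write_study(
    panels: dict[str, ExpressionPanel], truth: SimTruth, g: GenotypePanel, out_dir
) -> dict[str, Path]:
    """Emit the study as the pipeline's TSV dialects plus a truth table."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {"genotypes": out / "genotypes.tsv", "truth": out / "truth.tsv"}
    write_genotypes(g, paths["genotypes"])
    truth.to_frame().to_csv(paths["truth"], sep="\t", index=False)
    for treatment, panel in panels.items():
        p = out / f"expression_{treatment}.tsv"
        write_expression(panel, p)
        paths[f"expression_{treatment}"] = p
    return paths


def default_study(seed: int = 0, **overrides) -> SimConfig:
    """A study-shaped default configuration: a mix of planted architectures.

    Keeps the panel dimensions of the target design (109 segregants, ~2950
    markers, 2 treatments) while planting a handful of each architecture.
    """
    archs: list[Architecture] = []
    for _ in range(6):
        archs.append(Architecture("cis_additive", [None], effect=2.0))
        archs.append(Architecture("trans_additive", [None], effect=2.0))
    for _ in range(4):
        archs.append(Architecture("and_epistasis", [None, None], effect=2.0))
        archs.append(Architecture("direct_vqtl", [None], effect=2.0))
    # a regulatory hotspot: several phenotypes share one causal marker
    for _ in range(8):
        archs.append(Architecture("hotspot_member", [200], effect=2.0))
    archs.append(Architecture("duplicate_factor_3locus", [None, None, None], effect=2.0))
    cfg = SimConfig(architectures=archs, n_null_phenotypes=30, seed=seed)
    for key, val in overrides.items():
        setattr(cfg, key, val)
    return cfg
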
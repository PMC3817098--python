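"""End-to-end orchestration: scan -> threshold -> peaks -> classification ->
hotspots -> epistasis screen, from one configuration object.

Every stage writes its outputs as the documented TSVs so stages are also
independently runnable; a machine-readable manifest records the seed, the
configuration hash, and package versions for reproducibility.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import TESTS, genome_scan
from .epistasis import screen_phenotype
from .hotspots import count_in_hotspots, in_out_totals, qtl_vs_vqtl_chisq, uniformity_chisq
from .io_formats import (
    ExpressionPanel,
    GenotypePanel,
    HotspotSet,
    align_samples,
    read_expression,
    read_genotypes,
    read_hotspots_bed,
    write_peaks,
)
from .peaks import PeakSet, call_peaks, classify_peaks, summarize_counts
from .permutation import build_null, estimate_fdr, threshold_for_fdr

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All paths and parameters for one pipeline run.

    ``threshold_mode`` is either "fixed" (use ``fixed_threshold``, default
    1e-5) or "fdr" (invert the permutation null at ``target_fdr``).
    """

    genotype_path: str = ""
    expression_paths: dict = field(default_factory=dict)  # treatment -> path
    hotspot_bed: str | None = None
    tests: tuple[str, ...] = TESTS
    threshold_mode: str = "fixed"
    fixed_threshold: float = 1e-5
    target_fdr: float = 0.05
    perm_phenotypes: int = 200
    perm_rounds: int = 100
    peak_window_bp: int = 25_000
    two_peak_distance_bp: int = 50_000
    cis_distance_bp: int = 150_000
    candidate_window_bp: int = 10_000
    min_class_size: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("peak_window_bp", "two_peak_distance_bp", "cis_distance_bp", "candidate_window_bp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.threshold_mode == "fixed" and not 0.0 < self.fixed_threshold < 1.0:
            raise ValueError("fixed_threshold must be in (0,1)")
        if self.threshold_mode not in ("fixed", "fdr"):
            raise ValueError("threshold_mode must be 'fixed' or 'fdr'")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "tests" in data:
            data["tests"] = tuple(data["tests"])
        return cls(**data)


@dataclass
class PipelineResult:
    """Everything one run produced, keyed by (test, treatment) where relevant."""

    scans: dict
    thresholds: dict
    fdr_at_threshold: dict
    peak_sets: dict
    count_table: pd.DataFrame
    hotspot_tables: dict
    enrichment: dict
    interactions: dict
    manifest: dict


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raise with stage name
                raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
            logger.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
            return out

        return inner

    return wrap


def run_pipeline(
    cfg: PipelineConfig,
    out_dir,
    genotypes: GenotypePanel | None = None,
    expression: dict[str, ExpressionPanel] | None = None,
    hotspots: HotspotSet | None = None,
) -> PipelineResult:
    """Run every stage and write outputs + a run manifest under ``out_dir``.

    Panels may be passed in memory (as the library API does) or read from
    the configured paths. Deterministic given the config seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    @_stage("load")
    def load():
        g = genotypes if genotypes is not None else read_genotypes(cfg.genotype_path)
        panels = expression
        if panels is None:
            panels = {
                treatment: read_expression(path, treatment)
                for treatment, path in cfg.expression_paths.items()
            }
        aligned = {}
        g_out = g
        for treatment, panel in panels.items():
            g_out, aligned[treatment] = align_samples(g, panel)
        return g_out, aligned

    g, panels = load()

    hs = hotspots
    if hs is None and cfg.hotspot_bed:
        genome_size = {
            str(c): int(g.marker_pos[g.marker_chrom.astype(str) == str(c)].max())
            for c in pd.unique(g.marker_chrom.astype(str))
        }
        hs = read_hotspots_bed(cfg.hotspot_bed, genome_size)

    scans = {}
    thresholds = {}
    fdrs = {}
    peak_sets: dict = {}

    @_stage("scan")
    def do_scans():
        for test in cfg.tests:
            for treatment, panel in panels.items():
                scans[(test, treatment)] = genome_scan(
                    panel, g, test, min_class_size=cfg.min_class_size
                )

    do_scans()

    @_stage("threshold")
    def do_thresholds():
        # four independent nulls, one per test x treatment set
        for i, ((test, treatment), scan) in enumerate(sorted(scans.items())):
            panel = panels[treatment]
            null = build_null(
                panel,
                g,
                test,
                n_phenotypes=min(cfg.perm_phenotypes, panel.n_phenotypes),
                n_permutations=cfg.perm_rounds,
                seed=cfg.seed + 1000 + i,
                min_class_size=cfg.min_class_size,
            )
            if cfg.threshold_mode == "fixed":
                t = cfg.fixed_threshold
            else:
                t = threshold_for_fdr(null, scan, cfg.target_fdr)
            thresholds[(test, treatment)] = t
            if np.isfinite(t):
                fdrs[(test, treatment)] = estimate_fdr(null, scan, t).fdr

    do_thresholds()

    @_stage("peaks")
    def do_peaks():
        for (test, treatment), scan in scans.items():
            t = thresholds[(test, treatment)]
            if not np.isfinite(t):
                peak_sets[(test, treatment)] = PeakSet(
                    peaks=[], threshold=t, scan_id=f"{test}:{treatment}"
                )
                continue
            all_peaks = []
            for pid in scan.phenotype_ids:
                ps = call_peaks(scan, pid, t, window_bp=cfg.peak_window_bp)
                all_peaks.extend(ps.peaks)
            pset = PeakSet(peaks=all_peaks, threshold=t, scan_id=f"{test}:{treatment}")
            classify_peaks(pset, panels[treatment])
            peak_sets[(test, treatment)] = pset
            write_peaks(
                pset,
                out / f"peaks_{test}_{treatment}.tsv",
                out / f"peaks_{test}_{treatment}.bed",
            )

    do_peaks()

    count_table = summarize_counts(list(peak_sets.values()))
    count_table.to_csv(out / "peak_counts.tsv", sep="\t", index=False)

    hotspot_tables: dict = {}
    enrichment: dict = {}
    if hs is not None:

        @_stage("hotspots")
        def do_hotspots():
            frac = hs.covered_fraction()
            for treatment in panels:
                trans_peaks = PeakSet(
                    peaks=[
                        pk
                        for test in cfg.tests
                        for pk in peak_sets[(test, treatment)]
                        if pk.cis_trans == "trans"
                    ]
                )
                table = count_in_hotspots(trans_peaks, hs)
                hotspot_tables[treatment] = table
                table.to_csv(out / f"hotspot_counts_{treatment}.tsv", sep="\t", index=False)
                totals = in_out_totals(table)
                for test_label in ("QTL", "vQTL"):
                    cnt = totals[test_label]
                    if cnt["in"] + cnt["out"]:
                        enrichment[(treatment, test_label, "uniformity")] = uniformity_chisq(
                            cnt["in"], cnt["out"], frac
                        )
                tab = np.array(
                    [
                        [totals["QTL"]["in"], totals["QTL"]["out"]],
                        [totals["vQTL"]["in"], totals["vQTL"]["out"]],
                    ]
                )
                if (tab.sum(axis=0) > 0).all() and (tab.sum(axis=1) > 0).all():
                    enrichment[(treatment, "QTLvsvQTL", "2x2")] = qtl_vs_vqtl_chisq(tab)

        do_hotspots()

    interactions: dict = {}

    @_stage("epistasis")
    def do_epistasis():
        for treatment, panel in panels.items():
            vq = peak_sets.get(("brown_forsythe", treatment))
            q = peak_sets.get(("wilcoxon", treatment))
            if vq is None:
                continue
            by_pheno_v: dict[str, list[str]] = {}
            for pk in vq:
                if pk.member_ids:
                    by_pheno_v.setdefault(pk.phenotype_id, []).append(
                        pk.member_ids[pk.member_pos.index(pk.center_pos)]
                    )
            by_pheno_q: dict[str, list[str]] = {}
            if q is not None:
                for pk in q:
                    if pk.member_ids:
                        by_pheno_q.setdefault(pk.phenotype_id, []).append(
                            pk.member_ids[pk.member_pos.index(pk.center_pos)]
                        )
            for pid, vmarkers in by_pheno_v.items():
                others = by_pheno_q.get(pid, [])
                summaries = screen_phenotype(panel, g, pid, vmarkers, others)
                if summaries:
                    interactions[(treatment, pid)] = summaries

    do_epistasis()

    manifest = {
        "package": "vqtlscan",
        "version": __version__,
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(cfg).items()},
        "thresholds": {f"{t}:{tr}": float(v) for (t, tr), v in thresholds.items()},
        "numpy": np.__version__,
        "pandas": pd.__version__,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)

    return PipelineResult(
        scans=scans,
        thresholds=thresholds,
        fdr_at_threshold=fdrs,
        peak_sets=peak_sets,
        count_table=count_table,
        hotspot_tables=hotspot_tables,
        enrichment=enrichment,
        interactions=interactions,
        manifest=manifest,
    )
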
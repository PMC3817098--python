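"""Presentation-layer figures: peak-vs-gene scatter, Manhattan plots, GP maps.

Purely presentational; nothing here feeds back into the analysis.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .association import ScanResult
from .epistasis import GPMap
from .peaks import PeakSet


def _genome_offsets(chrom_labels, positions):
    """Cumulative bp offset per chromosome for genome-wide x-axes."""
    offsets = {}
    total = 0
    for c in dict.fromkeys(chrom_labels):
        mask = np.asarray(chrom_labels) == c
        offsets[c] = total
        total += int(np.max(np.asarray(positions)[mask])) + 1
    return offsets, total


def peak_position_scatter(peak_sets: list[PeakSet], expression_panel, ax=None):
    """Peak position vs affected-gene position; cis peaks fall on the diagonal."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    xs, ys, colors = [], [], []
    all_chrom, all_pos = [], []
    for ps in peak_sets:
        for pk in ps:
            all_chrom.append(pk.chrom)
            all_pos.append(pk.center_pos)
    known = expression_panel.position_known()
    for j, c in enumerate(expression_panel.gene_chrom):
        if known[j]:
            all_chrom.append(str(c))
            all_pos.append(int(expression_panel.gene_pos[j]))
    if not all_pos:
        ax.set_xlabel("peak position (genome bp)")
        ax.set_ylabel("gene position (genome bp)")
        return ax
    offsets, total = _genome_offsets(all_chrom, all_pos)
    for ps in peak_sets:
        for pk in ps:
            j = expression_panel.phenotype_index(pk.phenotype_id)
            if not known[j]:
                continue
            xs.append(offsets[pk.chrom] + pk.center_pos)
            ys.append(offsets[str(expression_panel.gene_chrom[j])] + expression_panel.gene_pos[j])
            colors.append("tab:red" if pk.test == "QTL" else "tab:blue")
    ax.scatter(xs, ys, s=8, c=colors, alpha=0.6)
    ax.set_xlim(0, total)
    ax.set_ylim(0, total)
    ax.set_xlabel("peak position (genome bp)")
    ax.set_ylabel("gene position (genome bp)")
    return ax


def manhattan(scan: ScanResult, phenotype_id: str, threshold: float | None = None, ax=None):
    """-log10(p) along the genome for one phenotype, with the threshold line."""
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    p = scan.row(phenotype_id)
    chroms = scan.marker_chrom.astype(str)
    offsets, total = _genome_offsets(chroms, scan.marker_pos)
    x = np.array([offsets[c] for c in chroms]) + scan.marker_pos
    with np.errstate(divide="ignore"):
        y = -np.log10(p)
    ax.scatter(x, y, s=4, c=[0.3 if offsets[c] // 1 % 2 else 0.6 for c in chroms], cmap="gray", vmin=0, vmax=1)
    if threshold is not None and np.isfinite(threshold):
        ax.axhline(-np.log10(threshold), linestyle=":", color="k")
    ax.set_xlim(0, total)
    ax.set_xlabel("genome position (bp)")
    ax.set_ylabel(r"$-\log_{10} p$")
    ax.set_title(f"{phenotype_id} [{scan.test}, {scan.treatment}]")
    return ax


def gp_map_bars(gpm: GPMap, ax=None):
    """Class means with +/-1 SE bars for a 2- or 3-locus GP map."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3))
    labels, means, ses = [], [], []
    for combo, c in sorted(gpm.classes.items()):
        labels.append("/".join("RM" if a else "BY" for a in combo))
        means.append(c["mean"])
        ses.append(c["se"] if np.isfinite(c.get("se", np.nan)) else 0.0)
    xs = np.arange(len(labels))
    ax.bar(xs, means, yerr=ses, capsize=3)
    ax.set_xticks(xs)
    ax.set_xticklabels(labels, rotation=45, ha="right")
    ax.set_ylabel("log2 expression")
    ax.set_title(f"{gpm.phenotype_id} [{gpm.treatment}] @ {', '.join(gpm.loci)}")
    return ax


def plot_outputs(result, out_dir, expression_panels: dict | None = None) -> list:
    """Write the standard figure set for a pipeline result; returns paths."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    if expression_panels:
        for treatment, panel in expression_panels.items():
            sets = [ps for (t, tr), ps in result.peak_sets.items() if tr == treatment]
            fig, ax = plt.subplots(figsize=(6, 6))
            peak_position_scatter(sets, panel, ax=ax)
            path = out / f"peak_scatter_{treatment}.png"
            fig.savefig(path, dpi=120)
            plt.close(fig)
            written.append(path)
    return written
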
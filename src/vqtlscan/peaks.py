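"""Collapse significant SNPs into association peaks; classify cis vs trans.

Peak definition: among the unassigned significant SNPs, the one with the
lowest p-value becomes a peak center (ties broken leftmost by chromosome
label, then position); every unassigned significant SNP on the same
chromosome within +/-25 kb of the center joins that peak; repeat until no
significant SNP remains. Two peak centers on the same chromosome therefore
end up more than 50 kb apart unless separated by an earlier greedy round.

A peak is *cis* when it lies on the same chromosome as, and within 150 kb
(inclusive) of, the gene whose expression it affects; *trans* otherwise;
*unknown* when the gene has no annotated position (such peaks count in
overall totals but not in cis/trans ones).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .association import ScanResult

PEAK_WINDOW_BP = 25_000
CIS_DISTANCE_BP = 150_000


@dataclass
class Peak:
    phenotype_id: str
    treatment: str
    test: str
    chrom: str
    center_pos: int
    center_p: float
    member_ids: list[str]
    member_pos: list[int]
    cis_trans: str = "unknown"

    def __post_init__(self) -> None:
        if self.member_ids:
            if any(abs(p - self.center_pos) > PEAK_WINDOW_BP for p in self.member_pos):
                raise ValueError("peak member outside +/-25 kb of center")
        if self.cis_trans not in ("cis", "trans", "unknown"):
            raise ValueError(f"bad cis_trans label: {self.cis_trans}")


@dataclass
class PeakSet:
    peaks: list[Peak]
    threshold: float | None = None
    scan_id: str | None = None

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)


def call_peaks(
    scan: ScanResult,
    phenotype_id: str,
    threshold: float,
    window_bp: int = PEAK_WINDOW_BP,
) -> PeakSet:
    """Greedy peak assignment for one phenotype's scan row."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0,1)")
    row = scan.row(phenotype_id)
    sig = np.flatnonzero(~np.isnan(row) & (row <= threshold))
    chrom = scan.marker_chrom.astype(str)
    pos = scan.marker_pos
    unassigned = set(int(i) for i in sig)
    peaks: list[Peak] = []
    while unassigned:
        # lowest p; ties -> leftmost by (chrom, pos)
        center = min(unassigned, key=lambda i: (row[i], chrom[i], pos[i]))
        members = sorted(
            i
            for i in unassigned
            if chrom[i] == chrom[center] and abs(int(pos[i]) - int(pos[center])) <= window_bp
        )
        unassigned.difference_update(members)
        peaks.append(
            Peak(
                phenotype_id=phenotype_id,
                treatment=scan.treatment,
                test="QTL" if scan.test == "wilcoxon" else "vQTL",
                chrom=chrom[center],
                center_pos=int(pos[center]),
                center_p=float(row[center]),
                member_ids=[scan.marker_ids[i] for i in members],
                member_pos=[int(pos[i]) for i in members],
            )
        )
    return PeakSet(peaks=peaks, threshold=threshold, scan_id=f"{scan.test}:{scan.treatment}")


def classify_cis_trans(
    peak: Peak,
    gene_chrom: str | None,
    gene_pos: float | None,
    cis_distance_bp: int = CIS_DISTANCE_BP,
) -> str:
    """cis iff same chromosome and |center - gene| <= 150 kb (inclusive)."""
    if gene_chrom is None or gene_pos is None or (isinstance(gene_pos, float) and np.isnan(gene_pos)):
        return "unknown"
    if str(peak.chrom) != str(gene_chrom):
        return "trans"
    return "cis" if abs(peak.center_pos - float(gene_pos)) <= cis_distance_bp else "trans"


def classify_peaks(peak_set: PeakSet, expression_panel) -> PeakSet:
    """Label every peak in place using the panel's gene positions."""
    for pk in peak_set.peaks:
        j = expression_panel.phenotype_index(pk.phenotype_id)
        pk.cis_trans = classify_cis_trans(
            pk, expression_panel.gene_chrom[j], expression_panel.gene_pos[j]
        )
    return peak_set


def summarize_counts(peak_sets: list[PeakSet]) -> pd.DataFrame:
    """Peak counts by test x treatment x cis/trans, plus the trans proportion.

    ``total`` counts every peak including unknown-position ones, so it can
    exceed cis + trans.
    """
    rows = []
    zero_rows: set[tuple[str, str]] = set()
    for ps in peak_sets:
        for pk in ps:
            rows.append({"test": pk.test, "treatment": pk.treatment, "cis_trans": pk.cis_trans})
        if not ps.peaks and ps.scan_id and ":" in ps.scan_id:
            # a scan that found nothing still gets a (zero-count) table row
            test_name, treatment = ps.scan_id.split(":", 1)
            zero_rows.add(("QTL" if test_name == "wilcoxon" else "vQTL", treatment))
    if not rows and not zero_rows:
        return pd.DataFrame(
            columns=["test", "treatment", "cis", "trans", "unknown", "total", "proportion_trans"]
        )
    df = pd.DataFrame(rows, columns=["test", "treatment", "cis_trans"])
    counts: dict[tuple[str, str], dict] = {key: {"cis": 0, "trans": 0, "unknown": 0} for key in zero_rows}
    for (test, treatment), grp in df.groupby(["test", "treatment"], sort=True):
        counts[(test, treatment)] = {
            "cis": int((grp["cis_trans"] == "cis").sum()),
            "trans": int((grp["cis_trans"] == "trans").sum()),
            "unknown": int((grp["cis_trans"] == "unknown").sum()),
        }
    out = []
    for (test, treatment) in sorted(counts):
        c = counts[(test, treatment)]
        cis, trans, unk = c["cis"], c["trans"], c["unknown"]
        prop = trans / (cis + trans) if (cis + trans) else np.nan
        out.append(
            {
                "test": test,
                "treatment": treatment,
                "cis": cis,
                "trans": trans,
                "unknown": unk,
                "total": cis + trans + unk,
                "proportion_trans": prop,
            }
        )
    return pd.DataFrame(out)
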
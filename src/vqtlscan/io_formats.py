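"""Tabular genomic formats and the in-memory panels the pipeline operates on.

Coordinates are 1-based inclusive internally (SGD convention); BED export
converts to 0-based half-open. Parental allele coding is fixed as BY=0, RM=1.
Missing genotype/phenotype codes accepted on input: ``NA``, the empty string,
and ``-``; all are normalized to NaN.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING_CODES = {"NA", "", "-", "nan", "NaN"}
ALLELE_CODES = {"BY": 0.0, "RM": 1.0, "0": 0.0, "1": 1.0}

BY = 0
RM = 1


class FormatError(ValueError):
    """Raised when an input file violates the documented TSV dialect."""


@dataclass
class GenotypePanel:
    """Haploid segregants x SNP markers, alleles coded by parental origin.

    ``calls`` is a float matrix with values in {0 (BY), 1 (RM), NaN (missing)},
    shape (n_segregants, n_markers). Markers are sorted by (chrom, pos) and
    positions are strictly increasing within each chromosome (duplicates are
    tolerated with a warning).
    """

    segregant_ids: list[str]
    marker_ids: list[str]
    marker_chrom: np.ndarray
    marker_pos: np.ndarray
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.marker_chrom = np.asarray(self.marker_chrom, dtype=object)
        self.marker_pos = np.asarray(self.marker_pos, dtype=np.int64)
        self.calls = np.asarray(self.calls, dtype=float)
        if len(self.segregant_ids) < 2:
            raise ValueError("a genotype panel needs at least 2 segregants")
        if self.calls.shape != (len(self.segregant_ids), len(self.marker_ids)):
            raise ValueError("calls shape does not match segregant/marker ids")
        valid = np.isnan(self.calls) | (self.calls == 0) | (self.calls == 1)
        if not valid.all():
            bad = np.argwhere(~valid)[0]
            raise ValueError(
                f"non-biallelic call at segregant {self.segregant_ids[bad[0]]}, "
                f"marker {self.marker_ids[bad[1]]}: {self.calls[tuple(bad)]}"
            )

    @property
    def n_segregants(self) -> int:
        return len(self.segregant_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def marker_index(self, marker_id: str) -> int:
        try:
            return self.marker_ids.index(marker_id)
        except ValueError:
            raise KeyError(f"unknown marker id: {marker_id}") from None

    def subset_segregants(self, indices: np.ndarray) -> "GenotypePanel":
        return GenotypePanel(
            segregant_ids=[self.segregant_ids[i] for i in indices],
            marker_ids=list(self.marker_ids),
            marker_chrom=self.marker_chrom.copy(),
            marker_pos=self.marker_pos.copy(),
            calls=self.calls[np.asarray(indices)],
        )


@dataclass
class ExpressionPanel:
    """Segregants x expression phenotypes for one treatment, log2 scale.

    ``values`` has shape (n_segregants, n_phenotypes); missing entries are NaN.
    Phenotypes with unknown genome position keep NaN in ``gene_pos`` / None in
    ``gene_chrom`` — they are flagged, never dropped.
    """

    segregant_ids: list[str]
    phenotype_ids: list[str]
    treatment: str
    values: np.ndarray
    gene_chrom: np.ndarray = field(default=None)  # type: ignore[assignment]
    gene_pos: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n_p = len(self.phenotype_ids)
        if self.gene_chrom is None:
            self.gene_chrom = np.full(n_p, None, dtype=object)
        else:
            self.gene_chrom = np.asarray(self.gene_chrom, dtype=object)
        if self.gene_pos is None:
            self.gene_pos = np.full(n_p, np.nan)
        else:
            self.gene_pos = np.asarray(self.gene_pos, dtype=float)
        if self.values.shape != (len(self.segregant_ids), n_p):
            raise ValueError("values shape does not match segregant/phenotype ids")
        finite = np.isfinite(self.values) | np.isnan(self.values)
        if not finite.all():
            raise ValueError("expression values must be finite where present")

    @property
    def n_segregants(self) -> int:
        return len(self.segregant_ids)

    @property
    def n_phenotypes(self) -> int:
        return len(self.phenotype_ids)

    def phenotype_index(self, phenotype_id: str) -> int:
        try:
            return self.phenotype_ids.index(phenotype_id)
        except ValueError:
            raise KeyError(f"unknown phenotype id: {phenotype_id}") from None

    def position_known(self) -> np.ndarray:
        """Boolean mask of phenotypes with a usable genome position."""
        has_chrom = np.array([c is not None for c in self.gene_chrom])
        return has_chrom & ~np.isnan(self.gene_pos)

    def subset_segregants(self, indices: np.ndarray) -> "ExpressionPanel":
        idx = np.asarray(indices)
        return ExpressionPanel(
            segregant_ids=[self.segregant_ids[i] for i in idx],
            phenotype_ids=list(self.phenotype_ids),
            treatment=self.treatment,
            values=self.values[idx],
            gene_chrom=self.gene_chrom.copy(),
            gene_pos=self.gene_pos.copy(),
        )


@dataclass
class HotspotSet:
    """Genomic intervals hosting trans-acting regulatory hotspots.

    Intervals are 1-based inclusive; overlapping intervals on the same
    chromosome are merged (with a warning) at construction. ``genome_size``
    maps chromosome label -> length in bp, used for the covered fraction.
    """

    intervals: list[tuple[str, int, int, str]]
    genome_size: dict[str, int]

    def __post_init__(self) -> None:
        merged: list[tuple[str, int, int, str]] = []
        by_chrom: dict[str, list[tuple[int, int, str]]] = {}
        for chrom, start, end, label in self.intervals:
            if end < start:
                raise ValueError(f"interval end < start for {label}")
            by_chrom.setdefault(chrom, []).append((int(start), int(end), label))
        for chrom in sorted(by_chrom):
            ivs = sorted(by_chrom[chrom])
            cur_s, cur_e, cur_l = ivs[0]
            for s, e, lab in ivs[1:]:
                if s <= cur_e + 1 and s <= cur_e:  # true overlap, not adjacency
                    logger.warning("merging overlapping hotspot intervals %s and %s", cur_l, lab)
                    cur_e = max(cur_e, e)
                    cur_l = f"{cur_l}+{lab}"
                else:
                    merged.append((chrom, cur_s, cur_e, cur_l))
                    cur_s, cur_e, cur_l = s, e, lab
            merged.append((chrom, cur_s, cur_e, cur_l))
        self.intervals = merged

    def covered_fraction(self) -> float:
        total = sum(self.genome_size.values())
        covered = sum(e - s + 1 for _, s, e, _ in self.intervals)
        frac = covered / total
        if not 0.0 <= frac <= 1.0:
            raise ValueError("hotspot coverage outside [0,1]; check genome_size")
        return frac

    def contains(self, chrom: str, pos: int) -> bool:
        """1-based inclusive membership; a position exactly on a boundary is inside."""
        return any(c == chrom and s <= pos <= e for c, s, e, _ in self.intervals)

    def which(self, chrom: str, pos: int) -> str | None:
        for c, s, e, lab in self.intervals:
            if c == chrom and s <= pos <= e:
                return lab
        return None


def _parse_call(raw: str, marker_id: str, segregant_id: str) -> float:
    token = raw.strip()
    if token in MISSING_CODES:
        return np.nan
    try:
        return ALLELE_CODES[token]
    except KeyError:
        raise FormatError(
            f"non-biallelic genotype code {token!r} at marker {marker_id}, "
            f"segregant {segregant_id}"
        ) from None


def read_genotypes(path) -> GenotypePanel:
    """Read a genotype TSV: header row of segregant IDs after marker_id/chrom/pos.

    Calls may be coded BY/RM or 0/1; missing as NA, empty, or ``-``. Markers
    are sorted by (chrom, pos) on load; duplicate positions produce a warning
    but are kept.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["marker_id", "chrom", "pos"]
    if list(df.columns[:3]) != required:
        raise FormatError(f"genotype file must start with columns {required}, got {list(df.columns[:3])}")
    segregant_ids = list(df.columns[3:])
    if not segregant_ids:
        raise FormatError("genotype file has no segregant call columns")
    raw = df.iloc[:, 3:].to_numpy(dtype=object)  # marker x segregant
    calls = np.empty((len(segregant_ids), len(df)))
    for j in range(raw.shape[0]):
        for i in range(raw.shape[1]):
            calls[i, j] = _parse_call(str(raw[j, i]), df.iat[j, 0], segregant_ids[i])
    marker_chrom = df["chrom"].to_numpy(dtype=object)
    marker_pos = df["pos"].astype(np.int64).to_numpy()
    order = np.lexsort((marker_pos, marker_chrom.astype(str)))
    marker_chrom = marker_chrom[order]
    marker_pos = marker_pos[order]
    marker_ids = [df["marker_id"].iloc[i] for i in order]
    calls = calls[:, order]
    for chrom in np.unique(marker_chrom.astype(str)):
        pos = marker_pos[marker_chrom.astype(str) == chrom]
        if len(pos) > 1 and (np.diff(pos) == 0).any():
            logger.warning("duplicate marker positions on %s; keeping both", chrom)
    return GenotypePanel(segregant_ids, marker_ids, marker_chrom, marker_pos, calls)


def write_genotypes(panel: GenotypePanel, path) -> None:
    codes = np.full(panel.calls.shape, "NA", dtype=object)
    codes[panel.calls == 0] = "BY"
    codes[panel.calls == 1] = "RM"
    df = pd.DataFrame(
        {"marker_id": panel.marker_ids, "chrom": panel.marker_chrom, "pos": panel.marker_pos}
    )
    for i, sid in enumerate(panel.segregant_ids):
        df[sid] = codes[i]
    df.to_csv(path, sep="\t", index=False)


def read_expression(path, treatment: str) -> ExpressionPanel:
    """Read an expression TSV: rows = phenotypes (phenotype_id, chrom, pos, values...).

    ``chrom``/``pos`` may be NA for phenotypes with unknown genome position;
    such phenotypes are kept and flagged via :meth:`ExpressionPanel.position_known`.
    """
    df = pd.read_csv(path, sep="\t", dtype={"phenotype_id": str, "chrom": str}, keep_default_na=False)
    required = ["phenotype_id", "chrom", "pos"]
    if list(df.columns[:3]) != required:
        raise FormatError(f"expression file must start with columns {required}, got {list(df.columns[:3])}")
    segregant_ids = list(df.columns[3:])
    if not segregant_ids:
        raise FormatError("expression file has no segregant value columns")
    vals = df.iloc[:, 3:].replace(list(MISSING_CODES), np.nan)
    values = vals.to_numpy(dtype=float).T  # segregant x phenotype
    if values.shape[0] != len(segregant_ids):
        raise FormatError("segregant count mismatch between header and values")
    gene_chrom = np.array(
        [None if c.strip() in MISSING_CODES else c for c in df["chrom"]], dtype=object
    )
    gene_pos = pd.to_numeric(df["pos"].replace(list(MISSING_CODES), np.nan), errors="raise").to_numpy(dtype=float)
    return ExpressionPanel(
        segregant_ids=segregant_ids,
        phenotype_ids=list(df["phenotype_id"]),
        treatment=treatment,
        values=values,
        gene_chrom=gene_chrom,
        gene_pos=gene_pos,
    )


def write_expression(panel: ExpressionPanel, path) -> None:
    df = pd.DataFrame(
        {
            "phenotype_id": panel.phenotype_ids,
            "chrom": ["NA" if c is None else c for c in panel.gene_chrom],
            "pos": ["NA" if np.isnan(p) else int(p) for p in panel.gene_pos],
        }
    )
    for i, sid in enumerate(panel.segregant_ids):
        df[sid] = panel.values[i]
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_hotspots_bed(path, genome_size: dict[str, int]) -> HotspotSet:
    """Read hotspot intervals from BED (0-based half-open) into 1-based inclusive."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            label = parts[3] if len(parts) > 3 else f"{chrom}:{start}-{end}"
            rows.append((chrom, start + 1, end, label))
    return HotspotSet(rows, genome_size)


def align_samples(
    g: GenotypePanel, e: ExpressionPanel
) -> tuple[GenotypePanel, ExpressionPanel]:
    """Restrict both panels, in identical order, to their common segregants.

    The common IDs keep the genotype panel's order. Dropped IDs are logged.
    Raises ValueError on an empty intersection. Idempotent.
    """
    common = [sid for sid in g.segregant_ids if sid in set(e.segregant_ids)]
    if not common:
        raise ValueError("no segregants shared between genotype and expression panels")
    dropped_g = [s for s in g.segregant_ids if s not in set(common)]
    dropped_e = [s for s in e.segregant_ids if s not in set(common)]
    if dropped_g:
        logger.info("dropping %d genotype-only segregants: %s", len(dropped_g), dropped_g)
    if dropped_e:
        logger.info("dropping %d expression-only segregants: %s", len(dropped_e), dropped_e)
    g_idx = np.array([g.segregant_ids.index(s) for s in common])
    e_idx = np.array([e.segregant_ids.index(s) for s in common])
    return g.subset_segregants(g_idx), e.subset_segregants(e_idx)


# ---------------------------------------------------------------------------
# Peak table / BED export (PeakSet is defined in peaks.py; imported lazily to
# avoid a module cycle)

PEAK_COLUMNS = [
    "phenotype",
    "treatment",
    "test",
    "chrom",
    "center_pos",
    "p",
    "n_snps",
    "cis_trans",
    "span_start",
    "span_end",
    "member_ids",
    "member_pos",
]


def write_peaks(peak_set, tsv_path, bed_path=None) -> None:
    """Write a PeakSet as TSV (+ optional companion BED6 of peak spans).

    The TSV carries member ids/positions so the table round-trips exactly;
    the BED span is the member-SNP extent converted to 0-based half-open.
    """
    rows = []
    bed_rows = []
    for pk in peak_set.peaks:
        span_start = int(min(pk.member_pos))
        span_end = int(max(pk.member_pos))
        rows.append(
            {
                "phenotype": pk.phenotype_id,
                "treatment": pk.treatment,
                "test": pk.test,
                "chrom": pk.chrom,
                "center_pos": pk.center_pos,
                "p": pk.center_p,
                "n_snps": len(pk.member_ids),
                "cis_trans": pk.cis_trans,
                "span_start": span_start,
                "span_end": span_end,
                "member_ids": ",".join(pk.member_ids),
                "member_pos": ",".join(str(int(p)) for p in pk.member_pos),
            }
        )
        score = 0 if pk.center_p <= 0 else min(1000, int(round(-10 * np.log10(pk.center_p))))
        bed_rows.append(
            (pk.chrom, span_start - 1, span_end, f"{pk.phenotype_id}|{pk.test}|{pk.treatment}", score, ".")
        )
    df = pd.DataFrame(rows, columns=PEAK_COLUMNS)
    df.to_csv(tsv_path, sep="\t", index=False)
    if bed_path is not None:
        with open(bed_path, "w") as fh:
            for r in bed_rows:
                fh.write("\t".join(str(x) for x in r) + "\n")


def read_peaks(tsv_path):
    """Read a peak TSV back into a PeakSet (inverse of :func:`write_peaks`)."""
    from .peaks import Peak, PeakSet

    df = pd.read_csv(tsv_path, sep="\t", dtype={"chrom": str, "member_ids": str, "member_pos": str})
    peaks = []
    for row in df.itertuples(index=False):
        member_ids = str(row.member_ids).split(",") if row.n_snps else []
        member_pos = [int(x) for x in str(row.member_pos).split(",")] if row.n_snps else []
        peaks.append(
            Peak(
                phenotype_id=str(row.phenotype),
                treatment=str(row.treatment),
                test=str(row.test),
                chrom=str(row.chrom),
                center_pos=int(row.center_pos),
                center_p=float(row.p),
                member_ids=member_ids,
                member_pos=member_pos,
                cis_trans=str(row.cis_trans),
            )
        )
    return PeakSet(peaks=peaks)
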
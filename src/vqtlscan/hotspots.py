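"""Trans-peak counts per regulatory hotspot and chi-square enrichment tests.

Hotspot intervals are an input (the boundaries come from inspection of the
genome-wide peak distribution, not from an algorithm here). Two tests:

* a 1-df goodness-of-fit of the in/out split against the genomic fraction
  the hotspots cover (are peaks uniformly placed?), and
* a 2x2 Pearson chi-square comparing how mean-effect peaks (QTL) and
  variance peaks (vQTL) distribute in vs out of hotspots.

Interval membership is 1-based inclusive: a peak exactly on a hotspot
boundary is inside. Pearson without continuity correction is the default
(counts are large in practice); Yates correction is available by flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import HotspotSet
from .peaks import PeakSet


@dataclass
class EnrichmentResult:
    table: np.ndarray
    chi2: float
    df: int
    p: float
    direction: str = ""  # "enriched" | "depleted" | ""


def count_in_hotspots(peak_set: PeakSet, hotspots: HotspotSet) -> pd.DataFrame:
    """Per-hotspot peak counts by test, plus an in/out total row.

    The caller restricts the peaks to trans-labelled ones when reproducing
    the hotspot tables; this function counts whatever it is given.
    """
    labels = [lab for _, _, _, lab in hotspots.intervals]
    counts = {lab: {"QTL": 0, "vQTL": 0} for lab in labels}
    outside = {"QTL": 0, "vQTL": 0}
    for pk in peak_set:
        lab = hotspots.which(str(pk.chrom), pk.center_pos)
        if lab is None:
            outside[pk.test] += 1
        else:
            counts[lab][pk.test] += 1
    rows = [
        {"hotspot": lab, "QTL": counts[lab]["QTL"], "vQTL": counts[lab]["vQTL"]}
        for lab in labels
    ]
    rows.append({"hotspot": "__outside__", "QTL": outside["QTL"], "vQTL": outside["vQTL"]})
    return pd.DataFrame(rows)


def in_out_totals(per_hotspot: pd.DataFrame) -> dict[str, dict[str, int]]:
    """Collapse a count_in_hotspots table to in/out totals per test."""
    inside = per_hotspot[per_hotspot["hotspot"] != "__outside__"]
    outside = per_hotspot[per_hotspot["hotspot"] == "__outside__"]
    return {
        test: {
            "in": int(inside[test].sum()),
            "out": int(outside[test].sum()) if len(outside) else 0,
        }
        for test in ("QTL", "vQTL")
    }


def uniformity_chisq(in_count: int, out_count: int, covered_fraction: float) -> EnrichmentResult:
    """Goodness-of-fit of (in, out) against the fraction of genome covered."""
    if not 0.0 < covered_fraction < 1.0:
        raise ValueError("covered_fraction must be in (0,1)")
    n = in_count + out_count
    if n == 0:
        raise ValueError("no peaks to test")
    expected = np.array([n * covered_fraction, n * (1 - covered_fraction)])
    observed = np.array([in_count, out_count], dtype=float)
    chi2, p = stats.chisquare(observed, expected)
    direction = "enriched" if in_count > expected[0] else ("depleted" if in_count < expected[0] else "")
    return EnrichmentResult(
        table=observed.astype(int), chi2=float(chi2), df=1, p=float(p), direction=direction
    )


def qtl_vs_vqtl_chisq(table, yates: bool = False) -> EnrichmentResult:
    """Pearson chi-square on a 2x2 {QTL, vQTL} x {in, out} contingency table."""
    tab = np.asarray(table, dtype=float)
    if tab.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if (tab.sum(axis=0) == 0).any() or (tab.sum(axis=1) == 0).any():
        raise ValueError("zero margin in contingency table")
    chi2, p, df, _ = stats.chi2_contingency(tab, correction=yates)
    return EnrichmentResult(table=tab.astype(int), chi2=float(chi2), df=int(df), p=float(p))
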
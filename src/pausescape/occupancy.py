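"""Factor occupancy at TSS windows across conditions and NELF-dismissal calls.

Two complementary dismissal methods are implemented.  The count-based method
tests, per gene, the depth-normalised fold change of TSS-window tags between
baseline and treatment with an exact two-sided binomial conditional test (the
zero-dispersion limit of a negative-binomial exact test; with one library per
condition no dispersion is estimable).  The peaks-as-background method calls
peaks on the baseline library with the treated library as background, and
flags genes whose TSS window contains a resulting summit.  Dismissal p-values
are gated raw (no multiplicity adjustment), with a BH-adjusted column emitted
alongside for users who want it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .annotation import GeneRegions, GenomeLayout
from .enrichment import Peak, call_peaks
from .tags import TagLibrary, count_in_regions

__all__ = [
    "tss_occupancy_table",
    "test_dismissal",
    "dismissal_table",
    "dismissal_by_peaks",
    "call_factor_positive",
]

FC_DISMISS = 0.5
P_DISMISS = 0.05


def tss_occupancy_table(
    libs: dict[str, TagLibrary], regions: list[GeneRegions]
) -> pd.DataFrame:
    """Per-gene TSS-window tag counts (raw and per-10M) per condition."""
    idx = pd.Index([r.gene.symbol for r in regions], name="symbol")
    out = pd.DataFrame(index=idx)
    for cond, lib in libs.items():
        counts = count_in_regions(lib, regions, "tss", "both")
        out[f"count_{cond}"] = counts
        out[f"per10M_{cond}"] = counts * (1e7 / lib.total)
    return out


def test_dismissal(
    count_0h: int, count_05h: int, total_0h: int, total_05h: int,
    fc_cut: float = FC_DISMISS, p_cut: float = P_DISMISS,
) -> tuple[float, float, bool]:
    """Depth-normalised fold change and exact binomial p for one gene.

    fc = (count_05h/total_05h) / (count_0h/total_0h); p is the two-sided
    exact binomial probability of seeing count_05h among count_0h+count_05h
    tags when each tag falls in the treated library with probability
    total_05h / (total_0h + total_05h).  Dismissed iff fc < fc_cut and
    p < p_cut.
    """
    if total_0h <= 0 or total_05h <= 0:
        raise ValueError("library totals must be positive")
    n = count_0h + count_05h
    if n == 0:
        return math.nan, 1.0, False
    if count_0h == 0:
        fc = math.inf
    else:
        fc = (count_05h / total_05h) / (count_0h / total_0h)
    p_success = total_05h / (total_0h + total_05h)
    p = stats.binomtest(count_05h, n, p_success, alternative="two-sided").pvalue
    return fc, float(p), bool(fc < fc_cut and p < p_cut)


def dismissal_table(
    lib_0h: TagLibrary, lib_05h: TagLibrary, regions: list[GeneRegions],
    fc_cut: float = FC_DISMISS, p_cut: float = P_DISMISS,
) -> pd.DataFrame:
    """Count-based dismissal calls for every gene."""
    c0 = count_in_regions(lib_0h, regions, "tss", "both")
    c5 = count_in_regions(lib_05h, regions, "tss", "both")
    rows = []
    for r, a, b in zip(regions, c0, c5):
        fc, p, dism = test_dismissal(int(a), int(b), lib_0h.total, lib_05h.total,
                                     fc_cut, p_cut)
        rows.append({
            "symbol": r.gene.symbol, "count_0h": int(a), "count_05h": int(b),
            "per10M_0h": a * 1e7 / lib_0h.total, "per10M_05h": b * 1e7 / lib_05h.total,
            "fc": fc, "pvalue": p, "dismissed": dism,
        })
    out = pd.DataFrame(rows).set_index("symbol")
    out["qvalue"] = multipletests(out["pvalue"].to_numpy(), method="fdr_bh")[1]
    return out


def dismissal_by_peaks(
    lib_0h: TagLibrary, lib_05h: TagLibrary, regions: list[GeneRegions],
    layout: GenomeLayout, window_size: int = 500, fdr: float = 0.001,
    fold_over_background: float | None = None, fc_cut: float = FC_DISMISS,
) -> pd.Series:
    """Peaks-as-background dismissal: baseline as enrichment, treated as
    background; a gene is flagged when a peak summit lands in its TSS window.

    The fold-over-background cutoff defaults to 1/fc_cut (= 2 at defaults) so
    that the differential peak call targets the same effect size as the
    count-based fc < fc_cut definition.
    """
    if fold_over_background is None:
        fold_over_background = 1.0 / fc_cut
    peaks = call_peaks(
        lib_0h, layout, window_size=window_size, fdr=fdr,
        background=lib_05h, min_fold_over_background=fold_over_background,
    )
    return call_factor_positive(peaks, regions)


def call_factor_positive(peaks: list[Peak], regions: list[GeneRegions]) -> pd.Series:
    """Factor-positive flag: >=1 peak summit inside the gene's TSS window."""
    summits: dict[str, np.ndarray] = {}
    for p in peaks:
        summits.setdefault(p.chrom, []).append(p.summit)
    summits = {c: np.sort(np.asarray(v, dtype=np.int64)) for c, v in summits.items()}
    flags = []
    for r in regions:
        pos = summits.get(r.gene.chrom)
        if pos is None:
            flags.append(False)
            continue
        lo, hi = r.tss_window
        flags.append(bool(np.searchsorted(pos, hi, "left") > np.searchsorted(pos, lo, "left")))
    return pd.Series(flags, index=pd.Index([r.gene.symbol for r in regions], name="symbol"))
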
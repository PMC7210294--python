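"""Poisson-background enrichment: FDR-derived integer count thresholds and
sliding-window peak calling.

The background model assumes tags fall uniformly over the effective genome, so
the count in a ``window_size`` window is Poisson with
lambda = total_tags * window_size / effective_size.  For an integer cutoff c
the estimated FDR is the expected number of background windows at or above c
divided by the number actually observed there; the enrichment threshold is the
smallest c whose estimated FDR is below the nominal rate (0.001 throughout the
pipeline).  Windows slide at half-window step; overlapping significant windows
are merged into peaks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .annotation import GenomeLayout, GeneRegions
from .tags import TagLibrary, normalize_per10M

__all__ = [
    "BackgroundModel",
    "EnrichmentThreshold",
    "Peak",
    "NoEnrichmentError",
    "fit_background",
    "window_counts",
    "fdr_threshold",
    "classify_active_tss",
    "call_peaks",
    "annotate_peaks",
]


class NoEnrichmentError(RuntimeError):
    """No integer cutoff achieves the nominal FDR on the observed counts."""


@dataclass(frozen=True)
class BackgroundModel:
    lam: float  # expected tags per window under uniform background
    window_size: int
    n_windows: int
    total_tags: int

    def __post_init__(self):
        if self.lam <= 0:
            raise ValueError("background lambda must be positive")


@dataclass(frozen=True)
class EnrichmentThreshold:
    threshold: int  # minimal significant integer tag count
    fdr: float
    model: BackgroundModel
    estimated_fdr: float  # estimated FDR at the threshold


@dataclass
class Peak:
    chrom: str
    start: int
    end: int
    count: int  # raw tag count in the merged span
    score: float  # per-10M tag count
    summit: int  # max-pileup base (leftmost on ties)
    annotation: str | None = None  # {tss, gene_body, intergenic}
    nearest_gene: str | None = None


def fit_background(lib: TagLibrary, layout: GenomeLayout, window_size: int) -> BackgroundModel:
    """Uniform-background Poisson rate for ``window_size`` windows.

    A tag of width w overlaps a window when its start falls in a
    (window + w - 1) bp corridor, so the background rate for overlap counting
    is total * (window + mean_width - 1) / genome; for 1-bp reduced tags this
    reduces to the plain total * window / genome.
    """
    if lib.total <= 0:
        raise ValueError("zero-depth library")
    size = layout.effective_size
    if size <= window_size:
        raise ValueError("effective genome size must exceed the window size")
    mean_width = float((lib.end - lib.start).mean()) if len(lib) else 1.0
    lam = lib.total * (window_size + mean_width - 1.0) / size
    step = window_size // 2
    return BackgroundModel(lam, window_size, int(size // step), lib.total)


def window_counts(lib: TagLibrary, layout: GenomeLayout, window_size: int):
    """Sliding-window tag counts (step = window/2) over every chromosome.

    Returns (chroms, starts, counts) as parallel arrays; windows are clipped
    at chromosome ends.
    """
    step = window_size // 2
    all_chroms, all_starts, all_counts = [], [], []
    for chrom, length in layout.chrom_lengths.items():
        n = int(length // step)
        if n == 0:
            continue
        starts = step * np.arange(n, dtype=np.int64)
        ends = np.minimum(starts + window_size, length)
        idx = lib._chrom_index(chrom)
        counts = (
            np.searchsorted(idx["starts"], ends, side="left")
            - np.searchsorted(idx["ends"], starts, side="right")
        )
        all_chroms.append(np.full(n, chrom, dtype=object))
        all_starts.append(starts)
        all_counts.append(counts.astype(np.int64))
    if not all_chroms:
        return np.array([], dtype=object), np.array([], np.int64), np.array([], np.int64)
    return (np.concatenate(all_chroms), np.concatenate(all_starts),
            np.concatenate(all_counts))


def estimated_fdr_curve(model: BackgroundModel, observed: np.ndarray) -> np.ndarray:
    """Estimated FDR for every integer cutoff 1..max(observed).

    entry [c-1] = n_windows * P(X >= c | Poisson lam) / max(1, #observed >= c)
    """
    observed = np.asarray(observed)
    cmax = int(observed.max(initial=0))
    cs = np.arange(1, cmax + 1)
    expected = model.n_windows * stats.poisson.sf(cs - 1, model.lam)
    # observed >= c via reverse cumulative histogram
    hist = np.bincount(np.clip(observed, 0, cmax), minlength=cmax + 1)
    n_at_or_above = hist[::-1].cumsum()[::-1][1:]  # index c-1 -> #obs >= c
    return expected / np.maximum(1, n_at_or_above)


def fdr_threshold(
    model: BackgroundModel, observed: np.ndarray, fdr: float = 0.001
) -> EnrichmentThreshold:
    """Smallest integer count whose estimated FDR is below ``fdr``.

    Raises :class:`NoEnrichmentError` when no cutoff up to the observed
    maximum achieves the bound.
    """
    if fdr >= 1.0:  # degenerate limit: every nonzero window is significant
        return EnrichmentThreshold(1, fdr, model, 1.0)
    curve = estimated_fdr_curve(model, observed)
    ok = np.nonzero(curve < fdr)[0]
    if ok.size == 0:
        raise NoEnrichmentError(
            f"no significant enrichment at FDR<{fdr} (max count "
            f"{int(np.asarray(observed).max(initial=0))})"
        )
    c = int(ok[0]) + 1
    return EnrichmentThreshold(c, fdr, model, float(curve[c - 1]))


def classify_active_tss(counts, threshold: EnrichmentThreshold | int) -> np.ndarray:
    """Active TSS flag: strictly more tags than the enrichment threshold."""
    t = threshold.threshold if isinstance(threshold, EnrichmentThreshold) else int(threshold)
    return np.asarray(counts) > t


# ---------------------------------------------------------------------------
# peak calling


def call_peaks(
    target: TagLibrary,
    layout: GenomeLayout,
    window_size: int = 500,
    fdr: float = 0.001,
    background: TagLibrary | None = None,
    min_fold_over_background: float = 4.0,
) -> list[Peak]:
    """Sliding-window Poisson-background peak calling.

    Windows whose count reaches the FDR threshold are kept; with a background
    library the per-10M target count must additionally be at least
    ``min_fold_over_background`` times the per-10M background count
    (condition-as-background differential mode).  Overlapping significant
    windows are merged; the peak score is the per-10M count in the merged span
    and the summit the maximum-pileup base.
    """
    if background is not None and background.total <= 0:
        raise ValueError("zero-depth background library")
    model = fit_background(target, layout, window_size)
    chroms, starts, counts = window_counts(target, layout, window_size)
    try:
        thr = fdr_threshold(model, counts, fdr)
    except NoEnrichmentError:
        return []
    sig = counts >= thr.threshold
    if background is not None:
        _, _, bg_counts = window_counts(background, layout, window_size)
        t10 = counts * (1e7 / target.total)
        b10 = bg_counts * (1e7 / background.total)
        sig &= t10 >= min_fold_over_background * b10
        sig &= counts > 0
    peaks: list[Peak] = []
    for chrom in layout.chrom_lengths:
        mask = sig & (chroms == chrom)
        if not mask.any():
            continue
        w_starts = starts[mask]
        w_ends = np.minimum(w_starts + window_size, layout.chrom_lengths[chrom])
        # merge overlapping windows (starts already sorted)
        merged = [[int(w_starts[0]), int(w_ends[0])]]
        for s, e in zip(w_starts[1:], w_ends[1:]):
            if s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], int(e))
            else:
                merged.append([int(s), int(e)])
        idx = target._chrom_index(chrom)
        for s, e in merged:
            count = int(
                np.searchsorted(idx["starts"], e, side="left")
                - np.searchsorted(idx["ends"], s, side="right")
            )
            peaks.append(Peak(
                chrom, s, e, count,
                score=float(count * 1e7 / target.total),
                summit=_summit(target, chrom, s, e),
            ))
    return peaks


def _summit(lib: TagLibrary, chrom: str, start: int, end: int) -> int:
    """Leftmost base of maximal pileup within [start, end)."""
    mask = (lib.chrom == chrom) & (lib.start < end) & (lib.end > start)
    if not mask.any():
        return start
    s = np.clip(lib.start[mask], start, end)
    e = np.clip(lib.end[mask], start, end)
    breaks = np.unique(np.concatenate([s, e, [start, end]]))
    delta = np.zeros(breaks.size, dtype=np.int64)
    np.add.at(delta, np.searchsorted(breaks, s), 1)
    np.add.at(delta, np.searchsorted(breaks, e), -1)
    cov = np.cumsum(delta)[:-1]
    return int(breaks[int(np.argmax(cov))])


def annotate_peaks(
    peaks: list[Peak], regions: list[GeneRegions]
) -> dict[str, float]:
    """Assign each peak a genomic category by summit membership with
    precedence tss > gene_body > intergenic; returns the category fractions.

    Peaks are annotated in place (``annotation`` and ``nearest_gene``).
    """
    by_chrom: dict[str, list[GeneRegions]] = {}
    for r in regions:
        by_chrom.setdefault(r.gene.chrom, []).append(r)
    tallies = {"tss": 0, "gene_body": 0, "intergenic": 0}
    for p in peaks:
        cat, gene = "intergenic", None
        best_dist = None
        for r in by_chrom.get(p.chrom, ()):
            lo, hi = r.tss_window
            if lo <= p.summit < hi:
                cat, gene = "tss", r.gene.symbol
                break
            blo, bhi = r.body
            if blo <= p.summit < bhi and cat != "tss":
                cat, gene = "gene_body", r.gene.symbol
        if gene is None:
            for r in by_chrom.get(p.chrom, ()):
                d = abs(p.summit - r.tss_pos)
                if best_dist is None or d < best_dist:
                    best_dist, gene = d, r.gene.symbol
        p.annotation = cat
        p.nearest_gene = gene
        tallies[cat] += 1
    n = max(1, len(peaks))
    return {k: v / n for k, v in tallies.items()}


def write_peaks(peaks: list[Peak], bed_path=None, tsv_path=None) -> None:
    """BED6 (score = per-10M x10 capped at 1000) and/or full TSV."""
    import pandas as pd

    if bed_path is not None:
        rows = [
            (p.chrom, p.start, p.end, f"peak_{i + 1}",
             min(1000, int(round(p.score * 10))), ".")
            for i, p in enumerate(peaks)
        ]
        pd.DataFrame(rows).to_csv(bed_path, sep="\t", header=False, index=False)
    if tsv_path is not None:
        pd.DataFrame(
            [
                {
                    "chrom": p.chrom, "start": p.start, "end": p.end,
                    "count": p.count, "per10M": p.score, "summit": p.summit,
                    "annotation": p.annotation, "nearest_gene": p.nearest_gene,
                }
                for p in peaks
            ]
        ).to_csv(tsv_path, sep="\t", index=False)
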
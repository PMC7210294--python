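"""Pausing-index computation and gene grouping.

The pausing index of a gene is the ratio of tag density (tags per kb) in its
TSS window to tag density in its gene body.  Genes whose TSS-window count
exceeds the enrichment threshold are TSS-active; active genes with PI >= 3 are
highly paused (group 1), with 1.5 <= PI < 3 moderately paused (group 2), and
all remaining genes - active with PI < 1.5 or TSS-inactive - are non-paused
(group 3).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation import GeneRegions
from .enrichment import EnrichmentThreshold, classify_active_tss
from .stats import ks_two_sample, mann_whitney_u
from .tags import SignalMatrix, TagLibrary, count_in_regions

__all__ = [
    "PausingRecord",
    "pausing_index",
    "classify_pausing",
    "pausing_table",
    "compare_pi_distributions",
    "boxed_signal_test",
    "summarize_groups",
]

PI_HIGH = 3.0
PI_MODERATE = 1.5


@dataclass(frozen=True)
class PausingRecord:
    symbol: str
    tss_count: int
    body_count: int
    tss_len: int
    body_len: int
    pi: float  # may be inf (empty body) or nan (no signal at all)
    tss_active: bool
    group: int  # 1 / 2 / 3
    assay: str


def pausing_index(tss_count: int, body_count: int, tss_len: int, body_len: int) -> float:
    """Ratio of per-kb densities, TSS window over gene body.

    An empty body with TSS signal gives +inf; no signal anywhere gives nan.
    """
    if min(tss_count, body_count) < 0:
        raise ValueError("counts must be non-negative")
    if tss_len <= 0 or body_len <= 0:
        raise ValueError("region lengths must be positive")
    if body_count == 0:
        return math.inf if tss_count > 0 else math.nan
    return (tss_count / tss_len) / (body_count / body_len)


def classify_pausing(
    pi: float, tss_active: bool, high: float = PI_HIGH, moderate: float = PI_MODERATE
) -> int:
    """Group 1/2/3 assignment; inactive TSS forces group 3 regardless of PI."""
    if high <= moderate:
        raise ValueError("high cutoff must exceed moderate cutoff")
    if not tss_active:
        return 3
    if math.isnan(pi):
        return 3
    if pi >= high:  # inf lands here: all signal is promoter-proximal
        return 1
    if pi >= moderate:
        return 2
    return 3


def pausing_table(
    lib: TagLibrary,
    regions: list[GeneRegions],
    threshold: EnrichmentThreshold | int,
    assay: str | None = None,
    high: float = PI_HIGH,
    moderate: float = PI_MODERATE,
) -> list[PausingRecord]:
    """Per-gene TSS/body counts, PI, activity, and group for one library.

    ChIP libraries are counted by >=1 bp overlap; PRO-seq libraries by the
    antisense-strand 1-bp convention with their own enrichment threshold.
    """
    assay = assay or lib.assay
    mode = "both" if assay == "chip" else "sense_via_antisense"
    tss_counts = count_in_regions(lib, regions, "tss", mode)
    body_counts = count_in_regions(lib, regions, "body", mode)
    active = classify_active_tss(tss_counts, threshold)
    records = []
    for r, tc, bc, act in zip(regions, tss_counts, body_counts, active):
        pi = pausing_index(int(tc), int(bc), r.tss_len, r.body_len)
        records.append(
            PausingRecord(
                r.gene.symbol, int(tc), int(bc), r.tss_len, r.body_len,
                pi, bool(act), classify_pausing(pi, bool(act), high, moderate), assay,
            )
        )
    return records


def records_frame(records: list[PausingRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records]).set_index("symbol")


def _capped(pi: np.ndarray) -> np.ndarray:
    """Replace infinite PIs with the finite maximum (ECDF/KS convention)."""
    pi = np.asarray(pi, dtype=np.float64)
    pi = pi[~np.isnan(pi)]
    finite = pi[np.isfinite(pi)]
    cap = finite.max() if finite.size else 0.0
    return np.where(np.isinf(pi), cap, pi)


def compare_pi_distributions(pi_a, pi_b) -> dict:
    """Two-sided two-sample KS on PI vectors plus the paired ECDF curves.

    Infinite PIs (empty gene bodies) are capped at the per-vector finite
    maximum before testing.
    """
    a = _capped(pi_a)
    b = _capped(pi_b)
    if a.size < 2 or b.size < 2:
        raise ValueError("each PI vector needs at least two finite values")
    stat, p = ks_two_sample(a, b)
    from .stats import ecdf

    xa, fa = ecdf(a)
    xb, fb = ecdf(b)
    return {
        "statistic": stat,
        "pvalue": p,
        "ecdf_a": (xa, fa),
        "ecdf_b": (xb, fb),
    }


def boxed_signal_test(
    matrix: SignalMatrix, groups: dict[str, list[str]], box: tuple[int, int]
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-gene tag sums in a TSS-relative box plus pairwise two-sided MWU
    between gene groups (the boxed box-plot comparisons).

    ``box`` is (start, end) in bp relative to the TSS in transcription
    direction and must align to the bin grid.
    """
    lo, hi = box
    if lo < -matrix.upstream or hi > matrix.downstream:
        raise ValueError("box outside the profile window")
    if (lo + matrix.upstream) % matrix.bin_size or (hi + matrix.upstream) % matrix.bin_size:
        raise ValueError("box must align to the bin grid")
    b0 = (lo + matrix.upstream) // matrix.bin_size
    b1 = (hi + matrix.upstream) // matrix.bin_size
    sums = matrix.values[:, b0:b1].sum(axis=1)
    per_gene = pd.Series(sums, index=pd.Index(matrix.genes, name="symbol"), name="box_count")
    names = list(groups)
    rows = []
    for i, ga in enumerate(names):
        for gb in names[i + 1 :]:
            xa = per_gene.loc[[g for g in groups[ga]]].to_numpy()
            xb = per_gene.loc[[g for g in groups[gb]]].to_numpy()
            u, p = mann_whitney_u(xa, xb)
            rows.append({"group_a": ga, "group_b": gb, "U": u, "pvalue": p})
    return pd.DataFrame(rows), per_gene


def summarize_groups(
    records: list[PausingRecord], labels: dict[str, set[str]]
) -> dict:
    """Group counts/fractions and both conditional overlap directions
    (P(label | group) and P(group | label)) against named boolean gene sets."""
    symbols = {r.symbol for r in records}
    group_of = {r.symbol: r.group for r in records}
    counts = {g: sum(1 for r in records if r.group == g) for g in (1, 2, 3)}
    n = len(records)
    out = {
        "counts": counts,
        "fractions": {g: counts[g] / n if n else 0.0 for g in counts},
        "labels": {},
    }
    for name, members in labels.items():
        unknown = set(members) - symbols
        if unknown:
            raise ValueError(f"label {name!r} names unknown genes: {sorted(unknown)[:5]}")
        in_group = {g: sum(1 for s in members if group_of[s] == g) for g in (1, 2, 3)}
        out["labels"][name] = {
            "n": len(members),
            "p_group_given_label": {
                g: in_group[g] / len(members) if members else 0.0 for g in (1, 2, 3)
            },
            "p_label_given_group": {
                g: in_group[g] / counts[g] if counts[g] else 0.0 for g in (1, 2, 3)
            },
        }
    return out
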
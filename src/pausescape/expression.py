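"""RNA-seq expression levels and response classes.

FPKM = count * 1e9 / (gene length * library size).  Condition-level FPKM
averages replicate fragment counts first and then normalises (using the mean
replicate library size), with per-replicate FPKM retained for testing.  All
fold changes are computed on (FPKM + 1); class gates follow the pipeline
defaults: q < 0.05 and FC >= 1.5 for LPS-inducible at 1 h, p < 0.05 with
FC >= 1.4 / <= 0.6 for the 0.5 h induced/suppressed and knockout up/down
classes, and superinduced / more-suppressed are the conjunctions of the 0.5 h
response with the same-direction knockout effect at 0.5 h.

Significance comes from a Welch t-test on log2(FPKM + 1) across replicates
with Benjamini-Hochberg adjustment - a deliberate replicate-level substitute
for isoform-aware differential machinery, which this pipeline does not model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ExpressionTable",
    "compute_fpkm",
    "classify_expressed",
    "replicate_test",
    "classify_lps_response",
    "classify_ko_effect",
    "classify_superinduced",
    "response_table",
]

FC_1H = 1.5
FC_UP = 1.4
FC_DOWN = 0.6
Q_CUT = 0.05
P_CUT = 0.05
FPKM_EXPRESSED = 1.0


@dataclass
class ExpressionTable:
    """Gene x sample fragment counts with sample metadata.

    ``counts``: DataFrame indexed by gene symbol, one column per sample.
    ``lengths``: per-gene length in bp (same index).
    ``samples``: DataFrame indexed by sample name with columns
    genotype ({WT, KO}), time ({0, 0.5, 1}, hours) and replicate.
    Library sizes default to column sums.
    """

    counts: pd.DataFrame
    lengths: pd.Series
    samples: pd.DataFrame
    library_sizes: pd.Series | None = None
    fpkm: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self):
        if (self.lengths <= 0).any():
            raise ValueError("gene lengths must be positive")
        if self.library_sizes is None:
            self.library_sizes = self.counts.sum(axis=0).astype(float)
        if (self.library_sizes <= 0).any():
            raise ValueError("library sizes must be positive")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative fragment counts")

    def condition_samples(self, genotype: str, time: float) -> list[str]:
        m = (self.samples["genotype"] == genotype) & (self.samples["time"] == time)
        names = list(self.samples.index[m])
        if not names:
            raise ValueError(f"no samples for genotype={genotype} time={time}")
        return names

    @classmethod
    def from_files(cls, counts_path, samples_path) -> "ExpressionTable":
        """Counts TSV (gene, length, one column per sample) + sample sidecar
        TSV (sample, genotype, time, replicate)."""
        df = pd.read_csv(counts_path, sep="\t", index_col=0)
        lengths = df.pop("length")
        meta = pd.read_csv(samples_path, sep="\t", index_col=0)
        sizes = None
        if "library_size" in meta.columns:
            sizes = meta["library_size"].astype(float).reindex(df.columns)
        return cls(df, lengths, meta, library_sizes=sizes)


def compute_fpkm(table: ExpressionTable) -> pd.DataFrame:
    """Per-sample FPKM; cached on the table."""
    scale = 1e9 / (table.lengths.to_numpy()[:, None] * table.library_sizes.to_numpy()[None, :])
    fpkm = table.counts * scale
    table.fpkm = fpkm
    return fpkm


def condition_fpkm(table: ExpressionTable, genotype: str, time: float) -> pd.Series:
    """Condition FPKM: mean replicate counts normalised by the mean replicate
    library size (average-then-normalise)."""
    names = table.condition_samples(genotype, time)
    mean_counts = table.counts[names].mean(axis=1)
    mean_lib = float(table.library_sizes[names].mean())
    return mean_counts * 1e9 / (table.lengths * mean_lib)


def classify_expressed(fpkm_rest: pd.Series, cutoff: float = FPKM_EXPRESSED) -> pd.Series:
    """Expressed iff resting-condition FPKM >= cutoff (inclusive)."""
    return fpkm_rest >= cutoff


def replicate_test(table: ExpressionTable, samples_a: list[str], samples_b: list[str]):
    """Per-gene Welch t on log2(FPKM+1) between two replicate groups.

    Returns (p, q) Series; with a single replicate on either side p is NaN and
    downstream classification proceeds on fold change alone (warned).
    Genes with identical values in both groups get p = 1.
    """
    if table.fpkm is None:
        compute_fpkm(table)
    if min(len(samples_a), len(samples_b)) < 2:
        warnings.warn(
            "fewer than 2 replicates on one side: p-values unavailable, "
            "classification will use fold changes only"
        )
        idx = table.counts.index
        na = pd.Series(np.nan, index=idx)
        return na, na.copy()
    a = np.log2(table.fpkm[samples_a].to_numpy() + 1.0)
    b = np.log2(table.fpkm[samples_b].to_numpy() + 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(a, b, axis=1, equal_var=False)
    p = np.asarray(res.pvalue, dtype=float)
    degenerate = np.isnan(p)
    # zero within-group variance: identical values -> no evidence (p=1)
    same = np.all(a == a[:, :1], axis=1) & np.all(b == b[:, :1], axis=1)
    p[degenerate & same & (a[:, 0] == b[:, 0])] = 1.0
    p[degenerate & same & (a[:, 0] != b[:, 0])] = 0.0
    tested = ~np.isnan(p)
    q = np.full_like(p, np.nan)
    if tested.any():
        q[tested] = multipletests(p[tested], method="fdr_bh")[1]
    idx = table.counts.index
    return pd.Series(p, index=idx), pd.Series(q, index=idx)


def _fc(treated: pd.Series, baseline: pd.Series) -> pd.Series:
    return (treated + 1.0) / (baseline + 1.0)


def _gate(p: pd.Series, cut: float) -> pd.Series:
    """Significance gate that degrades to all-pass when p is unavailable."""
    return p.isna() | (p < cut)


def classify_lps_response(
    f0: pd.Series, f05: pd.Series | None, f1: pd.Series | None,
    p05: pd.Series | None = None, q1: pd.Series | None = None,
    fc_1h: float = FC_1H, fc_up: float = FC_UP, fc_down: float = FC_DOWN,
) -> pd.DataFrame:
    """LPS response classes on (FPKM+1) fold changes.

    inducible_1h: q < 0.05 and FC(1 h / 0 h) >= 1.5;
    induced_05h:  p < 0.05 and FC(0.5 h / 0 h) >= 1.4;
    suppressed_05h: p < 0.05 and FC(0.5 h / 0 h) <= 0.6.
    All boundaries inclusive.
    """
    out = pd.DataFrame(index=f0.index)
    if f1 is not None:
        fc1 = _fc(f1, f0)
        out["fc_1h"] = fc1
        gate = _gate(q1, Q_CUT) if q1 is not None else pd.Series(True, index=f0.index)
        out["inducible_1h"] = gate & (fc1 >= fc_1h)
    if f05 is not None:
        fc05 = _fc(f05, f0)
        out["fc_05h"] = fc05
        gate = _gate(p05, P_CUT) if p05 is not None else pd.Series(True, index=f0.index)
        out["induced_05h"] = gate & (fc05 >= fc_up)
        out["suppressed_05h"] = gate & (fc05 <= fc_down)
    return out


def classify_ko_effect(
    f_wt: pd.Series, f_ko: pd.Series, p: pd.Series | None = None,
    fc_up: float = FC_UP, fc_down: float = FC_DOWN,
) -> pd.DataFrame:
    """Knockout effect within one condition: p < 0.05 and (FPKM+1) KO/WT
    fold change >= 1.4 (up) or <= 0.6 (down)."""
    fc = _fc(f_ko, f_wt)
    gate = _gate(p, P_CUT) if p is not None else pd.Series(True, index=f_wt.index)
    return pd.DataFrame(
        {"fc_ko": fc, "ko_up": gate & (fc >= fc_up), "ko_down": gate & (fc <= fc_down)}
    )


def classify_superinduced(response: pd.DataFrame, ko_05h: pd.DataFrame) -> pd.DataFrame:
    """Superinduced = LPS-induced (0.5 h) and KO-upregulated at 0.5 h;
    more-suppressed = LPS-suppressed (0.5 h) and KO-downregulated at 0.5 h."""
    out = pd.DataFrame(index=response.index)
    out["superinduced"] = response["induced_05h"] & ko_05h["ko_up"]
    out["more_suppressed"] = response["suppressed_05h"] & ko_05h["ko_down"]
    return out


def response_table(table: ExpressionTable) -> pd.DataFrame:
    """Full per-gene response classification from a replicate count table.

    Requires WT samples at 0, 0.5 and 1 h and KO samples at 0.5 h (KO at 0 h
    used when present for the resting knockout contrast).
    """
    compute_fpkm(table)
    f0 = condition_fpkm(table, "WT", 0.0)
    f05 = condition_fpkm(table, "WT", 0.5)
    f1 = condition_fpkm(table, "WT", 1.0)
    k05 = condition_fpkm(table, "KO", 0.5)

    p05, _ = replicate_test(
        table, table.condition_samples("WT", 0.0), table.condition_samples("WT", 0.5)
    )
    _, q1 = replicate_test(
        table, table.condition_samples("WT", 0.0), table.condition_samples("WT", 1.0)
    )
    pko, _ = replicate_test(
        table, table.condition_samples("WT", 0.5), table.condition_samples("KO", 0.5)
    )

    out = pd.DataFrame(index=table.counts.index)
    out["fpkm_rest"] = f0
    out["expressed"] = classify_expressed(f0)
    resp = classify_lps_response(f0, f05, f1, p05=p05, q1=q1)
    ko = classify_ko_effect(f05, k05, p=pko)
    out = out.join(resp).join(ko).join(classify_superinduced(resp, ko))
    # classes only apply to the expressed universe
    for col in ("inducible_1h", "induced_05h", "suppressed_05h",
                "ko_up", "ko_down", "superinduced", "more_suppressed"):
        out[col] &= out["expressed"]
    return out
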
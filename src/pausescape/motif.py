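"""Promoter motif scanning and binomial enrichment.

Promoters are scanned on both strands with a log-odds position weight matrix;
a promoter "hits" when some offset scores at least ``score_threshold`` times
the maximal attainable score (default 0.8).  Enrichment of a target promoter
set over a background set is the upper-tail binomial probability of the
observed number of hit promoters given the background hit rate.  The AP-1
target call applies this machinery at P < 0.001 to NELF-negative superinduced
genes, reporting both the per-gene hit flags and the set-level p.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .annotation import GeneRegions
from .stats import binom_upper_tail

__all__ = [
    "PWM",
    "MotifEnrichmentResult",
    "consensus_pwm",
    "load_jaspar_pwm",
    "AP1_CONSENSUS",
    "ETS_CONSENSUS",
    "extract_promoters",
    "scan_pwm",
    "motif_enrichment",
    "ap1_target_call",
]

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

AP1_CONSENSUS = "TGACTCA"  # canonical TPA-response element bound by Fos/Jun
ETS_CONSENSUS = "AGAGGAAGTG"  # PU.1/ETS purine-rich core (GGAA)


@dataclass
class PWM:
    """Per-position base probabilities with log-odds scoring machinery."""

    name: str
    matrix: np.ndarray  # (length, 4) probabilities over A,C,G,T
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )
    score_threshold: float = 0.8  # fraction of the maximal log-odds score
    pseudocount: float = 1e-3

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("PWM matrix must be (length, 4)")
        if self.matrix.shape[0] < 4:
            raise ValueError("PWM length must be >= 4")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each PWM position must sum to 1")

    @property
    def length(self) -> int:
        return self.matrix.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        p = self.matrix + self.pseudocount
        p /= p.sum(axis=1, keepdims=True)
        return np.log2(p / self.background)

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())


def consensus_pwm(consensus: str, name: str | None = None, p: float = 0.97) -> PWM:
    """PWM concentrated on a consensus string (probability ``p`` per base)."""
    m = np.full((len(consensus), 4), (1 - p) / 3)
    for i, base in enumerate(consensus.upper()):
        m[i, _BASE_INDEX[base]] = p
    return PWM(name or consensus, m)


def load_jaspar_pwm(path) -> PWM:
    """Read a JASPAR-style plain-text count matrix as a PWM."""
    from Bio import motifs

    with open(path) as fh:
        rec = motifs.read(fh, "jaspar")
    counts = np.array([rec.counts[b] for b in _BASES], dtype=np.float64).T
    probs = (counts + 0.5) / (counts + 0.5).sum(axis=1, keepdims=True)
    return PWM(rec.name or rec.matrix_id or "pwm", probs)


# ---------------------------------------------------------------------------
# sequence handling


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def extract_promoters(
    regions: list[GeneRegions], genome, upstream: int = 1000, downstream: int = 100
) -> dict[str, str]:
    """Strand-aware promoter sequences, TSS-relative [-upstream, +downstream).

    ``genome`` is any mapping of chromosome name to a string-sliceable
    sequence (e.g. an indexed FASTA).  Minus-strand promoters are
    reverse-complemented; windows are clipped at chromosome ends with a
    warning.
    """
    import warnings

    out = {}
    for r in regions:
        chrom = genome[r.gene.chrom]
        clen = len(chrom)
        tss = r.tss_pos
        if r.gene.strand == "+":
            lo, hi = tss - upstream, tss + downstream
        else:
            lo, hi = tss - downstream, tss + upstream
        if lo < 0 or hi > clen:
            warnings.warn(f"{r.gene.symbol}: promoter window clipped at chromosome edge")
            lo, hi = max(0, lo), min(clen, hi)
        seq = str(chrom[lo:hi]).upper()
        if r.gene.strand == "-":
            seq = _revcomp(seq)
        out[r.gene.symbol] = seq
    return out


def _encode(seq: str) -> np.ndarray:
    """A/C/G/T -> 0..3, anything else (N) -> 4."""
    arr = np.full(len(seq), 4, dtype=np.int8)
    for base, i in _BASE_INDEX.items():
        arr[np.frombuffer(seq.encode(), dtype=np.uint8) == ord(base)] = i
    return arr


def scan_pwm(seq: str, pwm: PWM) -> list[tuple[int, str]]:
    """All (offset, strand) with log-odds >= score_threshold * max score,
    scanning the sequence and its reverse complement.

    N bases score zero log-odds (background).  Reverse-strand hit offsets
    refer to the forward sequence (leftmost base of the matched window).
    """
    hits = []
    L = pwm.length
    if len(seq) < L:
        return hits
    cutoff = pwm.score_threshold * pwm.max_score
    lo = np.vstack([pwm.log_odds.T, np.zeros(pwm.length)])  # row 4 = N
    for strand, s in (("+", seq.upper()), ("-", _revcomp(seq.upper()))):
        enc = _encode(s)
        n_off = len(s) - L + 1
        # score all offsets: sum of per-position log-odds lookups
        scores = np.zeros(n_off)
        for j in range(L):
            scores += lo[enc[j : j + n_off], j]
        for off in np.nonzero(scores >= cutoff)[0]:
            pos = int(off) if strand == "+" else len(seq) - L - int(off)
            hits.append((pos, strand))
    hits.sort()
    return hits


def promoter_hit_flags(seqs: dict[str, str], pwm: PWM) -> dict[str, bool]:
    return {name: bool(scan_pwm(s, pwm)) for name, s in seqs.items()}


@dataclass(frozen=True)
class MotifEnrichmentResult:
    motif: str
    n_target: int
    k_target: int
    background_rate: float
    pvalue: float
    enriched: bool


def motif_enrichment(
    target_seqs: dict[str, str], background_seqs: dict[str, str], pwm: PWM,
    alpha: float = 0.001,
) -> MotifEnrichmentResult:
    """Binomial enrichment of PWM hits in target vs background promoters.

    p = P(X >= k_target | n_target, background hit rate), upper tail.
    """
    import warnings

    if not target_seqs or not background_seqs:
        raise ValueError("target and background sets must be non-empty")
    k_bg = sum(promoter_hit_flags(background_seqs, pwm).values())
    rate = k_bg / len(background_seqs)
    k = sum(promoter_hit_flags(target_seqs, pwm).values())
    n = len(target_seqs)
    if rate == 0.0:
        if k > 0:
            warnings.warn("zero background hit rate with target hits: p floored")
            p = float(np.finfo(float).tiny)
        else:
            p = 1.0
    else:
        p = binom_upper_tail(k, n, rate)
    return MotifEnrichmentResult(pwm.name, n, k, rate, p, p < alpha)


def ap1_target_call(
    superinduced: set[str], nelf_positive: dict[str, bool],
    promoter_seqs: dict[str, str], ap1: PWM | None = None,
    background_seqs: dict[str, str] | None = None, alpha: float = 0.001,
) -> dict:
    """AP-1 target summary over NELF-negative superinduced genes.

    Per gene, "AP-1 target" means >=1 PWM hit in the promoter window; the
    set-level binomial enrichment p (against ``background_seqs`` when given)
    is reported alongside with the k-of-n summary.
    """
    ap1 = ap1 or consensus_pwm(AP1_CONSENSUS, name="AP-1")
    universe = [g for g in superinduced if not nelf_positive.get(g, False)]
    seqs = {g: promoter_seqs[g] for g in universe if g in promoter_seqs}
    flags = promoter_hit_flags(seqs, ap1)
    out = {
        "genes": flags,
        "k": sum(flags.values()),
        "n": len(flags),
    }
    if background_seqs:
        res = motif_enrichment(seqs, background_seqs, ap1, alpha=alpha) if seqs else None
        out["enrichment"] = res
    return out
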
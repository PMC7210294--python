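"""Aligned-tag processing and counting.

A :class:`TagLibrary` holds one sequencing library as flat numpy arrays.  ChIP
tags are extended to the expected fragment length from their 5' anchor;
PRO-seq tags are reduced to the single 5' base of the read, which marks the 3'
end of the nascent RNA and hence the polymerase position.  Because PRO-seq
reads are complementary to the run-on product, transcription-active signal for
a gene is carried by tags on the *antisense* strand; `sense_via_antisense`
counting implements that convention.

Library depth (``total``) is fixed at load time and drives all per-10-million
normalisation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .annotation import GenomeLayout, GeneRegions

__all__ = [
    "Tag",
    "TagLibrary",
    "SignalMatrix",
    "load_tags",
    "library_from_arrays",
    "extend_chip_tags",
    "reduce_proseq_tags",
    "count_tags",
    "count_in_regions",
    "tss_matrix",
    "normalize_per10M",
    "average_profile",
    "export_bedgraph",
]


@dataclass(frozen=True)
class Tag:
    chrom: str
    start: int
    end: int
    strand: str


class TagStateError(RuntimeError):
    """Illegal processing-state transition (e.g. re-extending a library)."""


@dataclass
class TagLibrary:
    """One aligned library: parallel arrays plus processing state.

    ``total`` is the number of tags at load time and never changes under
    extension/reduction or region subsetting.
    """

    chrom: np.ndarray  # object / str array
    start: np.ndarray  # int64
    end: np.ndarray  # int64
    strand: np.ndarray  # '+'/'-' str array
    total: int
    assay: str  # {chip, proseq}
    state: str = "raw"  # {raw, extended, reduced}
    label: str = ""
    _index: dict = field(default_factory=dict, repr=False, compare=False)

    def __len__(self) -> int:
        return self.start.size

    def _chrom_index(self, chrom: str) -> dict:
        """Cached per-chromosome sorted views used by all counting paths."""
        idx = self._index.get(chrom)
        if idx is None:
            mask = self.chrom == chrom
            starts = np.sort(self.start[mask])
            ends = np.sort(self.end[mask])
            strands = self.strand[mask]
            pos = self.start[mask]  # for 1-bp reduced tags start == position
            idx = {
                "starts": starts,
                "ends": ends,
                "pos_plus": np.sort(pos[strands == "+"]),
                "pos_minus": np.sort(pos[strands == "-"]),
            }
            self._index[chrom] = idx
        return idx

    def chroms(self) -> list[str]:
        return sorted(set(self.chrom.tolist()))


def library_from_arrays(
    chrom, start, end, strand, assay: str, label: str = "", state: str = "raw",
    total: int | None = None,
) -> TagLibrary:
    chrom = np.asarray(chrom, dtype=object)
    start = np.asarray(start, dtype=np.int64)
    end = np.asarray(end, dtype=np.int64)
    strand = np.asarray(strand, dtype=object)
    if np.any(end <= start):
        raise ValueError("tag records require start < end")
    return TagLibrary(
        chrom, start, end, strand,
        total=int(total if total is not None else start.size),
        assay=assay, state=state, label=label,
    )


def load_tags(path, assay: str, label: str = "", fmt: str | None = None) -> TagLibrary:
    """Load a BED6 or BAM tag file as a raw :class:`TagLibrary`.

    BAM loading keeps mapped primary alignments only.  Strandless BED records
    ('.') are an error for PRO-seq (the strand convention is load-bearing) and
    a warning + '+' assignment for ChIP, where counting ignores strand.
    """
    if fmt is None:
        fmt = "bam" if str(path).endswith(".bam") else "bed"
    if fmt == "bam":
        return _load_bam(path, assay, label)
    chroms, starts, ends, strands = [], [], [], []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}:{lineno}: expected BED6 (>=6 columns)")
            c, s, e, _name, _score, st = fields[:6]
            s, e = int(s), int(e)
            if e <= s:
                raise ValueError(f"{path}:{lineno}: requires start < end")
            if st not in ("+", "-"):
                if assay == "proseq":
                    raise ValueError(
                        f"{path}:{lineno}: strandless record not allowed for PRO-seq"
                    )
                warnings.warn(f"{path}:{lineno}: strandless ChIP record, assigned '+'")
                st = "+"
            chroms.append(c)
            starts.append(s)
            ends.append(e)
            strands.append(st)
    return library_from_arrays(chroms, starts, ends, strands, assay=assay, label=label)


def _load_bam(path, assay: str, label: str) -> TagLibrary:
    import pysam

    chroms, starts, ends, strands = [], [], [], []
    with pysam.AlignmentFile(path, "rb") as bam:
        for rec in bam.fetch(until_eof=True):
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            chroms.append(rec.reference_name)
            starts.append(rec.reference_start)
            ends.append(rec.reference_end)
            strands.append("-" if rec.is_reverse else "+")
    return library_from_arrays(chroms, starts, ends, strands, assay=assay, label=label)


# ---------------------------------------------------------------------------
# processing


def extend_chip_tags(
    lib: TagLibrary,
    fragment_length: int = 150,
    layout: GenomeLayout | None = None,
    anchor: str = "five_prime",
) -> TagLibrary:
    """Extend ChIP tags to the expected fragment length.

    Default (``anchor='five_prime'``): the fragment keeps the read's 5'
    terminus and grows in the read's 3' direction to ``fragment_length`` bp —
    the standard fragment-length model.  ``anchor='three_prime'`` instead
    anchors the read's 3' terminal base and extends downstream from it.
    Fragments are clipped at position 0 and, when a layout is given, at
    chromosome ends.
    """
    if lib.assay != "chip":
        raise TagStateError("extension applies to ChIP libraries only")
    if lib.state != "raw":
        raise TagStateError(f"cannot extend a library in state {lib.state!r}")
    plus = lib.strand == "+"
    if anchor == "five_prime":
        start = np.where(plus, lib.start, lib.end - fragment_length)
        end = np.where(plus, lib.start + fragment_length, lib.end)
    elif anchor == "three_prime":
        start = np.where(plus, lib.end - 1, lib.start + 1 - fragment_length)
        end = np.where(plus, lib.end - 1 + fragment_length, lib.start + 1)
    else:
        raise ValueError(f"unknown extension anchor {anchor!r}")
    start = np.maximum(start, 0)
    if layout is not None:
        lengths = np.array([layout.chrom_lengths.get(c, np.iinfo(np.int64).max)
                            for c in lib.chrom], dtype=np.int64)
        end = np.minimum(end, lengths)
    return TagLibrary(lib.chrom, start.astype(np.int64), end.astype(np.int64),
                      lib.strand, lib.total, lib.assay, "extended", lib.label)


def reduce_proseq_tags(lib: TagLibrary) -> TagLibrary:
    """Reduce PRO-seq reads to the single base at their 5' terminus."""
    if lib.assay != "proseq":
        raise TagStateError("reduction applies to PRO-seq libraries only")
    if lib.state != "raw":
        raise TagStateError(f"cannot reduce a library in state {lib.state!r}")
    plus = lib.strand == "+"
    start = np.where(plus, lib.start, lib.end - 1).astype(np.int64)
    return TagLibrary(lib.chrom, start, start + 1, lib.strand,
                      lib.total, lib.assay, "reduced", lib.label)


def _require_processed(lib: TagLibrary):
    want = "extended" if lib.assay == "chip" else "reduced"
    if lib.state != want:
        raise TagStateError(
            f"{lib.assay} library must be {want} before counting (state={lib.state!r})"
        )


# ---------------------------------------------------------------------------
# counting


def count_tags(
    lib: TagLibrary,
    chrom: str,
    interval: tuple[int, int],
    gene_strand: str | None = None,
    strand_mode: str = "both",
) -> int:
    """Tags attributable to ``interval``.

    ``both`` counts tags overlapping the interval by >=1 bp (ChIP).
    ``sense_via_antisense`` counts reduced PRO-seq tags inside the interval
    whose aligned strand is opposite to ``gene_strand``.
    """
    _require_processed(lib)
    lo, hi = interval
    idx = lib._chrom_index(chrom)
    if strand_mode == "both":
        n_started = np.searchsorted(idx["starts"], hi, side="left")
        n_ended = np.searchsorted(idx["ends"], lo, side="right")
        return int(n_started - n_ended)
    if strand_mode == "sense_via_antisense":
        if lib.assay != "proseq":
            raise ValueError("sense_via_antisense counting requires a PRO-seq library")
        if gene_strand not in ("+", "-"):
            raise ValueError("gene_strand required for sense_via_antisense counting")
        pos = idx["pos_minus"] if gene_strand == "+" else idx["pos_plus"]
        return int(np.searchsorted(pos, hi, side="left")
                   - np.searchsorted(pos, lo, side="left"))
    raise ValueError(f"unknown strand_mode {strand_mode!r}")


def count_in_regions(
    lib: TagLibrary, regions: list[GeneRegions], which: str = "tss",
    strand_mode: str = "both",
) -> np.ndarray:
    """Vectorised per-gene counts over TSS windows (``which='tss'``) or gene
    bodies (``which='body'``)."""
    out = np.empty(len(regions), dtype=np.int64)
    for i, r in enumerate(regions):
        iv = r.tss_window if which == "tss" else r.body
        out[i] = count_tags(lib, r.gene.chrom, iv, r.gene.strand, strand_mode)
    return out


@dataclass
class SignalMatrix:
    """Per-gene binned tag counts around the TSS, oriented in transcription
    direction (bin 0 is the most upstream bin)."""

    genes: list[str]
    values: np.ndarray  # (n_genes, n_bins), float64
    bin_size: int
    upstream: int
    downstream: int
    normalization: str = "raw"  # {raw, per10M}
    strand_mode: str = "both"

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    def bin_of(self, offset: int) -> int:
        """Bin index containing a position at ``offset`` bp from the TSS
        (negative = upstream) in transcription direction."""
        return (offset + self.upstream) // self.bin_size


def tss_matrix(
    lib: TagLibrary,
    regions: list[GeneRegions],
    upstream: int = 1000,
    downstream: int = 2000,
    bin_size: int = 10,
    strand_mode: str = "both",
) -> SignalMatrix:
    """Binned tag counts from ``upstream`` bp before to ``downstream`` bp after
    each TSS (defaults 1 kb / 2 kb at 10 bp: 300 bins)."""
    _require_processed(lib)
    if not regions:
        raise ValueError("no regions given")
    if (upstream + downstream) % bin_size:
        raise ValueError("window size must be divisible by bin_size")
    n_bins = (upstream + downstream) // bin_size
    values = np.zeros((len(regions), n_bins), dtype=np.float64)
    for i, r in enumerate(regions):
        tss = r.tss_pos
        if r.gene.strand == "+":
            edges = tss - upstream + bin_size * np.arange(n_bins + 1, dtype=np.int64)
        else:
            edges = tss - downstream + bin_size * np.arange(n_bins + 1, dtype=np.int64)
        idx = lib._chrom_index(r.gene.chrom)
        if strand_mode == "both":
            n_started = np.searchsorted(idx["starts"], edges[1:], side="left")
            n_ended = np.searchsorted(idx["ends"], edges[:-1], side="right")
            row = (n_started - n_ended).astype(np.float64)
        elif strand_mode == "sense_via_antisense":
            if lib.assay != "proseq":
                raise ValueError("sense_via_antisense requires a PRO-seq library")
            pos = idx["pos_minus"] if r.gene.strand == "+" else idx["pos_plus"]
            cuts = np.searchsorted(pos, edges, side="left")
            row = np.diff(cuts).astype(np.float64)
        else:
            raise ValueError(f"unknown strand_mode {strand_mode!r}")
        if r.gene.strand == "-":
            row = row[::-1]
        values[i] = row
    return SignalMatrix(
        [r.gene.symbol for r in regions], values, bin_size, upstream, downstream,
        "raw", strand_mode,
    )


def normalize_per10M(x, total: int):
    """Scale counts to per-10-million-tags units: x * 1e7 / total."""
    if total <= 0:
        raise ValueError("library total must be positive for normalisation")
    return np.asarray(x, dtype=np.float64) * (1e7 / total)


def average_profile(m: SignalMatrix) -> np.ndarray:
    """Per-bin mean across genes (the metaprofile)."""
    if m.values.shape[0] < 1:
        raise ValueError("empty matrix")
    return m.values.mean(axis=0)


# ---------------------------------------------------------------------------
# bedGraph export


def export_bedgraph(lib: TagLibrary, path, name: str | None = None) -> None:
    """Per-base coverage in per-10M units, runs of equal value merged."""
    _require_processed(lib)
    scale = 1e7 / lib.total if lib.total else 0.0
    with open(path, "w") as out:
        out.write(f'track type=bedGraph name="{name or lib.label or "coverage"}"\n')
        for chrom in lib.chroms():
            mask = lib.chrom == chrom
            starts = lib.start[mask]
            ends = lib.end[mask]
            breaks = np.unique(np.concatenate([starts, ends]))
            delta = np.zeros(breaks.size, dtype=np.int64)
            np.add.at(delta, np.searchsorted(breaks, starts), 1)
            np.add.at(delta, np.searchsorted(breaks, ends), -1)
            if breaks.size < 2:
                continue
            cov = np.cumsum(delta)[:-1]  # coverage on [breaks[i], breaks[i+1])
            run_start, run_val = breaks[0], cov[0]
            for j in range(1, cov.size):
                if cov[j] != run_val:
                    if run_val > 0:
                        out.write(
                            f"{chrom}\t{run_start}\t{breaks[j]}\t{run_val * scale:.12g}\n"
                        )
                    run_start, run_val = breaks[j], cov[j]
            if run_val > 0:
                out.write(f"{chrom}\t{run_start}\t{breaks[-1]}\t{run_val * scale:.12g}\n")
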
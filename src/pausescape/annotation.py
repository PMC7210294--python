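"""Gene annotation handling: parsing, unique-longest-variant reduction, and
strand-aware TSS / gene-body region definition.

All coordinates are 0-based half-open internally.  refFlat and BED inputs pass
through unchanged; GTF (1-based inclusive) is shifted on input.  The TSS of a
minus-strand gene is its span end; "downstream" always means the direction of
transcription.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "GenomeLayout",
    "GeneModel",
    "GeneRegions",
    "load_gene_annotation",
    "select_unique_longest",
    "define_regions",
    "write_regions_bed",
    "DEFAULT_DROP_PATTERNS",
]

#: chromosome names (or substring patterns) removed by the default filter:
#: mitochondrial plus anything flagged "random" / unplaced.
DEFAULT_DROP_PATTERNS = ("chrM", "chrMT", "random", "chrUn")


class AnnotationParseError(ValueError):
    """Raised for malformed annotation records; message names the line."""


@dataclass(frozen=True)
class GenomeLayout:
    """Chromosome inventory; ``effective_size`` is the Poisson-background
    denominator (total bp across retained chromosomes)."""

    chrom_lengths: dict[str, int]

    def __post_init__(self):
        for name, length in self.chrom_lengths.items():
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length")

    @property
    def chrom_names(self) -> list[str]:
        return list(self.chrom_lengths)

    @property
    def effective_size(self) -> int:
        return sum(self.chrom_lengths.values())

    def filtered(self, drop_patterns=DEFAULT_DROP_PATTERNS) -> "GenomeLayout":
        """Layout restricted to chromosomes passing the name filter."""
        keep = {
            name: length
            for name, length in self.chrom_lengths.items()
            if not _chrom_dropped(name, drop_patterns)
        }
        return GenomeLayout(keep)


@dataclass(frozen=True)
class GeneModel:
    """One transcript span: the unit reduced to unique genes downstream."""

    symbol: str
    transcript_id: str
    chrom: str
    strand: str
    start: int
    end: int

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.transcript_id}: strand must be + or -")
        if not self.start < self.end:
            raise ValueError(f"{self.transcript_id}: requires start < end")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def tss(self) -> int:
        """TSS coordinate: span start on +, span end on -."""
        return self.start if self.strand == "+" else self.end


@dataclass(frozen=True)
class GeneRegions:
    """Strand-aware TSS window and gene body for one gene.

    The TSS window spans ``tss_flank`` bp either side of the TSS; the body runs
    from the window's downstream edge (in transcription direction) to the TTS.
    Together they tile [TSS - flank, TTS] with no gap or overlap.
    """

    gene: GeneModel
    tss_flank: int = 250

    def __post_init__(self):
        if self.tss_flank <= 0:
            raise ValueError("tss_flank must be positive")
        if self.gene.length <= self.tss_flank:
            raise ValueError(
                f"{self.gene.symbol}: gene length {self.gene.length} bp does not "
                f"exceed tss_flank {self.tss_flank} bp"
            )

    @property
    def tss_pos(self) -> int:
        return self.gene.tss

    @property
    def tss_window(self) -> tuple[int, int]:
        return (self.tss_pos - self.tss_flank, self.tss_pos + self.tss_flank)

    @property
    def body(self) -> tuple[int, int]:
        if self.gene.strand == "+":
            return (self.tss_pos + self.tss_flank, self.gene.end)
        return (self.gene.start, self.tss_pos - self.tss_flank)

    @property
    def tss_len(self) -> int:
        return 2 * self.tss_flank

    @property
    def body_len(self) -> int:
        lo, hi = self.body
        return hi - lo


def _chrom_dropped(name: str, patterns) -> bool:
    for pat in patterns:
        if pat in ("chrM", "chrMT"):  # mitochondrial names match exactly
            if name == pat:
                return True
        elif pat in name:
            return True
    return False


# ---------------------------------------------------------------------------
# parsing


def load_gene_annotation(path, fmt: str = "refflat") -> list[GeneModel]:
    """Parse transcripts from a refFlat TSV, BED12 or GTF file.

    Returns one :class:`GeneModel` per transcript record, coordinates
    normalised to 0-based half-open.
    """
    fmt = fmt.lower()
    if fmt == "refflat":
        return _load_refflat(path)
    if fmt == "bed12":
        return _load_bed12(path)
    if fmt == "gtf":
        return _load_gtf(path)
    raise ValueError(f"unknown annotation format {fmt!r}")


def _iter_data_lines(path):
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line


def _load_refflat(path) -> list[GeneModel]:
    # refFlat columns: geneName name chrom strand txStart txEnd [cds/exon...]
    genes = []
    for lineno, line in _iter_data_lines(path):
        fields = line.split("\t")
        if len(fields) < 6:
            raise AnnotationParseError(f"{path}:{lineno}: expected >=6 refFlat columns")
        symbol, tx_id, chrom, strand, s, e = fields[:6]
        genes.append(_make_gene(symbol, tx_id, chrom, strand, s, e, path, lineno))
    return genes


def _load_bed12(path) -> list[GeneModel]:
    genes = []
    for lineno, line in _iter_data_lines(path):
        fields = line.split("\t")
        if len(fields) < 6:
            raise AnnotationParseError(f"{path}:{lineno}: expected >=6 BED columns")
        chrom, s, e, name, _score, strand = fields[:6]
        # BED "name" doubles as transcript id; symbol taken from name up to
        # the first '|' when present (symbol|transcript convention).
        symbol, _, tx = name.partition("|")
        genes.append(_make_gene(symbol, tx or name, chrom, strand, s, e, path, lineno))
    return genes


_GTF_ATTR = re.compile(r'(\w+) "([^"]*)"')


def _load_gtf(path) -> list[GeneModel]:
    genes = []
    for lineno, line in _iter_data_lines(path):
        fields = line.split("\t")
        if len(fields) < 9:
            raise AnnotationParseError(f"{path}:{lineno}: expected 9 GTF columns")
        chrom, _src, feature, s, e, _score, strand, _frame, attrs = fields[:9]
        if feature != "transcript":
            continue
        attr = dict(_GTF_ATTR.findall(attrs))
        symbol = attr.get("gene_name") or attr.get("gene_id", "")
        tx = attr.get("transcript_id", "")
        if not symbol or not tx:
            raise AnnotationParseError(
                f"{path}:{lineno}: transcript record lacks gene/transcript id"
            )
        try:
            start = int(s) - 1  # GTF is 1-based inclusive
            end = int(e)
        except ValueError:
            raise AnnotationParseError(f"{path}:{lineno}: non-integer coordinates")
        genes.append(_make_gene(symbol, tx, chrom, strand, start, end, path, lineno))
    return genes


def _make_gene(symbol, tx_id, chrom, strand, start, end, path, lineno) -> GeneModel:
    try:
        start = int(start)
        end = int(end)
    except ValueError:
        raise AnnotationParseError(f"{path}:{lineno}: non-integer coordinates")
    try:
        return GeneModel(symbol, tx_id, chrom, strand, start, end)
    except ValueError as exc:
        raise AnnotationParseError(f"{path}:{lineno}: {exc}")


# ---------------------------------------------------------------------------
# reduction and regions


def select_unique_longest(
    genes: list[GeneModel],
    min_length: int = 1000,
    drop_patterns=DEFAULT_DROP_PATTERNS,
) -> list[GeneModel]:
    """Reduce transcripts to one gene per symbol.

    Transcripts on dropped chromosomes (mitochondrial / "random") are removed
    first; per surviving symbol the longest variant is kept (ties broken by
    lexicographically smallest transcript id); genes shorter than
    ``min_length`` are then removed.  Output sorted by (chrom, start, symbol).
    """
    if not genes:
        raise ValueError("empty annotation input")
    best: dict[str, GeneModel] = {}
    for g in genes:
        if _chrom_dropped(g.chrom, drop_patterns):
            continue
        cur = best.get(g.symbol)
        if (
            cur is None
            or g.length > cur.length
            or (g.length == cur.length and g.transcript_id < cur.transcript_id)
        ):
            best[g.symbol] = g
    out = [g for g in best.values() if g.length >= min_length]
    out.sort(key=lambda g: (g.chrom, g.start, g.symbol))
    if not out:
        warnings.warn("no genes survive the unique-longest / length / chromosome filters")
    return out


def define_regions(gene: GeneModel, tss_flank: int = 250) -> GeneRegions:
    """TSS window (±``tss_flank``) and gene body (+flank..TTS) for one gene."""
    return GeneRegions(gene, tss_flank)


def write_regions_bed(regions: list[GeneRegions], path) -> None:
    """Audit BED6: one row per TSS window and per body, name=symbol:region."""
    rows = []
    for r in regions:
        for kind, (lo, hi) in (("tss", r.tss_window), ("body", r.body)):
            rows.append((r.gene.chrom, lo, hi, f"{r.gene.symbol}:{kind}", 0, r.gene.strand))
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)
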
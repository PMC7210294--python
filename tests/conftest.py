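import numpy as np
import pytest

from pausescape import annotation as ann
from pausescape import tags
from pausescape.synthetic import GeneratorConfig, build_dataset


@pytest.fixture
def refflat_file(tmp_path):
    """Three-gene refFlat with a multi-variant symbol, a chrM gene and a
    short gene, for exercising the unique-longest reduction."""
    rows = [
        ("A", "tA1", "chr1", "+", 1000, 1900),
        ("A", "tA2", "chr1", "+", 1000, 2500),
        ("A", "tA3", "chr1", "+", 1200, 2400),
        ("B", "tB1", "chrM", "+", 0, 5000),
        ("C", "tC1", "chr1", "-", 5000, 5800),
        ("D", "tD1", "chr2", "-", 10000, 15000),
    ]
    p = tmp_path / "genes.refflat"
    with open(p, "w") as fh:
        for r in rows:
            fh.write("\t".join(map(str, r)) + "\n")
    return p


def make_library(records, assay="chip", state="raw", total=None):
    """TagLibrary from (chrom, start, end, strand) tuples."""
    if not records:
        return tags.library_from_arrays([], [], [], [], assay=assay, state=state,
                                        total=total or 0)
    c, s, e, st = zip(*records)
    return tags.library_from_arrays(c, s, e, st, assay=assay, state=state, total=total)


@pytest.fixture
def small_dataset():
    """Compact synthetic study reused by slower tests (module scope would
    hide generator regressions; it is cheap enough to rebuild)."""
    return build_dataset(GeneratorConfig(seed=1, n_genes=80, chrom_length=3_000_000))


def brute_count_overlap(lib, chrom, lo, hi):
    """Independent recount: tags overlapping [lo, hi) by >= 1 bp."""
    n = 0
    for i in range(len(lib)):
        if lib.chrom[i] == chrom and lib.start[i] < hi and lib.end[i] > lo:
            n += 1
    return n


def brute_count_antisense(lib, chrom, lo, hi, gene_strand):
    """Independent recount: 1-bp tags inside [lo, hi) on the strand opposite
    the gene."""
    want = "-" if gene_strand == "+" else "+"
    n = 0
    for i in range(len(lib)):
        if (
            lib.chrom[i] == chrom
            and lib.strand[i] == want
            and lo <= lib.start[i] < hi
        ):
            n += 1
    return n
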
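"""Seeded generator for a complete toy pausing study with per-gene truth.

The generator emulates the statistical structure of a macrophage
pausing/activation experiment on a single synthetic chromosome: Pol II ChIP
tags pile up in TSS windows in proportion to each gene's true pausing level
and uniformly over gene bodies; LPS applies pause-release to induced genes
(TSS mass moves into the body); NELF tags co-occupy Pol II-paused TSSs, drop
by a dismissal factor at 0.5 h and are restored at 1 h; PU.1 tags mark a
group-1-enriched subset of TSSs; PRO-seq reads are emitted antisense to the
gene with their 5' base at the polymerase position; RNA-seq replicate counts
are negative-binomial around condition/genotype fold changes; and promoter
sequences carry planted AP-1 / ETS consensus motifs.

Everything is reproducible from a single integer seed, and the generator
never calls pipeline code, so parameter-recovery tests close the loop
independently.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import GeneModel, GenomeLayout, GeneRegions
from .tags import TagLibrary, library_from_arrays

__all__ = [
    "GeneratorConfig",
    "SyntheticDataset",
    "build_dataset",
    "generate_dataset",
    "generate_null_background",
    "generate_promoter_set",
]

_AP1 = "TGACTCA"
_ETS = "AGAGGAAGTG"


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic experiment.

    Defaults describe a paper-like regime: three quarters of genes paused
    (groups 1/2 at true PI 8/2), a transient NELF dismissal at 0.5 h restored
    by 1 h, LPS fold changes of 3 (induced) and 0.3 (suppressed), and a
    knockout that superinduces a majority of the early-induced genes.
    """

    n_genes: int = 300
    chrom: str = "chrS"
    chrom_length: int = 10_000_000
    seed: int = 0

    group_fractions: tuple = (0.50, 0.26, 0.24)
    pi_means: tuple = (8.0, 2.0, 0.8)

    # tag placement
    read_length: int = 36
    fragment_length: int = 150
    body_density: float = 25.0  # Pol II tags per kb of gene body
    background_rate: float = 0.004  # uniform tags per bp (lambda=2 per 500 bp)
    tss_offset_mean: float = 50.0  # pause position downstream of TSS, bp
    tss_offset_sd: float = 80.0
    tss_flank: int = 250

    # LPS pause-release (applied to induced genes in treated libraries)
    release_body_gain: float = 2.5
    release_pi_drop: float = 3.0

    # NELF / PU.1 occupancy
    nelf_prob_by_group: tuple = (0.32, 0.15, 0.08)
    nelf_tss_depth: float = 60.0
    nelf_background_rate: float = 0.002
    nelf_dismissal_fraction: float = 0.5  # of NELF+ genes dismissed at 0.5 h
    nelf_dismissal_factor: float = 0.5  # occupancy multiplier at 0.5 h
    pu1_prob_by_group: tuple = (0.7, 0.5, 0.3)
    pu1_tss_depth: float = 50.0

    # PRO-seq
    proseq_body_density: float = 25.0
    proseq_background_rate: float = 0.001
    pause_window: tuple = (20, 60)  # polymerase offsets downstream of TSS

    # RNA-seq
    lps_class_probs: tuple = (0.60, 0.20, 0.20)  # null / induced / suppressed
    lps_fc_induced: float = 3.0
    lps_fc_suppressed: float = 0.3
    ko_effect_prob: float = 0.6  # induced/suppressed genes with a KO effect
    ko_fc_up: float = 3.0  # symmetric with the LPS effect magnitude
    ko_fc_down: float = 0.3
    nb_dispersion: float = 0.05
    n_replicates: int = 3
    # nominal mapped fragments per library: the simulated genes are a small
    # slice of a real transcriptome, so depth is fixed rather than the slice
    # sum (avoids composition artefacts in FPKM fold changes)
    rnaseq_library_size: int = 1_000_000
    unexpressed_fraction: float = 0.10
    base_mean_log_range: tuple = (8.5, 12.0)  # log2 of expressed base counts

    # promoters
    promoter_upstream: int = 1000
    promoter_downstream: int = 100
    ap1_target_fraction: float = 0.69  # of NELF- superinduced genes

    def __post_init__(self):
        if abs(sum(self.group_fractions) - 1) > 1e-9:
            raise ValueError("group fractions must sum to 1")
        if abs(sum(self.lps_class_probs) - 1) > 1e-9:
            raise ValueError("LPS class probabilities must sum to 1")
        for name in ("body_density", "background_rate", "nelf_tss_depth"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class SyntheticDataset:
    config: GeneratorConfig
    layout: GenomeLayout
    genes: list  # GeneModel per gene (already unique)
    truth: pd.DataFrame  # per-gene ground truth, indexed by symbol
    libraries: dict  # label -> raw TagLibrary
    counts: pd.DataFrame  # RNA-seq fragment counts, gene x sample
    lengths: pd.Series
    samples: pd.DataFrame
    promoters: dict  # symbol -> promoter sequence (TSS-relative window)

    def expression_table(self):
        from .expression import ExpressionTable

        return ExpressionTable(
            self.counts, self.lengths, self.samples,
            library_sizes=self.samples["library_size"].astype(float).reindex(
                self.counts.columns),
        )


# ---------------------------------------------------------------------------
# gene placement and truth


def _place_genes(cfg: GeneratorConfig, rng: np.random.Generator) -> list[GeneModel]:
    genes = []
    cursor = 20_000
    width = len(str(cfg.n_genes))
    for i in range(cfg.n_genes):
        length = int(rng.integers(2_000, 8_001))
        gap = int(rng.integers(8_000, 20_001))
        start = cursor
        end = start + length
        if end + 20_000 > cfg.chrom_length:
            raise ValueError("chromosome too short for the requested gene count")
        strand = "+" if rng.random() < 0.5 else "-"
        sym = f"G{i + 1:0{width}d}"
        genes.append(GeneModel(sym, f"T{i + 1:0{width}d}", cfg.chrom, strand, start, end))
        cursor = end + gap
    return genes


def _assign_truth(cfg: GeneratorConfig, rng: np.random.Generator,
                  genes: list[GeneModel]) -> pd.DataFrame:
    n = len(genes)
    groups = rng.choice([1, 2, 3], size=n, p=list(cfg.group_fractions))
    pi_level = np.array([cfg.pi_means[g - 1] for g in groups])
    nelf = rng.random(n) < np.array([cfg.nelf_prob_by_group[g - 1] for g in groups])
    pu1 = rng.random(n) < np.array([cfg.pu1_prob_by_group[g - 1] for g in groups])
    dismissed = nelf & (rng.random(n) < cfg.nelf_dismissal_fraction)

    expressed = rng.random(n) >= cfg.unexpressed_fraction
    lo, hi = cfg.base_mean_log_range
    base_mean = np.where(
        expressed, 2.0 ** rng.uniform(lo, hi, size=n), rng.uniform(0.05, 0.4, size=n)
    )
    lps = rng.choice(["null", "induced", "suppressed"], size=n, p=list(cfg.lps_class_probs))
    lps = np.where(expressed, lps, "null")  # responses only defined when expressed
    fc05 = np.where(lps == "induced", cfg.lps_fc_induced,
                    np.where(lps == "suppressed", cfg.lps_fc_suppressed, 1.0))
    fc1h = fc05.copy()  # the response persists through 1 h in this model
    has_ko = (lps != "null") & (rng.random(n) < cfg.ko_effect_prob)
    ko_fc = np.where(has_ko & (lps == "induced"), cfg.ko_fc_up,
                     np.where(has_ko & (lps == "suppressed"), cfg.ko_fc_down, 1.0))
    superinduced = (lps == "induced") & (ko_fc >= cfg.ko_fc_up)
    more_suppressed = (lps == "suppressed") & (ko_fc <= cfg.ko_fc_down)
    ap1 = superinduced & ~nelf & (rng.random(n) < cfg.ap1_target_fraction)

    return pd.DataFrame(
        {
            "group": groups,
            "pi_level": pi_level,
            "nelf_positive": nelf,
            "pu1_positive": pu1,
            "dismissed": dismissed,
            "dismissal_factor": np.where(dismissed, cfg.nelf_dismissal_factor, 1.0),
            "expressed": expressed,
            "base_mean": base_mean,
            "lps_class": lps,
            "fc_05h_true": fc05,
            "fc_1h_true": fc1h,
            "ko_fc_true": ko_fc,
            "superinduced_true": superinduced,
            "more_suppressed_true": more_suppressed,
            "ap1_target": ap1,
        },
        index=pd.Index([g.symbol for g in genes], name="symbol"),
    )


# ---------------------------------------------------------------------------
# tag emission helpers


def _chip_reads_from_positions(cfg, rng, positions: np.ndarray):
    """Raw 36-bp reads whose 150-bp five-prime extension is centred on each
    binding position (random read strand)."""
    half = cfg.fragment_length // 2
    strands = np.where(rng.random(positions.size) < 0.5, "+", "-").astype(object)
    plus = strands == "+"
    start = np.where(plus, positions - half, positions + half - cfg.read_length)
    start = np.maximum(start, 0)
    end = start + cfg.read_length
    return start.astype(np.int64), end.astype(np.int64), strands


def _tss_positions(cfg, rng, gene: GeneModel, k: int) -> np.ndarray:
    """Binding positions around the pause site, truncated to the TSS window."""
    sign = 1 if gene.strand == "+" else -1
    off = rng.normal(cfg.tss_offset_mean, cfg.tss_offset_sd, size=k)
    off = np.clip(off, -cfg.tss_flank, cfg.tss_flank - 1)
    return (gene.tss + sign * off).astype(np.int64)


def _body_interval(cfg, gene: GeneModel) -> tuple[int, int]:
    """Gene body in genomic coordinates: TSS+flank to the TTS."""
    if gene.strand == "+":
        return gene.start + cfg.tss_flank, gene.end
    return gene.start, gene.end - cfg.tss_flank


def _make_chip_library(cfg, rng, genes, tss_mean, body_mean_per_kb,
                       background_rate, label) -> TagLibrary:
    """Generic ChIP library: per-gene Poisson TSS and body mass plus uniform
    background.  ``tss_mean``/``body_mean_per_kb`` are per-gene arrays; body
    tags land in the gene body proper (downstream of the TSS window) so the
    realised density ratio tracks the true pausing level."""
    starts, ends, strands = [], [], []
    for i, g in enumerate(genes):
        k = rng.poisson(tss_mean[i])
        pos = [_tss_positions(cfg, rng, g, k)] if k else []
        blo, bhi = _body_interval(cfg, g)
        kb = rng.poisson(body_mean_per_kb[i] * (bhi - blo) / 1000)
        if kb:
            pos.append(rng.integers(blo, bhi, size=kb).astype(np.int64))
        if pos:
            p = np.concatenate(pos)
            s, e, st = _chip_reads_from_positions(cfg, rng, p)
            starts.append(s)
            ends.append(e)
            strands.append(st)
    nbg = rng.poisson(background_rate * cfg.chrom_length)
    if nbg:
        p = rng.integers(0, cfg.chrom_length, size=nbg).astype(np.int64)
        s, e, st = _chip_reads_from_positions(cfg, rng, p)
        starts.append(s)
        ends.append(e)
        strands.append(st)
    start = np.concatenate(starts) if starts else np.array([], np.int64)
    end = np.concatenate(ends) if ends else np.array([], np.int64)
    strand = np.concatenate(strands) if strands else np.array([], object)
    order = np.argsort(start, kind="stable")
    return library_from_arrays(
        np.full(start.size, cfg.chrom, dtype=object), start[order], end[order],
        strand[order], assay="chip", label=label,
    )


def _polii_library(cfg, rng, genes, truth, condition: str) -> TagLibrary:
    """Pol II ChIP tags; ``condition`` in {rest, lps}.  Under LPS, induced
    genes gain body density and shed TSS mass (pause-release)."""
    pi = truth["pi_level"].to_numpy(dtype=float)
    body = np.full(len(genes), cfg.body_density)
    tss_factor = np.ones(len(genes))
    if condition != "rest":
        induced = (truth["lps_class"] == "induced").to_numpy()
        body = np.where(induced, body * cfg.release_body_gain, body)
        tss_factor = np.where(
            induced, cfg.release_body_gain / cfg.release_pi_drop, 1.0
        )
    tss_mean = pi * cfg.body_density * (2 * cfg.tss_flank / 1000) * tss_factor
    return _make_chip_library(
        cfg, rng, genes, tss_mean, body, cfg.background_rate, f"polII_{condition}"
    )


def _nelf_library(cfg, rng, genes, truth, condition: str) -> TagLibrary:
    """NELF-E ChIP tags; ``condition`` in {0h, 05h, 1h}.  At 0.5 h dismissed
    genes keep only ``dismissal_factor`` of their occupancy; 1 h restores."""
    nelf = truth["nelf_positive"].to_numpy()
    depth = np.where(nelf, cfg.nelf_tss_depth, 0.0)
    if condition == "05h":
        depth = depth * truth["dismissal_factor"].to_numpy()
    return _make_chip_library(
        cfg, rng, genes, depth, np.zeros(len(genes)), cfg.nelf_background_rate,
        f"nelfe_{condition}",
    )


def _pu1_library(cfg, rng, genes, truth) -> TagLibrary:
    depth = np.where(truth["pu1_positive"].to_numpy(), cfg.pu1_tss_depth, 0.0)
    return _make_chip_library(
        cfg, rng, genes, depth, np.zeros(len(genes)), cfg.nelf_background_rate,
        "pu1_rest",
    )


def _proseq_library(cfg, rng, genes, truth, condition: str) -> TagLibrary:
    """PRO-seq reads: aligned antisense to the gene, 5' base at the polymerase
    position (paused mass just downstream of the TSS, elongating mass uniform
    over the body)."""
    starts, ends, strands = [], [], []
    pi = truth["pi_level"].to_numpy(dtype=float)
    induced = (truth["lps_class"] == "induced").to_numpy()
    for i, g in enumerate(genes):
        body_density = cfg.proseq_body_density
        tss_factor = 1.0
        if condition != "rest" and induced[i]:
            body_density *= cfg.release_body_gain
            tss_factor = cfg.release_body_gain / cfg.release_pi_drop
        k_pause = rng.poisson(pi[i] * cfg.proseq_body_density
                              * (2 * cfg.tss_flank / 1000) * tss_factor)
        blo, bhi = _body_interval(cfg, g)
        k_body = rng.poisson(body_density * (bhi - blo) / 1000)
        sign = 1 if g.strand == "+" else -1
        pos = []
        if k_pause:
            off = rng.integers(cfg.pause_window[0], cfg.pause_window[1] + 1, size=k_pause)
            pos.append(g.tss + sign * off)
        if k_body:
            pos.append(rng.integers(blo, bhi, size=k_body))
        if not pos:
            continue
        p = np.concatenate(pos).astype(np.int64)
        read_strand = "-" if g.strand == "+" else "+"
        if read_strand == "+":
            s = p
        else:
            s = p - cfg.read_length + 1
        s = np.maximum(s, 0)
        starts.append(s)
        ends.append(s + cfg.read_length)
        strands.append(np.full(p.size, read_strand, dtype=object))
    nbg = rng.poisson(cfg.proseq_background_rate * cfg.chrom_length)
    if nbg:
        p = rng.integers(0, cfg.chrom_length, size=nbg).astype(np.int64)
        st = np.where(rng.random(nbg) < 0.5, "+", "-").astype(object)
        starts.append(p)
        ends.append(p + cfg.read_length)
        strands.append(st)
    start = np.concatenate(starts) if starts else np.array([], np.int64)
    end = np.concatenate(ends) if ends else np.array([], np.int64)
    strand = np.concatenate(strands) if strands else np.array([], object)
    order = np.argsort(start, kind="stable")
    return library_from_arrays(
        np.full(start.size, cfg.chrom, dtype=object), start[order], end[order],
        strand[order], assay="proseq", label=f"proseq_{condition}",
    )


# ---------------------------------------------------------------------------
# RNA-seq and promoters


_CONDITIONS = (("WT", 0.0), ("WT", 0.5), ("WT", 1.0), ("KO", 0.0), ("KO", 0.5))


def _rnaseq_counts(cfg, rng, genes, truth):
    base = truth["base_mean"].to_numpy()
    fc05 = truth["fc_05h_true"].to_numpy()
    fc1h = truth["fc_1h_true"].to_numpy()
    ko = truth["ko_fc_true"].to_numpy()
    cond_mean = {
        ("WT", 0.0): base,
        ("WT", 0.5): base * fc05,
        ("WT", 1.0): base * fc1h,
        ("KO", 0.0): base,  # NELF loss leaves resting expression unchanged here
        ("KO", 0.5): base * fc05 * ko,
    }
    shape = 1.0 / cfg.nb_dispersion
    cols, names, meta = [], [], []
    for genotype, time in _CONDITIONS:
        for rep in range(1, cfg.n_replicates + 1):
            m = cond_mean[(genotype, time)]
            lam = rng.gamma(shape, m / shape)
            cols.append(rng.poisson(lam))
            name = f"{genotype}_{time:g}h_r{rep}"
            names.append(name)
            meta.append({"sample": name, "genotype": genotype,
                         "time": time, "replicate": rep,
                         "library_size": cfg.rnaseq_library_size})
    counts = pd.DataFrame(
        np.column_stack(cols), columns=names,
        index=pd.Index([g.symbol for g in genes], name="symbol"),
    )
    samples = pd.DataFrame(meta).set_index("sample")
    return counts, samples


def _random_seq(rng, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])


def _plant(rng, seq: str, motif: str) -> str:
    pos = int(rng.integers(0, len(seq) - len(motif) + 1))
    return seq[:pos] + motif + seq[pos + len(motif):]


def _promoters(cfg, rng, genes, truth) -> dict[str, str]:
    n = cfg.promoter_upstream + cfg.promoter_downstream
    out = {}
    ap1 = truth["ap1_target"]
    pu1 = truth["pu1_positive"]
    group = truth["group"]
    for g in genes:
        seq = _random_seq(rng, n)
        if pu1[g.symbol] and group[g.symbol] == 1:
            seq = _plant(rng, seq, _ETS)
        if ap1[g.symbol]:
            seq = _plant(rng, seq, _AP1)
        out[g.symbol] = seq
    return out


# ---------------------------------------------------------------------------
# entry points


def build_dataset(cfg: GeneratorConfig) -> SyntheticDataset:
    """Generate the full in-memory study from ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    genes = _place_genes(cfg, rng)
    truth = _assign_truth(cfg, rng, genes)
    libraries = {
        "polII_rest": _polii_library(cfg, rng, genes, truth, "rest"),
        "polII_lps1h": _polii_library(cfg, rng, genes, truth, "lps"),
        "nelfe_0h": _nelf_library(cfg, rng, genes, truth, "0h"),
        "nelfe_05h": _nelf_library(cfg, rng, genes, truth, "05h"),
        "nelfe_1h": _nelf_library(cfg, rng, genes, truth, "1h"),
        "pu1_rest": _pu1_library(cfg, rng, genes, truth),
        "proseq_rest": _proseq_library(cfg, rng, genes, truth, "rest"),
        "proseq_lps05h": _proseq_library(cfg, rng, genes, truth, "lps"),
    }
    counts, samples = _rnaseq_counts(cfg, rng, genes, truth)
    promoters = _promoters(cfg, rng, genes, truth)
    layout = GenomeLayout({cfg.chrom: cfg.chrom_length})
    lengths = pd.Series([g.length for g in genes],
                        index=counts.index, name="length")
    return SyntheticDataset(cfg, layout, genes, truth, libraries,
                            counts, lengths, samples, promoters)


def generate_dataset(cfg: GeneratorConfig, out_dir) -> dict:
    """Generate and write the study to ``out_dir``; returns the file map."""
    ds = build_dataset(cfg)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    ann = out / "annotation.refflat"
    with open(ann, "w") as fh:
        for g in ds.genes:
            fh.write(f"{g.symbol}\t{g.transcript_id}\t{g.chrom}\t{g.strand}"
                     f"\t{g.start}\t{g.end}\n")
    paths["annotation"] = ann

    for label, lib in ds.libraries.items():
        assay = "proseq" if lib.assay == "proseq" else "chip"
        p = out / f"{assay}_{label}.bed"
        _write_bed6(lib, p)
        paths[label] = p

    counts_path = out / "counts.tsv"
    table = ds.counts.copy()
    table.insert(0, "length", ds.lengths)
    table.to_csv(counts_path, sep="\t")
    paths["counts"] = counts_path
    samples_path = out / "samples.tsv"
    ds.samples.to_csv(samples_path, sep="\t")
    paths["samples"] = samples_path

    fasta = out / "promoters.fasta"
    with open(fasta, "w") as fh:
        for name, seq in ds.promoters.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
    paths["promoters"] = fasta

    truth_path = out / "truth.tsv"
    ds.truth.to_csv(truth_path, sep="\t")
    paths["truth"] = truth_path
    layout_path = out / "genome.tsv"
    with open(layout_path, "w") as fh:
        for name, length in ds.layout.chrom_lengths.items():
            fh.write(f"{name}\t{length}\n")
    paths["layout"] = layout_path
    return paths


def _write_bed6(lib: TagLibrary, path) -> None:
    with open(path, "w") as fh:
        for i in range(len(lib)):
            fh.write(f"{lib.chrom[i]}\t{lib.start[i]}\t{lib.end[i]}"
                     f"\ttag{i + 1}\t0\t{lib.strand[i]}\n")


def generate_null_background(
    n_tags: int, chrom_length: int, seed: int, chrom: str = "chrN",
    read_length: int = 36, assay: str = "chip",
) -> TagLibrary:
    """Homogeneous Poisson tag library with no planted structure (FDR
    calibration input).  Exactly ``n_tags`` uniform tags."""
    rng = np.random.default_rng(seed)
    if n_tags == 0:
        return library_from_arrays([], [], [], [], assay=assay, label="null")
    pos = np.sort(rng.integers(0, chrom_length, size=n_tags)).astype(np.int64)
    strand = np.where(rng.random(n_tags) < 0.5, "+", "-").astype(object)
    return library_from_arrays(
        np.full(n_tags, chrom, dtype=object), pos, pos + read_length, strand,
        assay=assay, label="null",
    )


def generate_promoter_set(
    n: int, plant_fraction: float, seed: int, motif: str = _AP1, length: int = 300
) -> tuple[dict[str, str], dict[str, bool]]:
    """Random promoter set with the motif planted in a fixed fraction.

    Returns (sequences, planted flags); planting happens in the first
    round(n * plant_fraction) promoters of the shuffled order.
    """
    rng = np.random.default_rng(seed)
    k = int(round(n * plant_fraction))
    planted_idx = set(rng.permutation(n)[:k].tolist())
    seqs, flags = {}, {}
    for i in range(n):
        name = f"P{i + 1:04d}"
        seq = _random_seq(rng, length)
        if i in planted_idx:
            seq = _plant(rng, seq, motif)
        seqs[name] = seq
        flags[name] = i in planted_idx
    return seqs, flags
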
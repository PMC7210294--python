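"""End-to-end orchestration: annotation -> tags -> enrichment -> pausing ->
occupancy -> expression -> motifs -> summary report.

`run_all` consumes a directory laid out like `synthetic.generate_dataset`
output (or any real data arranged the same way), applies every stage with the
thresholds in :class:`RunConfig`, writes each intermediate table under the
output directory, and returns the report dictionary.  The run is fully
deterministic: no stage draws random numbers, so re-running on the same
inputs reproduces every output byte for byte.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotation as ann
from . import enrichment, motif, occupancy, pausing, tags
from .expression import ExpressionTable, response_table

__all__ = ["RunConfig", "run_all", "crosstab_report"]


@dataclass
class RunConfig:
    """Every numeric threshold of the pipeline, with its standard default."""

    tss_flank: int = 250
    min_gene_length: int = 1000
    window_size: int = 500
    fdr: float = 0.001
    pi_high: float = 3.0
    pi_moderate: float = 1.5
    fc_1h: float = 1.5
    fc_up: float = 1.4
    fc_down: float = 0.6
    dismissal_fc: float = 0.5
    p_cut: float = 0.05
    q_cut: float = 0.05
    fragment_length: int = 150
    extension_anchor: str = "five_prime"
    promoter_upstream: int = 1000
    promoter_downstream: int = 100
    motif_alpha: float = 0.001
    motif_score_threshold: float = 0.8
    profile_upstream: int = 1000
    profile_downstream: int = 2000
    profile_bin: int = 10

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


_LIBRARIES = {
    # label -> (file name, assay)
    "polII_rest": ("chip_polII_rest.bed", "chip"),
    "polII_lps1h": ("chip_polII_lps1h.bed", "chip"),
    "nelfe_0h": ("chip_nelfe_0h.bed", "chip"),
    "nelfe_05h": ("chip_nelfe_05h.bed", "chip"),
    "nelfe_1h": ("chip_nelfe_1h.bed", "chip"),
    "pu1_rest": ("chip_pu1_rest.bed", "chip"),
    "proseq_rest": ("proseq_proseq_rest.bed", "proseq"),
    "proseq_lps05h": ("proseq_proseq_lps05h.bed", "proseq"),
}


def _load_layout(path) -> ann.GenomeLayout:
    lengths = {}
    with open(path) as fh:
        for line in fh:
            name, length = line.split()
            lengths[name] = int(length)
    return ann.GenomeLayout(lengths)


def _read_promoters(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def _process(lib: tags.TagLibrary, cfg: RunConfig,
             layout: ann.GenomeLayout) -> tags.TagLibrary:
    if lib.assay == "chip":
        return tags.extend_chip_tags(lib, cfg.fragment_length, layout,
                                     cfg.extension_anchor)
    return tags.reduce_proseq_tags(lib)


def _library_threshold(lib, layout, cfg) -> enrichment.EnrichmentThreshold:
    model = enrichment.fit_background(lib, layout, cfg.window_size)
    _, _, counts = enrichment.window_counts(lib, layout, cfg.window_size)
    return enrichment.fdr_threshold(model, counts, cfg.fdr)


def run_all(data_dir, out_dir, config: RunConfig | None = None) -> dict:
    """Execute the full analysis over a study directory; see module doc."""
    cfg = config or RunConfig()
    data = Path(data_dir)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"thresholds": dataclasses.asdict(cfg)}

    def _stage(name, fn):
        try:
            return fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    # ---- annotation
    layout = _stage("layout", lambda: _load_layout(data / "genome.tsv"))
    transcripts = _stage(
        "annotation",
        lambda: ann.load_gene_annotation(data / "annotation.refflat", "refflat"),
    )
    genes = ann.select_unique_longest(transcripts, cfg.min_gene_length)
    regions = [ann.define_regions(g, cfg.tss_flank) for g in genes]
    ann.write_regions_bed(regions, out / "gene_regions.bed")
    report["n_transcripts"] = len(transcripts)
    report["n_genes"] = len(genes)

    # ---- tag libraries
    libs: dict[str, tags.TagLibrary] = {}
    for label, (fname, assay) in _LIBRARIES.items():
        path = data / fname
        if not path.exists():
            raise FileNotFoundError(f"missing tag file for {label!r}: {path}")
        raw = _stage(label, lambda p=path, a=assay, l=label: tags.load_tags(p, a, l))
        libs[label] = _process(raw, cfg, layout)
    report["library_totals"] = {k: v.total for k, v in libs.items()}

    # ---- enrichment thresholds and pausing tables
    thr_chip = _library_threshold(libs["polII_rest"], layout, cfg)
    thr_chip_lps = _library_threshold(libs["polII_lps1h"], layout, cfg)
    thr_pro = _library_threshold(libs["proseq_rest"], layout, cfg)
    thr_pro_lps = _library_threshold(libs["proseq_lps05h"], layout, cfg)
    report["thresholds_data_derived"] = {
        "polII_rest": thr_chip.threshold,
        "polII_lps1h": thr_chip_lps.threshold,
        "proseq_rest": thr_pro.threshold,
        "proseq_lps05h": thr_pro_lps.threshold,
    }
    tables = {
        "chip_rest": pausing.pausing_table(libs["polII_rest"], regions, thr_chip,
                                           high=cfg.pi_high, moderate=cfg.pi_moderate),
        "chip_lps1h": pausing.pausing_table(libs["polII_lps1h"], regions, thr_chip_lps,
                                            high=cfg.pi_high, moderate=cfg.pi_moderate),
        "proseq_rest": pausing.pausing_table(libs["proseq_rest"], regions, thr_pro,
                                             high=cfg.pi_high, moderate=cfg.pi_moderate),
        "proseq_lps05h": pausing.pausing_table(libs["proseq_lps05h"], regions,
                                               thr_pro_lps, high=cfg.pi_high,
                                               moderate=cfg.pi_moderate),
    }
    for name, recs in tables.items():
        pausing.records_frame(recs).to_csv(out / f"pausing_{name}.tsv", sep="\t")
    report["group_counts"] = {
        name: {g: sum(1 for r in recs if r.group == g) for g in (1, 2, 3)}
        for name, recs in tables.items()
    }

    # ---- factor occupancy
    nelf_peaks = enrichment.call_peaks(libs["nelfe_0h"], layout, cfg.window_size, cfg.fdr)
    report["nelf_peak_distribution"] = enrichment.annotate_peaks(nelf_peaks, regions)
    enrichment.write_peaks(nelf_peaks, out / "nelfe_peaks.bed", out / "nelfe_peaks.tsv")
    nelf_pos = occupancy.call_factor_positive(nelf_peaks, regions)
    pu1_peaks = enrichment.call_peaks(libs["pu1_rest"], layout, cfg.window_size, cfg.fdr)
    pu1_pos = occupancy.call_factor_positive(pu1_peaks, regions)

    occ = occupancy.tss_occupancy_table(
        {c: libs[f"nelfe_{c}"] for c in ("0h", "05h", "1h")}, regions
    )
    dism = occupancy.dismissal_table(libs["nelfe_0h"], libs["nelfe_05h"], regions,
                                     cfg.dismissal_fc, cfg.p_cut)
    dism_peaks = occupancy.dismissal_by_peaks(
        libs["nelfe_0h"], libs["nelfe_05h"], regions, layout, cfg.window_size,
        cfg.fdr, fc_cut=cfg.dismissal_fc,
    )
    occ["nelf_positive"] = nelf_pos
    occ["pu1_positive"] = pu1_pos
    occ = occ.join(dism[["fc", "pvalue", "qvalue", "dismissed"]])
    occ["dismissed_by_peaks"] = dism_peaks
    occ.to_csv(out / "occupancy.tsv", sep="\t")
    a = occ["dismissed"] & occ["nelf_positive"]
    b = occ["dismissed_by_peaks"] & occ["nelf_positive"]
    union = int((a | b).sum())
    report["dismissal"] = {
        "by_counts": int(a.sum()),
        "by_peaks": int(b.sum()),
        "jaccard": float((a & b).sum() / union) if union else 1.0,
    }

    # ---- expression classes
    table = _stage(
        "expression",
        lambda: ExpressionTable.from_files(data / "counts.tsv", data / "samples.tsv"),
    )
    resp = response_table(table)
    resp.to_csv(out / "response.tsv", sep="\t")
    report["response_counts"] = {
        c: int(resp[c].sum())
        for c in ("expressed", "inducible_1h", "induced_05h", "suppressed_05h",
                  "ko_up", "ko_down", "superinduced", "more_suppressed")
    }

    # ---- PI distribution shift of induced paused genes
    chip_rest = pausing.records_frame(tables["chip_rest"])
    chip_lps = pausing.records_frame(tables["chip_lps1h"])
    induced = resp.index[resp["induced_05h"]]
    g1 = chip_rest.index[(chip_rest["group"] == 1)]
    sel = [s for s in induced if s in set(g1)]
    report["pause_release"] = None
    if len(sel) >= 2:
        comp = pausing.compare_pi_distributions(
            chip_rest.loc[sel, "pi"].to_numpy(), chip_lps.loc[sel, "pi"].to_numpy()
        )
        pd.DataFrame({
            "pi_rest": np.concatenate([comp["ecdf_a"][0]]),
            "ecdf_rest": np.concatenate([comp["ecdf_a"][1]]),
        }).to_csv(out / "ecdf_rest.tsv", sep="\t", index=False)
        report["pause_release"] = {
            "n_genes": len(sel),
            "ks_statistic": comp["statistic"],
            "ks_pvalue": comp["pvalue"],
            "median_pi_rest": float(np.median(chip_rest.loc[sel, "pi"].replace(
                np.inf, np.nan).dropna())),
            "median_pi_lps": float(np.median(chip_lps.loc[sel, "pi"].replace(
                np.inf, np.nan).dropna())),
        }

    # ---- boxed NELF signal by pausing group
    mat = tags.tss_matrix(libs["nelfe_0h"], regions, cfg.profile_upstream,
                          cfg.profile_downstream, cfg.profile_bin)
    groups = {
        f"group{g}": [r.symbol for r in tables["chip_rest"] if r.group == g]
        for g in (1, 2, 3)
    }
    groups = {k: v for k, v in groups.items() if v}
    mwu, _counts = pausing.boxed_signal_test(mat, groups, (-cfg.tss_flank, cfg.tss_flank))
    mwu.to_csv(out / "nelf_boxed_mwu.tsv", sep="\t", index=False)
    report["nelf_boxed_mwu"] = mwu.to_dict("records")

    # ---- promoter motifs
    promoters = _read_promoters(data / "promoters.fasta")
    super_set = set(resp.index[resp["superinduced"]])
    nelf_flags = nelf_pos.to_dict()
    background = {g: s for g, s in promoters.items() if g not in super_set}
    ap1 = motif.ap1_target_call(
        super_set, nelf_flags, promoters,
        motif.consensus_pwm(motif.AP1_CONSENSUS, name="AP-1"),
        background_seqs=background, alpha=cfg.motif_alpha,
    )
    report["ap1_targets"] = {"k": ap1["k"], "n": ap1["n"]}
    if ap1.get("enrichment") is not None:
        report["ap1_targets"]["pvalue"] = ap1["enrichment"].pvalue

    # ---- crosstabs
    report["crosstab"] = crosstab_report(
        tables["chip_rest"],
        {"NELF+": nelf_pos, "PU.1+": pu1_pos,
         "LPS-inducible": resp["inducible_1h"]},
    )

    with open(out / "report.yaml", "w") as fh:
        yaml.safe_dump(_plain(report), fh, sort_keys=True)
    return report


def crosstab_report(records, flags: dict[str, pd.Series]) -> dict:
    """Conditional overlap fractions between pausing groups and boolean gene
    labels, in both directions."""
    labels = {}
    symbols = {r.symbol for r in records}
    for name, series in flags.items():
        members = {s for s, v in series.items() if bool(v) and s in symbols}
        labels[name] = members
    return pausing.summarize_groups(records, labels)


def _plain(obj):
    """YAML-serialisable copy (numpy scalars to python)."""
    if isinstance(obj, dict):
        return {str(k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj
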
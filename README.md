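# pausescape

Quantification of RNA polymerase II promoter-proximal pausing from aligned
sequencing tags, built around the analysis of pausing and pause-release in
LPS-activated macrophages: pausing indices and gene grouping from Pol II
ChIP-seq or PRO-seq, Poisson-background enrichment thresholds and peak
calling, NELF/PU.1 occupancy dynamics at transcription start sites,
expression-response classification from replicate RNA-seq counts, and
promoter motif enrichment. A fully seeded synthetic study generator makes
every stage verifiable by parameter recovery, so the whole pipeline can be
exercised and tested without downloading any sequencing data.

It is aimed at computational biologists who want a small, transparent,
tested implementation of this analysis stack — either to re-run the
procedure on their own aligned tags or to study how its thresholds and
statistics behave under controlled conditions.

## The statistics at the core

**Pausing index.** For a gene with TSS window *T* (TSS ± 250 bp) and gene
body *B* (TSS + 250 bp to the TTS), with tag counts `c_T`, `c_B` and lengths
`L_T`, `L_B` in bp,

    PI = (c_T / L_T) / (c_B / L_B)

i.e. the ratio of tag densities (tags per kb) between promoter and body.
Genes with an enriched ("active") TSS and PI ≥ 3 are highly paused
(group 1), 1.5 ≤ PI < 3 moderately paused (group 2), and everything else —
PI < 1.5 or no TSS enrichment — non-paused (group 3). ChIP tags are first
extended to the 150-bp expected fragment; PRO-seq reads are reduced to their
5′ base and counted on the strand *antisense* to the gene, which is where
the nascent-RNA-complementary reads of an engaged polymerase fall.

**Enrichment threshold.** Tags are counted in 500-bp windows sliding at
half-window steps. Under a uniform background the window count is Poisson
with rate λ = N·(w + f − 1)/G (N tags of footprint f bp, window w, genome
G). The TSS-activity cutoff is the smallest integer c whose estimated FDR

    FDR(c) = n_windows · P(X ≥ c | Poisson λ) / #{observed windows ≥ c}

drops below 0.001; the same machinery drives peak calling (overlapping
significant windows merged, optionally requiring a fold enrichment over a
background condition).

**Occupancy dynamics.** NELF dismissal between 0 h and 0.5 h of LPS is
called per gene when the depth-normalised TSS fold change is < 0.5 with
p < 0.05 from an exact two-sided binomial test, and cross-checked by calling
peaks on the baseline with the treated condition as background.

**Expression classes.** FPKM = counts·10⁹/(length·library size); a gene is
expressed when resting FPKM ≥ 1. On (FPKM+1) fold changes: LPS-inducible at
1 h (q < 0.05, FC ≥ 1.5), induced/suppressed at 0.5 h (p < 0.05, FC ≥ 1.4 /
≤ 0.6), knockout up/down (same gates on KO/WT), and superinduced =
LPS-induced ∧ KO-up. Significance comes from Welch t-tests on log2(FPKM+1)
across replicates with Benjamini–Hochberg adjustment.

**Motif enrichment.** Promoters (−1000..+100 bp around the TSS) are scanned
on both strands with a log-odds PWM; enrichment of a promoter set is the
upper-tail binomial probability of the observed number of hit promoters at
the background hit rate, with AP-1 targets called at P < 0.001.

## Worked example

```python
from pausescape.synthetic import GeneratorConfig, generate_dataset
from pausescape.pipeline import run_all

generate_dataset(GeneratorConfig(seed=1), "scratch/simulated_study")
report = run_all("scratch/simulated_study", "scratch/pipeline_run")
print(report["thresholds_data_derived"])   # {'polII_rest': 18, ...}
print(report["group_counts"]["chip_rest"])  # {1: 148, 2: 67, 3: 85}
```

The numbered scripts under `analysis/` run the same study step by step and
print what they find; on the default seed:

```
chip_rest: 98.3% of genes recover their true group
proseq_rest: 96.3% of genes recover their true group
pause-release: median PI of 47 induced genes drops 5.67 -> 2.19; KS D=0.511, p=2.49e-06
superinduced: 33 genes, 26 NELF-negative; AP-1 motif in 19 of 26 (set-level binomial p = 1.21e-11)
```

Reading these numbers: the pipeline re-derives each gene's pausing group
from raw tags with ≥96% agreement to the planted truth; LPS stimulation
visibly shifts the pausing-index distribution of induced genes down
(pause-release), and the AP-1 consensus is recovered in the promoters where
the generator planted it. Small summary tables land in `results/`, bulky
intermediates in `scratch/`.

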
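# Methods

## The quantification model

The pipeline treats a sequencing library as a bag of aligned 1-read tags and
derives everything from interval counting. ChIP tags are extended from their
5′ anchor in the read's 3′ direction to the expected 150-bp fragment length
(the standard fragment model; a `three_prime` anchor mode exists for the
literal alternative reading), clipped at position 0 and, when chromosome
lengths are known, at chromosome ends. PRO-seq reads are reduced to the
single 5′ base, which marks the 3′ end of the nascent RNA and hence the
polymerase position; because the sequenced read is complementary to the
run-on product, transcription-active signal for a gene is counted from tags
on the **antisense** strand only.

Gene coordinates are 0-based half-open everywhere; GTF input is shifted on
read. Transcripts are reduced to one gene per symbol (longest variant, ties
broken by smallest transcript id), mitochondrial (`chrM`/`chrMT`) and
`random`/`chrUn` contigs are dropped, and genes shorter than 1 kb are
removed — short genes leave too little body for a stable density ratio. The
TSS of a minus-strand gene is its span end; "downstream" always means the
direction of transcription. Each gene contributes a TSS window (TSS ±
`tss_flank`) and a body (window edge to the TTS) that tile
[TSS − flank, TTS] without gap or overlap.

The pausing index is the TSS/body ratio of per-kb tag densities. A gene with
an empty body but promoter signal has PI = +∞ and is treated as maximally
paused (group 1 when TSS-active); for ECDF/KS comparisons infinite PIs are
capped at the finite maximum of their vector rather than dropped, so
zero-body genes still contribute mass at the paused extreme. A gene with no
signal at all has undefined PI and falls in group 3.

## Tunable parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `tss_flank` | 250 | bp | promoter-proximal pause sits 20–60 bp downstream of the TSS; ±250 bp covers it with positioning noise |
| `fragment_length` | 150 | bp | sonicated ChIP fragment size |
| `window_size` | 500 | bp | enrichment search window; step is window/2 |
| `fdr` | 0.001 | — | nominal FDR of the integer count threshold |
| `pi_high`, `pi_moderate` | 3.0, 1.5 | — | group 1/2 boundaries (group 1 inclusive at 3, group 2 half-open [1.5, 3)) |
| `fc_1h`, `fc_up`, `fc_down` | 1.5, 1.4, 0.6 | — | (FPKM+1) fold-change gates; all inclusive |
| `q_cut`, `p_cut` | 0.05 | — | q gates the 1 h class, raw p the 0.5 h and KO classes |
| `dismissal_fc`, dismissal p | 0.5, 0.05 | — | NELF dismissal gates (fc strictly below, raw p) |
| promoter window | −1000..+100 | bp | motif-scan window around the TSS |
| `score_threshold` | 0.8 | fraction | PWM hit = log-odds ≥ 0.8 × maximal score |

## Numerical and procedural choices

**Background rate for window counting.** A fragment of width w overlaps a
w′-bp window whenever its start falls in a (w′ + w − 1)-bp corridor, so the
uniform-background Poisson rate is N·(w′ + w̄ − 1)/G with w̄ the mean
processed-tag width. For 1-bp reduced PRO-seq tags this reduces to the
textbook N·w′/G. Using the footprint-aware rate keeps the estimated FDR
honest for 150-bp fragments; with the plain rate, planted-site peak calling
admits boundary false positives.

**FDR threshold.** The threshold is the smallest integer c with
`n_windows · P(X ≥ c) / max(1, #observed ≥ c) < fdr`, scanned up to the
observed maximum; pure-background data typically has no such c and raises a
"no significant enrichment" error, which callers treat as zero calls. TSS
activity uses a strictly-greater comparison against the threshold
(count > c means enriched at the stated FDR, matching the way the
data-derived cutoffs are quoted); window significance in peak calling uses
count ≥ c, i.e. the threshold count itself is already significant. At
fdr ≥ 1 every nonzero window is significant by construction.

**Peaks.** Overlapping significant windows are merged; the peak score is the
per-10M count in the merged span and the summit the leftmost base of maximal
pileup. Peak-to-genome annotation is by summit membership with precedence
TSS > gene body > intergenic. In differential mode the per-10M target count
must exceed a fold multiple of the per-10M background count; the generic
default is 4×, but `dismissal_by_peaks` uses 1/`dismissal_fc` (= 2 at
defaults) so that the peak route targets the same effect size as the
count-based fc < 0.5 definition — with a 4× cut the two methods test
different hypotheses and cannot agree on moderate dismissal factors.

**Dismissal test.** With one library per condition no dispersion is
estimable, so the count-based method uses the exact binomial conditional
test (the zero-dispersion limit of a negative-binomial exact test): given
the combined tag count of a gene at 0 h and 0.5 h, the 0.5 h share is
binomial with success probability set by the library depths. P-values are
gated raw, matching the stated p < 0.05 rule; a BH-adjusted column is
emitted alongside. Note that a true dismissal factor exactly at the fc
boundary is called ~50% of the time by construction; detection is sharp for
factors clearly below the cutoff (≈95% sensitivity at factor 0.3 with
baseline counts ≥ 50).

**Rank/ECDF statistics.** Mann–Whitney U uses exact enumeration (classic
f(m,n,u) recurrence) when both groups are ≤ 20 without ties, otherwise the
tie-corrected normal approximation with continuity correction. The
two-sample KS test computes the ECDF sup-distance and evaluates the
one-sample KS null at the effective size nm/(n+m). Both match the scipy
reference implementations to 1e-12, which the tests assert.

**Expression machinery.** Condition FPKM averages replicate counts first and
then normalises (using the mean replicate library size); per-replicate FPKM
is kept for testing. Welch t on log2(FPKM+1) with BH adjustment substitutes
for isoform-aware differential tools, which are out of scope. With three
replicates the t statistic has ~4 degrees of freedom, so at NB dispersion
0.05 a 3-fold change yields p-values with median ≈ 0.008 — comfortably
under the raw 0.05 gate (≈95% power) but straddling the BH threshold of a
300-gene universe (≈0.01). The q-gated 1 h class is therefore intrinsically
conservative in this design, recovering roughly half to three quarters of
true positives at essentially perfect specificity; the raw-p classes and
the superinduced conjunction recover ≥90%/≥85%. Only more replicates or
lower dispersion would move this.

**Degenerate inputs.** Zero-variance replicate groups get p = 1 when the
group means agree and p = 0 when they differ; a single replicate per side
yields p = NA with fold-change-only classification and a warning. A zero
background motif hit rate with target hits floors the binomial p at the
smallest positive float with a warning.

## What the generator emulates — and what it does not

`synthetic.GeneratorConfig` defines the study conditions: 300 genes on a
10-Mb chromosome; pausing groups at fractions 0.50/0.26/0.24 with true PI
8/2/0.8; Pol II body density 25 tags/kb against a uniform 0.004 tags/bp
background (λ = 2 per 500-bp window); NELF co-occupancy (group-skewed
32%/15%/8%) at 60 expected TSS tags, half of NELF⁺ genes dismissed to 0.5×
at 0.5 h and restored at 1 h; PU.1 occupancy enriched in group 1; PRO-seq
reads antisense with pause mass at TSS+20..60; RNA-seq counts
negative-binomial (dispersion 0.05, three replicates) around planted fold
changes (LPS 3×/0.3×, knockout 3× symmetric); promoters of uniform base
composition with AP-1 (`TGACTCA`) planted in NELF⁻ superinduced targets and
an ETS consensus in PU.1⁺ group-1 promoters. TSS tag mass is placed around
the pause site (mean +50 bp, sd 80 bp, truncated to the window) and body
mass uniformly over the body proper, so the realised density ratio tracks
the true PI by construction. RNA-seq library size is a fixed nominal 10⁶
per sample: the simulated genes stand in for a small slice of a real
transcriptome, whose total depth their responses would not move; summing
the slice itself would leak composition bias into the planted fold changes.
Base expression is drawn from 2^8.5..2^12 counts so that the dispersion
floor, not Poisson counting noise, dominates replicate variance.

Not modelled: sequencing error, fragment-length variation, mappability and
blacklist structure, GC bias, replicate-level ChIP variability, isoform
structure (genes are span-level intervals), and genuine genomic sequence
composition (promoters are uniform-random, so PWM false-hit rates are lower
than on real promoters). Passing recovery tests therefore demonstrates the
correctness and calibration of the counting and testing machinery under the
stated statistical model, not robustness to these real-data artefacts.

## Problem sizes

The shipped analyses and tests run at the generator defaults (300 genes,
~10⁵ tags per library) with multi-seed loops of 3–20 replicates for
calibration and detection-rate estimates; null calibration uses 2×10⁵
windows per seed. These sizes give Monte-Carlo errors comfortably inside
the asserted margins while keeping any single run in seconds.

## Known limitations

- The peak caller is a single-rate Poisson-background model; no local
  lambda, input-chromatin control, or broad-domain mode.
- Exact bit-compatibility with established tools covering the same ground
  (HOMER's peak caller, DiffBind/edgeR, Cuffdiff) is not promised anywhere;
  the implemented contracts are the documented statistical definitions.
- Per-gene "AP-1 target" status is defined as ≥1 PWM hit in the promoter at
  the score threshold (with the set-level binomial p reported alongside);
  tools that rank against curated promoter-set backgrounds can differ on
  borderline promoters.
- The `random`-chromosome filter is substring-based (`random`, `chrUn`,
  exact `chrM`/`chrMT`) and may need extending for non-UCSC naming schemes.
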
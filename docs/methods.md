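# Methods

## Signal model

NOMe-seq superimposes two methylation signals on one bisulfite library. The
M.CviPI enzyme methylates GpC cytosines in accessible chromatin before
conversion, so after sequencing:

* a **GCH** cytosine (GCA/GCT/GCC, read 5'→3' on the strand carrying the C)
  reports *accessibility*: its methylation level estimates
  P(site accessible) × enzyme efficiency;
* a **WCG** cytosine (ACG/TCG) reports the *endogenous CpG methylome*;
* **GCG** is ambiguous (either signal could have methylated it) and **CCG**
  absorbs slight enzyme off-target activity; both are excluded from every
  statistic, at classification time, so no downstream stage can see them.

Contexts are strand-asymmetric, so sites are classified per strand and never
pooled into dyads; a minus-strand cytosine is reported at the plus-strand
coordinate of its complementary G. Any N flank makes a site unclassifiable
(dropped). Coordinates are 0-based half-open throughout; 1-based conversion
happens only in text-format writers/readers.

All regional summaries are **count-pooled**: methylated and unmethylated
read counts of qualifying sites are summed and the level is the pooled
proportion. This matches the windowed test below, makes summaries additive
over disjoint regions, and weights deep sites more than shallow ones. Sites
below the depth filter (default 3 reads, configurable everywhere) are
ignored; a region with no qualifying site has an *undefined* level (never
0). Duplicate call rows for one site are summed with a warning.

## Spike-in QC

An unmethylated λ phage spike-in travels through enzyme treatment and
conversion with the sample. Pooled GCH methylation on λ estimates the
in vitro enzyme efficiency (everything λ is accessible naked DNA); pooled
methylation at non-GCH λ cytosines (WCG + OTHER — λ has no endogenous
methylation, and using both classes maximises observations without bias)
estimates conversion failure. Samples are retained when efficiency ≥ 0.90
**and** conversion > 0.98; the boundaries are deliberate — an efficiency of
exactly 0.90 passes, a conversion rate of exactly 0.98 fails.

## Segmentation

The genome is tiled with sliding windows — 100 bp at 20 bp steps for NDRs,
40 bp at 20 bp steps for nucleosomes. Per window, GCH counts at depth ≥ 3
are pooled and compared against the genome-wide pooled GCH totals (the
background) in a 2×2 χ² test with 1 df and no continuity correction. The
statistic is N(ad−bc)²/(r₁r₂c₁c₂) with p from the χ² survival function,
floored at 1e-300 to keep −log10 finite; p = 1 when any marginal is zero or
the window proportion equals the background. A window with no qualifying
site is *undetected*, never significant. The background uses the full
genome totals including the tested window (the window is a vanishing
fraction of the genome; the resulting bias is negligible) and excludes no
regions. No multiple-testing correction is applied: the score cutoffs are
raw −log10 p thresholds (5 for NDRs, 3 for nucleosomes).

Direction: an NDR is a run of windows *enriched* for methylated GCH reads
(open chromatin = enzyme-methylated), a positioned nucleosome a run
*depleted* of them. Pipelines that use the opposite wording can set
`invert_directions`, which swaps the two call sets exactly.

Significant same-direction windows are merged when they overlap or abut
(gap tolerance configurable, default 0); a merged segment keeps the maximum
window score and must span ≥ 140 bp (NDR) or ≥ 60 bp (nucleosome). NDR
centers are classed against the nearest TSS: proximal iff distance
< 2,000 bp, with the tie at exactly 2 kb assigned distal ("at least 2 kb
away").

## Profiles, strata and correlations

Metaprofiles pool counts into fixed-width bins (default 20 bp) over
[−flank, +flank) around anchors, flipping minus-strand anchors so positive
offsets point downstream; empty bins are missing, not zero. Genes are
stratified by RPKM with boundary-literal cutoffs: high > 10, intermediate
(1, 10], low (0.1, 1], silenced ≤ 0.1. The promoter window is TSS ± 1 kb —
the source analyses never state their window, so this symmetric default
(matching the 2 kb proximal scale) is this package's choice and is
configurable. r1/r2 are Spearman correlations (mid-ranked ties, asymptotic
p) between expression and promoter GCH/WCG levels, dropping genes with
undefined levels pairwise; a sliding rank-window mean (window 100 genes,
step 1) is available for plotting parity.

## Specific NDRs and sample structure

Across samples, a proximal NDR is cell-type specific when its accessibility
tracks its nearest gene's expression: Spearman ρ > 0.6 with p < 0.1
(uncorrected) over ≥ 5 paired samples. The source procedure names three
pairwise correlations but one threshold; the gate here is the
accessibility–expression correlation (the pair the downstream heatmaps
display) and the methylation–expression correlation is reported as an
annotation only. Assignment is argmax of group-mean accessibility — no
assignment rule is stated in the source, and argmax is the minimal one.
The sample distance matrix is 1 − ρ (Spearman, pairwise-complete, ≥ 3
shared rows per pair); clustering/PCA/MDS of it is left to standard tools.

## Elements and repeats

Element classes pool levels over all their intervals; relative enrichment
is defined here as log2(class GCH level / genome GCH level) — the source
figure never defines its statistic, so this definition is the package's
own. Overlapping annotations count in every class (no precedence).
Promoter CpG classes follow the Weber-style convention on TSS ± 500 bp:
o/e = (#CpG × length)/(#C × #G); HCP iff o/e ≥ 0.75 and GC ≥ 0.55, LCP iff
o/e < 0.48, ICP otherwise; thresholds configurable.

## Synthetic-data generator

The generator emulates the measured regimes of the germline study design:

| parameter | default | meaning |
|---|---|---|
| `efficiency` | 0.93 | M.CviPI in vitro efficiency (λ-estimated ≈ 93%) |
| `conversion_failure` | 0.013 | bisulfite non-conversion (rate ≈ 98.7%) |
| `wcg_levels` | fgc 0.067, soma 0.647, heart 0.729, epiblast 0.777 | endogenous WCG regimes per cell type |
| `ndr_open_prob` / `baseline_open_prob` | 0.85 / 0.15 | openness inside planted NDRs vs elsewhere |
| `nucleosome_len` / `linker_len` / `protection` | 147 / 53 / 0.9 | phased array downstream of each TSS |
| `mean_depth` / `depth_dispersion` | 20 / 5 | negative-binomial coverage (no coverage model is stated in the source; NB is the standard overdispersed choice) |
| `lambda_length` / `lambda_spike_fraction` | 48,502 / 0.05 | λ spike-in; the source states the fraction inconsistently (0.1% vs 5%), so it is an explicit recorded parameter |
| `expr_*` coefficients | a −1.5, b +4, c −2, σ 0.3 | log10 RPKM = a + b·open + c·WCG + noise |

Per GCH site, P(read methylated) = open·efficiency, per WCG site the
compartment's endogenous level, per OTHER site 0; every probability is then
conversion-adjusted to p + (1−p)·conversion_failure. Counts are binomial at
NB-drawn depth. λ is its own reserved chromosome with GCH probability =
efficiency and non-GCH = conversion failure. Genes sit on fixed slots with
random strand; promoter NDRs are centered on TSSs; repeats/distal NDRs are
placed in the free space between gene footprints. All randomness flows from
one seed through fixed `SeedSequence` spawn keys, so identical configs give
byte-identical outputs.

Preset study conditions (used by tests and `scripts/acceptance.py`):

* **NDR recovery** — 1 Mb, 200 NDRs of 300 bp, open 0.85 in / 0.15 out,
  depth 20×, no arrays (everything outside the NDRs is at baseline).
* **Nucleosome recovery** — 147/53 arrays at protection 0.9. The baseline
  openness here is 0.5 (unstated in the source conditions): the χ² contrast
  needs protected stretches to be depleted *against the genome background*,
  which a mostly closed genome cannot provide. Spacing is measured between
  recovered segments matched (≤ 73 bp) to planted nucleosomes.
* **Expression coupling** — 5 Mb, 2,000 genes with per-gene promoter
  openness U(0.05, 0.9) and promoter WCG U(0.05, 0.95), noise σ 0.3.
* **Specific NDRs** — 9 samples, 3 groups × 3 replicates, 60 genes whose
  promoter NDRs are open (0.85) only in their group's samples, expression
  coupled per sample.
* **Repeats** — painted compartments: SVA open (0.70); L1 closed (0.08) and
  methylated (0.35) vs L2 (0.30 / 0.12); Alu vs MIR analogous; LTR closed.
  These openness/methylation values are this package's rendering of the
  qualitative orderings (young elements less open, more residual
  methylation); the source reports no per-family levels.

Problem sizes (1 Mb genomes, 20× depth, 2,000 genes) are chosen so every
stage exercises its full code path while a complete run of the suite plus
the acceptance script finishes in well under a minute each on one core.

### What the simulation does and does not show

The generator draws independent binomial counts per site from piecewise-
constant openness/methylation maps. Passing recovery tests therefore shows
the statistics, windowing, merging and filtering are implemented correctly
and have the expected operating characteristics under the stated regimes.
It does **not** establish performance on real libraries, which additionally
carry mapping bias, PCR duplicates, fragment-length effects, sequence-
composition-dependent coverage, fuzzy nucleosome positioning and
between-molecule heterogeneity — none of which are modelled. Read-level
co-methylation patterns are likewise out of scope: the pipeline consumes
site-level counts only.

## Numerical and degenerate-input choices

* χ² p-values floored at 1e-300; p = 1 for zero marginals or equal
  proportions; zero-depth windows skipped.
* Undefined levels propagate as None/NaN and are dropped pairwise in
  correlations; constant vectors make a correlation undefined (the NDR is
  skipped, not retained).
* Nearest-TSS ties between two equidistant TSSs resolve to the downstream
  one in sorted order (searchsorted convention); segments on chromosomes
  without any TSS are distal with no gene.
* Promoter windows are clipped at chromosome bounds.
* Empty inputs: an empty call table is a valid sample with zero sites; an
  empty genome, empty TSS set, or a background without qualifying sites
  raise errors.

## Known limitations

* No between-sample differential NDR test; the specific-NDR filter is the
  only cross-sample statistic.
* No multiple-testing control anywhere, by design (raw score cutoffs).
* Segmentation assumes the background is a single genome-wide proportion;
  copy-number variation or strong regional coverage bias would distort it.
* The GTF reader covers the exon/gene-attribute subset the pipeline needs,
  not the full specification.
* Alignment, duplicate removal, methylation extraction from reads, motif
  enrichment, homology lift-over, and RNA quantification are upstream or
  external concerns and are out of scope.
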
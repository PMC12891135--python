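# Methods

## Fragment model and conventions

A fragment is a double-stranded template mapped to the reference:
`(chrom, start, end, strand)` with 0-based half-open coordinates and strand
defined by the template's 5′-most read (read 1). All BED-like input is read
natively; SAM/BAM pairs are converted at the boundary (both mates MAPQ ≥ 30
by default, template length within 30–700 bp, duplicates collapsed). These
thresholds are configurable and logged; typical cfDNA pipelines filter to
"high-quality" reads without a universal standard.

## Motif features

Every fragment has two 5′ termini — the plus-strand 5′ end at `start` and
the minus-strand 5′ end at `end` — and both contribute one motif. Motifs
are read from the **reference** at the aligned coordinate (not from read
bases), which reflects the cleaved genomic context and is immune to
sequencing error. The minus-strand end contributes the reverse complement of
the reference k-mer ending at `end`. Both-ends counting doubles the number
of observations per fragment and makes the profile invariant to
reverse-complementing the genome. Windows containing `N` or overhanging a
chromosome edge are skipped and counted in the log, not errors.

Breakpoint motifs take `flank` bp (default 3) on each side of each 5′
cleavage point, oriented on the end's strand; background frequencies count
every window of both genome strands. All profiles carry all 4^k motifs and
sum to 1 within 1e-9.

The **N-index** is the normalised Shannon entropy H(p)/log(4^k) of the
end-motif profile (natural log, 0·log 0 := 0). No closed formula is
standard for "end-motif diversity"; normalised entropy is the common motif
diversity score, is 1 exactly at uniformity and 0 for a point mass, and is
invariant to motif relabelling. Raw-normalised breakpoint profiles are the
default model input; the observed/background enrichment vector is exposed
separately (`motif_enrichment`) rather than silently substituted, since
either representation is defensible.

## Size features

The length histogram uses a fixed 30–400 bp support so the **E-index**
(normalised entropy of the histogram) is comparable across samples; lengths
outside the support are tallied separately. Genome bins are fixed-width
tilings (5 Mb for coarse profiles, 100 kb for S/L ratios); a trailing
partial bin shorter than half the bin width is dropped. A bin fails when GC
< 0.3, mappability < 0.9, or it overlaps the blacklist at all — the strict
any-overlap reading keeps the rule simple and conservative. For the
synthetic genome, mappability is 1.0 everywhere except user-declared masked
intervals, so the filter logic is testable without a real mappability track.

Fragments are assigned to the bin containing their midpoint (unambiguous;
a fragment can straddle at most one bin boundary). Short fragments are
100–150 bp, long 151–220 bp, and the per-bin ratio S/L is left missing when
L = 0 (mean-imputed at the matrix stage — avoids infinities). Ratios are
z-scaled across bins within each sample before entering the feature matrix,
making the feature depth-invariant; raw counts are retained on the profile
object. Conservation holds exactly: pass-bin S+L counts plus out-of-class
and failed-bin fragments equal the total.

## Repeat features

Six categories are analysed: LINE, SINE, LTR, Satellite, transposable
elements (DNA, Retroposon, Rolling-Circle families) and RNA elements
(tRNA, srpRNA, snRNA, scRNA, rRNA). Unknown families map to `Unclassified`
and are excluded (logged). Membership is midpoint containment — not
any-overlap — so a fragment never counts in two adjacent elements; nested
annotations resolve to the smallest containing interval (most specific
label). Category frequencies are defined as the sum of their subfamily
frequencies, so the hierarchy is exactly additive by construction.

## Coverage features

Nucleosome profiling follows the weighted-midpoint convention: fragments
with length in 100–220 bp and midpoint within ±window of a site centre add
weight 1 (a `weights` hook accepts externally bias-corrected weights for
real data; the synthetic generator has no GC bias, so unit weights are the
default) to the 15 bp bin containing the midpoint. Bin edges lie on
multiples of the bin width in site-relative coordinates, so the bin count is
odd with the centre bin's left edge on the site centre. The default window
is 4995 bp (333 bins per side) — the nearest multiple of 15 to ~5 kb, since
the window must tile evenly into bins. Profiles are averaged across sites
(minus-strand sites flip the offset axis), smoothed with a Savitzky–Golay
filter (165 bp window, order 3 — the convention of nucleosome-profiling
tools; the filter family is standard, its parameters are not reported
consistently) and normalised to mean 1.

Summaries: central coverage = mean of bins within ±30 bp; mean coverage =
mean within ±1 kb; periodicity amplitude = 2|S|/N where S is the discrete
Fourier sum of the mean-subtracted profile evaluated **exactly** at the
190 bp nucleosome period (Goertzel-style rather than the nearest FFT grid
frequency — the window holds a non-integer number of 190 bp cycles, and
snapping to the FFT grid loses up to ~35% of a pure tone's amplitude to
scalloping, whereas the exact-frequency sum recovers a cosine's amplitude
to well under 1%). Mean subtraction makes a flat profile's amplitude
exactly 0. The 190 bp period is configurable.

## Classifier

"GLM" is realised as logistic regression with an L2 penalty — the standard
choice for n ≪ p fragmentomic matrices. Within every training split:
column-mean imputation, z-standardisation, and penalty strength chosen by
inner stratified CV (default 5-fold, capped by class size) over a small grid
(C ∈ {0.01, 0.1, 1}) on held-out log-loss. The outer loop is stratified
k-fold (default 10) repeated independently with re-drawn fold assignments
(default 200 repeats; tests and the bundled configs use 2–5); a sample's
out-of-fold score averages its held-out probabilities over repeats —
the resampled-fold repetition is the bootstrap element of the training
procedure. A locked model is refit on all training data with the same
recipe and is the only thing applied to validation samples; operating
thresholds are chosen on training out-of-fold scores (smallest threshold
whose specificity meets the target, which maximises sensitivity among
qualifying cutoffs under the score ≥ threshold rule) and applied unchanged.

Sample IDs and feature names are canonically sorted before training, and
all random streams derive from one master seed via `SeedSequence`, so
results are bit-reproducible and invariant to input row/column order.
In-sample scores of the locked model are reported separately from
out-of-fold scores; they are not interchangeable and the model file labels
both.

ROC/AUC use the rank-based curve with midrank tie handling (equal to the
concordant-pair probability with ties counted ½). Subgroup evaluation
compares the full benign set against the malignant subset of each stage
band (early = I+II, late = III+IV), restricts both classes for sex and
age (<65 / ≥65) subgroups, reports empty subgroups as absent, and contrasts
malignant-only scores across stage bands with a rank-sum test.

## Differential analysis

Two-sided Wilcoxon rank-sum tests per feature (sidedness is not prescribed
by convention; two-sided is the conservative default): exact distribution
for tie-free comparisons with combined n ≤ 20, otherwise the normal
approximation with tie and continuity corrections. Constant features get
p = 1 and a flag rather than an error. Benjamini–Hochberg q-values are
added across the tested family (raw p is also reported). `top_k` orders by
ascending p, breaking ties by |median difference| descending then name, and
exports a per-feature z-scored submatrix for heatmaps; a family whitelist
restricts the pool when desired.

## Synthetic cohort generator

The generator encodes the qualitative benign/malignant contrasts as
explicit, user-settable effect sizes, because parameter-recovery testing
needs known ground truth. Defaults (the package's study conditions):

- genome: i.i.d. bases, GC 0.41 (human-like), 2 × 500 kb chromosomes
  (tests scale down to 200–400 kb);
- annotation: non-overlapping elements, mean length 300 bp (Alu-like),
  densities LINE 0.15, SINE 0.10, LTR 0.08, Satellite 0.02, transposons
  0.03, RNA elements 0.005 — genome-like ordering at reduced totals so
  placement cannot thrash;
- benign class: length mixture (166±9 bp, w=0.80; 145±12, 0.12; 310±18,
  0.08) mimicking mono-/di-nucleosomal peaks; neutral cleavage; SINE
  sampling rate ×1.3 (the elevated-Alu benign signature); no site dips;
- malignant class: ×2 cleavage propensity at five 4-mers (CCCA, CCAA,
  CCAT, CCCT, CTCC), all length means shifted 10 bp shorter, LTR rate
  ×1.2, a 1.25× CNV-like gain over half of the last chromosome, and a 0.6
  midpoint depletion at target sites (Gaussian-shaped, SD 300 bp).

Fragments are drawn by sampling a strand and a 5′ cut position with
probability proportional to the cleavage bias of the cut 4-mer (reverse
complemented on the minus strand), then a length from the class mixture,
then accepting with probability proportional to the CNV multiplier, repeat
rate, and dip factor at the fragment midpoint. Bias applies at the 5′ cut
only — the other end is implied by the length — giving one well-defined
generative mechanism; observed end-motif enrichment is therefore roughly
the average of the biased and unbiased end (e.g. ×2 bias appears as ~×1.5
in the profile). Stage effects are modelled by scaling the malignant
profile's deviation from benign (multiplicative parameters geometrically,
length means arithmetically, dip depth linearly) per tumour stage.

What the generator does **not** emulate: sequencing error, base qualities,
duplicate reads, GC amplification bias, realistic chromatin structure, or
correlated regional fragmentation. Passing tests therefore demonstrate that
the extractors and model recover *injected* effects of the stated sizes
from idealised fragments — they do not certify performance on real plasma
WGS, whose effect sizes and confounders (batch, depth, GC) are outside this
model.

## Problem sizes and numerical choices

Tests and the acceptance script run cohorts of 30+30 samples at 3000–8000
fragments/sample on 0.3–0.5 Mb toy genomes with 5 CV repeats — sizes chosen
so the full suite completes in minutes while keeping per-bin and per-motif
counts large enough for the stated statistical tolerances. Degenerate
inputs are defined rather than crashed on: empty histograms and single-class
training raise `ValueError`; bins with zero long fragments give missing
ratios; constant differential features are flagged with p = 1; empty
subgroups are absent from reports. TSV round trips write 12 significant
digits; pipeline outputs are byte-identical across reruns of the same
config and seed.

## Known limitations

- The simulator's i.i.d. genome has no isochore/GC structure, so GC-bin
  filtering is exercised only via thresholds, not realistic GC gradients.
- CNV acceptance reweighting is per-fragment and global-depth-normalised;
  it changes regional composition, not total depth, so depth-sensitive
  statistics cannot be studied.
- The breakpoint-motif and 6-mer end-motif families (4096 columns each) are
  off by default in the bundled configs to keep the penalised fit
  well-conditioned at toy sample sizes; they are fully supported.
- Exact Wilcoxon p-values are limited to tie-free combined n ≤ 20;
  beyond that the corrected normal approximation is used.
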
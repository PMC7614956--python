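# Methods

This note records the models, conventions and design choices behind
`dropcrispr`, in the spirit of a statistical methods appendix.

## Coordinates and annotations

All in-memory coordinates are 0-based, half-open; feature tables on disk use
the BED dialect; only human-readable reports print 1-based positions. A
feature's TSS is derived from its span and strand (span start on `+`, last
base of the span on `-`), and all design windows are expressed in the
feature's transcriptional orientation: negative offsets are upstream of the
TSS.

## Guide design

Protospacers are 20-mers immediately 5′ of an NGG PAM, scanned on both
genomic strands (a bottom-strand site appears as CCN followed by the
reverse-complement protospacer on the top strand). The window/bin membership
anchor is the **cut site**, 3 bp 5′ of the PAM (between protospacer
positions 17 and 18) — the standard blunt-cut coordinate, chosen because it
is strand-symmetric; the window itself is the closed interval [−400, +100]
around the TSS.

Selection: when a feature has fewer than six candidates anywhere in the
window, all are kept. Otherwise the region [−300, 0) is tiled into six
half-open 50-bp bins and the highest-scoring guide per bin is kept;
candidates outside the binned region are ineligible in bin mode. Score ties
break to the smaller |TSS offset| and then the lexicographically smaller
protospacer so a library is a pure function of its inputs.

The default scorer, `clamp(1 − 2·|GC − 0.5| − 0.25·H, 0, 1)` with H = 1 for
any homopolymer run of ≥ 5 nt, is a deliberately simple, deterministic
stand-in for trained on-target models; any callable mapping a protospacer to
[0, 1] can be injected in its place, and the selection machinery is
agnostic to the scorer.

## Off-target filtering

The metric is full-length Hamming distance over the strand-normalized
20-mer: no indels, PAM excluded, no seed-region weighting. A guide is
removed when any *other* genomic PAM-adjacent site — a second occurrence of
its own sequence counts — or any other library guide lies at fewer than
three mismatches; both members of a conflicting pair are removed. Distance
0 uses an exact hash; distances ≤ 2 use a pigeonhole index over three
disjoint protospacer segments (two mismatches cannot hit all three
segments), so genome-scale filtering avoids the quadratic scan; the
brute-force scan is retained as the test oracle and as the fallback for
exact minima ≥ 3.

## Oligo cassettes and digest model

The 190-bp cassette is flank(11) · left site(11) · 4 × guide(20) separated
by 3 × spacer(22) · right site(11) · flank(11); the internal spacer carries
the BspQI heptamer GCTCTTC on both strands so digestion excises the
recognition sites along with the spacers. The digest uses a
single-breakpoint model: each heptamer occurrence cuts one nucleotide 3′ of
itself on its own strand, giving one double-strand breakpoint per site
(GCTCTTCN^). BspQI actually leaves 3-nt 5′ overhangs; modeling the two
staggered nicks would change fragment *ends* but not which guides are
released, which is the testable claim — each guide comes out in a 26-nt
AGG·guide·GTT fragment. Guides containing the recognition sequence (either
strand) are rejected, as are guides that would *create* a site across a
junction with the scaffold — the printed-layout junctions can only complete
a site through their terminal G, so a single-slot check suffices for all
slots. Incomplete final oligos are completed with a fixed filler 20-mer,
flagged in the synthesis manifest and excluded from libraries.

## Quantification

Demultiplexing is exact prefix matching over a prefix-free 4–6 nt barcode
set; counting extracts the 20-mer after the constant vector flank and looks
it up exactly. Exact matching is near-lossless here because the off-target
filter guarantees all library guides are mutually ≥ 3 mismatches apart; an
optional 1-mismatch mode (unique one-off neighborhoods) covers sequencing
errors at the cost of a 60× larger lookup table. Reads are conserved:
assigned + no_guide + no_barcode equals input reads.

## Enrichment model

Let y_gj be the count of guide g in sample j, N_j the sample's effective
library size (column sum × RLE factor), and x_j ∈ {high, low} its fraction.
The model is NB with log link and mean μ_gj = exp(β_g0 + β_g1·[x_j=high] +
log N_j), variance μ + φμ². Because the two-group design is
group-saturated, the full-model MLE decomposes into two independent
intercept fits, solved by a vectorized Newton iteration on the NB score
equation across all guides simultaneously; the reduced model drops the
group term. The LR statistic 2(ℓ_full − ℓ_reduced) is referred to χ²₁.

*Normalization.* Classical median-of-ratios: per sample, the median over
all-positive guides of the ratio to the guide's geometric mean, rescaled to
geometric mean 1. Guides failing the low-count filter (default CPM > 1 in
at least half the samples — configurable, since sequencing depth dictates
it) should be removed first.

*Dispersion.* The common φ maximizes the summed Cox–Reid adjusted profile
likelihood, APL(φ) = Σ_g [ℓ_g(β̂_g(φ), φ) − ½ log det(XᵀW_gX)], on a
25-point log-spaced grid over [10⁻⁴, 4] refined by bounded minimization to
an absolute tolerance of 10⁻⁴. The CR determinant factorizes over the two
groups for this design. Optional tagwise dispersions maximize a weighted
likelihood shrinking each guide toward the common curve with prior weight
`prior_df` (default 10); the common value is used for testing by default,
appropriate when thousands of guides share one library prep.

*Reporting.* The reported log₂ fold change is computed from pooled
per-fraction rates with a prior count of 0.125 added to each pooled count,
which keeps zero-count guides finite; the LRT itself uses raw counts.
All-zero guides are not fitted (p = 1, log₂FC = 0). P-values are BH
step-up adjusted (delegated to `statsmodels`; the hand step-up is the test
oracle). Enrichment calls use strict inequalities — log₂FC > 3 **and**
FDR < 0.05; a gene's representative guide is its highest-fold-change guide
passing the relaxed log₂FC > 3, FDR < 0.3 gate, so a high-effect,
middling-FDR guide can represent a gene it would not itself be called
enriched by.

*Cross-validation.* The GLM/LRT path is checked in the test suite against
(a) direct Nelder–Mead maximization of the NB likelihood and (b) edgeR's
`glmFit`/`glmLRT` at a shared fixed dispersion and offsets (agreement to
~10⁻³ on the LR statistic).

## Droplet arithmetic

Cell loading is Poisson with mean λ (cells per droplet): occupancy
probabilities are (e^{−λ}, λe^{−λ}, 1 − (1+λ)e^{−λ}) and a screen of D
droplets covers an L-guide library D·λ/L-fold. At the standard λ = 0.4,
67.0% of droplets are empty, 26.8% hold one cell and 6.2% more than one.

## Neighbor-orientation analysis

For an enriched guide targeting a non-coding RNA, features whose span
intersects the closed 1-kb window centred on the guide's cut site are
classified relative to the targeted strand: `antisense_overlapping`
(opposite strand, span covers the query), `divergent` (opposite strand,
transcribing away — bidirectional-promoter candidates), `convergent`
(opposite strand, transcribing toward the query), `sense_overlapping`,
`tandem_upstream` (query upstream of a same-strand feature) and
`tandem_downstream`. The `convergent` class is included so the
classification is total over every strand/position configuration, although
promoter-proximal queries rarely produce it. The window anchor (cut site
vs protospacer start) is the caller's choice; the cut site is the default
throughout.

## Synthetic data: what it does and does not emulate

`simulate_genome` plants one protospacer+NGG cassette per 50-bp promoter
bin (then second-pass sites) on a uniform-random background, so bin
selection, off-target screening and window arithmetic are exercised with
guaranteed material; it does not emulate nucleotide composition bias,
repeats, or overlapping genes, so off-target *rates* on real genomes are
not predicted by these tests. `simulate_screen_counts` draws NB counts
(gamma–Poisson, variance μ + φμ²) with lognormal per-guide abundances
(σ = 0.5, mimicking library skew), defaults of 200 mean reads per guide,
φ = 0.15, four replicates per fraction, and 5% of guides spiked at
log₂FC 4 applied symmetrically (+2 in high, −2 in low) so fraction library
sizes stay comparable. It does not model droplet co-encapsulation
crosstalk, growth competition, sorting impurity or PCR jackpotting;
passing calibration shows the inference machinery is correct under its own
model, not that real screens meet that model.

## Numerical choices and known limitations

- Newton intercept fits clamp β to ±40 (log scale) so all-zero groups stay
  finite; steps are clamped to ±5 and iterated to |Δ| < 10⁻¹⁰.
- The χ²₁ reference for the LRT is asymptotic. At 4 + 4 samples and depth
  ~200 the empirical type-I error at α = 0.05 is ≈ 0.05, but with many
  thousands of p-values a KS test can still detect the small
  finite-sample/discreteness deviation at some simulation seeds; this is a
  property of the chi-square approximation shared with standard NB GLM
  tooling, not of the implementation.
- Pipeline problem sizes (12-feature 20-kb demo genome; 2000–5000-guide
  calibration simulations) were chosen as the smallest sizes at which the
  design machinery saturates its bins and the calibration statistics are
  stable to the stated tolerances.
- Two-group designs only (high vs low fraction); replicates from multiple
  screen rounds are pooled as replicates. Batch terms, quasi-likelihood
  F-tests and alternative PAMs are out of scope.
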
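# Methods

`meiorec` links measures of meiotic 3D genome folding derived from binned
Hi-C contact maps to recombination activity at PRDM9 binding sites, DSB
hotspots (DMC1-SSDS peaks) and crossovers, and exercises the whole analysis
end-to-end on a synthetic genome with known ground truth.  This note
describes the models and procedures, the parameters that matter, the
numerical choices, and what the synthetic data can and cannot show.

## Genome tiling and track projection

All datasets are projected onto one fixed tiling of the genome into 5-kb
bins (`ceil(length / 5000)` bins per chromosome; the last bin may be
truncated).  Signal tracks (bedGraph) map to the per-bin **maximum** score;
feature sets (BED) map to the per-bin **covered fraction** after merging
overlapping features; a seven-state ChromHMM segmentation yields one
covered-fraction track per state.  Coordinates are 0-based half-open
throughout; an interval touching a bin boundary contributes to both
flanking bins.  Missing signal propagates as NaN and is never imputed as 0;
coverage of an absent feature is a true 0.

## Hi-C scores

Contacts are held as one symmetric balanced cis matrix per chromosome plus
a per-bin trans total; bins without coverage (or failing balancing) are
masked everywhere downstream.  An iterative-proportional balancing fallback
(50 iterations, tolerance 1e-5 on the variance of normalized marginals) is
available for raw counts; simulated matrices are used as generated.

* **cis/total ratio** — per-bin `cis / (cis + trans)` from raw contact
  sums, optionally pooled over a sliding window.  Low values mark spatially
  accessible chromatin.
* **Fine-grain compartment score** — whole-chromosome eigendecomposition
  fails on meiotic maps because contact signal decays steeply beyond
  ~10 Mb, so the leading eigenvector is computed within 10-Mb diagonal
  chunks: each chunk is observed/expected-normalized (each diagonal divided
  by its mean), converted to a Pearson correlation matrix, and reduced to
  its leading eigenvector, which is scaled to unit variance per chunk and
  sign-oriented so that its correlation with an activity reference (by
  default the summed coverage of the promoter/enhancer/gene-body ChromHMM
  states) is non-negative.  Two estimator details matter in practice and
  are this package's own choices: (1) the eigendecomposition runs on
  100-kb aggregated cells within each chunk — at 5-kb resolution the
  per-pair counts (≈0.07 expected contacts per pair at the default depth)
  are far too sparse for a stable eigenvector — and the coarse score is
  projected back onto the member bins; (2) chunks whose leading eigenvalue
  explains less than 10% of the correlation-matrix trace carry no
  checkerboard structure (observed in compartment-homogeneous regions,
  where the eigenvalue fraction drops to ~0.04 versus ≥0.2 for structured
  chunks) and are reported missing rather than filled with noise.  A short
  terminal chunk (< 2 Mb) is merged into its predecessor.
* **Insulation score** — for window *w* (default 100 kb), the mean contact
  in the `w × w` square spanning each bin's diagonal position, as
  `log2(value / chromosome mean)`; undefined within *w* of chromosome
  ends.  Minima mark domain boundaries.
* **FIRE score** — the FIRE statistic is reimplemented as a z-scored
  near-range contact frequency: total cis contact with partners at 15–200
  kb separation, divided by the number of *valid* partners in range (which
  removes chromosome-end and masked-neighbour bias), z-scored per
  chromosome.  This captures the documented meaning of the score
  (normalized local interaction frequency) without reproducing the
  original caller's regression internals; it is an approximation and
  labelled as such.
* **P(s) curves** — mean balanced contact per log-spaced separation bin
  (edge ratio 1.12), pooled genome-wide, optionally restricted to bin
  pairs that share a compartment label (compartments called on the ES map,
  mirroring the stage used for masking in the source analysis); distance
  bins supported by fewer than 100 pairs are missing, and the curve is
  normalized to 1 at its first populated bin.  A per-chromosome variant is
  available but the pooled curve is the default reporting domain.
* **Loop length** — the distance of the largest interior local maximum of
  `d log P / d log s` within 100 kb–10 Mb, after smoothing log P with a
  5-bin moving average; central differences on the log-spaced grid; ties
  resolve to the smaller distance; a curve with no interior local maximum
  (e.g. a pure power law) yields no estimate.

## Recombination maps and site-level statistics

* **Crossover score** — each crossover resolution interval distributes unit
  mass uniformly over the k bins it intersects (weight 1/k), giving
  prominence to sharply resolved crossovers while conserving total mass
  (sum of raw scores = number of crossovers).  The map is normalized by the
  median over *nonzero* bins — crossovers are sparse, so the all-bin median
  is 0 and unusable as a divisor.  A bp-length weight and an all-bin median
  are available behind flags as documented alternatives.
* **Sites** — the bin containing each peak's center (summit when the peak
  format carries one, else `floor((start+end)/2)`); duplicate bins
  collapse.  Fractional chromosomal position (bin start / chromosome
  length) is attached as a centromere-distance proxy, meaningful because
  mouse chromosomes are acrocentric.
* **Quartiles** — sites ranked descending by the chosen activity score
  (DMC1 for PRDM9 sites, crossover score for DSB sites), ties broken by
  genomic coordinate; top and bottom `floor(n/4)`.
* **Enrichment** — per variable and site group,
  `log2(group mean / genome-wide median)` (genome mean when the median is
  0, flagged); top-vs-bottom differences tested by two-sided Wilcoxon
  rank-sum — robust to the heavy-tailed ChIP-seq scores — with Bonferroni
  correction over variables (`p_adj = min(1, m·p)`) and a significance
  flag at `p_adj < 0.01`.

## Profiles and pileups

Sites are unoriented, so each per-site window is averaged with its own
reversal before aggregation (profiles are therefore exactly
mirror-symmetric; symmetrizing per site rather than after averaging leaves
the mean unchanged but makes the bootstrap CIs honest about per-site
variability).  Confidence intervals are percentile intervals from 1000
seeded bootstrap resamples over sites, implemented with multinomial row
weights (equivalent in distribution to index resampling at O(resamples ×
sites) memory).  Contact pileups divide each site-centered submatrix by the
chromosome's expected-by-distance profile before symmetrizing and
averaging, so a matrix equal to its own expected profile piles up to
exactly 1; the exact diagonal is undefined under O/E and is ignored, as are
masked cells.  Default flanks: ±50 kb for zoomed track profiles, ±500 kb
for broad profiles and matrices.

## PCA and forward-selected models

Chromatin variables at joint PRDM9–DSB sites (union of peak-center bins)
enter at two scales: the local value at the site bin and the mean over the
site ± 50 bins (101 bins ≈ 505 kb, the bin-symmetric realisation of a
"500-kb average"), ignoring missing bins and clipped at chromosome ends.
Columns are standardized (zero mean, unit SD); zero-variance columns are
dropped with a warning and rows with any missing feature are dropped and
counted.  PCA is computed by full SVD; each loading vector is oriented so
its largest-magnitude element is positive (a deterministic convention —
note that "PC1" may therefore come out aligned with either activity or
inactivity; interpretation should use the loadings, e.g. the sign of the
compartment-score loading).  Four components are retained by default.

Forward selection starts from an intercept-only OLS model and at each step
admits the candidate with the smallest entry p-value provided
`p < 0.001 / n` (n = total candidates, Bonferroni); it stops when no
candidate passes.  Adjustment covariates (binding score, chromosomal
position) *compete* in the selection rather than being forced in — the
source analysis reports position as "selected" in one model and not the
other, which is only possible if it was selectable.  Responses are used
unstandardized (t-statistics are scale-free; coefficients stay
interpretable).  Candidates whose addition makes the design matrix
ill-conditioned (condition number > 1e10) are skipped with a warning; ties
in p-value resolve to the lexicographically smaller name.  Three models are
fitted: DSB activity (DMC1 score) at PRDM9 sites, crossover likelihood at
DSB sites, and crossover likelihood at PRDM9 sites; naive baselines are
PRDM9-score-only, DMC1 + position, and PRDM9 + position respectively.

## The synthetic genome

The generator emulates the statistical structure the analysis relies on,
with every parameter fixed once in `SimConfig`:

| parameter | default | meaning |
|---|---|---|
| chrom_lengths | 3 × 60 Mb | genome size (desk-scale stand-in for 19 autosomes) |
| bin_size | 5 kb | tiling resolution |
| compartment_block_mean | 2 Mb | mean exponential A/B block length |
| ps_exponent | −1.0 | power-law contact decay |
| loop_size_A / loop_size_B | 0.7 / 2.1 Mb | loop shoulder scales (threefold apart) |
| shoulder_amp | 1.0 | multiplicative shoulder amplitude |
| compartment_strength | ES 1.0, zygonema 0.6, pachynema 0.75 | same-label contact boost per stage |
| cis_fraction_base ± delta | 0.80 ± 0.05 | expected cis/total (B above, A below) |
| read_depth | 5 × 10⁶ | expected cis contacts per chromosome |
| n_prdm9_peaks / n_crossovers | 3000 / 2000 | site and crossover counts |
| prdm9_frac_A | 0.57 | A-compartment share of PRDM9 peaks |
| dsb_bias_A / dsb_bias_genebody | 2.0 / 1.5 | DSB-score multipliers |
| gene_body_penalty | 0.2 | crossover weight in gene-body chromatin |

Compartment labels alternate in exponential-length blocks; a seven-state
segmentation draws exponential-length segments whose state frequencies
favour promoter/enhancer/gene-body states in A and unmarked chromatin in
B.  Expected cis contact between bins at separation s is
`s^α · (1 + shoulder(s; L)) · (1 + strength·[same label])`, with the
shoulder a log-normal bump (σ = 0.35 in log10 units) using the shared
compartment's loop size (geometric mean across labels).  The bump center is
placed at `L · 10^(σ + 0.075)` so that the maximum of `d log P/d log s` —
the quantity the loop-length estimator reads out — falls at the nominal
loop size L for the default amplitude; centering the bump at L itself would
put the derivative maximum near L/2.2 and misrepresent the injected value.
Counts are Poisson-sampled, factorised per (separation, label-combo) class
(class totals Poisson, positions uniform within class — exactly equivalent
to per-pair draws); per-bin trans totals are drawn conditionally on the
realised cis coverage so the expected cis/total matches the configured
fractions.  Stage compartment strengths keep meiotic checkerboards
attenuated relative to the interphase (ES) map while leaving the injected
labels recoverable at r ≥ 0.9, the recovery bar the downstream tests hold
the estimator to; zygonema can optionally receive a local cis/total dip at
PRDM9 bins (`prdm9_cis_dip`, default off — no quantitative magnitude is
established for that transient signal, so the generator does not assert
one).

DMC1 (DSB) peaks reuse the PRDM9 locations; scores multiply the PRDM9
score by the A-compartment and gene-body biases and log-normal noise.
Crossover sources are drawn without replacement at DSB peaks with weight
∝ DMC1 score × gene-body penalty × a linear ramp from 0.5 at the
chromosome start to 1.5 at the end (acrocentric pericentromeric
depletion), and are reported as log-uniform 5–200-kb resolution intervals
containing the source — emulating the resolution heterogeneity that
motivates inverse-length weighting.

**What the synthetic data does not show.**  Real meiotic maps carry TADs,
loop anchors, coverage biases, allele structure and peak-calling noise the
generator omits; DSB peaks are not a distinct (A-skewed) set from PRDM9
peaks, so the generator cannot reproduce the distinct PRDM9/DSB site counts
or the stronger A-skew of real DMC1 peaks; simulated feature structure is
lower-dimensional than real chromatin, so PCA concentrates more variance in
PC1 and the model R² values are not comparable to the source analysis'
real-data values.  Passing tests demonstrate that the estimators recover
known structure under the stated generative model, not that they would
behave identically on real data.

## Determinism and problem sizes

A single seed fans out into named substreams (one per stage), so reruns are
bitwise identical and any stage can be reproduced in isolation; bootstrap
and eigenvector computations use fixed starting states.  Unit tests run on
reduced genomes (10–30 Mb single chromosomes); recovery and calibration
checks use the default 3 × 60 Mb genome — the full-scale study conditions —
with 10 seeds for the loop-ratio recovery and 100–1000 replicates for the
statistical calibration.

## Known limitations

The FIRE score is a z-scored near-cis statistic, not the original caller's
HiCNormCis regression.  Compartment scores in regions without checkerboard
structure are reported missing by design.  The crossover-score
normalization (bin-count weight, nonzero median) follows the conservation
argument documented above; both alternatives are implemented behind flags
but not used by default.  Trans contacts exist only as per-bin totals, so
no trans-matrix analysis is possible.
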
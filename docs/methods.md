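# Methods

This note documents the models, estimators, numerical choices, and open
design decisions behind `proformquant`, and what the synthetic-data tests
do and do not demonstrate about real data.

## Data model and coordinates

A proteoform-spectrum match (PSM) carries an acquisition id, scan, retention
time (minutes), observed neutral monoisotopic mass (Da), an identification
(accession, gene, residue interval, modification shifts), a search-engine
E-value, a target/decoy flag, a precursor feature intensity, and a FAIMS
compensation-voltage channel label.  Residue coordinates are 1-based and
inclusive with the first residue of the signal peptide as 1, and all region
arithmetic uses closed intervals.  Proteoform identity
(`ProteoformKey`) canonicalizes modification delta masses to 2 decimals
before comparison; this matches the reporting precision of shift tables and
avoids float-identity fragility.

## Mass arithmetic

Atomic monoisotopic masses are hard-coded to 5 decimals (C 12.00000,
H 1.00783, N 14.00307, O 15.99491, S 31.97207, P 30.97376, Fe 55.93494) so
residue and modification masses are bit-stable.  Residue masses are derived
from elemental formulas through the same `mono_mass` routine, which makes
linearity (`mono_mass(a) + mono_mass(b) = mono_mass(a+b)`) exact.
Cysteine carries a fixed carbamidomethyl group (+57.02146 Da, iodoacetamide
alkylation).  The packaged modification table stores a formula-derived
`delta_da` for every entry (checked against the formula to 1e-4 Da) and,
for tentative assignments whose reported shifts differ from the named
composition (Leu/Ile→Ala −42.01 vs −42.047; His→Ala −66.01 vs −66.022; the
Hex2HexNAc1NeuGc3 glycan +1448.66 vs +1448.456), a separate `observed_da`
that takes precedence when matching observed shifts.  Shift matching uses a
0.1 Da tolerance by default, minimizing absolute error with ties broken by
name.

## FDR filtering

Filtering is at PSM level against a concatenated decoy database.  Records
are ranked by ascending E-value with targets placed before decoys at tied
scores (the conservative convention; the choice matters only for exact
ties).  Running FDR at rank *i* is `#decoys(≤i) / max(1, #targets(≤i))`;
q-values are the cumulative minimum of the running FDR from the worst rank
upward; targets with q ≤ 0.01 are kept and decoys are removed.  The filter
is applied globally across acquisitions by default (a per-dataset option
exists); with twelve similar acquisitions the global estimate is better
powered and the distinction is small.

## Retention-time alignment

The reference acquisition is the one with the most distinct proteoform keys
(ties: lexicographically first id).  For every other acquisition, anchors
pair the best-E-value observation of each shared key in the two runs.  The
local-to-reference map is LOESS (locally weighted degree-1 regression,
span 0.5, 2 robustness iterations — the smoother parameters are not
dictated by the method, these are conventional defaults); predictions
interpolate the fitted curve and extrapolate linearly from the boundary
segments, since chromatographic drift gradients persist at gradient ends.
Runs with fewer than 10 anchors fall back to the identity map with a
warning.  The reference run itself is mapped by the identity.

## Mass recalibration

Per acquisition, the median ppm error `(observed − theoretical)/theoretical
× 1e6` over confidently identified records (theoretical = residue masses +
water + fixed Cys modification + reported shifts) defines a single
correction; all masses in the acquisition are divided by
`(1 + median_ppm × 1e-6)`.  Per-dataset medians are the default (a global
option exists); a single median per run reflects the instrument-level bias
model — no mass-dependent calibration curve is attempted.  After
correction the per-run median ppm error of identified records is zero to
machine precision.

## Clustering and match-between-runs

Observations from all runs are agglomerated by complete linkage under the
scaled distance `d = max(|Δm|/(m̄·ppm_tol·1e-6), |ΔRT|/rt_tol)` (pair mean
mass in the denominator) and the tree is cut at `d = 1`; defaults are
10 ppm and 2.0 min, both config-exposed since the cross-run tolerances are
a user choice.  Complete linkage bounds a cluster's diameter by the
tolerances; single linkage can chain across them.  For scalability the
observations are first split at mass gaps wider than the ppm tolerance — no
complete-linkage cluster cut at 1 can bridge such a gap, so the partition
is exact, and each block is then clustered exactly.  At the generator's
default mass noise (2 ppm) this recovers the true membership with adjusted
Rand index > 0.95; at 3 ppm noise the expected within-cluster mass range
(~3σ of pairwise differences ≈ 13 ppm) exceeds the 10 ppm tolerance and
complete linkage necessarily splits clusters (ARI ≈ 0.92).  Splits are
benign downstream because clusters sharing a consensus key are re-merged at
roll-up.

Each cluster's consensus is the most frequent identified key among members
(ties: best E-value, then lexicographic label, flagged).  All members
inherit the consensus — the match-between-runs transfer.  Identification is
transferred only within clusters containing at least one identified member;
wholly unidentified clusters are retained for diagnostics but excluded from
gene-level statistics.

## Roll-up and quantification matrix

Within one (sample, CV channel), multiple member features contribute their
**maximum** intensity once — they are redundant sightings of the same
elution profile and summing would double count.  Across CV channels
contributions are **summed**, since FAIMS channels partition the ion
population.  Both choices are the package's reading of an otherwise
unspecified aggregation step and are config-switchable.  The quantification
matrix holds log2 rolled-up intensities (missing where unobserved) with a
parallel spectral-count matrix.

## Normalization and differential testing

Two-way Tukey median polish (row sweep, column sweep, effect re-centering;
tol 1e-6 on the largest sweep change, ≤ 50 iterations; missing cells
skipped) decomposes the log2 matrix into overall + row + column + residual.
Only the **column** (sample) effect is subtracted from the data: removing
row effects would erase the between-proteoform structure the analysis is
about.  The reconstruction identity holds to 1e-9; note that on even-sized
matrices the sweeps converge slowly, so residual medians are near but not
exactly zero at the iteration cap.

The paired design is tested as a one-sample problem on per-donor
differences `treated − control`, equivalent to donor blocking for complete
pairs.  The quantifiability filter requires ≥ 2 complete pairs.  Variance
moderation follows the standard empirical-Bayes scaled chi-square model:
with `s²_g` the sample variance of a proteoform's differences on
`d_g = n − 1` df, the prior `(d0, s0²)` is estimated by moment matching on
`log s²_g` (the pivot `e_g = log s²_g − ψ(d_g/2) + log(d_g/2)` has variance
`ψ'(d_g/2) + ψ'(d0/2)`, solved with a Newton trigamma inverse; `d0` is
capped at 1e6 to represent "effectively infinite", in which case
`s0² = exp(mean(e))`).  The posterior variance is
`s̃²_g = (d0 s0² + d_g s²_g)/(d0 + d_g)` and `t = mean/(s̃_g/√n)` is
referred to Student's t on `d0 + d_g` df, two-sided.  With `d0 = 0` the
procedure reduces exactly to the classical one-sample t (verified against
an independent implementation).  P values are Benjamini–Hochberg adjusted;
volcano classes use strict cutoffs p < 0.05 and |log2FC| > 1, and an
adjusted-significance flag at BH p < 0.05 is reported alongside (the
adjusted threshold is exposed in config since only the raw cutoffs are
canonical).

On a 2000-proteoform null panel with variances drawn from the prior
(d0 = 4, s0² = 0.05, 6 pairs) the estimator recovers d0 within [2, 8] and
s0² within 30%, and the realized type-I error at p < 0.05 stays inside
[0.04, 0.06], both for the test alone and for the full
normalize-then-test chain.

## Presence (condition-unique) testing

For a proteoform observed in `k` samples all falling in one condition group
of size `n_g` out of `N`, the reported probability is the exact
hypergeometric `C(n_g, k)/C(N, k)` — the chance that `k` uniform draws
without replacement all land in the group.  The test is one-sided per
group, not multiplicity-adjusted, and flagged significant below 0.01; for a
6 vs 6 design this requires k ≥ 5 (k = 5: 0.0076; k = 6: 1/924 ≈ 0.00108).
Proteoforms seen in both groups are not applicable.

## Region annotation

The packaged region map stores named prohormone products as closed residue
intervals (proglucagon GRPP/glucagon/oxyntomodulin/glicentin/GLP-1/major
proglucagon fragment; insulin B chain/C peptide/A chain; chromogranin-A
vasostatin-1, vasostatin-1/2, EA-92, LF-19/catestatin, GR-44; somatostatin
14 and 28).  A proteoform maps to the **smallest** region that fully
contains it (the most specific product: 53–81 is glucagon, not
oxyntomodulin).  Spanning or out-of-region proteoforms of a mapped gene are
"Other"; genes absent from the map are "unmapped".  GRPP is stored as
18–52 (the boundary used for trend counting) while the canonical mature
GRPP peptide 21–50 lies inside it; the data file notes this.  Regional
trends count only fully contained proteoforms, split by fold-change sign
(zero counts as neither).

## Synthetic-data generator

The generator emulates the study conditions: 6 donors × {control, treated},
one acquisition per sample, 3 CV channels (−55/−45/−35), and 40 proteoforms
per gene drawn from packaged precursor sequences (real UniProt INS, GCG,
SST, IAPP, PPY; a synthetic CHGA stand-in with authentic length and
processing-site layout, labelled as such).  Truncation termini favor
dibasic cleavage sites and known region boundaries (70% of draws), with the
remainder uniform; 30% of proteoforms carry one modification.  Latent
structure, per dataset: ppm bias ~ N(0, 3 ppm) with 2 ppm per-PSM noise;
a monotone cubic RT warp (intercept ±2 min, slope 0.95–1.05, small
quadratic/cubic terms, rejection-sampled for monotonicity on 0–120 min)
with 0.3 min per-PSM noise.  Abundance: log2 baseline ~ N(20, 2), donor
effect sd 0.5, residual sd 0.3, and region-wise treatment effects of
±1.5 log2 units injected into the major-proglucagon-fragment (+), GRPP (−),
vasostatin-1/2 (+) and LF-19/catestatin (−) regions — the sign pattern the
paired analysis is meant to detect.  Missingness is logistic in log2
abundance (intercept 1.4, slope 0.6 → ~80% presence at baseline); 3% of
proteoforms are treatment-only (never present in control), emulating
induced condition-unique observations.  Intensities are split across CV
channels by a Dirichlet(2,2,2) weight; each observed feature-channel gets
1 + Poisson(0.3) PSMs; target E-values follow 10^−(1+Gamma(2,1.5)) and
decoys (5% of PSMs) Uniform(0,1).  Where the underlying study does not
state a generative value, these are one-time choices of realistic
magnitudes, not tuned quantities.

The manifest records every latent variable, so expected cluster
memberships, fold changes, quantifiable sets, and presence probabilities
are recomputable exactly.  What passing these tests shows: the pipeline's
estimators recover the parameters of this generative model (biases within
±0.5 ppm, warp curves within 0.2 min, ARI > 0.95, calibrated type-I error,
100% sign recovery of ±1.5 effects at n = 6).  What they do not show:
robustness to features of real LC-MS data the generator omits — chimeric
spectra, co-eluting isobaric proteoforms, intensity-dependent mass error,
non-monotone RT anomalies, batch structure beyond a single warp/bias per
run, and real decoy score distributions.

## Problem sizes and determinism

Default test and acceptance runs use ~240 proteoforms across 12
acquisitions (~9000 PSMs) and 2000-proteoform null panels — sizes chosen so
the full suite exercises every stage in seconds while keeping binomial
noise on calibration checks within the stated bands.  All randomness flows
from explicit `numpy.random.default_rng` seeds; the same seed reproduces
byte-identical synthetic tables and pipeline outputs.

## Known limitations

- No feature detection or deconvolution: intensities are taken from the
  PSM tables as given.
- One identification per PSM row; ambiguous identifications are resolved
  upstream by the search engine.
- The moderated test assumes exchangeable variances across proteoforms
  given the prior; strong variance structure (e.g. intensity-dependent)
  would call for a trended prior, which is not implemented.
- Reproducing a real study's quantifiable/differential counts requires its
  deposited PSM or supplementary tables as input; the pipeline implements
  every step needed to recompute such counts once those tables are
  supplied, but ships no experimental data.
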
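# Methods

## The measurement model

Differential centrifugation of a whole-cell lysate produces a series of
pellets (1K, 3K, 6K, 12K, 24K, 80K × g) plus the final cytosolic
supernatant. Organelles are only partially separated, but each
compartment pellets with a characteristic, reproducible pattern, so a
protein's per-fraction abundance vector is a fingerprint of its
subcellular home. `dynamaps` works on such fingerprints in three
stages: supervised compartment assignment (static maps), detection of
induced localization changes between two conditions (dynamic maps), and
absolute quantification (cellular anatomy).

### Profiles and dialects

A profile is the abundance vector over the map fractions, re-normalized
to sum to 1, which places SILAC ratio data, label-free intensities and
TMT reporter intensities on one compositional scale. Dialects:

| dialect | fractions (map order) | input values |
|---|---|---|
| SILAC | 3K, 6K, 12K, 24K, 80K | heavy/light ratios, inverted to sample/reference before normalization |
| LFQ5 / TMT | 3K, 6K, 12K, 24K, 80K | intensities |
| LFQ6 | 3K, 6K, 12K, 24K, 80K, **1K** | intensities |

The nuclear-enriched 1K pellet is the *sixth data point*: including it
(with re-normalization, which shifts every fraction) markedly improves
the separation of nuclear-proximal clusters. Restricting an LFQ6
profile to the first five fractions and renormalizing is algebraically
identical to direct five-fraction normalization of the same raw
intensities; the test suite asserts this identity on random tables.

Classification requires complete profiles in every replicate map; there
is no imputation (imputed values would distort the SVM geometry).
SILAC profiles are renormalized to sum 1 like all other dialects, so
one profile semantics serves every quantification strategy.

## Static maps: SVM classification

Compartment boundaries are learned from marker proteins (curated
localizations, 12 compartments). The classifier is an RBF-kernel SVM,
one-vs-rest, class-balanced; `C` and `gamma` come from a grid search
(`C ∈ {1, 10, 100}`, `gamma ∈ {scale, 1, 10}`) under stratified k-fold
cross-validation with a fixed seed. Class probabilities are sigmoid-
calibrated (`CalibratedClassifierCV`, `ensemble=False`); the SVM score
of a prediction is the winning class's calibrated probability, which
makes confidence cutoffs transferable between maps. Pooled
out-of-fold predictions give the reported metrics: global prediction
accuracy (fraction of markers assigned to their annotated compartment)
and per-cluster recall, precision and F1 (harmonic mean).

Every profiled protein is classified; there is no "unclassified" bin.
Instead predictions are stratified into four confidence classes
(high / medium / low / very&nbsp;low) by three SVM-score cutoffs. Default
cutoffs are calibrated on the markers' cross-validated scores so that
marker accuracy above each cutoff is at least 95% / 90% / 80%; marker
accuracy within a class is the proxy for non-marker accuracy there.
Exact probability ties resolve to the alphabetically first compartment
and are flagged. Compartments with fewer markers than CV folds are
dropped with a warning by default (configurable to fold reduction
instead), which also covers restricted-label designs such as fast TMT
maps that resolve only 10 of 12 clusters.

Concordance between two maps is the fraction of shared non-marker
proteins with identical predictions, optionally restricted to proteins
scoring above a minimum in both maps. PCA projections (mean-centered,
deterministic sign: largest-magnitude loading positive) are provided
for visualization.

## Dynamic maps: the MR test

For each replicate pair of control and treated maps the per-protein
profiles are subtracted, giving delta profiles that sum to 0. Movement
magnitude and reproducibility are scored separately:

* **M score.** Each replicate's delta matrix is centered and scaled by
  a robust estimate (minimum covariance determinant, support fraction
  0.75, fixed seed); the squared robust Mahalanobis distance of a
  protein's delta to the center is referred to a χ² law and converted
  to an upper-tail p value. Sum-zero deltas are rank-deficient, so
  distances are computed in the span of the data (top components of the
  centered matrix — equivalent to a pseudo-inverse restricted to those
  components); the χ² degrees of freedom follow the five-point-profile
  convention (df = number of fractions, default 5), which is
  conservative relative to the effective rank F−1. Per protein the
  *largest* of the replicate p values is taken (the smallest observed
  shift), raised to the power of the replicate count, Benjamini-
  Hochberg-adjusted across proteins, and −log10-transformed.
* **R score.** The minimum pairwise Pearson correlation among the
  replicate delta profiles (triplicate design: three correlations).
  Zero-variance deltas yield R = 0 and are flagged.

Genuine translocators have high M *and* high R.

### Empirical FDR control

A mock experiment — control maps compared against control maps, where
no genuine movement exists — calibrates the cutoffs. The FDR estimate
of a cutoff pair is the plain ratio: mock hit rate divided by real
hit rate (`estimate_fdr`). Cutoff selection (`select_cutoffs`) scans an
(M, R) grid (M step 0.1 up to the observed maximum; R step 0.01 over
[0, 1] — calling a translocation asserts positively correlated
replicate shifts) and returns the admissible pair maximizing real hits,
ties to the larger M then R cutoff.

In simulation the naive scan substantially exceeds its nominal error
rate: the quadrant hit counts are
maximal at the loosest cutoffs, so the scan always sits on the
admissibility frontier where the small-count mock estimate is noisiest,
and null hit counts are overdispersed because a protein's delta
variance is compartment-dependent and correlated across replicates.
Three safeguards restore calibration:

1. **Common score scale.** The M score is a within-dataset BH
   transform, so the same numeric cutoff corresponds to different raw-p
   thresholds in the real and mock datasets once genuine movers shift
   the real dataset's BH ranks. Mock hits are therefore counted after
   mapping each mock protein's cubed worst-replicate p value through
   the real experiment's monotone p→M relation (`mock_equivalent_m`).
2. **Pairing-averaged mock.** Splitting 2k mock maps into k
   control-vs-control pairs is arbitrary; all 2k−1 disjoint pairings
   (round-robin schedule) are analyzed and their hit counts averaged,
   removing the dependence on the arbitrary split and shrinking the
   estimator's variance.
3. **Honest-region admissibility.** A cutoff pair is admissible only if
   (a) its quadrant meets the plain estimate, (b) every nested
   sub-quadrant containing real hits meets the plain estimate, (c)
   every sub-quadrant with at least 1/target real hits — large enough
   to certify the target at all — meets the estimate with +1 added to
   the mock hit count (the usual pseudocount guard of permutation-based
   error estimation), including the selected pair itself.

With these rules, the test suite's simulated experiments at the study
scale (≈2,000 proteins, 12 compartments, label-free noise, triplicate,
20 injected movers with total-variation shift 0.34, ten seeds) recover
movers at ≥ 0.9 recall with realized FDR at or below the 0.10 target,
and control-vs-control experiments yield essentially no movers. The
reported FDR remains the plain, unguarded ratio. A consequence of the
pseudocount is a detection floor: experiments with fewer than about
1/target·(1+average mock hits) candidate movers cannot certify the
target — e.g. ten movers cannot be certified at 10% FDR — mirroring the
practice of relaxing the target for shallow datasets.

### Null calibration, honestly stated

On exact multivariate-normal sum-zero deltas the classical-estimator
squared distances follow χ² with the effective-rank degrees of freedom
(KS distance from uniform < 0.05 at n = 5,000; the df = 5 convention is
then strictly conservative). Delta profiles from the synthetic
generator are *not* χ²-calibrated in the tail: multiplicative noise on
compartment-specific archetypes makes the null heavy-tailed and
protein-correlated across replicates. This miscalibration is a feature
of real profiling data too; it is absorbed by the mock comparison, not
by the p values, which is precisely why FDR control is empirical.
Reclassification after movement (`reclassify_after_movement`) removes
detected movers from the marker set and reports each protein's
compartment and score before and after treatment.

## Cellular anatomy: the proteomic ruler

Histones are stoichiometric with DNA, so the summed histone MS signal
anchors the total signal to a known mass: total protein mass per cell =
DNA mass per cell × (total intensity)/(histone intensity). Defaults:
DNA mass 6.5 × 10⁻¹² g (diploid human; mouse preset 5.9 × 10⁻¹²),
cellular protein concentration 200 g/L for volume estimation; both are
surfaced in output headers. Histones are recognized by gene-family
pattern (H1/H2A/H2B/H3/H4/HIST…) or an explicit ID list. Per protein:
mass = intensity share × total mass; copies = mass · N_A / MW;
concentration = copies/(N_A · volume). Copy numbers are invariant to
global intensity rescaling and linear in the DNA-mass constant, and
Σ copies·MW/N_A reproduces the total mass to 10⁻⁶ relative — both are
tested.

Whole-cell (seven-fraction) tables additionally yield pool splits:
nuclear = 1K, membrane = 3K–80K summed, cytosolic = supernatant, each
as a fraction of the per-protein total. Categories: `mostly_X` at
≥ 0.6; `nuclear_and_cytosolic` when nuclear and cytosolic are ≥ 0.3
with membrane < 0.2; otherwise `mixed`. The thresholds are declared
defaults (the category counts in published data do not pin them) and
are configurable.

Organelle composition sums per-protein mass over the proteins assigned
to each compartment (an explicit `unassigned` bin keeps the fractions
summing to 1) and lists each organelle's top-N proteins by mass share
(ties by protein ID). Proteome comparison across cell types uses gene
names as the orthology key (case-insensitive): qualitative overlap is
the shared-gene fraction of proteome A; quantitative overlap scales A's
masses by a cell-size ratio and sums min(scaled A, B) over shared
genes relative to A's total — a declared operationalization, exposed as
a parameter.

## The synthetic generator

The generator emulates the structure, not the biology, of a profiling
experiment. Twelve frozen archetype profiles (sum 1, map order
3K…80K, 1K) mimic differential-centrifugation behavior: mitochondria
pellet early, ER peaks mid-gradient, actin-binding proteins arrive
late, the nuclear pore complex concentrates in the 1K fraction. One
archetype pair (nuclear pore complex / large protein complex) differs
materially only in the 3K and 1K fractions — nearly identical on
fractions 2–5 — so its separation is carried by the sixth data point;
this pair drives the tested LFQ6-over-LFQ5 advantage. Seven-fraction
archetypes add a per-compartment cytosol share (large complexes and
actin-binding proteins are substantially cytosolic).

Per protein and map: profile = renormalize(archetype ⊙ exp(ε)) with
ε ~ N(0, σ²) i.i.d. per fraction, then intensity = profile ×
log-normal abundance (median 10⁷, ln-sd 1.5; molecular weights
log-normal around 50 kDa). The noise scales are calibration constants
ordered like the real quantification strategies' precision: σ = 0.08
(SILAC), 0.12 (TMT), 0.25 (LFQ). Replicates share the cohort
(identities, abundances, weights, marker flags — half of each
compartment's non-movers are markers) and differ only in noise;
treated-condition movers sit on (1−λ)·source + λ·target archetypes;
mock maps are extra control draws; whole-cell maps append eight
high-abundance histone rows for the ruler. Every stream derives
deterministically from one master seed. Truth tables are written
beside every dataset; tests consume them rather than generator
internals.

What the generator does not emulate — and hence what green tests do not
establish about real data: peptide-level identification and missingness
structure (optional quantile dropout exists but is off by default),
intensity-dependent noise, ratio compression, batch effects between
replicates, and markers that are themselves mislabeled. Conclusions
here are about the algorithms under a clean compositional noise model,
not about instrument performance.

## Problem sizes and numerical choices

Simulation-based tests run at 12 compartments × 167 proteins (≈2,000)
for the dynamic-maps checks and 12 × 50 for classification checks,
averaged over up to ten seeds — sizes chosen to match the study scale
while keeping the whole suite in the minutes range. Other fixed
choices: profile sum tolerance 10⁻⁹; p values floored at 10⁻³⁰⁰ before
cubing and after BH (caps M at 300); rank detection at 10⁻⁸ relative
singular value; MCD support fraction 0.75 with fixed seed;
`zero_is_missing` on for LFQ tables (the label-free convention of
writing 0 for absent) and off otherwise; fraction order is always
re-imposed from the configured gradient rather than trusted from input
column order.

## Known limitations

* The χ²/df convention is an approximation twice over (rank deficiency,
  non-normal noise); M scores are ordinal evidence, and error control
  comes only from the mock comparison.
* The mock estimator remains overdispersed across map sets; realized
  FDR at the selected cutoffs fluctuates seed to seed even though its
  average sits at or below the target.
* Calibrated SVM probabilities from small marker classes (< ~10 per
  class) are rough; confidence cutoffs calibrated on them should be
  treated as indicative.
* Orthology-by-gene-name overlap undercounts true orthologs with
  diverged symbols and conflates paralogs sharing a symbol.
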
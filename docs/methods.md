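# Methods

`songphylo` measures song syllables, classifies them to species, and asks
whether the acoustic differences between species carry phylogenetic signal.
This document describes each model, its parameters, the scope of the bundled
synthetic generator, the numerical choices made along the way, and the known
limitations.

## Preprocessing

Recordings are band-pass filtered to the analysis band (250–8000 Hz,
4th-order Butterworth applied forward-backward so the phase is unchanged) and
RMS-normalized to a common level (65 dB re unity full scale). Syllables are
segmented by thresholding the smoothed rectified amplitude envelope at a
proportion (default 0.10) of its peak: gaps shorter than `min_gap` (10 ms)
are merged, runs shorter than `min_duration` (10 ms) dropped. Bouts are runs
of syllables whose inter-syllable intervals stay below 2.5 s.

## Acoustic features

Each syllable is summarized by 21 features in three families:

- **Singular frequency measures** (10): spectral mean/median/quartiles of the
  mean power spectrum, fundamental-frequency mean/min/max, dominant-frequency
  mean/min/max.
- **Power-distribution measures** (8): spectral sd, IQR, skew, kurtosis,
  spectral entropy, spectral flatness, time entropy, and overall entropy
  (the product of spectral and time entropy).
- **Spectrotemporal measures** (3): duration, modulation index (dominant-track
  path length over its range), and dominant-frequency slope.

The dominant track is the per-frame peak-power frequency (512-sample frames,
50% overlap); its slope uses the time span between the first and last frame
centers, because dividing by the full clip duration would bias the slope low
by the half-window margin at each end.

The fundamental-frequency track uses normalized autocorrelation per frame
(1024-sample frames) with a search band of 250–3500 Hz. A frame is voiced
when some autocorrelation value in the lag range clears an absolute threshold
(0.5). The period is the **shortest lag at which an interior local peak
clears the threshold**, refined by parabolic interpolation: peaks at integer
multiples of the period are equally high, so a global argmax can halve the
estimated f0, while peaks at fractions of the period are weak or negative
for natural harmonic rolloffs. If the threshold is reached only at a
boundary of the search range there is no trustworthy period peak and the
frame counts as unvoiced. Clips with no voiced frame get missing f0
statistics — missingness is data, not an error. Spectral entropy of a
one-bin spectrum is defined as 0 (a single bin carries no frequency
uncertainty).

## Synthetic generator

The generator is the study's data source and its defaults are the study
conditions. `SynthSpec` draws, for each species on a bundled 7-tip tree:

- a **frequency trait**. At `tree_coupling = 1` (default) this is the
  deterministic 1-D configuration whose pairwise differences best correlate
  with the patristic distances (a strongly tree-aligned trait — the regime in
  which phylogenetic signal is detectable against a Brownian-motion null); at
  `tree_coupling = 0` it is a plain Brownian-motion draw, for which an
  evolutionary-model Mantel test should reject at roughly the nominal rate.
- **power and spectrotemporal family factors**, drawn independently of the
  tree (labile traits).

Feature vectors are per-species Gaussians with a shared low-rank
(`rank = 3`) within-species covariance, mapped affinely into physical units.
Between-family species-level spreads default to `(2.0, 0.6, 0.5)` sd units
for (frequency, power, spectrotemporal). Missing cells are injected
completely at random into the three f0 columns at rate 0.0622.

The waveform generator (`synth_dataset`) renders each syllable as a harmonic
stack (4 harmonics with 1/h amplitude rolloff) plus broadband noise, with a
per-clip linear frequency sweep. The sweep is clamped so the instantaneous
fundamental stays inside 260–7800 Hz over the whole syllable; an unclamped
sweep can push the frequency through zero, which is not a syllable at all.
`planted_feature_table` provides a separate design with 6 informative and 15
noise features whose class means are orthonormal contrasts, for validating
importance-based selection.

Scope: the generator is stylized. It produces low-rank Gaussian feature
tables and harmonic-stack waveforms, not real song; it exists to give the
statistical machinery data with known ground truth, not to imitate any
particular species.

## Imputation and principal components

Missing f0 cells are imputed per species by regularized iterative PCA: an
EM-style loop that alternates a rank-`ncp` reconstruction with singular
values shrunk by the estimated residual variance ((d² − σ²)/d) and refilling
of only the missing cells, on columns standardized over observed cells.
Observed cells are never altered. A diagnostic reports the mean absolute
correlation between the leading loading vectors of the imputed table and of
the complete cases.

PCA is computed on the correlation matrix, because the features mix Hz,
seconds and unitless quantities. Components with eigenvalue > 1 are retained
(Kaiser-Guttman); a loading is significant when |loading| ≥ √(1/f) with
f = 21 features. The boundary is inclusive, implemented with a 1e-12
tolerance so eigenvector rounding cannot exclude a loading exactly at the
threshold.

## Hypervolumes and overlap

Each species' cloud of PC scores is enclosed by a one-class SVM (RBF kernel,
`nu = 0.01`, `gamma = 0.5`). The enclosure threshold is the minimum decision
value over the training points, which guarantees every training point lies
inside its own volume. Volume is estimated by uniform Monte Carlo sampling
of the data bounding box expanded by 10% per side, with a binomial standard
error. Pairwise overlap uses **joint samples**: the same uniform draws are
tested against both volumes, so per-draw intersection ≤ each member and the
estimated Jaccard index never exceeds either directional overlap (shared
volume over one species' own volume). Directional asymmetry is tested by
Spearman correlation between the two directions over unordered pairs.

## Classification

A bagged forest of unpruned decision trees draws each bootstrap with
per-class probabilities proportional to class priors (motif share by
default), so training reflects the sampling design. Evaluation is
out-of-bag: each tree predicts the rows left out of its bootstrap.
Permutation importance is the increase in OOB error after permuting one
feature, averaged over trees and repeated over fresh forests with all
features available at every split. The selected subset is everything before
the largest gap between consecutive rank-ordered importances. Imbalance can
alternatively be corrected by SCUT resampling: every class is brought to
floor(total/k) syllables, undersampling by iteratively removing the most
redundant member and oversampling by SMOTE interpolation between same-class
nearest neighbors. Two classifiers are compared by a pooled-variance
two-sample t-test on per-species F1 scores.

## Overlap–misclassification association

Directional overlap and misclassification proportion are compared across all
k(k−1) = 42 directed heterospecific pairs. Both are log-transformed after
adding the Stahel constant q1²/q3 (quartiles of the positive values,
linear-interpolation quantiles), which keeps zeros finite without swamping
the small values; correlation is Pearson (or Spearman).

## Phylogenetic signal

Per feature (or PC score), species are compared by histogramming the pooled
z-scored values on a shared grid in 0.01 increments (bins centered on grid
points, relative frequencies because sample sizes differ ~20-fold); the
distance between two species is the sum of squared differences (SSD) between
their histograms, and each feature's matrix is max-normalized to [0, 1].

- **Standard Mantel**: Pearson correlation of the off-diagonal upper
  triangles, null by simultaneous row/column permutation, two-sided, with
  the add-one correction; small matrices can be tested exactly by enumerating
  all k! relabelings (the identity makes p strictly positive).
- **EM-Mantel**: the observed statistic is the Mantel correlation with the
  patristic distances; the null distribution is the same statistic for
  univariate Brownian-motion traits simulated on the tree (trait distance =
  absolute difference; Mantel r is scale-free so the BM rate is fixed at 1).
  One-tailed upper p with the add-one correction.
- **ppMantel**: phylogenetically weighted permutations. Each permutation
  composes k² transpositions, choosing pair (i, j) with probability
  proportional to (1/patristic distance)^(1/k_influence); k_influence = 1 is
  the strongest phylogenetic weighting and the chain flattens to uniform
  permutations as k_influence → ∞, recovering the standard Mantel.
- **Two-step testing**: every matrix is screened with the standard Mantel
  test, Benjamini-Hochberg corrected across the family; only survivors get
  the one-tailed EM-Mantel, again BH-corrected within that subset. A feature
  is flagged significant when it survives both steps. Phylogenetic inertia
  is the squared EM-Mantel correlation, reported as a whole-number percent.
- **Dendrogram congruence**: distance matrices are clustered (complete
  linkage), cut at k clusters, and compared by the Fowlkes-Mallows index
  T_k/√(P_k Q_k). The permutation-null expectation √(P_k Q_k)/(n(n−1)) and
  the Fowlkes-Mallows variance are closed forms; the one-tailed p uses the
  normal approximation.

## Numerical choices

- Permutation and simulation p-values use the add-one correction
  (1 + hits)/(1 + draws), so p is never zero; exact enumerations report the
  exact fraction instead.
- Comparisons against null statistics use a 1e-12 tolerance so ties are
  counted as extreme rather than lost to floating-point noise; the loading
  significance boundary is inclusive with the same tolerance.
- All derived seeds are drawn as integers below 2³¹ from a single
  `numpy.random.Generator`, so every pipeline run is reproducible from one
  seed; pipeline stage outputs are byte-identical across reruns.

## Limitations

- The f0 tracker searches 250–3500 Hz; a fundamental outside that band locks
  onto an in-band subharmonic. Even in band, extraction noise of a few
  percent can swap the ranks of species whose generative means differ by
  less than ~10%.
- SSD between histograms saturates at twice the mean squared bin mass once
  two species' distributions stop overlapping, so very distinct pairs all
  look maximally distant.
- One-class SVM volumes depend on `nu` and `gamma`; they are comparable
  within a run, not absolute niche sizes.
- The FMI p-value is a normal approximation, unreliable for very few leaves;
  the closed-form moments themselves are exact.
- The EM-Mantel null assumes Brownian motion; traits evolving under other
  models will be mis-calibrated.
- The generator's tree-aligned default (`tree_coupling = 1`) is a favorable
  regime for detecting signal; a pure BM trait (`tree_coupling = 0`) often
  carries little detectable signal on a 7-tip tree, which is a property of
  the statistics at small k, not a software defect.
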
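# Methods

This note documents the models, conventions and design choices behind
`synaptodyn`, in the spirit of a package methods appendix.  Nothing
here states an empirical result that the tests or
`scripts/acceptance.py` do not themselves compute.

## Numerical conventions

Centralized in `synaptodyn._stats` and used everywhere:

- sample standard deviation (`ddof=1`);
- average ranks for ties; the median of an even-count set is the mean
  of the two central values;
- quartiles by linear interpolation (numpy's default, "type 7");
- the normalized IQR divides the raw IQR by 1.349 (the IQR of a
  standard normal), so it estimates σ; when a column's IQR is zero the
  SD substitutes, and a column whose SD is also zero (to within
  1e-12 relative float tolerance) is dropped rather than normalized;
- Spearman p-values use the two-sided t approximation;
- missing feature cells propagate as missing (NaN), never as 0.

## Feature catalog

The catalog (`features.default_catalog`) is a curated, formula-faithful
set of 27 interpretable statistics: StatAv(2..10), negative and
positive outlier-timing mrmd (increment 0.01, extreme threshold ∓3.5),
local/global SD at fractions 0.01/0.05/0.1, DFA slope and log-log fit
SSR (windows log-spaced from 50 to T/4, linear detrending,
non-overlapping), four moments plus min/max, and lag-{1,2,3,5,10}
autocorrelations.  It is deliberately not a reimplementation of the
full massive-feature-extraction toolbox; the pipeline is
feature-agnostic beyond the catalog interface (a catalog is any
DataFrame of named callables with family tags).

Specific conventions where the underlying definitions leave room:

- **StatAv** discards the trailing `T mod n` points from the segments
  ("equally sized segments" requires equal bins); the full-series SD
  uses all points.
- **mrmd** maps time to [−1, 1]; thresholds that select no point are
  excluded from the median (a mean over an empty set is undefined).
  The positive variant mirrors the construction exactly.
- **DFA** returns both the slope and the SSR of the log-log fit; which
  of the two a given analysis should use is left to the caller, so
  both are separate catalog entries.

Features are normalized per column with the scaled robust sigmoid and
then min-max rescaled, which preserves within-column ranking exactly;
a feature that is constant across regions in *any* subject is dropped
from *all* subjects so per-subject matrices stay aligned.

## Consensus clustering

Louvain community detection runs on the subtype similarity matrix with
negative entries set to zero (modularity needs nonnegative weights;
the similarity's sign structure is preserved in the planted design by
construction).  Consensus follows the agreement-matrix iteration:
`reps` seeded Louvain runs, co-assignment fractions thresholded at
τ = 0.5, reclustered until all runs agree.  Clustering is stratified
by protein class; labels are made globally unique.  PSD95 cluster-mean
maps are named long-/short-lifetime by mean member lifetime (ties
toward "long"); members whose own lifetime disagrees with their
cluster's label are listed in the output metadata rather than
reassigned.

## Association and representative selection

The Bonferroni family is the number of features tested per density map
(not maps × features): each map's screen is corrected independently.
An optional |r| filter thins very large significant sets.  Feature
clustering uses average-linkage agglomerative clustering on 1 − r for
k = 2..10; the chosen k maximizes (mean within-cluster r − mean
between-cluster r) minus a penalty of 0.05 per cluster with fewer than
5 features.  The default representative is the feature with the
largest |r| inside the largest cluster; because "explainability" of a
feature is irreducibly a judgment call, an explicit user choice
overrides the default.

## Connectomes and coupling

The edge filter keeps candidate edges with p < 0.05.  (The polarity is
exposed as a flag because the opposite reading — omitting significant
edges — is incompatible with the sparse densities such filters are
known to produce.)  Functional connectomes average per-subject Pearson
matrices arithmetically on r; a Fisher-z option is exposed.  Functional
strength is the signed sum of correlations, with no absolute value or
threshold.

Communicability normalizes by s_i = (in-strength + out-strength)/2
with an ε = 1e-12 floor; on undirected graphs this reduces to the
standard row-strength normalization (the 2×2 cosh/sinh case in the
tests pins this convention).  Coupling regressions use OLS with an
intercept; adjusted R² uses n = |subset| − 1 observations and p = 1
(baseline) or 1 + number of density maps (augmented).  The added
regressor is the *target region's* density — the only reading under
which the regressor varies across a profile's observations.  The
Wilcoxon signed-rank comparison discards zero differences (classic
convention; `zero_method` is configurable) and reports a degenerate
flag with p = 1 when all differences are zero.

## Transcriptomics

Category scores use normalized expression (consistent with the
pipeline order: normalize, correlate, score).  A category's size is
counted on annotated genes present in the expression set with a finite
correlation; categories below the minimum size (default 100) are
excluded.  Scores are ranked without multiple-testing correction —
the output is a ranking, not a set of hypothesis tests.

## Reproducibility

Subgroup pairs are disjoint (non-disjoint pairs would share subjects
and inflate reproducibility); each unordered pair is enumerated once,
giving C(S,N)·C(S−N,N)/2 pairs.  The group mean in
individual-vs-group comparisons includes the subject itself by
default, with a leave-one-out flag.  The r̄(N) fit is unweighted least
squares on (ln N, r̄).

## The synthetic-data generator

The generator emulates the study conditions: 37 subtypes
(11 PSD95 / 7 SAP102 / 19 colocalized) over 88 regions; 10 subjects ×
1414 time points of standardized signal; a ~7%-dense weighted directed
connectome; awake/anaesthetized functional connectomes; ~2000 genes
from two section sources with 80 annotated categories.  Mechanisms are
stand-ins chosen for testability, not claims about biology.

**Spatial maps.** Latent maps are smooth low-rank gradients (few
sinusoids over the region axis plus ontology-block offsets), QR-
orthogonalized so planted mechanisms cannot leak into one another; the
colocalized singleton's map anti-correlates with the cluster latents so
it stays isolated under the zero-clipped Louvain step.  Subtype maps
are noisy exponential (hence nonnegative, monotone) transforms of
their cluster's latent; PSD95 lifetimes are drawn from disjoint high
(65–90%) and low (20–45%) ranges per cluster.

**Signals.** Per region: AR(1) noise with a per-region coefficient
drawn from U(0.3, 0.9); white observation noise with per-region
amplitude U(0, 0.7); a slow oscillation (period U(150, 600) frames,
amplitude U(0, 0.6) of the baseline SD).  All three nuisances are
independent of the planted maps and fixed across subjects: they give
autocorrelation- and fluctuation-scaling features map-independent
variance of their own, so the features that best measure the planted
mechanisms are the ones designed for them.  The planted mechanisms
are (i) per-segment mean offsets (10 segments, zero-sum per series)
whose SD is 0.05 + 0.7·u_long(r), and (ii) ~40 negative spikes of
≈6 total-SD whose times follow Beta(1 + 3·u_sap(r), 1) scaled into the
last 90% of the recording.  Spikes are mean-neutral within each
segment and avoid the initial window, so event *timing* does not leak
into segment-mean drift or initial-window variance; spike depth tracks
the full signal SD so standardized spike magnitude is uniform across
regions.  Each planted map is jittered at the region level
(SD 0.35) before driving its mechanism, which dilutes the recoverable
map–feature Spearman correlation to the target regime of ≈0.6.
Motion traces are lognormal and independent of the signal by default,
with a contamination dial; a smooth SNR map with a coupling dial
exercises the confound-regression check.

**Connectomes.** Edges are sampled by a Gumbel top-k scheme with
hubness tied to the long-lifetime map, so degree–density and
lifetime–degree analyses have signal; planted edges carry
p ~ U(0, 0.01) and an equal number of spurious candidates
p ~ U(0.05, 1), making the significance filter's behaviour directly
testable.  FC is a tanh of standardized communicability plus regional
density terms (long-lifetime and SAP102 in both states) and symmetric
noise.  The state manipulation adds a short-lifetime term in the awake
state and an equal-weight, region-shuffled copy of that map in the
anaesthetized state; the state term's dyadic matrix is sample-
orthogonalized against the other regressors so the state switch
redistributes FC variance without in-sample crosstalk — only the
short-lifetime map's coupling gain is genuinely state-dependent.

**Expression.** The planted category's 120 genes are noisy linear
transforms of the long-lifetime map (noise tuned to gene–density
r ≈ 0.6); background genes are independent smooth maps; the two
sources share latent expression plus independent noise, and only half
the genes are measured coronally.

**What passing tests do and do not show.** Recovery on this generator
demonstrates that the pipeline's statistics measure what they claim
and that its inference is calibrated under realistic sizes, spatial
smoothness and nuisance structure.  It does not validate the
biological claims on real data: real BOLD signals have richer temporal
structure than AR(1)+drift+spikes, real connectomes have geometry and
community structure the Gumbel sampler lacks, and real gene
categories overlap hierarchically.

## Problem sizes in the test suite

The acceptance-style tests run the full 88-region / 10-subject / 1414-
time-point configuration for mechanism recovery (20 seeds), the
coupling dissociation (100 replicates) and category recovery (20
seeds).  The familywise-error simulation uses 200 replicates at a
reduced 2-subject / 250-time-point configuration — FWER control is a
property of the screen, not of the sample size — and the
reproducibility oracle checks use 10 subjects of 120–200 regions of
Gaussian feature maps where the analytic attenuation curve
(Spearman-mapped reliability of means) is exact.

## Known limitations

- Louvain is run via networkx; very fine resolution limits
  (γ far from 1) are untested.
- The exact output of the original feature-extraction toolbox for the
  outlier-timing statistic may differ in detail (direction and
  normalization of the median over thresholds); the implementation
  here follows the construction documented above, and the
  time-reversal antisymmetry property pins the convention.
- Permutation-exact Spearman p-values are not implemented; at the
  region counts used here (≥ 44) the t approximation is adequate.
- No spatial-autocorrelation-preserving null models (spin or
  variogram tests): inference treats regions as exchangeable, which
  the generator's jitter respects but real spatially smooth maps may
  not.
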
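# Methods

This note documents the models, numerical conventions and design choices
behind `richclubnet`: what the analysis pipeline computes, what the
synthetic cohort generator emulates, and what passing tests do and do not
demonstrate about real diffusion-MRI data.

## Connectome construction

A subject's connectome is a symmetric, zero-diagonal, non-negative weight
matrix over a fixed parcellation (90 nodes by default, any n ≥ 3 accepted).
The primary weighting is the sum of inverse streamline lengths per region
pair, times a scaling constant `scale` that corrects for tractography
seeding density.  Because that constant is uniform within a subject, every
ratio-, classification- or rank-based result downstream is invariant to it;
only absolute strengths depend on it, so cross-dataset comparisons of raw
strengths require a consistent choice.  The default analysis uses
`scale = 10`, which puts genuine edges of the synthetic cohorts comfortably
above the weight threshold.  Thresholding removes weights strictly below
`tau` (default 1); weights equal to `tau` are kept.  The alternative
weighting divides the streamline count by the mean of the two region
volumes (the combination is symmetric in i and j; the volumes enter as a
plain average because no finer rule is defensible without anatomy).

Per-edge fibre length is the arithmetic mean of the lengths of the
streamlines forming the edge, recorded at build time and carried through
thresholding; it is what the median-split analysis operates on.

## Graph measures

Degree, density and total strength follow the standard definitions.  For
path-based measures an edge of weight w has traversal length 1/w — the
usual convention on strength-weighted connectomes, stated here prominently
because nothing in the data forces it.  Global efficiency is the mean of
1/d over ordered node pairs, with disconnected pairs contributing 0 (rather
than being excluded) so that efficiency remains comparable across networks
of different density.  Local efficiency of a node is the global efficiency
of the weighted subgraph induced on its neighbours; nodes with fewer than
two neighbours contribute 0.  Shortest paths are computed with Dijkstra's
algorithm on a sparse representation.

Normalization divides an observed efficiency by its mean over
degree-preserving random networks.  Randomization is Maslov–Sneppen
double-edge swapping in which weights travel with their edges, so the
degree sequence *and* the weight multiset are preserved exactly; proposals
creating self-loops or duplicate edges are rejected and retried, with 10
accepted swaps per edge by default.  Graphs admitting no valid swap (e.g. a
triangle) are returned unchanged with a warning rather than failing.

## Rich-club statistics

The weighted rich-club coefficient Φ(k) uses a strict degree threshold
(degree > k, "exceeding" the threshold): with S the qualifying nodes, Φ is
the summed weight of edges inside S divided by the sum of the |E_S|
largest edge weights in the whole network.  Φ is undefined (NaN, never 0)
when S has fewer than two nodes or no internal edges.  Φ_norm divides by
the mean Φ of the degree-preserving nulls; NaN propagates.

Three rich-node selection schemes are provided: (1) top n_rich nodes by
mean degree across all subjects of both groups (the primary scheme,
n_rich = 8 ≈ 9% of 90 nodes); (2) top n_rich by degree in a binary
group-averaged network containing edges present in ≥ 30% of subjects;
(3) per-subject top round(0.09·n) nodes.  Ties at the cut are broken by
higher node strength, then lower node index, and always logged — a
deterministic rule chosen because strength is the natural secondary
hubness criterion.

Edges are partitioned into rich / feeder / peripheral by how many endpoints
lie in the rich set; class strengths are summed edge weights, optionally
divided by total network strength, with rich/feeder and rich/peripheral
ratios (undefined and flagged when a denominator class is empty).  The
fibre-length median split dichotomizes feeder and peripheral edges at the
class median, ties going to "short" — an arbitrary but deterministic
convention, stated in every report.

## Inference

Group differences use Welch's unequal-variance t-test with
Welch–Satterthwaite degrees of freedom (the group sizes are unequal by
design).  Family-wise error over the family of class-strength measures is
controlled by permutation of group labels with the maximum-|t| statistic;
p-values use the add-one (Phipson–Smyth) estimator so they are never zero.
An alternative edge-cluster mode implements a network-based-statistic style
test: per permutation, edges with |t| above a primary threshold are kept
and the largest connected suprathreshold component size forms the null
distribution.  Both modes are exposed because "cluster" is ambiguous when
the measures are a handful of summary statistics; the mode used is recorded
in every report.

WMH volumes and lacune counts are log1p-transformed before use.
Marker-strength correlations (Pearson) correct each class strength for
overall connectivity by taking the residual from a regression on total
network strength.  Cognition models are ordinary least squares with the
outcome and continuous predictors z-scored (binary covariates left as-is),
reporting standardized betas, and variance inflation factors with a
multicollinearity flag at VIF > 5.  Mediation is the classical Sobel test:
a from M ~ X + covariates, b from Y ~ M + X + covariates,
z = a·b/√(b²se_a² + a²se_b²) against the standard normal; no bootstrap
variant is claimed.  Beyond the permutation FWE above, no additional
multiple-testing correction is applied to the descriptive comparisons;
a Bonferroni correction is appropriate when scanning over rich-club sizes.

## The synthetic cohort generator

The generator produces streamline tables and subject metadata whose
networks carry, by construction, the features the pipeline is meant to
detect.  It has no anatomical realism — no images, no lesion masks, no true
AAL geometry — only the statistical skeleton of a two-group SVD study.

**Geometry.**  Nodes are points in an ellipsoid with semi-axes
(60, 80, 55) mm, mirrored across the midline for bilateral symmetry.  The
8 hubs sit at deep, near-midline positions in two widely separated
anterior/posterior groups, so hub-hub distances (mean ≈ 85 mm) exceed
typical non-hub distances — rich-club edges are physically long, and the
template constructor enforces this as an invariant.

**Connectivity.**  Connection probability decays exponentially with
distance (scale 45 mm, prefactor 0.9, cap 0.95).  Hub-hub pairs are boosted
to near-certain connection; hub-nonhub pairs use a longer decay scale
(70 mm), reflecting the long-range reach of hubs and giving the feeder
class its long tail of tract lengths.  Realized edges receive Poisson
streamline counts whose means are set so that the built weight (at
scale 10) sits near 5 for rich, 3.5 for feeder and 3 for peripheral edges
with a mild decay in length — strong enough that genuine edges survive the
τ = 1 threshold even under lesioning.  Spurious connections appear on
unconnected pairs with probability 0.03 and 1–3 streamlines; these fall
below the threshold, which is what the threshold exists to remove.
Streamline lengths are positive-truncated normal around the inter-node
distance with SD equal to 10% of the distance (per-class length variances
are otherwise unconstrained, so the dispersion is a free modelling choice).
Per-subject biological variability is i.i.d. per-edge lognormal weight
noise (mean 1, SD 0.6); a single global factor per subject would cancel out
of every total-strength-corrected quantity and is therefore not a useful
noise model.

**Lesioning.**  Patients' streamlines are thinned per connection class:
each streamline of class c survives with probability
clip(1 − (1 − f_c)·severity_c, 0, 1), with default retention factors
(0.63, 0.79, 0.79) so the expected strength reductions are 37.0% for rich
and 20.7% for feeder/peripheral connections.  Severity is log1p(WMH)
normalized to mean 1 over the patient group — making the configured
reductions exact estimands — and is jittered per class by a mean-1
lognormal factor (SD 0.55, capped at 2.5× overall) modelling between-patient
variation in lesion topography.  The jitter matters twice: it produces the
negative correlation between WMH and *total-strength-corrected* rich-club
strength (without it, total strength is a noiseless proxy for lesion load
and the corrected correlation collapses to zero), and it decorrelates the
mediator from the exposure enough for the indirect pathway to be testable.
Controls are generated unlesioned; their small WMH loads are descriptive
only.

**Metadata and cognition.**  WMH is lognormal (patients mean 3.1, SD 2.6 mL;
controls 0.84, 1.2), lacune counts Poisson (means 1.38 / 0.45, matching a
~75% / ~36% prevalence of at least one lacune), brain volumes, age, sex and
premorbid-IQ marginals match the cohort tables the generator emulates.
Processing speed is β_rc·z(rich strength) + β_lac·z(log1p lacunes) + noise
with defaults (0.28, −0.33) and residual SD 0.70; executive function uses
(0.20, −0.27) with SD 0.85.  Scores are generated within group (z-scoring
inside each group), mirroring within-study scoring.  The residual SD is a
deliberate choice: it makes the configured WMH → rich-club → speed pathway
detectable by the Sobel test with high power (>85%) at the default
150–165-subject scale while keeping the recovered standardized beta within
0.1 of the configured coefficient; with a residual SD near 0.9 the
indirect effect would sit at the edge of detectability at this sample size.

**Reproducibility.**  All randomness flows from one master seed through
per-subject spawned seed sequences, so cohorts are bit-for-bit reproducible
and output files byte-identical across runs.

## What the synthetic data does not show

Passing the pipeline on generated cohorts demonstrates correctness of the
statistics and recoverability of planted effects — not validity on real
tractography.  The generator omits, among other things: spatially
correlated lesion fields (severity is per-class scalar, not per-tract),
distance- and curvature-dependent tractography failure, partial-volume and
crossing-fibre biases, hemispheric asymmetries, degree-strength coupling
beyond the hub boost, and any direct effect of lacune location on specific
tracts (lacunes affect cognition only, not the network, which is why the
lacune-mediation analogue is weak by construction).  Effect sizes recovered
from real data will differ accordingly.

## Numerical conventions and degenerate inputs

Undefined quantities are NaN with a warning, never silently zero: Φ with an
empty club, ratios with an empty denominator class, normalized efficiencies
with a zero null mean.  Empty streamline tables build an all-zero
connectome with a warning; malformed table rows raise errors naming the
line.  Matrices are written with full float precision and re-read with
round-trip parsing, so write/read is exact.  Welch's test refuses two
zero-variance samples; regressions check design-matrix rank and name the
collinear columns.  Default problem sizes for the null-model computations
(per-subject Φ_norm and normalized efficiencies on subject subsamples, with
tens of randomizations) were chosen so a full discovery-scale analysis runs
in minutes on one CPU; all of them are configuration parameters.
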
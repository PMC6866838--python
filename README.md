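# richclubnet

Weighted rich-club analysis of structural brain connectomes, built for
case-control studies of cerebral small vessel disease (SVD), together with a
synthetic cohort generator that emulates the statistical structure of such
studies so every stage of the pipeline can be exercised and tested without
MRI data.

## The scientific problem

Diffusion-MRI tractography turns each subject's white matter into a weighted
network over a 90-region (AAL-style) parcellation: regions are nodes, and
two regions are connected when streamlines end in both, with connection
strength

```
w_ij = s · Σ_f 1 / l_f
```

the sum of inverse streamline lengths l_f (a seeding-density correction s is
applied uniformly, and weights below a threshold τ = 1 are removed as likely
false positives).  A small set of high-degree *hub* regions — precuneus,
putamen, thalamus, superior frontal cortex — is densely interconnected by
physically long tracts, forming a **rich club**.  The weighted rich-club
coefficient at degree threshold k,

```
Φ(k) = W_{>k} / Σ_{l=1..E_{>k}} w_l^ranked ,
```

is the summed weight among nodes of degree > k divided by the sum of the
equally many strongest weights anywhere in the network; it is normalized by
its mean over degree-preserving random rewirings, and Φ_norm > 1 indicates
rich-club organisation.  Edges are classified as **rich** (both endpoints in
the rich club), **feeder** (one endpoint) or **peripheral** (neither).

In SVD, white-matter hyperintensities (WMH) and lacunes damage these
connections.  The package tests whether that damage falls *preferentially*
on rich-club connections: per-class connection strengths are compared
between patients and controls with Welch's t-tests and permutation
family-wise-error control, fibre-length effects are dissected with a median
split, and the clinical chain WMH → rich-club strength → processing speed is
quantified with covariate-adjusted standardized regression and the Sobel
test of the indirect effect, z = a·b / √(b²·se_a² + a²·se_b²).

The synthetic cohort generator plants an 8-node rich club among 90 nodes in
a mirrored ellipsoid, samples Poisson streamline counts with
distance-dependent connection probabilities, and lesions patient networks
class-specifically (default retention factors 0.63 / 0.79 / 0.79, i.e. 37%
rich and ~21% feeder/peripheral strength reductions) in proportion to each
subject's log-WMH load, so the configured effects are the estimands the
pipeline should recover.

## Worked example

```bash
# 1. simulate a two-group cohort (25 controls, 40 SVD patients)
cat > cohort.yaml <<'YAML'
n_control: 25
n_svd: 40
seed: 7
YAML
richclubnet simulate --config cohort.yaml --out cohort

# 2. run the analysis (permutations / null-model sizes set in a config)
cat > analysis.yaml <<'YAML'
seed: 7
n_perm: 5000
n_null: 50
norm_eff_subjects: 4
norm_eff_null: 20
phi_subjects: 8
phi_null: 15
YAML
richclubnet analyze --streamlines cohort/streamlines.tsv \
    --metadata cohort/metadata.tsv --config analysis.yaml --out results

# 3. render the report
richclubnet report --results results
```

The report printed for this cohort includes:

```
Group tests (control vs SVD)
----------------------------
  density                reduction=   8.7%  t=   6.39 df=  53.8 p=4.14e-08
  total_strength         reduction=  24.3%  t=  10.38 df=  46.1 p=1.21e-13
  global_efficiency      reduction=  21.1%  t=  11.39 df=  46.1 p=5.36e-15
  local_efficiency       reduction=  22.8%  t=  11.00 df=  50.2 p=5.61e-15
  rich                   reduction=  40.6%  t=   8.40 df=  60.9 p=9.02e-12, p_fwe=0.0002
  feeder                 reduction=  19.0%  t=   6.92 df=  58.2 p=3.87e-09, p_fwe=0.0002
  peripheral             reduction=  25.4%  t=   8.68 df=  45.1 p=3.51e-11, p_fwe=0.0002
  ratio_rich_feeder      reduction=  24.8%  t=   4.04 df=  57.1 p=0.000164
  ratio_rich_peripheral  reduction=  19.3%  t=   3.11 df=  52.5 p=0.00305

phi_norm (hub regime): control 1.41 vs SVD 1.18, p=0.0368
```

Reading it: patient networks are less dense and weaker overall, but the
rich-club connections lose about twice as much strength (40.6%) as feeder or
peripheral ones (19–25%), the rich/feeder and rich/peripheral strength
ratios drop significantly, and the normalized rich-club coefficient at the
hub regime is lower in patients — the preferential-disruption signature the
pipeline is designed to detect.  At this small simulated sample the Sobel
mediation of WMH on processing speed through rich-club strength is not yet
significant (z = −1.31); at the default discovery scale (50 vs 115) it is
detected in >90% of replicate cohorts.

The same steps are available as library calls (`richclubnet.cohort.generate_cohort`,
`richclubnet.pipeline.analyze_cohort`) returning pandas DataFrames.

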
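# Methods

This note documents the statistical and numerical choices behind
`sdcmap`: the disconnectome model, the voxel mapping machinery, the
SDC score, the prediction-model comparisons, and what the synthetic
cohort generator does and does not emulate.

## Geometry: lesions, streamlines and voxels

All volumes live on one `ReferenceGrid` (default 24×24×24 voxels at
4 mm isotropic — the smallest scale at which bundles, lesions and
clusters stay distinguishable while 10,000-permutation analyses remain
fast). The grid affine maps *voxel-box corners* to world mm: voxel `v`
occupies the half-open box `[v, v+1)` in voxel coordinates, so a point
lying exactly on a shared face belongs to the higher-index voxel.

Streamline-to-voxel assignment is exact 3-D digital differential
analysis: each polyline segment is cut at every integer plane crossing
and each sub-interval midpoint is floored to a voxel index (segment
endpoints included). This registers every voxel whose box the segment
genuinely intersects, including corner cuts of arbitrarily small chord
length — the test suite adjudicates such voxels against an independent
slab-clipping chord computation, and checks the bulk of the set
against 0.01-voxel-step supersampling. A zero-length streamline maps
to its single containing voxel with a warning.

A streamline is **disconnected** by a lesion when its voxel set meets
the lesion's nonzero voxels. Derived quantities:

- *severity map*: per voxel, 100 × (disconnected traversing
  streamlines) / (all traversing streamlines); defined as 0 where no
  streamline passes (those voxels never enter analysis masks, avoiding
  0/0).
- *tract-wise severity*: per tract, the percentage of its streamlines
  disconnected.
- *lesion volume*: nonzero-voxel count × voxel volume (cm³), plus the
  lesion/brain voxel fraction as the brain-size-adjusted variant (the
  adjustment formula is not standardized; both numbers are reported).

Binarization of severity maps uses an inclusive ≥ threshold, default
10% with 1% and 20% as first-class variants; binary maps are nested
across these thresholds by construction.

## Voxel mapping (VLSM / VDSM)

Inclusion requires a voxel to be affected in at least `min_count`
patients (default 5 for lesion masks) or a fraction of the cohort
(default 5%, converted by ceiling — 35 patients at n = 697).

Each included voxel's 2×2 table (affected × outcome) is tested with
the one-tailed Liebermeister quasi-exact test in its standard
augmented-table form: the upper hypergeometric tail of the table
(a+1, b, c, d+1). Z = Φ⁻¹(1 − p), clipped to ±8.2 (≈ Φ⁻¹ of 1 − 1e-16)
so perfectly separating voxels stay finite; degenerate margins (no
affected patients, or no events) yield p = 1 and the negative cap.
Negative Z values are representable but only positive Z enters
significance, matching the one-tailed design.

Both multiplicity controls come from one label-permutation engine
(maps are never modified, only the outcome vector is permuted by a
seeded generator; margins are preserved, so a single (k, a) → Z lookup
table serves all permutations):

- **FWE threshold**: the empirical (1 − α) quantile (upper method) of
  the per-permutation maximum Z over included voxels; α defaults to
  0.05.
- **Cluster-extent threshold**: per permutation the Z map is
  thresholded at the cluster-forming Z (p < 0.001), connected
  components are labelled, and the maximum component size recorded;
  the minimal cluster size is the smallest integer exceeding the 95th
  percentile of that null.

Cluster connectivity is 26-neighbour by default (6-neighbour
selectable and recorded in outputs). Surviving clusters are relabelled
in decreasing size order, ties broken by peak Z.

The identical machinery runs on lesion masks (VLSM), binarized
disconnection maps (VDSM), and any of the 14 binary symptom flags
(symptom-level VDSM; single-class symptoms are skipped with a warning).

## SDC score

For a patient with continuous severity map s(v), the raw score is
Σ_v z(v) · s(v)/100 over significant-cluster voxels v. Severities
enter as fractions; any positive rescaling would be absorbed by the
downstream regression coefficient, so this is a reporting convention
(recorded in outputs). The analysis scale is ln(1 + raw): defined at
zero (patients whose severity map misses every significant voxel score
exactly 0), monotone and order-preserving. Risk tertiles cut the score
at the 1/3 and 2/3 empirical quantiles with ties assigned to the lower
group; a fully tied score vector collapses to a single "low" group
with a warning.

In split-half runs each score records the identifier of the mapping it
came from, and the scorer refuses to score a patient against a mapping
whose training sample contained them. Tertiles for risk stratification
are computed on the pooled cross-fitted scores of the whole sample,
using the transformed scores.

## Outcome models and comparisons

Logistic fits are Newton/IRLS with step-halving (monotone likelihood),
convergence at likelihood change < 1e-10 and Newton step < 1e-6, a
coefficient-magnitude guard of 40 against separation, and Wald 95% CIs
on the log-odds scale. Categorical predictors are reference-coded
(sex: male; lesion localization: left hemispheric). Model 1 is the
log-SDC score alone; Model 2 adds imaging covariates (timing of
imaging, lesion localization, lesion volume); Model 3 adds all
remaining sociodemographic, clinical and psychological covariates. The
basic prediction model uses the 8 literature predictors (stroke
severity, disability, cognition, age, sex, education, neuroticism,
extraversion); enhanced adds the SDC score. Events-per-variable ≤ 10
triggers a warning; VIFs come from per-column auxiliary OLS
regressions.

Model comparison:

- **AUC**: rank-based concordance with ties counted one half.
- **Category-free NRI**: net up-classification among events plus net
  down-classification among non-events (exact ties contribute
  nothing); asymptotic SE from the two independent binomial-style
  variance terms; range −2..2.
- **IDI**: difference in discrimination slopes; SE from the paired
  per-patient differences.
- **Dominance analysis**: full 2^p subset enumeration with McFadden's
  pseudo-R² as fit statistic; general dominance averages a
  predictor's incremental contribution within subset sizes and then
  across sizes, and the values sum to the full-model R² (asserted to
  1e-10). Capped at 15 predictors. The two split directions'
  dominance vectors are combined by arithmetic mean.

Group comparisons use the tie-corrected normal-approximation rank-sum
test (two groups), Kruskal–Wallis (three risk groups), and Pearson
chi-square without continuity correction — the form that reproduces
published 2×2 worked examples. Tract-wise p-values are adjusted by
Benjamini–Hochberg step-up across all tracts.

If a half-sample mapping yields no significant clusters, the opposite
half's scores are identically zero; the enhanced model then collapses
onto the basic model (NRI = IDI = 0) and the per-half adjusted odds
ratio is reported as NaN rather than fabricated.

## Synthetic cohort generator

The generator is the package's study bed, not a brain model. It
produces:

- an atlas of `n_tracts` bundles (default 8 × 50 streamlines), each a
  cubic-spline curve through a distinct face-to-face corridor with
  per-streamline control-point jitter (3 mm), clipped to the grid;
  requesting more corridors than the grid can host fails explicitly;
- ellipsoidal single-component lesions with radii drawn from 6–16 mm;
  a configurable fraction (default 0.5) is centred on planted-tract
  streamline points and therefore intersects the planted corridor,
  while the remainder is rejection-sampled to miss it — so a fraction
  of 0 guarantees zero planted exposure;
- covariates with realistic marginals (median NIHSS 3, skewed; BI
  negatively coupled to NIHSS as the one deliberate collinearity for
  VIF testing; ~21% female; median age 59) but otherwise mutually
  independent;
- outcomes from logit p = β₀ + β_SDC · exposure + β'·(standardized
  covariates), where exposure is the mean disconnection *fraction*
  over the planted tracts (so β_SDC = 2 spans log-odds 2 between no
  and complete planted disconnection). β₀ defaults to logit(0.278), a
  realistic three-month PSD base rate. The HDRS-like total is drawn so
  the ≥ 10 cutoff reproduces the binary outcome exactly; 5 of 14
  symptom flags are coupled to disconnection exposure (configurable
  per-symptom tract coupling), 9 are independent noise.

Three independent random streams (atlas / lesions / outcomes) derive
from the master seed, so changing the cohort size never perturbs the
atlas. Identical configurations give byte-identical studies.

What the generator does **not** emulate: real brain geometry or
gray/white segmentation, hemispheric aphasia-exclusion bias,
population lesion-size distributions, or any claim about the true
generative model of depression. Calibration results on synthetic
cohorts (e.g. family-wise error rates, planted-pattern recovery)
therefore validate the *statistical machinery*, not clinical effect
sizes. Note that with a planted effect present, simulated cohort
prevalence sits above the β₀ base rate (≈ 40% at the defaults).

## Problem sizes and determinism

Default analyses in the test suite and acceptance script use a
24³-voxel grid (16³ for null-calibration batches), cohorts of 120–400
patients, 8 × 50 streamlines, and 500–1,000 permutations; the
permutation count is a parameter and 10,000 (the production setting)
changes only runtime. All seeds are explicit; the end-to-end pipeline
serializes to byte-identical JSON for a fixed configuration and seed,
with wall-clock timings excluded from the comparison.

## Known limitations

- The disconnectome is estimated from an atlas with the lesion
  embedded; it is a proxy for, not a measurement of, individual
  structural disconnection.
- Mass-univariate voxel tests inherit the usual caveats of
  lesion-symptom mapping (correlated lesion anatomy, uneven spatial
  power); crossing tracts of a planted corridor pick up association
  by shared lesion exposure, visible in the tract-wise results.
- The quantile rule for the cluster-extent null (95th percentile,
  smallest exceeding integer) and the 26-neighbour connectivity are
  conventions; both are recorded in output sidecars.
- Dominance analysis is exponential in the predictor count and is
  capped at 15 predictors.
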
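# Methods

## The models

`deprivix` implements a family of Bayesian *weighted quantile index*
logistic regressions for case-control data, together with the spatial
machinery needed to ask whether residual disease risk clusters in
space and whether measured exposures or selection bias can explain
such clusters.

### Weighted quantile indices

Every exposure variable is converted to an integer decile score
q ∈ {0, …, 9} over the pooled analytic sample (cases + controls).  An
index over C component variables is the weighted sum Σ_j w_j q_ij with
weights on the probability simplex under a Dirichlet(α) prior
(α_j = 1 by default, configurable).  The crude model is

    logit(p_i) = β0 + β1 Σ_j w_j1 q_ij1,

with a single index over the 11 block-group socioeconomic variables —
the neighborhood deprivation index (NDI).  Per-capita income, median
house value and median gross rent are rank-reversed first so every
component increases with deprivation.  β1 is the log-odds of case
status per one-decile increase of the weighted index; "OR per unit
increase in the NDI" refers to exp(β1).  The adjusted model adds
individual covariates z_i (child age and sex, ethnicity, household
income, mother's education and age, residence-since-birth, with
reference levels non-Hispanic White, income <$15,000 and
none/elementary education; a "missing" income level is kept as its own
category).  The chemical-mixture model adds seven more indices, one
per chemical class (PCBs, PAHs, insecticides, herbicides, metals,
tobacco markers, PBDEs; 67 analytes), each with its own effect β_k and
simplex weights — the grouped-index approach for correlated mixtures.

Effect priors are β ~ Normal(0, σ²) with σ ~ Uniform(0, 100) — each
index effect carries its own σ, the covariate block shares one, and
the intercept gets Normal(0, 1000²).  These are weakly informative at
the scale of log odds; their exact form is immaterial to the fits.

Chemical preprocessing: analytes observed in fewer than 20% of
subjects are dropped (inclusive threshold); remaining missing values
are imputed from per-analyte log-normal fits estimated by maximum
likelihood with below-detection-limit entries treated as left-censored
at the limit.  Below-LOD entries are imputed from the fit truncated
above at the LOD, not-measured entries from the untruncated fit.

### Spatial random effects and exceedance

The spatial model adds a per-subject exchangeable effect
u_i ~ Normal(0, σ_u²), σ_u ~ Uniform(0, 100), and a structured effect
v ~ MVN(0, Σ(ψ)) with Σ_ij = exp(−ψ d_ij) over pairwise residence
distances in km and ψ ~ Uniform(0.1, 1).  Note Σ is a correlation
matrix: v has unit marginal variance by construction.  A subject's
spatial odds is θ_i = exp(v_i); the exceedance probability q_i is the
posterior frequency of θ_i > 1 (strict inequality; the distinction is
measure-zero for continuous draws), and subjects with q_i ≥ 0.90 form
the elevated-risk area, summarized by its convex hull.

Geographic inputs in lon/lat are projected to a local planar km frame
(equirectangular about the centroid) before any distance or area
computation; the synthetic generator emits planar km directly.
Duplicate residences are jittered by ~1 m (logged) so Σ stays positive
definite; a small escalating ridge is added only if the Cholesky
factorization still fails.

### Cluster detection without covariates

Two standard detectors support the selection-bias study:

* **Bernoulli circular scan.** Circles centered at every subject grow
  through successive nearest neighbors up to half the sample; the
  Bernoulli likelihood ratio of case membership inside vs outside is
  maximized over all circles (high-rate circles only).  Significance
  is the Monte Carlo rank of the observed maximum among n_mc = 999
  label relabelings, p = rank/(n_mc + 1), significant below 0.05.
  Only the most likely cluster is reported.
* **BYM with ICAR prior.** logit(p_i) = β0 + u_i + v_i with a flat
  intercept prior, σ_u ~ Uniform(0, 10), and an intrinsic conditional
  autoregressive prior on v over the adjacency graph of the subjects'
  Voronoi cells (cells clipped to the bounding box padded by 10% so
  outer cells are finite; adjacency = shared boundary of positive
  length), τ_v ~ Gamma(0.001, 0.001).  v is recentered to zero mean
  within each connected component every iteration; isolated subjects
  keep v = 0 and rely on u alone.  Defaults: 2 chains, 15,000 burn-in,
  20,000 retained draws; the cluster is the set with posterior
  Pr(v_i > 0) > 0.90.

### Selection-bias augmentation

Given participation counts (eligible vs participating cases and
controls), the simulator adds pseudo-participants up to full
eligibility: a census tract is drawn with replacement by tract weight,
then a residence uniformly within the tract polygon.  Pseudo-case
weights use the population decile only.  Pseudo-control weights use
the product of the deciles for population, income deprivation
(max(income) − income) and education deprivation (percent without a
college degree) — the "equal" scheme — or apply the constants
(1, 1.5, 1.5) to those deciles — the "ses" scheme.  As printed, the
constants cancel after normalization, so the literal "ses" weights
equal the "equal" weights exactly; because the two schemes are
evidently meant to differ, a `power` variant (decile^1.5 for the two
deprivation deciles) is provided behind the `ses_variant`
configuration flag, defaulting to `literal`.  Neither reading is
asserted as the original intent.

Each augmented dataset is re-analyzed with the covariate-free
detectors (pseudo-subjects carry no covariates or chemicals), and the
presence, hull size (km²) and overlap with the observed reference
cluster are recorded; overlap percentage uses the simulated cluster's
hull as denominator.  Aggregates report the share of datasets with a
cluster, the median and 2.5/97.5-percentile interval of size and
overlap, and the share overlapping the reference.  The crude NDI model
can be refit to each augmented dataset, with pseudo-subjects taking
the SES values of the block group containing their sampled residence.

### Firth support

Univariate Firth-penalized logistic regression (penalty
½ log det I(β), Newton iterations with step-halving, convergence at
score norm < 1e-6 or 50 iterations) compares exposure effects inside a
detected risk area against the full sample.  Estimates are finite
under complete separation; 95% intervals use the profile penalized
likelihood with a logged Wald fallback.  One-class cluster subsets are
tolerated in the comparison table (the penalty keeps the fit finite)
and logged.

## Computation

All samplers are adaptive random-walk Metropolis-within-Gibbs schemes
written against numpy only.  Simplex weights are updated as a block on
the additive-log-ratio scale with the exact Dirichlet density plus
ALR Jacobian (the z-space target is Σ_j α_j log w_j + log-likelihood);
covariate effects are updated per coordinate with per-coordinate
adapted scales; proposal scales adapt toward standard acceptance
targets during burn-in only.  The structured spatial effect is updated
by elliptical slice sampling (three repeats per sweep); ψ by a random
walk on the logit of its bounded support in both centered and whitened
(fixed z = L⁻¹v) forms, refactorizing Σ on accepted moves; two
likelihood-invariant extra moves — a joint (β0, v) translation and a
random smooth-field exchange between u and v — accelerate mixing of
the weakly identified intercept/field-mean directions.  The BYM
structured effect is updated in conditionally independent color
classes of the adjacency graph (greedy coloring), with a conjugate
Gibbs draw for τ_v.

Default chain settings are 2 chains with 5,000/10,000
burn-in/retained draws for the index models and 10,000/10,000 for the
spatial models (all configurable); convergence is monitored by the
two-chain Gelman–Rubin statistic (weights diagnosed on the ALR
transform) with a 1.1 threshold — exceeding it sets a warning on the
returned samples rather than discarding them.  Tests and the
acceptance script use smaller problem sizes chosen so each experiment
completes in minutes on one core: recovery studies use 20 datasets of
n = 2,000 at 2 × 2,000 retained draws; spatial recovery uses 10
datasets of n = 600 at 1 × 900 retained draws after 1,500 burn-in;
the bias study uses 20 datasets per scheme with 199 scan relabelings
and 1,000/1,400 BYM draws.

### A note on σ_u identification

For individual-level Bernoulli outcomes, the per-subject exchangeable
effect u_i makes σ_u only weakly identified: integrating u out, a
subject whose linear predictor is ≈ 0 contributes a marginal
likelihood of exactly ½ for *any* σ_u, so in near-null designs the
σ_u posterior approaches its flat Uniform(0, 100) prior and mass at
large σ_u lets u absorb what the structured effect v would otherwise
capture, flattening exceedance probabilities.  (This can be verified
directly by Gauss–Hermite quadrature of the marginal likelihood as a
function of σ_u.)  The default sampler uses centered updates with
σ_u initialized at 0.5, which explores the small-σ_u region that the
exceedance surfaces are conditional on — matching how such models are
fit in practice with general-purpose Gibbs software.  An opt-in
partially marginalized move (`sigma_u_marginal_moves=True`), a joint
grid-proposal update of (σ_u, u, β0) with exact Hastings correction,
traverses the (σ_u, u) funnel and can be used to explore the full
posterior; under it, exceedance-based detection loses power in
near-null designs, which is a property of the model, not of the
sampler.  Fits with informative fixed effects pin σ_u and are not
affected to the same degree.

## The synthetic generator

The generator emulates the data *structure* the analysis assumes, not
any real place: a rectangular planar region (default 60 × 50 km) tiled
by jittered-Voronoi census tracts (default 100), each subdivided into
3–6 block groups; one latent deprivation surface with exponential
spatial covariance (range 25 km) drives tract median income and
education levels and all 11 block-group SES variables (single-factor
structure with independent noise, the premise under which a single
weighted index is well-defined); participant covariates are drawn
conditional on block-group deprivation, creating the confounding that
separates crude from adjusted estimates; chemicals are multivariate
log-normal within group with exchangeable correlation ρ = 0.6 and
left-censoring at per-analyte LODs placed at the 30th percentile.
Outcomes follow the logistic index model with configurable true
weights (default: 0.6 on Hispanic segregation, the rest uniform),
effects (default β1 = 0.4 per decile), covariate effects, and an
optional injected circular excess-risk area whose indicator can be
recorded as a measured risk factor.  Cases and controls are sampled
retrospectively from a large pool (rejecting configurations whose pool
cannot supply the requested counts); control participation can decay
with tract income-deprivation decile to emulate differential
participation.

The spatial-recovery experiments use a compact 30 × 25 km region so
that (a) the ψ ~ Uniform(0.1, 1) per-km decay prior implies
non-negligible correlation between neighboring subjects (spacing
≈ 1 km) and (b) a 5-km risk disk contains enough subjects (~50–100 of
600) for exceedance inference to be informative; with much sparser
geometry the disk holds ~25 subjects and no sampler can flag it
decisively.

What passing tests do **not** show about real data: the generator has
a single latent SES factor (real SES variables are multifactorial),
exchangeable within-group chemical correlation (real congener
correlation is structured), uniform residential density within block
groups (real density is clustered), and exact logistic outcomes (no
overdispersion or measurement error).  Recovery results are therefore
statements about internal consistency of the estimators, not about
field performance.

## Numerical choices and degenerate inputs

- Decile ties share the bin of their midrank (score
  ⌈10·midrank/n⌉ − 1); bins may be unequal under heavy ties; stored
  cut points allow scoring new data.  Variables with fewer than two
  distinct values are rejected.
- Scan LLR uses the convention 0·log 0 = 0 and reports only high-rate
  circles; p-values are rank-based with the +1 correction and can
  never be zero.
- Collinear point sets are rejected by the Voronoi adjacency;
  disconnected adjacency graphs are handled per component with
  islands carrying only exchangeable effects.
- Hull overlap of degenerate (empty or zero-area) polygons is 0.
- The censored log-normal MLE requires ≥3 observed positive values
  per analyte; Nelder–Mead on (μ, log σ) with censored-likelihood
  contributions.

## Known limitations

- The dense MVN prior on v limits the spatial model to roughly
  n ≤ 2,000 subjects (O(n³) refactorizations when ψ moves).
- Exceedance-based detection inherits the σ_u identification issue
  described above; its operating characteristics in near-null designs
  depend on the sampling regime.
- Only the most likely scan cluster is reported; secondary clusters,
  elliptic windows and the Poisson scan model are out of scope, as are
  approximate GP methods and spatio-temporal effects.
- The simulated-participant design cannot adjust for individual
  covariates or chemicals (none exist for pseudo-subjects); only the
  crude index model and covariate-free detection run on augmented
  data.
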
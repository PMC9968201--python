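"""Bayesian weighted-quantile index models for case-control data.

The central model expresses the log-odds of case status for subject *i*
as a linear function of one or more *weighted quantile indices*,

    logit(p_i) = beta_0 + sum_k beta_k (sum_j w_jk q_ijk) + z_i' phi,

where index k combines its C_k component variables through integer
decile scores q_ijk in {0, ..., 9} and nonnegative weights w_jk that lie
on the probability simplex under a Dirichlet prior.  beta_k is the
health effect of a one-decile increase in the weighted index, and the
posterior weights rank the relative importance of the components.  A
single index over area socioeconomic variables yields a neighborhood
deprivation index (NDI); additional indices over groups of correlated
chemical concentrations yield a grouped mixture analysis.

Priors follow the usual weakly-informative convention: each effect
beta ~ Normal(0, sigma^2) with sigma ~ Uniform(0, 100), and each weight
vector w_k ~ Dirichlet(alpha_k).  Estimation is by adaptive random-walk
Metropolis-within-Gibbs; weight vectors are updated as a block on the
additive-log-ratio scale with the exact Dirichlet density and Jacobian
correction, so no approximation to the simplex constraint is involved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# Variable coding
# ---------------------------------------------------------------------------

#: Block-group socioeconomic variables entering the deprivation index.
SES_VARIABLES = [
    "black_seg",
    "hisp_seg",
    "pct_poverty",
    "pct_public_assist",
    "pct_renters",
    "pct_no_hs",
    "pct_moved",
    "pct_foreign_born",
    "per_capita_income",
    "median_house_value",
    "median_gross_rent",
]

#: Variables whose natural direction decreases with deprivation; their rank
#: order is reversed so every component increases with deprivation.
REVERSED_SES_VARIABLES = [
    "per_capita_income",
    "median_house_value",
    "median_gross_rent",
]

# Individual covariate coding; the first level of each factor is the
# reference (non-Hispanic White, income <$15,000, none/elementary school).
ETHNICITY_LEVELS = ["nh_white", "hispanic", "nh_other"]
INCOME_LEVELS = ["lt15k", "15_29k", "30_44k", "45_59k", "60_74k", "ge75k", "missing"]
EDUCATION_LEVELS = ["none_elementary", "high_school", "some_college", "bachelor_plus"]


def orient_variables(blockgroups: pd.DataFrame) -> pd.DataFrame:
    """Negate the affluence-direction SES variables.

    ``per_capita_income``, ``median_house_value`` and ``median_gross_rent``
    decrease with deprivation; negating them reverses their rank order so
    that higher values of every component mean higher deprivation.
    Applying the operation twice restores the original rank order.
    """
    missing = [v for v in REVERSED_SES_VARIABLES if v not in blockgroups.columns]
    if missing:
        raise ValueError(f"missing reversed-orientation variables: {missing}")
    out = blockgroups.copy()
    for v in REVERSED_SES_VARIABLES:
        out[v] = -out[v]
    return out


def covariate_design(participants: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Build the individual-covariate design matrix (no intercept column).

    Factors are dummy-coded against the reference levels listed in the
    module constants; continuous covariates enter untransformed.
    """
    n = len(participants)
    cols: dict[str, np.ndarray] = {}
    cols["child_age"] = participants["child_age"].to_numpy(float)
    cols["female"] = participants["female"].to_numpy(float)
    eth = participants["ethnicity"].astype(str)
    for lev in ETHNICITY_LEVELS[1:]:
        cols[f"eth_{lev}"] = (eth == lev).to_numpy(float)
    inc = participants["household_income"].astype(str)
    for lev in INCOME_LEVELS[1:]:
        cols[f"inc_{lev}"] = (inc == lev).to_numpy(float)
    edu = participants["mother_education"].astype(str)
    for lev in EDUCATION_LEVELS[1:]:
        cols[f"edu_{lev}"] = (edu == lev).to_numpy(float)
    cols["mother_age"] = participants["mother_age"].to_numpy(float)
    cols["residence_since_birth"] = participants["residence_since_birth"].to_numpy(float)
    Z = np.column_stack([cols[c] for c in cols])
    assert Z.shape == (n, len(cols))
    return Z, list(cols)


# ---------------------------------------------------------------------------
# Chemical matrix preparation
# ---------------------------------------------------------------------------

def filter_chemicals(chemicals, min_nonmissing: float = 0.20):
    """Drop analytes observed in fewer than ``min_nonmissing`` of subjects.

    The threshold is inclusive: an analyte with exactly the minimum
    non-missing fraction is kept.  Returns ``(filtered, dropped)`` where
    ``dropped`` lists the removed analyte names.  ``chemicals`` is any
    object with ``values`` (DataFrame, NaN = missing), ``groups``,
    ``lods`` and ``reason`` attributes (see ``synthetic_data.ChemicalMatrix``).
    """
    frac = chemicals.values.notna().mean(axis=0)
    keep = frac[frac >= min_nonmissing].index.tolist()
    dropped = [a for a in chemicals.values.columns if a not in keep]
    if not keep:
        raise ValueError("all analytes fall below the non-missing threshold")
    if dropped:
        logger.info("filter_chemicals dropped %d analytes: %s", len(dropped), dropped)
    filtered = replace(
        chemicals,
        values=chemicals.values[keep],
        groups=chemicals.groups[keep],
        lods=chemicals.lods[keep],
        reason=chemicals.reason[keep],
    )
    return filtered, dropped


def _censored_lognormal_mle(obs_log: np.ndarray, n_cens: int, log_lod: float):
    """MLE of (mu, sigma) of a normal from observed logs plus ``n_cens``
    left-censored observations below ``log_lod``."""
    mu0, sd0 = obs_log.mean(), max(obs_log.std(ddof=0), 1e-3)
    if n_cens == 0:
        return mu0, sd0

    def nll(theta):
        mu, log_sd = theta
        sd = np.exp(log_sd)
        ll = stats.norm.logpdf(obs_log, mu, sd).sum()
        ll += n_cens * stats.norm.logcdf((log_lod - mu) / sd)
        return -ll

    res = optimize.minimize(nll, [mu0, np.log(sd0)], method="Nelder-Mead",
                            options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 2000})
    mu, sd = res.x[0], float(np.exp(res.x[1]))
    return mu, sd


def impute_lognormal(chemicals, seed: int):
    """Impute missing concentrations from per-analyte log-normal fits.

    For each analyte a normal distribution is fitted to the log
    concentrations by maximum likelihood, treating below-detection-limit
    entries as left-censored at the limit.  Below-LOD entries are then
    drawn from the fitted log-normal truncated above at the LOD;
    not-measured entries are drawn from the untruncated fit.  Observed
    values are untouched.  Returns a completed values DataFrame.
    """
    rng = np.random.default_rng(seed)
    values = chemicals.values.copy()
    for analyte in values.columns:
        col = values[analyte]
        obs = col.dropna()
        if len(obs) < 3:
            raise ValueError(f"analyte {analyte!r} has fewer than 3 observed values")
        if (obs <= 0).any():
            raise ValueError(f"analyte {analyte!r} has nonpositive observed values")
        reason = chemicals.reason[analyte]
        below = col.isna() & (reason == "below_lod")
        notmeas = col.isna() & (reason == "not_measured")
        if not (below.any() or notmeas.any()):
            continue
        log_lod = float(np.log(chemicals.lods[analyte])) if below.any() else -np.inf
        mu, sd = _censored_lognormal_mle(np.log(obs.to_numpy()), int(below.sum()), log_lod)
        if below.any():
            a = -np.inf
            b = (log_lod - mu) / sd
            draws = stats.truncnorm.rvs(a, b, loc=mu, scale=sd,
                                        size=int(below.sum()), random_state=rng)
            values.loc[below, analyte] = np.exp(draws)
        if notmeas.any():
            values.loc[notmeas, analyte] = np.exp(rng.normal(mu, sd, int(notmeas.sum())))
    return values


# ---------------------------------------------------------------------------
# Decile quantile scores
# ---------------------------------------------------------------------------

@dataclass
class QuantileMatrix:
    """Integer decile scores per subject and variable.

    ``scores`` holds values 0-9; ``cutpoints`` stores the nine empirical
    decile boundaries per variable for scoring new data; tied values share
    the bin of their midrank, so bins may be unequal under heavy ties.
    """

    scores: pd.DataFrame
    cutpoints: dict[str, np.ndarray]

    def apply(self, new_data: pd.DataFrame) -> pd.DataFrame:
        out = {}
        for col, cuts in self.cutpoints.items():
            v = new_data[col].to_numpy(float)
            out[col] = np.clip(np.searchsorted(cuts, v, side="right"), 0, 9)
        return pd.DataFrame(out, index=new_data.index)


def compute_deciles(values: pd.DataFrame, n_bins: int = 10) -> QuantileMatrix:
    """Assign decile scores 0..9 by midrank over the pooled sample.

    A value with midrank r among n observations scores
    ``ceil(n_bins * r / n) - 1``; ties therefore share one bin and the
    score of the smallest value is 0, of the largest n_bins-1.
    """
    scores = {}
    cutpoints = {}
    n = len(values)
    for col in values.columns:
        v = values[col].to_numpy(float)
        if len(np.unique(v)) < 2:
            raise ValueError(f"variable {col!r} has fewer than 2 distinct values")
        r = stats.rankdata(v, method="average")
        s = np.ceil(n_bins * r / n).astype(int) - 1
        scores[col] = np.clip(s, 0, n_bins - 1)
        cutpoints[col] = np.quantile(v, np.arange(1, n_bins) / n_bins)
    return QuantileMatrix(pd.DataFrame(scores, index=values.index), cutpoints)


# ---------------------------------------------------------------------------
# Model specification containers
# ---------------------------------------------------------------------------

@dataclass
class IndexTerm:
    """One weighted quantile index: name, component variables, decile
    scores (n x C) and Dirichlet concentration (C,)."""

    name: str
    variables: list[str]
    quantiles: np.ndarray
    alpha: np.ndarray

    def __post_init__(self):
        self.quantiles = np.asarray(self.quantiles, float)
        self.alpha = np.asarray(self.alpha, float)
        if self.quantiles.shape[1] != len(self.variables) or len(self.alpha) != len(self.variables):
            raise ValueError(f"index {self.name!r}: inconsistent dimensions")
        if np.any(self.alpha <= 0):
            raise ValueError(f"index {self.name!r}: Dirichlet concentration must be positive")


@dataclass
class ModelData:
    y: np.ndarray
    indices: list[IndexTerm]
    covariates: np.ndarray | None = None
    covariate_names: list[str] | None = None

    def __post_init__(self):
        self.y = np.asarray(self.y, float)
        if not set(np.unique(self.y)) <= {0.0, 1.0}:
            raise ValueError("outcome must be binary 0/1")
        if self.covariates is not None:
            self.covariates = np.asarray(self.covariates, float)
            if np.linalg.matrix_rank(
                np.column_stack([np.ones(len(self.y)), self.covariates])
            ) < self.covariates.shape[1] + 1:
                raise ValueError("covariate design matrix is rank deficient")


@dataclass
class McmcSettings:
    n_chains: int = 2
    n_burn: int = 5000
    n_save: int = 10000
    thin: int = 1
    seed: int = 0


@dataclass
class IndexModelSpec:
    """Prior and sampler settings for the index models."""

    alpha: float = 1.0            # Dirichlet concentration per component
    sigma_upper: float = 100.0    # upper bound of the Uniform prior on effect SDs
    rhat_threshold: float = 1.1
    mcmc: McmcSettings = field(default_factory=McmcSettings)


@dataclass
class PosteriorSamples:
    """MCMC output: one dict of draw arrays per chain.

    Scalar parameters are stored as (G,) arrays, weight vectors as (G, C).
    ``stacked`` concatenates chains for posterior summaries.
    """

    chains: list[dict[str, np.ndarray]]
    index_names: list[str]
    index_variables: dict[str, list[str]]
    covariate_names: list[str]
    accept_rates: dict[str, float] = field(default_factory=dict)
    warning: str | None = None

    def stacked(self, name: str) -> np.ndarray:
        return np.concatenate([c[name] for c in self.chains], axis=0)

    @property
    def parameter_names(self) -> list[str]:
        return list(self.chains[0])


# ---------------------------------------------------------------------------
# Sampler internals
# ---------------------------------------------------------------------------

def _softplus(x):
    return np.logaddexp(0.0, x)


def bernoulli_loglik(y, eta):
    """Log-likelihood of a logistic regression at linear predictor eta."""
    return float(np.sum(y * eta) - np.sum(_softplus(eta)))


def _alr_inv(z):
    """Inverse additive-log-ratio: z in R^(C-1) -> simplex point in R^C
    (last component is the reference)."""
    ez = np.exp(np.concatenate([z, [0.0]]))
    return ez / ez.sum()


class _AdaptiveScale:
    """Robbins-Monro step-size adaptation toward a target acceptance rate."""

    def __init__(self, scale=0.2, target=0.30):
        self.scale = scale
        self.target = target
        self.accepted = 0
        self.tried = 0

    def update(self, accepted: bool, adapt: bool):
        self.tried += 1
        self.accepted += accepted
        if adapt and self.tried % 50 == 0:
            rate = self.accepted / self.tried
            self.scale *= np.exp(1.5 * (rate - self.target))
            self.scale = float(np.clip(self.scale, 1e-4, 50.0))
            self.accepted = 0
            self.tried = 0

    @property
    def rate(self):
        return self.accepted / max(self.tried, 1)


class _FixedEffectsSampler:
    """State and update sweeps for the non-spatial part of the model.

    Maintains the fixed-effect linear predictor ``eta``; a caller-supplied
    ``offset`` (spatial random effects) is added at likelihood evaluation,
    which lets the spatial module reuse these updates unchanged.
    """

    def __init__(self, data: ModelData, spec: IndexModelSpec, rng: np.random.Generator,
                 prior_only: bool = False):
        self.y = data.y
        self.n = len(data.y)
        self.indices = data.indices
        self.Z = data.covariates
        self.spec = spec
        self.prior_only = prior_only

        self.beta0 = float(rng.normal(0.0, 0.5))
        self.beta = rng.normal(0.0, 0.5, len(self.indices))
        self.z_alr = [np.zeros(len(t.variables) - 1) for t in self.indices]
        self.w = [_alr_inv(z) for z in self.z_alr]
        self.comp = [t.quantiles @ w for t, w in zip(self.indices, self.w)]
        self.sigma_beta = np.full(len(self.indices), 10.0)
        if self.Z is not None:
            self.phi = rng.normal(0.0, 0.1, self.Z.shape[1])
            self.sigma_phi = 10.0
        else:
            self.phi = None
            self.sigma_phi = None
        self._refresh_eta()

        self.scales = {"beta0": _AdaptiveScale(0.1, 0.44)}
        for k, t in enumerate(self.indices):
            self.scales[f"beta[{k}]"] = _AdaptiveScale(0.1, 0.44)
            if len(t.variables) > 1:
                self.scales[f"w[{k}]"] = _AdaptiveScale(0.3, 0.234)
        if self.Z is not None:
            # per-coordinate scales: covariate columns differ in spread
            for j in range(self.Z.shape[1]):
                sd = max(float(self.Z[:, j].std()), 1e-3)
                self.scales[f"phi[{j}]"] = _AdaptiveScale(0.5 / sd / np.sqrt(self.n) * 10, 0.44)

    def _refresh_eta(self):
        eta = self.beta0 + np.zeros(self.n)
        for b, c in zip(self.beta, self.comp):
            eta = eta + b * c
        if self.Z is not None:
            eta = eta + self.Z @ self.phi
        self.eta = eta

    def loglik(self, eta, offset):
        if self.prior_only:
            return 0.0
        return bernoulli_loglik(self.y, eta + offset)

    def sweep(self, rng: np.random.Generator, offset, adapt: bool):
        ll = self.loglik(self.eta, offset)

        # intercept
        sc = self.scales["beta0"]
        prop = self.beta0 + sc.scale * rng.normal()
        eta_p = self.eta + (prop - self.beta0)
        ll_p = self.loglik(eta_p, offset)
        lprior = (prop**2 - self.beta0**2) / (2 * 1000.0**2)
        if np.log(rng.uniform()) < ll_p - ll - lprior:
            self.beta0, self.eta, ll = prop, eta_p, ll_p
            sc.update(True, adapt)
        else:
            sc.update(False, adapt)

        # index effects and weights
        for k, term in enumerate(self.indices):
            sc = self.scales[f"beta[{k}]"]
            prop = self.beta[k] + sc.scale * rng.normal()
            eta_p = self.eta + (prop - self.beta[k]) * self.comp[k]
            ll_p = self.loglik(eta_p, offset)
            dlp = -(prop**2 - self.beta[k] ** 2) / (2 * self.sigma_beta[k] ** 2)
            if np.log(rng.uniform()) < ll_p - ll + dlp:
                self.beta[k], self.eta, ll = prop, eta_p, ll_p
                sc.update(True, adapt)
            else:
                sc.update(False, adapt)

            if len(term.variables) > 1:
                sc = self.scales[f"w[{k}]"]
                z_p = self.z_alr[k] + sc.scale * rng.normal(size=len(self.z_alr[k]))
                w_p = _alr_inv(z_p)
                comp_p = term.quantiles @ w_p
                eta_p = self.eta + self.beta[k] * (comp_p - self.comp[k])
                ll_p = self.loglik(eta_p, offset)
                # Dirichlet(alpha) density on the simplex plus the ALR
                # Jacobian prod(w_j) gives sum(alpha_j log w_j) in z-space.
                dlp = float(term.alpha @ (np.log(w_p) - np.log(self.w[k])))
                if np.log(rng.uniform()) < ll_p - ll + dlp:
                    self.z_alr[k], self.w[k] = z_p, w_p
                    self.comp[k], self.eta, ll = comp_p, eta_p, ll_p
                    sc.update(True, adapt)
                else:
                    sc.update(False, adapt)

            # effect-SD hyperparameter: log-scale walk, Uniform(0,U) prior on sigma
            s = np.log(self.sigma_beta[k]) + 0.5 * rng.normal()
            sig_p = np.exp(s)
            if sig_p < self.spec.sigma_upper:
                cur = self.sigma_beta[k]
                dl = (-self.beta[k] ** 2 / (2 * sig_p**2)) - (-self.beta[k] ** 2 / (2 * cur**2))
                if np.log(rng.uniform()) < dl:
                    self.sigma_beta[k] = sig_p

        # covariate effects, one coordinate at a time
        if self.Z is not None:
            p = len(self.phi)
            for j in range(p):
                sc = self.scales[f"phi[{j}]"]
                prop = self.phi[j] + sc.scale * rng.normal()
                eta_p = self.eta + self.Z[:, j] * (prop - self.phi[j])
                ll_p = self.loglik(eta_p, offset)
                dlp = -(prop**2 - self.phi[j] ** 2) / (2 * self.sigma_phi**2)
                if np.log(rng.uniform()) < ll_p - ll + dlp:
                    self.phi[j], self.eta, ll = prop, eta_p, ll_p
                    sc.update(True, adapt)
                else:
                    sc.update(False, adapt)

            s = np.log(self.sigma_phi) + 0.5 * rng.normal()
            sig_p = np.exp(s)
            if sig_p < self.spec.sigma_upper:
                ssq = float(self.phi @ self.phi)
                dl = (1 - p) * (s - np.log(self.sigma_phi)) - ssq / 2 * (1 / sig_p**2 - 1 / self.sigma_phi**2)
                if np.log(rng.uniform()) < dl:
                    self.sigma_phi = sig_p
        return ll

    def record(self, store: dict, g: int):
        store["beta0"][g] = self.beta0
        for k, term in enumerate(self.indices):
            store[f"beta_{term.name}"][g] = self.beta[k]
            store[f"w_{term.name}"][g] = self.w[k]
            store[f"sigma_{term.name}"][g] = self.sigma_beta[k]
        if self.Z is not None:
            store["phi"][g] = self.phi
            store["sigma_phi"][g] = self.sigma_phi

    def allocate(self, G: int) -> dict[str, np.ndarray]:
        store = {"beta0": np.empty(G)}
        for term in self.indices:
            store[f"beta_{term.name}"] = np.empty(G)
            store[f"w_{term.name}"] = np.empty((G, len(term.variables)))
            store[f"sigma_{term.name}"] = np.empty(G)
        if self.Z is not None:
            store["phi"] = np.empty((G, self.Z.shape[1]))
            store["sigma_phi"] = np.empty(G)
        return store


def fit_index_model(spec: IndexModelSpec, data: ModelData,
                    prior_only: bool = False) -> PosteriorSamples:
    """Fit a Bayesian weighted-quantile index model by MCMC.

    Runs ``spec.mcmc.n_chains`` independent adaptive Metropolis-within-
    Gibbs chains and returns the retained draws.  Convergence is assessed
    with the Gelman-Rubin statistic on the effect parameters; a value
    above ``spec.rhat_threshold`` sets the ``warning`` field (the samples
    are still returned, never silently discarded).

    With ``prior_only=True`` the likelihood is flat and the draws target
    the prior — useful for prior-predictive checks.
    """
    mc = spec.mcmc
    ss = np.random.SeedSequence(mc.seed)
    chain_seeds = ss.spawn(mc.n_chains)
    chains = []
    accept = {}
    for c in range(mc.n_chains):
        rng = np.random.default_rng(chain_seeds[c])
        state = _FixedEffectsSampler(data, spec, rng, prior_only=prior_only)
        store = state.allocate(mc.n_save)
        for it in range(mc.n_burn):
            state.sweep(rng, 0.0, adapt=True)
        for g in range(mc.n_save):
            for _ in range(mc.thin):
                state.sweep(rng, 0.0, adapt=False)
            state.record(store, g)
        chains.append(store)
        for k, sc in state.scales.items():
            accept[f"chain{c}:{k}"] = sc.rate

    samples = PosteriorSamples(
        chains=chains,
        index_names=[t.name for t in data.indices],
        index_variables={t.name: t.variables for t in data.indices},
        covariate_names=data.covariate_names or [],
        accept_rates=accept,
    )
    if mc.n_chains >= 2:
        diag = gelman_rubin(samples)
        core = {k: v for k, v in diag.items() if k.startswith("beta")}
        bad = {k: v for k, v in core.items() if np.isfinite(v) and v > spec.rhat_threshold}
        if bad:
            samples.warning = f"Gelman-Rubin above {spec.rhat_threshold}: {bad}"
            logger.warning(samples.warning)
    return samples


# ---------------------------------------------------------------------------
# Posterior summaries and diagnostics
# ---------------------------------------------------------------------------

def rhat(chains: np.ndarray) -> float:
    """Potential scale reduction factor for one scalar parameter.

    ``chains`` is an (m, n) array of m chains with n draws each; the
    classic between/within-variance formula is used.  Returns NaN when
    the within-chain variance is zero.
    """
    chains = np.asarray(chains, float)
    m, n = chains.shape
    means = chains.mean(axis=1)
    W = chains.var(axis=1, ddof=1).mean()
    if W <= 0 or not np.isfinite(W):
        return float("nan")
    B = n * means.var(ddof=1)
    var_plus = (n - 1) / n * W + B / n
    return float(np.sqrt(var_plus / W))


def gelman_rubin(samples: PosteriorSamples) -> dict[str, float]:
    """Per-parameter Gelman-Rubin statistics across chains.

    Weight vectors are diagnosed on the additive-log-ratio transform
    (log w_j / w_C), which removes the simplex constraint.
    """
    if len(samples.chains) < 2:
        raise ValueError("Gelman-Rubin requires at least two chains")
    lens = {len(c["beta0"]) for c in samples.chains}
    if len(lens) != 1:
        raise ValueError("chains must have equal length")
    out: dict[str, float] = {}
    for name in samples.parameter_names:
        arrs = [c[name] for c in samples.chains]
        if arrs[0].ndim == 1:
            out[name] = rhat(np.stack(arrs))
        else:
            C = arrs[0].shape[1]
            if name.startswith("w_"):
                idx_name = name[2:]
                labels = samples.index_variables.get(idx_name, [str(j) for j in range(C)])
                for j in range(C - 1):
                    tr = [np.log(a[:, j]) - np.log(a[:, C - 1]) for a in arrs]
                    out[f"{name}[{labels[j]}/{labels[C-1]}]"] = rhat(np.stack(tr))
            else:
                for j in range(C):
                    out[f"{name}[{j}]"] = rhat(np.stack([a[:, j] for a in arrs]))
    return out


def summarize_index(samples: PosteriorSamples, index: str):
    """Odds-ratio summary and posterior weight profile for one index.

    The OR for a one-decile increase in the index is exp(beta); the table
    reports the posterior mean of the OR with an equal-tailed 95%
    credible interval from the 2.5 and 97.5 percentiles of the OR draws.
    """
    draws = samples.stacked(f"beta_{index}")
    or_draws = np.exp(draws)
    lo, hi = np.percentile(or_draws, [2.5, 97.5])
    w = samples.stacked(f"w_{index}")
    profile = pd.Series(w.mean(axis=0), index=samples.index_variables[index], name="weight")
    return {
        "index": index,
        "or_mean": float(or_draws.mean()),
        "or_lower": float(lo),
        "or_upper": float(hi),
        "beta_mean": float(draws.mean()),
        "beta_sd": float(draws.std(ddof=1)),
        "weights": profile,
    }


def summary_table(samples: PosteriorSamples) -> pd.DataFrame:
    """OR table over all indices and covariates (Table 1/2 style layout)."""
    rows = []
    for name in samples.index_names:
        s = summarize_index(samples, name)
        rows.append({"variable": name, "odds_ratio": s["or_mean"],
                     "ci_lower": s["or_lower"], "ci_upper": s["or_upper"]})
    if samples.covariate_names:
        phi = samples.stacked("phi")
        for j, cov in enumerate(samples.covariate_names):
            d = np.exp(phi[:, j])
            lo, hi = np.percentile(d, [2.5, 97.5])
            rows.append({"variable": cov, "odds_ratio": float(d.mean()),
                         "ci_lower": float(lo), "ci_upper": float(hi)})
    return pd.DataFrame(rows)


def save_posterior(samples: PosteriorSamples, outdir, prefix: str = "fit") -> None:
    """Write posterior draws (one CSV per chain) and a summary JSON with
    ORs, credible intervals, weight profiles and Gelman-Rubin statistics."""
    import json
    import pathlib

    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for c, chain in enumerate(samples.chains):
        cols = {}
        for name, arr in chain.items():
            if arr.ndim == 1:
                cols[name] = arr
            else:
                if name.startswith("w_"):
                    labels = samples.index_variables.get(name[2:])
                elif name == "phi":
                    labels = samples.covariate_names
                else:
                    labels = None
                for j in range(arr.shape[1]):
                    lab = labels[j] if labels else str(j)
                    cols[f"{name}[{lab}]"] = arr[:, j]
        pd.DataFrame(cols).to_csv(outdir / f"{prefix}_chain{c + 1}.csv", index=False)

    summary = {"indices": {}, "gelman_rubin": None}
    for name in samples.index_names:
        s = summarize_index(samples, name)
        summary["indices"][name] = {
            "or_mean": s["or_mean"], "or_lower": s["or_lower"],
            "or_upper": s["or_upper"], "weights": s["weights"].to_dict(),
        }
    if len(samples.chains) >= 2:
        summary["gelman_rubin"] = {k: (None if not np.isfinite(v) else v)
                                   for k, v in gelman_rubin(samples).items()}
    if samples.warning:
        summary["warning"] = samples.warning
    with open(outdir / f"{prefix}_summary.json", "w") as fh:
        json.dump(summary, fh, indent=1)


# ---------------------------------------------------------------------------
# Model-data assembly
# ---------------------------------------------------------------------------

def build_model_data(
    participants: pd.DataFrame,
    blockgroups: pd.DataFrame,
    chemicals: pd.DataFrame | None = None,
    chemical_groups: pd.Series | None = None,
    model: str = "crude",
    alpha: float = 1.0,
    extra_covariates: list[str] | None = None,
) -> ModelData:
    """Assemble outcome, decile indices and covariates for a model fit.

    ``model`` selects the structure: ``crude`` (NDI only), ``adjusted``
    (NDI + individual covariates) or ``chemicals`` (NDI + seven chemical
    group indices + covariates).  ``chemicals`` must be a completed
    (imputed) concentration DataFrame aligned to ``participants`` rows,
    with ``chemical_groups`` mapping analyte -> group name.
    ``extra_covariates`` appends numeric columns of ``participants`` to
    the covariate design (used e.g. for a recorded risk factor).
    """
    if model not in {"crude", "adjusted", "chemicals"}:
        raise ValueError(f"unknown model {model!r}")
    y = participants["y"].to_numpy(float)

    ses = participants[["bg_id"]].merge(
        blockgroups[["bg_id"] + SES_VARIABLES], on="bg_id", how="left", validate="many_to_one"
    )
    if ses[SES_VARIABLES].isna().any().any():
        missing = ses[ses[SES_VARIABLES].isna().any(axis=1)]["bg_id"].unique()
        raise ValueError(f"participants reference unknown block groups: {missing[:5]}")
    oriented = orient_variables(ses[SES_VARIABLES])
    q_ndi = compute_deciles(oriented).scores.to_numpy(float)
    indices = [IndexTerm("NDI", SES_VARIABLES, q_ndi, np.full(len(SES_VARIABLES), alpha))]

    if model == "chemicals":
        if chemicals is None or chemical_groups is None:
            raise ValueError("chemicals model requires a completed chemical matrix and groups")
        q_chem = compute_deciles(chemicals).scores
        for group in pd.unique(chemical_groups):
            members = [a for a in chemicals.columns if chemical_groups[a] == group]
            indices.append(IndexTerm(group, members,
                                     q_chem[members].to_numpy(float),
                                     np.full(len(members), alpha)))

    Z = None
    names = None
    if model in {"adjusted", "chemicals"}:
        Z, names = covariate_design(participants)
    if extra_covariates:
        extra = participants[extra_covariates].to_numpy(float)
        if Z is None:
            Z, names = extra, list(extra_covariates)
        else:
            Z = np.column_stack([Z, extra])
            names = names + list(extra_covariates)
    return ModelData(y=y, indices=indices, covariates=Z, covariate_names=names)
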
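"""Index models with subject-level spatial random effects.

Augments the weighted-quantile index model with an exchangeable effect
u_i ~ Normal(0, sigma_u^2) and a distance-correlated effect
v ~ MVN(0, Sigma(psi)) with Sigma_ij = exp(-psi * d_ij) over the
pairwise distances between residences (planar km).  The decay rate has
prior psi ~ Uniform(0.1, 1) and sigma_u ~ Uniform(0, 100).

Areas of elevated risk are read off the posterior of the spatial odds
theta_i = exp(v_i): the exceedance probability q_i is the posterior
frequency of theta_i > 1, and subjects with q_i >= 0.90 are flagged.
The structured effect v is updated by elliptical slice sampling under
its multivariate normal prior; psi by a random walk on the logit of its
bounded support, with the correlation matrix refactorized on each
accepted move.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import solve_triangular
from scipy.spatial.distance import cdist
from shapely.geometry import MultiPoint

from .index_models import (
    IndexModelSpec,
    McmcSettings,
    ModelData,
    PosteriorSamples,
    _FixedEffectsSampler,
    gelman_rubin,
)

logger = logging.getLogger(__name__)


@dataclass
class SpatialPriorSpec:
    psi_bounds: tuple[float, float] = (0.1, 1.0)
    sigma_u_upper: float = 100.0
    exceedance_threshold: float = 0.90

    def __post_init__(self):
        lo, hi = self.psi_bounds
        if not (0 < lo < hi):
            raise ValueError("psi bounds must be positive and ordered")


@dataclass
class SpatialEffects:
    """Posterior spatial-effect output.

    ``v_draws`` stacks post-burn-in draws of the structured effect over
    all chains (G_total x n); ``exceedance`` is the per-subject posterior
    frequency that exp(v_i) exceeds 1, and ``flagged`` marks subjects at
    or above the threshold.
    """

    v_draws: np.ndarray
    psi_draws: np.ndarray
    sigma_u_draws: np.ndarray
    exceedance: np.ndarray
    flagged: np.ndarray
    threshold: float = 0.90

    @property
    def theta_mean(self) -> np.ndarray:
        return np.exp(self.v_draws).mean(axis=0)


def project_lonlat_to_km(lon: np.ndarray, lat: np.ndarray) -> np.ndarray:
    """Project geographic coordinates to a local planar km frame
    (equirectangular about the centroid; adequate for study-region scales)."""
    lon, lat = np.asarray(lon, float), np.asarray(lat, float)
    lat0, lon0 = lat.mean(), lon.mean()
    x = np.radians(lon - lon0) * 6371.0 * np.cos(np.radians(lat0))
    y = np.radians(lat - lat0) * 6371.0
    return np.column_stack([x, y])


def _dedupe_coords(coords: np.ndarray, jitter_km: float = 1e-3) -> np.ndarray:
    """Jitter exact duplicate residences by ~1 m so the correlation matrix
    stays positive definite; deterministic and logged."""
    coords = np.asarray(coords, float).copy()
    _, inverse, counts = np.unique(coords, axis=0, return_inverse=True, return_counts=True)
    dup = counts[inverse] > 1
    if dup.any():
        logger.warning("jittering %d duplicate residence coordinates by %g km",
                       int(dup.sum()), jitter_km)
        rng = np.random.default_rng(12345)
        coords[dup] += rng.normal(0.0, jitter_km, (int(dup.sum()), 2))
    return coords


def exponential_covariance(coords: np.ndarray, psi: float) -> np.ndarray:
    """Correlation matrix Sigma_ij = exp(-psi * d_ij) over planar km
    coordinates; unit diagonal and symmetric by construction."""
    if psi <= 0:
        raise ValueError("psi must be positive")
    d = cdist(coords, coords)
    return np.exp(-psi * d)


def _chol_with_ridge(S: np.ndarray) -> np.ndarray:
    ridge = 0.0
    for _ in range(6):
        try:
            return np.linalg.cholesky(S + ridge * np.eye(len(S)))
        except np.linalg.LinAlgError:
            ridge = 1e-10 if ridge == 0 else ridge * 100
            logger.warning("Cholesky failed; adding ridge %g", ridge)
    raise np.linalg.LinAlgError("correlation matrix not positive definite after ridge policy")


def _mvn_logpdf_chol(v: np.ndarray, L: np.ndarray) -> float:
    w = solve_triangular(L, v, lower=True)
    return float(-0.5 * w @ w - np.log(np.diag(L)).sum() - 0.5 * len(v) * np.log(2 * np.pi))


def exceedance(v_draws: np.ndarray) -> np.ndarray:
    """Posterior exceedance probability per subject: the fraction of
    draws with spatial odds exp(v_i) strictly above 1."""
    v_draws = np.atleast_2d(np.asarray(v_draws, float))
    return (v_draws > 0.0).mean(axis=0)


class _SpatialChain:
    """One chain of the spatial sampler: fixed effects by delegation,
    u by vectorized sitewise Metropolis, v by elliptical slice, psi by
    bounded random walk with refactorization."""

    def __init__(self, data: ModelData, spec: IndexModelSpec, sp: SpatialPriorSpec,
                 coords: np.ndarray, rng: np.random.Generator,
                 fix_u_zero=False, fix_v_zero=False, psi_every: int = 5,
                 ess_repeats: int = 3, sigma_u_marginal_moves: bool = False):
        self.core = _FixedEffectsSampler(data, spec, rng)
        self.sp = sp
        self.coords = coords
        self.n = len(coords)
        self.y = data.y
        self.fix_u = fix_u_zero
        self.fix_v = fix_v_zero
        self.psi_every = psi_every
        self.ess_repeats = ess_repeats
        # Opt-in: sigma_u is weakly identified for per-subject Bernoulli
        # effects (its marginal likelihood is flat under a near-null linear
        # predictor), and these moves let the chain follow the flat prior
        # ridge to large sigma_u.  The default reproduces the conventional
        # centered updates, which explore the small-sigma_u regime that the
        # exceedance surfaces are conditional on; see the methods notes.
        self.sigma_u_marginal_moves = sigma_u_marginal_moves
        self.it = 0

        lo, hi = sp.psi_bounds
        self.psi = float(rng.uniform(lo, hi))
        self.L = _chol_with_ridge(exponential_covariance(coords, self.psi))
        self.v = np.zeros(self.n)
        self.u = np.zeros(self.n)
        self.sigma_u = 0.5
        self.u_scale = 0.5
        self.psi_scale = 0.5
        self.shift_scale = 0.2
        self.swap_scale = 0.2
        self.u_acc = []
        self.psi_acc = []
        self.shift_acc = []
        self.swap_acc = []

    # -- likelihood pieces -------------------------------------------------
    def _site_ll(self, eta):
        return self.y * eta - np.logaddexp(0.0, eta)

    def _ll_total(self, v):
        eta = self.core.eta + self.u + v
        return float(np.sum(self._site_ll(eta)))

    # -- updates -----------------------------------------------------------
    def _update_u(self, rng, adapt):
        prop = self.u + self.u_scale * rng.normal(size=self.n)
        eta0 = self.core.eta + self.u + self.v
        eta1 = self.core.eta + prop + self.v
        dll = self._site_ll(eta1) - self._site_ll(eta0)
        dlp = -(prop**2 - self.u**2) / (2 * self.sigma_u**2)
        acc = np.log(rng.uniform(size=self.n)) < dll + dlp
        self.u = np.where(acc, prop, self.u)
        rate = float(acc.mean())
        self.u_acc.append(rate)
        if adapt and len(self.u_acc) % 50 == 0:
            recent = float(np.mean(self.u_acc[-50:]))
            self.u_scale *= np.exp(1.5 * (recent - 0.44))
            self.u_scale = float(np.clip(self.u_scale, 1e-3, 10.0))

        # sigma_u, centered move: log random walk, Uniform(0, upper) prior
        s = np.log(self.sigma_u) + 0.3 * rng.normal()
        sig = float(np.exp(s))
        if sig < self.sp.sigma_u_upper:
            ssq = float(self.u @ self.u)
            dl = (1 - self.n) * (s - np.log(self.sigma_u)) \
                - ssq / 2 * (1 / sig**2 - 1 / self.sigma_u**2)
            if np.log(rng.uniform()) < dl:
                self.sigma_u = sig

    def _update_v_ess(self, rng):
        nu = self.L @ rng.normal(size=self.n)
        log_u = np.log(rng.uniform())
        ll0 = self._ll_total(self.v)
        theta = rng.uniform(0.0, 2 * np.pi)
        lo, hi = theta - 2 * np.pi, theta
        while True:
            v_new = self.v * np.cos(theta) + nu * np.sin(theta)
            if self._ll_total(v_new) > ll0 + log_u:
                self.v = v_new
                return
            if theta < 0:
                lo = theta
            else:
                hi = theta
            theta = rng.uniform(lo, hi)

    def _update_psi(self, rng, adapt):
        lo, hi = self.sp.psi_bounds
        t = np.log((self.psi - lo) / (hi - self.psi))
        t_prop = t + self.psi_scale * rng.normal()
        psi_prop = lo + (hi - lo) / (1 + np.exp(-t_prop))
        L_prop = _chol_with_ridge(exponential_covariance(self.coords, psi_prop))
        # Uniform prior on psi; logit-transform Jacobian (psi-lo)(hi-psi)
        lj = (np.log(psi_prop - lo) + np.log(hi - psi_prop)
              - np.log(self.psi - lo) - np.log(hi - self.psi))
        dl = _mvn_logpdf_chol(self.v, L_prop) - _mvn_logpdf_chol(self.v, self.L) + lj
        acc = np.log(rng.uniform()) < dl
        if acc:
            self.psi, self.L = psi_prop, L_prop
        self.psi_acc.append(float(acc))
        if adapt and len(self.psi_acc) % 25 == 0:
            recent = float(np.mean(self.psi_acc[-25:]))
            self.psi_scale *= np.exp(1.5 * (recent - 0.44))
            self.psi_scale = float(np.clip(self.psi_scale, 1e-3, 10.0))

    def _update_translation(self, rng, adapt):
        # joint (beta0 += d, v -= d) move: likelihood-invariant, targets the
        # weakly identified intercept/spatial-mean direction
        d = self.shift_scale * rng.normal()
        b0_new = self.core.beta0 + d
        v_new = self.v - d
        dlp = _mvn_logpdf_chol(v_new, self.L) - _mvn_logpdf_chol(self.v, self.L)
        dlp -= (b0_new**2 - self.core.beta0**2) / (2 * 1000.0**2)
        acc = np.log(rng.uniform()) < dlp
        if acc:
            self.core.beta0 = b0_new
            self.core.eta = self.core.eta + d
            self.v = v_new
        self.shift_acc.append(float(acc))
        if adapt and len(self.shift_acc) % 50 == 0:
            recent = float(np.mean(self.shift_acc[-50:]))
            self.shift_scale = float(np.clip(
                self.shift_scale * np.exp(1.5 * (recent - 0.44)), 1e-3, 10.0))

    def _update_sigma_u_joint(self, rng):
        """Joint (sigma_u, u) Metropolis with an independence proposal for u.

        A random-walk proposal for sigma_u is paired with a fresh draw of
        every u_i from a piecewise-constant grid approximation of its full
        conditional under the proposed sigma_u.  The Hastings ratio uses
        the exact grid proposal densities, so the move is valid at any
        grid resolution; it decouples sigma_u from the current u and lets
        the chain traverse the (sigma_u, u) funnel in both directions.
        """
        lo_t = np.log(self.sigma_u) + 0.6 * rng.normal()
        sig_p = float(np.exp(lo_t))
        if not 0 < sig_p < self.sp.sigma_u_upper:
            return
        b0_cur = self.core.beta0
        eta_nob0 = self.core.eta - b0_cur + self.v
        K = 81
        from numpy.polynomial.hermite_e import hermegauss

        gh_x, gh_w = hermegauss(31)
        gh_w = gh_w / gh_w.sum()

        def profile_b0(sig):
            # intercept maximizing the u-marginalized likelihood at this sigma
            from scipy.optimize import minimize_scalar

            def nll(b0):
                ll = eta_nob0[:, None] + b0 + sig * gh_x[None, :]
                m = (gh_w[None, :]
                     * np.exp(self.y[:, None] * ll - np.logaddexp(0.0, ll))).sum(axis=1)
                return -float(np.log(np.maximum(m, 1e-300)).sum())

            return minimize_scalar(nll, bounds=(b0_cur - 6, b0_cur + 6),
                                   method="bounded", options={"xatol": 1e-3}).x

        b0_star_p = profile_b0(sig_p)
        b0_prop = b0_star_p + 0.25 * rng.normal()

        def grid_and_logw(sig, b0):
            half = 6.0 * sig
            edges = np.linspace(-half, half, K + 1)
            mids = 0.5 * (edges[:-1] + edges[1:])
            e = eta_nob0[:, None] + b0 + mids[None, :]
            lw = self.y[:, None] * e - np.logaddexp(0.0, e) \
                - mids[None, :] ** 2 / (2 * sig**2)
            return edges, lw

        def logq_of(u, edges, lw):
            width = edges[1] - edges[0]
            lse = np.logaddexp.reduce(lw, axis=1)
            idx = np.clip(np.searchsorted(edges, u, side="right") - 1, 0, K - 1)
            inside = (u >= edges[0]) & (u <= edges[-1])
            lq = lw[np.arange(len(u)), idx] - lse - np.log(width)
            return float(np.where(inside, lq, -np.inf).sum())

        edges_p, lw_p = grid_and_logw(sig_p, b0_prop)
        lse_p = np.logaddexp.reduce(lw_p, axis=1)
        cum = np.cumsum(np.exp(lw_p - lse_p[:, None]), axis=1)
        r = rng.uniform(size=self.n)
        idx = (r[:, None] > cum).sum(axis=1)
        width = edges_p[1] - edges_p[0]
        u_prop = edges_p[np.clip(idx, 0, K - 1)] + width * rng.uniform(size=self.n)

        edges_c, lw_c = grid_and_logw(self.sigma_u, b0_cur)
        lq_fwd = logq_of(u_prop, edges_p, lw_p)
        lq_rev = logq_of(self.u, edges_c, lw_c)
        if not np.isfinite(lq_rev):
            return
        b0_star_c = profile_b0(self.sigma_u)
        lq_fwd += float(-0.5 * ((b0_prop - b0_star_p) / 0.25) ** 2)
        lq_rev += float(-0.5 * ((b0_cur - b0_star_c) / 0.25) ** 2)

        def log_target(u, sig, b0):
            eta = eta_nob0 + b0 + u
            ll = float(np.sum(self.y * eta - np.logaddexp(0.0, eta)))
            lp = float(-np.sum(u**2) / (2 * sig**2) - self.n * np.log(sig))
            lp += -b0**2 / (2 * 1000.0**2)
            return ll + lp + np.log(sig)   # log-scale RW Jacobian for sigma

        dl = (log_target(u_prop, sig_p, b0_prop)
              - log_target(self.u, self.sigma_u, b0_cur)
              + lq_rev - lq_fwd)
        if np.log(rng.uniform()) < dl:
            self.sigma_u = sig_p
            self.u = u_prop
            self.core.eta = self.core.eta + (b0_prop - b0_cur)
            self.core.beta0 = b0_prop

    def _update_psi_whitened(self, rng, adapt):
        # non-centered decay update: keep the whitened field z = L^-1 v
        # fixed, rebuild v under the proposed psi; the MVN prior cancels
        # exactly and only the likelihood ratio enters, which lets the
        # field amplitude rescale with the correlation range
        lo, hi = self.sp.psi_bounds
        t = np.log((self.psi - lo) / (hi - self.psi))
        t_prop = t + self.psi_scale * rng.normal()
        psi_prop = lo + (hi - lo) / (1 + np.exp(-t_prop))
        L_prop = _chol_with_ridge(exponential_covariance(self.coords, psi_prop))
        z = solve_triangular(self.L, self.v, lower=True)
        v_prop = L_prop @ z
        lj = (np.log(psi_prop - lo) + np.log(hi - psi_prop)
              - np.log(self.psi - lo) - np.log(hi - self.psi))
        dl = self._ll_total(v_prop) - self._ll_total(self.v) + lj
        if np.log(rng.uniform()) < dl:
            self.psi, self.L, self.v = psi_prop, L_prop, v_prop

    def _update_uv_swap(self, rng, adapt):
        # exchange mass between u and v along a random smooth field drawn
        # from v's prior; likelihood-invariant and symmetric (gamma and the
        # field are drawn afresh, so the reverse move is equally likely)
        s = self.L @ rng.normal(size=self.n)
        g = self.swap_scale * rng.normal()
        v_new = self.v + g * s
        u_new = self.u - g * s
        dlp = _mvn_logpdf_chol(v_new, self.L) - _mvn_logpdf_chol(self.v, self.L)
        dlp -= (u_new @ u_new - self.u @ self.u) / (2 * self.sigma_u**2)
        acc = np.log(rng.uniform()) < dlp
        if acc:
            self.v, self.u = v_new, u_new
        self.swap_acc.append(float(acc))
        if adapt and len(self.swap_acc) % 50 == 0:
            recent = float(np.mean(self.swap_acc[-50:]))
            self.swap_scale = float(np.clip(
                self.swap_scale * np.exp(1.5 * (recent - 0.30)), 1e-4, 10.0))

    def _update_u_translation(self, rng):
        # joint (beta0 += d, u -= d): the iid-effect mean is confounded
        # with the intercept in the same way as the spatial mean
        d = 0.5 * self.sigma_u / np.sqrt(self.n) * rng.normal() + \
            self.shift_scale * rng.normal()
        b0_new = self.core.beta0 + d
        u_new = self.u - d
        dlp = -((u_new @ u_new) - (self.u @ self.u)) / (2 * self.sigma_u**2)
        dlp -= (b0_new**2 - self.core.beta0**2) / (2 * 1000.0**2)
        if np.log(rng.uniform()) < dlp:
            self.core.beta0 = b0_new
            self.core.eta = self.core.eta + d
            self.u = u_new

    def sweep(self, rng, adapt):
        self.core.sweep(rng, self.u + self.v, adapt)
        if not self.fix_u:
            self._update_u(rng, adapt)
            if self.sigma_u_marginal_moves and self.it % 5 == 0:
                self._update_sigma_u_joint(rng)
        if not self.fix_v:
            for _ in range(self.ess_repeats):
                self._update_v_ess(rng)
            self._update_translation(rng, adapt)
            if not self.fix_u:
                self._update_uv_swap(rng, adapt)
            if self.it % self.psi_every == 0:
                self._update_psi(rng, adapt)
                self._update_psi_whitened(rng, adapt)
        if not self.fix_u:
            self._update_u_translation(rng)
        self.it += 1


def fit_spatial_model(
    data: ModelData,
    coords: np.ndarray,
    spec: IndexModelSpec | None = None,
    spatial_spec: SpatialPriorSpec | None = None,
    mcmc: McmcSettings | None = None,
    fix_u_zero: bool = False,
    fix_v_zero: bool = False,
) -> tuple[PosteriorSamples, SpatialEffects]:
    """Fit an index model with exchangeable and spatially structured
    random effects and compute exceedance probabilities.

    ``coords`` are planar km residence coordinates (project geographic
    input with :func:`project_lonlat_to_km` first).  Dense multivariate-
    normal updates limit practical sample sizes to roughly n <= 2000.
    Returns the posterior draws and a :class:`SpatialEffects` summary.
    """
    spec = spec or IndexModelSpec(mcmc=McmcSettings(n_burn=10000, n_save=10000))
    if mcmc is not None:
        spec = IndexModelSpec(alpha=spec.alpha, sigma_upper=spec.sigma_upper,
                              rhat_threshold=spec.rhat_threshold, mcmc=mcmc)
    sp = spatial_spec or SpatialPriorSpec()
    coords = _dedupe_coords(np.asarray(coords, float))
    mc = spec.mcmc

    ss = np.random.SeedSequence(mc.seed)
    chain_seeds = ss.spawn(mc.n_chains)
    chains = []
    v_all, psi_all, su_all = [], [], []
    for c in range(mc.n_chains):
        rng = np.random.default_rng(chain_seeds[c])
        chain = _SpatialChain(data, spec, sp, coords, rng,
                              fix_u_zero=fix_u_zero, fix_v_zero=fix_v_zero)
        store = chain.core.allocate(mc.n_save)
        store["psi"] = np.empty(mc.n_save)
        store["sigma_u"] = np.empty(mc.n_save)
        v_draws = np.empty((mc.n_save, chain.n))
        for _ in range(mc.n_burn):
            chain.sweep(rng, adapt=True)
        for g in range(mc.n_save):
            for _ in range(mc.thin):
                chain.sweep(rng, adapt=False)
            chain.core.record(store, g)
            store["psi"][g] = chain.psi
            store["sigma_u"][g] = chain.sigma_u
            v_draws[g] = chain.v
        chains.append(store)
        v_all.append(v_draws)
        psi_all.append(store["psi"])
        su_all.append(store["sigma_u"])

    samples = PosteriorSamples(
        chains=chains,
        index_names=[t.name for t in data.indices],
        index_variables={t.name: t.variables for t in data.indices},
        covariate_names=data.covariate_names or [],
    )
    if mc.n_chains >= 2:
        diag = gelman_rubin(samples)
        core = {k: v for k, v in diag.items() if k.startswith("beta")}
        bad = {k: v for k, v in core.items() if np.isfinite(v) and v > spec.rhat_threshold}
        if bad:
            samples.warning = f"Gelman-Rubin above {spec.rhat_threshold}: {bad}"
            logger.warning(samples.warning)

    v_stack = np.concatenate(v_all, axis=0)
    q = exceedance(v_stack)
    effects = SpatialEffects(
        v_draws=v_stack,
        psi_draws=np.concatenate(psi_all),
        sigma_u_draws=np.concatenate(su_all),
        exceedance=q,
        flagged=q >= sp.exceedance_threshold,
        threshold=sp.exceedance_threshold,
    )
    return samples, effects


def elevated_area(effects: SpatialEffects, participants: pd.DataFrame) -> dict:
    """Flagged subjects, their case/control composition and the convex
    hull of their residences.  Returns an empty hull when no subject is
    flagged."""
    idx = np.flatnonzero(effects.flagged)
    if len(idx) == 0:
        return {"members": [], "n_cases": 0, "n_controls": 0, "hull": None, "area_km2": 0.0}
    sub = participants.iloc[idx]
    pts = MultiPoint(list(zip(sub["x"], sub["y_coord"])))
    hull = pts.convex_hull
    return {
        "members": sub["subject_id"].tolist(),
        "n_cases": int((sub["y"] == 1).sum()),
        "n_controls": int((sub["y"] == 0).sum()),
        "hull": hull,
        "area_km2": float(hull.area),
    }
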
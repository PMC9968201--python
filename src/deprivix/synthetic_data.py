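"""Seeded synthetic case-control studies with neighborhood structure.

Generates the four linked tables the analysis consumes: a census-tract
frame (Voronoi polygons tiling a planar rectangular region, km units,
with population / income-deprivation / education-deprivation deciles), a
block-group table of 11 socioeconomic variables loading on one spatially
autocorrelated latent deprivation surface, a participant table drawn
retrospectively from a logistic outcome model with known index weights
and effects, and a chemical concentration matrix (67 analytes in 7
groups) with below-detection-limit censoring.

Every quantity the downstream models estimate — index weights, log-odds
effects, covariate effects, within-group chemical correlation, injected
spatial clusters, and control under-participation in deprived tracts —
is set explicitly in :class:`GeneratorConfig` and returned in the truth
record, so parameter recovery is testable end to end.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
import shapely
from shapely.geometry import MultiPoint, box, mapping
from shapely.ops import voronoi_diagram

from . import index_models
from .index_models import SES_VARIABLES, compute_deciles, orient_variables

#: Analyte counts per chemical class (67 analytes in 7 groups).
CHEM_GROUPS: dict[str, int] = {
    "PCBs": 14,
    "PAHs": 12,
    "insecticides": 12,
    "herbicides": 9,
    "metals": 9,
    "tobacco": 2,
    "PBDEs": 9,
}


def _default_ndi_weights() -> np.ndarray:
    # Dominant weight 0.6 on Hispanic segregation, remainder spread evenly.
    w = np.full(len(SES_VARIABLES), 0.4 / (len(SES_VARIABLES) - 1))
    w[SES_VARIABLES.index("hisp_seg")] = 0.6
    return w


@dataclass
class ClusterInjection:
    """A circular excess-risk area added to the generating model.

    The added log-odds apply to every pool subject whose residence falls
    inside the disk.  When ``record_exposure`` is true the in-disk
    indicator is stored as the participant column ``cluster_exposure``,
    representing a measured risk factor that fully carries the cluster
    effect (so a model adjusting for it can explain the cluster away).
    """

    center: tuple[float, float] = (40.0, 20.0)
    radius_km: float = 5.0
    log_odds: float = 1.5
    record_exposure: bool = True


@dataclass
class GeneratorConfig:
    """Generating parameters of a synthetic study."""

    seed: int = 0
    n_cases: int = 277
    n_controls: int = 306
    region: tuple[float, float] = (60.0, 50.0)    # km
    n_tracts: int = 100
    bg_per_tract: tuple[int, int] = (3, 6)
    latent_range_km: float = 25.0                 # range of the deprivation surface
    ses_noise: float = 0.5                        # independent noise on SES loadings
    beta0: float = -1.0
    beta_ndi: float = 0.4                         # log-odds per decile of the weighted NDI
    ndi_weights: np.ndarray = field(default_factory=_default_ndi_weights)
    chem_groups: dict[str, int] = field(default_factory=lambda: dict(CHEM_GROUPS))
    beta_chem: dict[str, float] = field(default_factory=dict)
    chem_weights: dict[str, np.ndarray] = field(default_factory=dict)
    chem_corr: float = 0.6                        # within-group log-scale correlation
    lod_censor_frac: float = 0.30
    not_measured_frac: float = 0.05               # extra missingness, PBDEs only
    covariate_effects: dict[str, float] = field(default_factory=lambda: {
        "eth_hispanic": 0.8,
        "inc_ge75k": -0.5,
        "edu_bachelor_plus": -0.3,
        "residence_since_birth": -0.3,
    })
    confounding_strength: float = 0.8             # covariate link to deprivation
    cluster: ClusterInjection | None = None
    control_low_ses_undersample: float = 0.0      # participation decay with deprivation
    pool_factor: float = 6.0

    def __post_init__(self):
        self.ndi_weights = np.asarray(self.ndi_weights, float)
        if not np.isclose(self.ndi_weights.sum(), 1.0) or np.any(self.ndi_weights <= 0):
            raise ValueError("ndi_weights must be positive and sum to 1")
        for g, w in self.chem_weights.items():
            w = np.asarray(w, float)
            if not np.isclose(w.sum(), 1.0) or np.any(w <= 0):
                raise ValueError(f"chem_weights[{g!r}] must be positive and sum to 1")
            self.chem_weights[g] = w
        if not 0.0 <= self.chem_corr < 1.0:
            raise ValueError("chem_corr must lie in [0, 1)")


@dataclass
class ChemicalMatrix:
    """Concentrations (ng/g) with missingness provenance.

    ``values`` has NaN for missing entries; ``reason`` distinguishes
    ``below_lod`` from ``not_measured``; ``lods`` holds the per-analyte
    detection limit and ``groups`` the chemical class of each analyte.
    """

    values: pd.DataFrame
    groups: pd.Series
    lods: pd.Series
    reason: pd.DataFrame


def _rngs(config: GeneratorConfig) -> dict[str, np.random.Generator]:
    ss = np.random.SeedSequence(config.seed)
    kids = ss.spawn(4)
    names = ["tracts", "blockgroups", "participants", "chemicals"]
    return {n: np.random.default_rng(k) for n, k in zip(names, kids)}


def _decile_1_10(values: np.ndarray) -> np.ndarray:
    """Decile labels 1..10 with exactly floor(J/10) per decile when J is a
    multiple of 10 (ties broken by position)."""
    J = len(values)
    order = np.argsort(values, kind="stable")
    ranks = np.empty(J, int)
    ranks[order] = np.arange(J)
    return (ranks * 10) // J + 1


def _voronoi_polygons(points: np.ndarray, envelope) -> list:
    """Finite Voronoi cells of ``points`` clipped to ``envelope``, returned
    in point order."""
    cells = voronoi_diagram(MultiPoint(points.tolist()), envelope=envelope)
    clipped = [c.intersection(envelope) for c in cells.geoms]
    tree = shapely.STRtree(clipped)
    out = [None] * len(points)
    pts = [shapely.Point(p) for p in points]
    for i, p in enumerate(pts):
        for j in tree.query(p, predicate="intersects"):
            out[i] = clipped[j]
            break
        if out[i] is None:  # numerical edge case: nearest cell
            out[i] = clipped[int(np.argmin([p.distance(c) for c in clipped]))]
    return out


def generate_tracts(config: GeneratorConfig) -> pd.DataFrame:
    """Generate a tract frame tiling the rectangular study region.

    Tracts are Voronoi cells of jittered grid points.  Median household
    income and percent-without-college-degree derive from a shared latent
    deprivation surface with exponential spatial covariance, so deprived
    tracts form contiguous areas; deciles are computed within the frame
    (income deprivation is the decile of max(income) - income).
    """
    J = config.n_tracts
    if J < 20:
        raise ValueError("at least 20 tracts are required")
    W, H = config.region
    if W * H / J < 0.5:
        raise ValueError(f"region {W}x{H} km too small for {J} tracts")
    rng = _rngs(config)["tracts"]

    # jittered grid seeds for roughly even cells
    nx = int(np.ceil(np.sqrt(J * W / H)))
    ny = int(np.ceil(J / nx))
    gx, gy = np.meshgrid((np.arange(nx) + 0.5) * W / nx, (np.arange(ny) + 0.5) * H / ny)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    pts = pts[rng.permutation(len(pts))[:J]]
    pts += rng.uniform(-0.25, 0.25, pts.shape) * np.array([W / nx, H / ny])

    region = box(0.0, 0.0, W, H)
    polys = _voronoi_polygons(pts, region)

    # latent deprivation surface over tract centroids
    cent = np.array([[p.centroid.x, p.centroid.y] for p in polys])
    d = cdist(cent, cent)
    K = np.exp(-d / config.latent_range_km) + 1e-8 * np.eye(J)
    dep = np.linalg.cholesky(K) @ rng.normal(size=J)

    income = 60000.0 * np.exp(-0.45 * dep + 0.12 * rng.normal(size=J))
    no_college = 100.0 / (1 + np.exp(-(0.3 + 0.8 * dep + 0.3 * rng.normal(size=J))))
    population = np.round(np.exp(rng.normal(8.3, 0.4, J))).astype(int) + 100

    frame = pd.DataFrame({
        "tract_id": [f"T{i:04d}" for i in range(J)],
        "population": population,
        "median_income": income,
        "pct_no_college": no_college,
        "latent_deprivation": dep,
        "centroid_x": cent[:, 0],
        "centroid_y": cent[:, 1],
    })
    frame["polygon"] = polys
    frame["pop_decile"] = _decile_1_10(population.astype(float))
    frame["inc_deprivation_decile"] = _decile_1_10(income.max() - income)
    frame["edu_deprivation_decile"] = _decile_1_10(no_college)
    return frame


def generate_blockgroups(config: GeneratorConfig, tracts: pd.DataFrame) -> pd.DataFrame:
    """Sub-tessellate each tract into 3-6 block groups and attach the 11
    SES variables, each loading on the tract deprivation surface plus
    independent noise (single-factor structure)."""
    rng = _rngs(config)["blockgroups"]
    lo, hi = config.bg_per_tract
    rows = []
    for _, tr in tracts.iterrows():
        poly = tr["polygon"]
        k = int(rng.integers(lo, hi + 1))
        pts = _sample_in_polygon(poly, k, rng)
        cells = _voronoi_polygons(pts, poly) if k > 1 else [poly]
        for j, cell in enumerate(cells):
            rows.append({
                "bg_id": f"{tr['tract_id']}B{j}",
                "tract_id": tr["tract_id"],
                "polygon": cell,
                "latent_deprivation": tr["latent_deprivation"] + 0.3 * rng.normal(),
            })
    bg = pd.DataFrame(rows)
    d = bg["latent_deprivation"].to_numpy()
    n = len(bg)
    s = config.ses_noise

    def pct(b0, load):
        return 100.0 / (1 + np.exp(-(b0 + load * d + s * rng.normal(size=n))))

    bg["black_seg"] = pct(-2.0, 0.7)
    bg["hisp_seg"] = pct(-0.6, 1.1)
    bg["pct_poverty"] = pct(-1.8, 0.9)
    bg["pct_public_assist"] = pct(-2.5, 0.8)
    bg["pct_renters"] = pct(-0.7, 0.7)
    bg["pct_no_hs"] = pct(-1.6, 1.0)
    bg["pct_moved"] = pct(-1.4, 0.5)
    bg["pct_foreign_born"] = pct(-1.5, 0.8)
    bg["per_capita_income"] = 30000.0 * np.exp(-0.5 * d + 0.3 * s * rng.normal(size=n))
    bg["median_house_value"] = 300000.0 * np.exp(-0.6 * d + 0.3 * s * rng.normal(size=n))
    bg["median_gross_rent"] = 1200.0 * np.exp(-0.4 * d + 0.3 * s * rng.normal(size=n))
    return bg


def _sample_in_polygon(poly, k: int, rng: np.random.Generator,
                       max_tries: int = 200) -> np.ndarray:
    """Uniform points inside a polygon by batched bounding-box rejection."""
    minx, miny, maxx, maxy = poly.bounds
    out = np.empty((0, 2))
    for _ in range(max_tries):
        m = max(4 * (k - len(out)), 16)
        cand = np.column_stack([rng.uniform(minx, maxx, m), rng.uniform(miny, maxy, m)])
        inside = shapely.contains_xy(poly, cand[:, 0], cand[:, 1])
        out = np.vstack([out, cand[inside]])
        if len(out) >= k:
            return out[:k]
    raise RuntimeError(f"polygon sampling failed after {max_tries} batches")


def censor_below_lod(values: pd.DataFrame, lods: pd.Series,
                     groups: pd.Series | None = None) -> ChemicalMatrix:
    """Flag concentrations below the per-analyte detection limit as missing.

    Values strictly below the LOD become NaN with reason ``below_lod``;
    all other entries are unchanged.  LODs must be nonnegative (a LOD of
    zero censors nothing).
    """
    lods = lods.reindex(values.columns)
    if (lods < 0).any():
        raise ValueError("detection limits must be nonnegative")
    censored = values.copy()
    reason = pd.DataFrame("", index=values.index, columns=values.columns)
    below = values.lt(lods, axis=1) & values.notna()
    censored[below] = np.nan
    reason[below] = "below_lod"
    reason[values.isna()] = "not_measured"
    if groups is None:
        groups = pd.Series("ungrouped", index=values.columns)
    return ChemicalMatrix(values=censored, groups=groups, lods=lods, reason=reason)


def _chem_analyte_names(chem_groups: dict[str, int]) -> tuple[list[str], pd.Series]:
    names, grp = [], []
    for g, c in chem_groups.items():
        for j in range(c):
            names.append(f"{g}_{j+1:02d}")
            grp.append(g)
    return names, pd.Series(grp, index=names, name="group")


def generate_participants(config: GeneratorConfig, tracts: pd.DataFrame,
                          blockgroups: pd.DataFrame):
    """Draw the participant table and chemical matrix from the generating
    logistic model.

    A large residential pool is simulated (tract chosen proportional to
    population, block group uniform within tract, residence uniform in the
    block-group polygon).  Outcomes follow
    ``logit(p) = beta0 + beta_ndi * NDI + sum_k beta_k * chem_k + z'phi
    [+ cluster]`` with decile-score indices computed over the pool; the
    requested numbers of cases and controls are then sampled without
    replacement (controls optionally under-sampled in deprived tracts,
    emulating differential participation).  Returns
    ``(participants, chemicals, truth)``.
    """
    rng = _rngs(config)["participants"]
    crng = _rngs(config)["chemicals"]
    n_req = config.n_cases + config.n_controls
    n_pool = int(np.ceil(config.pool_factor * n_req))

    # residence assignment
    p_tract = tracts["population"].to_numpy(float)
    p_tract = p_tract / p_tract.sum()
    t_idx = rng.choice(len(tracts), n_pool, p=p_tract)
    bg_by_tract = blockgroups.groupby("tract_id").indices
    tract_ids = tracts["tract_id"].to_numpy()
    bg_idx = np.array([
        rng.choice(bg_by_tract[tract_ids[t]]) for t in t_idx
    ])
    coords = np.empty((n_pool, 2))
    for b in np.unique(bg_idx):
        mask = bg_idx == b
        coords[mask] = _sample_in_polygon(blockgroups["polygon"].iloc[b], int(mask.sum()), rng)

    dep = blockgroups["latent_deprivation"].to_numpy()[bg_idx]
    cs = config.confounding_strength

    # individual covariates, linked to block-group deprivation
    child_age = rng.uniform(0.0, 8.0, n_pool)
    female = rng.integers(0, 2, n_pool)
    logits = np.column_stack([
        np.zeros(n_pool),                       # nh_white
        -0.7 + cs * dep,                        # hispanic
        np.full(n_pool, -1.2),                  # nh_other
    ])
    pr = np.exp(logits)
    pr /= pr.sum(axis=1, keepdims=True)
    eth_codes = np.array([rng.choice(3, p=row) for row in pr])
    ethnicity = np.array(index_models.ETHNICITY_LEVELS)[eth_codes]

    li = -0.7 * cs * dep + rng.normal(size=n_pool)
    inc_code = np.digitize(li, [-1.5, -0.8, -0.2, 0.3, 0.8])  # 0..5, 0 = lowest income? see below
    # digitize gives low latent -> low code; reverse so high latent income -> high bracket
    income = np.array(index_models.INCOME_LEVELS[:6], dtype=object)[inc_code]
    income[rng.uniform(size=n_pool) < 0.08] = "missing"
    le = -0.6 * cs * dep + rng.normal(size=n_pool)
    edu_code = np.digitize(le, [-1.2, -0.3, 0.6])
    education = np.array(index_models.EDUCATION_LEVELS, dtype=object)[edu_code]
    mother_age = np.clip(rng.normal(28.0, 5.5, n_pool), 15.0, 45.0)
    res_birth = (rng.uniform(size=n_pool) < 0.6).astype(int)

    pool = pd.DataFrame({
        "subject_id": [f"P{i:06d}" for i in range(n_pool)],
        "x": coords[:, 0],
        "y_coord": coords[:, 1],
        "child_age": child_age,
        "female": female,
        "ethnicity": ethnicity,
        "household_income": income,
        "mother_education": education,
        "mother_age": mother_age,
        "residence_since_birth": res_birth,
        "bg_id": blockgroups["bg_id"].to_numpy()[bg_idx],
        "tract_id": blockgroups["tract_id"].to_numpy()[bg_idx],
    })

    # chemicals: per group multivariate log-normal with exchangeable correlation
    names, groups = _chem_analyte_names(config.chem_groups)
    logX = np.empty((n_pool, len(names)))
    col = 0
    for g, C in config.chem_groups.items():
        rho = config.chem_corr
        cov = (1 - rho) * np.eye(C) + rho * np.ones((C, C))
        L = np.linalg.cholesky(cov)
        mu = np.log(50.0) + crng.normal(0.0, 0.5, C)   # analyte-specific levels
        logX[:, col:col + C] = mu + crng.normal(size=(n_pool, C)) @ L.T
        col += C
    chem_pool = pd.DataFrame(np.exp(logX), columns=names)

    # generating linear predictor
    ses = blockgroups.loc[bg_idx, SES_VARIABLES].reset_index(drop=True)
    q_ndi = compute_deciles(orient_variables(ses)).scores.to_numpy(float)
    ndi_index = q_ndi @ config.ndi_weights

    eta = config.beta0 + config.beta_ndi * ndi_index
    chem_index_truth = {}
    for g, C in config.chem_groups.items():
        beta_g = config.beta_chem.get(g, 0.0)
        members = [a for a in names if groups[a] == g]
        w = config.chem_weights.get(g)
        if w is None:
            w = np.full(C, 1.0 / C)
        q_g = compute_deciles(chem_pool[members]).scores.to_numpy(float)
        idx_g = q_g @ w
        chem_index_truth[g] = idx_g
        if beta_g != 0.0:
            eta = eta + beta_g * idx_g

    Z, znames = index_models.covariate_design(pool)
    phi = np.array([config.covariate_effects.get(c, 0.0) for c in znames])
    eta = eta + Z @ phi

    in_disk = np.zeros(n_pool, bool)
    if config.cluster is not None:
        c = np.asarray(config.cluster.center)
        in_disk = np.hypot(coords[:, 0] - c[0], coords[:, 1] - c[1]) <= config.cluster.radius_km
        eta = eta + config.cluster.log_odds * in_disk

    y = (rng.uniform(size=n_pool) < 1.0 / (1.0 + np.exp(-eta))).astype(int)
    pool["y"] = y
    if config.cluster is not None and config.cluster.record_exposure:
        pool["cluster_exposure"] = in_disk.astype(int)

    # retrospective sampling of the requested case/control totals
    case_idx = np.flatnonzero(y == 1)
    ctrl_idx = np.flatnonzero(y == 0)
    if len(case_idx) < config.n_cases or len(ctrl_idx) < config.n_controls:
        raise ValueError(
            f"pool of {n_pool} produced {len(case_idx)} cases / {len(ctrl_idx)} controls; "
            f"requested {config.n_cases}/{config.n_controls} — increase pool_factor"
        )
    sel_cases = rng.choice(case_idx, config.n_cases, replace=False)
    s = config.control_low_ses_undersample
    if s > 0:
        inc_dec = tracts.set_index("tract_id")["inc_deprivation_decile"]
        dec = inc_dec.loc[pool["tract_id"].iloc[ctrl_idx]].to_numpy(float)
        wts = np.exp(-s * (dec - 1.0) / 9.0)
        wts /= wts.sum()
        sel_ctrl = rng.choice(ctrl_idx, config.n_controls, replace=False, p=wts)
    else:
        sel_ctrl = rng.choice(ctrl_idx, config.n_controls, replace=False)
    sel = np.concatenate([sel_cases, sel_ctrl])
    sel.sort()

    participants = pool.iloc[sel].reset_index(drop=True)
    chem_true = chem_pool.iloc[sel].reset_index(drop=True)

    lods = chem_pool.quantile(config.lod_censor_frac)
    chemicals = censor_below_lod(chem_true, lods, groups)
    if config.not_measured_frac > 0:
        pbde = [a for a in names if groups[a] == "PBDEs"]
        if pbde:
            nm = crng.uniform(size=(len(participants), len(pbde))) < config.not_measured_frac
            vals = chemicals.values.copy()
            rs = chemicals.reason.copy()
            sub = vals[pbde].to_numpy()
            sub[nm] = np.nan
            vals[pbde] = sub
            rsub = rs[pbde].to_numpy(object)
            rsub[nm] = "not_measured"
            rs[pbde] = rsub
            chemicals = ChemicalMatrix(vals, chemicals.groups, chemicals.lods, rs)

    truth = {
        "beta0": config.beta0,
        "beta_ndi": config.beta_ndi,
        "ndi_weights": config.ndi_weights.tolist(),
        "beta_chem": dict(config.beta_chem),
        "covariate_effects": {c: float(v) for c, v in zip(znames, phi)},
        "pool_case_fraction": float(y.mean()),
        "pool_size": n_pool,
        "in_disk_sampled": in_disk[sel].astype(int).tolist(),
        "cluster": asdict(config.cluster) if config.cluster else None,
        "true_chemicals": chem_true,
        "pool_eta": eta,
        "pool_y": y,
        "pool_in_disk": in_disk,
    }
    return participants, chemicals, truth


def generate_study(config: GeneratorConfig) -> dict:
    """Generate all four tables plus the truth record for one seed."""
    tracts = generate_tracts(config)
    blockgroups = generate_blockgroups(config, tracts)
    participants, chemicals, truth = generate_participants(config, tracts, blockgroups)
    return {
        "tracts": tracts,
        "blockgroups": blockgroups,
        "participants": participants,
        "chemicals": chemicals,
        "truth": truth,
    }


def write_study(study: dict, outdir) -> None:
    """Write participants.csv, chemicals.csv, blockgroups.csv,
    tracts.geojson and truth.json to ``outdir``."""
    import pathlib

    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    study["participants"].to_csv(outdir / "participants.csv", index=False)
    study["chemicals"].values.to_csv(outdir / "chemicals.csv", index=False)
    study["blockgroups"].drop(columns="polygon").to_csv(outdir / "blockgroups.csv", index=False)

    features = []
    for _, tr in study["tracts"].iterrows():
        props = {k: (v.item() if isinstance(v, np.generic) else v)
                 for k, v in tr.items() if k != "polygon"}
        features.append({"type": "Feature", "geometry": mapping(tr["polygon"]),
                         "properties": props})
    with open(outdir / "tracts.geojson", "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)

    truth = {k: v for k, v in study["truth"].items()
             if k not in {"true_chemicals", "pool_eta", "pool_y", "pool_in_disk"}}
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1)
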
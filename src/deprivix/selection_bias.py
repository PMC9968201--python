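"""Pseudo-participant simulation for selection-bias sensitivity analysis.

Not all eligible subjects of a case-control study participate, and
controls in deprived areas participate least.  To probe whether an
observed spatial cluster could be an artifact of that differential
participation, simulated participants are added until full eligibility
is restored: each pseudo-subject receives a census tract drawn with
tract-level sampling weights and a uniform residence within the tract
polygon.  Pseudo-cases are weighted by population decile only;
pseudo-controls by the product of the deciles for population, income
deprivation (max(income) - income) and education deprivation (percent
without a college degree), either with equal emphasis ("equal" scheme)
or with 50% extra emphasis on the two deprivation deciles ("ses"
scheme).  Cluster detection (scan and/or BYM) and the crude
deprivation-index model are re-run on each augmented dataset and the
persistence of the observed cluster is summarized.

Note on the "ses" scheme: multiplying deciles by constants cancels
after normalization, so the literal constants-inside-the-product form
reproduces the equal weights exactly; a ``power`` variant
(decile ** 1.5 for the two deprivation deciles) that genuinely
up-weights deprived tracts is provided as a configuration choice.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely

from . import cluster_detection, index_models
from .cluster_detection import BymSpec, ClusterResult, hull_overlap
from .index_models import IndexModelSpec, McmcSettings
from .synthetic_data import _sample_in_polygon

logger = logging.getLogger(__name__)


@dataclass
class StudyDesign:
    """Participation counts defining how many pseudo-subjects to add."""

    eligible_cases: int = 324
    participating_cases: int = 277
    eligible_controls: int = 407
    participating_controls: int = 306

    @property
    def n_pseudo_cases(self) -> int:
        return self.eligible_cases - self.participating_cases

    @property
    def n_pseudo_controls(self) -> int:
        return self.eligible_controls - self.participating_controls

    @property
    def analytic_n(self) -> int:
        return self.participating_cases + self.participating_controls

    @property
    def eligible_n(self) -> int:
        return self.eligible_cases + self.eligible_controls


@dataclass
class SchemeWeights:
    scheme: str
    weights: np.ndarray         # per tract, sums to 1
    constants: tuple[float, float, float]  # (population, income, education)


def tract_weights(tracts: pd.DataFrame, scheme: str = "equal",
                  variant: str = "literal", role: str = "control") -> SchemeWeights:
    """Per-tract sampling weights for pseudo-participants.

    ``role="case"`` weights by population decile alone.  For controls,
    ``scheme="equal"`` uses the plain product of the three deciles;
    ``scheme="ses"`` applies the constants (1, 1.5, 1.5) to population,
    income deprivation and education deprivation.  With
    ``variant="literal"`` the constants enter multiplicatively and
    cancel under normalization; ``variant="power"`` raises the two
    deprivation deciles to the 1.5 power instead, which strictly
    up-weights deprived tracts.
    """
    pop = tracts["pop_decile"].to_numpy(float)
    inc = tracts["inc_deprivation_decile"].to_numpy(float)
    edu = tracts["edu_deprivation_decile"].to_numpy(float)
    if role == "case":
        w = pop.copy()
        constants = (1.0, 0.0, 0.0)
    elif scheme == "equal":
        w = inc * edu * pop
        constants = (1.0, 1.0, 1.0)
    elif scheme == "ses":
        constants = (1.0, 1.5, 1.5)
        if variant == "literal":
            w = (1.5 * inc) * (1.5 * edu) * (1.0 * pop)
        elif variant == "power":
            w = inc**1.5 * edu**1.5 * pop
        else:
            raise ValueError(f"unknown ses variant {variant!r}")
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    total = w.sum()
    if total <= 0:
        raise ValueError("all tract weights are zero")
    return SchemeWeights(scheme=scheme, weights=w / total, constants=constants)


def sample_pseudo_participants(tracts: pd.DataFrame, weights: SchemeWeights,
                               n: int, rng: np.random.Generator,
                               label: int = 0) -> pd.DataFrame:
    """Draw ``n`` pseudo-subjects: tract with replacement by weight, then
    a uniform residence inside the tract polygon."""
    if n == 0:
        return pd.DataFrame(columns=["x", "y_coord", "y", "tract_id", "pseudo"])
    t_idx = rng.choice(len(tracts), n, p=weights.weights)
    xs = np.empty(n)
    ys = np.empty(n)
    for t in np.unique(t_idx):
        mask = t_idx == t
        pts = _sample_in_polygon(tracts["polygon"].iloc[int(t)], int(mask.sum()), rng)
        xs[mask], ys[mask] = pts[:, 0], pts[:, 1]
    return pd.DataFrame({
        "x": xs,
        "y_coord": ys,
        "y": label,
        "tract_id": tracts["tract_id"].to_numpy()[t_idx],
        "pseudo": 1,
    })


def _locate_blockgroups(points: pd.DataFrame, blockgroups: pd.DataFrame) -> pd.Series:
    """Block-group id containing each point (nearest cell on boundary ties)."""
    polys = list(blockgroups["polygon"])
    tree = shapely.STRtree(polys)
    ids = blockgroups["bg_id"].to_numpy()
    out = []
    for x, y in zip(points["x"], points["y_coord"]):
        p = shapely.Point(x, y)
        cand = tree.query(p, predicate="intersects")
        if len(cand) == 0:
            cand = [tree.nearest(p)]
        out.append(ids[int(cand[0])])
    return pd.Series(out, index=points.index, name="bg_id")


@dataclass
class BiasSimResult:
    per_dataset: pd.DataFrame
    aggregate: pd.DataFrame
    reference: dict[str, ClusterResult]
    hulls: dict[str, list] = field(default_factory=dict)   # method -> hull per dataset (or None)
    ndi_or_mean: float | None = None


def detection_frequency_grid(hulls: list, bounds: tuple[float, float, float, float],
                             cell_km: float = 2.0) -> list[dict]:
    """How often each map cell fell inside a detected cluster.

    ``hulls`` holds one convex-hull polygon (or None) per simulated
    dataset; the result is a list of GeoJSON features on a regular grid
    with properties ``count`` and ``pct`` — the map of
    detection frequency across the simulation.
    """
    import shapely
    from shapely.geometry import box, mapping

    minx, miny, maxx, maxy = bounds
    xs = np.arange(minx, maxx, cell_km)
    ys = np.arange(miny, maxy, cell_km)
    found = [h for h in hulls if h is not None]
    n = len(hulls)
    features = []
    for x in xs:
        for y in ys:
            cell = box(x, y, min(x + cell_km, maxx), min(y + cell_km, maxy))
            c = cell.centroid
            count = sum(1 for h in found if h.intersects(c))
            if count:
                features.append({
                    "type": "Feature", "geometry": mapping(cell),
                    "properties": {"count": count,
                                   "pct": 100.0 * count / max(n, 1)},
                })
    return features


def _fit_crude_ndi(aug: pd.DataFrame, blockgroups: pd.DataFrame,
                   mcmc: McmcSettings) -> tuple[float, float, float]:
    data = index_models.build_model_data(aug, blockgroups, model="crude")
    spec = IndexModelSpec(mcmc=mcmc)
    samples = index_models.fit_index_model(spec, data)
    s = index_models.summarize_index(samples, "NDI")
    return s["or_mean"], s["or_lower"], s["or_upper"]


def run_bias_simulation(
    observed: pd.DataFrame,
    tracts: pd.DataFrame,
    design: StudyDesign | None = None,
    blockgroups: pd.DataFrame | None = None,
    n_datasets: int = 100,
    schemes: tuple[str, ...] = ("equal", "ses"),
    methods: tuple[str, ...] = ("scan", "bym"),
    seed: int = 0,
    ses_variant: str = "literal",
    fit_ndi: bool = False,
    scan_n_mc: int = 999,
    bym_spec: BymSpec | None = None,
    ndi_mcmc: McmcSettings | None = None,
    reference: dict[str, ClusterResult] | None = None,
) -> BiasSimResult:
    """Augment the observed study to full eligibility and re-detect.

    For every scheme and dataset, pseudo-cases (population-weighted
    tracts) and pseudo-controls (scheme-weighted tracts) are added, the
    requested detection methods re-run, and the presence, hull size and
    overlap with the observed reference cluster recorded.  Optionally
    the crude deprivation-index model is refit to each augmented dataset
    (pseudo-subjects take the SES values of the block group containing
    their sampled residence).  Per-dataset seeds derive from the master
    seed by fixed offsets, so the whole simulation is reproducible.
    """
    design = design or StudyDesign()
    obs_xy = observed[["x", "y_coord"]].to_numpy(float)
    obs_y = observed["y"].to_numpy(int)
    bym_spec = bym_spec or BymSpec()

    if reference is None:
        reference = {}
        for method in methods:
            reference[method] = _detect(obs_xy, obs_y, method, scan_n_mc, bym_spec, seed)
            logger.info("observed %s reference: found=%s area=%.1f km^2", method,
                        reference[method].found, reference[method].area_km2)

    rows = []
    ndi_ors = []
    hulls: dict[str, list] = {m: [] for m in methods}
    for scheme in schemes:
        w_ctrl = tract_weights(tracts, scheme=scheme, variant=ses_variant, role="control")
        w_case = tract_weights(tracts, role="case")
        for ds in range(n_datasets):
            scheme_off = zlib.crc32(scheme.encode()) % 2**16
            rng = np.random.default_rng(np.random.SeedSequence((seed, scheme_off, ds)))
            pc = sample_pseudo_participants(tracts, w_case, design.n_pseudo_cases, rng, label=1)
            pk = sample_pseudo_participants(tracts, w_ctrl, design.n_pseudo_controls, rng, label=0)
            pseudo = pd.concat([pc, pk], ignore_index=True)
            xy = np.vstack([obs_xy, pseudo[["x", "y_coord"]].to_numpy(float)]) \
                if len(pseudo) else obs_xy
            yy = np.concatenate([obs_y, pseudo["y"].to_numpy(int)]) if len(pseudo) else obs_y

            row = {"scheme": scheme, "dataset": ds}
            for method in methods:
                res = _detect(xy, yy, method, scan_n_mc, bym_spec,
                              int(rng.integers(2**31)))
                ref = reference[method]
                inter, pct, overlaps = hull_overlap(res.hull if res.found else None,
                                                    ref.hull if ref.found else None)
                row[f"{method}_found"] = res.found
                row[f"{method}_area_km2"] = res.area_km2 if res.found else 0.0
                row[f"{method}_overlap_km2"] = inter
                row[f"{method}_overlap_pct"] = pct
                row[f"{method}_overlaps"] = overlaps
                hulls[method].append(res.hull if res.found else None)
            if fit_ndi and scheme == schemes[0]:
                if blockgroups is None:
                    raise ValueError("fit_ndi requires blockgroups")
                aug = observed.copy()
                aug["pseudo"] = 0
                if len(pseudo):
                    pseudo = pseudo.copy()
                    pseudo["bg_id"] = _locate_blockgroups(pseudo, blockgroups)
                    aug = pd.concat([aug, pseudo], ignore_index=True)
                mc = ndi_mcmc or McmcSettings(n_burn=1500, n_save=2000,
                                              seed=int(rng.integers(2**31)))
                or_mean, lo, hi = _fit_crude_ndi(aug, blockgroups, mc)
                row["ndi_or"], row["ndi_or_lower"], row["ndi_or_upper"] = or_mean, lo, hi
                ndi_ors.append(or_mean)
            rows.append(row)

    per_dataset = pd.DataFrame(rows)
    agg_rows = []
    for scheme in schemes:
        sub = per_dataset[per_dataset["scheme"] == scheme]
        for method in methods:
            sizes = sub[f"{method}_area_km2"].to_numpy(float)
            over = sub[f"{method}_overlap_pct"].to_numpy(float)
            agg_rows.append({
                "method": method,
                "scheme": scheme,
                "pct_with_cluster": 100.0 * sub[f"{method}_found"].mean(),
                "size_median": float(np.median(sizes)),
                "size_lo": float(np.percentile(sizes, 2.5)),
                "size_hi": float(np.percentile(sizes, 97.5)),
                "overlap_median": float(np.median(over)),
                "overlap_lo": float(np.percentile(over, 2.5)),
                "overlap_hi": float(np.percentile(over, 97.5)),
                "pct_with_overlap": 100.0 * sub[f"{method}_overlaps"].mean(),
            })
    aggregate = pd.DataFrame(agg_rows)
    return BiasSimResult(
        per_dataset=per_dataset,
        aggregate=aggregate,
        reference=reference,
        hulls=hulls,
        ndi_or_mean=float(np.mean(ndi_ors)) if ndi_ors else None,
    )


def _detect(xy: np.ndarray, y: np.ndarray, method: str, scan_n_mc: int,
            bym_spec: BymSpec, seed: int) -> ClusterResult:
    if method == "scan":
        return cluster_detection.bernoulli_scan(xy, y, n_mc=scan_n_mc, seed=seed)
    if method == "bym":
        from dataclasses import replace

        return cluster_detection.fit_bym(xy, y, replace(bym_spec, seed=seed))
    raise ValueError(f"unknown detection method {method!r}")
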
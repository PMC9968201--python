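"""Covariate-free spatial cluster detection for case-control points.

Two detectors are provided, mirroring standard practice in spatial
epidemiology:

* a circular Bernoulli scan statistic: the likelihood ratio of case
  membership inside vs outside every circle centered at a subject
  location and passing through each other location is maximized, and
  significance is judged by the rank of the observed maximum among
  Monte Carlo relabelings of case/control status (p = rank / (n_mc+1),
  significant below 0.05);

* a Besag-York-Mollie (BYM) logistic model with an exchangeable effect
  and an intrinsic conditional-autoregressive (ICAR) structured effect
  on the adjacency graph of the subjects' Voronoi cells; subjects with
  posterior Pr(v_i > 0) > 0.90 form the detected cluster.

Hull-geometry utilities (convex-hull area in km^2, pairwise overlap)
support the persistence summaries of the selection-bias simulation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import shapely
from scipy.spatial.distance import cdist
from shapely.geometry import MultiPoint, box

logger = logging.getLogger(__name__)


@dataclass
class ClusterResult:
    method: str                      # "scan" | "bym"
    members: np.ndarray              # indices into the input locations
    hull: object                     # shapely geometry or None
    area_km2: float
    p_value: float | None = None     # scan only
    llr: float | None = None         # scan only
    significant: bool = False
    exceedance: np.ndarray | None = None   # bym only

    @property
    def found(self) -> bool:
        return self.significant and len(self.members) > 0


# ---------------------------------------------------------------------------
# Bernoulli scan statistic
# ---------------------------------------------------------------------------

def _xlogy(x, y):
    with np.errstate(divide="ignore", invalid="ignore"):
        out = x * np.log(y)
    return np.where(x == 0, 0.0, out)


def _scan_llr_table(cum_cases: np.ndarray, sizes: np.ndarray, C: int, N: int) -> np.ndarray:
    """Bernoulli log-likelihood ratio for circles with ``sizes`` subjects of
    which ``cum_cases`` are cases; high-rate circles only (else -inf)."""
    c = cum_cases
    nz = sizes
    inside_rate = c / nz
    outside_rate = (C - c) / np.maximum(N - nz, 1)
    llr = (
        _xlogy(c, c / nz)
        + _xlogy(nz - c, (nz - c) / nz)
        + _xlogy(C - c, (C - c) / np.maximum(N - nz, 1))
        + _xlogy(N - nz - (C - c), (N - nz - (C - c)) / np.maximum(N - nz, 1))
        - (_xlogy(C, C / N) + _xlogy(N - C, (N - C) / N))
    )
    return np.where(inside_rate > outside_rate, llr, -np.inf)


def _max_llr(order: np.ndarray, labels: np.ndarray, kmax: int, C: int, N: int):
    """Maximum LLR over all (center, prefix-size) circles given the
    distance ordering of subjects per center."""
    lab = labels[order]                      # (N, N) labels in distance order
    cum = np.cumsum(lab, axis=1)[:, :kmax]   # cases within k nearest
    sizes = np.arange(1, kmax + 1)[None, :]
    llr = _scan_llr_table(cum, sizes, C, N)
    flat = np.argmax(llr)
    i, k = np.unravel_index(flat, llr.shape)
    return float(llr[i, k]), int(i), int(k + 1)


def bernoulli_scan(locations: np.ndarray, labels: np.ndarray,
                   max_frac: float = 0.5, n_mc: int = 999,
                   seed: int = 0) -> ClusterResult:
    """Most likely high-rate circular cluster under the Bernoulli model.

    Circles are centered at each subject and grown through successive
    nearest neighbors up to ``max_frac`` of all subjects.  The observed
    maximum likelihood ratio is ranked among ``n_mc`` random relabelings
    of case status; ``p = rank / (n_mc + 1)`` and the cluster is
    significant when p < 0.05.
    """
    locations = np.asarray(locations, float)
    labels = np.asarray(labels, int)
    N = len(labels)
    C = int(labels.sum())
    if C == 0 or C == N:
        raise ValueError("scan requires at least one case and one control")
    if not 0 < max_frac <= 0.5:
        raise ValueError("max_frac must lie in (0, 0.5]")
    kmax = max(int(np.floor(max_frac * N)), 1)

    d = cdist(locations, locations)
    order = np.argsort(d, axis=1, kind="stable")
    obs_llr, i_star, k_star = _max_llr(order, labels, kmax, C, N)
    members = order[i_star, :k_star]

    rng = np.random.default_rng(seed)
    rank = 1
    for _ in range(n_mc):
        perm = rng.permutation(labels)
        mc_llr, _, _ = _max_llr(order, perm, kmax, C, N)
        if mc_llr >= obs_llr:
            rank += 1
    p = rank / (n_mc + 1)

    pts = MultiPoint(locations[members].tolist())
    hull = pts.convex_hull
    return ClusterResult(
        method="scan",
        members=np.sort(members),
        hull=hull,
        area_km2=float(hull.area),
        p_value=p,
        llr=obs_llr,
        significant=p < 0.05,
    )


# ---------------------------------------------------------------------------
# Voronoi adjacency
# ---------------------------------------------------------------------------

def voronoi_adjacency(locations: np.ndarray, pad_frac: float = 0.10):
    """Adjacency lists of the subjects' Voronoi cells.

    Cells are clipped to the bounding box of the points padded by
    ``pad_frac`` so that outer cells are finite; two subjects are
    adjacent iff their clipped cells share a boundary segment of
    positive length.  Collinear inputs are rejected.
    """
    locations = np.asarray(locations, float)
    n = len(locations)
    if n < 3:
        raise ValueError("Voronoi adjacency requires at least 3 points")
    hull = MultiPoint(locations.tolist()).convex_hull
    if hull.area <= 1e-12:
        raise ValueError("points are collinear; Voronoi adjacency undefined")

    minx, miny, maxx, maxy = hull.bounds
    px = pad_frac * max(maxx - minx, 1e-6)
    py = pad_frac * max(maxy - miny, 1e-6)
    envelope = box(minx - px, miny - py, maxx + px, maxy + py)

    from shapely.ops import voronoi_diagram

    cells_raw = voronoi_diagram(MultiPoint(locations.tolist()), envelope=envelope)
    clipped = [c.intersection(envelope) for c in cells_raw.geoms]
    tree = shapely.STRtree(clipped)
    cell_of = np.full(n, -1)
    for i in range(n):
        p = shapely.Point(locations[i])
        cand = tree.query(p, predicate="intersects")
        if len(cand):
            cell_of[i] = cand[0]
        else:
            cell_of[i] = int(np.argmin([p.distance(c) for c in clipped]))
    cells = [clipped[cell_of[i]] for i in range(n)]

    adj: list[set[int]] = [set() for _ in range(n)]
    ctree = shapely.STRtree(cells)
    for i in range(n):
        for j in ctree.query(cells[i], predicate="intersects"):
            j = int(j)
            if j <= i:
                continue
            inter = cells[i].intersection(cells[j])
            if inter.length > 1e-9:
                adj[i].add(j)
                adj[j].add(i)
    return [sorted(s) for s in adj]


# ---------------------------------------------------------------------------
# BYM model with ICAR prior
# ---------------------------------------------------------------------------

@dataclass
class BymSpec:
    sigma_u_upper: float = 10.0
    tau_v_shape: float = 0.001
    tau_v_rate: float = 0.001
    n_chains: int = 2
    n_burn: int = 15000
    n_save: int = 20000
    exceedance_threshold: float = 0.90
    seed: int = 0


def _graph_coloring(adj: list[list[int]]) -> list[np.ndarray]:
    g = nx.Graph()
    g.add_nodes_from(range(len(adj)))
    for i, nbrs in enumerate(adj):
        g.add_edges_from((i, j) for j in nbrs if j > i)
    colors = nx.greedy_color(g, strategy="largest_first")
    k = max(colors.values()) + 1
    return [np.array([i for i, c in colors.items() if c == col]) for col in range(k)]


def fit_bym(locations: np.ndarray, labels: np.ndarray,
            spec: BymSpec | None = None) -> ClusterResult:
    """Fit the BYM logistic model and flag the elevated-risk cluster.

    ``logit(p_i) = beta0 + u_i + v_i`` with a flat prior on the
    intercept, u_i ~ Normal(0, sigma_u^2) with sigma_u ~ Uniform(0, 10),
    and an ICAR prior on v over the Voronoi adjacency graph with
    precision tau_v ~ Gamma(0.001, 0.001).  v is recentered to sum to
    zero within each connected component every iteration (the usual ICAR
    identifiability constraint); isolated subjects keep v = 0.  The
    detected cluster is the set of subjects with posterior
    Pr(v_i > 0) above the exceedance threshold.

    Structured effects are updated by Metropolis sweeps over the color
    classes of the adjacency graph (conditionally independent blocks),
    tau_v by its conjugate Gibbs draw.
    """
    spec = spec or BymSpec()
    locations = np.asarray(locations, float)
    y = np.asarray(labels, float)
    n = len(y)
    adj = voronoi_adjacency(locations)
    deg = np.array([len(a) for a in adj], float)
    edges = np.array([(i, j) for i, nbrs in enumerate(adj) for j in nbrs if j > i])

    g = nx.Graph()
    g.add_nodes_from(range(n))
    g.add_edges_from(edges.tolist())
    comps = [np.array(sorted(c)) for c in nx.connected_components(g)]
    n_comp = len(comps)
    islands = np.array([c[0] for c in comps if len(c) == 1], int)
    if len(islands):
        logger.warning("%d isolated subjects receive only exchangeable effects", len(islands))
    colors = _graph_coloring(adj)

    # neighbor bookkeeping for vectorized conditional means
    nbr_flat = np.concatenate([np.array(a, int) for a in adj if a]) if any(adj) else np.array([], int)
    nbr_ptr = np.cumsum([0] + [len(a) for a in adj])

    def nbr_sum(v):
        s = np.add.reduceat(v[nbr_flat], nbr_ptr[:-1][deg > 0]) if len(nbr_flat) else np.zeros(0)
        out = np.zeros(n)
        out[deg > 0] = s
        return out

    def site_ll(eta):
        return y * eta - np.logaddexp(0.0, eta)

    ss = np.random.SeedSequence(spec.seed)
    exceed_chains = []
    vsum_mean = []
    for cseed in ss.spawn(spec.n_chains):
        rng = np.random.default_rng(cseed)
        beta0 = 0.0
        u = np.zeros(n)
        v = np.zeros(n)
        sigma_u = 0.5
        tau_v = 1.0
        b_scale, u_scale, v_scale = 0.2, 0.5, 0.5
        v_pos = np.zeros(n)
        vsum_acc = 0.0
        G = spec.n_save
        b_acc, u_accs, v_accs = [], [], []
        for it in range(spec.n_burn + G):
            adapt = it < spec.n_burn
            eta = beta0 + u + v

            # intercept (flat prior)
            prop = beta0 + b_scale * rng.normal()
            dll = float(np.sum(site_ll(eta + (prop - beta0)) - site_ll(eta)))
            acc = np.log(rng.uniform()) < dll
            if acc:
                beta0 = prop
                eta = beta0 + u + v
            b_acc.append(float(acc))
            if adapt and len(b_acc) % 50 == 0:
                b_scale = float(np.clip(b_scale * np.exp(1.5 * (np.mean(b_acc[-50:]) - 0.44)),
                                        1e-3, 10.0))

            # exchangeable effects, sitewise vectorized
            up = u + u_scale * rng.normal(size=n)
            dll = site_ll(beta0 + up + v) - site_ll(eta)
            dlp = -(up**2 - u**2) / (2 * sigma_u**2)
            accv = np.log(rng.uniform(size=n)) < dll + dlp
            u = np.where(accv, up, u)
            eta = beta0 + u + v
            u_accs.append(float(accv.mean()))
            if adapt and len(u_accs) % 50 == 0:
                u_scale = float(np.clip(u_scale * np.exp(1.5 * (np.mean(u_accs[-50:]) - 0.44)),
                                        1e-3, 10.0))

            # sigma_u: log walk, Uniform(0, upper) prior
            s = np.log(sigma_u) + 0.3 * rng.normal()
            sig = float(np.exp(s))
            if sig < spec.sigma_u_upper:
                ssq = float(u @ u)
                dl = (1 - n) * (s - np.log(sigma_u)) - ssq / 2 * (1 / sig**2 - 1 / sigma_u**2)
                if np.log(rng.uniform()) < dl:
                    sigma_u = sig

            # structured effects by color classes; ICAR full conditional
            # v_i ~ Normal(mean of neighbors, 1/(tau_v * deg_i))
            for cls in colors:
                cls_deg = deg[cls]
                active = cls[cls_deg > 0]
                if len(active) == 0:
                    continue
                m = nbr_sum(v)[active] / deg[active]
                vp = v.copy()
                vp[active] = v[active] + v_scale * rng.normal(size=len(active))
                dll = site_ll(beta0 + u + vp)[active] - site_ll(eta)[active]
                dlp = -tau_v * deg[active] / 2 * ((vp[active] - m) ** 2 - (v[active] - m) ** 2)
                accv = np.log(rng.uniform(size=len(active))) < dll + dlp
                v[active] = np.where(accv, vp[active], v[active])
                eta = beta0 + u + v
                v_accs.append(float(accv.mean()))
            if adapt and len(v_accs) >= 50 and len(v_accs) % 50 == 0:
                v_scale = float(np.clip(v_scale * np.exp(1.5 * (np.mean(v_accs[-50:]) - 0.44)),
                                        1e-3, 10.0))

            # sum-to-zero recentering per connected component
            for comp in comps:
                if len(comp) > 1:
                    v[comp] -= v[comp].mean()
            if len(islands):
                v[islands] = 0.0

            # conjugate Gibbs for tau_v
            if len(edges):
                quad = float(np.sum((v[edges[:, 0]] - v[edges[:, 1]]) ** 2))
                shape = spec.tau_v_shape + 0.5 * (n - len(islands) - (n_comp - len(islands)))
                tau_v = float(rng.gamma(shape, 1.0 / (spec.tau_v_rate + 0.5 * quad)))

            if it >= spec.n_burn:
                v_pos += (v > 0.0)
                vsum_acc += float(v.sum())
        exceed_chains.append(v_pos / G)
        vsum_mean.append(vsum_acc / G)

    q = np.mean(exceed_chains, axis=0)
    flagged = q > spec.exceedance_threshold
    members = np.flatnonzero(flagged)
    if len(members) >= 1:
        pts = MultiPoint(locations[members].tolist())
        hull = pts.convex_hull
        area = float(hull.area)
    else:
        hull, area = None, 0.0
    return ClusterResult(
        method="bym",
        members=members,
        hull=hull,
        area_km2=area,
        significant=len(members) > 0,
        exceedance=q,
    )


# ---------------------------------------------------------------------------
# Hull geometry
# ---------------------------------------------------------------------------

def hull_area(points: np.ndarray) -> float:
    """Convex-hull area in km^2; zero for fewer than three points."""
    points = np.asarray(points, float)
    if len(points) < 3:
        return 0.0
    return float(MultiPoint(points.tolist()).convex_hull.area)


def hull_overlap(hull_sim, hull_obs) -> tuple[float, float, bool]:
    """Intersection area of two hulls, the percentage of the simulated
    hull covered, and whether any overlap exists."""
    if hull_sim is None or hull_obs is None:
        return 0.0, 0.0, False
    if getattr(hull_sim, "area", 0.0) <= 0 or getattr(hull_obs, "area", 0.0) <= 0:
        return 0.0, 0.0, False
    inter = hull_sim.intersection(hull_obs).area
    pct = 100.0 * inter / hull_sim.area
    return float(inter), float(pct), inter > 0
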
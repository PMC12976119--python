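"""Synthetic study-system generators with known ground truth.

Three generators emulate the inputs of a stream-amphipod barcoding study:

* a dendritic stream network (binary confluence tree draining to a single
  outlet) with downstream-non-increasing elevation;
* a site table whose habitat covariates (slope, Strahler order, drainage
  category, elevation, an elevation-lapse temperature) are derived from
  the network itself, plus a logistic presence/absence model on those
  covariates;
* COI-like haplotype alignments from a two-epoch ("sudden expansion")
  coalescent with infinite-sites mutation, optionally organised into
  divergent haplotype groups whose samples are spatially clustered
  around group centroids.

Time and parameter scaling follow the mismatch-distribution convention
for haploid mitochondrial data: time t is measured in mutational units
(t = 2*u*generations) and theta = 2*N*u, so a pair of lineages that
coalesces at time t differs at Poisson(t) positions.  Concretely, with k
lineages the coalescence rate is C(k,2)/theta1 for t < tau and
C(k,2)/theta0 for t >= tau, and mutations fall on each branch as Poisson
with rate 1/2 per unit time.  Infinite-sites placement assigns every
mutation a previously unused alignment column; if the mutation count
exceeds the alignment length the simulation aborts with an error rather
than silently falling back to finite sites, so S and pi remain exact for
oracle computations.

Every operation draws from a single seeded generator; there is no global
random state.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .popgen_core import HaplotypeAlignment, collapse_haplotypes
from .stream_geometry import (
    SiteRecord,
    StreamNetwork,
    StreamNetworkError,
    drainage_category,
    river_order_category,
    site_slope,
    strahler_order,
)

BASES = np.frombuffer(b"ACGT", dtype="S1")

# Default study-scale conditions: a catchment of ~50 x 50 km, ~1000-site
# sampling campaigns with a presence fraction around 15%, and 658-bp
# barcodes — the scale of the field system the generators emulate.
DEFAULT_EXTENT = (0.0, 0.0, 50_000.0, 50_000.0)
DEFAULT_SEQ_LEN = 658
DEFAULT_LAPSE_C_PER_KM = 6.5
DEFAULT_SEA_LEVEL_TEMP_C = 21.0


class SimulationError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Parameter containers


@dataclass
class PresenceModel:
    """Logistic presence/absence model on site covariates.

    The defaults plant the qualitative habitat signal of a lowland,
    warm-water species: strong avoidance of steep slopes, preference for
    warmer (lower-elevation) reaches and higher stream orders, with an
    intercept tuned to give a minority presence fraction on the default
    network.
    """

    intercept: float = -15.5
    coef_slope: float = -1.2        # per % channel slope
    coef_temp: float = 0.75         # per degree C
    coef_order: float = 0.35        # per Strahler order level

    def linear_predictor(self, slope, temp, order):
        return (self.intercept + self.coef_slope * np.asarray(slope)
                + self.coef_temp * np.asarray(temp)
                + self.coef_order * np.asarray(order))


@dataclass
class ExpansionParams:
    """Two-epoch coalescent parameters in mutational units.

    theta0 is the pre-expansion and theta1 the post-expansion scaled
    mutation parameter (theta = 2Nu); tau the expansion time (2ut).
    """

    theta0: float
    theta1: float
    tau: float
    n: int
    seq_len: int = DEFAULT_SEQ_LEN
    flags: list = field(default_factory=list)

    def __post_init__(self):
        if self.theta0 < 0 or self.theta1 <= 0 or self.tau < 0:
            raise ValueError("require theta0 >= 0, theta1 > 0, tau >= 0")
        if self.n < 2:
            raise ValueError("sample size must be >= 2")
        if self.seq_len <= 0:
            raise ValueError("seq_len must be positive")
        if self.theta0 > self.theta1:
            self.flags.append("theta0 > theta1: models a contraction, not an expansion")


# ---------------------------------------------------------------------------
# Stream-network generator


def generate_stream_network(n_sources: int,
                            extent: Sequence[float] = DEFAULT_EXTENT,
                            seed: int = 0) -> StreamNetwork:
    """Random dendritic network: n_sources headwaters merging to one outlet.

    Headwater channels receive steep elevation drops and lowland segments
    gentle ones, so channel slopes span roughly 0.1-15%.  Per-edge
    drainage areas (km^2) accumulate downstream from random headwater
    contributions.
    """
    if n_sources < 1:
        raise ValueError("n_sources must be >= 1")
    x0, y0, x1, y1 = map(float, extent)
    if x1 <= x0 or y1 <= y0:
        raise ValueError(f"degenerate extent {extent!r}")
    rng = np.random.default_rng(seed)
    g = nx.DiGraph()
    width, height = x1 - x0, y1 - y0

    xs = np.sort(rng.uniform(x0 + 0.02 * width, x1 - 0.02 * width, n_sources))
    active = []
    for i, x in enumerate(xs):
        y = y1 - rng.uniform(0.0, 0.08 * height)
        elev = rng.uniform(500.0, 1800.0)
        g.add_node(i, x=float(x), y=float(y), elevation=float(elev))
        active.append({"node": i, "x": float(x), "y": float(y), "elev": float(elev),
                       "area": float(rng.uniform(2.0, 20.0)), "depth": 0})
    next_id = n_sources

    def add_edge(parent, child_node, child_xy, child_elev, area):
        px, py, pz = parent["x"], parent["y"], parent["elev"]
        cx, cy = child_xy
        mx = (px + cx) / 2 + rng.uniform(-0.02, 0.02) * width
        my = (py + cy) / 2
        mz = pz - (pz - child_elev) * rng.uniform(0.3, 0.7)
        geom = [(px, py, pz), (mx, my, mz), (cx, cy, child_elev)]
        g.add_edge(parent["node"], child_node, geometry=geom, drainage_km2=area)

    while len(active) > 1:
        i = int(rng.integers(len(active) - 1))
        a, b = active[i], active[i + 1]
        cx = (a["x"] + b["x"]) / 2 + rng.uniform(-0.03, 0.03) * width
        cx = min(max(cx, x0), x1)
        step = height / (n_sources + 1) * rng.uniform(0.6, 1.4)
        cy = max(min(a["y"], b["y"]) - step, y0 + 0.02 * height)
        depth = max(a["depth"], b["depth"]) + 1
        seg_len = max(np.hypot(cx - a["x"], cy - a["y"]),
                      np.hypot(cx - b["x"], cy - b["y"]))
        # steeper gradients near the headwaters, gentle in lowland reaches
        lo, hi = (0.01, 0.15) if depth <= 1 else (0.0005, 0.02)
        gradient = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        drop = min(gradient * seg_len, 0.9 * min(a["elev"], b["elev"]))
        celev = min(a["elev"], b["elev"]) - drop
        node = next_id
        next_id += 1
        g.add_node(node, x=float(cx), y=float(cy), elevation=float(celev))
        area = a["area"] + b["area"] + float(rng.uniform(0.5, 5.0))
        add_edge(a, node, (cx, cy), celev, a["area"])
        add_edge(b, node, (cx, cy), celev, b["area"])
        active[i:i + 2] = [{"node": node, "x": float(cx), "y": float(cy),
                            "elev": float(celev), "area": area, "depth": depth}]

    last = active[0]
    ox = min(max(last["x"] + rng.uniform(-0.05, 0.05) * width, x0), x1)
    oy = y0
    seg_len = np.hypot(ox - last["x"], oy - last["y"])
    drop = min(float(np.exp(rng.uniform(np.log(0.0005), np.log(0.01)))) * seg_len,
               0.95 * last["elev"])
    oelev = last["elev"] - drop
    outlet = next_id
    g.add_node(outlet, x=float(ox), y=float(oy), elevation=float(oelev))
    add_edge(last, outlet, (ox, oy), oelev,
             last["area"] + float(rng.uniform(0.5, 5.0)))
    return StreamNetwork(g)


# ---------------------------------------------------------------------------
# Site generator


def generate_sites(network: StreamNetwork, n_sites: int, seed: int = 0,
                   reach: float = 100.0,
                   lapse_c_per_km: float = DEFAULT_LAPSE_C_PER_KM,
                   sea_level_temp_c: float = DEFAULT_SEA_LEVEL_TEMP_C,
                   spring_dist: float = 50.0) -> pd.DataFrame:
    """Anchor n_sites random sites on the network and derive covariates.

    Sites are placed on edges chosen with probability proportional to
    edge length, then uniformly along the edge.  Positions whose slope
    section is invalid (squeezed between outlet and confluence) are
    resampled.  The temperature covariate is a linear elevation lapse.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    rng = np.random.default_rng(seed)
    edges = list(network.graph.edges)
    lengths = np.array([network.edge_length(*e) for e in edges])
    probs = lengths / lengths.sum()
    orders = strahler_order(network)

    from .stream_geometry import _walk  # walk helper shared with site_slope

    rows = []
    attempts = 0
    while len(rows) < n_sites:
        attempts += 1
        if attempts > 50 * n_sites:
            raise SimulationError("could not place sites with valid slope sections")
        e = edges[int(rng.choice(len(edges), p=probs))]
        pos = float(rng.uniform(0.0, network.edge_length(*e)))
        site = SiteRecord(site_id=len(rows), edge=e, dist_along=pos)
        try:
            res = site_slope(network, site, reach=reach)
        except StreamNetworkError:
            continue
        x, y = network.point_at(*e, pos)
        elev = network.elevation_at(*e, pos)
        is_spring = _walk(network, e, pos, spring_dist, "up")[0] == "spring"
        order = orders[e]
        area = float(network.graph.edges[e].get("drainage_km2", np.nan))
        if not np.isfinite(area):
            area = 5.0 * order ** 2  # crude fallback when edges lack areas
        rows.append(
            {
                "site_id": len(rows),
                "x": x,
                "y": y,
                "edge_u": e[0],
                "edge_v": e[1],
                "dist_along": pos,
                "habitat": "spring" if is_spring else "stream",
                "slope_pct": res.slope_pct,
                "order": order,
                "order_cat": river_order_category(order, is_spring),
                "drainage_km2": area,
                "drainage_cat": drainage_category(area, is_spring),
                "elevation": elev,
                "temperature": sea_level_temp_c - lapse_c_per_km * elev / 1000.0,
            }
        )
    return pd.DataFrame(rows)


def simulate_presence(sites: pd.DataFrame, model: PresenceModel | None = None,
                      seed: int = 0, column: str = "presence") -> pd.DataFrame:
    """Add a Bernoulli presence column from the logistic habitat model."""
    from scipy.special import expit

    model = model or PresenceModel()
    out = sites.copy()
    for cov in ("slope_pct", "temperature", "order"):
        bad = out.index[~np.isfinite(out[cov].to_numpy(float))].tolist()
        if bad:
            ids = out.loc[bad, "site_id"].tolist()
            raise ValueError(f"non-finite covariate {cov!r} at sites {ids}")
    lp = model.linear_predictor(out["slope_pct"], out["temperature"], out["order"])
    prob = expit(lp)
    rng = np.random.default_rng(seed)
    out[column + "_prob"] = prob
    out[column] = (rng.random(len(out)) < prob).astype(int)
    return out


# ---------------------------------------------------------------------------
# Two-epoch coalescent


def _simulate_branches(n: int, theta0: float, theta1: float, tau: float, rng):
    """Coalescent genealogy; yields (descendant sample indices, branch length).

    Branch lengths are in mutational units.  theta0 == 0 collapses all
    lineages surviving at tau instantaneously (star genealogy).
    """
    lineages = [(i,) for i in range(n)]
    birth = {lin: 0.0 for lin in lineages}
    branches = []
    t = 0.0
    while len(lineages) > 1:
        k = len(lineages)
        pairs = k * (k - 1) / 2.0
        if t < tau:
            w = rng.exponential(theta1 / pairs)
            if t + w > tau:
                if theta0 == 0.0:
                    # everything alive at tau coalesces at tau
                    for lin in lineages:
                        branches.append((lin, tau - birth[lin]))
                    merged = tuple(i for lin in lineages for i in lin)
                    lineages = [merged]
                    birth[merged] = tau
                    break
                t = tau + rng.exponential(theta0 / pairs)
            else:
                t += w
        else:
            if theta0 == 0.0:
                for lin in lineages:
                    branches.append((lin, t - birth[lin]))
                merged = tuple(i for lin in lineages for i in lin)
                lineages = [merged]
                birth[merged] = t
                break
            t += rng.exponential(theta0 / pairs)
        i, j = rng.choice(k, size=2, replace=False)
        i, j = int(i), int(j)
        a, b = lineages[i], lineages[j]
        branches.append((a, t - birth[a]))
        branches.append((b, t - birth[b]))
        merged = a + b
        lineages = [lin for m, lin in enumerate(lineages) if m not in (i, j)]
        lineages.append(merged)
        birth[merged] = t
    return branches


def _mutate_branches(branches, rng):
    """Poisson(length / 2) mutations per branch; returns per-mutation carrier tuples."""
    carriers = []
    lens = np.array([b[1] for b in branches])
    counts = rng.poisson(lens / 2.0)
    for (desc, _), m in zip(branches, counts):
        carriers.extend([desc] * int(m))
    return carriers


def simulate_coalescent_expansion(params: ExpansionParams,
                                  seed: int = 0,
                                  rng: np.random.Generator | None = None,
                                  ancestral: np.ndarray | None = None,
                                  sample_prefix: str = "s") -> HaplotypeAlignment:
    """Simulate an alignment under the sudden-expansion coalescent.

    Mutations are placed by infinite sites: each gets a fresh alignment
    column and flips the ancestral base to a random different base for
    its carriers.  Raises :class:`SimulationError` when the mutation
    count exceeds ``seq_len`` (increase ``seq_len`` instead of accepting
    a finite-sites approximation).
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    branches = _simulate_branches(params.n, params.theta0, params.theta1,
                                  params.tau, rng)
    carriers = _mutate_branches(branches, rng)
    m = len(carriers)
    if m > params.seq_len:
        raise SimulationError(
            f"{m} mutations exceed the {params.seq_len} available positions; "
            "rerun with a larger seq_len (infinite-sites placement does not "
            "reuse positions)"
        )
    if ancestral is None:
        ancestral = BASES[rng.integers(0, 4, params.seq_len)]
    mat = np.tile(ancestral, (params.n, 1))
    positions = rng.choice(params.seq_len, size=m, replace=False)
    for pos, desc in zip(positions, carriers):
        anc = mat[0, pos]
        derived = BASES[BASES != anc][rng.integers(0, 3)]
        mat[list(desc), pos] = derived
    ids = [f"{sample_prefix}{i}" for i in range(params.n)]
    return HaplotypeAlignment(ids, mat)


def _summaries_from_carriers(n: int, carriers) -> tuple[int, float, int]:
    npairs = n * (n - 1) / 2.0
    s = len(carriers)
    pi = sum(len(d) * (n - len(d)) for d in carriers) / npairs
    sigs = [[] for _ in range(n)]
    for b, desc in enumerate(carriers):
        for i in desc:
            sigs[i].append(b)
    k = len({tuple(sig) for sig in sigs})
    return s, pi, k


def simulate_neutral_summaries(n: int, theta: float, rng) -> tuple[int, float, int]:
    """Fast constant-size coalescent summaries (S, pi, haplotype count).

    Sequence-free path used for simulation nulls: S is the mutation
    count, pi accumulates c(n-c)/C(n,2) per mutation, and the haplotype
    count is the number of distinct mutation signatures.
    """
    if theta <= 0:
        return 0, 0.0, 1
    branches = _simulate_branches(n, theta, theta, 0.0, rng)
    return _summaries_from_carriers(n, _mutate_branches(branches, rng))


def simulate_expansion_summaries(n: int, theta0: float, theta1: float,
                                 tau: float, rng) -> tuple[int, float, int]:
    """Fast two-epoch coalescent summaries (S, pi, haplotype count)."""
    branches = _simulate_branches(n, theta0, theta1, tau, rng)
    return _summaries_from_carriers(n, _mutate_branches(branches, rng))


def simulate_pair_differences(theta0: float, theta1: float, tau: float,
                              reps: int, seed: int = 0,
                              rng: np.random.Generator | None = None) -> np.ndarray:
    """Vectorised pairwise-difference draws for n = 2 (Monte-Carlo oracle)."""
    rng = rng if rng is not None else np.random.default_rng(seed)
    recent = rng.exponential(theta1, reps)
    t = np.where(recent <= tau, recent,
                 tau + (rng.exponential(theta0, reps) if theta0 > 0 else 0.0))
    return rng.poisson(t)


# ---------------------------------------------------------------------------
# Spatial placement of sequences


def assign_sequences_to_sites(alignment: HaplotypeAlignment,
                              sites: pd.DataFrame,
                              n_centroids: int = 3,
                              decay_scale: float = 15_000.0,
                              seed: int = 0,
                              presence_column: str = "presence") -> pd.DataFrame:
    """Place each sample at a presence site, clustered by haplotype.

    Haplotypes are partitioned into ``n_centroids`` clusters (nearest of
    randomly chosen medoid haplotypes by Hamming distance); each cluster
    receives a random presence site as its geographic centroid and its
    samples land on presence sites with probability proportional to
    exp(-distance / decay_scale).  ``decay_scale = 0`` confines every
    cluster to its centroid site.
    """
    if presence_column in sites.columns:
        pres = sites[sites[presence_column] == 1].reset_index(drop=True)
    else:
        pres = sites.reset_index(drop=True)
    if len(pres) == 0:
        raise ValueError("no presence sites to place sequences on")
    if n_centroids < 1:
        raise ValueError("n_centroids must be >= 1")
    rng = np.random.default_rng(seed)

    table = collapse_haplotypes(alignment)
    k = table.k
    n_centroids = min(n_centroids, k)
    hap_mat = np.frombuffer("".join(table.sequences).encode(), dtype="S1"
                            ).reshape(k, -1)
    medoids = rng.choice(k, size=n_centroids, replace=False)
    dist_to_medoid = np.stack(
        [(hap_mat != hap_mat[m]).sum(axis=1) for m in medoids], axis=1
    )
    hap_cluster = dist_to_medoid.argmin(axis=1)
    sample_cluster = {}
    for h, members in enumerate(table.members):
        for sid in members:
            sample_cluster[sid] = int(hap_cluster[h])

    centroid_sites = rng.choice(len(pres), size=n_centroids, replace=len(pres) < n_centroids)
    xy = pres[["x", "y"]].to_numpy(float)
    rows = []
    for sid in alignment.sample_ids:
        c = sample_cluster[sid]
        cxy = xy[centroid_sites[c]]
        d = np.hypot(xy[:, 0] - cxy[0], xy[:, 1] - cxy[1])
        if decay_scale <= 0:
            site_idx = int(d.argmin())
        else:
            w = np.exp(-d / decay_scale)
            w /= w.sum()
            site_idx = int(rng.choice(len(pres), p=w))
        rows.append({"sample_id": sid,
                     "site_id": pres.loc[site_idx, "site_id"],
                     "cluster": c})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Whole-study bundle


@dataclass
class StudyTruth:
    seed: int
    n_sources: int
    presence_model: dict
    groups: list          # per-group dicts: tau, theta0, theta1, n
    group_divergence_steps: int


def simulate_study(n_sources: int = 12, n_sites: int = 300,
                   groups: Sequence[ExpansionParams] | None = None,
                   group_divergence_steps: int = 12,
                   extent: Sequence[float] = DEFAULT_EXTENT,
                   presence_model: PresenceModel | None = None,
                   n_centroids_per_group: int = 1,
                   decay_scale: float = 12_000.0,
                   seed: int = 0):
    """Generate a self-consistent synthetic study bundle.

    Returns (network, sites, alignment, sample_table, truth).  Haplotype
    groups are simulated as independent sudden expansions on a shared
    ancestral sequence, separated by ``group_divergence_steps`` fixed
    private mutations per group, then placed on presence sites clustered
    around one centroid per group (a modelling convenience: the real
    demography linking the groups is unknown).
    """
    rng = np.random.default_rng(seed)
    presence_model = presence_model or PresenceModel()
    if groups is None:
        groups = [
            ExpansionParams(theta0=0.5, theta1=60.0, tau=2.5, n=120),
            ExpansionParams(theta0=0.2, theta1=40.0, tau=1.3, n=80),
        ]
    seq_len = groups[0].seq_len

    network = generate_stream_network(n_sources, extent,
                                      seed=int(rng.integers(2 ** 31)))
    sites = generate_sites(network, n_sites, seed=int(rng.integers(2 ** 31)))
    sites = simulate_presence(sites, presence_model,
                              seed=int(rng.integers(2 ** 31)))
    if sites["presence"].sum() == 0:
        # guarantee at least one presence site to anchor sequences
        sites.loc[sites["slope_pct"].idxmin(), "presence"] = 1

    ancestral = BASES[rng.integers(0, 4, seq_len)]
    position_pool = rng.permutation(seq_len)
    pool_cursor = 0
    mats, ids, labels = [], [], []
    for gi, params in enumerate(groups):
        sub = simulate_coalescent_expansion(
            params, rng=rng, ancestral=ancestral, sample_prefix=f"g{gi}_"
        )
        mat = sub.matrix.copy()
        # fixed private differences separating this group from the others
        for _ in range(group_divergence_steps if gi > 0 else 0):
            if pool_cursor >= seq_len:
                raise SimulationError("seq_len too short for group divergence")
            pos = position_pool[pool_cursor]
            pool_cursor += 1
            anc = ancestral[pos]
            mat[:, pos] = BASES[BASES != anc][rng.integers(0, 3)]
        mats.append(mat)
        ids.extend(sub.sample_ids)
        labels.extend([gi] * params.n)
    alignment = HaplotypeAlignment(ids, np.vstack(mats))

    samples = []
    for gi, params in enumerate(groups):
        idx = [i for i, lab in enumerate(labels) if lab == gi]
        sub = alignment.subset(idx)
        placed = assign_sequences_to_sites(
            sub, sites, n_centroids=n_centroids_per_group,
            decay_scale=decay_scale, seed=int(rng.integers(2 ** 31)),
        )
        placed["group"] = gi
        samples.append(placed)
    sample_table = pd.concat(samples, ignore_index=True)
    site_of = dict(zip(sample_table["sample_id"], sample_table["site_id"]))
    alignment.site_ids = [site_of[sid] for sid in alignment.sample_ids]

    truth = StudyTruth(
        seed=seed,
        n_sources=n_sources,
        presence_model=asdict(presence_model),
        groups=[{"tau": p.tau, "theta0": p.theta0, "theta1": p.theta1, "n": p.n}
                for p in groups],
        group_divergence_steps=group_divergence_steps,
    )
    return network, sites, alignment, sample_table, truth


def write_truth(truth: StudyTruth, path) -> None:
    with open(path, "w") as fh:
        json.dump(asdict(truth), fh, indent=2)
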
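"""Randomization tests of habitat preference and the two-species contrasts.

The core procedure compares habitat characteristics of the sites where a
species is present against random subsets of all sampled sites: B random
subsets of the same size as the presence set are drawn without
replacement, and a per-direction p-value is the proportion of subsets
whose statistic is strictly more extreme (higher, or lower) than the
observed one.  With two-sided testing, each direction is judged at
alpha/2 (the study convention: p < 0.025 per tail).  Both the raw
proportion and the bias-corrected (k+1)/(B+1) form are reported; the raw
form is the default used downstream.

Also provided: a Monte-Carlo Pearson chi-squared contrast between two
species' category profiles (sites hosting both species appear in both
rows), the Wilcoxon rank-sum slope contrast, minimum-distance spatial
thinning of presence/absence records, and Spearman-cluster + VIF
predictor pre-selection for distribution modelling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree


@dataclass
class TestConfig:
    B: int = 1000
    alpha_two_sided: float = 0.025      # per-tail threshold for two-sided tests
    seed: int = 0
    summaries: tuple = ("min", "mean", "median", "max")

    def __post_init__(self):
        if self.B < 1:
            raise ValueError("B must be >= 1")
        if not 0 < self.alpha_two_sided < 0.5:
            raise ValueError("alpha_two_sided must lie in (0, 0.5)")


@dataclass
class RandomizationResult:
    observed: dict                      # statistic -> observed value
    null: dict                          # statistic -> (B,) null draws
    p_low: dict                         # fraction of null strictly below observed
    p_high: dict                        # fraction strictly above
    p_tie: dict                         # fraction exactly equal
    p_low_corrected: dict               # tie-inclusive (k+1)/(B+1): valid form
    p_high_corrected: dict
    B: int
    subset_size: int
    seed: int

    def significant(self, alpha: float = 0.025) -> dict:
        """Per-statistic direction flag at the per-tail threshold."""
        out = {}
        for key in self.observed:
            if self.p_high[key] < alpha:
                out[key] = "over"
            elif self.p_low[key] < alpha:
                out[key] = "under"
            else:
                out[key] = "ns"
        return out


def _directional_p(null: np.ndarray, obs: float, B: int) -> tuple:
    """Raw strict proportions plus tie-inclusive bias-corrected p-values.

    The raw form mirrors the study's wording ("proportion of subsets more
    extreme"); the corrected form (#{at least as extreme} + 1) / (B + 1)
    counts ties and is the exchangeable-valid permutation p-value.
    """
    low = int((null < obs).sum())
    high = int((null > obs).sum())
    tie = B - low - high
    return (low / B, high / B, tie / B,
            (low + tie + 1) / (B + 1), (high + tie + 1) / (B + 1))


def _draw_subsets(rng, B: int, n_total: int, size: int) -> np.ndarray:
    """(B, size) indices of subsets drawn without replacement."""
    keys = rng.random((B, n_total))
    return np.argpartition(keys, size - 1, axis=1)[:, :size]


def category_randomization_test(sites: pd.DataFrame, presence: str,
                                category: str,
                                config: TestConfig | None = None
                                ) -> RandomizationResult:
    """Observed per-category presence counts vs counts in random subsets."""
    config = config or TestConfig()
    pres_mask = sites[presence].to_numpy() == 1
    n_pres = int(pres_mask.sum())
    n_total = len(sites)
    if n_pres < 1:
        raise ValueError("no presence sites")
    if n_pres > n_total:
        raise ValueError("presence count exceeds total sites")
    cats = sites[category]
    if isinstance(cats.dtype, pd.CategoricalDtype):
        levels = list(cats.cat.categories)
    else:
        levels = sorted(pd.unique(cats), key=str)
    codes = pd.Categorical(cats, categories=levels).codes.astype(int)
    K = len(levels)

    obs = np.bincount(codes[pres_mask], minlength=K)
    rng = np.random.default_rng(config.seed)
    idx = _draw_subsets(rng, config.B, n_total, n_pres)
    null = np.zeros((config.B, K), dtype=int)
    np.add.at(null, (np.arange(config.B)[:, None], codes[idx]), 1)

    observed, nulls, p_lo, p_hi, p_tie, p_loc, p_hic = {}, {}, {}, {}, {}, {}, {}
    for k, level in enumerate(levels):
        observed[level] = int(obs[k])
        nulls[level] = null[:, k]
        lo, hi, tie, loc, hic = _directional_p(null[:, k], obs[k], config.B)
        p_lo[level], p_hi[level], p_tie[level] = lo, hi, tie
        p_loc[level], p_hic[level] = loc, hic
    return RandomizationResult(observed, nulls, p_lo, p_hi, p_tie, p_loc, p_hic,
                               config.B, n_pres, config.seed)


def continuous_randomization_test(sites: pd.DataFrame, presence: str,
                                  value: str,
                                  config: TestConfig | None = None
                                  ) -> RandomizationResult:
    """Summary statistics of a continuous variable vs random subsets."""
    config = config or TestConfig()
    vals = sites[value].to_numpy(float)
    if not np.all(np.isfinite(vals)):
        raise ValueError(f"non-finite values in column {value!r}")
    pres_mask = sites[presence].to_numpy() == 1
    n_pres = int(pres_mask.sum())
    if n_pres < 1:
        raise ValueError("no presence sites")
    stat_funcs = {"min": np.min, "mean": np.mean, "median": np.median,
                  "max": np.max}
    unknown = set(config.summaries) - set(stat_funcs)
    if unknown:
        raise ValueError(f"unknown summary statistics {unknown}")

    rng = np.random.default_rng(config.seed)
    idx = _draw_subsets(rng, config.B, len(sites), n_pres)
    subset_vals = vals[idx]                      # (B, n_pres)

    observed, nulls, p_lo, p_hi, p_tie, p_loc, p_hic = {}, {}, {}, {}, {}, {}, {}
    for name in config.summaries:
        f = stat_funcs[name]
        obs = float(f(vals[pres_mask]))
        null = f(subset_vals, axis=1)
        observed[name] = obs
        nulls[name] = null
        lo, hi, tie, loc, hic = _directional_p(null, obs, config.B)
        p_lo[name], p_hi[name], p_tie[name] = lo, hi, tie
        p_loc[name], p_hic[name] = loc, hic
    return RandomizationResult(observed, nulls, p_lo, p_hi, p_tie, p_loc, p_hic,
                               config.B, n_pres, config.seed)


# ---------------------------------------------------------------------------
# Two-species contrasts


def species_category_chisq(sites: pd.DataFrame, presence_a: str,
                           presence_b: str, category: str,
                           B_mc: int = 2000, seed: int = 0) -> tuple[float, float]:
    """Monte-Carlo Pearson chi-squared on the 2 x K category-count table.

    Row A holds per-category counts of sites where species A is present,
    row B likewise (dual-presence sites are counted in both rows).  The
    null tables are sampled with both margins fixed and
    p = (1 + #{X2_sim >= X2_obs}) / (B_mc + 1).
    """
    cats = sites[category]
    levels = sorted(pd.unique(cats), key=str)
    codes = pd.Categorical(cats, categories=levels).codes.astype(int)
    row_a = np.bincount(codes[sites[presence_a].to_numpy() == 1],
                        minlength=len(levels))
    row_b = np.bincount(codes[sites[presence_b].to_numpy() == 1],
                        minlength=len(levels))
    keep = (row_a + row_b) > 0
    row_a, row_b = row_a[keep], row_b[keep]
    if len(row_a) < 2:
        raise ValueError("need at least two categories with nonzero totals")
    if row_a.sum() == 0 or row_b.sum() == 0:
        raise ValueError("a species has zero presence sites")

    def x2(ra, rb):
        table = np.stack([ra, rb]).astype(float)
        exp = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
        return float(((table - exp) ** 2 / exp).sum())

    obs = x2(row_a, row_b)
    rng = np.random.default_rng(seed)
    colsum = (row_a + row_b).astype(int)
    n_a = int(row_a.sum())
    count = 0
    for _ in range(B_mc):
        sim_a = rng.multivariate_hypergeometric(colsum, n_a)
        if x2(sim_a, colsum - sim_a) >= obs - 1e-12:
            count += 1
    p = (1 + count) / (B_mc + 1)
    return obs, p


def rank_sum_test(values_a, values_b,
                  alternative: str = "two-sided") -> tuple[float, float]:
    """Wilcoxon rank-sum contrast; returns (W, p).

    W is the Mann-Whitney statistic for group A (the rank sum of A in the
    pooled sample minus its minimum).  Exact enumeration is used for
    samples of at most 50 without ties; otherwise the normal
    approximation with tie and continuity corrections.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    if np.isnan(a).any() or np.isnan(b).any():
        raise ValueError("NaN values in input")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (max(a.size, b.size) <= 50 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative=alternative, method=method,
                             use_continuity=True)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Spatial thinning


def _violating_pairs(xy: np.ndarray, min_dist: float) -> list:
    tree = cKDTree(xy)
    return sorted(
        tree.query_pairs(min_dist, output_type="ndarray").tolist(),
        key=lambda ij: (float(np.hypot(*(xy[ij[0]] - xy[ij[1]]))), ij[0], ij[1]),
    )


def _break_pairs(n: int, pairs: list, degree: np.ndarray,
                 rng=None) -> np.ndarray:
    """One thinning pass: process pairs by distance, drop one intact member.

    Deterministic when ``rng`` is None (drop the member with more
    violations, ties to the higher index); otherwise a random member.
    """
    alive = np.ones(n, dtype=bool)
    for i, j in pairs:
        if alive[i] and alive[j]:
            if rng is None:
                drop = j if (degree[j], j) >= (degree[i], i) else i
            else:
                drop = j if rng.random() < 0.5 else i
            alive[drop] = False
    return alive


def _thin_one_class(xy: np.ndarray, min_dist: float, reps: int, rng
                    ) -> np.ndarray:
    """Greedy thinning; returns the boolean keep mask of the best restart.

    Violating pairs are processed in order of increasing distance.  The
    first restart breaks pairs deterministically (the single greedy pass
    baseline); the remaining restarts drop a random member.  The restart
    retaining the most points wins, so the result is never worse than
    the deterministic pass.
    """
    n = len(xy)
    if n <= 1:
        return np.ones(n, dtype=bool)
    pairs = _violating_pairs(xy, min_dist)
    if not pairs:
        return np.ones(n, dtype=bool)
    degree = np.zeros(n, dtype=int)
    for i, j in pairs:
        degree[i] += 1
        degree[j] += 1
    best = _break_pairs(n, pairs, degree)
    for _ in range(max(reps - 1, 0)):
        alive = _break_pairs(n, pairs, degree, rng)
        if alive.sum() > best.sum():
            best = alive
    return best


def spatial_thin(sites: pd.DataFrame, presence: str,
                 min_dist: float = 2000.0, reps: int = 20,
                 seed: int = 0) -> pd.DataFrame:
    """Three-step minimum-distance thinning of presence/absence records.

    1. absences within ``min_dist`` of any presence are removed;
    2. presences are thinned to pairwise distances >= min_dist;
    3. the remaining absences are thinned likewise.
    Steps 2-3 use randomized greedy pair-breaking with ``reps`` restarts,
    keeping the largest retained set.  Returns the retained rows.
    """
    if min_dist <= 0:
        raise ValueError("min_dist must be positive")
    rng = np.random.default_rng(seed)
    xy = sites[["x", "y"]].to_numpy(float)
    pres_mask = sites[presence].to_numpy() == 1
    pres_xy = xy[pres_mask]
    abs_idx = np.flatnonzero(~pres_mask)

    if len(pres_xy) and len(abs_idx):
        d, _ = cKDTree(pres_xy).query(xy[abs_idx], k=1)
        abs_idx = abs_idx[d >= min_dist]

    pres_idx = np.flatnonzero(pres_mask)
    keep_pres = pres_idx[_thin_one_class(xy[pres_idx], min_dist, reps, rng)] \
        if len(pres_idx) else pres_idx
    keep_abs = abs_idx[_thin_one_class(xy[abs_idx], min_dist, reps, rng)] \
        if len(abs_idx) else abs_idx
    keep = np.sort(np.concatenate([keep_pres, keep_abs]))
    return sites.iloc[keep]


def greedy_thin_baseline(xy: np.ndarray, min_dist: float) -> np.ndarray:
    """Deterministic single greedy pass (comparison baseline).

    Breaks violating pairs in order of increasing distance, always
    dropping the member with more remaining violations (ties to the
    higher index) — the pass the randomized restarts must match or beat.
    """
    n = len(xy)
    if n <= 1:
        return np.ones(n, dtype=bool)
    pairs = _violating_pairs(xy, min_dist)
    degree = np.zeros(n, dtype=int)
    for i, j in pairs:
        degree[i] += 1
        degree[j] += 1
    return _break_pairs(n, pairs, degree)


# ---------------------------------------------------------------------------
# Predictor selection


@dataclass
class PredictorSelection:
    clusters: list                      # list of variable-name lists
    representatives: list               # one per cluster, by preference
    selected: list                      # after VIF pruning
    vif: dict                           # selected variable -> VIF
    excluded_constant: list = field(default_factory=list)


def _vif(frame: pd.DataFrame) -> dict:
    from statsmodels.stats.outliers_influence import variance_inflation_factor
    from statsmodels.tools import add_constant

    if frame.shape[1] == 1:
        return {frame.columns[0]: 1.0}
    X = add_constant(frame.to_numpy(float))
    return {col: float(variance_inflation_factor(X, i + 1))
            for i, col in enumerate(frame.columns)}


def select_predictors(table: pd.DataFrame, rho_cut: float = 0.7,
                      vif_max: float = 3.0,
                      preference: list | None = None) -> PredictorSelection:
    """Spearman-cluster then VIF-prune variable pre-selection.

    Variables joined by |Spearman rho| >= rho_cut form clusters
    (connected components); one representative per cluster is chosen by
    the preference order (default: input column order), then
    representatives are dropped in reverse preference until every VIF is
    below ``vif_max``.  Constant variables are excluded with a warning.
    """
    import warnings

    import networkx as nx

    if table.shape[1] < 2 or table.shape[0] < 3:
        raise ValueError("need at least 2 variables and 3 rows")
    constant = [c for c in table.columns if table[c].nunique() <= 1]
    if constant:
        warnings.warn(f"constant variables excluded: {constant}")
    cols = [c for c in table.columns if c not in constant]
    pref = [c for c in (preference or list(table.columns)) if c in cols]
    pref += [c for c in cols if c not in pref]

    rho = table[cols].corr(method="spearman").abs()
    g = nx.Graph()
    g.add_nodes_from(cols)
    for i, ci in enumerate(cols):
        for cj in cols[i + 1:]:
            if rho.loc[ci, cj] >= rho_cut:
                g.add_edge(ci, cj)
    rank = {c: i for i, c in enumerate(pref)}
    clusters = [sorted(comp, key=lambda c: rank[c])
                for comp in nx.connected_components(g)]
    clusters.sort(key=lambda comp: rank[comp[0]])
    representatives = [comp[0] for comp in clusters]

    selected = sorted(representatives, key=lambda c: rank[c])
    while len(selected) >= 1:
        vifs = _vif(table[selected])
        if all(v < vif_max for v in vifs.values()) or len(selected) == 1:
            break
        # drop the least-preferred representative among VIF offenders
        offenders = [c for c in selected if vifs[c] >= vif_max]
        selected.remove(max(offenders, key=lambda c: rank[c]))
    return PredictorSelection(clusters, representatives, selected,
                              _vif(table[selected]), constant)
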
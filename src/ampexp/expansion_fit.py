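"""Sudden-expansion (demographic) model for mismatch distributions.

A population at mutation-drift equilibrium with scaled mutation parameter
theta0 grows instantaneously to theta1 at time tau (mutational units)
before the present.  Under this model the number of differences between a
random pair of sequences is Poisson-mixed over the pair's coalescence
time, whose density is piecewise exponential:

    f(t) = exp(-t/theta1) / theta1                      for t < tau
    f(t) = exp(-tau/theta1) exp(-(t-tau)/theta0)/theta0 for t >= tau

giving class probabilities that reduce to the geometric equilibrium
distribution theta^j / (1+theta)^(j+1) when tau = 0 or theta0 = theta1.
The integrals are evaluated with regularised incomplete gamma functions
in log space, which stays stable for small theta0 (the near-star limit).

Parameters (tau, theta0, theta1) are estimated by least squares between
observed and expected relative class frequencies (SSD), with a
deterministic multi-start bounded optimisation.  Goodness of fit (SSD and
Harpending's raggedness index) is assessed by parametric bootstrap:
coalescent samples are simulated under the fitted parameters, refitted,
and the p-value is the fraction of replicates with a statistic at least
as large as observed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from math import comb

import numpy as np
from scipy import optimize, stats

from .popgen_core import HaplotypeAlignment, mismatch_distribution

# deterministic multi-start grid for the SSD optimiser; the model is an
# expansion, so the search space is constrained to theta1 >= theta0
# (parameterised as tau, log theta0, log of the growth ratio theta1/theta0)
START_TAU = (0.5, 1.0, 2.0, 4.0, 8.0)
START_THETA0 = (0.1, 1.0, 10.0)
START_THETA1 = (1.0, 10.0, 100.0, 1000.0)
BOUNDS_TAU = (0.0, 200.0)
BOUNDS_LOG_THETA0 = (np.log(1e-4), np.log(1e3))
BOUNDS_LOG_RATIO = (0.0, np.log(1e8))
OPT_TOL = 1e-8


@dataclass
class MismatchDistribution:
    """Pairwise-difference counts for a sample of n sequences."""

    counts: np.ndarray              # counts by difference class 0..d_max
    n: int

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 1 or len(self.counts) == 0:
            raise ValueError("counts must be a non-empty 1-D vector")
        expected_pairs = comb(self.n, 2)
        if self.counts.sum() != expected_pairs:
            raise ValueError(
                f"counts sum to {self.counts.sum()}, expected C({self.n},2)="
                f"{expected_pairs}"
            )

    @classmethod
    def from_alignment(cls, alignment: HaplotypeAlignment) -> "MismatchDistribution":
        return cls(mismatch_distribution(alignment), alignment.n)

    @property
    def freqs(self) -> np.ndarray:
        return self.counts / self.counts.sum()

    @property
    def d_max(self) -> int:
        return len(self.counts) - 1


@dataclass
class ExpansionFit:
    tau: float
    theta0: float
    theta1: float
    ssd: float
    raggedness: float
    p_ssd: float | None = None
    p_raggedness: float | None = None
    bootstrap_reps: int = 0
    flags: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# Model expectation


def expected_mismatch_sudden(tau: float, theta0: float, theta1: float,
                             d_max: int) -> tuple[np.ndarray, float]:
    """Class probabilities P(j differences), j = 0..d_max, plus tail mass.

    Returns (probs, tail) with probs.sum() + tail == 1.
    """
    for name, val in (("tau", tau), ("theta0", theta0), ("theta1", theta1)):
        if not np.isfinite(val) or val < 0:
            raise ValueError(f"non-finite or negative {name}: {val!r}")
    if theta1 <= 0:
        raise ValueError("theta1 must be positive")
    j = np.arange(d_max + 1)
    shape = j + 1.0

    # recent epoch: integral over t in [0, tau) at rate 1/theta1
    b = 1.0 + 1.0 / theta1
    if tau > 0:
        log_term1 = (-np.log(theta1) - shape * np.log(b)
                     + stats.gamma.logcdf(b * tau, a=shape))
        term1 = np.exp(log_term1)
    else:
        term1 = np.zeros_like(shape)

    # ancient epoch: lineages surviving past tau coalesce at rate 1/theta0
    if theta0 > 0:
        a = 1.0 + 1.0 / theta0
        log_term2 = (tau / theta0 - tau / theta1 - np.log(theta0)
                     - shape * np.log(a)
                     + stats.gamma.logsf(a * tau, a=shape))
        term2 = np.exp(log_term2)
    else:
        # theta0 = 0: survivors coalesce exactly at tau -> Poisson(tau)
        term2 = np.exp(-tau / theta1) * stats.poisson.pmf(j, tau if tau > 0 else 0.0)

    probs = np.clip(term1 + term2, 0.0, None)
    tail = max(1.0 - probs.sum(), 0.0)
    return probs, tail


# ---------------------------------------------------------------------------
# Raggedness


def raggedness(mismatch: MismatchDistribution | np.ndarray) -> float:
    """Harpending's raggedness index over relative frequencies x_0..x_d.

    Hr = sum_{i=1..d} (x_i - x_{i-1})^2 with d the maximum observed
    difference class; a monomorphic distribution (d = 0) is treated as
    d = 1 with x_1 = 0, giving Hr = 1.
    """
    if isinstance(mismatch, MismatchDistribution):
        x = mismatch.freqs
    else:
        x = np.asarray(mismatch, dtype=float)
        if x.size == 0:
            raise ValueError("empty mismatch distribution")
        total = x.sum()
        if total <= 0:
            raise ValueError("mismatch distribution sums to zero")
        x = x / total
    if len(x) == 1:
        x = np.array([x[0], 0.0])
    return float(((x[1:] - x[:-1]) ** 2).sum())


# ---------------------------------------------------------------------------
# SSD fitting


def ssd_of(tau: float, theta0: float, theta1: float,
           freqs: np.ndarray) -> float:
    """SSD between observed relative frequencies and the model expectation."""
    probs, _ = expected_mismatch_sudden(tau, theta0, theta1, len(freqs) - 1)
    return float(((freqs - probs) ** 2).sum())


def _ssd_vec(params_vec: np.ndarray, freqs: np.ndarray) -> float:
    tau, log_t0, log_ratio = params_vec
    t0 = np.exp(log_t0)
    return ssd_of(tau, t0, t0 * np.exp(log_ratio), freqs)


def _to_vec(tau: float, theta0: float, theta1: float) -> tuple:
    t0 = min(max(theta0, 1e-4), 1e3)
    ratio = max(theta1 / t0, 1.0)
    return (tau, np.log(t0), np.log(ratio))


def start_grid() -> list:
    """Feasible (tau, theta0, theta1) start triples of the deterministic grid."""
    return [(t, t0, max(t1, t0))
            for t, t0, t1 in itertools.product(START_TAU, START_THETA0,
                                               START_THETA1)]


def fit_sudden_expansion(mismatch: MismatchDistribution,
                         starts: str = "full",
                         extra_starts: list | None = None) -> ExpansionFit:
    """Least-squares fit of (tau, theta0, theta1) to a mismatch distribution.

    The search is restricted to genuine expansions (theta1 >= theta0).
    ``starts='full'`` uses the deterministic 5 x 3 x 4 grid of start
    points; ``starts='fast'`` a reduced grid (used for bootstrap refits,
    where the fitted parameters of the parent fit are supplied via
    ``extra_starts``).  Reported SSD is the attained minimum.
    """
    freqs = mismatch.freqs
    flags = []
    if mismatch.d_max == 0:
        # monomorphic: every pair identical, the model degenerates
        flags.append("monomorphic sample: degenerate fit tau=0")
        return ExpansionFit(tau=0.0, theta0=0.0, theta1=1e-3,
                            ssd=0.0, raggedness=raggedness(mismatch), flags=flags)

    if starts == "full":
        grid = [_to_vec(*s) for s in start_grid()]
    else:
        mean_d = float((np.arange(len(freqs)) * freqs).sum())
        grid = [_to_vec(max(mean_d, 0.5), 0.5, max(2 * mean_d, 1.0)),
                _to_vec(1.0, 0.1, 10.0),
                _to_vec(4.0, 1.0, 100.0)]
    if extra_starts:
        grid = [_to_vec(*s) for s in extra_starts] + grid

    bounds = [BOUNDS_TAU, BOUNDS_LOG_THETA0, BOUNDS_LOG_RATIO]
    # screen the start grid, polish only the most promising starts
    scored = sorted(grid, key=lambda s: _ssd_vec(np.asarray(s), freqs))
    best = None
    for start in scored[:6]:
        res = optimize.minimize(_ssd_vec, np.asarray(start), args=(freqs,),
                                method="L-BFGS-B", bounds=bounds,
                                options={"ftol": OPT_TOL, "gtol": 1e-10})
        if best is None or res.fun < best.fun:
            best = res
    tau, log_t0, log_ratio = best.x
    theta0 = float(np.exp(log_t0))
    return ExpansionFit(tau=float(tau), theta0=theta0,
                        theta1=float(theta0 * np.exp(log_ratio)),
                        ssd=float(best.fun),
                        raggedness=raggedness(mismatch), flags=flags)


# ---------------------------------------------------------------------------
# Parametric bootstrap


def simulate_mismatch(n: int, theta0: float, theta1: float, tau: float,
                      rng) -> MismatchDistribution:
    """One coalescent sample's mismatch distribution (sequence-free path)."""
    from .synthetic_data import _mutate_branches, _simulate_branches

    branches = _simulate_branches(n, theta0, theta1, tau, rng)
    carriers = _mutate_branches(branches, rng)
    geno = np.zeros((n, max(len(carriers), 1)), dtype=np.int8)
    for m, desc in enumerate(carriers):
        geno[list(desc), m] = 1
    # pairwise Hamming distances via 0/1 genotype matrix products
    ones = geno @ geno.T
    tot = geno.sum(axis=1)
    diff = tot[:, None] + tot[None, :] - 2 * ones
    iu = np.triu_indices(n, k=1)
    counts = np.bincount(diff[iu].astype(int))
    return MismatchDistribution(counts, n)


def bootstrap_expansion_pvalues(fit: ExpansionFit, n: int,
                                B: int = 1000, seed: int = 0,
                                observed: MismatchDistribution | None = None
                                ) -> ExpansionFit:
    """Parametric-bootstrap p-values for SSD and raggedness.

    Simulates B coalescent samples of size n under the fitted
    (tau, theta0, theta1), refits each, and reports
    p = #(statistic_rep >= statistic_obs) / B for both SSD and Hr.
    Returns a new ExpansionFit with the p-value fields populated.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)
    theta0 = max(fit.theta0, 0.0)
    ge_ssd = ge_hr = 0
    for _ in range(B):
        mm = simulate_mismatch(n, theta0, fit.theta1, fit.tau, rng)
        refit = fit_sudden_expansion(
            mm, starts="fast",
            extra_starts=[(fit.tau, fit.theta0, fit.theta1)],
        )
        if refit.ssd >= fit.ssd:
            ge_ssd += 1
        if refit.raggedness >= fit.raggedness:
            ge_hr += 1
    # a finite bootstrap never justifies a literal zero: report the
    # (k+1)/(B+1) bound when no replicate reaches the observed statistic
    p_ssd = ge_ssd / B if ge_ssd > 0 else 1.0 / (B + 1)
    p_hr = ge_hr / B if ge_hr > 0 else 1.0 / (B + 1)
    return ExpansionFit(
        tau=fit.tau, theta0=fit.theta0, theta1=fit.theta1, ssd=fit.ssd,
        raggedness=fit.raggedness, p_ssd=p_ssd, p_raggedness=p_hr,
        bootstrap_reps=B, flags=list(fit.flags),
    )


def fit_alignment(alignment: HaplotypeAlignment, B: int = 0,
                  seed: int = 0) -> ExpansionFit:
    """Convenience: mismatch -> fit -> (optional) bootstrap p-values."""
    mm = MismatchDistribution.from_alignment(alignment)
    fit = fit_sudden_expansion(mm)
    if B > 0:
        fit = bootstrap_expansion_pvalues(fit, alignment.n, B=B, seed=seed,
                                          observed=mm)
    return fit
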
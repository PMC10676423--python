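"""Piecewise-constant effective-size trajectories from a folded 1D SFS.

The deterministic expected-SFS evaluator combines two classical results.
Under piecewise-constant diploid size N(t) the number of ancestral lineages
is a pure-death chain in rescaled time tau = int dt / (2 N(t)), dying from
k to k-1 at rate C(k,2); the expected real-time duration spent with k
lineages is obtained per epoch from the chain's matrix exponential and its
integral, E[T_k] = sum_e 2 N_e * int_{epoch e} P(A(tau) = k) dtau (solved
with the bidiagonal generator, which is numerically stable at sample sizes
where the classical alternating-sum eigenexpansion is not). The expected
unfolded spectrum then follows from the standard combinatorial weights
P(a level-k branch subtends i of n tips) = C(n-i-1, k-2) / C(n-1, k-1):
E[L_i] = sum_k k E[T_k] p(n, k, i), folded and normalized over polymorphic
classes.

The trajectory fitter is a compact stairway-style estimator: per multinomial
bootstrap replicate of the SFS it splits sites into training/testing
fractions, maximizes the training composite likelihood for each candidate
number of size-change breakpoints, picks the breakpoint count by testing
likelihood (overfitting control), refits on the full replicate, and pins
the absolute scale through theta = 4*Ne*mu and the mutation opportunity L.
The trajectory is summarized by the pointwise median and 2.5/97.5 percentile
bands across replicates on a common time grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm, solve
from scipy.optimize import minimize
from scipy.special import gammaln

from .genotype_io import ScalingConfig
from .sfs_builder import SFS1D, fold_1d

logger = logging.getLogger("demog")

__all__ = [
    "NeTrajectory",
    "StairwayConfig",
    "expected_sfs_piecewise",
    "expected_total_branch_length",
    "fit_stairway",
]

_N_CAP = 400  # chromosomes; expm-based evaluator is dense in (n-1)^2


@dataclass
class NeTrajectory:
    """Summary of the inferred size history on a common time grid
    (generations before present), with bootstrap percentile bands."""

    time_gen: np.ndarray
    ne_median: np.ndarray
    ne_lo: np.ndarray
    ne_hi: np.ndarray
    scaling: ScalingConfig = field(default_factory=ScalingConfig)
    replicates: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)

    @property
    def time_years(self) -> np.ndarray:
        return self.time_gen * self.scaling.generation_years

    def to_table(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time_gen": self.time_gen,
                "time_years": self.time_years,
                "Ne_median": self.ne_median,
                "Ne_lo": self.ne_lo,
                "Ne_hi": self.ne_hi,
            }
        )


@dataclass(frozen=True)
class StairwayConfig:
    """Settings for the trajectory fit.

    mutation_opportunity is the number of surveyed sites L entering
    theta = 4*Ne*mu; when None it is approximated as n_snps / 0.05 (5% of
    surveyed sites polymorphic, a reduced-representation-scale guess) and
    absolute sizes/times are then only approximate — the trajectory shape
    is unaffected.
    """

    training_fraction: float = 0.67
    breakpoints: tuple[int, ...] = (0, 1, 2, 3, 4)
    n_bootstrap: int = 100
    mutation_opportunity: float | None = None
    scaling: ScalingConfig = field(default_factory=ScalingConfig)
    seed: int = 0
    grid_points: int = 48

    def __post_init__(self) -> None:
        if not (0.0 < self.training_fraction < 1.0):
            raise ValueError("training fraction must be in (0, 1)")
        if self.mutation_opportunity is not None and self.mutation_opportunity <= 0:
            raise ValueError("mutation opportunity must be positive")


# ---------------------------------------------------------------------------
# Deterministic expected SFS under piecewise-constant Ne


def _death_chain_occupancy(n: int, epoch_dtau: np.ndarray) -> np.ndarray:
    """Integral of P(A_n(tau) = k) over each epoch's tau-interval.

    Returns (n_epochs, n-1) with columns for k = n..2. The last epoch is
    treated as infinite."""
    m = n - 1  # transient states k = n..2
    lam = np.array([0.5 * k * (k - 1) for k in range(n, 1, -1)])
    Q = np.zeros((m, m))
    for i in range(m):
        Q[i, i] = -lam[i]
        if i + 1 < m:
            Q[i, i + 1] = lam[i]
    v = np.zeros(m)
    v[0] = 1.0
    out = np.zeros((len(epoch_dtau), m))
    for e, dtau in enumerate(epoch_dtau):
        if np.isinf(dtau):
            out[e] = solve(-Q.T, v)
            v = np.zeros(m)
        else:
            E = expm(Q.T * dtau)
            v_next = E @ v
            out[e] = solve(-Q.T, v - v_next)
            v = v_next
    return out


def _level_durations(sizes: np.ndarray, times: np.ndarray, n: int) -> np.ndarray:
    """E[T_k] for k = n..2 (generations) under piecewise-constant diploid
    sizes; `times` are the epoch boundaries (len(sizes) - 1 of them)."""
    if n > _N_CAP:
        raise ValueError(f"sample size {n} chromosomes exceeds evaluator cap {_N_CAP}")
    sizes = np.asarray(sizes, float)
    times = np.asarray(times, float)
    bounds = np.concatenate([[0.0], times, [np.inf]])
    dtau = np.diff(bounds) / (2.0 * sizes)
    occ = _death_chain_occupancy(n, dtau)
    return (occ * (2.0 * sizes)[:, None]).sum(axis=0)


from functools import lru_cache


@lru_cache(maxsize=8)
def _pk_weights(n: int) -> np.ndarray:
    """(n-1, n-1) matrix W[k-2, i-1] = P(level-k branch subtends i tips),
    computed in log space and cached per sample size."""
    ks = np.arange(2, n + 1)[:, None]  # level
    iis = np.arange(1, n)[None, :]  # subtended tips
    with np.errstate(invalid="ignore"):
        logw = (
            _log_choose_arr(n - iis - 1, ks - 2) - _log_choose_arr(n - 1, ks - 1)
        )
    W = np.where(np.isneginf(logw), 0.0, np.exp(logw))
    W[np.isnan(W)] = 0.0
    return W


def _log_choose_arr(a, b):
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    out = gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)
    bad = (b < 0) | (b > a)
    return np.where(bad, -np.inf, out)


def _unfolded_branch_lengths(sizes, times, n: int) -> np.ndarray:
    """E[L_i] = sum_k k E[T_k] P(level-k branch subtends i tips), i=1..n-1."""
    Tk = _level_durations(sizes, times, n)  # k = n..2
    W = _pk_weights(n)
    out = np.zeros(n - 1)
    for j, k in enumerate(range(n, 1, -1)):
        out += k * Tk[j] * W[k - 2]
    return out


def expected_sfs_piecewise(sizes, times, n_chromosomes: int) -> np.ndarray:
    """Expected folded SFS proportions (classes 0..n_chromosomes//2, class 0
    structurally zero) under piecewise-constant diploid Ne."""
    n = int(n_chromosomes)
    if n < 2:
        raise ValueError("need at least 2 chromosomes")
    Li = _unfolded_branch_lengths(sizes, times, n)  # i = 1..n-1
    full = np.concatenate([[0.0], Li, [0.0]])  # classes 0..n
    folded = fold_1d(full)
    return folded / folded.sum()


def expected_total_branch_length(sizes, times, n_chromosomes: int) -> float:
    """E[total genealogy length] in generations (for theta/L scaling)."""
    n = int(n_chromosomes)
    Tk = _level_durations(sizes, times, n)
    ks = np.arange(n, 1, -1)
    return float((ks * Tk).sum())


# ---------------------------------------------------------------------------
# Trajectory fitting


def _watterson_ne(S: int, L: float, n: int, mu: float) -> float:
    a_n = np.sum(1.0 / np.arange(1, n))
    theta = S / (L * a_n)
    return max(theta / (4.0 * mu), 1.0)


def _boundaries(ne_anchor: float, n: int, b: int) -> np.ndarray:
    """b epoch boundaries on a geometric time ladder spanning the sample's
    informative range under a constant anchor size: from roughly the
    expected first-coalescence scale (0.005 * 4 Ne) to half the expected
    TMRCA scale (0.5 * 4 Ne)."""
    if b == 0:
        return np.array([])
    if b == 1:
        fracs = np.array([0.05])
    else:
        fracs = np.geomspace(0.002, 0.5, b)
    return 4.0 * ne_anchor * fracs


def _scale_term(S: float, L: float, q: float) -> float:
    """Binomial segregating-sites log-likelihood term S ln q + (L-S) ln(1-q)
    with q the per-site polymorphism probability mu * E[T_total]; pins the
    absolute (N, T) scale that SFS proportions alone cannot identify."""
    q = min(max(q, 1e-300), 1.0 - 1e-12)
    return float(S * np.log(q) + (L - S) * np.log1p(-q))


def _fit_sizes(
    counts: np.ndarray, times: np.ndarray, n: int, ne0: float, L: float, mu: float
) -> tuple[np.ndarray, float]:
    """Maximize the folded multinomial composite likelihood (plus the
    segregating-sites scale term) over per-epoch log-sizes with fixed epoch
    boundaries. Returns (sizes, loglik)."""
    poly = counts[1:].astype(float)
    S = float(poly.sum())
    n_epochs = len(times) + 1

    def negll(x):
        sizes = np.exp(x)
        Li = _unfolded_branch_lengths(sizes, times, n)
        full = np.concatenate([[0.0], Li, [0.0]])
        folded = fold_1d(full)
        tot = folded.sum()
        p = np.maximum(folded[1:] / tot, 1e-12)
        # total genealogy length = sum_i L_i exactly
        return -(float(poly @ np.log(p)) + _scale_term(S, L, mu * tot))

    x0 = np.full(n_epochs, np.log(ne0))
    lo, hi = np.log(ne0 * 1e-3), np.log(ne0 * 1e3)
    res = minimize(
        negll, x0, method="L-BFGS-B", bounds=[(lo, hi)] * n_epochs,
        options={"maxiter": 80, "ftol": 1e-10},
    )
    return np.exp(res.x), -float(res.fun)


def _test_loglik(counts: np.ndarray, sizes, times, n: int, L: float, mu: float) -> float:
    Li = _unfolded_branch_lengths(sizes, times, n)
    full = np.concatenate([[0.0], Li, [0.0]])
    folded = fold_1d(full)
    p = np.maximum(folded[1:] / folded.sum(), 1e-12)
    S = float(counts[1:].sum())
    return float(counts[1:].astype(float) @ np.log(p)) + _scale_term(S, L, mu * folded.sum())


def _step_eval(bounds: np.ndarray, sizes: np.ndarray, grid: np.ndarray) -> np.ndarray:
    idx = np.searchsorted(bounds, grid, side="right")
    return np.asarray(sizes)[idx]


def fit_stairway(obs: SFS1D, cfg: StairwayConfig | None = None) -> NeTrajectory:
    """Estimate the Ne trajectory from a folded 1D minor-allele SFS."""
    cfg = cfg or StairwayConfig()
    n = 2 * obs.n  # chromosomes
    counts = obs.counts.astype(np.int64)
    S = int(counts[1:].sum())
    if S == 0:
        raise ValueError("observed SFS has no polymorphic sites")
    if counts[2:].sum() == 0:
        logger.warning("fit_stairway: all sites are singletons; expect wide bands")
    L = cfg.mutation_opportunity if cfg.mutation_opportunity is not None else S / 0.05
    mu = cfg.scaling.mu
    rng = np.random.default_rng(cfg.seed)

    # anchor the epoch ladder at the Watterson-equivalent size; under the
    # scale-pinned likelihood the fitted total genealogy length is held at
    # S / (mu L), so refitting would return the same anchor (fixpoint after
    # a single update)
    ne_anchor = _watterson_ne(S, L, n, mu)

    probs = counts / counts.sum()
    reps: list[tuple[np.ndarray, np.ndarray]] = []
    for _ in range(cfg.n_bootstrap):
        boot = rng.multinomial(counts.sum(), probs)
        train = rng.binomial(boot, cfg.training_fraction)
        test = boot - train
        L_train = L * cfg.training_fraction
        L_test = L * (1.0 - cfg.training_fraction)
        best = None
        for b in cfg.breakpoints:
            times = _boundaries(ne_anchor, n, b)
            sizes, _ = _fit_sizes(train, times, n, ne_anchor, L_train, mu)
            tll = _test_loglik(test, sizes, times, n, L_test, mu)
            # penalize only via held-out likelihood; ties keep fewer epochs
            if best is None or tll > best[0] + 1e-9:
                best = (tll, b)
        times = _boundaries(ne_anchor, n, best[1])
        sizes, _ = _fit_sizes(boot, times, n, ne_anchor, L, mu)
        reps.append((times, sizes))

    t_hi = max((r[0][-1] * 3 if len(r[0]) else 0) for r in reps)
    t_hi = max(t_hi, 4.0 * ne_anchor)
    grid = np.geomspace(max(t_hi * 1e-4, 1.0), t_hi, cfg.grid_points)
    curves = np.array([_step_eval(b, s, grid) for b, s in reps])
    return NeTrajectory(
        time_gen=grid,
        ne_median=np.median(curves, axis=0),
        ne_lo=np.percentile(curves, 2.5, axis=0),
        ne_hi=np.percentile(curves, 97.5, axis=0),
        scaling=cfg.scaling,
        replicates=reps,
    )
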
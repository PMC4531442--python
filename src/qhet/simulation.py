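"""Null-level and power simulation engine for the homogeneity tests.

Replicates two-arm binomial meta-analyses under either a common odds
ratio (level simulations) or a random-effects model in which the
per-study log odds ratios are drawn from N(theta, tau^2) (power
simulations), and measures the rejection rate of each requested test at a
nominal level.

All per-replicate computation is vectorised: a replicate batch is a pair
of (reps, K) count matrices, and each test's p-values are computed on the
whole batch at once, including the full gamma-reference chain for the
corrected Q test.  Replicates on which a test is undefined (sparse data
for Breslow-Day, a degenerate gamma reference) are counted separately and
excluded from that test's denominator.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, logit

from .null_moments import _expected_q_batch, corrected_mean, variance_q

__all__ = [
    "SimConfig",
    "TestRate",
    "SimResult",
    "TEST_NAMES",
    "homogeneous_grid",
    "heterogeneous_configs",
    "simulate_level",
    "simulate_power",
    "results_to_dataframe",
    "write_results_csv",
]

TEST_NAMES = ("q_gamma", "q_chisq", "breslow_day", "tarone")

_ALIASES = {
    "qgamma": "q_gamma",
    "q_gamma": "q_gamma",
    "gamma": "q_gamma",
    "chisq": "q_chisq",
    "q_chisq": "q_chisq",
    "bd": "breslow_day",
    "breslow_day": "breslow_day",
    "tarone": "tarone",
}

#: Probability clamp for treatment arms pushed to the boundary by extreme
#: random-effects draws; clamped replicates are counted in SimResult.
_P_CLAMP = 1e-12


def canonical_test_name(name: str) -> str:
    try:
        return _ALIASES[name.lower().replace("-", "_")]
    except KeyError:
        raise ValueError(f"unknown test {name!r}; choose from {TEST_NAMES}") from None


@dataclass(frozen=True)
class SimConfig:
    """One simulation scenario.

    ``sizes``, ``q`` and ``p_c`` are per-study vectors of length ``k``
    (scalars are broadcast).  ``theta`` is the common log odds ratio,
    ``tau`` the between-study SD of the random-effects model (0 for level
    simulations).  ``pairing_order`` is metadata recording how size and
    probability vectors were paired in heterogeneous designs (2 = the
    probability vector reversed against the size vector).
    """

    k: int
    sizes: tuple[int, ...]
    q: tuple[float, ...]
    p_c: tuple[float, ...]
    theta: float
    tau: float = 0.0
    pairing_order: int = 1
    reps: int = 10_000
    seed: int = 0
    nominal: float = 0.05

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("need at least two studies")

        def broadcast(name, val, cast):
            vals = (val,) * self.k if np.isscalar(val) else tuple(val)
            if len(vals) != self.k:
                raise ValueError(f"{name} must have length k={self.k}, got {len(vals)}")
            return tuple(cast(v) for v in vals)

        object.__setattr__(self, "sizes", broadcast("sizes", self.sizes, int))
        object.__setattr__(self, "q", broadcast("q", self.q, float))
        object.__setattr__(self, "p_c", broadcast("p_c", self.p_c, float))
        if self.tau < 0:
            raise ValueError("tau must be nonnegative")
        if not 0 < self.nominal < 1:
            raise ValueError("nominal level must be in (0, 1)")
        if np.any(self.n_c < 1) or np.any(self.n_t < 1):
            raise ValueError("every arm must have at least one subject")
        pc = np.array(self.p_c)
        if np.any((pc <= 0) | (pc >= 1)):
            raise ValueError("control probabilities must be in (0, 1)")

    @property
    def n_c(self) -> np.ndarray:
        return np.round(np.array(self.sizes) * np.array(self.q)).astype(int)

    @property
    def n_t(self) -> np.ndarray:
        return np.array(self.sizes, dtype=int) - self.n_c

    @property
    def p_t(self) -> np.ndarray:
        """Treatment probabilities implied by (p_c, theta) at tau = 0."""
        return expit(logit(np.array(self.p_c)) + self.theta)


def default_reps(k: int) -> int:
    """Standard replicate count: 10,000 for K <= 20, 1,000 for larger K."""
    return 10_000 if k <= 20 else 1_000


def homogeneous_grid() -> list[SimConfig]:
    """The full grid of identical-study level scenarios (648 configs).

    Cross of K in {5,10,20,40}, N in {90,150,210}, q in {1/3,1/2,2/3},
    p_C in {0.1,0.2,0.4} and theta in {0,0.5,1,1.5,2,3}, every study in a
    scenario sharing the same parameters.
    """
    grid = []
    for k, n, q, p_c, theta in itertools.product(
        (5, 10, 20, 40),
        (90, 150, 210),
        (1.0 / 3.0, 0.5, 2.0 / 3.0),
        (0.1, 0.2, 0.4),
        (0.0, 0.5, 1.0, 1.5, 2.0, 3.0),
    ):
        grid.append(
            SimConfig(
                k=k, sizes=n, q=q, p_c=p_c, theta=theta, reps=default_reps(k)
            )
        )
    return grid


#: Size vectors for the unequal-study designs (averages 90, 150, 210).
HETEROGENEOUS_SIZES = (
    (36, 48, 54, 60, 252),
    (96, 108, 114, 120, 312),
    (163, 173, 178, 184, 352),
)

#: Control-probability vectors per common log odds ratio, chosen to keep
#: the implied treatment probabilities away from 1.
HETEROGENEOUS_PC = {
    0.0: (0.1, 0.3, 0.5, 0.7, 0.9),
    0.5: (0.15, 0.3, 0.45, 0.6, 0.75),
    1.0: (0.1, 0.25, 0.4, 0.55, 0.7),
    1.5: (0.1, 0.25, 0.4, 0.55, 0.7),
    2.0: (0.1, 0.2, 0.3, 0.4, 0.5),
    3.0: (0.1, 0.17, 0.24, 0.31, 0.38),
}


def heterogeneous_configs() -> list[SimConfig]:
    """Unequal-study level scenarios with balanced arms (q = 1/2).

    For each size vector, theta and pairing order, the K=5 base vectors
    are repeated 2, 4 and 8 times for K = 10, 20 and 40.  Pairing order 1
    aligns the sorted probability vector with the sorted sizes; order 2
    reverses only the probability vector.
    """
    configs = []
    for sizes5, theta, order, rep in itertools.product(
        HETEROGENEOUS_SIZES, sorted(HETEROGENEOUS_PC), (1, 2), (1, 2, 4, 8)
    ):
        pc5 = HETEROGENEOUS_PC[theta]
        if order == 2:
            pc5 = pc5[::-1]
        k = 5 * rep
        configs.append(
            SimConfig(
                k=k,
                sizes=sizes5 * rep,
                q=0.5,
                p_c=pc5 * rep,
                theta=theta,
                pairing_order=order,
                reps=default_reps(k),
            )
        )
    return configs


# ---------------------------------------------------------------------------
# vectorised per-replicate test kernels
# ---------------------------------------------------------------------------


def _q_corrected_batch(x, y, n_t, n_c):
    """Q on 1/2-corrected effects for a (reps, K) batch.

    Returns (Q, theta_w, zeta_hat)."""
    lt = np.log((x + 0.5) / (n_t - x + 0.5))
    lc = np.log((y + 0.5) / (n_c - y + 0.5))
    theta = lt - lc
    var = (
        1.0 / (x + 0.5)
        + 1.0 / (n_t - x + 0.5)
        + 1.0 / (y + 0.5)
        + 1.0 / (n_c - y + 0.5)
    )
    w = 1.0 / var
    tw = (w * theta).sum(axis=-1) / w.sum(axis=-1)
    q = (w * (theta - tw[..., None]) ** 2).sum(axis=-1)
    return q, tw, lc


def _q_standard_batch(x, y, n_t, n_c):
    """Conventional Q for a batch; 1/2 added to all cells of zero-cell tables."""
    a = np.where((x == 0) | (x == n_t) | (y == 0) | (y == n_c), 0.5, 0.0)
    lt = np.log((x + a) / (n_t - x + a))
    lc = np.log((y + a) / (n_c - y + a))
    theta = lt - lc
    var = 1.0 / (x + a) + 1.0 / (n_t - x + a) + 1.0 / (y + a) + 1.0 / (n_c - y + a)
    w = 1.0 / var
    tw = (w * theta).sum(axis=-1) / w.sum(axis=-1)
    return (w * (theta - tw[..., None]) ** 2).sum(axis=-1)


def _q_gamma_batch(x, y, n_t, n_c):
    """Gamma-referenced Q p-values for a batch.

    Returns (p_values, valid): invalid replicates (nonpositive corrected
    mean, a theoretically possible degeneracy) get NaN p-values.
    """
    k = x.shape[-1]
    q, tw, zeta = _q_corrected_batch(x, y, n_t, n_c)
    e_th = _expected_q_batch(tw, zeta, n_t, n_c)
    e = corrected_mean(e_th, k)
    v = variance_q(e, k)
    valid = np.isfinite(e) & np.isfinite(v) & (e > 0) & (v > 0)
    alpha = np.where(valid, e * e / np.where(valid, v, 1.0), np.nan)
    beta = np.where(valid, v / np.where(valid, e, 1.0), np.nan)
    p = stats.gamma.sf(q, a=alpha, scale=beta)
    return p, valid


def _q_chisq_batch(x, y, n_t, n_c):
    k = x.shape[-1]
    q = _q_standard_batch(x, y, n_t, n_c)
    return stats.chi2.sf(q, k - 1), np.ones(q.shape, dtype=bool)


def _bd_batch(x, y, n_t, n_c, tarone=False):
    """Breslow-Day (or Tarone) p-values for a batch.

    Studies with degenerate margins are dropped replicate-wise with df
    reduced; replicates with fewer than two usable studies or an
    inestimable Mantel-Haenszel odds ratio are flagged invalid.
    """
    n = n_t + n_c
    m = x + y
    usable = (m > 0) & (m < n)
    k_used = usable.sum(axis=-1)
    num = (x * (n_c - y) / n).sum(axis=-1)
    den = (y * (n_t - x) / n).sum(axis=-1)
    valid = (k_used >= 2) & (num > 0) & (den > 0)
    psi = np.where(valid, num / np.where(den > 0, den, 1.0), 1.0)[..., None]

    lo = np.maximum(0.0, (m - n_c).astype(float))
    hi = np.minimum(m, n_t).astype(float)
    a = psi - 1.0
    b = -(psi * (n_t + m) + (n_c - m))
    c = psi * n_t * m
    near_one = np.abs(a) < 1e-9
    a_safe = np.where(near_one, 1.0, a)
    disc = np.maximum(b * b - 4.0 * a_safe * c, 0.0)
    sq = np.sqrt(disc)
    r1 = (-b + sq) / (2.0 * a_safe)
    r2 = (-b - sq) / (2.0 * a_safe)
    root = np.where((lo < r1) & (r1 < hi), r1, r2)
    expected = np.where(near_one, n_t * m / n, root)
    expected = np.where(usable, expected, 0.5)  # placeholder on dropped studies
    var = 1.0 / (
        1.0 / expected
        + 1.0 / (n_t - expected)
        + 1.0 / (m - expected)
        + 1.0 / (n_c - m + expected)
    )
    contrib = np.where(usable, (x - expected) ** 2 / var, 0.0)
    stat = contrib.sum(axis=-1)
    if tarone:
        resid = np.where(usable, x - expected, 0.0).sum(axis=-1)
        var_sum = np.where(usable, var, 0.0).sum(axis=-1)
        stat = np.maximum(stat - resid**2 / var_sum, 0.0)
    df = np.maximum(k_used - 1, 1)
    p = stats.chi2.sf(stat, df)
    return np.where(valid, p, np.nan), valid


_KERNELS = {
    "q_gamma": _q_gamma_batch,
    "q_chisq": _q_chisq_batch,
    "breslow_day": lambda x, y, nt, nc: _bd_batch(x, y, nt, nc, tarone=False),
    "tarone": lambda x, y, nt, nc: _bd_batch(x, y, nt, nc, tarone=True),
}


# ---------------------------------------------------------------------------
# the simulation driver
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TestRate:
    """Rejection bookkeeping for one test in one scenario."""

    __test__ = False  # not a pytest test class despite the name

    test: str
    rejections: int
    n_valid: int
    n_undefined: int

    @property
    def proportion(self) -> float:
        return self.rejections / self.n_valid if self.n_valid else float("nan")

    @property
    def mcse(self) -> float:
        if not self.n_valid:
            return float("nan")
        p = self.proportion
        return float(np.sqrt(p * (1.0 - p) / self.n_valid))


@dataclass(frozen=True)
class SimResult:
    """Achieved rejection rates of the requested tests for one scenario."""

    config: SimConfig
    reps: int
    rates: dict[str, TestRate] = field(default_factory=dict)
    n_clamped: int = 0


def _draw_counts(config: SimConfig, rng: np.random.Generator):
    """Draw a (reps, K) batch of tables under the scenario's model.

    The random-effects draw is skipped entirely when tau = 0 so that
    level and power simulations consume identical random streams there.
    """
    n_t, n_c = config.n_t, config.n_c
    pc = np.broadcast_to(np.array(config.p_c), (config.reps, config.k))
    zeta = logit(np.array(config.p_c))
    if config.tau > 0:
        theta_i = rng.normal(config.theta, config.tau, size=(config.reps, config.k))
    else:
        theta_i = config.theta
    pt = expit(zeta + theta_i)
    clamped = int(np.count_nonzero((pt < _P_CLAMP) | (pt > 1.0 - _P_CLAMP)))
    pt = np.clip(pt, _P_CLAMP, 1.0 - _P_CLAMP)
    pt = np.broadcast_to(pt, (config.reps, config.k))
    x = rng.binomial(n_t, pt, size=(config.reps, config.k))
    y = rng.binomial(n_c, pc, size=(config.reps, config.k))
    return x, y, clamped


def _run(config: SimConfig, tests: Iterable[str]) -> SimResult:
    names = [canonical_test_name(t) for t in tests]
    rng = np.random.default_rng(config.seed)
    x, y, clamped = _draw_counts(config, rng)
    n_t = config.n_t.astype(float)
    n_c = config.n_c.astype(float)
    rates: dict[str, TestRate] = {}
    for name in names:
        p, valid = _KERNELS[name](x.astype(float), y.astype(float), n_t, n_c)
        rej = int(np.count_nonzero(p[valid] < config.nominal))
        rates[name] = TestRate(
            test=name,
            rejections=rej,
            n_valid=int(valid.sum()),
            n_undefined=int((~valid).sum()),
        )
    return SimResult(config=config, reps=config.reps, rates=rates, n_clamped=clamped)


def simulate_level(config: SimConfig, tests: Sequence[str] = TEST_NAMES) -> SimResult:
    """Achieved type-I error of the requested tests under homogeneity.

    Each replicate draws per-arm binomial counts with a common log odds
    ratio ``config.theta`` and runs each test at ``config.nominal``.
    Requires ``config.tau == 0``; bit-reproducible given ``config.seed``.
    """
    if config.tau != 0:
        raise ValueError("level simulations require tau = 0; use simulate_power")
    return _run(config, tests)


def simulate_power(config: SimConfig, tests: Sequence[str] = TEST_NAMES) -> SimResult:
    """Rejection rate under the random-effects model theta_i ~ N(theta, tau^2).

    Per replicate, K study-level log odds ratios are drawn, treatment
    probabilities derived from the fixed control probabilities, binomial
    counts drawn, and each test run at the nominal level.  With tau = 0
    this reduces exactly to :func:`simulate_level`, drawing the same
    tables for the same seed.
    """
    return _run(config, tests)


def results_to_dataframe(results: Iterable[SimResult]) -> pd.DataFrame:
    """One row per scenario x test: config fields, rejection rate, MCSE."""
    rows = []
    for r in results:
        c = r.config
        for rate in r.rates.values():
            rows.append(
                {
                    "k": c.k,
                    "sizes": ";".join(map(str, c.sizes)),
                    "q": ";".join(f"{v:g}" for v in c.q),
                    "p_c": ";".join(f"{v:g}" for v in c.p_c),
                    "theta": c.theta,
                    "tau": c.tau,
                    "pairing_order": c.pairing_order,
                    "nominal": c.nominal,
                    "seed": c.seed,
                    "test": rate.test,
                    "rejections": rate.rejections,
                    "n_valid": rate.n_valid,
                    "n_undefined": rate.n_undefined,
                    "reps": r.reps,
                    "level": rate.proportion,
                    "mcse": rate.mcse,
                }
            )
    return pd.DataFrame(rows)


def write_results_csv(results: Iterable[SimResult], path) -> None:
    results_to_dataframe(results).to_csv(path, index=False)
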
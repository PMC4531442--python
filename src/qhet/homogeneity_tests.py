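"""Homogeneity tests for odds ratios across K independent 2x2 studies.

Three tests of the null hypothesis that all studies share a common odds
ratio:

* ``q_gamma_test`` -- Cochran's Q on 1/2-corrected log odds ratios,
  referred to a gamma distribution whose shape and scale are matched to
  the estimated finite-sample null mean and variance of Q;
* ``q_chisq_test`` -- the conventional Q (no corrections except for zero
  cells) referred to chi-square(K-1);
* ``breslow_day_test`` -- the Breslow-Day statistic comparing observed
  treatment-arm events to their expectations under the Mantel-Haenszel
  common odds ratio, with the optional Tarone adjustment.

All p-values are upper-tail: heterogeneity inflates each statistic.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy import stats

from .effects import MetaDataset, StudyTable, cochran_q, estimate_effects, pooled_effect, q_standard
from .null_moments import (
    DegenerateNullError,
    NullSpec,
    gamma_params,
    q_null_moments,
)

__all__ = [
    "TestResult",
    "BDComponents",
    "q_gamma_test",
    "q_chisq_test",
    "mantel_haenszel_or",
    "bd_expected_cell",
    "breslow_day_test",
]


@dataclass(frozen=True)
class TestResult:
    """Outcome of one homogeneity test.

    ``reference`` names the null distribution the statistic was referred
    to; ``diagnostics`` carries the intermediate chain (null moments,
    gamma parameters, excluded studies, ...) where applicable.
    """

    method: str
    statistic: float
    p_value: float
    reference: str
    diagnostics: dict[str, Any] = field(default_factory=dict)


@dataclass(frozen=True)
class BDComponents:
    """Intermediates of the Breslow-Day statistic.

    Mantel-Haenszel odds ratio, per-study expected treatment events given
    that odds ratio, and the per-study asymptotic variances.
    """

    psi_hat: float
    expected: np.ndarray
    variances: np.ndarray


def q_gamma_test(dataset: MetaDataset) -> TestResult:
    """Gamma-referenced Cochran's Q test of odds-ratio homogeneity.

    Computes Q on the 1/2-corrected log odds ratios, estimates the null
    mean and variance of Q by the delta-method expansion evaluated at the
    plug-in null (pooled effect theta_w, corrected control logits) with
    fitted calibration corrections, matches a gamma distribution to those
    moments and reports the upper-tail probability of Q.

    Raises
    ------
    DegenerateNullError
        If the corrected null mean is nonpositive, in which case no gamma
        reference exists for the configuration.
    """
    if dataset.k < 2:
        raise ValueError("homogeneity tests require K >= 2 studies")
    ests = estimate_effects(dataset)
    theta_w = pooled_effect(ests)
    q = cochran_q(ests)
    _, n_t, _, n_c = dataset.arrays()
    null = NullSpec(
        theta=theta_w,
        zetas=np.array([e.zeta_hat for e in ests]),
        n_t=n_t,
        n_c=n_c,
    )
    mom = q_null_moments(null)
    if mom.e_corr <= 0.0:
        raise DegenerateNullError(
            f"corrected null mean of Q is {mom.e_corr:.4g} <= 0; "
            "the gamma reference is undefined for this configuration"
        )
    ga = gamma_params(mom.e_corr, mom.var_corr)
    p = float(stats.gamma.sf(q, a=ga.alpha, scale=ga.beta))
    return TestResult(
        method="q_gamma",
        statistic=q,
        p_value=p,
        reference=f"gamma(alpha={ga.alpha:.6g}, beta={ga.beta:.6g})",
        diagnostics={
            "theta_w": theta_w,
            "e_th": mom.e_th,
            "e_corr": mom.e_corr,
            "var_corr": mom.var_corr,
            "alpha": ga.alpha,
            "beta": ga.beta,
        },
    )


def q_chisq_test(dataset: MetaDataset) -> TestResult:
    """Conventional Q test: Q_stand referred to chi-square(K-1)."""
    if dataset.k < 2:
        raise ValueError("homogeneity tests require K >= 2 studies")
    stat = q_standard(dataset)
    df = dataset.k - 1
    return TestResult(
        method="q_chisq",
        statistic=stat,
        p_value=float(stats.chi2.sf(stat, df)),
        reference=f"chi-square({df})",
        diagnostics={"df": df},
    )


def mantel_haenszel_or(dataset: MetaDataset) -> float:
    """Mantel-Haenszel pooled odds ratio.

    ``psi_hat = [sum_j x_j (n_Cj - y_j)/N_j] / [sum_j y_j (n_Tj - x_j)/N_j]``.
    Robust to sparse strata, but inestimable when either cross-product sum
    is zero.
    """
    num = math.fsum(s.x * (s.n_c - s.y) / s.n for s in dataset)
    den = math.fsum(s.y * (s.n_t - s.x) / s.n for s in dataset)
    if num <= 0.0 or den <= 0.0:
        raise ValueError(
            "Mantel-Haenszel odds ratio inestimable: a cross-product sum is zero "
            "(data too sparse)"
        )
    return num / den


def bd_expected_cell(table: StudyTable, psi: float) -> float:
    """Expected treatment-arm events given a common odds ratio ``psi``.

    Solves ``psi = A (n_c - m + A) / [(n_t - A)(m - A)]`` for the unique
    admissible root inside ``(max(0, m - n_c), min(m, n_t))``, where
    ``m = x + y`` is the total number of events.  The equation is quadratic
    for psi != 1 and linear (hypergeometric mean ``n_t m / N``) at psi = 1;
    the linear branch is also used within 1e-12 of psi = 1 for numerical
    stability.
    """
    if psi <= 0.0:
        raise ValueError("psi must be positive")
    m = table.x + table.y
    n_t, n_c, n = table.n_t, table.n_c, table.n
    if m == 0 or m == n:
        raise ValueError(
            "degenerate margins (no events or all events): expected cell is "
            "forced to the boundary and the study carries no information"
        )
    lo = max(0.0, float(m - n_c))
    hi = min(float(m), float(n_t))
    if abs(psi - 1.0) < 1e-12:
        return n_t * m / n
    # (psi - 1) A^2 - [psi (n_t + m) + (n_c - m)] A + psi n_t m = 0
    a = psi - 1.0
    b = -(psi * (n_t + m) + (n_c - m))
    c = psi * n_t * m
    disc = b * b - 4.0 * a * c
    if disc < 0.0:
        raise RuntimeError("no real root for the expected-cell equation")
    sq = math.sqrt(disc)
    for root in ((-b + sq) / (2.0 * a), (-b - sq) / (2.0 * a)):
        if lo < root < hi:
            return root
    raise RuntimeError(
        f"no admissible root in ({lo}, {hi}) for psi={psi}; this should not "
        "occur for valid tables"
    )


def _bd_variance(table: StudyTable, a: float) -> float:
    m = table.x + table.y
    return 1.0 / (
        1.0 / a
        + 1.0 / (table.n_t - a)
        + 1.0 / (m - a)
        + 1.0 / (table.n_c - m + a)
    )


def breslow_day_test(dataset: MetaDataset, tarone: bool = False) -> TestResult:
    """Breslow-Day test of odds-ratio homogeneity, optionally Tarone-adjusted.

    ``X^2_BD = sum_j (x_j - A_j)^2 / Var(x_j | psi_hat)`` where A_j is the
    expected treatment-arm count under the Mantel-Haenszel odds ratio and
    ``Var(x_j|psi_hat) = [1/A_j + 1/(n_Tj - A_j) + 1/(m_j - A_j)
    + 1/(n_Cj - m_j + A_j)]^(-1)``.  With ``tarone=True`` the statistic is
    reduced by ``(sum_j (x_j - A_j))^2 / sum_j Var_j``, which restores the
    asymptotic chi-square distribution exactly.

    Studies with degenerate margins (no events or all events) carry no
    information about the odds ratio; they are dropped from the sum with
    the degrees of freedom reduced accordingly, and a warning is issued.
    For very sparse data the test may be undefined altogether.
    """
    if dataset.k < 2:
        raise ValueError("homogeneity tests require K >= 2 studies")
    usable = [s for s in dataset if 0 < s.x + s.y < s.n]
    n_dropped = dataset.k - len(usable)
    if len(usable) < 2:
        raise ValueError(
            "Breslow-Day test undefined: fewer than two studies with "
            "non-degenerate margins"
        )
    if n_dropped:
        warnings.warn(
            f"Breslow-Day: dropped {n_dropped} study(ies) with degenerate "
            "margins; degrees of freedom reduced accordingly",
            stacklevel=2,
        )
    psi = mantel_haenszel_or(dataset)
    expected = np.array([bd_expected_cell(s, psi) for s in usable])
    variances = np.array([_bd_variance(s, a) for s, a in zip(usable, expected)])
    resid = np.array([s.x for s in usable]) - expected
    stat = float(np.sum(resid * resid / variances))
    method = "breslow_day"
    if tarone:
        stat -= float(resid.sum() ** 2 / variances.sum())
        stat = max(stat, 0.0)
        method = "tarone"
    df = len(usable) - 1
    return TestResult(
        method=method,
        statistic=stat,
        p_value=float(stats.chi2.sf(stat, df)),
        reference=f"chi-square({df})",
        diagnostics={
            "psi_hat": psi,
            "df": df,
            "n_excluded": n_dropped,
            "components": BDComponents(psi_hat=psi, expected=expected, variances=variances),
        },
    )
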
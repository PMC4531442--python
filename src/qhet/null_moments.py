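"""Finite-sample null moments of Cochran's Q for log odds ratios.

Under homogeneity, Q on 1/2-corrected log odds ratios is stochastically
smaller than its asymptotic chi-square(K-1) reference: both its mean and
variance fall below K-1 and 2(K-1), increasingly so for small studies and
event probabilities far from 1/2.  This module assembles the machinery to
quantify that:

* exact moments (orders 1-4) of the corrected empirical logit
  ``L_{1/2}(X) - logit(p)`` for X ~ Binomial(n, p), by full enumeration of
  the n+1 outcomes (:func:`arm_logit_moments`);
* the mixed moments of the effect deviation Theta = theta_hat - theta and
  nuisance deviation Z = zeta_hat - zeta needed by the delta-method
  expansion (:func:`joint_null_moments`);
* the weight function f(theta, zeta) whose value at the estimates equals
  the inverse of the Gart variance estimate, and its analytic partial
  derivatives (:func:`weight_function`, :func:`weight_derivatives`);
* the order-1/n delta-method expansion of E[Q] under the null
  (:func:`expected_q_theoretical`);
* fitted linear/quadratic corrections mapping the theoretical mean to
  calibrated mean and variance of Q (:func:`corrected_mean`,
  :func:`variance_q`), and gamma moment matching (:func:`gamma_params`).

The corrected-mean slope 0.687 and the variance quadratic coefficients
(4.74, -12.17, 9.42) are regression constants calibrated against large
simulation panels; they are adopted as fixed constants here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit, gammaln

__all__ = [
    "MEAN_CORRECTION_SLOPE",
    "VARIANCE_COEFFS",
    "ArmMoments",
    "MixedMoments",
    "WeightDerivs",
    "NullSpec",
    "QNullMoments",
    "GammaApprox",
    "DegenerateNullError",
    "arm_logit_moments",
    "joint_null_moments",
    "weight_function",
    "weight_derivatives",
    "expected_q_theoretical",
    "corrected_mean",
    "variance_q",
    "gamma_params",
    "q_null_moments",
]

#: Slope of the fitted linear relation between the chi-square 'correction'
#: (K-1) - E[Q] and its delta-method prediction (K-1) - E_th[Q].
MEAN_CORRECTION_SLOPE = 0.687

#: Coefficients (c0, c1, c2) of the fitted variance relation
#: Var[Q] = c0*(K-1) + c1*E[Q] + c2*E[Q]^2/(K-1).
VARIANCE_COEFFS = (4.74, -12.17, 9.42)


class DegenerateNullError(ValueError):
    """Raised when the corrected null moments are unusable (e.g. E[Q] <= 0)."""


# ---------------------------------------------------------------------------
# exact arm-wise moments of the corrected logit
# ---------------------------------------------------------------------------


def _raw_arm_moments(n: int, p) -> tuple[np.ndarray, ...]:
    """Raw moments (orders 1-4) of L_{1/2}(X) - logit(p), X ~ Bin(n, p).

    Vectorised over ``p``; sums run over all n+1 binomial outcomes with
    probabilities evaluated in log space, so tails underflow gracefully
    rather than producing 0 * inf artefacts.
    """
    n = int(n)
    if n < 1:
        raise ValueError("n must be >= 1")
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0.0) | (p >= 1.0)):
        raise ValueError("p must lie strictly inside (0, 1)")
    x = np.arange(n + 1, dtype=float)
    log_binom = gammaln(n + 1.0) - gammaln(x + 1.0) - gammaln(n - x + 1.0)
    ell = np.log((x + 0.5) / (n - x + 0.5))
    logp = np.log(p)[..., None]
    log1mp = np.log1p(-p)[..., None]
    pmf = np.exp(log_binom + x * logp + (n - x) * log1mp)
    d = ell - (logp - log1mp)
    term = pmf * d
    m1 = term.sum(axis=-1)
    term = term * d
    m2 = term.sum(axis=-1)
    term = term * d
    m3 = term.sum(axis=-1)
    term = term * d
    m4 = term.sum(axis=-1)
    return m1, m2, m3, m4


@dataclass(frozen=True)
class ArmMoments:
    """Exact moments of the corrected logit error for one binomial arm.

    ``raw`` are moments of ``L_{1/2}(X) - logit(p)`` about zero (i.e. about
    the true parameter); ``central`` are about the mean of the estimator.
    The first raw moment is the bias of the corrected logit, of order
    1/n^2.
    """

    n: int
    p: float
    raw: tuple[float, float, float, float]
    central: tuple[float, float, float, float]


def arm_logit_moments(n: int, p: float) -> ArmMoments:
    """Exact orders 1-4 moments of ``L_{1/2}(X) - logit(p)``.

    Computed by full enumeration of the binomial support -- no asymptotic
    approximation is involved.
    """
    m1, m2, m3, m4 = (float(m) for m in _raw_arm_moments(n, p))
    c1 = m1
    c2 = m2 - m1**2
    c3 = m3 - 3.0 * m2 * m1 + 2.0 * m1**3
    c4 = m4 - 4.0 * m3 * m1 + 6.0 * m2 * m1**2 - 3.0 * m1**4
    return ArmMoments(n=int(n), p=float(p), raw=(m1, m2, m3, m4), central=(c1, c2, c3, c4))


@dataclass(frozen=True)
class MixedMoments:
    """Joint null moments of Theta = theta_hat - theta and Z = zeta_hat - zeta.

    All expectations are taken about the true parameter values.  Fields are
    floats for scalar inputs and arrays when the arm probabilities were
    vectorised.
    """

    t2: np.ndarray  # E[Theta^2]
    t3: np.ndarray  # E[Theta^3]
    t4: np.ndarray  # E[Theta^4]
    tz: np.ndarray  # E[Theta Z]
    t2z: np.ndarray  # E[Theta^2 Z]
    t3z: np.ndarray  # E[Theta^3 Z]
    t2z2: np.ndarray  # E[Theta^2 Z^2]
    z2: np.ndarray  # E[Z^2]


def joint_null_moments(n_t: int, n_c: int, p_t, p_c) -> MixedMoments:
    """Mixed moments of (Theta, Z) from exact per-arm moments.

    Writing A = L_{1/2}(x) - logit(p_t) and B = L_{1/2}(y) - logit(p_c),
    the treatment and control arms are independent, Theta = A - B and
    Z = B, so every mixed moment expands binomially into products of raw
    arm moments.
    """
    a1, a2, a3, a4 = _raw_arm_moments(n_t, p_t)
    b1, b2, b3, b4 = _raw_arm_moments(n_c, p_c)
    return MixedMoments(
        t2=a2 - 2.0 * a1 * b1 + b2,
        t3=a3 - 3.0 * a2 * b1 + 3.0 * a1 * b2 - b3,
        t4=a4 - 4.0 * a3 * b1 + 6.0 * a2 * b2 - 4.0 * a1 * b3 + b4,
        tz=a1 * b1 - b2,
        t2z=a2 * b1 - 2.0 * a1 * b2 + b3,
        t3z=a3 * b1 - 3.0 * a2 * b2 + 3.0 * a1 * b3 - b4,
        t2z2=a2 * b2 - 2.0 * a1 * b3 + b4,
        z2=b2,
    )


# ---------------------------------------------------------------------------
# the weight function and its derivatives
# ---------------------------------------------------------------------------


def _g_and_derivs(theta, zeta, n_t, n_c):
    # g = 1/f; uses (1+e^u)^2/e^u = 2 + 2 cosh(u) for symmetric stability
    u = theta + zeta
    at = 1.0 / (np.asarray(n_t, dtype=float) + 1.0)
    ac = 1.0 / (np.asarray(n_c, dtype=float) + 1.0)
    with np.errstate(over="ignore"):
        cu, su = np.cosh(u), np.sinh(u)
        cz, sz = np.cosh(zeta), np.sinh(zeta)
        g = (2.0 + 2.0 * cu) * at + (2.0 + 2.0 * cz) * ac
        g_t = 2.0 * su * at
        g_z = 2.0 * su * at + 2.0 * sz * ac
        g_tt = 2.0 * cu * at
        g_zz = 2.0 * cu * at + 2.0 * cz * ac
    return g, g_t, g_z, g_tt, g_zz


def weight_function(theta, zeta, n_t, n_c):
    """Inverse-variance weight f(theta, zeta) for one study.

    ``f = [ (1+e^(theta+zeta))^2 / ((n_t+1) e^(theta+zeta))
          + (1+e^zeta)^2 / ((n_c+1) e^zeta) ]^(-1)``,
    evaluated via ``(1+e^u)^2/e^u = 2 + 2 cosh(u)``.  Evaluated at the
    1/2-corrected estimates (theta_hat, zeta_hat) this equals the
    reciprocal of the Gart variance estimate exactly.  For very large
    |theta+zeta| or |zeta| the weight underflows to its correct limit 0.
    """
    g = _g_and_derivs(theta, zeta, n_t, n_c)[0]
    with np.errstate(divide="ignore"):
        f = np.where(np.isfinite(g), 1.0 / g, 0.0)
    if f.ndim == 0:
        return float(f)
    return f


@dataclass(frozen=True)
class WeightDerivs:
    """f and its partial derivatives up to total order two at (theta, zeta)."""

    f: np.ndarray
    f_theta: np.ndarray
    f_zeta: np.ndarray
    f_theta_theta: np.ndarray
    f_theta_zeta: np.ndarray
    f_zeta_zeta: np.ndarray


def weight_derivatives(theta, zeta, n_t, n_c) -> WeightDerivs:
    """Analytic partials of the weight function via f = 1/g.

    With g the reciprocal weight (a sum of cosh terms), the chain rule
    gives ``f_a = -g_a f^2`` and ``f_ab = (2 g_a g_b / g - g_ab) f^2``.
    The mixed partial is symmetric by construction since
    ``g_{theta zeta} = g_{theta theta}``.  Broadcastable over all
    arguments; overflow in cosh yields the correct limit of zero for f and
    all partials.
    """
    g, g_t, g_z, g_tt, g_zz = _g_and_derivs(theta, zeta, n_t, n_c)
    g_tz = g_tt  # both equal 2 cosh(theta+zeta)/(n_t+1)
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        f = 1.0 / g
        f2 = f * f
        out = (
            f,
            -g_t * f2,
            -g_z * f2,
            (2.0 * g_t * g_t / g - g_tt) * f2,
            (2.0 * g_t * g_z / g - g_tz) * f2,
            (2.0 * g_z * g_z / g - g_zz) * f2,
        )
    finite = np.isfinite(g)
    out = tuple(np.where(finite, np.nan_to_num(o, nan=0.0, posinf=0.0, neginf=0.0), 0.0) for o in out)
    return WeightDerivs(*out)


# ---------------------------------------------------------------------------
# delta-method expansion of E[Q] under homogeneity
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NullSpec:
    """Parameters pinning down the null distribution of Q.

    The common log odds ratio ``theta``, per-study control log odds
    ``zetas`` and the per-study arm sizes.  In the plug-in test these are
    the pooled estimate theta_w and the corrected control logits.
    """

    theta: float
    zetas: np.ndarray
    n_t: np.ndarray
    n_c: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "zetas", np.asarray(self.zetas, dtype=float))
        object.__setattr__(self, "n_t", np.asarray(self.n_t, dtype=int))
        object.__setattr__(self, "n_c", np.asarray(self.n_c, dtype=int))
        k = self.zetas.shape[-1]
        if self.n_t.shape != (k,) or self.n_c.shape != (k,):
            raise ValueError("zetas, n_t, n_c must have matching length K")
        if np.any(self.n_t < 1) or np.any(self.n_c < 1):
            raise ValueError("arm sizes must be >= 1")
        if not (np.all(np.isfinite(self.zetas)) and np.isfinite(self.theta)):
            raise ValueError("theta and zetas must be finite")

    @property
    def k(self) -> int:
        return self.zetas.shape[-1]

    @property
    def p_c(self) -> np.ndarray:
        return expit(self.zetas)

    @property
    def p_t(self) -> np.ndarray:
        return expit(self.zetas + self.theta)

    @classmethod
    def from_probabilities(cls, theta: float, p_c, n_t, n_c) -> "NullSpec":
        p_c = np.asarray(p_c, dtype=float)
        return cls(theta=float(theta), zetas=np.log(p_c / (1.0 - p_c)), n_t=n_t, n_c=n_c)


def _pair_sum(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """sum over ordered pairs i != j of u_i * v_j along the last axis."""
    return u.sum(axis=-1) * v.sum(axis=-1) - (u * v).sum(axis=-1)


def _expected_q_batch(theta, zetas, n_t, n_c):
    """Delta-method E[Q] expansion, vectorised over leading axes.

    ``theta`` has shape ``S``, ``zetas`` shape ``S + (K,)``; ``n_t`` and
    ``n_c`` are length-K integer vectors.  Returns an array of shape ``S``.
    """
    theta = np.asarray(theta, dtype=float)
    zetas = np.asarray(zetas, dtype=float)
    n_t = np.asarray(n_t)
    n_c = np.asarray(n_c)
    k = zetas.shape[-1]
    if k < 2:
        raise ValueError("the expansion requires K >= 2 studies")

    p_c = expit(zetas)
    p_t = expit(zetas + theta[..., None])

    # exact mixed moments, study by study (arm sizes differ across studies)
    shape = zetas.shape
    t2 = np.empty(shape)
    t3 = np.empty(shape)
    t4 = np.empty(shape)
    tz = np.empty(shape)
    t2z = np.empty(shape)
    t3z = np.empty(shape)
    t2z2 = np.empty(shape)
    z2 = np.empty(shape)
    for i in range(k):
        mm = joint_null_moments(int(n_t[i]), int(n_c[i]), p_t[..., i], p_c[..., i])
        t2[..., i] = mm.t2
        t3[..., i] = mm.t3
        t4[..., i] = mm.t4
        tz[..., i] = mm.tz
        t2z[..., i] = mm.t2z
        t3z[..., i] = mm.t3z
        t2z2[..., i] = mm.t2z2
        z2[..., i] = mm.z2

    d = weight_derivatives(theta[..., None], zetas, n_t, n_c)
    w, ft, fz = d.f, d.f_theta, d.f_zeta
    ftt, ftz, fzz = d.f_theta_theta, d.f_theta_zeta, d.f_zeta_zeta
    w0 = w.sum(axis=-1)
    wk = w0[..., None]
    u = 1.0 - w / wk
    u2 = u * u

    # own-study terms of the expansion (Taylor coefficients already folded in)
    own = (
        w * u * t2
        + u2 * ft * t3
        + u2 * fz * t2z
        + 0.5 * u2 * (ftt - 2.0 * ft * ft / wk) * t4
        + u2 * (ftz - 2.0 * ft * fz / wk) * t3z
        + 0.5 * u2 * (fzz - 2.0 * fz * fz / wk) * t2z2
    ).sum(axis=-1)

    # cross-study terms: each factorises into per-i and per-j sums
    a = ft * t2  # f_theta_i E[Theta_i^2]
    b = fz * tz  # f_zeta_j E[Theta_j Z_j]
    w2t2 = w * w * t2

    t_tt = (1.0 / 8.0) * (
        (-8.0 / w0**3) * _pair_sum(ft * ft * t2, w2t2)
        + (4.0 / w0**2) * _pair_sum(ftt * t2, w2t2)
        + (8.0 / w0**2) * (2.0 * _pair_sum(w * a, u * a) - w0 * _pair_sum(a, a))
    )
    t_zz_cross = (1.0 / w0**2) * (
        2.0 * _pair_sum(w * b, u * b) - w0 * _pair_sum(b, b)
    )
    t_mixed = 0.5 * (
        (4.0 / w0**2)
        * (_pair_sum(w * t2 * ft, u * b) + _pair_sum(u * t2 * ft, w * b) - w0 * _pair_sum(t2 * ft, b))
        + (2.0 / w0**2) * _pair_sum(w2t2, ftz * tz)
        + (-4.0 / w0**3) * _pair_sum(w2t2, ft * fz * tz)
    )
    t_z2 = (0.5 / w0**2) * _pair_sum(w2t2, fzz * z2) - (1.0 / w0**3) * _pair_sum(
        w2t2, fz * fz * z2
    )

    return own + t_tt + t_zz_cross + t_mixed + t_z2


def expected_q_theoretical(null: NullSpec) -> float:
    """Theoretical null mean E_th[Q] from the delta-method expansion.

    Combines exact mixed moments of the corrected logit estimators with
    the analytic derivatives of Q with respect to the per-study effect and
    nuisance estimates, keeping terms through order 1/n.  Converges to
    K-1 as the arm sizes grow; for small studies with event probabilities
    away from 1/2 it falls below K-1.
    """
    return float(_expected_q_batch(np.float64(null.theta), null.zetas, null.n_t, null.n_c))


# ---------------------------------------------------------------------------
# fitted corrections and gamma matching
# ---------------------------------------------------------------------------


def corrected_mean(e_th: float, k: int):
    """Calibrated null mean of Q from the theoretical expansion.

    The expansion over-predicts the chi-square 'correction' (K-1) - E[Q]
    by a roughly constant factor; the fitted relation
    ``(K-1) - E[Q] = 0.687 [(K-1) - E_th[Q]]`` maps it onto the simulated
    mean.  A nonpositive result indicates a configuration outside the
    calibrated regime; callers that need a gamma reference must treat it
    as degenerate rather than clamp.
    """
    if k < 2:
        raise ValueError("K must be >= 2")
    km1 = k - 1.0
    return km1 - MEAN_CORRECTION_SLOPE * (km1 - np.asarray(e_th, dtype=float))


def variance_q(e_corr: float, k: int):
    """Calibrated null variance of Q from the fitted quadratic.

    ``Var[Q] = 4.74 (K-1) - 12.17 E[Q] + 9.42 E[Q]^2 / (K-1)``.  Writing
    r = E[Q]/(K-1), this is (K-1)(9.42 r^2 - 12.17 r + 4.74); the
    quadratic's discriminant is negative, so the variance is strictly
    positive for any real mean.  At E[Q] = K-1 it gives 1.99 (K-1),
    essentially the chi-square value 2(K-1).
    """
    if k < 2:
        raise ValueError("K must be >= 2")
    c0, c1, c2 = VARIANCE_COEFFS
    e = np.asarray(e_corr, dtype=float)
    return c0 * (k - 1.0) + c1 * e + c2 * e * e / (k - 1.0)


@dataclass(frozen=True)
class QNullMoments:
    """Null moments of Q: theoretical mean, corrected mean, variance."""

    e_th: float
    e_corr: float
    var_corr: float


def q_null_moments(null: NullSpec) -> QNullMoments:
    """Full chain E_th -> corrected E[Q] -> Var[Q] for one null spec."""
    e_th = expected_q_theoretical(null)
    e_corr = float(corrected_mean(e_th, null.k))
    var_corr = float(variance_q(e_corr, null.k))
    return QNullMoments(e_th=e_th, e_corr=e_corr, var_corr=var_corr)


@dataclass(frozen=True)
class GammaApprox:
    """Shape/scale of the gamma distribution matched to (E[Q], Var[Q])."""

    alpha: float
    beta: float


def gamma_params(e_corr: float, var_corr: float) -> GammaApprox:
    """Moment-matched gamma parameters ``alpha = E^2/V``, ``beta = V/E``.

    The chi-square(K-1) special case corresponds to E = K-1, V = 2(K-1),
    i.e. alpha = (K-1)/2 and beta = 2.
    """
    e = float(e_corr)
    v = float(var_corr)
    if e <= 0.0 or v <= 0.0:
        raise DegenerateNullError(
            f"gamma matching needs positive mean and variance, got E={e}, V={v}"
        )
    return GammaApprox(alpha=e * e / v, beta=v / e)
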
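import math

import numpy as np
import pytest
from scipy import stats
from scipy.special import expit, logit

from qhet import (
    DegenerateNullError,
    NullSpec,
    arm_logit_moments,
    corrected_mean,
    expected_q_theoretical,
    gamma_params,
    joint_null_moments,
    q_null_moments,
    variance_q,
    weight_derivatives,
    weight_function,
)
from qhet.null_moments import MEAN_CORRECTION_SLOPE, _expected_q_batch


def brute_force_mixed_moments(n_t, n_c, p_t, p_c):
    """Oracle: full 2-D enumeration over all (x, y) outcome pairs."""
    xs = np.arange(n_t + 1)
    ys = np.arange(n_c + 1)
    px = stats.binom.pmf(xs, n_t, p_t)
    py = stats.binom.pmf(ys, n_c, p_c)
    a = np.log((xs + 0.5) / (n_t - xs + 0.5)) - logit(p_t)
    b = np.log((ys + 0.5) / (n_c - ys + 0.5)) - logit(p_c)
    prob = np.outer(px, py)
    theta = a[:, None] - b[None, :]
    z = np.broadcast_to(b, prob.shape)
    m = lambda e: float((prob * e).sum())
    return {
        "t2": m(theta**2),
        "t3": m(theta**3),
        "t4": m(theta**4),
        "tz": m(theta * z),
        "t2z": m(theta**2 * z),
        "t3z": m(theta**3 * z),
        "t2z2": m(theta**2 * z**2),
        "z2": m(z**2),
    }


class TestArmLogitMoments:
    def test_tiny_arm_hand_enumeration(self):
        # n=2, p=0.3: outcomes 0,1,2 with probabilities 0.49, 0.42, 0.09
        am = arm_logit_moments(2, 0.3)
        ell = [math.log(0.5 / 2.5), 0.0, math.log(2.5 / 0.5)]
        d = [v - math.log(0.3 / 0.7) for v in ell]
        probs = [0.49, 0.42, 0.09]
        for order in range(1, 5):
            expected = sum(p * dv**order for p, dv in zip(probs, d))
            assert am.raw[order - 1] == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("n", [3, 10, 41])
    def test_odd_moments_vanish_at_half(self, n):
        # L_{1/2}(n - x) = -L_{1/2}(x), so the distribution of the error is
        # symmetric when p = 1/2
        am = arm_logit_moments(n, 0.5)
        assert am.raw[0] == pytest.approx(0.0, abs=1e-13)
        assert am.raw[2] == pytest.approx(0.0, abs=1e-13)

    def test_variance_matches_asymptotic_expansion(self):
        # second moment vs 1/(np(1-p)) + (1+2p)^2 / (2 n^2 p^2 (1-p)^2)
        n, p = 1000, 0.5
        am = arm_logit_moments(n, p)
        approx = 1 / (n * p * (1 - p)) + (1 + 2 * p) ** 2 / (
            2 * n**2 * p**2 * (1 - p) ** 2
        )
        assert am.raw[1] == pytest.approx(approx, rel=0.01)

    @pytest.mark.parametrize("p", [0.2, 0.4])
    def test_bias_decays_faster_than_n_to_three_halves(self, p):
        biases = [abs(arm_logit_moments(n, p).central[0]) for n in (20, 40, 80, 160)]
        for small, large in zip(biases, biases[1:]):
            assert large < small / 2**1.5

    def test_rejects_boundary_probability(self):
        with pytest.raises(ValueError):
            arm_logit_moments(10, 0.0)
        with pytest.raises(ValueError):
            arm_logit_moments(10, 1.0)


class TestJointNullMoments:
    @pytest.mark.parametrize(
        "n_t, n_c, p_t, p_c",
        [
            (3, 3, 0.5, 0.5),
            (3, 3, 0.2, 0.7),
            (6, 5, 0.35, 0.1),
            (2, 6, 0.8, 0.45),
            (6, 6, 0.05, 0.95),
        ],
    )
    def test_matches_exhaustive_enumeration(self, n_t, n_c, p_t, p_c):
        mm = joint_null_moments(n_t, n_c, p_t, p_c)
        oracle = brute_force_mixed_moments(n_t, n_c, p_t, p_c)
        for name, val in oracle.items():
            assert float(getattr(mm, name)) == pytest.approx(
                val, rel=1e-12, abs=1e-15
            ), name

    def test_effect_variance_positive_and_cross_moment_negative(self):
        mm = joint_null_moments(30, 30, 0.3, 0.3)
        assert float(mm.t2) > 0
        # E[Theta Z] = E[A]E[B] - E[B^2]: the bias product is O(1/n^2) while
        # E[B^2] is O(1/n), so the cross moment is negative for moderate n
        assert float(mm.tz) < 0


class TestWeightFunction:
    @pytest.mark.parametrize("n", [4, 45, 300])
    def test_balanced_null_value(self, n):
        # at theta = zeta = 0 with equal arms the weight is (n+1)/8
        assert weight_function(0.0, 0.0, n, n) == pytest.approx((n + 1) / 8.0, rel=1e-13)

    def test_maximised_at_zero_control_log_odds(self):
        zs = np.linspace(-4, 4, 41)
        f = weight_function(0.0, zs, 50, 50)
        assert np.argmax(f) == 20

    def test_extreme_arguments_underflow_to_zero(self):
        assert weight_function(800.0, 200.0, 50, 50) == 0.0

    def test_derivatives_match_finite_differences(self, rng):
        h = 1e-5
        for _ in range(40):
            th = float(rng.uniform(-2.5, 2.5))
            ze = float(rng.uniform(-2.5, 2.5))
            n_t, n_c = (int(v) for v in rng.integers(5, 300, 2))
            d = weight_derivatives(th, ze, n_t, n_c)
            f = lambda a, b: weight_function(a, b, n_t, n_c)
            fd_t = (f(th + h, ze) - f(th - h, ze)) / (2 * h)
            fd_z = (f(th, ze + h) - f(th, ze - h)) / (2 * h)
            fd_tt = (f(th + h, ze) - 2 * f(th, ze) + f(th - h, ze)) / h**2
            fd_zz = (f(th, ze + h) - 2 * f(th, ze) + f(th, ze - h)) / h**2
            fd_tz = (
                f(th + h, ze + h) - f(th + h, ze - h) - f(th - h, ze + h) + f(th - h, ze - h)
            ) / (4 * h**2)
            scale = float(d.f)
            assert float(d.f_theta) == pytest.approx(fd_t, rel=1e-6, abs=1e-6 * scale)
            assert float(d.f_zeta) == pytest.approx(fd_z, rel=1e-6, abs=1e-6 * scale)
            assert float(d.f_theta_theta) == pytest.approx(fd_tt, rel=1e-4, abs=1e-4 * scale)
            assert float(d.f_zeta_zeta) == pytest.approx(fd_zz, rel=1e-4, abs=1e-4 * scale)
            assert float(d.f_theta_zeta) == pytest.approx(fd_tz, rel=1e-4, abs=1e-4 * scale)


def expected_q_pair_loop(theta, zetas, n_t, n_c):
    """Naive double-loop assembly of the expansion, as an algebra oracle
    for the factorized O(K) implementation."""
    k = len(zetas)
    ders = [weight_derivatives(theta, zetas[i], int(n_t[i]), int(n_c[i])) for i in range(k)]
    w = np.array([float(d.f) for d in ders])
    w_tot = w.sum()
    u = 1.0 - w / w_tot
    moms = [
        joint_null_moments(
            int(n_t[i]), int(n_c[i]), float(expit(zetas[i] + theta)), float(expit(zetas[i]))
        )
        for i in range(k)
    ]
    total = 0.0
    for i in range(k):
        d, m = ders[i], moms[i]
        ft, fz = float(d.f_theta), float(d.f_zeta)
        ftt, ftz, fzz = (
            float(d.f_theta_theta),
            float(d.f_theta_zeta),
            float(d.f_zeta_zeta),
        )
        total += w[i] * u[i] * float(m.t2)
        total += u[i] ** 2 * ft * float(m.t3)
        total += u[i] ** 2 * fz * float(m.t2z)
        total += 0.5 * u[i] ** 2 * (ftt - 2 * ft**2 / w_tot) * float(m.t4)
        total += u[i] ** 2 * (ftz - 2 * ft * fz / w_tot) * float(m.t3z)
        total += 0.5 * u[i] ** 2 * (fzz - 2 * fz**2 / w_tot) * float(m.t2z2)
    for i in range(k):
        for j in range(k):
            if i == j:
                continue
            di, dj = ders[i], ders[j]
            fti, fzi = float(di.f_theta), float(di.f_zeta)
            ftj, fzj = float(dj.f_theta), float(dj.f_zeta)
            t2i, t2j = float(moms[i].t2), float(moms[j].t2)
            tzi, tzj = float(moms[i].tz), float(moms[j].tz)
            z2j = float(moms[j].z2)
            bracket = w[i] * u[j] + w[j] * u[i] - w_tot
            d7 = (
                -4 / w_tot**3 * (w[j] ** 2 * fti**2 + w[i] ** 2 * ftj**2)
                + 2 / w_tot**2 * (w[j] ** 2 * float(di.f_theta_theta) + w[i] ** 2 * float(dj.f_theta_theta))
                + 8 / w_tot**2 * bracket * fti * ftj
            )
            total += d7 / 8 * t2i * t2j
            d8 = 2 / w_tot**2 * bracket * fzi * fzj
            total += d8 / 2 * tzi * tzj
            d9 = (
                4 / w_tot**2 * bracket * fti * fzj
                + 2 * w[i] ** 2 / w_tot**2 * float(dj.f_theta_zeta)
                - 4 * w[i] ** 2 / w_tot**3 * ftj * fzj
            )
            total += d9 / 2 * t2i * tzj
            d10 = (
                2 * w[i] ** 2 / w_tot**2 * float(dj.f_zeta_zeta)
                - 4 * w[i] ** 2 / w_tot**3 * fzj**2
            )
            total += d10 / 4 * t2i * z2j
    return total


def fd_taylor_assembled_mean(theta0, zetas0, n_t, n_c, h=0.04):
    """Oracle: assemble the expansion from finite-difference Taylor
    coefficients of the explicit Q function, bypassing the analytic
    derivative formulas entirely."""
    import itertools

    k = len(zetas0)
    n_t = np.asarray(n_t, dtype=float)
    n_c = np.asarray(n_c, dtype=float)

    def q_fun(v):
        th, ze = v[:k], v[k:]
        g = (2 + 2 * np.cosh(th + ze)) / (n_t + 1) + (2 + 2 * np.cosh(ze)) / (n_c + 1)
        f = 1 / g
        tw = (f * th).sum() / f.sum()
        return (f * (th - tw) ** 2).sum()

    x0 = np.concatenate([np.full(k, theta0), zetas0])
    stencils = {
        1: ([-1, 1], [-0.5, 0.5]),
        2: ([-1, 0, 1], [1.0, -2.0, 1.0]),
        3: ([-2, -1, 1, 2], [-0.5, 1.0, -1.0, 0.5]),
        4: ([-2, -1, 0, 1, 2], [1.0, -4.0, 6.0, -4.0, 1.0]),
    }

    def fd(orders):
        items = list(orders.items())

        def rec(i, x):
            if i == len(items):
                return q_fun(x)
            var, od = items[i]
            offs, wts = stencils[od]
            tot = 0.0
            for o, wgt in zip(offs, wts):
                xx = x.copy()
                xx[var] += o * h
                tot += wgt * rec(i + 1, xx)
            return tot / h**od

        return rec(0, x0.copy())

    p_c = expit(zetas0)
    p_t = expit(zetas0 + theta0)
    mm = [joint_null_moments(int(n_t[i]), int(n_c[i]), p_t[i], p_c[i]) for i in range(k)]
    total = 0.0
    for i in range(k):
        m = mm[i]
        total += fd({i: 2}) / 2 * float(m.t2)
        total += fd({i: 3}) / 6 * float(m.t3)
        total += fd({i: 2, k + i: 1}) / 2 * float(m.t2z)
        total += fd({i: 4}) / 24 * float(m.t4)
        total += fd({i: 3, k + i: 1}) / 6 * float(m.t3z)
        total += fd({i: 2, k + i: 2}) / 4 * float(m.t2z2)
    for i, j in itertools.permutations(range(k), 2):
        mi, mj = mm[i], mm[j]
        total += fd({i: 2, j: 2}) / 8 * float(mi.t2) * float(mj.t2)
        total += fd({i: 1, k + i: 1, j: 1, k + j: 1}) / 2 * float(mi.tz) * float(mj.tz)
        total += fd({i: 2, j: 1, k + j: 1}) / 2 * float(mi.t2) * float(mj.tz)
        total += fd({i: 2, k + j: 2}) / 4 * float(mi.t2) * float(mj.z2)
    return total


class TestExpectedQTheoretical:
    def test_matches_finite_difference_taylor_assembly(self):
        # derivative table and cross-sum algebra vs direct numerical
        # differentiation of Q itself
        zetas = np.array([-1.2, -0.4, -2.0])
        n_t = np.array([31, 45, 60])
        n_c = np.array([29, 45, 40])
        ns = NullSpec(theta=0.7, zetas=zetas, n_t=n_t, n_c=n_c)
        oracle = fd_taylor_assembled_mean(0.7, zetas, n_t, n_c)
        assert expected_q_theoretical(ns) == pytest.approx(oracle, rel=5e-4)

    def test_factorized_sums_match_pair_loop(self, rng):
        for _ in range(5):
            k = int(rng.integers(2, 7))
            zetas = rng.uniform(-2.5, 1.0, k)
            n_t = rng.integers(10, 120, k)
            n_c = rng.integers(10, 120, k)
            theta = float(rng.uniform(-1.5, 1.5))
            ns = NullSpec(theta=theta, zetas=zetas, n_t=n_t, n_c=n_c)
            mine = expected_q_theoretical(ns)
            oracle = expected_q_pair_loop(theta, zetas, n_t, n_c)
            assert mine == pytest.approx(oracle, rel=1e-10)

    def test_batch_evaluation_matches_scalar(self, rng):
        k = 4
        thetas = rng.uniform(-1, 1, 7)
        zetas = rng.uniform(-2, 0, (7, k))
        n_t = np.array([30, 45, 60, 25])
        n_c = np.array([35, 45, 20, 50])
        batch = _expected_q_batch(thetas, zetas, n_t, n_c)
        for r in range(7):
            scalar = expected_q_theoretical(
                NullSpec(theta=float(thetas[r]), zetas=zetas[r], n_t=n_t, n_c=n_c)
            )
            assert batch[r] == pytest.approx(scalar, rel=1e-12)

    def test_converges_to_chisquare_mean_for_large_studies(self):
        ns = NullSpec.from_probabilities(0.0, [0.4] * 5, [5000] * 5, [5000] * 5)
        assert abs(expected_q_theoretical(ns) - 4.0) < 0.02

    def test_below_chisquare_mean_for_small_studies(self):
        ns = NullSpec.from_probabilities(0.0, [0.1] * 10, [45] * 10, [45] * 10)
        assert expected_q_theoretical(ns) < 9.0

    def test_correction_shrinks_with_study_size(self):
        # (K-1) - E_th decreases along the study-size ladder 90 -> 150 -> 210
        k, p_c, theta = 10, 0.2, 1.0
        corrections = []
        for n in (90, 150, 210, 2000):
            half = n // 2
            ns = NullSpec.from_probabilities(theta, [p_c] * k, [half] * k, [half] * k)
            corrections.append((k - 1) - expected_q_theoretical(ns))
        assert corrections == sorted(corrections, reverse=True)
        assert corrections[-1] < 0.05

    def test_rejects_single_study(self):
        with pytest.raises(ValueError):
            expected_q_theoretical(
                NullSpec(theta=0.0, zetas=np.array([-1.0]), n_t=[20], n_c=[20])
            )


class TestCorrectedMoments:
    @pytest.mark.parametrize(
        "e_th, k, expected", [(14.18, 17, 14.75), (15.14, 18, 15.72)]
    )
    def test_mean_correction_worked_examples(self, e_th, k, expected):
        assert round(float(corrected_mean(e_th, k)), 2) == expected

    @pytest.mark.parametrize("k", [2, 5, 17])
    def test_zero_correction_fixed_point(self, k):
        assert float(corrected_mean(k - 1.0, k)) == pytest.approx(k - 1.0)

    def test_corrected_mean_stays_below_df_when_expansion_does(self):
        for k in (3, 10, 25):
            for e_th in np.linspace(0.1, k - 1, 7):
                assert float(corrected_mean(e_th, k)) <= k - 1 + 1e-12

    @pytest.mark.parametrize(
        "e_th, k, expected", [(14.18, 17, 24.43), (15.14, 18, 26.22)]
    )
    def test_variance_worked_examples(self, e_th, k, expected):
        # chained from the printed theoretical mean through the unrounded
        # corrected mean; the inputs themselves are printed to 2 dp, so one
        # unit in the last printed place is the attainable precision
        e_corr = float(corrected_mean(e_th, k))
        assert float(variance_q(e_corr, k)) == pytest.approx(expected, abs=0.011)

    @pytest.mark.parametrize("k", [2, 10, 41])
    def test_variance_at_chisquare_mean(self, k):
        # substituting E = K-1 gives 1.99 (K-1), close to the chi-square 2(K-1)
        assert float(variance_q(k - 1.0, k)) == pytest.approx(1.99 * (k - 1), rel=1e-12)

    def test_variance_strictly_positive_for_any_mean(self):
        for k in (2, 5, 40):
            e = np.linspace(-3 * k, 5 * k, 101)
            assert np.all(variance_q(e, k) > 0)


class TestGammaParams:
    def test_chisquare_special_case(self):
        k = 13
        g = gamma_params(k - 1.0, 2.0 * (k - 1))
        assert g.alpha == pytest.approx((k - 1) / 2)
        assert g.beta == pytest.approx(2.0)

    def test_moment_match_is_exact(self, rng):
        for _ in range(20):
            e = float(rng.uniform(0.5, 40))
            v = float(rng.uniform(0.5, 80))
            g = gamma_params(e, v)
            assert g.alpha * g.beta == pytest.approx(e, rel=1e-10)
            assert g.alpha * g.beta**2 == pytest.approx(v, rel=1e-10)

    def test_rejects_nonpositive_moments(self):
        with pytest.raises(DegenerateNullError):
            gamma_params(-0.3, 5.0)
        with pytest.raises(DegenerateNullError):
            gamma_params(4.0, 0.0)


# six scenarios spanning the simulation grid: K, N, q, p_C, theta
CALIBRATION_CONFIGS = [
    (5, 90, 0.5, 0.1, 0.0),
    (5, 150, 0.5, 0.2, 0.5),
    (10, 90, 1 / 3, 0.4, 1.0),
    (10, 210, 0.5, 0.1, 0.0),
    (20, 150, 2 / 3, 0.2, 1.5),
    (20, 210, 0.5, 0.4, 2.0),
]


def simulate_q_lor(k, n, q, p_c, theta, reps, seed):
    """Monte-Carlo draw of Q on 1/2-corrected effects under homogeneity."""
    n_c = int(round(q * n))
    n_t = n - n_c
    p_t = float(expit(logit(p_c) + theta))
    rng = np.random.default_rng(seed)
    x = rng.binomial(n_t, p_t, (reps, k)).astype(float)
    y = rng.binomial(n_c, p_c, (reps, k)).astype(float)
    lt = np.log((x + 0.5) / (n_t - x + 0.5))
    lc = np.log((y + 0.5) / (n_c - y + 0.5))
    th = lt - lc
    var = 1 / (x + 0.5) + 1 / (n_t - x + 0.5) + 1 / (y + 0.5) + 1 / (n_c - y + 0.5)
    w = 1 / var
    tw = (w * th).sum(axis=1) / w.sum(axis=1)
    return (w * (th - tw[:, None]) ** 2).sum(axis=1)


class TestCalibrationAgainstSimulation:
    @pytest.mark.parametrize("k, n, q, p_c, theta", CALIBRATION_CONFIGS)
    def test_corrected_moments_track_simulated_moments(self, k, n, q, p_c, theta):
        # the fitted corrections are global regressions (R^2 ~ 97-98.5%);
        # per-configuration residuals of a few percent are their intrinsic
        # accuracy, so the bands here are relative, not Monte-Carlo
        n_c = int(round(q * n))
        n_t = n - n_c
        ns = NullSpec.from_probabilities(theta, [p_c] * k, [n_t] * k, [n_c] * k)
        mom = q_null_moments(ns)
        qs = simulate_q_lor(k, n, q, p_c, theta, reps=50_000, seed=7_654_321)
        assert mom.e_corr == pytest.approx(qs.mean(), rel=0.03)
        assert mom.var_corr == pytest.approx(qs.var(ddof=1), rel=0.08)
        # and the theoretical expansion itself must under-shoot K-1 on the
        # same side as the simulation
        assert (k - 1 - mom.e_th) * (k - 1 - qs.mean()) >= 0

    def test_gamma_reference_beats_chisquare_on_distribution(self):
        # the whole point of the gamma approximation: in a harsh scenario
        # the matched gamma fits the null distribution of Q far better than
        # chi-square(K-1)
        k, n, q, p_c, theta = 10, 90, 0.5, 0.1, 0.0
        ns = NullSpec.from_probabilities(theta, [p_c] * k, [45] * k, [45] * k)
        mom = q_null_moments(ns)
        g = gamma_params(mom.e_corr, mom.var_corr)
        qs = simulate_q_lor(k, n, q, p_c, theta, reps=10_000, seed=99)
        ks_gamma = stats.kstest(qs, stats.gamma(a=g.alpha, scale=g.beta).cdf).statistic
        ks_chi2 = stats.kstest(qs, stats.chi2(k - 1).cdf).statistic
        assert ks_gamma < ks_chi2 / 3
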
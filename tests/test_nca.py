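"""Non-compartmental analysis: AUC, terminal slope, summary identities."""

import math

import numpy as np
import pytest

from e0703pk import (
    ConcentrationTimeProfile,
    InvalidProfileError,
    bioavailability,
    clearance_per_kg,
    clearance_total,
    compute_auc,
    estimate_lambda_z,
    nca_summary,
)
from e0703pk.synth import OneCompartmentPK


def profile(t, c, dose=1.0, route="oral", per_kg=True, bw=None):
    return ConcentrationTimeProfile(
        times=np.asarray(t, float), concentrations=np.asarray(c, float),
        dose_amount=dose, route=route, dose_per_kg=per_kg, body_weight=bw,
    )


class TestAUC:
    def test_zero_profile(self):
        assert compute_auc(profile([0, 1], [0, 0])) == 0.0

    def test_rectangle(self):
        p = profile(np.linspace(0, 10, 11), np.ones(11))
        assert compute_auc(p) == pytest.approx(10.0)

    @pytest.mark.parametrize("method", ["linear", "linear_up_log_down"])
    def test_matches_fine_grid_quadrature_of_interpolant(self, method):
        """AUC of a sampled mono-exponential equals numeric quadrature of the
        same piecewise interpolant to <0.1%."""
        t = np.linspace(0, 12, 10)
        c = 100.0 * np.exp(-0.3 * t)
        p = profile(t, c)
        # oracle: 10,000-step quadrature of the segment interpolant
        expected = 0.0
        for i in range(t.size - 1):
            tt = np.linspace(t[i], t[i + 1], 10_000)
            if method == "linear_up_log_down" and c[i + 1] < c[i]:
                k = np.log(c[i] / c[i + 1]) / (t[i + 1] - t[i])
                cc = c[i] * np.exp(-k * (tt - t[i]))
            else:
                cc = np.interp(tt, t[i:i + 2], c[i:i + 2])
            expected += np.trapezoid(cc, tt)
        assert compute_auc(p, method) == pytest.approx(expected, rel=1e-3)

    def test_additivity_over_interior_split(self, rng):
        """AUC[t0,t2] = AUC[t0,t1] + AUC[t1,t2] at any interior sample."""
        for _ in range(20):
            t = np.sort(rng.uniform(0, 24, size=10))
            t[0] = 0.0
            c = rng.lognormal(0, 1, size=10)
            for method in ("linear", "linear_up_log_down"):
                full = compute_auc(profile(t, c), method)
                k = rng.integers(2, 8)
                left = compute_auc(profile(t[: k + 1], c[: k + 1]), method)
                right = compute_auc(profile(t[k:], c[k:]), method)
                assert full == pytest.approx(left + right, rel=1e-12)

    def test_requires_two_points(self):
        with pytest.raises(InvalidProfileError):
            profile([0.0], [1.0])


class TestLambdaZ:
    def test_exact_monoexponential(self):
        t = np.linspace(2, 12, 6)
        p = profile(t, 50 * np.exp(-0.2 * t))
        lam, n, r2 = estimate_lambda_z(p)
        assert lam == pytest.approx(0.2, abs=1e-12)
        assert n >= 3 and r2 == pytest.approx(1.0)

    def test_cmax_excluded_for_oral(self):
        t = np.array([0, 1, 2, 4, 8, 12, 16.0])
        c = np.array([0, 5, 10, 8, 4, 2, 1.0])
        lam, n, _ = estimate_lambda_z(profile(t, c))
        assert n <= 5  # only points strictly after Tmax (t=2) may be used

    def test_biexponential_recovers_slow_eigenvalue(self):
        """With terminal samples spanning >= 2 slow half-lives, lambda-z is
        within 5% of the slow rate constant of the generating model."""
        slow, fast = 0.1, 1.5
        t = np.array([0.25, 0.5, 1, 2, 4, 8, 12, 18, 24, 30, 36.0])
        c = 80 * np.exp(-fast * t) + 20 * np.exp(-slow * t)
        lam, _, _ = estimate_lambda_z(profile(t, c, route="intravenous"))
        assert lam == pytest.approx(slow, rel=0.05)

    def test_not_estimable_reports_missing(self):
        res = nca_summary(profile([0, 1, 2], [0, 5, 10]))
        assert math.isnan(res.auc_0_inf) and math.isnan(res.t_half)
        assert res.cmax == 10.0 and res.auc_0_t > 0


class TestSummary:
    def test_one_compartment_recovery_within_2pct(self):
        """Noise-free one-compartment profile, 14 samples over 5 half-lives:
        CL and V recovered within 2%."""
        model = OneCompartmentPK(cl_l_h=2.0, v_l=20.0)  # t1/2 = 6.93 h
        t = np.linspace(0.0, 35, 15)
        c = model.concentration(t, 10.0, "intravenous")
        res = nca_summary(profile(t, c, dose=10.0, route="intravenous",
                                  per_kg=False, bw=1.0))
        assert res.cl_over_f_per_kg == pytest.approx(2.0, rel=0.02)
        assert res.vss_over_f_per_kg == pytest.approx(20.0, rel=0.02)

    def test_vss_identity_and_auc_ordering(self):
        t = np.array([0, 0.5, 1, 2, 4, 8, 12, 24.0])
        c = np.array([0, 40, 60, 50, 30, 12, 5, 0.7])
        res = nca_summary(profile(t, c, dose=5.0))
        assert res.auc_0_inf >= res.auc_0_t
        assert res.vss_over_f_per_kg == pytest.approx(
            res.cl_over_f_per_kg * res.mrt, rel=1e-12
        )
        assert res.t_half == pytest.approx(math.log(2) / res.lambda_z)

    def test_dose_proportionality_gives_identical_cl_f(self):
        t = np.array([0, 0.5, 1, 2, 4, 8, 12, 24.0])
        c = np.array([0, 40, 60, 50, 30, 12, 5, 0.7])
        lo = nca_summary(profile(t, c, dose=5.0))
        hi = nca_summary(profile(t, 4 * c, dose=20.0))
        assert hi.cl_over_f_per_kg == pytest.approx(lo.cl_over_f_per_kg)
        assert hi.cmax == pytest.approx(4 * lo.cmax)
        assert hi.auc_0_inf == pytest.approx(4 * lo.auc_0_inf)

    def test_blq_handling(self):
        p = profile([0, 1, 2, 4, 6], [0, 10, np.nan, 0, 2])
        # NaN and the mid-profile zero drop; leading zero stays
        assert p.times.tolist() == [0, 1, 6]

    def test_total_dose_needs_body_weight(self):
        p = profile([0, 1, 2, 4, 8], [0, 10, 8, 4, 1], dose=5.0, per_kg=False)
        from e0703pk import ConfigurationError

        with pytest.raises(ConfigurationError):
            nca_summary(p)


class TestDoseNormalization:
    """The arithmetic behind the printed summary tables."""

    def test_per_kg_clearance(self):
        assert clearance_per_kg(5.0, 560.7) == pytest.approx(8.92, rel=1e-3)

    def test_total_clearance(self):
        assert clearance_total(13.5, 4802.7) == pytest.approx(2.811, rel=1e-3)


class TestBioavailability:
    def test_identity(self):
        assert bioavailability(100, 5, 100, 5) == pytest.approx(100.0)

    def test_half_exposure(self):
        assert bioavailability(50, 5, 100, 5) == pytest.approx(50.0)

    def test_monkey_group_means(self):
        # 30 mg/kg oral vs 3 mg/kg IV group means give 0.77% by the formula
        f = bioavailability(370.6, 30.0, 4802.7, 3.0)
        assert f == pytest.approx(0.7716, rel=1e-3)

    def test_missing_auc(self):
        from e0703pk import NotEstimableError

        with pytest.raises(NotEstimableError):
            bioavailability(math.nan, 5, 100, 5)
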
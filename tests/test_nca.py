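"""Non-compartmental analysis: terminal-slope fitting, trapezoids, and the
derived parameter identities."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

import meropkpd as m
from meropkpd.nca import auc_aumc, fit_lambda_z


def exp_profile(lam=0.5, c0=10.0, times=(1.0, 2.0, 3.0, 4.0, 5.0)):
    samples = tuple((t, c0 * math.exp(-lam * t)) for t in times)
    return m.ConcentrationTimeProfile("exp", 1000.0, 0.5, samples)


class TestProfileValidation:
    def test_requires_four_samples(self):
        with pytest.raises(ValueError, match="at least 4"):
            m.ConcentrationTimeProfile("x", 1000, 0.5, ((1, 1), (2, 1), (3, 1)))

    def test_requires_increasing_times(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            m.ConcentrationTimeProfile("x", 1000, 0.5, ((1, 1), (1, 1), (2, 1), (3, 1)))

    def test_rejects_negative_concentration(self):
        with pytest.raises(ValueError, match="non-negative"):
            m.ConcentrationTimeProfile("x", 1000, 0.5, ((1, 1), (2, -1), (3, 1), (4, 1)))

    def test_lloq_samples_dropped_not_zeroed(self):
        p = m.ConcentrationTimeProfile(
            "x", 1000, 0.5,
            ((1, 10.0), (2, 5.0), (3, 2.0), (3.5, 1.0), (4, 0.01)), lloq=0.05,
        )
        q = p.quantifiable()
        assert len(q.samples) == 4
        assert all(c >= 0.05 for _, c in q.samples)


class TestFitLambdaZ:
    def test_exact_exponential_tail(self):
        lz, r2, n = fit_lambda_z(exp_profile(lam=0.5))
        assert lz == pytest.approx(0.5, abs=1e-12)
        assert r2 == pytest.approx(1.0, abs=1e-12)
        assert n == 4  # ties resolved toward more points (Cmax excluded)

    def test_flat_profile_not_estimable(self):
        p = m.ConcentrationTimeProfile("flat", 1000, 0.5, ((1, 5), (2, 5), (3, 5), (4, 5)))
        with pytest.raises(m.TerminalPhaseError, match="not estimable"):
            fit_lambda_z(p)

    def test_too_few_points_not_estimable(self):
        # Cmax at the third point leaves only one terminal candidate
        p = m.ConcentrationTimeProfile("x", 1000, 0.5, ((1, 1), (2, 5), (3, 9), (4, 6)))
        with pytest.raises(m.TerminalPhaseError):
            fit_lambda_z(p)

    def test_manual_k_uses_last_points(self):
        lz, _, n = fit_lambda_z(exp_profile(), strategy=3)
        assert n == 3
        assert lz == pytest.approx(0.5, abs=1e-12)

    def test_noise_free_infusion_profile_recovers_ke(self, noise_free_profile):
        profile, cl, vd = noise_free_profile
        lz, r2, _ = fit_lambda_z(profile)
        assert lz == pytest.approx(cl / vd, abs=1e-6)
        assert r2 == pytest.approx(1.0, abs=1e-9)


class TestAucAumc:
    def test_linear_trapezoid(self):
        p = m.ConcentrationTimeProfile("x", 1000, 0.5, ((0.5, 1.0), (1, 4.0), (2, 2.0), (3, 1.0)))
        auc, _ = auc_aumc(p, method="linear")
        # 0.25 (lead-in from C(0)=0) + 1.25 + 3 + 1.5
        assert auc == pytest.approx(6.0)

    def test_log_trapezoid_exact_on_exponential(self):
        lam, c0 = 0.5, 10.0
        p = exp_profile(lam=lam, c0=c0, times=(1.0, 2.0, 3.0, 4.0))
        auc, _ = auc_aumc(p, method="linear_up_log_down")
        lead_in = 1.0 * c0 * math.exp(-lam) / 2.0  # linear from C(0)=0
        exact_tail = (c0 * math.exp(-lam) - c0 * math.exp(-4 * lam)) / lam
        assert auc == pytest.approx(lead_in + exact_tail, rel=1e-12)

    def test_matches_quadrature_on_model_profile(self, noise_free_profile):
        profile, cl, vd = noise_free_profile
        auc, _ = auc_aumc(profile)
        truth, _ = quad(
            lambda t: m.single_dose_conc(t, cl, vd, 1000.0, 0.5), 0, 7.5, limit=200
        )
        assert auc == pytest.approx(truth, rel=0.02)


class TestRunNCA:
    def test_recovers_cl_and_vz_from_noise_free_profile(self, noise_free_profile):
        profile, cl, vd = noise_free_profile
        res = m.run_nca(profile)
        assert res.cl == pytest.approx(cl, rel=0.03)
        assert res.vz == pytest.approx(vd, rel=0.03)

    def test_parameter_identities_hold_exactly(self, noise_free_profile):
        profile, _, _ = noise_free_profile
        r = m.run_nca(profile)
        assert r.cl == pytest.approx(profile.dose_mg / r.auc_inf, rel=1e-12)
        assert r.vz == pytest.approx(profile.dose_mg / (r.lambda_z * r.auc_inf), rel=1e-12)
        assert r.t_half == pytest.approx(math.log(2) / r.lambda_z, rel=1e-12)
        assert r.auc_inf >= r.auc_last
        assert r.cmax == max(profile.concs)
        assert r.tmax == profile.times[int(np.argmax(profile.concs))]

    def test_dose_doubling_linearity(self, noise_free_profile):
        profile, _, _ = noise_free_profile
        import dataclasses

        doubled = dataclasses.replace(profile.scaled(2.0), dose_mg=2 * profile.dose_mg)
        r1, r2 = m.run_nca(profile), m.run_nca(doubled)
        assert r2.auc_inf == pytest.approx(2 * r1.auc_inf, rel=1e-12)
        assert r2.cl == pytest.approx(r1.cl, rel=1e-12)

    def test_truncation_increases_extrapolated_share(self, noise_free_profile):
        profile, _, _ = noise_free_profile
        import dataclasses

        short = dataclasses.replace(profile, samples=profile.samples[:5])
        assert m.run_nca(short).pct_extrapolated > m.run_nca(profile).pct_extrapolated

    def test_denser_sampling_improves_recovery(self):
        cl, vd = 7.7, 22.6
        errs = {}
        for n, label in ((8, "sparse"), (50, "dense")):
            times = np.linspace(0.25, 7.5, n)
            c = m.single_dose_conc(times, cl, vd, 1000.0, 0.5)
            p = m.ConcentrationTimeProfile("x", 1000.0, 0.5, tuple(zip(times, c)))
            errs[label] = abs(m.run_nca(p).cl / cl - 1)
        assert errs["dense"] < errs["sparse"]


@settings(max_examples=30, derandomize=True, deadline=None)
@given(factor=st.floats(min_value=0.1, max_value=10.0, allow_nan=False))
def test_concentration_scaling_invariance(factor):
    """Scaling all concentrations by c scales AUC/AUMC/Cmax by c and leaves
    lambda_z and t1/2 unchanged (dose-linearity of NCA)."""
    cl, vd = 6.0, 20.0
    times = list(m.STUDY_SCHEDULE)
    c = m.single_dose_conc(times, cl, vd, 1000.0, 0.5)
    base = m.ConcentrationTimeProfile("x", 1000.0, 0.5, tuple(zip(times, c)))
    r1, r2 = m.run_nca(base), m.run_nca(base.scaled(factor))
    assert r2.auc_last == pytest.approx(factor * r1.auc_last, rel=1e-9)
    assert r2.cmax == pytest.approx(factor * r1.cmax, rel=1e-9)
    assert r2.lambda_z == pytest.approx(r1.lambda_z, rel=1e-9)
    assert r2.t_half == pytest.approx(r1.t_half, rel=1e-9)
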
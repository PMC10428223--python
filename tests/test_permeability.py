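import numpy as np
import pytest
from scipy.integrate import quad

from permeoskin import (Constants, NM_PER_PS_TO_CM_PER_H, enhancement_ratio,
                        flux, permeability_coefficient, resistance_profile)

from conftest import make_profile


def piecewise_profiles(segments, nodes_per_segment=21):
    """Build pmf/diffusion profiles from (length_nm, dG, D) segments.

    Each segment is sampled on a node-centered grid including its exact
    boundaries (interior boundaries doubled with a 1e-9 nm offset so the
    step is represented exactly). Returns (pmf, diffusion, closed-form
    single-bilayer resistance in ps/nm computed independently as
    sum L_i e^{beta G_i} / D_i).
    """
    beta = Constants().beta
    z_parts, g_parts, d_parts = [], [], []
    z0 = 0.0
    closed = 0.0
    for i, (length, dg, dcoef) in enumerate(segments):
        zs = np.linspace(z0, z0 + length, nodes_per_segment)
        if i > 0:
            zs[0] += 1e-9  # keep the grid strictly increasing across the step
        z_parts.append(zs)
        g_parts.append(np.full(zs.size, dg))
        d_parts.append(np.full(zs.size, dcoef))
        closed += length * np.exp(beta * dg) / dcoef
        z0 += length
    z = np.concatenate(z_parts)
    pmf = make_profile(z, np.concatenate(g_parts), "pmf")
    diff = make_profile(z, np.concatenate(d_parts), "diffusion")
    return pmf, diff, closed


class TestResistanceProfile:
    def test_flat_profile_closed_form(self, flat_pmf, unit_diffusion, constants):
        r = resistance_profile(flat_pmf, unit_diffusion, constants)
        # dG=0, D=1 nm^2/ps over ~5 nm: R = L/D in ps/nm, converted to h/cm
        span = flat_pmf.z[-1] - flat_pmf.z[0]
        assert r.values[-1] == pytest.approx(span / NM_PER_PS_TO_CM_PER_H, rel=1e-12)

    def test_rt_ln2_doubles_resistance(self, flat_pmf, unit_diffusion, constants):
        base = resistance_profile(flat_pmf, unit_diffusion, constants).values[-1]
        lifted = flat_pmf.replace(values=flat_pmf.values
                                  + constants.rt * np.log(2.0))
        doubled = resistance_profile(lifted, unit_diffusion, constants).values[-1]
        assert doubled == pytest.approx(2.0 * base, rel=1e-12)

    def test_half_step_analytic(self, constants):
        # dG = 0 on the first half, G on the second: R = (L/2)(1+e^{bG})/D
        g_step = 6.0
        pmf, diff, _ = piecewise_profiles([(2.5, 0.0, 0.5), (2.5, g_step, 0.5)])
        r = resistance_profile(pmf, diff, constants).values[-1]
        analytic = 2.5 * (1 + np.exp(constants.beta * g_step)) / 0.5
        assert r * NM_PER_PS_TO_CM_PER_H == pytest.approx(analytic, rel=1e-3)

    def test_cumulative_and_nondecreasing(self, constants, rng):
        z = 0.01 * (np.arange(300) + 0.5)
        pmf = make_profile(z, rng.uniform(0, 15, z.size), "pmf")
        diff = make_profile(z, rng.uniform(0.001, 0.01, z.size), "diffusion")
        r = resistance_profile(pmf, diff, constants)
        assert r.values[0] == 0.0
        assert np.all(np.diff(r.values) >= 0)

    def test_grid_mismatch_errors(self, flat_pmf, constants):
        short = make_profile([1.0, 2.0, 3.0], np.ones(3), "diffusion")
        with pytest.raises(Exception, match="cover"):
            resistance_profile(flat_pmf, short, constants)


class TestPermeabilityCoefficient:
    def test_flat_profile_kp(self, flat_pmf, unit_diffusion, constants):
        res = permeability_coefficient(flat_pmf, unit_diffusion, constants,
                                       n_bilayers=1)
        span = flat_pmf.z[-1] - flat_pmf.z[0]
        assert res.kp == pytest.approx(NM_PER_PS_TO_CM_PER_H / span, rel=1e-12)

    def test_n_bilayers_scales_kp_exactly(self, flat_pmf, unit_diffusion, constants):
        one = permeability_coefficient(flat_pmf, unit_diffusion, constants, 1)
        thirty = permeability_coefficient(flat_pmf, unit_diffusion, constants, 30)
        assert one.kp == pytest.approx(30.0 * thirty.kp, rel=1e-12)

    def test_gaussian_barrier_vs_quadrature_oracle(self, constants):
        beta = constants.beta
        z = 0.001 * (np.arange(5000) + 0.5)
        dg = 20.0 * np.exp(-((z - 2.5) ** 2) / 0.5)
        pmf = make_profile(z, dg, "pmf")
        diff = make_profile(z, np.full(z.size, 0.001), "diffusion")
        res = permeability_coefficient(pmf, diff, constants, n_bilayers=1)
        integral, _ = quad(
            lambda x: np.exp(beta * 20.0 * np.exp(-((x - 2.5) ** 2) / 0.5)) / 0.001,
            z[0], z[-1], limit=200)
        kp_oracle = NM_PER_PS_TO_CM_PER_H / integral
        assert res.kp == pytest.approx(kp_oracle, rel=5e-3)

    def test_piecewise_constant_closed_form(self, constants, rng):
        for _ in range(20):
            nseg = rng.integers(2, 6)
            segments = [(float(rng.uniform(0.5, 1.5)),
                         float(rng.uniform(0, 12)),
                         float(rng.uniform(0.001, 0.01))) for _ in range(nseg)]
            pmf, diff, closed_ps_per_nm = piecewise_profiles(segments)
            res = permeability_coefficient(pmf, diff, constants, n_bilayers=30)
            kp_oracle = NM_PER_PS_TO_CM_PER_H / (30.0 * closed_ps_per_nm)
            assert res.kp == pytest.approx(kp_oracle, rel=1e-3)

    def test_monotone_in_pmf_and_diffusion(self, constants, rng):
        z = 0.01 * (np.arange(200) + 0.5)
        for _ in range(25):
            base = rng.uniform(0, 10, z.size)
            bump = rng.uniform(0, 5, z.size)
            d = rng.uniform(0.001, 0.01, z.size)
            pmf_lo = make_profile(z, base, "pmf")
            pmf_hi = make_profile(z, base + bump, "pmf")
            diff = make_profile(z, d, "diffusion")
            diff_lo = make_profile(z, d * rng.uniform(0.2, 1.0, z.size), "diffusion")
            kp = permeability_coefficient(pmf_lo, diff, constants).kp
            assert permeability_coefficient(pmf_hi, diff, constants).kp <= kp
            assert permeability_coefficient(pmf_lo, diff_lo, constants).kp <= kp

    def test_grid_refinement_converges(self, constants):
        def kp_at(spacing):
            z = spacing * (np.arange(int(5.0 / spacing)) + 0.5)
            dg = 15.0 * np.exp(-((z - 2.5) ** 2) / 0.3)
            pmf = make_profile(z, dg, "pmf")
            diff = make_profile(z, np.full(z.size, 0.002), "diffusion")
            return permeability_coefficient(pmf, diff, constants).kp

        coarse, mid, fine = kp_at(0.04), kp_at(0.02), kp_at(0.01)
        assert abs(fine - mid) < abs(mid - coarse)

    def test_stderr_envelope_propagation(self, flat_pmf, unit_diffusion, constants):
        sigma = np.full(len(flat_pmf), 1.0)
        res = permeability_coefficient(flat_pmf, unit_diffusion, constants,
                                       pmf_stderr=sigma)
        # constant +-1 kJ/mol envelope shifts log kp by beta/ln10 each way
        expected = constants.beta / np.log(10.0)
        assert res.stderr_log_kp == pytest.approx(expected, rel=1e-9)

    def test_log_kp_consistent(self, flat_pmf, unit_diffusion, constants):
        res = permeability_coefficient(flat_pmf, unit_diffusion, constants)
        assert res.log_kp == pytest.approx(np.log10(res.kp), abs=1e-14)


class TestEnhancementRatioAndFlux:
    def test_geraniol_row(self):
        assert enhancement_ratio(-2.74, -3.79) == pytest.approx(11.22, abs=0.01)
        assert round(enhancement_ratio(-2.74, -3.79)) == 11

    def test_identity(self):
        assert enhancement_ratio(-3.0, -3.0) == 1.0

    def test_caffeine_oleic_row(self):
        assert round(enhancement_ratio(-1.92, -3.00)) == 12

    def test_flux_unit_arithmetic(self):
        assert flux(1e-3, 1000.0) == pytest.approx(1.0)
        assert flux(1e-3, 0.0) == 0.0
        assert flux(1e-3, 2000.0) == pytest.approx(2.0 * flux(1e-3, 1000.0))

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            flux(1e-3, -1.0)
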
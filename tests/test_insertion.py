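import math

import numpy as np
import pytest

from permeoskin import (BilayerGeometry, Component, Constants, FormulationSpec,
                        apply_headgroup_cap, formulation_count,
                        make_water_insertion_fixture, number_density_per_nm3,
                        place_molecules, scale_plan, slice_counts)

from conftest import make_profile


def simple_spec(conc_g_per_l=100.0, molar_mass=100.0, volume=100.0, name="pe"):
    return FormulationSpec(
        components=[Component(name=name, concentration=conc_g_per_l,
                              molar_mass=molar_mass, unit="g/L")],
        system_volume=volume, ethanol_evaporation_fraction=0.0)


def domain_profile(values_fn, geometry=None, spacing=0.01):
    geometry = geometry or BilayerGeometry()
    n = int(round((geometry.z_max - geometry.z_min) / spacing))
    z = geometry.z_min + spacing * (np.arange(n) + 0.5)
    return make_profile(z, values_fn(z), "pmf")


class TestFormulationCount:
    def test_one_molecule_per_nm3(self):
        # concentration chosen so the number density is exactly 1 nm^-3
        m = 100.0
        conc = m / (6.02214076e23 * 1e-24)  # g/L
        spec = simple_spec(conc, m, volume=100.0)
        assert formulation_count(spec, "pe") == pytest.approx(100.0, rel=1e-12)

    def test_thymol_pure_liquid_density(self):
        # 0.97 g/cm^3, MW 150.22 -> 3.9 molecules nm^-3
        density = number_density_per_nm3(970.0, 150.22)
        assert density == pytest.approx(3.9, abs=0.05)

    def test_ethanol_evaporation_halves_ethanol(self):
        ethanol = Component("ethanol", 60.0, 46.07, unit="%w/v")
        drug = Component("caffeine", 20.0, 194.19, unit="mg/L")
        spec = FormulationSpec(components=[ethanol, drug], system_volume=100.0,
                               ethanol_evaporation_fraction=0.5)
        no_evap = FormulationSpec(components=[ethanol, drug], system_volume=100.0,
                                  ethanol_evaporation_fraction=0.0)
        c_evap = spec.effective_grams_per_liter("ethanol")
        c_raw = no_evap.effective_grams_per_liter("ethanol")
        # half the ethanol mass remains, in a smaller solution volume
        removed_volume = 0.5 * 600.0 / 789.0
        assert c_evap == pytest.approx(0.5 * c_raw / (1 - removed_volume))
        # the co-solute is concentrated by the volume loss
        assert spec.effective_grams_per_liter("caffeine") == pytest.approx(
            no_evap.effective_grams_per_liter("caffeine") / (1 - removed_volume))

    def test_unknown_component_errors(self):
        with pytest.raises(KeyError):
            formulation_count(simple_spec(), "nope")


class TestSliceCounts:
    def test_zero_profile_distributes_c_uniformly(self, constants, geometry):
        spec = simple_spec(100.0, 100.0, volume=50.0)
        c = formulation_count(spec, "pe")
        plan = slice_counts(domain_profile(np.zeros_like), spec, "pe", 20,
                            constants, geometry)
        assert plan.total == pytest.approx(round(c), abs=20 * 0.5)
        counts = [s.count for s in plan.per_slice]
        assert max(counts) - min(counts) <= 1

    def test_single_favorable_slice_closed_form(self, constants, geometry):
        spec = simple_spec(100.0, 100.0, volume=50.0)
        c_slice = formulation_count(spec, "pe") / 20.0
        width = (geometry.z_max - geometry.z_min) / 20.0
        lo = geometry.z_min + 7 * width

        def values(z):
            v = np.full(z.size, 80.0)  # effectively +inf elsewhere
            v[(z >= lo) & (z <= lo + width)] = -constants.rt * math.log(2.0)
            return v

        plan = slice_counts(domain_profile(values), spec, "pe", 20,
                            constants, geometry)
        # interpolation at the slice edges leaks less than one molecule
        assert plan.total == pytest.approx(2.0 * c_slice, abs=1.0)

    def test_uniform_shift_scales_counts_by_exp_beta_c(self, constants, geometry):
        spec = simple_spec(500.0, 100.0, volume=200.0)
        shift = 2.0
        base = domain_profile(lambda z: 5.0 * np.sin(z))
        shifted = base.replace(values=base.values + shift)
        p0 = slice_counts(base, spec, "pe", 20, constants, geometry)
        p1 = slice_counts(shifted, spec, "pe", 20, constants, geometry)
        factor = math.exp(-constants.beta * shift)
        for s0, s1 in zip(p0.per_slice, p1.per_slice):
            assert s1.count == pytest.approx(s0.count * factor, abs=1.0)

    def test_linear_in_concentration(self, constants, geometry):
        base = domain_profile(lambda z: 2.0 * np.cos(z))
        p1 = slice_counts(base, simple_spec(100.0, 100.0, 100.0), "pe", 20,
                          constants, geometry)
        p2 = slice_counts(base, simple_spec(200.0, 100.0, 100.0), "pe", 20,
                          constants, geometry)
        for s1, s2 in zip(p1.per_slice, p2.per_slice):
            assert s2.count == pytest.approx(2 * s1.count, abs=1.0)


class TestHeadgroupCap:
    def test_water_bookkeeping_below_cap(self, constants):
        pmf, spec, geometry, water_mass = make_water_insertion_fixture()
        plan = slice_counts(pmf, spec, "water", 20, constants, geometry)
        assert plan.total == 100
        capped = apply_headgroup_cap(plan, geometry, water_mass, cap_ratio=2.5)
        assert not capped.capped
        assert capped.total == 100
        ratio = capped.metadata["headgroup_mass_ratio"]
        assert ratio == pytest.approx(190.0 / 90.0, rel=1e-9)
        assert ratio < 2.5

    def test_overfull_headgroup_scaled_down(self, constants):
        pmf, spec, geometry, water_mass = make_water_insertion_fixture()
        plan = slice_counts(pmf, spec, "water", 20, constants, geometry)
        big = scale_plan(plan, 10.0)  # 1000 planned waters
        capped = apply_headgroup_cap(big, geometry, water_mass, cap_ratio=2.5)
        assert capped.capped
        limit = (2.5 - 1.0) * water_mass
        assert capped.mass("headgroup", geometry) <= limit
        # floor-rounded proportional scaling: as close to the cap as integers allow
        assert capped.mass("headgroup", geometry) >= limit - capped.molar_mass

    def test_cap_is_idempotent(self, constants):
        pmf, spec, geometry, water_mass = make_water_insertion_fixture()
        big = scale_plan(slice_counts(pmf, spec, "water", 20, constants, geometry), 5.0)
        once = apply_headgroup_cap(big, geometry, water_mass)
        twice = apply_headgroup_cap(once, geometry, water_mass)
        assert [s.count for s in once.per_slice] == [s.count for s in twice.per_slice]

    def test_tail_slices_never_modified(self, constants, geometry):
        spec = simple_spec(3000.0, 100.0, volume=500.0)
        base = domain_profile(lambda z: np.where(
            (z > 1.0) & (z < 1.4), -6.0, np.where(np.abs(z - 3.2) < 0.2, -6.0, 40.0)))
        plan = slice_counts(base, spec, "pe", 20, Constants(), geometry)
        tail_before = [s.count for s in plan.per_slice
                       if geometry.classify(s.center) != "headgroup"]
        capped = apply_headgroup_cap(plan, geometry, water_mass_present=18.015)
        tail_after = [s.count for s in capped.per_slice
                      if geometry.classify(s.center) != "headgroup"]
        assert capped.capped
        assert tail_before == tail_after


class TestScaleAndPlace:
    def test_stepwise_escalation_series(self, constants):
        pmf, spec, geometry, _ = make_water_insertion_fixture(inserted_target=16)
        plan16 = slice_counts(pmf, spec, "water", 20, constants, geometry)
        assert plan16.total == 16
        assert scale_plan(plan16, 1.5).total == 24
        pmf18 = make_water_insertion_fixture(inserted_target=18)[0]
        plan18 = slice_counts(pmf18, spec, "water", 20, constants, geometry)
        assert plan18.total == 18
        assert scale_plan(plan18, 2.0).total == 36
        assert scale_plan(plan18, 3.0).total == 54

    def test_scale_factor_one_is_identity(self, constants):
        pmf, spec, geometry, _ = make_water_insertion_fixture()
        plan = slice_counts(pmf, spec, "water", 20, constants, geometry)
        assert [s.count for s in scale_plan(plan, 1.0).per_slice] == \
            [s.count for s in plan.per_slice]

    def test_placement_deterministic_and_bounded(self, constants):
        pmf, spec, geometry, _ = make_water_insertion_fixture()
        plan = slice_counts(pmf, spec, "water", 20, constants, geometry)
        a = place_molecules(plan, (5.5, 6.0), seed=7)
        b = place_molecules(plan, (5.5, 6.0), seed=7)
        c = place_molecules(plan, (5.5, 6.0), seed=8)
        assert a.lateral_positions == b.lateral_positions
        assert a.lateral_positions != c.lateral_positions
        assert len(a.lateral_positions) == plan.total
        for x, y, z in a.lateral_positions:
            assert 0 <= x < 5.5 and 0 <= y < 6.0
            assert geometry.z_min <= z <= geometry.z_max

    def test_empty_plan_gives_no_positions(self, constants, geometry):
        spec = simple_spec(0.0, 100.0, volume=100.0)
        plan = slice_counts(domain_profile(np.zeros_like), spec, "pe", 20,
                            constants, geometry)
        placed = place_molecules(plan, (5.0, 5.0), seed=1)
        assert plan.total == 0 and placed.lateral_positions == []
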
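"""Domination sub-maps, TUD factors, safety scaling, quantization, plans."""

import numpy as np
import pytest

import ipdtplan as ip
from ipdtplan.optimize import (
    SafetyLimits,
    audit_plan,
    domination_submaps,
    fluence_safe_scale,
    irradiance_safe_scale,
    optimize_plan,
    parametric_sweep,
    quantize_and_cap,
    treatment_times,
    tud_factors,
)

from conftest import synthetic_maps, tumor_cs_box

LIMITS = SafetyLimits()


@pytest.fixture()
def scene():
    return tumor_cs_box()


def field_like(scene, node_values_fn):
    return node_values_fn(scene.nodes)


class TestDominationSubmaps:
    def test_three_node_example(self, scene):
        """Per-node: A=[5,2,9], B=[3,4,9] -> A keeps 5, B keeps 4, tie zeroed."""
        a = np.zeros(scene.n_nodes)
        b = np.zeros(scene.n_nodes)
        a[:3] = [5.0, 2.0, 9.0]
        b[:3] = [3.0, 4.0, 9.0]
        maps = synthetic_maps(scene, [a, b])
        subs = domination_submaps(maps)
        assert subs[0].masked_field[:3].tolist() == [5.0, 0.0, 0.0]
        assert subs[1].masked_field[:3].tolist() == [0.0, 4.0, 0.0]

    def test_tie_assigned_to_lowest_id_when_configured(self, scene):
        a = np.full(scene.n_nodes, 7.0)
        b = np.full(scene.n_nodes, 7.0)
        maps = synthetic_maps(scene, [a, b])
        subs = domination_submaps(maps, assign_ties_to_lowest=True)
        assert np.allclose(subs[0].masked_field, 7.0)
        assert np.allclose(subs[1].masked_field, 0.0)

    def test_single_fiber_keeps_whole_field(self, scene):
        f = np.abs(np.sin(np.arange(scene.n_nodes)))
        maps = synthetic_maps(scene, [f])
        subs = domination_submaps(maps)
        assert np.allclose(subs[0].masked_field, f)

    def test_partition_property_bruteforce(self, scene):
        """At most one nonzero sub-map per node; nonzero value equals that
        fiber's irradiance and strictly exceeds all others (brute force)."""
        rng = np.random.default_rng(17)
        phi = rng.integers(0, 8, (4, scene.n_nodes)).astype(float)  # many ties
        maps = synthetic_maps(scene, phi)
        subs = domination_submaps(maps)
        stacked = np.array([s.masked_field for s in subs])
        assert np.all((stacked > 0).sum(axis=0) <= 1)
        for node in range(scene.n_nodes):
            for k in range(4):
                others = np.delete(phi[:, node], k)
                if stacked[k, node] > 0:
                    assert stacked[k, node] == phi[k, node]
                    assert phi[k, node] > others.max()
                elif phi[k, node] > others.max():
                    assert stacked[k, node] == phi[k, node]
        # sum of sub-maps never exceeds the node-wise max
        assert np.all(stacked.sum(axis=0) <= phi.max(axis=0) + 1e-12)

    def test_empty_maps_rejected(self, scene):
        maps = synthetic_maps(scene, [np.zeros(scene.n_nodes)])
        maps.cdfs = []
        maps.unit_fields = maps.unit_fields[:0]
        maps.reference_intensities = maps.reference_intensities[:0]
        maps.intensities = maps.intensities[:0]
        maps.times = maps.times[:0]
        with pytest.raises(ValueError):
            domination_submaps(maps)


class TestTUDFactors:
    def _maps_with_cs_peak(self, scene, peaks):
        cs = scene.region_node_indices("critical_structure")
        fields = []
        for p in peaks:
            f = np.zeros(scene.n_nodes)
            f[cs[0]] = p  # single dominating hot node per fiber
            fields.append(f)
        return synthetic_maps(scene, fields)

    def test_ratio_examples(self, scene):
        maps = self._maps_with_cs_peak(scene, [4.3])
        subs = domination_submaps(maps)
        assert tud_factors(subs, maps, LIMITS)[0] == pytest.approx(2.0)
        maps = self._maps_with_cs_peak(scene, [17.2])
        subs = domination_submaps(maps)
        assert tud_factors(subs, maps, LIMITS)[0] == pytest.approx(0.5)

    def test_matches_direct_division(self, scene):
        rng = np.random.default_rng(23)
        maps = synthetic_maps(scene, rng.uniform(0, 20, (3, scene.n_nodes)))
        subs = domination_submaps(maps)
        cs = scene.region_node_indices("critical_structure")
        factors = tud_factors(subs, maps, LIMITS)
        for k in range(3):
            peak = subs[k].masked_field[cs].max()
            expected = 8.6 / peak if peak > 0 else np.inf
            assert factors[k] == pytest.approx(expected)

    def test_empty_cs_gives_infinite_sentinel(self):
        from conftest import make_box_scene

        sc = make_box_scene(region_fn=lambda c: np.where(c[:, 0] < 1, 1, 3))
        maps = synthetic_maps(sc, [np.ones(sc.n_nodes)])
        subs = domination_submaps(maps)
        assert np.isinf(tud_factors(subs, maps, LIMITS)[0])


class TestIrradianceSafeScale:
    def test_single_offender_scaled_to_exact_equality(self, scene):
        cs = scene.region_node_indices("critical_structure")
        hot = np.zeros(scene.n_nodes)
        hot[cs[0]] = 17.2
        cold = np.zeros(scene.n_nodes)
        cold[cs[-1]] = 1.0
        maps = synthetic_maps(scene, [hot, cold])
        out, _ = irradiance_safe_scale(maps, LIMITS)
        phi = out.current_fields()
        assert phi[0, cs[0]] == pytest.approx(8.6)  # scaled by exactly 0.5
        assert out.intensities[0] == pytest.approx(50.0)

    def test_safe_fibers_scale_up_but_stay_safe(self, scene):
        cs = scene.region_node_indices("critical_structure")
        f = np.zeros(scene.n_nodes)
        f[cs[0]] = 4.3  # factor 2 at intensity 100
        maps = synthetic_maps(scene, [f])
        out, _ = irradiance_safe_scale(maps, LIMITS)
        assert out.intensities[0] > maps.intensities[0]
        assert out.current_fields()[0, cs].max() <= 8.6 + 1e-9

    def test_no_critical_structures_caps_intensities(self):
        from conftest import make_box_scene

        sc = make_box_scene(region_fn=lambda c: np.where(c[:, 0] < 1, 1, 3))
        maps = synthetic_maps(sc, [np.ones(sc.n_nodes)])
        out, log = irradiance_safe_scale(maps, LIMITS)
        assert np.allclose(out.intensities, 400.0)


class TestFluenceSafeScale:
    def test_single_dominant_fiber_halved(self, scene):
        cs = scene.region_node_indices("critical_structure")
        f = np.zeros(scene.n_nodes)
        f[cs[0]] = 38.0  # 38 mW/cm^2 x 500 s = 19 J/cm^2
        maps = synthetic_maps(scene, [f], times=[500.0])
        out, _ = fluence_safe_scale(maps, LIMITS)
        flu = (out.current_fields() * out.times[:, None]).sum(axis=0) / 1000.0
        assert flu[cs].max() == pytest.approx(9.5)
        assert out.intensities[0] == pytest.approx(50.0)

    def test_already_safe_unchanged(self, scene):
        maps = synthetic_maps(scene, [np.full(scene.n_nodes, 5.0)], times=[500.0])
        out, _ = fluence_safe_scale(maps, LIMITS)  # 2.5 J/cm^2 everywhere
        assert np.allclose(out.intensities, maps.intensities)

    def test_two_equal_contributors_scaled_equally(self, scene):
        cs = scene.region_node_indices("critical_structure")
        f = np.zeros(scene.n_nodes)
        f[cs[0]] = 19.0
        maps = synthetic_maps(scene, [f, f.copy()], times=[500.0, 500.0])
        out, _ = fluence_safe_scale(maps, LIMITS)
        flu = (out.current_fields() * out.times[:, None]).sum(axis=0) / 1000.0
        assert flu[cs].max() <= 9.5 + 1e-9
        assert out.intensities[0] == pytest.approx(out.intensities[1], rel=1e-9)
        # brute-force check: the common factor solves 2 f T c = 9.5 exactly
        assert flu[cs].max() == pytest.approx(9.5)


class TestQuantizeAndCap:
    def test_floor_to_grid(self):
        assert quantize_and_cap([437.0], [1.5], LIMITS)[0] == 420.0

    def test_cap_binds_on_grid(self):
        assert quantize_and_cap([650.0], [1.5], LIMITS)[0] == 600.0

    def test_zero_passthrough(self):
        assert quantize_and_cap([0.0], [1.5], LIMITS)[0] == 0.0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            quantize_and_cap([-1.0], [1.5], LIMITS)

    def test_never_rounds_up(self):
        rng = np.random.default_rng(31)
        powers = rng.uniform(0, 800, 100)
        q = quantize_and_cap(powers, np.full(100, 1.5), LIMITS)
        assert np.all(q <= powers + 1e-9)
        assert np.allclose(q % 20.0, 0.0)


class TestTreatmentTimes:
    def test_unit_arithmetic(self):
        cdf = ip.CDFPlacement((0, 0, 0), (0, 0, 1.0), 2.0, 0.098)
        t = treatment_times([200.0], [100.0], [cdf])
        assert t[0] == pytest.approx(100.0 * cdf.surface_area / 0.2)

    def test_doubling_power_halves_time(self):
        cdf = ip.CDFPlacement((0, 0, 0), (0, 0, 1.0), 2.0, 0.098)
        t1 = treatment_times([200.0], [100.0], [cdf])
        t2 = treatment_times([400.0], [100.0], [cdf])
        assert t1[0] == pytest.approx(2 * t2[0])

    def test_zero_fluence_zero_time(self):
        cdf = ip.CDFPlacement((0, 0, 0), (0, 0, 1.0), 2.0, 0.098)
        assert treatment_times([200.0], [0.0], [cdf])[0] == 0.0

    def test_zero_power_with_fluence_rejected(self):
        cdf = ip.CDFPlacement((0, 0, 0), (0, 0, 1.0), 2.0, 0.098)
        with pytest.raises(ValueError):
            treatment_times([0.0], [10.0], [cdf])


class TestOptimizePlan:
    def _toy_maps(self, scene):
        cs = scene.region_node_indices("critical_structure")
        tumor = scene.region_node_indices("tumor")
        f1 = np.zeros(scene.n_nodes)
        f1[tumor] = 30.0
        f1[cs] = 6.0
        f2 = np.zeros(scene.n_nodes)
        f2[tumor] = 12.0
        f2[cs[: len(cs) // 2]] = 11.0
        return synthetic_maps(scene, [f1, f2], times=[500.0, 500.0])

    def test_plan_is_safe_and_quantized(self, scene):
        maps = self._toy_maps(scene)
        plan = optimize_plan(maps, LIMITS)
        assert np.allclose(plan.powers_mw % 20.0, 0.0)
        assert np.all(plan.intensities_mw_per_cm <= 400.0 + 1e-9)
        assert plan.safety["irradiance_safe"] and plan.safety["fluence_safe"]

    def test_plan_deterministic(self, scene):
        maps = self._toy_maps(scene)
        p1 = optimize_plan(maps, LIMITS)
        p2 = optimize_plan(maps, LIMITS)
        assert p1.to_dict() == p2.to_dict()

    def test_no_critical_structures_hits_cap_and_improves_dose(self):
        from conftest import make_box_scene
        from ipdtplan.dose import dose_report

        sc = make_box_scene(region_fn=lambda c: np.where(c[:, 0] < 1, 1, 3))
        tumor = sc.region_node_indices("tumor")
        f = np.zeros(sc.n_nodes)
        f[tumor] = 5.0  # at 100 mW/cm: subtherapeutic; cap x4 fixes it
        maps = synthetic_maps(sc, [f], times=[9000.0])
        plan = optimize_plan(maps, LIMITS)
        assert np.allclose(plan.intensities_mw_per_cm, 400.0)
        initial = dose_report(
            maps.with_intensities([LIMITS.intensity_min]), LIMITS.effective_irradiance
        )
        assert plan.dose.effective_dose_dvh >= initial.effective_dose_dvh

    def test_fiber_far_from_cs_reaches_cap_exactly(self, scene):
        # strictly interior tumor nodes (interface nodes are shared with
        # the critical-structure region): zero at CS -> TUD sentinel
        f = np.where(scene.nodes[:, 0] < 0.9, 10.0, 0.0)
        maps = synthetic_maps(scene, [f], times=[500.0])
        plan = optimize_plan(maps, LIMITS)
        assert plan.intensities_mw_per_cm[0] == pytest.approx(400.0)

    def test_unsafe_plan_never_emitted(self, scene):
        maps = self._toy_maps(scene)
        plan = optimize_plan(maps, LIMITS)
        final = maps.with_intensities(plan.intensities_mw_per_cm).with_times(plan.times_s)
        audit = audit_plan(final, LIMITS)
        assert audit["irradiance_safe"] and audit["fluence_safe"]

    def test_times_compensate_quantization(self, scene):
        """Surface fluence (power x time / area) is preserved through the
        20 mW floor: quantizing power down lengthens the exposure."""
        maps = self._toy_maps(scene)
        plan = optimize_plan(maps, LIMITS)
        for k in range(2):
            if plan.powers_mw[k] > 0:
                assert plan.times_s[k] >= 500.0 - 1e-9


class TestParametricSweep:
    def test_seventeen_rows_and_grid(self, scene):
        maps = synthetic_maps(scene, [np.ones(scene.n_nodes)], times=[500.0])
        table = parametric_sweep(maps, 0, LIMITS)
        assert len(table) == 17
        assert table["intensity_mW_per_cm"].tolist() == list(range(80, 401, 20))

    def test_cs_maximum_scales_linearly(self, scene):
        cs = scene.region_node_indices("critical_structure")
        f = np.zeros(scene.n_nodes)
        f[cs[0]] = 3.0
        maps = synthetic_maps(scene, [f], times=[500.0])
        table = parametric_sweep(maps, 0, LIMITS)
        irr = table["cs_max_irradiance_mW_cm2"].to_numpy()
        s = table["intensity_mW_per_cm"].to_numpy()
        assert np.allclose(irr, 3.0 * s / 100.0, rtol=1e-12)

    def test_drvh_nondecreasing_in_intensity(self, scene):
        rng = np.random.default_rng(41)
        maps = synthetic_maps(scene, [rng.uniform(0, 15, scene.n_nodes)], times=[500.0])
        table = parametric_sweep(maps, 0, LIMITS)
        assert np.all(np.diff(table["tumor_drvh_percent"].to_numpy()) >= -1e-12)
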
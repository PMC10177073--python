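"""FEM assembly, steady/transient solves, analytic oracle, probing."""

import numpy as np
import pytest
from scipy.special import k0

import ipdtplan as ip
from ipdtplan.fem import (
    SourceSpec,
    TransientSettings,
    flux_balance,
    mesh_convergence_study,
    solve_transient,
)
from ipdtplan.geometry import Scene

from conftest import PHANTOM_PROPS, make_box_scene


def single_tet_scene() -> Scene:
    """Reference tetrahedron (0, e1, e2, e3) with all-outer boundary."""
    nodes = np.array([[0.0, 0, 0], [1.0, 0, 0], [0, 1.0, 0], [0, 0, 1.0]])
    tets = np.array([[0, 1, 2, 3]])
    facets = np.array([[0, 1, 2], [0, 1, 3], [0, 2, 3], [1, 2, 3]])
    return Scene(
        nodes=nodes,
        tets=tets,
        tet_region=np.array([3]),
        region_names={3: "normal_tissue"},
        facets=facets,
        facet_tag=np.ones(4, dtype=np.int64),
        surface_names={1: "outer"},
    )


class TestAssembly:
    def test_single_tet_matches_hand_integrals(self):
        """P1 operators on the reference tet against closed-form integrals."""
        scene = single_tet_scene()
        props = {"normal_tissue": ip.TUMOR_TISSUE}
        sys_ = ip.assemble_system(scene, props)
        p = props["normal_tissue"]
        vol = 1.0 / 6.0
        # grad(lambda) = [(-1,-1,-1), e1, e2, e3] -> K_ij = alpha V g_i.g_j
        g = np.array([[-1.0, -1, -1], [1, 0, 0], [0, 1, 0], [0, 0, 1]])
        k_exact = p.alpha_n * vol * (g @ g.T)
        assert np.allclose(sys_.stiffness.toarray(), k_exact, rtol=1e-12)
        m_exact = vol / 20.0 * (np.ones((4, 4)) + np.eye(4))
        assert np.allclose(sys_.mass.toarray(), m_exact, rtol=1e-12)
        assert np.allclose(
            sys_.absorption.toarray(), p.c_n * p.mu_a * m_exact, rtol=1e-12
        )
        # Robin: triangle mass A/12 (1 + I) per outer facet, c_n weighted
        areas = scene.facet_areas()
        s_exact = np.zeros((4, 4))
        pat = (np.ones((3, 3)) + np.eye(3)) / 12.0
        for f, a in zip(scene.facets, areas):
            s_exact[np.ix_(f, f)] += p.c_n * a * pat
        assert np.allclose(sys_.robin.toarray(), s_exact, rtol=1e-12)

    def test_zero_absorption_zeroes_operator(self):
        scene = single_tet_scene()
        props = {"normal_tissue": ip.OpticalProperties.from_reduced(0.0, 5.0)}
        sys_ = ip.assemble_system(scene, props)
        assert np.allclose(sys_.absorption.toarray(), 0.0)

    def test_two_region_stiffness_is_sum_of_parts(self):
        scene = make_box_scene(n=(2, 1, 1), region_fn=lambda c: np.where(c[:, 0] < 1, 1, 2))
        pa = ip.TUMOR_TISSUE
        pb = ip.BLOOD
        full = ip.assemble_system(scene, {"tumor": pa, "critical_structure": pb})
        # independent brute-force assembly, element by element
        n = scene.n_nodes
        k_ref = np.zeros((n, n))
        for tet, tag in zip(scene.tets, scene.tet_region):
            x = scene.nodes[tet]
            e = x[1:] - x[0]
            vol = np.linalg.det(e) / 6.0
            gr = np.zeros((4, 3))
            gr[1:] = np.linalg.inv(e).T
            gr[0] = -gr[1:].sum(axis=0)
            alpha = (pa if tag == 1 else pb).alpha_n
            k_ref[np.ix_(tet, tet)] += alpha * vol * (gr @ gr.T)
        assert np.allclose(full.stiffness.toarray(), k_ref, rtol=1e-10)

    def test_operators_symmetric_psd(self, coarse_phantom_solution):
        sys_, _ = coarse_phantom_solution
        for op in (sys_.stiffness, sys_.absorption, sys_.robin, sys_.mass):
            d = op - op.T
            assert abs(d).max() < 1e-6 * max(abs(op).max(), 1.0)
        # PSD via Rayleigh quotients on random vectors
        rng = np.random.default_rng(0)
        v = rng.standard_normal((sys_.scene.n_nodes, 8))
        for op in (sys_.stiffness, sys_.absorption, sys_.robin):
            q = np.einsum("nk,nk->k", v, op @ v)
            assert np.all(q > -1e-8 * np.abs(q).max())

    def test_missing_region_property_named(self):
        scene = single_tet_scene()
        with pytest.raises(KeyError, match="normal_tissue"):
            ip.assemble_system(scene, {"tumor": ip.TUMOR_TISSUE})


class TestSteadySolve:
    def test_zero_sources_gives_zero_field(self, coarse_phantom_solution):
        sys_, _ = coarse_phantom_solution
        fld = ip.solve_steady(sys_, [SourceSpec("diffuser_0", 0.0)])
        assert np.allclose(fld.values, 0.0)

    def test_dirichlet_attained_exactly(self, coarse_phantom_solution):
        sys_, fld = coarse_phantom_solution
        nodes = sys_.dirichlet_nodes["diffuser_0"]
        p_laser = sys_.scene.cdfs[0].p_laser
        assert np.allclose(fld.values[nodes], p_laser, rtol=0, atol=0)

    def test_residual_small(self, coarse_phantom_solution):
        _, fld = coarse_phantom_solution
        assert fld.meta["residual"] <= 1e-10

    def test_linearity_in_p_laser(self, coarse_phantom_solution):
        sys_, fld = coarse_phantom_solution
        p = sys_.scene.cdfs[0].p_laser
        double = ip.solve_steady(sys_, [SourceSpec("diffuser_0", 2 * p)])
        denom = np.maximum(np.abs(fld.values), 1e-30)
        nz = np.abs(fld.values) > 1e-12 * p
        assert np.max(np.abs(double.values - 2 * fld.values)[nz] / denom[nz]) < 1e-10

    def test_field_bounded_by_source(self, coarse_phantom_solution, small_phantom_solution):
        sys_, fld = coarse_phantom_solution
        p = sys_.scene.cdfs[0].p_laser
        assert fld.values.max() <= p * (1 + 1e-12)
        # discrete maximum-principle slack on graded anisotropic meshes;
        # the undershoot is small relative to the source and shrinks under
        # refinement (it sits where the field is ~1e-4 of the source value)
        assert fld.values.min() >= -1e-3 * p
        _, fine = small_phantom_solution
        assert fine.values.min() > fld.values.min()

    def test_steady_invariant_to_refractive_index(self, coarse_phantom):
        """c_n cancels at steady state for a uniform-index domain."""
        f1 = ip.solve_steady(
            ip.assemble_system(
                coarse_phantom,
                {"phantom": ip.OpticalProperties.from_reduced(0.224, 4.99, 1.0)},
            ),
            ip.sources_from_cdfs(coarse_phantom),
        )
        f2 = ip.solve_steady(
            ip.assemble_system(
                coarse_phantom,
                {"phantom": ip.OpticalProperties.from_reduced(0.224, 4.99, 1.52)},
            ),
            ip.sources_from_cdfs(coarse_phantom),
        )
        assert np.allclose(f1.values, f2.values, rtol=1e-9, atol=1e-9)

    def test_singular_system_rejected(self):
        scene = single_tet_scene()
        scene.surface_names = {1: "shaft_0"}  # no outer boundary, no diffuser
        props = {"normal_tissue": ip.OpticalProperties.from_reduced(0.0, 5.0)}
        sys_ = ip.assemble_system(scene, props)
        with pytest.raises(ValueError, match="singular"):
            ip.solve_steady(sys_, [])

    def test_unknown_source_surface_rejected(self, coarse_phantom_solution):
        sys_, _ = coarse_phantom_solution
        with pytest.raises(KeyError, match="diffuser_9"):
            ip.solve_steady(sys_, [SourceSpec("diffuser_9", 100.0)])

    def test_flux_balance_identity(self, coarse_phantom_solution):
        sys_, fld = coarse_phantom_solution
        bal = flux_balance(sys_, fld, ip.sources_from_cdfs(sys_.scene))
        assert bal["relative_imbalance"] < 1e-8
        assert bal["absorbed"] > 0 and bal["source_inflow"] > 0


class TestSuperposition:
    def test_two_fiber_field_is_sum_of_single_fiber_fields(self, tiny_airway_maps):
        maps = tiny_airway_maps
        scene = maps.scene
        sys_ = ip.assemble_system(scene, ip.DEFAULT_PROPERTIES)
        both = ip.solve_steady(
            sys_,
            [
                SourceSpec("diffuser_0", scene.cdfs[0].p_laser),
                SourceSpec("diffuser_1", scene.cdfs[1].p_laser),
            ],
        )
        total = maps.unit_fields.sum(axis=0)
        denom = np.maximum(np.abs(both.values), 1e-12 * both.values.max())
        assert np.max(np.abs(both.values - total) / denom) < 1e-10


class TestAnalyticCylinder:
    def test_boundary_value(self):
        assert ip.analytic_infinite_cylinder(ip.PHANTOM, 0.049, 317.0, 0.049) == (
            pytest.approx(317.0)
        )

    def test_bessel_ratio_value(self):
        val = ip.analytic_infinite_cylinder(ip.PHANTOM, 0.049, 1.0, 0.5)
        mu = ip.PHANTOM.mu_eff
        assert val == pytest.approx(k0(mu * 0.5) / k0(mu * 0.049), rel=1e-12)

    def test_strictly_decreasing(self):
        v = ip.analytic_infinite_cylinder(ip.PHANTOM, 0.049, 1.0, np.linspace(0.05, 2, 40))
        assert np.all(np.diff(v) < 0)

    def test_inside_fiber_rejected(self):
        with pytest.raises(ValueError):
            ip.analytic_infinite_cylinder(ip.PHANTOM, 0.049, 1.0, 0.01)


class TestProbeField:
    def test_probe_at_node_exact(self, coarse_phantom_solution):
        _, fld = coarse_phantom_solution
        scene = fld.scene
        i = scene.n_nodes // 3
        assert ip.probe_field(fld, scene.nodes[i])[0] == pytest.approx(
            fld.values[i], rel=1e-9
        )

    def test_probe_at_centroid_is_nodal_mean(self, coarse_phantom_solution):
        _, fld = coarse_phantom_solution
        scene = fld.scene
        tet = scene.tets[scene.n_tets // 2]
        c = scene.nodes[tet].mean(axis=0)
        assert ip.probe_field(fld, c)[0] == pytest.approx(
            fld.values[tet].mean(), rel=1e-9
        )

    def test_constant_field_reproduced(self, coarse_phantom):
        fld = ip.ScalarField(coarse_phantom, np.full(coarse_phantom.n_nodes, 7.5))
        pts = np.array([[0.3, 0.2, 0.1], [2.0, -1.0, 3.0], [-4.0, 4.0, -4.0]])
        assert np.allclose(ip.probe_field(fld, pts), 7.5, rtol=1e-12)

    def test_outside_point_rejected(self, coarse_phantom):
        fld = ip.ScalarField(coarse_phantom, np.zeros(coarse_phantom.n_nodes))
        with pytest.raises(ValueError, match="outside"):
            ip.probe_field(fld, [[50.0, 0.0, 0.0]])


class TestTransient:
    def test_zero_dynamics(self, coarse_phantom_solution):
        sys_, _ = coarse_phantom_solution
        res = solve_transient(
            sys_,
            [SourceSpec("diffuser_0", 0.0)],
            TransientSettings(dt=1e-10, t_end=5e-10, p_bg=0.0),
        )
        assert np.allclose(res.frames, 0.0)

    def test_initial_frame_is_background(self, coarse_phantom_solution):
        sys_, _ = coarse_phantom_solution
        src = ip.sources_from_cdfs(sys_.scene)
        res = solve_transient(sys_, src, TransientSettings(dt=1e-10, t_end=3e-10, p_bg=2.5))
        fixed = sys_.all_dirichlet
        free = np.setdiff1d(np.arange(sys_.scene.n_nodes), fixed)
        assert np.allclose(res.frames[0][free], 2.5)
        assert np.allclose(res.frames[0][fixed], sys_.scene.cdfs[0].p_laser)

    def test_final_frame_reaches_steady_state(self, coarse_phantom_solution):
        """t_end >> 1/(c_n mu_a) (~0.2 ns here) drives the transient to the
        steady solution."""
        sys_, steady = coarse_phantom_solution
        src = ip.sources_from_cdfs(sys_.scene)
        res = solve_transient(
            sys_, src, TransientSettings(dt=5e-10, t_end=4e-8, p_bg=0.0)
        )
        num = np.linalg.norm(res.frames[-1] - steady.values)
        assert num / np.linalg.norm(steady.values) < 1e-6

    def test_first_order_dt_convergence(self, coarse_phantom_solution):
        sys_, steady = coarse_phantom_solution
        src = ip.sources_from_cdfs(sys_.scene)
        t_end = 8e-10
        frames = {}
        for dt in (2e-10, 1e-10, 5e-11):
            frames[dt] = solve_transient(
                sys_, src, TransientSettings(dt=dt, t_end=t_end)
            ).frames[-1]
        e1 = np.linalg.norm(frames[2e-10] - frames[5e-11])
        e2 = np.linalg.norm(frames[1e-10] - frames[5e-11])
        assert e2 < e1  # halving dt shrinks the change: first-order stepping

    def test_invalid_dt_rejected(self):
        with pytest.raises(ValueError):
            TransientSettings(dt=0.0, t_end=1.0)


class TestConvergenceStudy:
    def test_probed_change_shrinks(self):
        df = mesh_convergence_study(
            lambda h: ip.make_phantom_scene(target_h=h),
            levels=3,
            properties=PHANTOM_PROPS,
            coarsest_h=1.6,
            refine_ratio=1.4,
        )
        changes = df["successive_rel_change"].to_numpy()
        assert np.isnan(changes[0])
        assert changes[2] < changes[1]
        assert df["n_tets"].is_monotonic_increasing

    def test_single_level_rejected(self):
        with pytest.raises(ValueError):
            mesh_convergence_study(
                lambda h: ip.make_phantom_scene(target_h=h),
                levels=1,
                properties=PHANTOM_PROPS,
                coarsest_h=2.0,
            )

    def test_identical_levels_zero_change(self, coarse_phantom):
        df = mesh_convergence_study(
            lambda h: coarse_phantom,
            levels=2,
            properties=PHANTOM_PROPS,
            coarsest_h=1.47,
            refine_ratio=1.0,
        )
        assert df["successive_rel_change"].iloc[1] == pytest.approx(0.0, abs=1e-12)
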
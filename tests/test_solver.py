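"""Meshing, assembly and harmonic solves on small problems.

The expensive analytic-oracle comparisons (monopole, two-shell, bipole,
refinement studies) live in the acceptance suite; here the solver contracts
are exercised on meshes small enough for exact direct solves.
"""

import numpy as np
import pytest

from dbsfem import phantom as ph
from dbsfem.dielectrics import DispersiveMedium
from dbsfem.electrodes import make_design, place
from dbsfem.phantom import GM, WM, ELECTRODE_INS, ELECTRODE_METAL
from dbsfem.solver import (CORE_CONTACT, OUTER_CONTACT, INSULATED,
                           graded_axis, make_box_mesh, mesh_domain,
                           solve_harmonic, scale_to_current, contact_current)


def small_bipolar_mesh(n=9, sigma=0.25):
    ax = np.linspace(-0.5, 0.5, n)
    mesh = make_box_mesh(ax, ax, ax, label=GM,
                         core_pred=lambda p: np.linalg.norm(
                             p - [0, 0, -0.3], axis=1) <= 0.14,
                         outer_pred=lambda p: np.linalg.norm(
                             p - [0, 0, 0.3], axis=1) <= 0.14)
    media = {GM: DispersiveMedium.constant(GM, sigma)}
    return mesh, media


class TestGradedAxis:
    def test_covers_interval_and_honours_fine_spacing(self):
        ax = graded_axis(-2.0, 2.0, [(-0.3, 0.3, 0.05)], 0.4, growth=1.3)
        assert ax[0] == -2.0 and ax[-1] == pytest.approx(2.0)
        d = np.diff(ax)
        assert (d > 0).all()
        inside = (ax[:-1] >= -0.3) & (ax[1:] <= 0.3)
        assert d[inside].max() <= 0.05 + 1e-12
        assert d.max() <= 0.4 + 1e-12

    def test_growth_bounded(self):
        ax = graded_axis(-2.0, 2.0, [(-0.2, 0.2, 0.04)], 0.5, growth=1.35)
        d = np.diff(ax)
        ratios = d[1:] / d[:-1]
        assert ratios.max() < 1.6          # bounded cell-size jumps


@pytest.fixture(scope="module")
def meshed(tiny_phantom_aniso):
    # ring moved down so it stays inside the small test phantom
    d = make_design("BLUNT", outer_contact_offset=1.2,
                    outer_contact_length=0.4)
    pl = place(d, tiny_phantom_aniso, "STN")
    return mesh_domain(tiny_phantom_aniso, d, pl), d, pl


class TestMeshDomain:
    def test_contact_sets_nonempty_disjoint(self, meshed):
        mesh, _, _ = meshed
        core = mesh.node_sets[CORE_CONTACT]
        outer = mesh.node_sets[OUTER_CONTACT]
        assert len(core) > 0 and len(outer) > 0
        assert np.intersect1d(core, outer).size == 0

    def test_every_element_labelled_once(self, meshed):
        mesh, _, _ = meshed
        assert np.isin(mesh.elem_label,
                       [ph.CSF, GM, WM, ph.ENCAP,
                        ELECTRODE_INS, ELECTRODE_METAL]).all()

    def test_encap_elements_present_around_shaft(self, tiny_phantom):
        from dbsfem.phantom import carve_encapsulation
        from dbsfem.electrodes import shaft_track
        d = make_design("BLUNT", outer_contact_offset=1.2,
                        outer_contact_length=0.4)
        pl = place(d, tiny_phantom, "STN")
        carved = carve_encapsulation(tiny_phantom,
                                     shaft_track(d, pl, tiny_phantom))
        mesh = mesh_domain(carved, d, pl)
        assert (mesh.elem_label == ph.ENCAP).sum() > 0

    def test_resolution_control_halves_edge_length(self, tiny_phantom_aniso):
        d = make_design("BLUNT", outer_contact_offset=1.2,
                        outer_contact_length=0.4)
        pl = place(d, tiny_phantom_aniso, "STN")
        m1 = mesh_domain(tiny_phantom_aniso, d, pl, resolution_control=1.0)
        m2 = mesh_domain(tiny_phantom_aniso, d, pl, resolution_control=2.0)
        assert np.diff(m2.zs).min() == pytest.approx(
            np.diff(m1.zs).min() / 2, rel=1e-9)

    def test_wm_elements_carry_anisotropy(self, meshed):
        mesh, _, _ = meshed
        assert mesh.elem_tensor_idx.size > 0
        assert (mesh.elem_label.ravel()[mesh.elem_tensor_idx] == WM).all()
        dets = np.linalg.det(mesh.elem_tensors)
        assert np.max(np.abs(dets - 1.0)) < 1e-9

    def test_label_histogram_matches_phantom_fractions(self, tiny_phantom):
        """On a uniform-resolution grid the element label fractions match the
        phantom's voxel label fractions within 5% (electrode cells aside)."""
        from dbsfem.solver import _embed
        d = make_design("BLUNT", outer_contact_offset=1.2,
                        outer_contact_length=0.4)
        pl = place(d, tiny_phantom, "STN")
        ax = np.arange(-1.5, 1.5 + 1e-9, 0.05)
        mesh = _embed(tiny_phantom, d, pl, ax, ax, ax)
        lab_m = mesh.elem_label.ravel()
        tissue = ~np.isin(lab_m, [ELECTRODE_INS, ELECTRODE_METAL])
        lab_p = tiny_phantom.label_grid.ravel()
        for lab in (ph.CSF, GM, WM):
            f_mesh = (lab_m[tissue] == lab).mean()
            f_ph = (lab_p == lab).mean()
            assert f_mesh == pytest.approx(f_ph, abs=0.05)

    def test_boundary_facets_tagged_exactly_once(self, meshed):
        mesh, _, _ = meshed
        facets = mesh.boundary_facets()
        ne = mesh.shape_elems
        n_ext = 2 * (ne[0] * ne[1] + ne[1] * ne[2] + ne[0] * ne[2])
        counts = {tag: sum(len(f["tissue_elem"]) for f in fs)
                  for tag, fs in facets.items()}
        assert counts[INSULATED] == n_ext
        assert counts[CORE_CONTACT] > 0 and counts[OUTER_CONTACT] > 0
        # contact facet sets are disjoint by construction: a facet pairs one
        # metal element of a single contact with one non-metal element
        core, outer = mesh._metal_masks()
        assert not (core & outer).any()


class TestSolveHarmonic:
    def test_constant_potential_solution(self):
        mesh, media = small_bipolar_mesh()
        sol = solve_harmonic(mesh, media, 0.0, contact_potentials=(0.7, 0.7))
        assert np.allclose(sol.phi, 0.7)
        assert abs(sol.contact_current) < 1e-15

    def test_swapping_contacts_negates_potential(self):
        mesh, media = small_bipolar_mesh()
        s1 = solve_harmonic(mesh, media, 0.0, contact_potentials=(0.5, -0.5))
        s2 = solve_harmonic(mesh, media, 0.0, contact_potentials=(-0.5, 0.5))
        assert np.allclose(s1.phi, -s2.phi, atol=1e-12)

    def test_superposition_of_unit_excitations(self):
        """Solutions for (1,0) and (0,1) contact drives superpose to the
        constant (1,1) case."""
        mesh, media = small_bipolar_mesh()
        s10 = solve_harmonic(mesh, media, 0.0, contact_potentials=(1.0, 0.0))
        s01 = solve_harmonic(mesh, media, 0.0, contact_potentials=(0.0, 1.0))
        assert np.allclose(s10.phi + s01.phi, 1.0, atol=1e-10)

    def test_doubling_potentials_doubles_current(self):
        mesh, media = small_bipolar_mesh()
        s1 = solve_harmonic(mesh, media, 0.0, contact_potentials=(0.5, -0.5))
        s2 = solve_harmonic(mesh, media, 0.0, contact_potentials=(1.0, -1.0))
        assert s2.contact_current == pytest.approx(2 * s1.contact_current,
                                                   rel=1e-12)

    def test_residual_below_tolerance(self):
        mesh, media = small_bipolar_mesh()
        sol = solve_harmonic(mesh, media, 0.0)
        assert sol.residual <= 1e-9

    def test_complex_solve_conjugate_symmetry(self, media):
        mesh, _ = small_bipolar_mesh()
        sol = solve_harmonic(mesh, media, 1e4)
        assert np.iscomplexobj(sol.phi)
        # dissipative medium: currents lead the potential (positive susceptance)
        assert sol.contact_current.imag > 0

    def test_consistent_currents_balance(self, media):
        mesh, _ = small_bipolar_mesh()
        sol = solve_harmonic(mesh, media, 1e3)
        imbalance = abs(sol.contact_current + sol.outer_current) \
            / abs(sol.contact_current)
        assert imbalance < 1e-8

    def test_no_contacts_is_singular(self):
        ax = np.linspace(-0.5, 0.5, 5)
        with pytest.raises(ValueError):
            make_box_mesh(ax, ax, ax, core_nodes=[], outer_nodes=[])

    def test_negative_frequency_rejected(self):
        mesh, media = small_bipolar_mesh()
        with pytest.raises(ValueError):
            solve_harmonic(mesh, media, -10.0)


class TestCurrentControl:
    def test_rescaling_hits_target_current(self):
        mesh, media = small_bipolar_mesh()
        sol = solve_harmonic(mesh, media, 0.0)
        target = 60e-6
        scaled = scale_to_current(sol, target)
        assert abs(scaled.contact_current - target) / target < 1e-12

    def test_scale_factor_recorded(self):
        mesh, media = small_bipolar_mesh()
        sol = solve_harmonic(mesh, media, 0.0)
        scaled = scale_to_current(sol, 2 * sol.contact_current)
        assert scaled.scale_applied == pytest.approx(2.0)
        assert np.allclose(scaled.phi, 2 * sol.phi)

    def test_zero_current_rejected(self):
        mesh, media = small_bipolar_mesh()
        sol = solve_harmonic(mesh, media, 0.0, contact_potentials=(0.3, 0.3))
        with pytest.raises(ValueError, match="zero"):
            scale_to_current(sol, 60e-6)

    def test_surface_current_agrees_with_consistent(self):
        ax = np.linspace(-0.8, 0.8, 25)
        mesh = make_box_mesh(ax, ax, ax, label=GM,
                             core_pred=lambda p: np.linalg.norm(
                                 p - [0, 0, -0.25], axis=1) <= 0.16,
                             outer_pred=lambda p: np.linalg.norm(
                                 p - [0, 0, 0.25], axis=1) <= 0.16)
        media = {GM: DispersiveMedium.constant(GM, 0.25)}
        sol = solve_harmonic(mesh, media, 0.0)
        i_surf = contact_current(sol, mesh, media, CORE_CONTACT, "surface")
        assert i_surf.real == pytest.approx(sol.contact_current.real, rel=0.1)


class TestFieldEvaluation:
    def test_uniform_gradient_recovered(self):
        """A linear potential (uniform field between two plates) is
        reproduced exactly by the element-local gradient."""
        ax = np.linspace(0, 1, 6)
        mesh = make_box_mesh(ax, ax, ax, label=GM,
                             core_pred=lambda p: p[:, 2] < 1e-9,
                             outer_pred=lambda p: p[:, 2] > 1 - 1e-9)
        media = {GM: DispersiveMedium.constant(GM, 0.2)}
        sol = solve_harmonic(mesh, media, 0.0, contact_potentials=(1.0, 0.0))
        pts = np.array([[0.5, 0.5, 0.5], [0.21, 0.77, 0.33]])
        E = sol.field_at(mesh, pts)
        assert np.allclose(E.real, [[0, 0, 1.0]] * 2, atol=1e-9)
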
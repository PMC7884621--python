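"""Phantom construction, encapsulation carving and anisotropy mapping."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dbsfem.phantom import (Ellipsoid, Slab, Track,
                            build_phantom, carve_encapsulation,
                            make_anisotropy, fa_to_eigenvalue_ratio,
                            VoxelTensorField, CSF, GM, WM, ENCAP)


class TestBuildPhantom:
    def test_every_voxel_labelled(self, tiny_phantom):
        assert np.isin(tiny_phantom.label_grid, [CSF, GM, WM, ENCAP]).all()

    def test_masks_carry_gm_or_wm(self, tiny_phantom):
        lab = tiny_phantom.label_grid
        for name in ("STN", "EPN", "THALAMUS"):
            m = tiny_phantom.region_masks[name]
            assert (lab[m] == GM).all(), name
        assert (lab[tiny_phantom.region_masks["IC"]] == WM).all()

    def test_stn_is_oblate(self, tiny_config):
        sx, sy, sz = tiny_config.stn.semi_axes
        assert min(sx, sy) > sz  # lateral extent exceeds dorsoventral

    def test_epn_smaller_lateral_extent_than_stn(self, tiny_config):
        assert max(tiny_config.epn.semi_axes[:2]) < \
            max(tiny_config.stn.semi_axes[:2])

    def test_deterministic_given_seed(self, tiny_config):
        a = build_phantom(tiny_config)
        b = build_phantom(tiny_config)
        assert np.array_equal(a.label_grid, b.label_grid)
        for k in a.region_masks:
            assert np.array_equal(a.region_masks[k], b.region_masks[k])

    def test_zero_size_ic_gives_empty_mask(self, tiny_config):
        import copy
        cfg = copy.deepcopy(tiny_config)
        cfg.ic_sheet = Slab(bounds=((0.5, 0.5), (-1.0, 1.0), (0.0, 0.1)))
        ph = build_phantom(cfg)
        assert not ph.region_masks["IC"].any()

    def test_overlapping_targets_error_names_pair(self, tiny_config):
        import copy
        cfg = copy.deepcopy(tiny_config)
        cfg.epn = Ellipsoid(center=(-0.6, 0.0, -0.5),
                            semi_axes=(0.25, 0.25, 0.2))
        with pytest.raises(ValueError, match="STN and EPN"):
            build_phantom(cfg)

    def test_shapes_outside_domain_rejected(self, tiny_config):
        import copy
        cfg = copy.deepcopy(tiny_config)
        cfg.stn = Ellipsoid(center=(-1.4, 0.0, -0.5),
                            semi_axes=(0.35, 0.3, 0.2))
        with pytest.raises(ValueError, match="outside the domain"):
            build_phantom(cfg)

    def test_csf_rind_at_boundary(self, tiny_phantom):
        assert (tiny_phantom.label_grid[0] == CSF).all()
        assert (tiny_phantom.label_grid[:, :, -1] == CSF).all()

    def test_voxel_center_convention(self, tiny_phantom):
        # centre of voxel (0,0,0) is origin + voxel/2
        pts = tiny_phantom.origin + 0.5 * tiny_phantom.voxel_size
        assert (tiny_phantom.world_to_index(pts) == 0).all()

    def test_nifti_roundtrip(self, tiny_phantom_aniso, tmp_path):
        from dbsfem.phantom import TissuePhantom
        ph = tiny_phantom_aniso
        ph.to_nifti(str(tmp_path / "ph"), include_tensors=True)
        back = TissuePhantom.from_nifti(str(tmp_path / "ph"))
        assert np.array_equal(back.label_grid, ph.label_grid)
        assert back.voxel_size == pytest.approx(ph.voxel_size)
        assert np.allclose(back.origin, ph.origin)
        assert set(back.region_masks) == set(ph.region_masks)
        assert np.array_equal(back.region_masks["STN"],
                              ph.region_masks["STN"])
        assert back.tensor_field.n_anisotropic > 0
        pts = np.array([[0.65, 0.0, 0.075]])   # inside the WM sheet
        assert np.allclose(back.tensor_at(pts), ph.tensor_at(pts), atol=1e-6)


class TestCarveEncapsulation:
    def track(self, ph, radius=0.25):
        top = ph.domain_bounds[1][2] - 1e-9
        return Track(p0=(-0.7, 0.0, -0.3), p1=(-0.7, 0.0, top), radius=radius)

    def test_shell_thickness_in_voxels(self, tiny_config):
        """0.1 mm shell on 0.025 mm voxels is 4 +- 1 voxels thick, matching a
        brute-force count of voxels satisfying the distance predicate."""
        import copy
        cfg = copy.deepcopy(tiny_config)
        cfg.voxel_size = 0.025
        cfg.domain_extent = (2.0, 2.0, 2.0)
        cfg.stn = Ellipsoid(center=(-0.4, 0.0, -0.3), semi_axes=(0.2, 0.2, 0.1))
        cfg.epn = Ellipsoid(center=(0.4, 0.0, -0.3), semi_axes=(0.15, 0.15, 0.12))
        cfg.thalamus = Slab(bounds=((-0.8, 0.8), (-0.8, 0.8), (0.2, 0.6)))
        cfg.ic_sheet = Slab(bounds=((0.2, 0.7), (-0.8, 0.8), (0.0, 0.1)))
        cfg.csf_layer = 0.1
        ph = build_phantom(cfg)
        tr = Track(p0=(0.0, 0.0, -0.2), p1=(0.0, 0.0, 0.95), radius=0.25)
        out = carve_encapsulation(ph, tr, thickness=0.1)
        # brute-force reference count over all voxel centres
        xs, ys, zs = ph.voxel_centers_1d()
        X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
        pts = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=-1)
        d = tr.surface_distance(pts).reshape(ph.shape)
        expected = (d > 0) & (d <= 0.1)
        assert np.array_equal(out.label_grid == ENCAP, expected)
        # radial thickness through the shaft at mid-height: 4 +- 1 voxels
        k = np.searchsorted(zs, 0.4)
        j = np.searchsorted(ys, 0.0)
        row = out.label_grid[:, j, k]
        runs = np.flatnonzero(row == ENCAP)
        left = runs[runs < len(xs) // 2]
        assert 3 <= len(left) <= 5

    def test_thin_shell_floors_to_one_voxel_with_warning(self, tiny_phantom,
                                                         caplog):
        import logging
        with caplog.at_level(logging.WARNING, logger="dbsfem.phantom"):
            out = carve_encapsulation(tiny_phantom, self.track(tiny_phantom),
                                      thickness=0.01)
        assert "widening" in caplog.text
        assert (out.label_grid == ENCAP).any()

    def test_shell_outside_shaft(self, tiny_phantom):
        """Encapsulation voxels never intersect the electrode interior."""
        tr = self.track(tiny_phantom)
        out = carve_encapsulation(tiny_phantom, tr)
        xs, ys, zs = out.voxel_centers_1d()
        X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
        pts = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=-1)
        inside = tr.surface_distance(pts).reshape(out.shape) <= 0
        assert not ((out.label_grid == ENCAP) & inside).any()

    def test_track_outside_domain_rejected(self, tiny_phantom):
        tr = Track(p0=(0, 0, -5.0), p1=(0, 0, 1.0), radius=0.2)
        with pytest.raises(ValueError, match="outside"):
            carve_encapsulation(tiny_phantom, tr)

    def test_masks_exclude_scar(self, tiny_phantom):
        tr = Track(p0=(-0.7, 0.0, -0.35), p1=(-0.7, 0.0, 1.3), radius=0.25)
        out = carve_encapsulation(tiny_phantom, tr)
        enc = out.label_grid == ENCAP
        for m in out.region_masks.values():
            assert not (m & enc).any()


class TestAnisotropy:
    def test_fa_zero_gives_identity(self, tiny_phantom):
        out = make_anisotropy(tiny_phantom, None, 0.0)
        assert out.tensor_field.n_anisotropic == 0

    def test_eigenvalue_normalisation_closed_form(self):
        """Eigenvalues (4,1,1) normalise to (4,1,1)/4^(1/3) with det 1."""
        # fa for ratio 4: invert the prolate FA relation
        fa = 3.0 / np.sqrt(18.0)
        rho = fa_to_eigenvalue_ratio(fa)
        assert rho == pytest.approx(4.0, rel=1e-12)
        lam = np.array([rho, 1.0, 1.0]) / rho ** (1 / 3)
        assert np.prod(lam) == pytest.approx(1.0, abs=1e-12)
        assert lam[0] / lam[1] == pytest.approx(4.0, rel=1e-12)

    def test_wm_tensors_unit_determinant(self, tiny_phantom_aniso):
        tf = tiny_phantom_aniso.tensor_field
        assert tf.n_anisotropic > 0
        T = VoxelTensorField.unpack(tf.components)
        dets = np.linalg.det(T)
        assert np.max(np.abs(dets - 1.0)) < 1e-9

    def test_geometric_mean_preserved_under_scaling(self, tiny_phantom_aniso):
        """Multiplying a unit-det tensor by sigma keeps geometric-mean sigma."""
        T = VoxelTensorField.unpack(tiny_phantom_aniso.tensor_field.components[0])
        sigma = 0.17
        ev = np.linalg.eigvalsh(sigma * T)
        assert np.prod(ev) ** (1 / 3) == pytest.approx(sigma, rel=1e-9)

    def test_gm_voxels_identity(self, tiny_phantom_aniso):
        ph = tiny_phantom_aniso
        gm_pts = np.array([[-0.7, 0.0, -0.5]])  # inside the STN (gray matter)
        assert np.allclose(ph.tensor_at(gm_pts), np.eye(3))

    def test_nonunit_directions_normalised_with_warning(self, tiny_phantom):
        with pytest.warns(UserWarning, match="normaliz"):
            out = make_anisotropy(tiny_phantom,
                                  lambda p: np.full((len(p), 3), 2.0), 0.5)
        T = VoxelTensorField.unpack(out.tensor_field.components)
        assert np.max(np.abs(np.linalg.det(T) - 1.0)) < 1e-9

    @given(fa=st.floats(min_value=0.0, max_value=0.95))
    @settings(max_examples=30, deadline=None)
    def test_fa_ratio_monotone_and_unit(self, fa):
        rho = fa_to_eigenvalue_ratio(fa)
        assert rho >= 1.0
        lam = np.array([rho, 1.0, 1.0]) / rho ** (1 / 3)
        assert np.prod(lam) == pytest.approx(1.0, abs=1e-9)
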
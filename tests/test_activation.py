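"""Probe lattice, divergence stencil, thresholding and performance shares."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dbsfem.activation import (seed_probe_grid, field_divergence, classify,
                               evaluate_performance, compare_designs,
                               ActivationReport, PROBE_SPACING, PROBE_RADIUS,
                               THRESHOLD_E, THRESHOLD_DIV)
from dbsfem.electrodes import make_design, place


@pytest.fixture(scope="module")
def grid_and_placement(tiny_phantom):
    d = make_design("BLUNT")
    pl = place(d, tiny_phantom, "STN")
    return seed_probe_grid(pl, d), d, pl


class TestProbeGrid:
    def test_spacing_is_005mm(self, grid_and_placement):
        grid, _, _ = grid_and_placement
        assert grid.spacing == PROBE_SPACING
        xs = np.unique(grid.points[:, 0])
        assert np.allclose(np.diff(xs), PROBE_SPACING)

    def test_probe_points_within_2mm_ball(self, grid_and_placement):
        grid, _, _ = grid_and_placement
        pts = grid.points[grid.valid_mask]
        r = np.linalg.norm(pts - grid.center, axis=1)
        assert r.max() <= PROBE_RADIUS + 1e-9

    def test_count_bounded_by_full_lattice_and_ball(self, grid_and_placement):
        """Probe count is below the 81^3 cube and close to the brute-force
        count of lattice points inside the 2 mm ball, minus exclusions."""
        grid, _, _ = grid_and_placement
        assert grid.shape == (81, 81, 81)
        assert grid.n_probe_points <= 81 ** 3
        ball_count = int(grid.ball_mask.sum())
        # brute-force lattice-in-sphere reference on the same offsets
        offs = PROBE_SPACING * np.arange(-40, 41)
        X, Y, Z = np.meshgrid(offs, offs, offs, indexing="ij")
        expect = int((X ** 2 + Y ** 2 + Z ** 2 <= PROBE_RADIUS ** 2 + 1e-12).sum())
        assert ball_count == expect
        assert grid.n_probe_points == ball_count - int(
            (grid.ball_mask & grid.electrode_mask).sum())

    def test_no_point_inside_electrode(self, grid_and_placement):
        grid, d, pl = grid_and_placement
        pts = grid.points[grid.valid_mask]
        z, rho = pl.local_coords(pts)
        assert not d.inside(z, rho).any()

    def test_identical_for_identical_tip_pose(self, tiny_phantom):
        d1 = make_design("BLUNT")
        d2 = make_design("BLUNT", outer_contact_length=0.4)
        pl = place(d1, tiny_phantom, "EPN")
        g1 = seed_probe_grid(pl, d1)
        g2 = seed_probe_grid(pl, d2)
        assert np.array_equal(g1.points, g2.points)
        assert np.array_equal(g1.ball_mask, g2.ball_mask)


class TestFieldDivergence:
    def test_uniform_field_zero(self):
        E = np.tile(np.array([1.0, -2.0, 0.5]), (9, 9, 9, 1))
        div = field_divergence(E, 0.05)
        assert np.allclose(div, 0.0, atol=1e-12)

    def test_linear_field_unit_divergence(self):
        """E = (x, 0, 0) V/mm per mm has divergence exactly 1 V/mm^2."""
        x = 0.05 * np.arange(9)
        X, Y, Z = np.meshgrid(x, x, x, indexing="ij")
        E = np.stack([X, np.zeros_like(X), np.zeros_like(X)], axis=-1)
        div = field_divergence(E, 0.05)
        assert np.allclose(div, 1.0, atol=1e-12)

    def test_monopole_field_second_order_accurate(self):
        """|div E| of the analytically sampled point-source field matches the
        symbolic divergence (zero away from the source) to O(h^2)."""
        h = 0.05
        x = h * np.arange(-12, 13) + 0.025   # offset to avoid the singularity
        X, Y, Z = np.meshgrid(x, x, x, indexing="ij")
        R = np.stack([X, Y, Z], axis=-1)
        r = np.linalg.norm(R, axis=-1)
        E = R / r[..., None] ** 3
        div = field_divergence(E, h)
        interior = (slice(2, -2),) * 3
        r_in = r[interior]
        far = r_in > 0.4
        # second-order bound: |err| <= C h^2 * max|d^3 E| ~ C h^2 / r^5
        bound = 12.0 * h ** 2 / r_in[far] ** 5
        assert np.all(np.abs(div[interior][far]) <= bound)

    def test_bad_shape_rejected(self):
        with pytest.raises(ValueError):
            field_divergence(np.zeros((4, 4, 4)), 0.05)


class TestClassify:
    def test_above_threshold_active(self):
        assert classify(np.array([0.40]), THRESHOLD_E)[0]

    def test_exact_threshold_not_active(self):
        """Strict inequality: |E| = 0.323 V/mm exactly is not activated."""
        assert not classify(np.array([THRESHOLD_E]), THRESHOLD_E)[0]

    def test_infinite_threshold_zero_activation(self):
        assert not classify(np.array([1e9, 1e12]), np.inf).any()

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            classify(np.array([1.0]), -0.1)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_activated_volume_monotone_in_threshold(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.exponential(0.3, 500)
        counts = [classify(vals, t).sum()
                  for t in np.linspace(0, 1.2, 13)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestEvaluatePerformance:
    def make_report(self, grid, phantom, values):
        return evaluate_performance({"E": values}, grid, phantom, "STN",
                                    design_name="BLUNT")

    def test_all_active_inside_target_gives_100(self, grid_and_placement,
                                                tiny_phantom):
        grid, _, _ = grid_and_placement
        vals = np.zeros(len(grid.points))
        in_stn = np.zeros(len(grid.points), dtype=bool)
        in_stn[grid.valid_mask] = tiny_phantom.mask_at(
            "STN", grid.points[grid.valid_mask])
        vals[in_stn] = 1.0
        rep = self.make_report(grid, tiny_phantom, vals)
        assert rep.target_share["E"] == pytest.approx(100.0)

    def test_share_arithmetic(self):
        """0.362 mm^3 of 1.0585 mm^3 activated inside the target is a 34.2%
        share (the published blunt-end STN figures are mutually consistent)."""
        assert 100 * 0.362 / 1.0585 == pytest.approx(34.2, abs=0.05)

    def test_share_matches_point_counts(self, grid_and_placement,
                                        tiny_phantom, rng):
        grid, _, _ = grid_and_placement
        vals = rng.exponential(0.2, len(grid.points))
        rep = self.make_report(grid, tiny_phantom, vals)
        valid = grid.valid_mask
        act = vals[valid] > THRESHOLD_E
        stn = tiny_phantom.mask_at("STN", grid.points[valid])
        assert rep.total_volume["E"] == pytest.approx(
            act.sum() * grid.point_volume)
        assert rep.target_share["E"] == pytest.approx(
            100 * (act & stn).sum() / act.sum())

    def test_region_volumes_bounded_by_total(self, grid_and_placement,
                                             tiny_phantom, rng):
        grid, _, _ = grid_and_placement
        vals = rng.exponential(0.2, len(grid.points))
        rep = self.make_report(grid, tiny_phantom, vals)
        assert sum(rep.region_volume["E"].values()) <= \
            rep.total_volume["E"] + 1e-12
        assert 0.0 <= rep.target_share["E"] <= 100.0

    def test_share_invariant_under_volume_rescaling(self, grid_and_placement,
                                                    tiny_phantom, rng):
        grid, _, _ = grid_and_placement
        vals = rng.exponential(0.2, len(grid.points))
        r1 = self.make_report(grid, tiny_phantom, vals)
        g2 = ActivationReport(
            design_name="x", target_name="STN", thresholds=r1.thresholds,
            total_volume={k: 2 * v for k, v in r1.total_volume.items()},
            region_volume={k: {n: 2 * v for n, v in d.items()}
                           for k, d in r1.region_volume.items()})
        share2 = 100 * g2.region_volume["E"]["STN"] / g2.total_volume["E"]
        assert share2 == pytest.approx(r1.target_share["E"])

    def test_no_activation_reports_nan_with_warning(self, grid_and_placement,
                                                    tiny_phantom):
        grid, _, _ = grid_and_placement
        with pytest.warns(UserWarning, match="undefined"):
            rep = self.make_report(grid, tiny_phantom,
                                   np.zeros(len(grid.points)))
        assert np.isnan(rep.target_share["E"])

    def test_unknown_region_rejected(self, grid_and_placement, tiny_phantom):
        grid, _, _ = grid_and_placement
        with pytest.raises(KeyError):
            evaluate_performance({"E": np.zeros(len(grid.points))}, grid,
                                 tiny_phantom, "PUTAMEN")


class TestCompareDesigns:
    def test_table_shape_and_determinism(self, grid_and_placement,
                                         tiny_phantom, rng):
        grid, _, _ = grid_and_placement
        vals = rng.exponential(0.2, len(grid.points))
        rep = evaluate_performance({"E": vals, "divE": vals * 2}, grid,
                                   tiny_phantom, "STN", design_name="BLUNT")
        table = compare_designs([rep, rep])
        assert table.shape[0] == 2
        assert {"share_E_pct", "share_divE_pct"} <= set(table.columns)
        assert table.iloc[0].equals(table.iloc[1])
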
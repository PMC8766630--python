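"""Flow post-processing: summaries, moving averages, cross sections."""

import numpy as np
import pytest
from scipy import ndimage

from rhinoflow.postproc import (
    Centerline,
    SLAB_HALF_FACTOR,
    boundary_summary,
    centerline_profiles,
    cross_section_cells,
    moving_average,
    naive_centerline,
    section_average,
    slab_mask,
    total_pressure,
)
from rhinoflow.tlb.lattice import CS2


def duct_mask(nx=6, ny=6, nz=30):
    return np.ones((nx, ny, nz), bool)


class TestBoundarySummary:
    def _openings(self, mask):
        pm = np.zeros_like(mask)
        pm[:, :, 0] = True
        nl = np.zeros_like(mask)
        nl[: mask.shape[0] // 2, :, -1] = True
        nr = np.zeros_like(mask)
        nr[mask.shape[0] // 2 :, :, -1] = True
        return {
            "pharynx": {"mask": pm, "normal": (0, 0, -1)},
            "nostril_left": {"mask": nl, "normal": (0, 0, 1)},
            "nostril_right": {"mask": nr, "normal": (0, 0, 1)},
        }

    def test_uniform_fields_zero_differences(self):
        mask = duct_mask()
        rho = np.ones(mask.shape)
        v = np.zeros((3,) + mask.shape)
        v[2] = 0.01
        s = boundary_summary(rho, v, None, self._openings(mask))
        for side in ("left", "right"):
            assert s.dp_dyn[side] == pytest.approx(0.0, abs=1e-15)
            assert s.dp_stat[side] == pytest.approx(0.0, abs=1e-15)

    def test_additivity_exact(self):
        rng = np.random.default_rng(0)
        mask = duct_mask()
        rho = 1 + 0.01 * rng.standard_normal(mask.shape)
        v = 0.01 * rng.standard_normal((3,) + mask.shape)
        s = boundary_summary(rho, v, None, self._openings(mask))
        for side in ("left", "right"):
            assert s.dp_tot[side] == s.dp_dyn[side] + s.dp_stat[side]

    def test_toy_arrays_match_bruteforce_sums(self):
        rng = np.random.default_rng(1)
        mask = duct_mask(2, 5, 4)
        rho = 1 + 0.05 * rng.standard_normal(mask.shape)
        v = 0.05 * rng.standard_normal((3,) + mask.shape)
        T = 300 + rng.standard_normal(mask.shape)
        op = self._openings(mask)
        s = boundary_summary(rho, v, T, op, T_body=309.15)
        pm, nl = op["pharynx"]["mask"], op["nostril_left"]["mask"]
        dyn = 0.5 * rho * (v**2).sum(axis=0)
        expected = dyn[pm].sum() / pm.sum() - dyn[nl].sum() / nl.sum()
        assert s.dp_dyn["left"] == pytest.approx(expected, rel=1e-12)
        assert s.dT == pytest.approx(T[pm].mean() - 309.15, rel=1e-12)
        # mass flux: inward normal for the pharynx is +z
        mdot = (rho * 0 + 1.0 * v[2])[pm].sum()
        assert s.mdot["pharynx"] == pytest.approx(mdot, rel=1e-12)

    def test_empty_boundary_rejected(self):
        mask = duct_mask()
        op = self._openings(mask)
        op["nostril_left"]["mask"] = np.zeros_like(mask)
        with pytest.raises(ValueError, match="empty boundary"):
            boundary_summary(np.ones(mask.shape), np.zeros((3,) + mask.shape), None, op)


class TestMovingAverage:
    def test_constant_series_unchanged(self):
        out = moving_average(np.full(20, 3.7), 4)
        np.testing.assert_allclose(out.values, 3.7, rtol=1e-14)

    def test_linear_ramp_unchanged_in_interior(self):
        x = np.arange(30.0)
        out = moving_average(x, 6)
        np.testing.assert_allclose(out.values[3:-3], x[3:-3], rtol=1e-12)

    def test_random_series_matches_windowed_sum_oracle(self):
        rng = np.random.default_rng(2)
        a = rng.standard_normal(50)
        out = moving_average(a, 4)
        for t in range(2, 48):
            assert out.values[t] == pytest.approx(a[t - 2 : t + 3].mean(), rel=1e-12)

    def test_odd_interval_rejected_with_suggestion(self):
        with pytest.raises(ValueError, match="try"):
            moving_average(np.arange(10.0), 3)


class TestCrossSections:
    def test_straight_duct_axis_normal_layers(self):
        mask = duct_mask(5, 5, 20)
        origin = np.zeros(3)
        cs = cross_section_cells(mask, origin, 1.0, (2, 2, 10), (0, 0, 1))
        zs = np.unique(cs.cells[:, 2])
        # slab half-thickness sqrt(3)/2 < 1 admits one or two layers
        assert 1 <= len(zs) <= 2
        assert 10 in zs
        assert cs.H_cs % 25 == 0

    def test_two_parallel_ducts_connectivity(self):
        mask = np.zeros((11, 5, 20), bool)
        mask[:4] = True  # duct A
        mask[7:] = True  # duct B
        cs = cross_section_cells(mask, np.zeros(3), 1.0, (1, 2, 10), (0, 0, 1))
        assert np.all(cs.cells[:, 0] < 4)

    def test_y_phantom_matches_bruteforce_slab_component_oracle(self):
        # Y-shaped mask: single trunk splitting into two branches
        mask = np.zeros((21, 5, 30), bool)
        mask[8:13, :, :10] = True  # trunk
        for z in range(10, 30):
            off = (z - 10) // 2
            mask[max(8 - off, 0) : max(13 - off, 3), :, z] = True
            mask[min(8 + off, 18) : min(13 + off, 21), :, z] = True
        rng = np.random.default_rng(3)
        fluid = np.argwhere(mask)
        for _ in range(50):
            seed_cell = fluid[rng.integers(len(fluid))]
            n = rng.standard_normal(3)
            n /= np.linalg.norm(n)
            point = seed_cell.astype(float)
            cs = cross_section_cells(mask, np.zeros(3), 1.0, point, n)
            # oracle: brute-force slab mask, scipy connected components
            slab = slab_mask(mask, np.zeros(3), 1.0, point, n)
            slab[tuple(seed_cell)] = True
            lab, _ = ndimage.label(slab, structure=np.ones((3, 3, 3)))
            want = lab == lab[tuple(seed_cell)]
            got = np.zeros_like(want)
            got[tuple(cs.cells.T)] = True
            np.testing.assert_array_equal(got, want)

    def test_seed_outside_rejected(self):
        mask = duct_mask()
        with pytest.raises(ValueError, match="outside"):
            cross_section_cells(mask, np.zeros(3), 1.0, (50, 2, 2), (0, 0, 1))

    def test_section_average(self):
        mask = duct_mask(4, 4, 10)
        fld = np.ones(mask.shape)
        cs = cross_section_cells(mask, np.zeros(3), 1.0, (2, 2, 5), (0, 0, 1))
        assert section_average(cs, fld) == 1.0
        fld2 = np.zeros(mask.shape)
        fld2[tuple(cs.cells[0])] = 2.0 * cs.H_cs
        assert section_average(cs, fld2) == pytest.approx(2.0)


class TestProfiles:
    def test_linear_pressure_drop_profile(self):
        mask = duct_mask(5, 5, 40)
        z = np.arange(40)
        p = np.tile(1.0 - 0.002 * z, (5, 5, 1))
        cl = {"main": np.stack([np.full(40, 2.0), np.full(40, 2.0), z], axis=1)}
        df = centerline_profiles({"p_tot": p}, mask, np.zeros(3), 1.0, cl, 20)
        got = df["p_tot"].to_numpy()
        s = df["arclength_pct"].to_numpy() / 100 * 39
        expected = 1.0 - 0.002 * s
        np.testing.assert_allclose(got, expected, rtol=2e-2)

    def test_station_count_upper_bound_and_flat_temperature(self):
        mask = duct_mask(5, 5, 20)
        p = np.ones(mask.shape)
        T = np.full(mask.shape, 300.0)
        cl = {
            "main": np.stack(
                [np.full(20, 2.0), np.full(20, 2.0), np.arange(20.0)], axis=1
            )
        }
        df = centerline_profiles({"p_tot": p, "T": T}, mask, np.zeros(3), 1.0, cl, 12)
        assert len(df) <= 12
        np.testing.assert_allclose(df["T"], 300.0)

    def test_total_pressure_definition(self):
        rho = np.array([[[1.02]]])
        v = np.zeros((3, 1, 1, 1))
        v[0] = 0.1
        assert total_pressure(rho, v)[0, 0, 0] == pytest.approx(
            1.02 * CS2 + 0.5 * 1.02 * 0.01
        )


class TestNaiveCenterline:
    def test_duct_phantom_axis(self):
        from rhinoflow.phantoms import make_duct

        duct = make_duct(10, 10, 100)
        cl = naive_centerline(duct)
        assert cl.points[0, 2] == 0.0
        assert cl.points[-1, 2] == 100.0
        np.testing.assert_allclose(cl.points[:, :2], 0.0)

    def test_l_bend_ridge_within_one_cell_of_medial_axis(self):
        # voxelized L-shaped tube: path should hug the analytic axis
        mask = np.zeros((30, 9, 30), bool)
        mask[2:7, 2:7, 2:28] = True  # arm along z at x~4
        mask[2:28, 2:7, 2:7] = True  # arm along x at z~4
        cl = naive_centerline(
            mask=mask, origin=(0, 0, 0), dx=1.0,
            endpoints=[(4, 4, 27), (27, 4, 4)],
        )
        for p in cl.points:
            d_axis1 = np.hypot(p[0] - 4, p[1] - 4)
            d_axis2 = np.hypot(p[2] - 4, p[1] - 4)
            assert min(d_axis1, d_axis2) <= 1.5

    def test_torus_segment_arclength_within_2pct(self):
        from rhinoflow.phantoms import make_torus_segment

        t = make_torus_segment()
        cl = naive_centerline(t)
        assert cl.arclength == pytest.approx(t.arc_length, rel=0.02)

    def test_endpoint_outside_mask_rejected(self):
        mask = np.ones((5, 5, 5), bool)
        with pytest.raises(ValueError, match="endpoint"):
            naive_centerline(mask=mask, endpoints=[(0, 0, 0), (9, 9, 9)])
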
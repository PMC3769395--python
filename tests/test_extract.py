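"""Norm time courses, z-maps, ROI definition, windowed measurements."""

import numpy as np
import pandas as pd
import pytest

from deepmeg import anatomy, extract, inverse
from deepmeg.errors import InvalidConfigError


def _volume_space(n_nodes=4, hemisphere="right", seed=0):
    rng = np.random.default_rng(seed)
    nodes = np.array([[0.02, -0.004, -0.018]]) + 0.002 * rng.normal(size=(n_nodes, 3))
    frames = np.broadcast_to(np.eye(3), (n_nodes, 3, 3)).copy()
    return anatomy.VolumeSourceSpace(
        nodes, 0.002, "amygdala", np.array([hemisphere] * n_nodes), frames
    )


def _estimate_for(space, comps, times):
    """SourceEstimate with given (n_nodes, 3, n_times) trihedral components."""
    n_nodes = space.n_sources
    index = [
        ("amygdala", i, f"e{k+1}", str(space.hemisphere[i]))
        for i in range(n_nodes)
        for k in range(3)
    ]
    return inverse.SourceEstimate(comps.reshape(3 * n_nodes, -1), times, index)


class TestAmygdalaTimecourse:
    times = np.linspace(-0.2, 0.6, 11)

    def test_three_four_five_norm(self):
        space = _volume_space(1)
        comps = np.zeros((1, 3, 11))
        comps[0, 0, 5], comps[0, 1, 5] = 3e-9, 4e-9
        tc = extract.amygdala_timecourse(_estimate_for(space, comps, self.times), space)
        assert tc["right"][5] == pytest.approx(5e-9)
        assert tc["right"][0] == 0.0

    def test_frame_rotation_invariance(self, rng):
        """Rotating every node's frame (and components consistently) leaves
        the norm time course unchanged."""
        from scipy.stats import special_ortho_group

        space = _volume_space(3)
        comps = rng.normal(size=(3, 3, 11)) * 1e-9
        tc0 = extract.amygdala_timecourse(_estimate_for(space, comps, self.times), space)
        rotated = comps.copy()
        for i in range(3):
            R = special_ortho_group.rvs(3, random_state=10 + i)
            rotated[i] = R @ comps[i]
        tc1 = extract.amygdala_timecourse(
            _estimate_for(space, rotated, self.times), space
        )
        np.testing.assert_allclose(tc1["right"], tc0["right"], rtol=1e-12)

    def test_hemisphere_trace_is_node_mean(self, rng):
        space = _volume_space(2)
        comps = rng.normal(size=(2, 3, 11)) * 1e-9
        est = _estimate_for(space, comps, self.times)
        tc = extract.amygdala_timecourse(est, space)
        a = np.linalg.norm(comps[0], axis=0)
        b = np.linalg.norm(comps[1], axis=0)
        np.testing.assert_allclose(tc["right"], (a + b) / 2.0, rtol=1e-12)


class TestZScoreMap:
    times = np.linspace(-0.2, 0.6, 801)

    def test_baseline_is_standardized(self, rng):
        data = rng.normal(2.0, 3.0, size=(5, 801))
        z = extract.zscore_map(data, self.times)
        base = z.data[:, (self.times >= -0.2) & (self.times < 0.0)]
        np.testing.assert_allclose(base.mean(axis=1), 0.0, atol=1e-6)
        np.testing.assert_allclose(base.std(axis=1), 1.0, atol=1e-6)

    def test_two_sigma_excursion_maps_to_z2(self):
        data = np.zeros((1, 801))
        rng = np.random.default_rng(0)
        base_mask = (self.times >= -0.2) & (self.times < 0.0)
        data[0, base_mask] = rng.normal(5.0, 2.0, base_mask.sum())
        mu = data[0, base_mask].mean()
        sd = data[0, base_mask].std()
        data[0, -1] = mu + 2 * sd
        z = extract.zscore_map(data, self.times)
        assert z.data[0, -1] == pytest.approx(2.0)

    def test_affine_invariance(self, rng):
        data = rng.normal(size=(4, 801))
        z0 = extract.zscore_map(data, self.times)
        z1 = extract.zscore_map(3.7 * data + 11.0, self.times)
        np.testing.assert_allclose(z1.data, z0.data, rtol=1e-9, atol=1e-9)

    def test_zero_sd_vertex_flagged(self):
        data = np.ones((2, 801))
        data[1] = np.random.default_rng(0).normal(size=801)
        z = extract.zscore_map(data, self.times)
        assert z.flagged[0] and not z.flagged[1]
        assert np.all(z.data[0] == 0.0)


@pytest.fixture(scope="module")
def surface():
    return anatomy.build_template_cortex(500)


class TestPeakRoi:
    def _zmap_peaked_at(self, surface, vertex, times):
        data = np.zeros((surface.n_sources, len(times)))
        active = times >= 0.13
        data[vertex, active] = 10.0
        rng = np.random.default_rng(0)
        base = (times >= -0.2) & (times < 0.0)
        data[:, base] += rng.normal(0, 1.0, (surface.n_sources, base.sum()))
        return extract.zscore_map(data, times)

    def test_single_active_vertex_size_one(self, surface):
        times = np.linspace(-0.2, 0.6, 801)
        zmap = self._zmap_peaked_at(surface, 123, times)
        roi = extract.define_peak_roi(zmap, (0.13, 0.17), 1, surface)
        assert roi.center == 123
        assert list(roi.members) == [123]

    @pytest.mark.parametrize("size", [77, 82])
    def test_configured_sizes_honoured(self, surface, size):
        times = np.linspace(-0.2, 0.6, 801)
        zmap = self._zmap_peaked_at(surface, 40, times)
        roi = extract.define_peak_roi(zmap, (0.13, 0.17), size, surface)
        assert roi.size == size
        assert roi.center in roi.members

    def test_full_region_request_returns_region(self, surface):
        times = np.linspace(-0.2, 0.6, 801)
        zmap = self._zmap_peaked_at(surface, 10, times)
        search = np.arange(0, 50)
        roi = extract.define_peak_roi(zmap, (0.13, 0.17), 50, surface, search)
        assert set(roi.members) == set(search)

    def test_roi_members_are_geodesic_neighbourhood(self, surface):
        times = np.linspace(-0.2, 0.6, 801)
        zmap = self._zmap_peaked_at(surface, 77, times)
        roi = extract.define_peak_roi(zmap, (0.13, 0.17), 20, surface)
        dist = extract.geodesic_distances(surface, roi.center)
        inside = dist[roi.members].max()
        outside_ids = np.setdiff1d(np.arange(surface.n_sources), roi.members)
        # no excluded vertex is strictly closer than an included one
        assert np.all(dist[outside_ids] >= inside - 1e-12)

    def test_leakage_guard_roi_depends_only_on_grand_average(self, surface):
        """Permuting condition labels (i.e. which condition map is which)
        cannot change the ROI, which sees only the grand average."""
        times = np.linspace(-0.2, 0.6, 801)
        rng = np.random.default_rng(5)
        maps = [
            self._zmap_peaked_at(surface, 200, times).data + rng.normal(size=(500, 801))
            for _ in range(4)
        ]
        grand1 = extract.ZMap(np.mean(maps, axis=0), times, (-0.2, 0), np.zeros(500, bool))
        grand2 = extract.ZMap(
            np.mean([maps[2], maps[0], maps[3], maps[1]], axis=0),
            times, (-0.2, 0), np.zeros(500, bool),
        )
        roi1 = extract.define_peak_roi(grand1, (0.13, 0.17), 15, surface)
        roi2 = extract.define_peak_roi(grand2, (0.13, 0.17), 15, surface)
        np.testing.assert_array_equal(roi1.members, roi2.members)


class TestClusterRois:
    def test_separated_clouds_recovered_exactly(self, rng):
        a = rng.normal(0, 0.001, (30, 3))
        b = rng.normal(0, 0.001, (25, 3)) + np.array([0.05, 0, 0])
        coords = np.vstack([a, b])
        rois = extract.cluster_volume_rois(coords, 2, seed=0)
        sets = sorted([set(r.members) for r in rois], key=len)
        assert sets == [set(range(30, 55)), set(range(30))]

    def test_k1_contains_all_with_central_center(self, rng):
        coords = rng.normal(size=(40, 3))
        (roi,) = extract.cluster_volume_rois(coords, 1, seed=0)
        assert set(roi.members) == set(range(40))
        centroid = coords.mean(axis=0)
        d = np.linalg.norm(coords - centroid, axis=1)
        assert roi.center == int(np.argmin(d))

    def test_fixed_seed_deterministic(self, rng):
        coords = rng.normal(size=(60, 3))
        r1 = extract.cluster_volume_rois(coords, 3, seed=11)
        r2 = extract.cluster_volume_rois(coords, 3, seed=11)
        for a, b in zip(r1, r2):
            np.testing.assert_array_equal(a.members, b.members)


class TestWindowMeans:
    def test_constant_trace(self):
        times = np.arange(0, 1.0, 1 / 1250.0)
        df = extract.window_means(np.full_like(times, 3.3), times, subject="s1")
        assert np.allclose(df["value"], 3.3)
        assert set(df["window"]) == {"130-170", "190-230", "230-270", "270-310", "310-350"}

    def test_late_analysis_emits_four_rows(self):
        times = np.arange(0, 1.0, 1 / 1250.0)
        late = {k: extract.ANALYSIS_WINDOWS[k] for k in extract.LATE_WINDOWS}
        df = extract.window_means(np.zeros_like(times), times, late)
        assert len(df) == 4

    def test_linear_ramp_mean_is_window_midpoint(self):
        """Closed-form integral oracle: mean of x(t)=t over [a,b) is the
        midpoint, up to half a sample period."""
        times = np.arange(-0.2, 0.6, 1 / 1250.0)
        trace = times.copy()
        for label, (a, b) in extract.ANALYSIS_WINDOWS.items():
            m = extract.window_mean(trace, times, (a, b))
            assert abs(m - (a + b) / 2.0) <= 0.5 / 1250.0

    def test_half_open_windows_do_not_double_count(self):
        times = np.arange(0, 0.5, 1 / 1250.0)
        trace = np.zeros_like(times)
        counted = np.zeros_like(times, bool)
        for a, b in extract.ANALYSIS_WINDOWS.values():
            m = (times >= a) & (times < b)
            assert not (counted & m).any()
            counted |= m

    def test_scaling_commutes_with_extraction(self, rng):
        times = np.arange(-0.2, 0.6, 1 / 1250.0)
        trace = rng.normal(size=times.shape)
        df1 = extract.window_means(trace, times)
        df2 = extract.window_means(5.0 * trace, times)
        np.testing.assert_allclose(df2["value"], 5.0 * df1["value"], rtol=1e-12)

    def test_measurement_table_factorial_coverage(self, rng):
        times = np.arange(-0.2, 0.6, 1 / 1250.0)
        traces = {
            (s, "amygdala", h, e, g): rng.normal(size=times.shape)
            for s in ("sub01", "sub02")
            for h in ("left", "right")
            for e in ("fearful", "neutral")
            for g in ("direct", "averted")
        }
        table = extract.measurement_table(traces, times)
        assert len(table) == 2 * 2 * 2 * 2 * 5
        per_subject = table.groupby("subject").size()
        assert (per_subject == 40).all()
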
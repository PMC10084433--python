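import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import readgaze as rg
from readgaze.events import GAZE_COLUMNS, _binocular_position

DT = 1000.0 / 60.0


class TestGeometry:
    def test_pixel_to_degree_hand_example(self):
        # 30 px at 0.30 mm/px pitch, 650 mm viewing distance:
        # 2*atan(30*0.30 / (2*650)) ~ 0.79 degrees
        geom = rg.ScreenGeometry(width_mm=0.30 * 1280, height_mm=0.30 * 1024,
                                 viewing_distance_mm=650.0)
        assert geom.px_to_deg(30.0) == pytest.approx(
            np.degrees(2 * np.arctan(9.0 / 1300.0)), abs=1e-9)
        assert geom.px_to_deg(30.0) == pytest.approx(0.793, abs=2e-3)

    def test_small_angle_linearity_within_one_percent(self, geometry):
        px5 = geometry.deg_to_px(5.0)
        d = np.linspace(1, px5, 50)
        deg = geometry.px_to_deg(d)
        linear = deg[0] * d / d[0]
        assert np.all(np.abs(deg - linear) / deg <= 0.01)
        assert np.all(np.diff(deg) > 0)

    def test_round_trip(self, geometry):
        assert geometry.px_to_deg(geometry.deg_to_px(1.0)) == pytest.approx(1.0)

    def test_non_square_pixels_rejected(self):
        with pytest.raises(ValueError, match="pitch"):
            rg.ScreenGeometry(width_mm=400.0, height_mm=346.9)


class TestDetectFixations:
    def test_two_clusters_with_sweep_give_two_fixations(self, stream_factory):
        # two stationary ~300 ms clusters separated by a ~40 ms transit
        stream = stream_factory([(300, 400, 18), (500, 400, 2),
                                 (700, 400, 18)])
        fix = rg.detect_fixations(stream)
        assert len(fix) == 2
        assert fix["centroid_x_px"].round().tolist() == [300, 700]

    def test_cluster_below_minimum_duration_dropped(self, stream_factory):
        stream = stream_factory([(300, 400, 3)])  # ~33 ms span
        assert len(rg.detect_fixations(stream)) == 0

    def test_blink_only_stream_yields_no_fixations(self, stream_factory):
        stream = stream_factory([(0, 0, 60)])
        assert len(rg.detect_fixations(stream)) == 0

    def test_empty_stream(self):
        empty = pd.DataFrame(columns=GAZE_COLUMNS)
        assert len(rg.detect_fixations(empty)) == 0

    def test_non_monotone_timestamps_rejected(self, stream_factory):
        stream = stream_factory([(300, 400, 10)])
        stream.loc[5, "time_ms"] = 0.0
        with pytest.raises(ValueError, match="increasing"):
            rg.detect_fixations(stream)

    def test_blink_splits_fixation(self, stream_factory):
        stream = stream_factory([(300, 400, 10), (0, 0, 3), (300, 400, 10)])
        fix = rg.detect_fixations(stream)
        assert len(fix) == 2

    def test_fixations_ordered_and_non_overlapping(self, small_events):
        fixations, _, _ = small_events
        for _, grp in fixations.groupby(["participant", "article"]):
            onsets = grp["onset_ms"].to_numpy()
            offsets = grp["offset_ms"].to_numpy()
            assert np.all(np.diff(onsets) > 0)
            assert np.all(offsets[:-1] < onsets[1:])
            assert np.all(grp["duration_ms"] >= 80.0)

    @given(st.data())
    def test_matches_brute_force_oracle(self, geometry, fixation_oracle,
                                        data):
        n = data.draw(st.integers(10, 200))
        rng = np.random.default_rng(data.draw(st.integers(0, 10_000)))
        # random walk with occasional jumps and blink runs
        x = np.cumsum(rng.choice([0.0, 0.0, 0.0, 120.0], size=n)
                      + rng.normal(0, 4, n)) + 500
        y = 400 + rng.normal(0, 4, n)
        blink = np.zeros(n, bool)
        for _ in range(data.draw(st.integers(0, 3))):
            s = rng.integers(0, n)
            blink[s:s + rng.integers(1, 5)] = True
        x[blink] = 0.0
        y[blink] = 0.0
        t = np.arange(n) * DT
        stream = pd.DataFrame({
            "time_ms": t, "left_x_px": x, "left_y_px": y,
            "right_x_px": x, "right_y_px": y,
            "left_pupil_px": 25.0, "right_pupil_px": 25.0})
        fix = rg.detect_fixations(stream, geometry)
        disp_px = geometry.deg_to_px(1.0)
        expected = fixation_oracle(t, x, y, blink, disp_px, 80.0, 2 * DT)
        assert len(fix) == len(expected)
        for (i, j), row in zip(expected, fix.itertuples()):
            assert row.onset_ms == pytest.approx(t[i])
            assert row.offset_ms == pytest.approx(t[j])


class TestSaccades:
    def test_three_fixations_give_two_saccades(self, stream_factory):
        stream = stream_factory([(300, 400, 18), (500, 400, 1),
                                 (700, 400, 18), (900, 400, 1),
                                 (1100, 400, 18)])
        fix = rg.detect_fixations(stream)
        sac = rg.derive_saccades(fix, stream)
        assert len(fix) == 3
        assert len(sac) == 2
        assert np.all(sac["duration_ms"] > 0)

    def test_fewer_than_two_fixations_give_no_saccades(self, stream_factory):
        stream = stream_factory([(300, 400, 18)])
        fix = rg.detect_fixations(stream)
        assert len(rg.derive_saccades(fix, stream)) == 0

    def test_blink_interval_flagged_and_regression_excluded(
            self, stream_factory):
        stream = stream_factory([(700, 400, 18), (0, 0, 3), (300, 400, 18)])
        fix = rg.detect_fixations(stream)
        sac = rg.derive_saccades(fix, stream)
        assert len(sac) == 1
        assert bool(sac["is_blink"].iloc[0])
        # backward displacement, but blink saccades are never regressions
        assert not bool(sac["is_regression"].iloc[0])

    def test_amplitude_degrees_hand_example(self, stream_factory):
        geom = rg.ScreenGeometry(width_mm=0.30 * 1280, height_mm=0.30 * 1024,
                                 viewing_distance_mm=650.0)
        stream = stream_factory([(400, 500, 18), (415, 500, 1),
                                 (430, 500, 18)])
        # tight dispersion threshold so the 30 px step separates fixations
        fix = rg.detect_fixations(stream, geom, dispersion_deg=0.3)
        sac = rg.derive_saccades(fix, stream, geom)
        assert len(sac) == 1
        assert sac["amplitude_deg"].iloc[0] == pytest.approx(
            np.degrees(2 * np.arctan(30 * 0.30 / (2 * 650.0))), rel=1e-6)

    def test_saccade_count_is_fixations_minus_one(self, small_events):
        fixations, saccades, _ = small_events
        nf = fixations.groupby(["participant", "article"]).size()
        ns = saccades.groupby(["participant", "article"]).size()
        assert (nf - 1).equals(ns)

    def test_regressions_subset_of_non_blink(self, small_events):
        _, saccades, _ = small_events
        assert not (saccades["is_regression"] & saccades["is_blink"]).any()


class TestRegressionRule:
    @pytest.mark.parametrize("dx,dy,expected", [
        (-50, 0, True),     # leftward re-read
        (120, 0, False),    # progressive saccade
        (-10, -10, False),  # both components below the 20 px floor
        (0, -25, True),     # upward (northwards) jump to an earlier line
        (-20, 0, True),     # boundary: exactly 20 px counts
        (-19.9, 19.9, False),
        (-900, 46, True),   # line-return sweep is NOT exempted
    ])
    def test_or_rule(self, dx, dy, expected):
        assert bool(rg.classify_regression(dx, dy)) is expected

    def test_near_zero_regressions_without_generator_regressions(
            self, monkeypatch):
        """With the regression channel off, only line-return sweeps remain;
        non-sweep saccades regress at a negligible rate."""
        import readgaze.simulate as sim
        monkeypatch.setattr(sim, "BASE_REGRESSION_PROB", 0.0)
        cfg = rg.GeneratorConfig(
            n_participants=2, n_articles=3, dropout_rate=0.0,
            n_partial_sessions=0, rng_seed=3, blink_rate_per_min=0.0)
        study = rg.generate_study(cfg)
        aois = {a: lay.aois for a, lay in study.layouts.items()}
        _, sac, _ = rg.extract_study_events(study.gaze, aois)
        nonblink = sac[~sac["is_blink"]]
        sweep = (nonblink["dx_px"] <= -20) & (nonblink["dy_px"] >= 20)
        non_sweep = nonblink[~sweep]
        rate = non_sweep["is_regression"].mean()
        assert rate < 0.02


class TestPeakSpeed:
    def test_stationary_interval_zero_speed(self, stream_factory):
        stream = stream_factory([(300, 400, 18), (300, 400, 1),
                                 (300, 400, 18)])
        fix = rg.detect_fixations(stream)
        # a single stationary cluster: no saccade, so construct one manually
        assert len(fix) == 1
        t = stream["time_ms"].to_numpy()
        x, y, _ = _binocular_position(stream)
        speeds = np.hypot(np.diff(x), np.diff(y)) / np.diff(t)
        assert np.max(speeds) == 0.0

    def test_sixty_degrees_per_second(self, geometry, stream_factory):
        one_deg_px = geometry.deg_to_px(1.0)
        stream = stream_factory([(300, 400, 18),
                                 (300 + one_deg_px, 400, 18)])
        fix = rg.detect_fixations(stream, geometry, dispersion_deg=0.5)
        sac = rg.derive_saccades(fix, stream, geometry)
        # 1 degree crossed in one 16.67 ms inter-sample interval
        assert sac["peak_speed_deg_s"].iloc[0] == pytest.approx(60.0,
                                                                rel=0.01)

    def test_equals_brute_force_max_over_pairs(self, small_study, geometry):
        stream = next(iter(small_study.gaze.values()))
        fix = rg.detect_fixations(stream, geometry)
        sac = rg.derive_saccades(fix, stream, geometry)
        t = stream["time_ms"].to_numpy()
        x, y, _ = _binocular_position(stream)
        for _, row in sac.head(50).iterrows():
            idx = np.flatnonzero((t >= row.onset_ms) & (t <= row.offset_ms))
            best = 0.0
            for a, b in zip(idx[:-1], idx[1:]):
                d = float(geometry.px_to_deg(np.hypot(x[b] - x[a],
                                                      y[b] - y[a])))
                best = max(best, d / ((t[b] - t[a]) / 1000.0))
            assert row.peak_speed_deg_s == pytest.approx(best, rel=1e-9)
            assert rg.peak_speed(row, stream, geometry) == pytest.approx(
                best, rel=1e-9)


class TestAoiFilter:
    AOIS = {"title": [100, 50, 900, 120], "content": [100, 150, 900, 800]}

    def _fixations(self, points):
        return pd.DataFrame({
            "onset_ms": np.arange(len(points)) * 400.0,
            "offset_ms": np.arange(len(points)) * 400.0 + 300.0,
            "duration_ms": 300.0,
            "centroid_x_px": [p[0] for p in points],
            "centroid_y_px": [p[1] for p in points],
            "mean_pupil_px": 25.0,
        })

    def test_inside_content_kept(self):
        fix = self._fixations([(500, 400)])
        out, _ = rg.filter_aoi(fix, pd.DataFrame(columns=["fix_from",
                                                          "fix_to"]),
                               self.AOIS)
        assert len(out) == 1 and out["aoi_label"].iloc[0] == "content"

    def test_max_edge_is_exclusive(self):
        fix = self._fixations([(900, 400), (100, 800), (100, 150)])
        out, _ = rg.filter_aoi(fix, pd.DataFrame(columns=["fix_from",
                                                          "fix_to"]),
                               self.AOIS)
        # half-open: x=900 and y=800 fall outside, min edges inside
        assert len(out) == 1
        assert out["centroid_y_px"].iloc[0] == 150

    def test_missing_aois_is_an_error(self):
        with pytest.raises(ValueError, match="AOI"):
            rg.filter_aoi(self._fixations([(1, 1)]), pd.DataFrame(), {})

    def test_mixed_set_brute_force_membership(self, geometry):
        rng = np.random.default_rng(5)
        pts = [(500, 400)] * 6 + [(50, 50), (1000, 900), (950, 400),
                                  (500, 130)]
        rng.shuffle(pts)
        fix = self._fixations(pts)
        stream = pd.DataFrame({
            "time_ms": np.arange(len(pts) * 2) * 200.0,
            "left_x_px": 500.0, "left_y_px": 400.0,
            "right_x_px": 500.0, "right_y_px": 400.0,
            "left_pupil_px": 25.0, "right_pupil_px": 25.0})
        sac = rg.derive_saccades(fix, stream, geometry)
        kept_fix, kept_sac = rg.filter_aoi(fix, sac, self.AOIS)

        def inside(p):
            return any(r[0] <= p[0] < r[2] and r[1] <= p[1] < r[3]
                       for r in self.AOIS.values())

        assert len(kept_fix) == sum(inside(p) for p in pts) == 6
        expected_sac = sum(inside(a) and inside(b)
                           for a, b in zip(pts[:-1], pts[1:]))
        assert len(kept_sac) == expected_sac
        # remapped indices must point at the filtered fixation table
        if len(kept_sac):
            assert kept_sac["fix_to"].max() <= len(kept_fix) - 1
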
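"""Wave-dynamics metrics on constructed traces: CV, AFCL, DF, phase, PS."""

import math

import numpy as np
import pytest

from afvtrial import wavedyn
from afvtrial.substrate import Geometry
from afvtrial.tissue import SimulationTrace
from afvtrial.wavedyn import (
    WaveMetrics,
    afcl,
    cv_between,
    dominant_frequency,
    phase_field,
    ps_detect,
    ps_track,
    smax_map,
)


def make_trace(t, frames):
    return SimulationTrace(t=np.asarray(t, dtype=float),
                           frames=np.asarray(frames, dtype=np.float32),
                           stimulus_log=[])


def periodic_trace(freq_hz, n_nodes=6, dur_ms=4000.0, dt_ms=1.0,
                   amplitude=40.0, baseline=-60.0):
    t = np.arange(0.0, dur_ms, dt_ms)
    v = baseline + amplitude * np.sin(2 * np.pi * freq_hz * t / 1000.0)
    fr = np.tile(v[:, None, None], (1, 1, n_nodes))
    return make_trace(t, fr)


class TestCvBetween:
    def setup_method(self):
        self.geom = Geometry(nx=80, ny=80, spacing=0.5)

    def test_hand_arithmetic(self):
        """35 mm in 50 ms -> 0.7 m/s."""
        lat = np.full((80, 80), np.nan)
        lat[0, 0], lat[0, 70] = 10.0, 60.0
        cv = cv_between(lat, (0, 0), (0, 70), self.geom)
        assert cv == pytest.approx(0.7)

    def test_doubling_distance_doubles_cv(self):
        lat = np.zeros((80, 80))
        lat[0, 20], lat[0, 40] = 40.0, 40.0
        lat[0, 0] = 0.0
        cv1 = cv_between(lat, (0, 0), (0, 20), self.geom)
        cv2 = cv_between(lat, (0, 0), (0, 40), self.geom)
        assert cv2 == pytest.approx(2 * cv1)

    def test_same_node_rejected(self):
        lat = np.zeros((80, 80))
        with pytest.raises(ValueError):
            cv_between(lat, (3, 3), (3, 3), self.geom)

    def test_upstream_b_rejected(self):
        lat = np.zeros((80, 80))
        lat[0, 0], lat[0, 10] = 50.0, 10.0
        with pytest.raises(ValueError, match="after"):
            cv_between(lat, (0, 0), (0, 10), self.geom)


class TestAfcl:
    def test_periodic_pacing_recovers_cycle_length(self):
        tr = periodic_trace(6.0)     # 6 Hz -> 166.7 ms
        val = afcl(tr, 0.0, 4000.0, node_stride=1)
        assert val == pytest.approx(1000.0 / 6.0, abs=2.0)

    def test_mean_of_node_means(self):
        """Two nodes with intervals {150,160} and {170,180} -> 165 ms."""
        t = np.arange(0.0, 700.0, 1.0)
        fr = np.full((len(t), 1, 2), -80.0, dtype=np.float32)

        def spike(node, when):
            i = np.searchsorted(t, when)
            fr[i:i + 20, 0, node] = 0.0

        for when in (10.0, 160.0, 320.0):          # intervals 150, 160
            spike(0, when)
        for when in (10.0, 180.0, 360.0):          # intervals 170, 180
            spike(1, when)
        tr = make_trace(t, fr)
        assert afcl(tr, 0.0, 700.0, node_stride=1) == pytest.approx(165.0, abs=1.0)

    def test_quiescent_window_undefined(self):
        t = np.arange(0.0, 3000.0, 1.0)
        fr = np.full((len(t), 2, 2), -80.0, dtype=np.float32)
        assert math.isnan(afcl(make_trace(t, fr), 0.0, 3000.0, node_stride=1))


class TestDominantFrequency:
    def test_pure_sinusoid(self):
        tr = periodic_trace(6.0)
        _, peak, mean = dominant_frequency(tr, 0.0, 4000.0, node_stride=1)
        assert peak == pytest.approx(6.0, abs=0.3)
        assert mean == pytest.approx(6.0, abs=0.3)

    def test_split_population(self):
        """Half nodes at 4 Hz, half at 8 Hz: mean 6 Hz, peak 8 Hz."""
        t = np.arange(0.0, 4000.0, 1.0)
        v4 = -60 + 40 * np.sin(2 * np.pi * 4.0 * t / 1000.0)
        v8 = -60 + 40 * np.sin(2 * np.pi * 8.0 * t / 1000.0)
        fr = np.stack([np.tile(v4[:, None], (1, 2)),
                       np.tile(v8[:, None], (1, 2))], axis=1)
        tr = make_trace(t, fr)
        _, peak, mean = dominant_frequency(tr, 0.0, 4000.0, node_stride=1)
        assert peak == pytest.approx(8.0, abs=0.3)
        assert mean == pytest.approx(6.0, abs=0.3)

    def test_dominant_component_wins(self):
        t = np.arange(0.0, 4000.0, 1.0)
        v = (-60 + 40 * np.sin(2 * np.pi * 7.0 * t / 1000.0)
             + 15 * np.sin(2 * np.pi * 4.0 * t / 1000.0))
        fr = np.tile(v[:, None, None], (1, 1, 4))
        _, peak, _ = dominant_frequency(make_trace(t, fr), 0.0, 4000.0,
                                        node_stride=1)
        assert peak == pytest.approx(7.0, abs=0.3)

    def test_short_window_rejected(self):
        tr = periodic_trace(6.0, dur_ms=1000.0)
        with pytest.raises(ValueError, match="2 s"):
            dominant_frequency(tr, 0.0, 1000.0)

    def test_peak_ge_mean_always(self):
        tr = periodic_trace(5.0)
        _, peak, mean = dominant_frequency(tr, 0.0, 4000.0, node_stride=1)
        assert peak >= mean


class TestPhase:
    def test_sinusoid_phase_advances_and_wraps(self):
        tr = periodic_trace(5.0, dur_ms=2000.0)
        phase, mask = phase_field(tr, 0.0, 2000.0)
        assert mask.all()
        p = phase[:, 0, 0]
        assert p.min() < -3.0 and p.max() > 3.0       # wraps
        # unwrapped phase advances by ~2*pi per 200 ms period
        un = np.unwrap(p[200:1800])
        rate = (un[-1] - un[0]) / (1.6)               # rad per s
        assert rate == pytest.approx(2 * np.pi * 5.0, rel=0.05)

    def test_constant_signal_masked(self):
        t = np.arange(0.0, 2000.0, 1.0)
        fr = np.full((len(t), 2, 2), -80.0, dtype=np.float32)
        _, mask = phase_field(make_trace(t, fr), 0.0, 2000.0)
        assert not mask.any()

    def test_quarter_period_offset_is_half_pi(self):
        t = np.arange(0.0, 2000.0, 1.0)
        w = 2 * np.pi * 5.0 / 1000.0
        a = np.sin(w * t)
        b = np.sin(w * (t - 50.0))                    # quarter of 200 ms
        fr = np.stack([a, b], axis=1)[:, :, None]
        phase, _ = phase_field(make_trace(t, fr), 0.0, 2000.0)
        dp = np.angle(np.exp(1j * (phase[500:1500, 0, 0]
                                   - phase[500:1500, 1, 0])))
        assert np.mean(dp) == pytest.approx(np.pi / 2, abs=0.1)


class TestPsDetect:
    def test_planar_wave_has_no_singularity(self):
        ys, xs = np.mgrid[0:40, 0:40]
        phase = np.angle(np.exp(1j * 0.3 * xs))
        assert ps_detect(phase) == []

    def test_analytic_spiral_has_one_positive_ps(self):
        ys, xs = np.mgrid[0:41, 0:41]
        phase = np.arctan2(ys - 20.0 + 0.5, xs - 20.0 + 0.5)
        found = ps_detect(phase)
        assert len(found) == 1
        x, y, q = found[0]
        assert q == 1
        assert math.hypot(x - 20.0, y - 20.0) < 1.5

    def test_negated_spiral_flips_charge(self):
        ys, xs = np.mgrid[0:41, 0:41]
        phase = -np.arctan2(ys - 20.0 + 0.5, xs - 20.0 + 0.5)
        found = ps_detect(phase)
        assert len(found) == 1
        assert found[0][2] == -1

    def test_total_charge_of_opposite_pair_is_zero(self):
        ys, xs = np.mgrid[0:60, 0:60]
        phase = np.angle(np.exp(1j * (
            np.arctan2(ys - 30.0 + 0.5, xs - 15.0 + 0.5)
            - np.arctan2(ys - 30.0 + 0.5, xs - 45.0 + 0.5))))
        found = ps_detect(phase)
        assert sum(q for _, _, q in found) == 0
        assert len(found) == 2


class TestPsTrack:
    def test_stationary_ps_counts_and_lifespan(self):
        frames = [[(10.0, 10.0, 1)] for _ in range(100)]
        tracks, n_ps, life = ps_track(frames, frame_dt=1.0, spacing=1.0)
        assert n_ps == 100
        assert len(tracks) == 1
        assert life == pytest.approx(99.0)

    def test_empty_frames(self):
        tracks, n_ps, life = ps_track([[] for _ in range(50)], 1.0)
        assert tracks == [] and n_ps == 0
        assert math.isnan(life)

    def test_association_respects_charge(self):
        """Two opposite-charge PSs crossing paths never swap charges."""
        frames = []
        for i in range(20):
            frames.append([(float(i), 10.0, 1), (float(19 - i), 10.0, -1)])
        tracks, n_ps, _ = ps_track(frames, 1.0, max_jump_mm=3.0, spacing=1.0)
        assert n_ps == 40
        for tr in tracks:
            xs = [p[0] for p in tr.positions]
            steps = np.abs(np.diff(xs))
            assert (steps <= 3.0).all()
            if tr.charge == 1:
                assert xs[-1] >= xs[0]
            else:
                assert xs[-1] <= xs[0]


class TestSmaxMap:
    @staticmethod
    def _samples(y0, a1, tau1):
        di = np.linspace(40.0, 350.0, 10)
        return list(zip(di, y0 + a1 * (1 - np.exp(-di / tau1))))

    def test_argmax_at_injected_steep_node(self):
        per_node = {(0, 0): self._samples(60, 150, 100),
                    (0, 1): self._samples(60, 150, 100),
                    (5, 5): self._samples(60, 250, 40)}
        mean_smax, argmax, per = smax_map(per_node)
        assert argmax == (5, 5)
        assert len(per) == 3
        assert mean_smax > 0

    def test_flat_restitution_is_zero(self):
        per_node = {(i, 0): [(d, 150.0) for d in (50, 100, 200, 300)]
                    for i in range(4)}
        mean_smax, _, _ = smax_map(per_node)
        assert mean_smax == pytest.approx(0.0, abs=1e-6)

    def test_insufficient_nodes_excluded(self):
        per_node = {(0, 0): self._samples(60, 150, 100),
                    (1, 1): [(100.0, 200.0)]}        # too few samples
        _, _, per = smax_map(per_node)
        assert (1, 1) not in per


class TestWaveMetricsInvariants:
    def test_peak_below_mean_rejected(self):
        m = WaveMetrics(peak_df=4.0, mean_df=6.0)
        with pytest.raises(ValueError):
            m.validate()

    def test_row_uses_table_column_names(self):
        row = WaveMetrics().as_row()
        assert set(row) == set(wavedyn.METRIC_COLUMNS)
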
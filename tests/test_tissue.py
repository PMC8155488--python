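"""Monodomain solver: conservation, isochrones, termination, LAT, CV laws."""

import math

import numpy as np
import pytest

from afvtrial import cellmodel, substrate as sub_mod, tissue
from afvtrial.cellmodel import ConductanceScales
from afvtrial.substrate import Geometry, Substrate
from afvtrial.tissue import (
    SimulationTrace,
    StimulusProtocol,
    burst_protocol,
    detect_termination,
    initial_field,
    lat_map,
    plane_wave_cv,
    run_tissue,
    s1_protocol,
    step_tissue,
)

IDENT = ConductanceScales.identity()


def uniform_sheet(n=41, spacing=0.5, d_long=0.1, aniso=1.0, angle=0.0):
    geom = Geometry(nx=n, ny=n, spacing=spacing)
    return Substrate(geometry=geom,
                     voltage=np.full(geom.shape, 5.0),
                     fibrotic=np.zeros(geom.shape, dtype=bool),
                     fiber_angle=np.full(geom.shape, angle),
                     d_long=d_long, anisotropy=aniso)


class TestDiffusionOperator:
    def test_uniform_field_diffuses_to_exactly_zero(self):
        sub = uniform_sheet()
        wE, wW, wN, wS, cxy = tissue._diffusion_weights(sub)
        v = np.full(sub.geometry.shape, -37.5)
        out = np.empty_like(v)
        tissue._diffuse(v, wE, wW, wN, wS, cxy, out)
        assert (out == 0.0).all()

    def test_axis_fluxes_conserve_total_charge(self):
        """No-flux boundaries: the flux-form axis terms sum to zero over the
        sheet for any field (cross terms off for a fiber-aligned sheet)."""
        sub = uniform_sheet(aniso=2.0)      # angle 0 -> Dxy = 0
        wE, wW, wN, wS, cxy = tissue._diffusion_weights(sub)
        assert (cxy == 0.0).all()
        rng = np.random.default_rng(0)
        v = rng.uniform(-80, 20, sub.geometry.shape)
        out = np.empty_like(v)
        tissue._diffuse(v, wE, wW, wN, wS, cxy, out)
        assert abs(out.sum()) < 1e-9 * np.abs(out).sum()

    def test_fibrotic_nodes_are_no_flux_holes(self):
        sub = uniform_sheet(n=21)
        sub.fibrotic[10, 10] = True
        wE, wW, wN, wS, cxy = tissue._diffusion_weights(sub)
        assert wE[10, 9] == 0.0 and wW[10, 11] == 0.0
        assert wN[9, 10] == 0.0 and wS[11, 10] == 0.0

    def test_uniform_resting_field_stays_spatially_uniform(self):
        sub = uniform_sheet(n=11)
        y = initial_field(sub)
        step_tissue(y, sub, IDENT, dt=0.05, n_steps=200)
        v = y[0]
        assert v.max() - v.min() < 1e-12


class TestStepAndStability:
    def test_cfl_violation_rejected(self):
        sub = uniform_sheet(d_long=1.0)
        y = initial_field(sub)
        with pytest.raises(ValueError, match="stability"):
            step_tissue(y, sub, IDENT, dt=0.2, n_steps=1)

    def test_instability_aborts_with_diagnostics(self):
        sub = uniform_sheet(n=11, d_long=0.01)
        proto = StimulusProtocol("S1_train", (5, 5), (1.0,), amplitude=1e4)
        with pytest.raises(FloatingPointError, match="200 mV"):
            run_tissue(sub, IDENT, proto, 60.0, dt=0.05, record_dt=1.0)

    def test_determinism_bit_identical(self):
        sub = sub_mod.build_substrate(seed=3, size_mm=12.0, spacing=0.5,
                                      d_long=0.1, anisotropy=2.0)
        proto = s1_protocol(sub.landmarks["septal_pacing_site"], 300.0, 1)
        a, _ = run_tissue(sub, IDENT, proto, 120.0, dt=0.05)
        b, _ = run_tissue(sub, IDENT, proto, 120.0, dt=0.05)
        assert np.array_equal(a.frames, b.frames)
        assert np.array_equal(a.activation_times, b.activation_times,
                              equal_nan=True)

    def test_lut_reaction_matches_exact_single_cell(self):
        """Tissue fast path against the exact ODE path on decoupled nodes."""
        sub = uniform_sheet(n=3, d_long=1e-6)
        ys, xs = np.mgrid[0:3, 0:3]
        proto = StimulusProtocol("S1_train", (1, 1), (1.0,),
                                 amplitude=25.0, duration=2.0, site_radius=5.0)
        tr, _ = run_tissue(sub, IDENT, proto, 400.0, dt=0.02, record_dt=0.5)
        apd_tissue = cellmodel.measure_apd90(tr.t, tr.frames[:, 1, 1].astype(float))
        cell = cellmodel.pace_cell(IDENT, 600.0, 1, dt=0.02,
                                   stim_amplitude=25.0)
        apd_cell = cellmodel.measure_apd90(*cell.beat(0))
        # tabulated kinetics track the exact path to within a few ms of APD
        assert apd_tissue == pytest.approx(apd_cell, abs=5.0)


class TestWavefronts:
    def test_isotropic_isochrones_are_circular(self):
        sub = uniform_sheet(n=61, d_long=0.15)
        proto = StimulusProtocol("S1_train", (30, 30), (1.0,),
                                 amplitude=80.0, duration=2.0, site_radius=1.0)
        tr, _ = run_tissue(sub, IDENT, proto, 40.0, dt=0.05, record_dt=5.0)
        act = tr.activation_times
        # radius reached along +x, -x, +y, -y at matched activation time
        radii = []
        for d in range(5, 30):
            times = [act[30, 30 + d], act[30, 30 - d],
                     act[30 + d, 30], act[30 - d, 30]]
            if any(math.isnan(t) for t in times):
                break
            radii.append(times)
        radii = np.array(radii[5:])          # skip the stimulus footprint
        assert len(radii) >= 5
        spread = radii.max(axis=1) / radii.min(axis=1)
        assert spread.max() < 1.05           # < 5% eccentricity

    def test_anisotropic_axis_ratio_follows_sqrt_d(self):
        """4:1 diffusion anisotropy gives ~2:1 elliptical isochrones (the
        transverse axis runs slightly slower than the sqrt-D plane-wave
        ratio because of wavefront curvature)."""
        sub = uniform_sheet(n=161, spacing=0.25, d_long=0.2, aniso=4.0)
        proto = StimulusProtocol("S1_train", (80, 80), (1.0,),
                                 amplitude=80.0, duration=2.0,
                                 site_radius=0.75)
        tr, _ = run_tissue(sub, IDENT, proto, 30.0, dt=0.05, record_dt=5.0)
        act = tr.activation_times
        t_ref = act[80, 80 + 60]             # along fibers (x)
        assert not math.isnan(t_ref)
        col = act[80:, 80]                   # across fibers (y)
        reached = np.nonzero(col <= t_ref)[0]
        ry = reached.max()
        assert 60 / ry == pytest.approx(2.0, rel=0.2)

    def test_cv_scales_as_sqrt_of_diffusion(self):
        cv1 = plane_wave_cv(0.1, IDENT, dt=0.05)
        cv2 = plane_wave_cv(0.2, IDENT, dt=0.05)
        assert cv2 / cv1 == pytest.approx(math.sqrt(2.0), rel=0.05)

    def test_spatial_refinement_changes_cv_below_5pct(self):
        """In the converged-resolution regime, halving the spacing moves the
        plane-wave CV by under 5%."""
        cv_h = plane_wave_cv(0.1, IDENT, n_nodes=120, spacing=0.125, dt=0.005)
        cv_h2 = plane_wave_cv(0.1, IDENT, n_nodes=240, spacing=0.0625,
                              dt=0.005)
        assert cv_h == pytest.approx(cv_h2, rel=0.05)


class TestTermination:
    @staticmethod
    def _trace(v_fun, dur=8000.0, dt=1.0):
        t = np.arange(0.0, dur, dt)
        fr = np.asarray(v_fun(t), dtype=np.float32)
        tr = SimulationTrace(t=t, frames=fr, stimulus_log=[])
        tr.induction_end = 1000.0
        return tr

    def test_all_resting_terminates_at_induction_end(self):
        tr = self._trace(lambda t: np.full((len(t), 4, 4), -80.0))
        assert detect_termination(tr) == pytest.approx(1000.0, abs=2.0)

    def test_persistent_oscillation_never_terminates(self):
        def osc(t):
            v = -60 + 40 * np.sin(2 * np.pi * 6.0 * t / 1000.0)
            return np.tile(v[:, None, None], (1, 4, 4))
        assert detect_termination(self._trace(osc)) is None

    def test_quiescence_from_4000ms_with_500ms_window(self):
        def late_quiet(t):
            # oscillation that never dips below the activation threshold,
            # then abrupt quiescence at t = 4000 ms
            v = np.where(t < 4000.0,
                         -20 + 15 * np.sin(2 * np.pi * 6.0 * t / 1000.0),
                         -80.0)
            return np.tile(v[:, None, None], (1, 3, 3))
        tr = self._trace(late_quiet)
        assert detect_termination(tr, quiescence_window=500.0) == pytest.approx(
            4000.0, abs=5.0)

    def test_missing_induction_marker_rejected(self):
        tr = self._trace(lambda t: np.full((len(t), 2, 2), -80.0))
        tr.induction_end = None
        with pytest.raises(ValueError):
            detect_termination(tr)


class TestLatMap:
    def test_plane_wave_lat_range_matches_distance_over_speed(self):
        """50 mm at the measured plane-wave speed spans distance/CV in LAT."""
        geom = Geometry(nx=101, ny=3, spacing=0.5)
        sub = Substrate(geometry=geom, voltage=np.full(geom.shape, 5.0),
                        fibrotic=np.zeros(geom.shape, dtype=bool),
                        fiber_angle=np.zeros(geom.shape),
                        d_long=0.1, anisotropy=1.0)
        proto = StimulusProtocol("S1_train", (1, 0), (1.0,), amplitude=80.0,
                                 duration=2.0, site_radius=1.0)
        tr, _ = run_tissue(sub, IDENT, proto, 250.0, dt=0.05, record_dt=1.0)
        lat = lat_map(tr, 0.0, 250.0)
        row = lat[1]
        assert not np.isnan(row).any()
        assert np.nanargmin(row) <= 2        # stimulus end activates first
        cv = plane_wave_cv(0.1, IDENT, spacing=0.5, dt=0.05)
        expected_range = 0.5 * 90 / cv       # central 90 nodes
        measured = row[95] - row[5]
        assert measured == pytest.approx(expected_range, rel=0.15)

    def test_reduced_coupling_crosses_a_scar_wall(self):
        """A solid fibrotic wall blocks conduction when fibrosis is
        non-conducting but lets a slowed wave through in reduced-coupling
        mode."""
        results = {}
        for mode in ("non_conducting", "reduced_coupling"):
            sub = uniform_sheet(n=31, d_long=0.15)
            sub.fibrotic[:, 15] = True
            sub.fibrosis_mode = mode
            proto = StimulusProtocol("S1_train", (15, 2), (1.0,),
                                     amplitude=80.0, duration=2.0,
                                     site_radius=1.5)
            tr, _ = run_tissue(sub, IDENT, proto, 120.0, dt=0.05,
                               record_dt=2.0)
            results[mode] = tr.activation_times[15, 25]
        assert math.isnan(results["non_conducting"])
        assert not math.isnan(results["reduced_coupling"])

    def test_fibrotic_nodes_have_missing_lat(self):
        sub = uniform_sheet(n=21, d_long=0.15)
        sub.fibrotic[5, 5] = True
        proto = StimulusProtocol("S1_train", (10, 10), (1.0,), amplitude=80.0,
                                 duration=2.0, site_radius=1.0)
        tr, _ = run_tissue(sub, IDENT, proto, 60.0, dt=0.05, record_dt=1.0)
        lat = lat_map(tr, 0.0, 60.0)
        assert math.isnan(lat[5, 5])
        assert not math.isnan(lat[10, 10])


class TestProtocols:
    def test_burst_ramps_cycle_length_down(self):
        p = burst_protocol((0, 0), cl_start=200.0, cl_end=120.0, n_stimuli=20)
        assert len(p.onsets) == 20
        gaps = np.diff(p.onsets)
        assert gaps[0] == pytest.approx(200.0)
        assert gaps[-1] == pytest.approx(120.0)
        assert (np.diff(gaps) <= 1e-9).all()

    def test_nonincreasing_onsets_rejected(self):
        with pytest.raises(ValueError):
            StimulusProtocol("S1_train", (0, 0), (5.0, 4.0))
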
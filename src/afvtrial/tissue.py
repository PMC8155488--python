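"""Monodomain tissue solver on a monolayer substrate.

Couples the atrial cell model over a 2D lattice through an anisotropic
diffusion operator (finite-volume 5-point fluxes for the axis terms plus a
centered 9-point cross-derivative term), with no-flux outer boundaries and
zero-flux fibrotic holes.  Operator splitting per step: explicit diffusion
on V, then the Rush–Larsen/Euler reaction step of every conducting node.

Conventions: the diffusion tensor per node is
``D = D_T I + (D_L - D_T) f f^T`` with ``f`` the local fiber unit vector
and ``D_T = D_L / anisotropy``; spacing in mm, D in mm^2/ms, so CV comes
out in mm/ms (= m/s).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numba import njit

from .cellmodel import (
    N_STATES,
    SCALE_NAMES,
    _RESTING,
    _TAU_FCA,
    _TAU_U,
    _step_cell_lut,
    build_rate_table,
    ConductanceScales,
)
from .substrate import Substrate

__all__ = [
    "StimulusProtocol",
    "SimulationTrace",
    "step_tissue",
    "run_tissue",
    "run_case",
    "CaseResult",
    "plane_wave_cv",
    "detect_termination",
    "lat_map",
    "burst_protocol",
    "s1_protocol",
]

#: V threshold (mV) defining "activated" for termination and LAT bookkeeping.
ACTIVATION_THRESHOLD = -40.0


# ---------------------------------------------------------------------------
# Stimulus protocols
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StimulusProtocol:
    """A train of rectangular stimuli at one site.

    ``kind`` is descriptive ("S1_train", "ramp", "burst_induction");
    ``onsets`` are stimulus start times in ms; the stimulated region is a
    disc of ``site_radius`` mm around lattice node ``site`` (iy, ix).
    """

    kind: str
    site: tuple[int, int]
    onsets: tuple[float, ...]
    amplitude: float = 80.0          # pA/pF
    duration: float = 2.0            # ms
    site_radius: float = 1.0         # mm

    def __post_init__(self) -> None:
        if len(self.onsets) == 0:
            raise ValueError("protocol needs at least one stimulus")
        if any(b <= a for a, b in zip(self.onsets, self.onsets[1:])):
            raise ValueError("stimulus onsets must be strictly increasing")
        if self.duration <= 0 or self.amplitude < 0:
            raise ValueError("invalid stimulus shape")

    @property
    def end(self) -> float:
        return self.onsets[-1] + self.duration


def s1_protocol(
    site: tuple[int, int],
    cycle_length: float = 600.0,
    n_beats: int = 6,
    t0: float = 1.0,
    **kw,
) -> StimulusProtocol:
    """Constant-CL S1 pacing train."""
    onsets = tuple(t0 + cycle_length * k for k in range(n_beats))
    return StimulusProtocol("S1_train", site, onsets, **kw)


def burst_protocol(
    site: tuple[int, int],
    cl_start: float = 200.0,
    cl_end: float = 120.0,
    n_stimuli: int = 20,
    t0: float = 1.0,
    **kw,
) -> StimulusProtocol:
    """AF-induction burst: ``n_stimuli`` beats with CL ramped down linearly."""
    cls = np.linspace(cl_start, cl_end, max(n_stimuli - 1, 1))
    onsets = [t0]
    for cl in cls[: n_stimuli - 1]:
        onsets.append(onsets[-1] + cl)
    return StimulusProtocol("burst_induction", site, tuple(onsets), **kw)


def ramp_protocol(
    site: tuple[int, int],
    cycle_lengths: Sequence[float] | None = None,
    beats_per_cl: int = 8,
    t0: float = 1.0,
    **kw,
) -> StimulusProtocol:
    """Decremental-ramp restitution pacing (S1 stages of decreasing CL)."""
    if cycle_lengths is None:
        cycle_lengths = np.arange(600.0, 199.0, -25.0)
    onsets = [t0]
    for cl in cycle_lengths:
        for _ in range(beats_per_cl):
            onsets.append(onsets[-1] + cl)
    return StimulusProtocol("ramp", site, tuple(onsets[:-1]), **kw)


# ---------------------------------------------------------------------------
# Diffusion operator assembly
# ---------------------------------------------------------------------------

def _diffusion_weights(sub: Substrate) -> tuple[np.ndarray, ...]:
    """Edge weights (1/ms) for the masked anisotropic Laplacian.

    Axis terms are finite-volume fluxes with arithmetic-mean edge
    diffusivity, zeroed on edges that cross the boundary or touch a
    fibrotic node (no-flux).  In reduced-coupling mode fibrotic nodes stay
    in the tissue with their diffusivity scaled down instead.  The cross
    term uses the node's own Dxy and is dropped wherever any of the four
    diagonal neighbors is missing.
    """
    h = sub.geometry.spacing
    th = sub.fiber_angle
    dl = sub.d_long
    dt_ = dl / sub.anisotropy
    dxx = dt_ + (dl - dt_) * np.cos(th) ** 2
    dyy = dt_ + (dl - dt_) * np.sin(th) ** 2
    dxy = (dl - dt_) * np.sin(th) * np.cos(th)
    if sub.fibrosis_mode == "reduced_coupling":
        scale = np.where(sub.fibrotic, sub.fibrotic_coupling, 1.0)
        dxx = dxx * scale
        dyy = dyy * scale
        dxy = dxy * scale

    cond = sub.conducting
    ny, nx = cond.shape
    wE = np.zeros((ny, nx))
    wN = np.zeros((ny, nx))
    wE[:, :-1] = 0.5 * (dxx[:, :-1] + dxx[:, 1:]) / h**2
    wE[:, :-1] *= cond[:, :-1] & cond[:, 1:]
    wN[:-1, :] = 0.5 * (dyy[:-1, :] + dyy[1:, :]) / h**2
    wN[:-1, :] *= cond[:-1, :] & cond[1:, :]
    wW = np.zeros_like(wE)
    wW[:, 1:] = wE[:, :-1]
    wS = np.zeros_like(wN)
    wS[1:, :] = wN[:-1, :]

    cxy = dxy / (4.0 * h**2)
    ok = cond.copy()
    ok[[0, -1], :] = False
    ok[:, [0, -1]] = False
    inner = ok.copy()
    inner[1:-1, 1:-1] &= (cond[:-2, :-2] & cond[:-2, 2:]
                          & cond[2:, :-2] & cond[2:, 2:])
    cxy = np.where(inner, cxy, 0.0)
    return wE, wW, wN, wS, cxy


@njit(cache=True)
def _diffuse(v, wE, wW, wN, wS, cxy, out):
    """out = div(D grad v) with masked no-flux edges."""
    ny, nx = v.shape
    for iy in range(ny):
        for ix in range(nx):
            acc = 0.0
            if ix + 1 < nx:
                acc += wE[iy, ix] * (v[iy, ix + 1] - v[iy, ix])
            if ix - 1 >= 0:
                acc += wW[iy, ix] * (v[iy, ix - 1] - v[iy, ix])
            if iy + 1 < ny:
                acc += wN[iy, ix] * (v[iy + 1, ix] - v[iy, ix])
            if iy - 1 >= 0:
                acc += wS[iy, ix] * (v[iy - 1, ix] - v[iy, ix])
            c = cxy[iy, ix]
            if c != 0.0:
                acc += 2.0 * c * (v[iy + 1, ix + 1] - v[iy + 1, ix - 1]
                                  - v[iy - 1, ix + 1] + v[iy - 1, ix - 1])
            out[iy, ix] = acc


@njit(cache=True)
def _run_kernel(y, cond, wE, wW, wN, wS, cxy, svec, dt, n_steps, t_offset,
                stim_starts, stim_dur, stim_amp, stim_mask,
                frames, frame_stride, act_time, act_refrac,
                tab, rlf_fca, rlf_u):
    """Advance the tissue ``n_steps`` steps, recording decimated V frames.

    ``y``: (N_STATES, ny, nx); ``frames``: (n_frames, ny, nx) float32 is
    filled every ``frame_stride`` steps.  ``act_time`` logs every upward
    crossing of the activation threshold (latest crossing per node);
    ``act_refrac`` is working memory.  Returns 0 on success, 1 on
    numerical blow-up.
    """
    ny = y.shape[1]
    nx = y.shape[2]
    dv = np.empty((ny, nx))
    n_stim = stim_starts.size
    ptr = 0
    rec = 0
    yflat = y.reshape(N_STATES, ny * nx)
    for i in range(n_steps):
        t = t_offset + i * dt
        while ptr < n_stim and t >= stim_starts[ptr] + stim_dur:
            ptr += 1
        stim_on = ptr < n_stim and stim_starts[ptr] <= t < stim_starts[ptr] + stim_dur

        _diffuse(y[0], wE, wW, wN, wS, cxy, dv)

        for iy in range(ny):
            for ix in range(nx):
                if not cond[iy, ix]:
                    continue
                k = iy * nx + ix
                v_old = y[0, iy, ix]
                istim = stim_amp if (stim_on and stim_mask[iy, ix]) else 0.0
                _step_cell_lut(yflat, k, svec, istim, dt, tab, rlf_fca, rlf_u)
                y[0, iy, ix] += dt * dv[iy, ix]
                v_new = y[0, iy, ix]
                if v_new > 200.0 or v_new < -200.0 or v_new != v_new:
                    return 1
                # log upward threshold crossings (with a simple refractory latch)
                if act_refrac[iy, ix] == 0:
                    if v_old < ACTIVATION_THRESHOLD <= v_new:
                        act_time[iy, ix] = t
                        act_refrac[iy, ix] = 1
                else:
                    if v_new < ACTIVATION_THRESHOLD - 10.0:
                        act_refrac[iy, ix] = 0

        if i % frame_stride == 0 and rec < frames.shape[0]:
            for iy in range(ny):
                for ix in range(nx):
                    frames[rec, iy, ix] = y[0, iy, ix]
            rec += 1
    return 0


# ---------------------------------------------------------------------------
# Public stepping / running API
# ---------------------------------------------------------------------------

def initial_field(sub: Substrate) -> np.ndarray:
    """Resting-state field, shape (N_STATES, ny, nx)."""
    ny, nx = sub.geometry.shape
    y = np.empty((N_STATES, ny, nx))
    y[:] = _RESTING[:, None, None]
    return y


def step_tissue(
    y: np.ndarray,
    sub: Substrate,
    scales: ConductanceScales,
    dt: float = 0.05,
    n_steps: int = 1,
    stim_mask: np.ndarray | None = None,
    stim_amp: float = 0.0,
) -> np.ndarray:
    """Advance the state field in place by ``n_steps`` (diffusion + reaction).

    Exposed mainly for tests and small experiments; long runs should go
    through :func:`run_tissue` which also records frames and activations.
    """
    _check_cfl(sub, dt)
    ny, nx = sub.geometry.shape
    wE, wW, wN, wS, cxy = _diffusion_weights(sub)
    cond = sub.conducting
    mask = np.zeros((ny, nx), dtype=np.bool_) if stim_mask is None else stim_mask
    frames = np.empty((0, ny, nx), dtype=np.float32)
    act = np.full((ny, nx), np.nan)
    refrac = np.zeros((ny, nx), dtype=np.int8)
    starts = np.array([0.0]) if stim_amp > 0 else np.empty(0)
    status = _run_kernel(y, cond, wE, wW, wN, wS, cxy, scales.as_vector(),
                         dt, n_steps, 0.0, starts, n_steps * dt, stim_amp,
                         mask, frames, n_steps + 1, act, refrac,
                         build_rate_table(dt), math.exp(-dt / _TAU_FCA),
                         math.exp(-dt / _TAU_U))
    if status != 0:
        raise FloatingPointError(
            f"tissue integration unstable (|V| > 200 mV) with dt={dt}")
    return y


def _check_cfl(sub: Substrate, dt: float) -> None:
    h = sub.geometry.spacing
    if dt > h * h / (4.0 * sub.d_long):
        raise ValueError(
            f"dt={dt} violates diffusion stability for spacing {h} mm and "
            f"D={sub.d_long} mm^2/ms (need dt <= {h*h/(4*sub.d_long):.4f} ms)")


def _site_mask(sub: Substrate, site: tuple[int, int], radius_mm: float) -> np.ndarray:
    ny, nx = sub.geometry.shape
    ys, xs = np.mgrid[0:ny, 0:nx]
    r_nodes = radius_mm / sub.geometry.spacing
    return ((ys - site[0]) ** 2 + (xs - site[1]) ** 2) <= max(r_nodes, 1.0) ** 2


@dataclass
class SimulationTrace:
    """Decimated V(t) field plus stimulus log and event markers."""

    t: np.ndarray                  # (n_frames,) ms
    frames: np.ndarray             # (n_frames, ny, nx) float32 mV
    stimulus_log: list[dict]       # one entry per stimulus delivered
    induction_end: float | None = None
    termination_time: float | None = None
    activation_times: np.ndarray | None = None   # last-crossing LAT, ms
    meta: dict = field(default_factory=dict)

    @property
    def frame_dt(self) -> float:
        return float(self.t[1] - self.t[0]) if len(self.t) > 1 else math.nan

    def window(self, t0: float, t1: float) -> tuple[np.ndarray, np.ndarray]:
        m = (self.t >= t0) & (self.t < t1)
        return self.t[m], self.frames[m]

    def save(self, path) -> None:
        """Chunked binary container (.npz) with metadata for reloading."""
        import json as _json

        np.savez_compressed(
            path, t=self.t, frames=self.frames,
            activation_times=(self.activation_times
                              if self.activation_times is not None
                              else np.empty(0)),
            induction_end=np.float64(self.induction_end
                                     if self.induction_end is not None
                                     else np.nan),
            termination_time=np.float64(self.termination_time
                                        if self.termination_time is not None
                                        else np.nan),
            meta_json=np.bytes_(_json.dumps(
                {"stimulus_log": self.stimulus_log, **self.meta},
                default=str).encode()))

    @classmethod
    def load(cls, path) -> "SimulationTrace":
        import json as _json

        with np.load(path) as z:
            meta = _json.loads(bytes(z["meta_json"]).decode())
            log = meta.pop("stimulus_log", [])
            ind = float(z["induction_end"])
            term = float(z["termination_time"])
            act = z["activation_times"]
            return cls(t=z["t"], frames=z["frames"], stimulus_log=log,
                       induction_end=None if math.isnan(ind) else ind,
                       termination_time=None if math.isnan(term) else term,
                       activation_times=act if act.size else None,
                       meta=meta)


def run_tissue(
    sub: Substrate,
    scales: ConductanceScales,
    protocol: StimulusProtocol,
    duration: float,
    dt: float = 0.05,
    record_dt: float = 1.0,
    y: np.ndarray | None = None,
) -> tuple[SimulationTrace, np.ndarray]:
    """Run one protocol on the substrate; returns (trace, final state field).

    Deterministic given (substrate, scales, protocol, dt).  The state field
    may be passed in to chain runs (e.g. pacing followed by induction).
    """
    _check_cfl(sub, dt)
    ny, nx = sub.geometry.shape
    if y is None:
        y = initial_field(sub)
    wE, wW, wN, wS, cxy = _diffusion_weights(sub)
    cond = sub.conducting
    mask = _site_mask(sub, protocol.site, protocol.site_radius) & cond
    n_steps = int(round(duration / dt))
    stride = max(1, int(round(record_dt / dt)))
    n_frames = (n_steps + stride - 1) // stride
    frames = np.empty((n_frames, ny, nx), dtype=np.float32)
    act = np.full((ny, nx), np.nan)
    refrac = np.zeros((ny, nx), dtype=np.int8)
    status = _run_kernel(
        y, cond, wE, wW, wN, wS, cxy, scales.as_vector(), dt, n_steps, 0.0,
        np.asarray(protocol.onsets, dtype=np.float64),
        protocol.duration, protocol.amplitude, mask,
        frames, stride, act, refrac,
        build_rate_table(dt), math.exp(-dt / _TAU_FCA),
        math.exp(-dt / _TAU_U))
    if status != 0:
        raise FloatingPointError(
            f"tissue integration unstable (|V| > 200 mV) with dt={dt}")
    t = np.arange(n_frames) * stride * dt
    log = [{"site": protocol.site, "time": s, "amplitude": protocol.amplitude,
            "duration": protocol.duration} for s in protocol.onsets]
    trace = SimulationTrace(
        t=t, frames=frames, stimulus_log=log, activation_times=act,
        meta={"dt": dt, "record_dt": record_dt, "protocol": protocol.kind,
              "scales": scales.as_dict(), "substrate": dict(sub.manifest)})
    return trace, y


def _kernel_args(sub: Substrate, scales: ConductanceScales, dt: float):
    from .cellmodel import _TAU_FCA, _TAU_U, build_rate_table

    wE, wW, wN, wS, cxy = _diffusion_weights(sub)
    return (
        sub.conducting, wE, wW, wN, wS, cxy, scales.as_vector(), dt,
        build_rate_table(dt), math.exp(-dt / _TAU_FCA),
        math.exp(-dt / _TAU_U),
    )


def induce_cross_field(
    sub: Substrate,
    scales: ConductanceScales,
    duration: float,
    dt: float = 0.05,
    record_dt: float = 1.0,
    s1_amplitude: float = 80.0,
    repol_threshold: float = -60.0,
    s2_offset: float = 30.0,
    s2_region: str = "half",
) -> SimulationTrace:
    """S1–S2 cross-field reentry induction followed by a free run.

    An S1 plane wave is launched from the left edge; a probe pass measures
    when the sheet center has repolarized behind the wave, and the S2
    half-field stimulus (bottom half-plane by default; a quadrant is
    available) is delivered ``s2_offset`` ms after that moment — inside the vulnerable window regardless of the
    condition's APD and CV (the offset biases the timing toward the middle
    of the window, where the created rotor is strongest).  The trace's
    ``induction_end`` marks the S2 time.  Deterministic given (substrate,
    scales, dt).
    """
    _check_cfl(sub, dt)
    ny, nx = sub.geometry.shape
    ys, xs = np.mgrid[0:ny, 0:nx]
    cond = sub.conducting
    s1_mask = (xs < 2) & cond
    if s2_region == "half":
        # perpendicular half-plane: breaks along the whole S1 tail, seeding
        # a counter-rotating rotor pair (more robust than a single spiral)
        s2_mask = (ys < ny // 2) & cond
    elif s2_region == "quadrant":
        s2_mask = (xs < nx // 2) & (ys < ny // 2) & cond
    else:
        raise ValueError(f"unknown s2_region {s2_region!r}")
    args = _kernel_args(sub, scales, dt)
    cond_a, wE, wW, wN, wS, cxy, svec, _, tab, rlf_fca, rlf_u = args

    def run_segment(y, mask, onset, amp, seg_dur, rec_stride):
        n_steps = int(round(seg_dur / dt))
        n_frames = (n_steps + rec_stride - 1) // rec_stride
        frames = np.empty((n_frames, ny, nx), dtype=np.float32)
        act = np.full((ny, nx), np.nan)
        refrac = np.zeros((ny, nx), dtype=np.int8)
        onsets = np.array([onset]) if onset is not None else np.empty(0)
        status = _run_kernel(y, cond_a, wE, wW, wN, wS, cxy, svec, dt,
                             n_steps, 0.0, onsets, 2.0, amp, mask,
                             frames, rec_stride, act, refrac, tab,
                             rlf_fca, rlf_u)
        if status != 0:
            raise FloatingPointError(
                f"tissue integration unstable (|V| > 200 mV) with dt={dt}")
        return frames

    # probe pass: when does the sheet mid-region repolarize behind S1?
    # (the literal center may be fibrotic, so probe the conducting node
    # nearest the center)
    cy, cx = np.unravel_index(
        np.argmin(np.where(cond, (ys - ny / 2) ** 2 + (xs - nx / 2) ** 2,
                           np.inf)), cond.shape)
    probe_dur = 800.0
    probe_stride = max(1, int(round(2.0 / dt)))
    y_probe = initial_field(sub)
    frames = run_segment(y_probe, s1_mask, 1.0, s1_amplitude,
                         probe_dur, probe_stride)
    center = frames[:, cy, cx].astype(float)
    t_probe = np.arange(len(center)) * probe_stride * dt
    up = np.nonzero(center > ACTIVATION_THRESHOLD)[0]
    if up.size == 0:
        raise RuntimeError("S1 plane wave failed to reach the sheet center")
    after = np.nonzero((t_probe > t_probe[up[0]])
                       & (center < repol_threshold))[0]
    if after.size == 0:
        raise RuntimeError("sheet center never repolarized after S1")
    t2 = float(t_probe[after[0]]) + s2_offset

    # definitive run: S1 to t2, then S2 and the free-running window
    y = initial_field(sub)
    stride = max(1, int(round(record_dt / dt)))
    fr1 = run_segment(y, s1_mask, 1.0, s1_amplitude, t2, stride)
    fr2 = run_segment(y, s2_mask, 0.0, s1_amplitude, duration, stride)
    frames = np.concatenate([fr1, fr2], axis=0)
    t = np.arange(frames.shape[0]) * stride * dt
    log = [{"site": "left_edge", "time": 1.0, "amplitude": s1_amplitude,
            "duration": 2.0, "kind": "S1_plane"},
           {"site": f"s2_{s2_region}", "time": t2,
            "amplitude": s1_amplitude, "duration": 2.0, "kind": "S2_field"}]
    trace = SimulationTrace(
        t=t, frames=frames, stimulus_log=log, induction_end=t2 + 2.0,
        meta={"dt": dt, "record_dt": record_dt, "protocol": "cross_field",
              "s2_time": t2, "scales": dict(zip(SCALE_NAMES, svec.tolist())),
              "substrate": dict(sub.manifest)})
    return trace


# ---------------------------------------------------------------------------
# Event detection and LAT
# ---------------------------------------------------------------------------

def detect_termination(
    trace: SimulationTrace,
    threshold: float = ACTIVATION_THRESHOLD,
    quiescence_window: float = 500.0,
) -> float | None:
    """Earliest post-induction time with all nodes quiescent for a window.

    A case terminates at time T if every node stays below ``threshold``
    throughout [T, T + quiescence_window].  Returns None when activity
    persists to the end of the trace.
    """
    if trace.induction_end is None:
        raise ValueError("trace has no induction-end marker")
    t, fr = trace.t, trace.frames
    start = np.searchsorted(t, trace.induction_end)
    active = (fr[start:] > threshold).any(axis=(1, 2))
    n_win = max(1, int(round(quiescence_window / trace.frame_dt)))
    if len(active) < 1:
        return None
    # quiescent run-length ending criterion; last frames shorter than the
    # window cannot prove termination
    run = 0
    for i, a in enumerate(active):
        run = 0 if a else run + 1
        if run >= n_win:
            return float(t[start + i - n_win + 1])
    return None


def lat_map(
    trace: SimulationTrace, t0: float, t1: float
) -> np.ndarray:
    """Per-node local activation time within [t0, t1): time of max dV/dt.

    Nodes that never depolarize above the activation threshold inside the
    window get NaN (missing LAT).
    """
    t, fr = trace.window(t0, t1)
    if len(t) < 3:
        raise ValueError("window too short for LAT")
    dv = np.diff(fr.astype(np.float64), axis=0)
    idx = np.argmax(dv, axis=0)
    lat = t[idx] + 0.5 * trace.frame_dt
    peak = fr.max(axis=0)
    lat = np.where(peak > ACTIVATION_THRESHOLD, lat, np.nan)
    return lat


# ---------------------------------------------------------------------------
# Plane-wave CV (calibration primitive)
# ---------------------------------------------------------------------------

def plane_wave_cv(
    d_long: float,
    scales: ConductanceScales,
    n_nodes: int = 100,
    spacing: float = 0.25,
    dt: float = 0.05,
) -> float:
    """Conduction velocity (m/s) of a plane wave on a uniform 1D strand.

    Stimulates one end and fits distance against threshold-crossing time
    over the central half of the strand; returns 0 if the wave fails to
    propagate.
    """
    from .substrate import Geometry, Substrate, VoltagePointSet

    geom = Geometry(nx=n_nodes, ny=3, spacing=spacing)
    sub = Substrate(
        geometry=geom,
        voltage=np.full(geom.shape, 5.0),
        fibrotic=np.zeros(geom.shape, dtype=bool),
        fiber_angle=np.zeros(geom.shape),
        d_long=d_long,
        anisotropy=1.0,
        manifest={"calibration_strand": True},
    )
    proto = StimulusProtocol("S1_train", site=(1, 0), onsets=(1.0,),
                             amplitude=80.0, duration=2.0,
                             site_radius=2.0 * spacing)
    # duration: generous bound for slow waves
    duration = 30.0 + n_nodes * spacing / 0.05
    trace, _ = run_tissue(sub, scales, proto, duration, dt=dt, record_dt=5.0)
    act = trace.activation_times[1]          # middle row
    i0, i1 = int(0.25 * n_nodes), int(0.75 * n_nodes)
    xs = np.arange(n_nodes) * spacing
    seg_t = act[i0:i1]
    if np.any(np.isnan(seg_t)):
        return 0.0
    slope = np.polyfit(seg_t, xs[i0:i1], 1)[0]   # mm/ms == m/s
    return float(abs(slope))


# ---------------------------------------------------------------------------
# Case orchestration
# ---------------------------------------------------------------------------

@dataclass
class CaseResult:
    """Everything one condition produces on one substrate."""

    sr_trace: SimulationTrace | None
    af_trace: SimulationTrace | None
    restitution_samples: dict[tuple[int, int], list[tuple[float, float]]] | None
    induction_end: float | None
    termination_time: float | None
    meta: dict = field(default_factory=dict)


def run_case(
    sub: Substrate,
    sr_scales: ConductanceScales,
    af_scales: ConductanceScales,
    af_duration: float = 8000.0,
    dt: float = 0.05,
    record_dt: float = 1.0,
    sr_beats: int = 4,
    sr_cl: float = 600.0,
    induction: str = "cross_field",
    burst: StimulusProtocol | None = None,
    run_sr: bool = True,
    run_af: bool = True,
) -> CaseResult:
    """Run the per-case protocol set: SR pacing, then AF induction.

    APD90/CV come from the SR-parameterized pacing run; the AF-dynamics
    window (AFCL, DF, PS, termination) from the AF-parameterized induction
    run, following the convention that sinus-rhythm currents parameterize
    the paced measurements and AF-remodeled currents the fibrillation
    measurements.  ``induction`` selects S1–S2 cross-field reentry
    initiation (default) or septal burst pacing.
    """
    site = sub.landmarks.get("septal_pacing_site", (2, 2))
    sr_trace = None
    if run_sr:
        proto = s1_protocol(site, cycle_length=sr_cl, n_beats=sr_beats)
        sr_trace, _ = run_tissue(sub, sr_scales, proto,
                                 duration=sr_cl * sr_beats + 1.0,
                                 dt=dt, record_dt=record_dt)
    af_trace = None
    induction_end = None
    term = None
    if run_af:
        if induction == "cross_field":
            af_trace = induce_cross_field(sub, af_scales,
                                          duration=af_duration, dt=dt,
                                          record_dt=record_dt)
            induction_end = af_trace.induction_end
        elif induction == "burst":
            if burst is None:
                burst = burst_protocol(site)
            induction_end = burst.end
            af_trace, _ = run_tissue(sub, af_scales, burst,
                                     duration=induction_end + af_duration,
                                     dt=dt, record_dt=record_dt)
            af_trace.induction_end = induction_end
        else:
            raise ValueError(f"unknown induction mode {induction!r}")
        term = detect_termination(af_trace)
        af_trace.termination_time = term
    return CaseResult(sr_trace=sr_trace, af_trace=af_trace,
                      restitution_samples=None,
                      induction_end=induction_end, termination_time=term,
                      meta={"dt": dt, "af_duration": af_duration,
                            "induction": induction})
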
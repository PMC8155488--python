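"""Wave-dynamics and electrophysiology metrics.

Computes the per-case quantities of an in-silico AF study from simulation
traces: APD90 and conduction velocity from paced (sinus-rhythm
parameterized) runs; AF cycle length, dominant frequency, and phase
singularities from fibrillation (AF-parameterized) runs; and restitution
slope maps.

Conventions chosen here (the quantities' operational definitions):

* AFCL is the mean inter-activation interval — successive depolarizations
  per node, node means averaged over the analyzed node set — computed
  independently of DF rather than as its reciprocal.
* DF is the frequency of maximal spectral power per node within a 3–15 Hz
  band, on mean-subtracted, Hann-tapered windows of >= 2 s; *peak DF* is
  the max over nodes, *mean DF* the mean, so peak >= mean by construction.
* Phase is the analytic-signal (Hilbert) phase of mean-subtracted V; a
  phase singularity is a lattice plaquette where the wrapped phase
  difference integrates to ±2π (topological charge ±1).
* The *PS number* is the cumulative count of per-frame PS detections over
  the analysis window (not the concurrent count); *PS life span* is the
  mean lifetime of charge-respecting nearest-neighbor tracks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy.signal import hilbert, periodogram

from .cellmodel import fit_restitution, measure_apd90
from .substrate import Geometry
from .tissue import ACTIVATION_THRESHOLD, SimulationTrace

__all__ = [
    "WaveMetrics",
    "PhaseSingularityTrack",
    "cv_between",
    "activation_times_per_node",
    "afcl",
    "dominant_frequency",
    "phase_field",
    "ps_detect",
    "ps_track",
    "smax_map",
    "apd90_map",
]

#: Table-style column order for exported metric rows.
METRIC_COLUMNS = (
    "APD90 (ms)", "CV (m/s)", "Mean Smax", "Mean AFCL (ms)",
    "Peak DF (Hz)", "Mean DF (Hz)", "PS number (N)", "PS life span (ms)",
)


@dataclass
class WaveMetrics:
    """One case's electrophysiology and wave-dynamics summary."""

    apd90: float = math.nan          # ms
    cv: float = math.nan             # m/s
    mean_smax: float = math.nan      # dimensionless
    mean_afcl: float = math.nan      # ms
    peak_df: float = math.nan        # Hz
    mean_df: float = math.nan        # Hz
    ps_number: float = math.nan      # cumulative detections (N)
    ps_lifespan: float = math.nan    # ms
    terminated: bool = False
    termination_time: float | None = None

    def validate(self) -> None:
        if (not math.isnan(self.peak_df) and not math.isnan(self.mean_df)
                and self.peak_df < self.mean_df - 1e-9):
            raise ValueError("peak DF must be >= mean DF over the same node set")
        if not math.isnan(self.ps_number) and self.ps_number < 0:
            raise ValueError("PS number must be >= 0")

    def as_row(self) -> dict[str, float]:
        vals = (self.apd90, self.cv, self.mean_smax, self.mean_afcl,
                self.peak_df, self.mean_df, self.ps_number, self.ps_lifespan)
        return dict(zip(METRIC_COLUMNS, vals))

    def as_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# Paced-run metrics: CV and APD90 maps
# ---------------------------------------------------------------------------

def cv_between(
    lat: np.ndarray,
    site_a: tuple[int, int],
    site_b: tuple[int, int],
    geometry: Geometry,
) -> float:
    """Conduction velocity (m/s) between two activated nodes.

    Straight-line (sheet-geodesic) distance divided by the LAT difference;
    B must activate after A.
    """
    if site_a == site_b:
        raise ValueError("need two distinct nodes")
    ta, tb = lat[site_a], lat[site_b]
    if math.isnan(ta) or math.isnan(tb):
        raise ValueError("LAT undefined at one of the sites")
    dt = tb - ta
    if dt <= 0:
        raise ValueError("site B does not activate after site A")
    h = geometry.spacing
    dist = h * math.hypot(site_b[0] - site_a[0], site_b[1] - site_a[1])
    return dist / dt    # mm/ms == m/s


def apd90_map(
    trace: SimulationTrace,
    t0: float,
    t1: float,
    node_stride: int = 4,
) -> np.ndarray:
    """Per-node APD90 (ms) for the beat inside [t0, t1), NaN where undefined.

    Evaluated on a strided node subset for speed; unsampled nodes are NaN.
    """
    t, fr = trace.window(t0, t1)
    ny, nx = fr.shape[1:]
    out = np.full((ny, nx), np.nan)
    for iy in range(0, ny, node_stride):
        for ix in range(0, nx, node_stride):
            out[iy, ix] = measure_apd90(t, fr[:, iy, ix].astype(float))
    return out


# ---------------------------------------------------------------------------
# AF-run metrics: AFCL, DF, phase, PS
# ---------------------------------------------------------------------------

def activation_times_per_node(
    t: np.ndarray,
    v: np.ndarray,
    threshold: float = ACTIVATION_THRESHOLD,
) -> list[np.ndarray]:
    """Upward threshold-crossing times for each node of a (n_t, n_nodes) block."""
    above = v > threshold
    out = []
    for k in range(v.shape[1]):
        a = above[:, k]
        idx = np.nonzero(~a[:-1] & a[1:])[0] + 1
        out.append(t[idx])
    return out


def _node_subset(frames: np.ndarray, node_stride: int,
                 conducting: np.ndarray | None = None) -> np.ndarray:
    ny, nx = frames.shape[1:]
    iy, ix = np.mgrid[0:ny:node_stride, 0:nx:node_stride]
    sel = np.ones(iy.shape, dtype=bool)
    if conducting is not None:
        sel = conducting[iy, ix]
    return frames[:, iy[sel], ix[sel]]


def afcl(
    trace: SimulationTrace,
    t0: float,
    t1: float,
    node_stride: int = 4,
    conducting: np.ndarray | None = None,
) -> float:
    """Mean AF cycle length (ms) over [t0, t1): NaN when undefined.

    Per node, the mean interval between successive activations; the case
    value is the mean of node means over nodes with >= 2 activations.
    """
    t, fr = trace.window(t0, t1)
    if len(t) < 3:
        return math.nan
    v = _node_subset(fr, node_stride, conducting).astype(float)
    node_means = []
    for times in activation_times_per_node(t, v):
        if len(times) >= 2:
            node_means.append(np.diff(times).mean())
    if not node_means:
        return math.nan
    return float(np.mean(node_means))


def dominant_frequency(
    trace: SimulationTrace,
    t0: float,
    t1: float,
    band: tuple[float, float] = (3.0, 15.0),
    node_stride: int = 4,
    conducting: np.ndarray | None = None,
) -> tuple[np.ndarray, float, float]:
    """Per-node dominant frequency within ``band`` plus (peak, mean) DF in Hz.

    Windows shorter than 2 s are rejected (insufficient spectral
    resolution).  Nodes with negligible variance are excluded.
    """
    t, fr = trace.window(t0, t1)
    if len(t) < 2 or (t[-1] - t[0]) < 2000.0:
        raise ValueError("DF needs an analysis window of at least 2 s")
    fs = 1000.0 / trace.frame_dt          # Hz
    v = _node_subset(fr, node_stride, conducting).astype(float)
    v = v - v.mean(axis=0, keepdims=True)
    freqs, pxx = periodogram(v, fs=fs, window="hann", axis=0)
    sel = (freqs >= band[0]) & (freqs <= band[1])
    if not sel.any():
        raise ValueError("no spectral bins inside the DF band")
    fb, pb = freqs[sel], pxx[sel]
    dfs = fb[np.argmax(pb, axis=0)]
    active = v.std(axis=0) > 1.0          # mV; flat nodes carry no DF
    dfs = dfs[active]
    if dfs.size == 0:
        return dfs, math.nan, math.nan
    return dfs, float(dfs.max()), float(dfs.mean())


def phase_field(
    trace: SimulationTrace,
    t0: float,
    t1: float,
    min_std: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Instantaneous analytic-signal phase of V, per node, over a window.

    Returns (phase, mask): ``phase`` has shape (n_t, ny, nx) in (−π, π];
    ``mask`` flags nodes with enough oscillation for a defined phase.
    One full action-potential cycle traverses 2π.
    """
    t, fr = trace.window(t0, t1)
    if len(t) < 8:
        raise ValueError("window too short for phase analysis")
    v = fr.astype(float)
    v = v - v.mean(axis=0, keepdims=True)
    analytic = hilbert(v, axis=0)
    phase = np.angle(analytic)
    mask = v.std(axis=0) > min_std
    return phase, mask


def ps_detect(phase_frame: np.ndarray) -> list[tuple[float, float, int]]:
    """Phase singularities of one phase frame as (x, y, charge) tuples.

    Integrates wrapped phase differences counterclockwise around each
    elementary plaquette; a winding of ±2π marks a singularity of
    topological charge ±1.  Positions are plaquette centers in node
    coordinates.
    """
    p = phase_frame

    def wrap(a):
        return (a + np.pi) % (2 * np.pi) - np.pi

    # counterclockwise around the plaquette (iy,ix)->(iy,ix+1)->(iy+1,ix+1)->(iy+1,ix)
    d1 = wrap(p[:-1, 1:] - p[:-1, :-1])
    d2 = wrap(p[1:, 1:] - p[:-1, 1:])
    d3 = wrap(p[1:, :-1] - p[1:, 1:])
    d4 = wrap(p[:-1, :-1] - p[1:, :-1])
    winding = d1 + d2 + d3 + d4
    charge = np.rint(winding / (2 * np.pi)).astype(int)
    ys, xs = np.nonzero(charge != 0)
    return [(float(x) + 0.5, float(y) + 0.5, int(charge[y, x]))
            for y, x in zip(ys, xs)]


@dataclass
class PhaseSingularityTrack:
    """One tracked phase singularity through consecutive frames."""

    birth_frame: int
    charge: int
    positions: list[tuple[float, float]] = field(default_factory=list)

    @property
    def death_frame(self) -> int:
        return self.birth_frame + len(self.positions) - 1

    def lifespan(self, frame_dt: float) -> float:
        return (len(self.positions) - 1) * frame_dt


def ps_track(
    frames_ps: Sequence[list[tuple[float, float, int]]],
    frame_dt: float,
    max_jump_mm: float = 5.0,
    spacing: float = 1.0,
) -> tuple[list[PhaseSingularityTrack], int, float]:
    """Track PSs across frames; returns (tracks, PS number, mean lifespan ms).

    Frame-to-frame association is greedy nearest-neighbor, restricted to
    equal topological charge and jumps below ``max_jump_mm``.  The PS
    number is the cumulative count of per-frame detections over the whole
    window; the mean lifespan is over completed tracks (NaN with no
    tracks).
    """
    max_jump = max_jump_mm / spacing
    tracks: list[PhaseSingularityTrack] = []
    open_tracks: list[PhaseSingularityTrack] = []
    total_detections = 0
    for fi, detections in enumerate(frames_ps):
        total_detections += len(detections)
        unmatched = list(range(len(detections)))
        next_open: list[PhaseSingularityTrack] = []
        # match existing tracks to nearest same-charge detection
        for tr in open_tracks:
            px, py = tr.positions[-1]
            best, best_d = None, max_jump
            for di in unmatched:
                x, y, q = detections[di]
                if q != tr.charge:
                    continue
                d = math.hypot(x - px, y - py)
                if d <= best_d:
                    best, best_d = di, d
            if best is not None:
                x, y, _ = detections[best]
                tr.positions.append((x, y))
                unmatched.remove(best)
                next_open.append(tr)
            else:
                tracks.append(tr)
        for di in unmatched:
            x, y, q = detections[di]
            t = PhaseSingularityTrack(birth_frame=fi, charge=q,
                                      positions=[(x, y)])
            next_open.append(t)
        open_tracks = next_open
    tracks.extend(open_tracks)
    if tracks:
        mean_life = float(np.mean([t.lifespan(frame_dt) for t in tracks]))
    else:
        mean_life = math.nan
    return tracks, total_detections, mean_life


def ps_analysis(
    trace: SimulationTrace,
    t0: float,
    t1: float,
    spacing: float,
    max_jump_mm: float = 5.0,
) -> tuple[int, float, np.ndarray]:
    """PS statistics for an analysis window.

    Returns (PS number = cumulative detections, mean PS lifespan in ms,
    per-frame total topological charge).
    """
    phase, mask = phase_field(trace, t0, t1)
    phase = np.where(mask[None, :, :], phase, 0.0)
    # plaquettes whose four corners are all phase-defined
    plaq_ok = mask[:-1, :-1] & mask[:-1, 1:] & mask[1:, :-1] & mask[1:, 1:]

    def wrap(a):
        return (a + np.pi) % (2 * np.pi) - np.pi

    per_frame: list[list[tuple[float, float, int]]] = []
    charge = np.zeros(phase.shape[0], dtype=int)
    # chunk the winding computation to bound memory on long windows
    for lo in range(0, phase.shape[0], 256):
        p = phase[lo:lo + 256]
        winding = (wrap(p[:, :-1, 1:] - p[:, :-1, :-1])
                   + wrap(p[:, 1:, 1:] - p[:, :-1, 1:])
                   + wrap(p[:, 1:, :-1] - p[:, 1:, 1:])
                   + wrap(p[:, :-1, :-1] - p[:, 1:, :-1]))
        q = np.rint(winding / (2 * np.pi)).astype(int)
        q *= plaq_ok
        charge[lo:lo + 256] = q.sum(axis=(1, 2))
        for k in range(q.shape[0]):
            ys, xs = np.nonzero(q[k])
            per_frame.append([(float(x) + 0.5, float(y) + 0.5,
                               int(q[k, y, x]))
                              for y, x in zip(ys, xs)])
    _, n_ps, life = ps_track(per_frame, trace.frame_dt, max_jump_mm, spacing)
    return n_ps, life, charge


# ---------------------------------------------------------------------------
# Restitution-slope maps
# ---------------------------------------------------------------------------

def smax_map(
    samples_per_node: dict[tuple[int, int], Sequence[tuple[float, float]]],
    min_samples: int = 4,
) -> tuple[float, tuple[int, int] | None, dict[tuple[int, int], float]]:
    """Per-node restitution fits: (mean Smax, argmax node, per-node Smax).

    Nodes with fewer than ``min_samples`` (DI, APD) pairs or a degenerate
    DI spread are excluded; a warning-grade situation (over half the nodes
    excluded) is reported by the caller inspecting the returned dict.
    """
    per_node: dict[tuple[int, int], float] = {}
    for node, samples in samples_per_node.items():
        samples = list(samples)
        if len(samples) < min_samples:
            continue
        dis = {round(s[0], 9) for s in samples}
        if len(dis) < 2:
            continue
        try:
            per_node[node] = fit_restitution(samples).smax
        except (ValueError, RuntimeError):
            continue
    if not per_node:
        return math.nan, None, per_node
    smaxes = np.array(list(per_node.values()))
    argmax_node = max(per_node, key=per_node.get)
    return float(smaxes.mean()), argmax_node, per_node
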
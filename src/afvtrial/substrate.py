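"""Synthetic atrial substrate generation.

Stands in for the patient-specific inputs of an electroanatomical mapping
study: a monolayer sheet geometry, a spatially correlated bipolar-voltage
field sampled at catheter-like point density, inverse-distance-weighted
(IDW) interpolation of those points, a voltage-dependent fibrosis
probability map, a smooth fiber-orientation field, and calibration of the
longitudinal diffusion coefficient so that the simulated plane-wave
conduction velocity matches a target.

Every generator here is a pure function of (parameters, seed), so a
substrate is exactly reproducible from its manifest.  Distances are in mm,
time in ms, voltages in mV, diffusion coefficients in mm^2/ms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .cellmodel import ConductanceScales

__all__ = [
    "Geometry",
    "VoltagePointSet",
    "Substrate",
    "idw_interpolate",
    "synth_voltage_field",
    "fibrosis_from_voltage",
    "logistic_fibrosis_probability",
    "fiber_field",
    "calibrate_diffusion",
    "build_substrate",
    "substrate_to_vtk",
]

#: Bipolar-voltage cutoff (mV) conventionally separating low-voltage /
#: fibrotic-prone tissue from healthy tissue on clinical maps.
LOW_VOLTAGE_CUTOFF = 0.5


@dataclass(frozen=True)
class Geometry:
    """Regular 2D lattice monolayer: ``ny x nx`` nodes, ``spacing`` mm apart."""

    nx: int
    ny: int
    spacing: float

    def __post_init__(self) -> None:
        if self.nx < 2 or self.ny < 2:
            raise ValueError("lattice needs at least 2 nodes per axis")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.ny, self.nx)

    @property
    def n_nodes(self) -> int:
        return self.nx * self.ny

    @property
    def extent_mm(self) -> tuple[float, float]:
        return ((self.nx - 1) * self.spacing, (self.ny - 1) * self.spacing)

    def node_positions(self) -> np.ndarray:
        """(n_nodes, 2) array of (x, y) positions in mm, row-major."""
        ys, xs = np.mgrid[0:self.ny, 0:self.nx]
        return np.column_stack([xs.ravel(), ys.ravel()]).astype(float) * self.spacing


@dataclass
class VoltagePointSet:
    """Point-sampled bipolar voltage map: positions (mm) and amplitudes (mV)."""

    positions: np.ndarray      # (n, 2)
    values: np.ndarray         # (n,), >= 0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] not in (2, 3):
            raise ValueError("positions must be (n, 2) or (n, 3)")
        if self.values.shape != (self.positions.shape[0],):
            raise ValueError("positions/values length mismatch")
        if np.any(self.values < 0):
            raise ValueError("bipolar amplitudes must be >= 0")

    def __len__(self) -> int:
        return len(self.values)

    def to_text(self) -> str:
        cols = "x_mm\ty_mm\tbipolar_mV"
        rows = [f"{p[0]:.4f}\t{p[1]:.4f}\t{v:.5f}"
                for p, v in zip(self.positions, self.values)]
        return "\n".join([cols] + rows) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "VoltagePointSet":
        lines = [ln for ln in text.strip().splitlines() if ln.strip()]
        data = np.array([[float(x) for x in ln.split("\t")] for ln in lines[1:]])
        return cls(data[:, :-1], data[:, -1])


@dataclass
class Substrate:
    """Monolayer substrate: everything the tissue solver needs per node.

    ``fibrotic`` nodes are non-conducting by default (zero-flux holes in
    the diffusion operator); ``d_long`` is the longitudinal diffusion
    coefficient and ``anisotropy`` the ratio D_long / D_trans.
    """

    geometry: Geometry
    voltage: np.ndarray            # (ny, nx) bipolar mV
    fibrotic: np.ndarray           # (ny, nx) bool
    fiber_angle: np.ndarray        # (ny, nx) radians
    d_long: float                  # mm^2/ms
    anisotropy: float              # >= 1
    points: VoltagePointSet | None = None
    landmarks: dict[str, tuple[int, int]] = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)
    #: "non_conducting" removes fibrotic nodes from the tissue entirely;
    #: "reduced_coupling" keeps them excitable with diffusion scaled by
    #: ``fibrotic_coupling``.
    fibrosis_mode: str = "non_conducting"
    fibrotic_coupling: float = 0.1

    def __post_init__(self) -> None:
        if self.fibrosis_mode not in ("non_conducting", "reduced_coupling"):
            raise ValueError(f"unknown fibrosis mode {self.fibrosis_mode!r}")
        if not (0.0 < self.fibrotic_coupling <= 1.0):
            raise ValueError("fibrotic_coupling must be in (0, 1]")
        shp = self.geometry.shape
        self._check_arrays(shp)

    def _check_arrays(self, shp) -> None:
        for name in ("voltage", "fibrotic", "fiber_angle"):
            arr = getattr(self, name)
            if arr.shape != shp:
                raise ValueError(f"{name} shape {arr.shape} != geometry {shp}")
        if self.d_long <= 0:
            raise ValueError("d_long must be positive")
        if self.anisotropy < 1:
            raise ValueError("anisotropy = D_long/D_trans must be >= 1")
        if len(set(self.landmarks.values())) != len(self.landmarks):
            raise ValueError("landmark nodes must be distinct")

    @property
    def fiber_vectors(self) -> np.ndarray:
        """(ny, nx, 2) unit vectors along the local fiber direction."""
        return np.stack([np.cos(self.fiber_angle), np.sin(self.fiber_angle)],
                        axis=-1)

    @property
    def fibrotic_fraction(self) -> float:
        return float(self.fibrotic.mean())

    @property
    def conducting(self) -> np.ndarray:
        """Nodes the solver integrates; all nodes in reduced-coupling mode."""
        if self.fibrosis_mode == "reduced_coupling":
            return np.ones(self.geometry.shape, dtype=bool)
        return ~self.fibrotic


# ---------------------------------------------------------------------------
# IDW interpolation
# ---------------------------------------------------------------------------

def idw_interpolate(
    points: VoltagePointSet,
    query: np.ndarray,
    power: float = 2.0,
    radius: float = 10.0,
) -> np.ndarray:
    """Inverse-distance-weighted interpolation within a cutoff radius.

    The value at query j is sum_i w_ij R_i with w_ij = d_ij^-a normalized
    over the known points within ``radius`` of j.  A query coinciding with
    a known point returns that point's value exactly; queries with no known
    point in radius get NaN (a missing-value marker, never zero).
    """
    if power <= 0:
        raise ValueError("power must be positive")
    if radius <= 0:
        raise ValueError("radius must be positive")
    query = np.atleast_2d(np.asarray(query, dtype=float))
    tree = cKDTree(points.positions)
    neighbors = tree.query_ball_point(query, r=radius)
    out = np.full(len(query), np.nan)
    for jj, idx in enumerate(neighbors):
        if not idx:
            continue
        d = np.linalg.norm(points.positions[idx] - query[jj], axis=1)
        exact = d < 1e-12
        if exact.any():
            out[jj] = points.values[np.asarray(idx)[exact][0]]
            continue
        w = d ** (-power)
        out[jj] = np.sum(w * points.values[idx]) / np.sum(w)
    return out


# ---------------------------------------------------------------------------
# Synthetic voltage field and fibrosis
# ---------------------------------------------------------------------------

def synth_voltage_field(
    geometry: Geometry,
    correlation_length: float = 8.0,
    low_voltage_fraction: float = 0.3,
    seed: int | np.random.Generator = 0,
    n_points: int = 600,
    cutoff: float = LOW_VOLTAGE_CUTOFF,
) -> tuple[VoltagePointSet, np.ndarray]:
    """Seeded, spatially correlated bipolar-voltage field plus a point sample.

    A Gaussian random field with the requested correlation length (mm) is
    mapped through a lognormal quantile transform so that amplitudes are
    positive and the fraction of nodes below ``cutoff`` equals
    ``low_voltage_fraction`` (exactly, by construction of the transform).
    ``n_points`` nodes (>= 500 to mirror catheter mapping density) are
    subsampled into a :class:`VoltagePointSet`.
    """
    if not (0.0 <= low_voltage_fraction <= 1.0):
        raise ValueError("low_voltage_fraction must be in [0, 1]")
    if correlation_length < geometry.spacing:
        raise ValueError("correlation length must be >= lattice spacing")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))

    sigma_nodes = correlation_length / geometry.spacing
    white = rng.standard_normal(geometry.shape)
    smooth = ndimage.gaussian_filter(white, sigma=sigma_nodes, mode="reflect")
    # rank-transform to uniform quantiles, then to lognormal amplitudes
    ranks = smooth.ravel().argsort().argsort().astype(float)
    q = (ranks + 0.5) / ranks.size
    # lognormal with median chosen so P(v < cutoff) = low_voltage_fraction
    from scipy.stats import norm
    sigma_ln = 1.2
    if low_voltage_fraction in (0.0, 1.0):
        # degenerate targets: push the whole distribution clear of the cutoff
        mu = (math.log(cutoff) + (5.0 if low_voltage_fraction == 0 else -5.0)
              * sigma_ln)
    else:
        mu = math.log(cutoff) - sigma_ln * norm.ppf(low_voltage_fraction)
    z = norm.ppf(np.clip(q, 1e-9, 1 - 1e-9))
    voltage = np.exp(mu + sigma_ln * z).reshape(geometry.shape)

    # catheter-like subsample
    n_points = int(n_points)
    if n_points < 1 or n_points > geometry.n_nodes:
        raise ValueError("n_points out of range")
    idx = rng.choice(geometry.n_nodes, size=n_points, replace=False)
    pos = geometry.node_positions()[idx]
    vals = voltage.ravel()[idx]
    return VoltagePointSet(pos, vals), voltage


def logistic_fibrosis_probability(
    midpoint_mv: float = 0.4, steepness: float = 10.0, p_max: float = 0.9
) -> Callable[[np.ndarray], np.ndarray]:
    """Monotone non-increasing logistic map from bipolar voltage to P(fibrosis).

    Low-voltage tissue is fibrosis-prone; the probability saturates at
    ``p_max`` as voltage -> 0 and decays towards 0 for healthy amplitudes.
    """
    from scipy.special import expit

    def prob(v: np.ndarray) -> np.ndarray:
        v = np.asarray(v, dtype=float)
        return p_max * expit(-steepness * (v - midpoint_mv))
    return prob


def fibrosis_from_voltage(
    voltage: np.ndarray,
    probability: Callable[[np.ndarray], np.ndarray] | None = None,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Per-node Bernoulli fibrosis flags with p = probability(voltage).

    The probability function must map mV to [0, 1] and be monotone
    non-increasing in voltage (validated on a grid).
    """
    if probability is None:
        probability = logistic_fibrosis_probability()
    grid = np.linspace(0.0, 10.0, 201)
    p_grid = np.asarray(probability(grid), dtype=float)
    if np.any(p_grid < -1e-12) or np.any(p_grid > 1 + 1e-12):
        raise ValueError("probability function must map into [0, 1]")
    if np.any(np.diff(p_grid) > 1e-9):
        raise ValueError("probability function must be monotone non-increasing")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    p = np.clip(np.asarray(probability(voltage), dtype=float), 0.0, 1.0)
    return rng.random(voltage.shape) < p


# ---------------------------------------------------------------------------
# Fiber orientation
# ---------------------------------------------------------------------------

def fiber_field(
    geometry: Geometry,
    pattern: str = "random-smooth",
    seed: int | np.random.Generator = 0,
    base_angle: float = 0.0,
    smooth_length: float = 10.0,
) -> np.ndarray:
    """Rule-based synthetic fiber angles (radians), one per node.

    Patterns: ``uniform`` (all ``base_angle``), ``swirl`` (tangential field
    around the sheet center), ``random-smooth`` (Gaussian-filtered random
    orientations, smooth on the ``smooth_length`` scale).
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    ny, nx = geometry.shape
    if pattern == "uniform":
        return np.full((ny, nx), float(base_angle))
    if pattern == "swirl":
        ys, xs = np.mgrid[0:ny, 0:nx].astype(float)
        cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
        return np.arctan2(xs - cx, -(ys - cy))  # tangent of circles about center
    if pattern == "random-smooth":
        sigma = smooth_length / geometry.spacing
        # a scaled smooth scalar field avoids the director singularities
        # that component-wise smoothing produces
        z = ndimage.gaussian_filter(rng.standard_normal((ny, nx)), sigma,
                                    mode="reflect")
        z /= max(z.std(), 1e-12)
        return base_angle + (np.pi / 4.0) * z
    raise ValueError(f"unknown fiber pattern {pattern!r}")


def substrate_to_vtk(sub: Substrate) -> str:
    """Legacy-VTK (ASCII structured points) export of the per-node fields.

    Point data: bipolar voltage (mV), fibrosis flag, fiber angle (rad).
    Viewable in ParaView/VisIt; kept dependency-free.
    """
    geom = sub.geometry
    lines = [
        "# vtk DataFile Version 3.0",
        "afvtrial substrate",
        "ASCII",
        "DATASET STRUCTURED_POINTS",
        f"DIMENSIONS {geom.nx} {geom.ny} 1",
        "ORIGIN 0 0 0",
        f"SPACING {geom.spacing} {geom.spacing} 1",
        f"POINT_DATA {geom.n_nodes}",
    ]

    def scalars(name: str, arr: np.ndarray, fmt: str) -> None:
        lines.append(f"SCALARS {name} float 1")
        lines.append("LOOKUP_TABLE default")
        lines.extend(fmt % v for v in arr.ravel())

    scalars("bipolar_voltage_mV", sub.voltage, "%.5f")
    scalars("fibrosis", sub.fibrotic.astype(float), "%.0f")
    scalars("fiber_angle_rad", sub.fiber_angle, "%.5f")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Diffusion calibration
# ---------------------------------------------------------------------------

def _strand_cv(
    d_long: float,
    scales: ConductanceScales,
    n_nodes: int = 100,
    spacing: float = 0.25,
    dt: float = 0.05,
) -> float:
    """Plane-wave conduction velocity (m/s) on a 1D calibration strand."""
    from .tissue import plane_wave_cv
    return plane_wave_cv(d_long, scales, n_nodes=n_nodes, spacing=spacing, dt=dt)


def calibrate_diffusion(
    scales: ConductanceScales,
    target_cv: float = 0.7,
    tolerance: float = 0.02,
    d_lo: float = 0.005,
    d_hi: float = 1.0,
    spacing: float = 0.25,
    dt: float = 0.05,
    max_iter: int = 40,
) -> tuple[float, float]:
    """Bisection on D_long until plane-wave CV matches ``target_cv`` (m/s).

    Returns (D_long, achieved CV).  Raises if the target lies outside the
    CV range achievable within [d_lo, d_hi].
    """
    if target_cv <= 0:
        raise ValueError("target CV must be positive")
    d_hi = min(d_hi, 0.9 * spacing * spacing / (4.0 * dt))   # stay CFL-stable
    cv_lo = _strand_cv(d_lo, scales, spacing=spacing, dt=dt)
    cv_hi = _strand_cv(d_hi, scales, spacing=spacing, dt=dt)
    if not (cv_lo <= target_cv <= cv_hi):
        raise ValueError(
            f"target CV {target_cv} m/s unreachable: achievable range "
            f"[{cv_lo:.3f}, {cv_hi:.3f}] m/s for D in [{d_lo}, {d_hi}]")
    lo, hi = d_lo, d_hi
    d_mid, cv_mid = d_hi, cv_hi
    for _ in range(max_iter):
        d_mid = math.sqrt(lo * hi)      # CV ~ sqrt(D): bisect in log space
        cv_mid = _strand_cv(d_mid, scales, spacing=spacing, dt=dt)
        if abs(cv_mid - target_cv) <= tolerance:
            return d_mid, cv_mid
        if cv_mid < target_cv:
            lo = d_mid
        else:
            hi = d_mid
    return d_mid, cv_mid


# ---------------------------------------------------------------------------
# Full substrate assembly
# ---------------------------------------------------------------------------

def build_substrate(
    seed: int = 0,
    size_mm: float = 50.0,
    spacing: float = 0.25,
    correlation_length: float = 8.0,
    low_voltage_fraction: float = 0.3,
    fiber_pattern: str = "random-smooth",
    d_long: float = 0.1,
    anisotropy: float = 2.0,
    fibrosis_probability: Callable[[np.ndarray], np.ndarray] | None = None,
    n_points: int = 600,
    idw_power: float = 2.0,
    idw_radius: float = 10.0,
) -> Substrate:
    """Generate a complete synthetic substrate from a seed.

    The voltage field is point-sampled and re-interpolated through the IDW
    rule (emulating the clinical map-building step); fibrosis flags are
    drawn from the voltage-dependent probability; fibers follow the
    requested pattern.  Landmarks ``septal_pacing_site`` and
    ``appendage_roi`` sit at opposite corners, emulating the high-septum to
    appendage measurement path.  All randomness derives from ``seed``.
    """
    n = int(round(size_mm / spacing)) + 1
    geom = Geometry(nx=n, ny=n, spacing=spacing)
    rng = np.random.default_rng(seed)
    points, _truth = synth_voltage_field(
        geom, correlation_length, low_voltage_fraction, rng,
        n_points=min(n_points, geom.n_nodes))
    interp = idw_interpolate(points, geom.node_positions(),
                             power=idw_power, radius=idw_radius)
    voltage = interp.reshape(geom.shape)
    # nodes out of reach of every sample point fall back to the cutoff value
    voltage = np.where(np.isnan(voltage), LOW_VOLTAGE_CUTOFF, voltage)
    fib = fibrosis_from_voltage(voltage, fibrosis_probability, rng)
    angles = fiber_field(geom, fiber_pattern, rng)
    # Landmarks sit in viable tissue toward opposite corners, as a mapping
    # catheter would be positioned: candidates are restricted to the
    # largest conducting cluster (so pacing can reach the whole sheet),
    # preferring nodes that are close to the corner and locally
    # non-fibrotic.  A small disc around the pacing site is kept
    # conducting so stimuli always capture.
    density = ndimage.uniform_filter(fib.astype(float),
                                     size=max(3, int(round(3.0 / spacing))))
    labels, n_clusters = ndimage.label(~fib)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels,
                               index=np.arange(1, n_clusters + 1))
    main = 1 + int(np.argmax(sizes))
    ys, xs = np.mgrid[0:geom.ny, 0:geom.nx]
    margin = max(2, int(round(2.0 / spacing)))
    interior = ((ys >= margin) & (ys < geom.ny - margin)
                & (xs >= margin) & (xs < geom.nx - margin))
    candidates = (labels == main) & interior
    diag = math.hypot(geom.ny, geom.nx)

    def best_node(corner_iy: int, corner_ix: int) -> tuple[int, int]:
        dist = np.hypot(ys - corner_iy, xs - corner_ix) / diag
        score = np.where(candidates, density + dist, np.inf)
        iy, ix = np.unravel_index(np.argmin(score), score.shape)
        return (int(iy), int(ix))

    landmarks = {
        "septal_pacing_site": best_node(0, 0),
        "appendage_roi": best_node(geom.ny - 1, geom.nx - 1),
    }
    py, px = landmarks["septal_pacing_site"]
    pacing_disc = ((ys - py) ** 2 + (xs - px) ** 2) <= (1.5 / spacing) ** 2
    fib[pacing_disc] = False
    fib[landmarks["appendage_roi"]] = False
    manifest = {
        "seed": seed, "size_mm": size_mm, "spacing": spacing,
        "correlation_length": correlation_length,
        "low_voltage_fraction": low_voltage_fraction,
        "fiber_pattern": fiber_pattern, "d_long": d_long,
        "anisotropy": anisotropy, "n_points": n_points,
        "idw_power": idw_power, "idw_radius": idw_radius,
    }
    return Substrate(geometry=geom, voltage=voltage, fibrotic=fib,
                     fiber_angle=angles, d_long=d_long, anisotropy=anisotropy,
                     points=points, landmarks=landmarks, manifest=manifest)
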
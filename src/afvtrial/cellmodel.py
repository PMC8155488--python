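"""Human atrial myocyte ionic model (Courtemanche–Ramirez–Nattel family).

Implements the CRN action-potential model (21 state variables: membrane
potential, 15 Hodgkin–Huxley-type gates, 5 intracellular concentrations)
with a multiplier vector on the maximal conductances / pump rates, so that
genotype, AF remodeling and channel-blocking drugs enter purely as
conductance scaling.  On top of the ODE core sit the measurement
operations used throughout the package: single-cell pacing with a
diastolic-threshold stimulus, APD90 measurement, a decremental-ramp
restitution protocol, and the exponential restitution fit

    APD(DI) = y0 + A1 * (1 - exp(-DI / tau1))

whose maximal slope over the observed diastolic intervals (attained at the
smallest captured DI for a saturating fit) is the restitution-slope marker
Smax.

Numerics: forward Euler on membrane potential and concentrations with
Rush–Larsen exponential updates on all gates, default dt = 0.01 ms for
single-cell work.  The acetylcholine-activated K+ current is carried as a
scale slot for completeness but has zero baseline conductance, so its
multiplier is inert unless a conductance is configured.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields as dataclass_fields
from typing import Sequence

import numpy as np
from numba import njit
from scipy.optimize import curve_fit

__all__ = [
    "SCALE_NAMES",
    "STATE_NAMES",
    "ConductanceScales",
    "CellState",
    "RestitutionCurve",
    "PacedTraces",
    "resting_state",
    "derivatives",
    "diastolic_threshold",
    "pace_cell",
    "measure_apd90",
    "restitution_protocol",
    "fit_restitution",
]

# ---------------------------------------------------------------------------
# State and scale vector layouts
# ---------------------------------------------------------------------------

STATE_NAMES = (
    "V", "m", "h", "j", "oa", "oi", "ua", "ui", "xr", "xs",
    "d", "f", "fCa", "u", "v", "w", "Na_i", "K_i", "Ca_i", "Ca_up", "Ca_rel",
)

#: Order of the conductance/pump multiplier vector.
SCALE_NAMES = (
    "gNa", "gK1", "gto", "gKr", "gCaL", "gKur", "gKs",
    "INaCa_max", "INaK_max", "Iup_max", "Krel", "Caup_max", "ACh",
)

N_STATES = len(STATE_NAMES)
N_SCALES = len(SCALE_NAMES)

# Published initial conditions (quiescent steady state) of the CRN model.
_RESTING = np.array([
    -81.18,        # V (mV)
    2.908e-3,      # m
    9.649e-1,      # h
    9.775e-1,      # j
    3.043e-2,      # oa
    9.992e-1,      # oi
    4.966e-3,      # ua
    9.986e-1,      # ui
    3.296e-5,      # xr
    1.869e-2,      # xs
    1.367e-4,      # d
    9.996e-1,      # f
    7.755e-1,      # fCa
    0.0,           # u
    1.0,           # v
    9.992e-1,      # w
    11.17,         # Na_i (mM)
    139.0,         # K_i (mM)
    1.013e-4,      # Ca_i (mM)
    1.488,         # Ca_up (mM)
    1.488,         # Ca_rel (mM)
])


@dataclass(frozen=True)
class ConductanceScales:
    """Multipliers on the model's maximal conductances and pump rates.

    1.0 means the unscaled model value (100%); the identity vector is all
    ones.  ``ACh`` multiplies the acetylcholine-activated K+ conductance,
    which is zero at baseline.
    """

    gNa: float = 1.0
    gK1: float = 1.0
    gto: float = 1.0
    gKr: float = 1.0
    gCaL: float = 1.0
    gKur: float = 1.0
    gKs: float = 1.0
    INaCa_max: float = 1.0
    INaK_max: float = 1.0
    Iup_max: float = 1.0
    Krel: float = 1.0
    Caup_max: float = 1.0
    ACh: float = 1.0

    def __post_init__(self) -> None:
        for f in dataclass_fields(self):
            v = getattr(self, f.name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"scale {f.name} must be finite and >= 0, got {v}")

    def as_vector(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in SCALE_NAMES], dtype=np.float64)

    def as_dict(self) -> dict[str, float]:
        return {n: getattr(self, n) for n in SCALE_NAMES}

    @classmethod
    def from_vector(cls, vec: Sequence[float]) -> "ConductanceScales":
        vec = np.asarray(vec, dtype=float)
        if vec.shape != (N_SCALES,):
            raise ValueError(f"expected {N_SCALES} scales, got shape {vec.shape}")
        return cls(**dict(zip(SCALE_NAMES, vec.tolist())))

    @classmethod
    def identity(cls) -> "ConductanceScales":
        return cls()


@dataclass
class CellState:
    """Full ionic state of one atrial myocyte as a named view on a vector."""

    y: np.ndarray = field(default_factory=lambda: _RESTING.copy())

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=np.float64)
        if self.y.shape != (N_STATES,):
            raise ValueError(f"state vector must have length {N_STATES}")

    def __getattr__(self, name: str):
        if name in STATE_NAMES:
            return self.y[STATE_NAMES.index(name)]
        raise AttributeError(name)

    def validate(self) -> None:
        """Check physical invariants: gates in [0,1], concentrations > 0."""
        if not np.all(np.isfinite(self.y)):
            raise ValueError("non-finite state (numerical blow-up; use a smaller dt)")
        gates = self.y[1:16]
        if gates.min() < -1e-9 or gates.max() > 1 + 1e-9:
            raise ValueError("gating variable outside [0, 1]")
        if self.y[16:].min() <= 0:
            raise ValueError("non-positive ionic concentration")

    def copy(self) -> "CellState":
        return CellState(self.y.copy())


def resting_state() -> CellState:
    """The model's published quiescent state (identity scales)."""
    return CellState(_RESTING.copy())


# ---------------------------------------------------------------------------
# Model constants (CRN 1998 formulation)
# ---------------------------------------------------------------------------

_R = 8.3143          # J / (mol K)
_T = 310.0           # K
_F = 96.4867         # C / mmol
_RTF = _R * _T / _F

CM = 100.0           # membrane capacitance, pF
_VI = 13668.0        # intracellular volume, um^3
_VUP = 1109.52       # SR uptake compartment volume, um^3
_VREL = 96.48        # SR release compartment volume, um^3

_KO = 5.4            # mM
_NAO = 140.0         # mM
_CAO = 1.8           # mM

_GNA = 7.8           # nS/pF
_GK1 = 0.09
_GTO = 0.1652
_GKR = 0.029411765
_GKS = 0.12941176
_GCAL = 0.12375
_GBCA = 0.001131
_GBNA = 0.0006744375
_GACH = 0.0          # baseline ACh-activated K+ conductance (zero)

_INAK_MAX = 0.59933874   # pA/pF
_INACA_MAX = 1600.0      # pA/pF
_IPCA_MAX = 0.275        # pA/pF
_IUP_MAX = 0.005         # mM/ms
_KUP = 0.00092           # mM
_KREL = 30.0             # 1/ms
_CAUP_MAX = 15.0         # mM

_KM_NAI = 10.0
_KM_KO = 1.5
_KM_NA = 87.5
_KM_CA = 1.38
_KSAT = 0.1
_GAMMA = 0.35

_CMDN_MAX = 0.05
_TRPN_MAX = 0.07
_CSQN_MAX = 10.0
_KM_CMDN = 0.00238
_KM_TRPN = 0.0005
_KM_CSQN = 0.8

_TAU_TR = 180.0
_TAU_U = 8.0
_TAU_FCA = 2.0
_KQ10 = 3.0


# ---------------------------------------------------------------------------
# Core physics: one scalar evaluation of all currents and gate kinetics
# ---------------------------------------------------------------------------

@njit(cache=True)
def _physics(V, m, h, j, oa, oi, ua, ui, xr, xs, d, f, fca, u, v, w,
             nai, ki, cai, caup, carel,
             sNa, sK1, sto, sKr, sCaL, sKur, sKs,
             sNaCa, sNaK, sIup, sKrel, sCaup, sACh):
    """All ionic currents, concentration fluxes and gate kinetics at one state.

    Returns (minus_iion [mV/ms], dNai, dKi, dCai, dCaup, dCarel [mM/ms],
    then 15 (inf, tau) pairs for gates in state order).
    """
    # Nernst potentials
    ena = _RTF * math.log(_NAO / nai)
    ek = _RTF * math.log(_KO / ki)
    eca = 0.5 * _RTF * math.log(_CAO / cai)

    # --- membrane currents (pA/pF) -------------------------------------
    ina = sNa * _GNA * m * m * m * h * j * (V - ena)
    ik1 = sK1 * _GK1 * (V - ek) / (1.0 + math.exp(0.07 * (V + 80.0)))
    ito = sto * _GTO * oa * oa * oa * oi * (V - ek)
    gkur = 0.005 + 0.05 / (1.0 + math.exp(-(V - 15.0) / 13.0))
    ikur = sKur * gkur * ua * ua * ua * ui * (V - ek)
    ikr = sKr * _GKR * xr * (V - ek) / (1.0 + math.exp((V + 15.0) / 22.4))
    iks = sKs * _GKS * xs * xs * (V - ek)
    ical = sCaL * _GCAL * d * f * fca * (V - 65.0)
    ikach = sACh * _GACH * (V - ek)

    sigma = (math.exp(_NAO / 67.3) - 1.0) / 7.0
    fnak = 1.0 / (1.0 + 0.1245 * math.exp(-0.1 * V / _RTF)
                  + 0.0365 * sigma * math.exp(-V / _RTF))
    inak = sNaK * _INAK_MAX * fnak * (_KO / (_KO + _KM_KO)) \
        / (1.0 + (_KM_NAI / nai) ** 1.5)

    expg = math.exp(_GAMMA * V / _RTF)
    expg1 = math.exp((_GAMMA - 1.0) * V / _RTF)
    inaca = sNaCa * _INACA_MAX * (expg * nai ** 3 * _CAO - expg1 * _NAO ** 3 * cai) \
        / ((_KM_NA ** 3 + _NAO ** 3) * (_KM_CA + _CAO) * (1.0 + _KSAT * expg1))

    ipca = _IPCA_MAX * cai / (0.0005 + cai)
    ibna = _GBNA * (V - ena)
    ibca = _GBCA * (V - eca)

    iion = (ina + ik1 + ito + ikur + ikr + iks + ical + ikach
            + inak + inaca + ipca + ibna + ibca)

    # --- SR calcium handling (mM/ms) -----------------------------------
    irel = sKrel * _KREL * u * u * v * w * (carel - cai)
    itr = (caup - carel) / _TAU_TR
    iup = sIup * _IUP_MAX / (1.0 + _KUP / cai)
    iupleak = sIup * _IUP_MAX * caup / (sCaup * _CAUP_MAX)

    # --- concentration derivatives -------------------------------------
    dnai = (-3.0 * inak - 3.0 * inaca - ibna - ina) * CM / (_F * _VI)
    dki = (2.0 * inak - ik1 - ito - ikur - ikr - iks - ikach) * CM / (_F * _VI)

    b1 = (2.0 * inaca - ipca - ical - ibca) * CM / (2.0 * _F * _VI) \
        + (_VUP * (iupleak - iup) + irel * _VREL) / _VI
    b2 = 1.0 + _TRPN_MAX * _KM_TRPN / ((cai + _KM_TRPN) ** 2) \
        + _CMDN_MAX * _KM_CMDN / ((cai + _KM_CMDN) ** 2)
    dcai = b1 / b2

    dcaup = iup - iupleak - itr * _VREL / _VUP
    dcarel = (itr - irel) / (1.0 + _CSQN_MAX * _KM_CSQN / ((carel + _KM_CSQN) ** 2))

    # --- gate kinetics: (inf, tau) per gate ----------------------------
    # m
    dv = V + 47.13
    if abs(dv) < 1e-10:
        am = 3.2
    else:
        am = 0.32 * dv / (1.0 - math.exp(-0.1 * dv))
    bm = 0.08 * math.exp(-V / 11.0)
    tm = 1.0 / (am + bm)
    minf = am * tm

    # h, j
    if V >= -40.0:
        ah = 0.0
        bh = 1.0 / (0.13 * (1.0 + math.exp(-(V + 10.66) / 11.1)))
        aj = 0.0
        bj = 0.3 * math.exp(-2.535e-7 * V) / (1.0 + math.exp(-0.1 * (V + 32.0)))
    else:
        ah = 0.135 * math.exp(-(V + 80.0) / 6.8)
        bh = 3.56 * math.exp(0.079 * V) + 3.1e5 * math.exp(0.35 * V)
        aj = (-1.2714e5 * math.exp(0.2444 * V) - 3.474e-5 * math.exp(-0.04391 * V)) \
            * (V + 37.78) / (1.0 + math.exp(0.311 * (V + 79.23)))
        bj = 0.1212 * math.exp(-0.01052 * V) / (1.0 + math.exp(-0.1378 * (V + 40.14)))
    th = 1.0 / (ah + bh)
    hinf = ah * th
    tj = 1.0 / (aj + bj)
    jinf = aj * tj

    # oa, oi (Ito gates)
    aoa = 0.65 / (math.exp(-(V + 10.0) / 8.5) + math.exp(-(V - 30.0) / 59.0))
    boa = 0.65 / (2.5 + math.exp((V + 82.0) / 17.0))
    toa = 1.0 / ((aoa + boa) * _KQ10)
    oainf = 1.0 / (1.0 + math.exp(-(V + 20.47) / 17.54))

    aoi = 1.0 / (18.53 + math.exp((V + 113.7) / 10.95))
    boi = 1.0 / (35.56 + math.exp(-(V + 1.26) / 7.44))
    toi = 1.0 / ((aoi + boi) * _KQ10)
    oiinf = 1.0 / (1.0 + math.exp((V + 43.1) / 5.3))

    # ua, ui (IKur gates)
    aua = 0.65 / (math.exp(-(V + 10.0) / 8.5) + math.exp(-(V - 30.0) / 59.0))
    bua = 0.65 / (2.5 + math.exp((V + 82.0) / 17.0))
    tua = 1.0 / ((aua + bua) * _KQ10)
    uainf = 1.0 / (1.0 + math.exp(-(V + 30.3) / 9.6))

    aui = 1.0 / (21.0 + math.exp(-(V - 185.0) / 28.0))
    bui = math.exp((V - 158.0) / 16.0)
    tui = 1.0 / ((aui + bui) * _KQ10)
    uiinf = 1.0 / (1.0 + math.exp((V - 99.45) / 27.48))

    # xr
    dv = V + 14.1
    if abs(dv) < 1e-10:
        axr = 0.0015
    else:
        axr = 0.0003 * dv / (1.0 - math.exp(-dv / 5.0))
    dv = V - 3.3328
    if abs(dv) < 1e-10:
        bxr = 7.3898e-5 * 5.1237
    else:
        bxr = 7.3898e-5 * dv / (math.exp(dv / 5.1237) - 1.0)
    txr = 1.0 / (axr + bxr)
    xrinf = 1.0 / (1.0 + math.exp(-(V + 14.1) / 6.5))

    # xs
    dv = V - 19.9
    if abs(dv) < 1e-10:
        axs = 4e-5 * 17.0
        bxs = 3.5e-5 * 9.0
    else:
        axs = 4e-5 * dv / (1.0 - math.exp(-dv / 17.0))
        bxs = 3.5e-5 * dv / (math.exp(dv / 9.0) - 1.0)
    txs = 0.5 / (axs + bxs)
    xsinf = 1.0 / math.sqrt(1.0 + math.exp(-(V - 19.9) / 12.7))

    # d, f, fCa (ICaL gates)
    dv = V + 10.0
    if abs(dv) < 1e-10:
        td = 1.0 / (0.035 * 6.24 * 2.0)
    else:
        e = math.exp(-dv / 6.24)
        td = (1.0 - e) / (0.035 * dv * (1.0 + e))
    dinf = 1.0 / (1.0 + math.exp(-dv / 8.0))

    tf = 9.0 / (0.0197 * math.exp(-(0.0337 ** 2) * dv * dv) + 0.02)
    finf = 1.0 / (1.0 + math.exp((V + 28.0) / 6.9))

    fcainf = 1.0 / (1.0 + cai / 0.00035)
    tfca = _TAU_FCA

    # u, v, w (SR release gates driven by Fn)
    fn = 1e-12 * _VREL * irel \
        - (5e-13 / _F) * (0.5 * ical * CM - 0.2 * inaca * CM)
    uinf = 1.0 / (1.0 + math.exp(-(fn - 3.4175e-13) / 1.367e-15))
    tu = _TAU_U
    vinf = 1.0 - 1.0 / (1.0 + math.exp(-(fn - 6.835e-14) / 1.367e-15))
    tv = 1.91 + 2.09 / (1.0 + math.exp(-(fn - 3.4175e-13) / 1.367e-15))

    dv = V - 7.9
    if abs(dv) < 1e-10:
        tw = 6.0 * 0.2 / 1.3
    else:
        e = math.exp(-dv / 5.0)
        tw = 6.0 * (1.0 - e) / ((1.0 + 0.3 * e) * dv)
    winf = 1.0 - 1.0 / (1.0 + math.exp(-(V - 40.0) / 17.0))

    return (-iion, dnai, dki, dcai, dcaup, dcarel,
            minf, tm, hinf, th, jinf, tj, oainf, toa, oiinf, toi,
            uainf, tua, uiinf, tui, xrinf, txr, xsinf, txs,
            dinf, td, finf, tf, fcainf, tfca, uinf, tu, vinf, tv, winf, tw)


@njit(cache=True)
def _step_cell(y, k, s, istim, dt):
    """Advance node column ``y[:, k]`` one step (Euler V/conc, RL gates)."""
    (mi, dnai, dki, dcai, dcaup, dcarel,
     minf, tm, hinf, th, jinf, tj, oainf, toa, oiinf, toi,
     uainf, tua, uiinf, tui, xrinf, txr, xsinf, txs,
     dinf, td, finf, tf, fcainf, tfca, uinf, tu, vinf, tv, winf, tw) = _physics(
        y[0, k], y[1, k], y[2, k], y[3, k], y[4, k], y[5, k], y[6, k], y[7, k],
        y[8, k], y[9, k], y[10, k], y[11, k], y[12, k], y[13, k], y[14, k],
        y[15, k], y[16, k], y[17, k], y[18, k], y[19, k], y[20, k],
        s[0], s[1], s[2], s[3], s[4], s[5], s[6],
        s[7], s[8], s[9], s[10], s[11], s[12])

    y[0, k] += dt * (mi + istim)
    y[16, k] += dt * dnai
    y[17, k] += dt * dki
    y[18, k] += dt * dcai
    y[19, k] += dt * dcaup
    y[20, k] += dt * dcarel

    y[1, k] = minf - (minf - y[1, k]) * math.exp(-dt / tm)
    y[2, k] = hinf - (hinf - y[2, k]) * math.exp(-dt / th)
    y[3, k] = jinf - (jinf - y[3, k]) * math.exp(-dt / tj)
    y[4, k] = oainf - (oainf - y[4, k]) * math.exp(-dt / toa)
    y[5, k] = oiinf - (oiinf - y[5, k]) * math.exp(-dt / toi)
    y[6, k] = uainf - (uainf - y[6, k]) * math.exp(-dt / tua)
    y[7, k] = uiinf - (uiinf - y[7, k]) * math.exp(-dt / tui)
    y[8, k] = xrinf - (xrinf - y[8, k]) * math.exp(-dt / txr)
    y[9, k] = xsinf - (xsinf - y[9, k]) * math.exp(-dt / txs)
    y[10, k] = dinf - (dinf - y[10, k]) * math.exp(-dt / td)
    y[11, k] = finf - (finf - y[11, k]) * math.exp(-dt / tf)
    y[12, k] = fcainf - (fcainf - y[12, k]) * math.exp(-dt / tfca)
    y[13, k] = uinf - (uinf - y[13, k]) * math.exp(-dt / tu)
    y[14, k] = vinf - (vinf - y[14, k]) * math.exp(-dt / tv)
    y[15, k] = winf - (winf - y[15, k]) * math.exp(-dt / tw)


# ---------------------------------------------------------------------------
# Tabulated voltage-dependent rates (tissue fast path)
# ---------------------------------------------------------------------------
#
# All purely voltage-dependent quantities — the 12 V-driven gates'
# steady-states and Rush–Larsen factors exp(−dt/τ(V)), plus the IK1/IKr
# rectification, IKur conductance, Na/K-pump voltage factor and the
# exchanger exponentials — are precomputed on a fine V grid and linearly
# interpolated inside the tissue kernel.  The Ca²⁺/Fn-driven gates (fCa, u,
# v) stay analytic.  Tables are built once per dt and cached.

_TAB_VMIN = -100.0
_TAB_VMAX = 80.0
_TAB_DV = 0.05
_N_TAB_COLS = 30

_RATE_TABLES: dict[float, np.ndarray] = {}


def build_rate_table(dt: float) -> np.ndarray:
    """Voltage lookup table for one integration step size."""
    if dt in _RATE_TABLES:
        return _RATE_TABLES[dt]
    v = np.arange(_TAB_VMIN, _TAB_VMAX + _TAB_DV / 2, _TAB_DV)
    n = v.size
    tab = np.empty((n, _N_TAB_COLS))
    idx = 0
    state = _RESTING.copy()
    for i in range(n):
        out = _physics(v[i], *state[1:], *np.ones(N_SCALES))
        # gate (inf, rl-factor) pairs for the 12 V-driven gates, in state
        # order: m h j oa oi ua ui xr xs d f w
        gate_slots = (0, 1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 14)
        for c, g in enumerate(gate_slots):
            inf = out[6 + 2 * g]
            tau = out[7 + 2 * g]
            tab[i, 2 * c] = inf
            tab[i, 2 * c + 1] = math.exp(-dt / tau)
        tab[i, 24] = 1.0 / (1.0 + math.exp(0.07 * (v[i] + 80.0)))
        tab[i, 25] = 0.005 + 0.05 / (1.0 + math.exp(-(v[i] - 15.0) / 13.0))
        tab[i, 26] = 1.0 / (1.0 + math.exp((v[i] + 15.0) / 22.4))
        sigma = (math.exp(_NAO / 67.3) - 1.0) / 7.0
        tab[i, 27] = 1.0 / (1.0 + 0.1245 * math.exp(-0.1 * v[i] / _RTF)
                            + 0.0365 * sigma * math.exp(-v[i] / _RTF))
        tab[i, 28] = math.exp(_GAMMA * v[i] / _RTF)
        tab[i, 29] = math.exp((_GAMMA - 1.0) * v[i] / _RTF)
        idx += 1
    _RATE_TABLES[dt] = tab
    return tab


@njit(cache=True)
def _step_cell_lut(y, k, s, istim, dt, tab, rlf_fca, rlf_u):
    """Tabulated-rates variant of the cell step (tissue fast path)."""
    V = y[0, k]
    if V < _TAB_VMIN:
        V = _TAB_VMIN
    elif V > _TAB_VMAX - _TAB_DV:
        V = _TAB_VMAX - _TAB_DV
    x = (V - _TAB_VMIN) / _TAB_DV
    i = int(x)
    fr = x - i

    nai = y[16, k]
    ki = y[17, k]
    cai = y[18, k]
    caup = y[19, k]
    carel = y[20, k]

    ena = _RTF * math.log(_NAO / nai)
    ek = _RTF * math.log(_KO / ki)
    eca = 0.5 * _RTF * math.log(_CAO / cai)

    Vm = y[0, k]
    m = y[1, k]
    h = y[2, k]
    jg = y[3, k]
    oa = y[4, k]
    oi = y[5, k]
    ua = y[6, k]
    ui = y[7, k]
    xr = y[8, k]
    xs = y[9, k]
    d = y[10, k]
    f = y[11, k]
    fca = y[12, k]
    u = y[13, k]
    vg = y[14, k]
    w = y[15, k]

    rect_k1 = tab[i, 24] * (1.0 - fr) + tab[i + 1, 24] * fr
    gkur = tab[i, 25] * (1.0 - fr) + tab[i + 1, 25] * fr
    rect_kr = tab[i, 26] * (1.0 - fr) + tab[i + 1, 26] * fr
    fnak = tab[i, 27] * (1.0 - fr) + tab[i + 1, 27] * fr
    expg = tab[i, 28] * (1.0 - fr) + tab[i + 1, 28] * fr
    expg1 = tab[i, 29] * (1.0 - fr) + tab[i + 1, 29] * fr

    ina = s[0] * _GNA * m * m * m * h * jg * (Vm - ena)
    ik1 = s[1] * _GK1 * (Vm - ek) * rect_k1
    ito = s[2] * _GTO * oa * oa * oa * oi * (Vm - ek)
    ikur = s[5] * gkur * ua * ua * ua * ui * (Vm - ek)
    ikr = s[3] * _GKR * xr * (Vm - ek) * rect_kr
    iks = s[6] * _GKS * xs * xs * (Vm - ek)
    ical = s[4] * _GCAL * d * f * fca * (Vm - 65.0)
    ikach = s[12] * _GACH * (Vm - ek)

    inak = s[8] * _INAK_MAX * fnak * (_KO / (_KO + _KM_KO)) \
        / (1.0 + (_KM_NAI / nai) ** 1.5)
    inaca = s[7] * _INACA_MAX * (expg * nai ** 3 * _CAO - expg1 * _NAO ** 3 * cai) \
        / ((_KM_NA ** 3 + _NAO ** 3) * (_KM_CA + _CAO) * (1.0 + _KSAT * expg1))
    ipca = _IPCA_MAX * cai / (0.0005 + cai)
    ibna = _GBNA * (Vm - ena)
    ibca = _GBCA * (Vm - eca)

    iion = (ina + ik1 + ito + ikur + ikr + iks + ical + ikach
            + inak + inaca + ipca + ibna + ibca)

    irel = s[10] * _KREL * u * u * vg * w * (carel - cai)
    itr = (caup - carel) / _TAU_TR
    iup = s[9] * _IUP_MAX / (1.0 + _KUP / cai)
    iupleak = s[9] * _IUP_MAX * caup / (s[11] * _CAUP_MAX)

    dnai = (-3.0 * inak - 3.0 * inaca - ibna - ina) * CM / (_F * _VI)
    dki = (2.0 * inak - ik1 - ito - ikur - ikr - iks - ikach) * CM / (_F * _VI)
    b1 = (2.0 * inaca - ipca - ical - ibca) * CM / (2.0 * _F * _VI) \
        + (_VUP * (iupleak - iup) + irel * _VREL) / _VI
    b2 = 1.0 + _TRPN_MAX * _KM_TRPN / ((cai + _KM_TRPN) ** 2) \
        + _CMDN_MAX * _KM_CMDN / ((cai + _KM_CMDN) ** 2)

    y[0, k] += dt * (-iion + istim)
    y[16, k] += dt * dnai
    y[17, k] += dt * dki
    y[18, k] += dt * b1 / b2
    y[19, k] += dt * (iup - iupleak - itr * _VREL / _VUP)
    y[20, k] += dt * (itr - irel) / (1.0 + _CSQN_MAX * _KM_CSQN
                                     / ((carel + _KM_CSQN) ** 2))

    # V-driven gates from the table
    for c in range(12):
        inf = tab[i, 2 * c] * (1.0 - fr) + tab[i + 1, 2 * c] * fr
        rlf = tab[i, 2 * c + 1] * (1.0 - fr) + tab[i + 1, 2 * c + 1] * fr
        slot = c + 1 if c < 11 else 15      # m..f occupy 1..11, w is 15
        y[slot, k] = inf - (inf - y[slot, k]) * rlf

    # Ca/Fn-driven gates analytically
    fcainf = 1.0 / (1.0 + cai / 0.00035)
    y[12, k] = fcainf - (fcainf - fca) * rlf_fca
    fn = 1e-12 * _VREL * irel - (5e-13 / _F) * (0.5 * ical * CM - 0.2 * inaca * CM)
    e_fn = math.exp(-(fn - 3.4175e-13) / 1.367e-15)
    uinf = 1.0 / (1.0 + e_fn)
    y[13, k] = uinf - (uinf - u) * rlf_u
    vinf = 1.0 - 1.0 / (1.0 + math.exp(-(fn - 6.835e-14) / 1.367e-15))
    tv = 1.91 + 2.09 / (1.0 + e_fn)
    y[14, k] = vinf - (vinf - vg) * math.exp(-dt / tv)


@njit(cache=True)
def _run_cell(y, s, n_steps, dt, stim_starts, stim_amp, stim_dur, stride, v_out):
    """Integrate a single cell with a rectangular stimulus schedule.

    ``y`` has shape (N_STATES, 1); V is recorded every ``stride`` steps.
    """
    n_stim = stim_starts.size
    ptr = 0
    rec = 0
    for i in range(n_steps):
        t = i * dt
        while ptr < n_stim and t >= stim_starts[ptr] + stim_dur:
            ptr += 1
        istim = 0.0
        if ptr < n_stim and stim_starts[ptr] <= t < stim_starts[ptr] + stim_dur:
            istim = stim_amp
        _step_cell(y, 0, s, istim, dt)
        if i % stride == 0:
            v_out[rec] = y[0, 0]
            rec += 1
    return rec


# ---------------------------------------------------------------------------
# Public single-cell operations
# ---------------------------------------------------------------------------

def derivatives(
    state: CellState, scales: ConductanceScales, i_stim: float = 0.0
) -> np.ndarray:
    """Time derivative of the full state vector (units per ms).

    ``i_stim`` is a depolarizing stimulus current density in pA/pF
    (positive values depolarize).
    """
    state.validate()
    y = state.y
    s = scales.as_vector()
    out = _physics(*y, *s)
    minus_iion, dnai, dki, dcai, dcaup, dcarel = out[:6]
    dy = np.empty(N_STATES)
    dy[0] = minus_iion + i_stim
    dy[16] = dnai
    dy[17] = dki
    dy[18] = dcai
    dy[19] = dcaup
    dy[20] = dcarel
    for g in range(15):
        inf = out[6 + 2 * g]
        tau = out[7 + 2 * g]
        dy[1 + g] = (inf - y[1 + g]) / tau
    return dy


def _simulate(
    scales: ConductanceScales,
    stim_starts: np.ndarray,
    t_total: float,
    dt: float,
    stim_amp: float,
    stim_dur: float,
    record_dt: float,
    y0: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Low-level driver: returns (t, V, final state vector)."""
    stride = max(1, int(round(record_dt / dt)))
    n_steps = int(round(t_total / dt))
    y = np.empty((N_STATES, 1))
    y[:, 0] = _RESTING if y0 is None else y0
    v_out = np.empty(n_steps // stride + 1)
    nrec = _run_cell(y, scales.as_vector(), n_steps, dt,
                     np.asarray(stim_starts, dtype=np.float64),
                     stim_amp, stim_dur, stride, v_out)
    v = v_out[:nrec]
    t = np.arange(nrec) * stride * dt
    if not np.all(np.isfinite(v)):
        raise FloatingPointError(
            "membrane potential diverged (non-finite V); use a smaller dt")
    return t, v, y[:, 0].copy()


_THRESHOLD_CACHE: dict[tuple, float] = {}


def diastolic_threshold(
    scales: ConductanceScales,
    dt: float = 0.01,
    stim_dur: float = 2.0,
    lo: float = 0.5,
    hi: float = 200.0,
    rel_tol: float = 0.05,
) -> float:
    """Diastolic capture threshold (pA/pF) by bisection from rest.

    A probe stimulus captures if V crosses 0 mV within 50 ms.  The result
    is cached per (scales, dt, duration).
    """
    key = (tuple(scales.as_vector()), dt, stim_dur)
    if key in _THRESHOLD_CACHE:
        return _THRESHOLD_CACHE[key]

    def captures(amp: float) -> bool:
        _, v, _ = _simulate(scales, np.array([1.0]), 50.0, dt, amp, stim_dur, 0.1)
        return bool(v.max() > 0.0)

    if not captures(hi):
        raise RuntimeError(f"no capture even at {hi} pA/pF; cell inexcitable")
    if captures(lo):
        hi = lo  # already below threshold bracket; keep lo as answer
    while hi - lo > rel_tol * hi:
        mid = 0.5 * (lo + hi)
        if captures(mid):
            hi = mid
        else:
            lo = mid
    _THRESHOLD_CACHE[key] = hi
    return hi


@dataclass
class PacedTraces:
    """Result of a pacing run: continuous V(t) plus per-beat views."""

    t: np.ndarray                    # ms, whole run
    v: np.ndarray                    # mV, whole run
    cycle_length: float              # ms
    beat_starts: np.ndarray          # stimulus onset times, ms
    captured: np.ndarray             # bool per beat (upstroke above 0 mV)
    stim_amplitude: float            # pA/pF
    final_state: np.ndarray          # state vector at end of run

    def beat(self, k: int) -> tuple[np.ndarray, np.ndarray]:
        """(t, V) slice of beat ``k`` (from its stimulus to the next)."""
        t0 = self.beat_starts[k]
        t1 = (self.beat_starts[k + 1]
              if k + 1 < len(self.beat_starts) else self.t[-1] + 1e-9)
        m = (self.t >= t0) & (self.t < t1)
        return self.t[m], self.v[m]

    @property
    def all_captured(self) -> bool:
        return bool(self.captured.all())

    def last_beat(self) -> tuple[np.ndarray, np.ndarray]:
        return self.beat(len(self.beat_starts) - 1)

    def to_text(self) -> str:
        """Whole-run trace as tab-delimited text (time_ms, V_mV)."""
        lines = ["time_ms\tV_mV"]
        lines += [f"{t:.3f}\t{v:.4f}" for t, v in zip(self.t, self.v)]
        return "\n".join(lines) + "\n"

    def save(self, path) -> None:
        """Binary array container (.npz) with the stimulus metadata."""
        np.savez_compressed(
            path, t=self.t, v=self.v, beat_starts=self.beat_starts,
            captured=self.captured, final_state=self.final_state,
            cycle_length=self.cycle_length,
            stim_amplitude=self.stim_amplitude)


def pace_cell(
    scales: ConductanceScales,
    cycle_length: float = 600.0,
    n_beats: int = 10,
    dt: float = 0.01,
    stim_amplitude: float | None = None,
    stim_duration: float = 2.0,
    record_dt: float = 0.1,
    y0: np.ndarray | None = None,
) -> PacedTraces:
    """Pace a single cell with an S1 train and return all beats.

    The stimulus defaults to twice the diastolic threshold for 2 ms.  The
    run is fully deterministic.  Beats whose upstroke never reaches 0 mV
    are flagged as capture failures, never silently dropped.
    """
    if n_beats < 1:
        raise ValueError("n_beats must be >= 1")
    if cycle_length <= 0:
        raise ValueError("cycle_length must be positive")
    if stim_amplitude is None:
        stim_amplitude = 2.0 * diastolic_threshold(scales, dt, stim_duration)
    starts = 1.0 + cycle_length * np.arange(n_beats)
    t_total = 1.0 + cycle_length * n_beats
    t, v, yf = _simulate(scales, starts, t_total, dt,
                         stim_amplitude, stim_duration, record_dt, y0=y0)
    captured = np.empty(n_beats, dtype=bool)
    for k in range(n_beats):
        t0 = starts[k]
        t1 = starts[k + 1] if k + 1 < n_beats else t[-1] + 1e-9
        m = (t >= t0) & (t < t1)
        captured[k] = v[m].max() > 0.0 if m.any() else False
    return PacedTraces(t=t, v=v, cycle_length=cycle_length, beat_starts=starts,
                       captured=captured, stim_amplitude=stim_amplitude,
                       final_state=yf)


def measure_apd90(
    t: np.ndarray, v: np.ndarray, repol_fraction: float = 0.9
) -> float:
    """APD at ``repol_fraction`` repolarization for one beat; NaN if undefined.

    Activation is the time of maximal dV/dt; the resting reference is the
    pre-upstroke minimum of the same beat; the threshold is
    ``V_rest + (1 - repol_fraction) * (V_peak - V_rest)``, with linear
    interpolation between samples at the downstroke crossing.
    """
    t = np.asarray(t, dtype=float)
    v = np.asarray(v, dtype=float)
    if t.size < 3:
        return math.nan
    dvdt = np.diff(v) / np.diff(t)
    i_act = int(np.argmax(dvdt))
    if dvdt[i_act] <= 0:
        return math.nan            # no upstroke at all
    t_act = t[i_act]
    v_rest = v[: i_act + 1].min() if i_act > 0 else v[0]
    seg_v = v[i_act:]
    seg_t = t[i_act:]
    i_peak = int(np.argmax(seg_v))
    v_peak = seg_v[i_peak]
    if v_peak <= v_rest + 1.0:
        return math.nan            # flat trace, no actual AP
    thr = v_rest + (1.0 - repol_fraction) * (v_peak - v_rest)
    below = np.nonzero(seg_v[i_peak:] <= thr)[0]
    if below.size == 0:
        return math.nan            # never repolarizes within the trace
    i_c = i_peak + below[0]
    if i_c == 0:
        return math.nan
    # linear interpolation between the bracketing samples
    v1, v2 = seg_v[i_c - 1], seg_v[i_c]
    t1, t2 = seg_t[i_c - 1], seg_t[i_c]
    t_cross = t1 + (thr - v1) * (t2 - t1) / (v2 - v1) if v2 != v1 else t2
    return float(t_cross - t_act)


def restitution_protocol(
    scales: ConductanceScales,
    cycle_lengths: Sequence[float] | None = None,
    beats_per_cl: int = 8,
    dt: float = 0.01,
    stim_amplitude: float | None = None,
    stim_duration: float = 2.0,
    record_dt: float = 0.1,
) -> list[tuple[float, float]]:
    """Decremental-ramp restitution: one (DI, APD90) pair per stage.

    Defaults to cycle lengths 600 down to 200 ms in 25 ms decrements with
    8 beats per stage, continuing from the previous stage's state.  At each
    stage the last beat is sampled; DI = CL − APD90 of the preceding beat.
    Stages with capture failure or non-positive DI are excluded.
    """
    if cycle_lengths is None:
        cycle_lengths = np.arange(600.0, 199.0, -25.0)
    cls = np.asarray(list(cycle_lengths), dtype=float)
    if cls.size == 0 or np.any(np.diff(cls) >= 0):
        raise ValueError("cycle lengths must be strictly decreasing")
    if stim_amplitude is None:
        stim_amplitude = 2.0 * diastolic_threshold(scales, dt, stim_duration)

    samples: list[tuple[float, float]] = []
    y0: np.ndarray | None = None
    for cl in cls:
        tr = pace_cell(scales, cl, beats_per_cl, dt, stim_amplitude,
                       stim_duration, record_dt, y0=y0)
        y0 = tr.final_state
        if not (tr.captured[-1] and tr.captured[-2]):
            continue
        apd_prev = measure_apd90(*tr.beat(beats_per_cl - 2))
        apd_last = measure_apd90(*tr.beat(beats_per_cl - 1))
        if math.isnan(apd_prev) or math.isnan(apd_last):
            continue
        di = cl - apd_prev
        if di <= 0:
            continue
        samples.append((float(di), float(apd_last)))
    if not samples:
        raise RuntimeError("restitution ramp produced no captured samples")
    return samples


@dataclass
class RestitutionCurve:
    """Fitted exponential restitution curve and its maximal observed slope."""

    samples: list[tuple[float, float]]
    y0: float
    A1: float
    tau1: float
    smax: float

    def predict(self, di: np.ndarray) -> np.ndarray:
        di = np.asarray(di, dtype=float)
        return self.y0 + self.A1 * (1.0 - np.exp(-di / self.tau1))


def _resti_model(di, y0, a1, tau1):
    return y0 + a1 * (1.0 - np.exp(-di / tau1))


def fit_restitution(samples: Sequence[tuple[float, float]]) -> RestitutionCurve:
    """Least-squares fit of APD(DI) = y0 + A1 (1 − exp(−DI/τ1)).

    Smax is the slope of the fitted curve at the smallest observed DI,
    (A1/τ1)·exp(−DI_min/τ1) — the maximum over the observed domain for a
    saturating (A1 ≥ 0) fit.  Falls back to a finite-difference slope when
    the optimizer cannot converge.
    """
    samples = [(float(a), float(b)) for a, b in samples]
    if len(samples) < 4:
        raise ValueError("need at least 4 (DI, APD90) samples")
    di = np.array([s[0] for s in samples])
    apd = np.array([s[1] for s in samples])
    if np.unique(di).size < 2:
        raise ValueError("degenerate samples: all DIs identical")

    di_min = float(di.min())
    apd_span = float(apd.max() - apd.min())
    p0 = (float(apd.min()), max(apd_span, 1e-3), max(di_min, 30.0))
    try:
        popt, _ = curve_fit(
            _resti_model, di, apd, p0=p0,
            bounds=([-np.inf, 0.0, 1e-6], [np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
        y0_, a1, tau1 = (float(x) for x in popt)
        smax = (a1 / tau1) * math.exp(-di_min / tau1)
    except RuntimeError:
        # non-convergence: steepest finite-difference slope as fallback
        order = np.argsort(di)
        d_s, a_s = di[order], apd[order]
        slopes = np.diff(a_s) / np.diff(d_s)
        smax = float(max(slopes.max(), 0.0)) if slopes.size else 0.0
        y0_, a1, tau1 = float(a_s[0]), 0.0, math.nan
    return RestitutionCurve(samples=samples, y0=y0_, A1=a1, tau1=tau1,
                            smax=float(max(smax, 0.0)))
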
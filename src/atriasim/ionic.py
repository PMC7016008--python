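"""Courtemanche–Ramirez–Nattel (CRN) human atrial myocyte model.

The CRN model describes the human atrial action potential with 21 state
variables: membrane potential ``vm`` (mV), 15 Hodgkin–Huxley-type gating
variables (dimensionless, in [0, 1]) and 5 ionic pools (intracellular Na+,
K+, Ca2+ and the uptake/release compartments of the sarcoplasmic reticulum,
mM).  Constants follow the original 1998 formulation as curated in the
public model repositories.

Electrical remodeling is expressed through :class:`IonChannelScaling` — one
multiplicative factor per targeted membrane current.  Two canonical
profiles are provided:

* :func:`af_remodeling_profile` — chronic atrial-fibrillation remodeling
  (I_K1 +100 %, I_NCX +40 %, I_Na −10 %, I_to −70 %, I_CaL −50 %,
  I_Kur −50 %);
* :func:`fibrosis_remodeling_profile` — additional down-regulation in
  fibrotic tissue (I_K1 −50 %, I_CaL −50 %, I_Na −40 %), applied
  multiplicatively on top of any base profile.

Two numerical routes are exposed: :func:`crn_derivatives` (vectorized
NumPy right-hand side, used for steady-state and algebraic checks and as a
plain-ODE entry point) and a numba-compiled Rush–Larsen stepper used by
:func:`integrate_cell` and by the tissue solver (gates updated
exponentially via their steady state and time constant, potential and
concentrations by forward Euler).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from numba import njit

__all__ = [
    "N_STATE",
    "IDX_VM",
    "GATE_SLICE",
    "CONC_SLICE",
    "STATE_NAMES",
    "IonChannelScaling",
    "neutral_profile",
    "af_remodeling_profile",
    "fibrosis_remodeling_profile",
    "CellState",
    "resting_state",
    "crn_currents",
    "crn_derivatives",
    "StimulusTrain",
    "ActionPotentialTrace",
    "integrate_cell",
    "compute_apd90",
    "DT_MIN",
    "DT_MAX",
    "UPSTROKE_DVDT",
]

# ---------------------------------------------------------------------------
# State layout
# ---------------------------------------------------------------------------

STATE_NAMES = (
    "vm",
    "m", "h", "j",            # fast Na+ current gates
    "oa", "oi",               # transient outward K+ gates
    "ua", "ui",               # ultrarapid delayed rectifier gates
    "xr", "xs",               # rapid / slow delayed rectifier gates
    "d", "f", "fca",          # L-type Ca2+ gates
    "u", "v", "w",            # SR Ca2+-release gates
    "nai", "ki", "cai", "ca_up", "ca_rel",
)
N_STATE = 21
IDX_VM = 0
GATE_SLICE = slice(1, 16)
CONC_SLICE = slice(16, 21)

# Adaptive time-step bounds (ms) and the upstroke criterion (mV/ms) that
# switches between them.
DT_MIN = 0.01
DT_MAX = 0.1
UPSTROKE_DVDT = 1.0

# ---------------------------------------------------------------------------
# Model constants (units: mV, ms, pA, pF, nS, mM, µm^3)
# ---------------------------------------------------------------------------

R_GAS = 8.3143          # J / (mol K)
TEMP = 310.0            # K
FARADAY = 96.4867       # C / mmol
RTF = R_GAS * TEMP / FARADAY  # ≈ 26.71 mV

CM = 100.0              # membrane capacitance, pF

V_I = 13668.0           # intracellular volume, µm^3
V_UP = 1109.52          # SR uptake compartment volume
V_REL = 96.48           # SR release compartment volume

NA_O = 140.0            # extracellular Na+, mM
K_O = 5.4               # extracellular K+
CA_O = 1.8              # extracellular Ca2+

G_NA = 7.8              # nS/pF
G_K1 = 0.09
G_TO = 0.1652
G_KR = 0.029411765
G_KS = 0.12941176
G_CAL = 0.12375
G_B_CA = 0.001131
G_B_NA = 0.0006744375

I_NAK_MAX = 0.59933874  # pA/pF
KM_NAI = 10.0
KM_KO = 1.5
I_NACA_MAX = 1600.0     # pA/pF
KM_NA = 87.5
KM_CA = 1.38
K_SAT = 0.1
GAMMA = 0.35
I_PCA_MAX = 0.275       # pA/pF

K_REL = 30.0            # ms^-1
I_UP_MAX = 0.005        # mM/ms
K_UP = 0.00092
CA_UP_MAX = 15.0
TAU_TR = 180.0          # ms
TAU_F_CA = 2.0
TAU_U = 8.0

CMDN_MAX = 0.05
TRPN_MAX = 0.07
CSQN_MAX = 10.0
KM_CMDN = 0.00238
KM_TRPN = 0.0005
KM_CSQN = 0.8

K_Q10 = 3.0             # temperature scaling of I_to / I_Kur kinetics

SIGMA_NAK = (np.exp(NA_O / 67.3) - 1.0) / 7.0

# Default rectangular stimulus: ~2x diastolic threshold.
STIM_AMPLITUDE = -2000.0  # pA
STIM_DURATION = 2.0       # ms

# Published resting steady state.
_REST = np.array([
    -81.18,
    2.908e-3, 9.649e-1, 9.775e-1,
    3.043e-2, 9.992e-1,
    4.966e-3, 9.986e-1,
    3.296e-5, 1.869e-2,
    1.367e-4, 9.996e-1, 7.755e-1,
    0.0, 1.0, 9.992e-1,
    1.117e1, 1.39e2, 1.013e-4, 1.488, 1.488,
])


def resting_state() -> np.ndarray:
    """Return the published CRN resting state as a fresh (21,) array."""
    return _REST.copy()


# ---------------------------------------------------------------------------
# Channel-scaling profiles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IonChannelScaling:
    """Multiplicative scaling of the six remodeling-targeted currents.

    Factors multiply the CRN formulation of the corresponding current; all
    other currents are left untouched (factor 1).  The neutral profile has
    every factor equal to one.
    """

    f_na: float = 1.0
    f_to: float = 1.0
    f_kur: float = 1.0
    f_k1: float = 1.0
    f_cal: float = 1.0
    f_ncx: float = 1.0

    def __post_init__(self) -> None:
        for name in ("f_na", "f_to", "f_kur", "f_k1", "f_cal", "f_ncx"):
            if not getattr(self, name) > 0:
                raise ValueError(f"scaling factor {name} must be > 0")

    def compose(self, other: "IonChannelScaling") -> "IonChannelScaling":
        """Return the profile whose factors are the products of both."""
        return IonChannelScaling(
            f_na=self.f_na * other.f_na,
            f_to=self.f_to * other.f_to,
            f_kur=self.f_kur * other.f_kur,
            f_k1=self.f_k1 * other.f_k1,
            f_cal=self.f_cal * other.f_cal,
            f_ncx=self.f_ncx * other.f_ncx,
        )

    def as_array(self) -> np.ndarray:
        """Factor vector in kernel order (Na, to, Kur, K1, CaL, NCX)."""
        return np.array(
            [self.f_na, self.f_to, self.f_kur, self.f_k1, self.f_cal, self.f_ncx]
        )


def neutral_profile() -> IonChannelScaling:
    """Identity profile: every factor 1."""
    return IonChannelScaling()


def af_remodeling_profile() -> IonChannelScaling:
    """Chronic-AF electrical remodeling of the CRN currents."""
    return IonChannelScaling(
        f_k1=2.0, f_ncx=1.4, f_na=0.9, f_to=0.3, f_cal=0.5, f_kur=0.5
    )


def fibrosis_remodeling_profile(
    base: IonChannelScaling | None = None,
) -> IonChannelScaling:
    """Fibrotic-myocyte down-regulation applied on top of ``base``.

    I_K1 and I_CaL are halved and I_Na reduced by 40 % relative to the base
    profile (factors multiply, so applying twice is not idempotent).
    """
    if base is None:
        base = neutral_profile()
    return base.compose(IonChannelScaling(f_k1=0.5, f_cal=0.5, f_na=0.6))


# ---------------------------------------------------------------------------
# CellState view
# ---------------------------------------------------------------------------

@dataclass
class CellState:
    """Typed view over the 21-component CRN state vector."""

    vector: np.ndarray

    def __post_init__(self) -> None:
        self.vector = np.asarray(self.vector, dtype=float)
        if self.vector.shape != (N_STATE,):
            raise ValueError(f"CellState expects shape ({N_STATE},)")

    @property
    def vm(self) -> float:
        return float(self.vector[IDX_VM])

    @property
    def gates(self) -> np.ndarray:
        return self.vector[GATE_SLICE]

    @property
    def concentrations(self) -> np.ndarray:
        return self.vector[CONC_SLICE]

    def validate(self) -> None:
        """Raise ``ValueError`` if the state violates its physical bounds."""
        if not np.all(np.isfinite(self.vector)):
            raise ValueError("non-finite state component")
        g = self.gates
        if np.any(g < -1e-9) or np.any(g > 1 + 1e-9):
            raise ValueError("gating variable outside [0, 1]")
        if np.any(self.concentrations <= 0):
            raise ValueError("non-positive ionic concentration")
        if not (-100.0 <= self.vm <= 60.0):
            raise ValueError(f"vm {self.vm:.1f} mV outside [-100, 60]")


# ---------------------------------------------------------------------------
# Rate equations (NumPy route)
# ---------------------------------------------------------------------------

def _safe_div(num, den, limit):
    """num/den with the removable singularity den→0 replaced by ``limit``."""
    den = np.asarray(den, dtype=float)
    small = np.abs(den) < 1e-10
    out = np.where(small, limit, num / np.where(small, 1.0, den))
    return out


def _gate_inf_tau(v, cai, fn):
    """Steady states and time constants for all 15 gates (vectorized).

    Returns two dicts keyed by gate name.  ``fn`` is the SR-release flux
    signal driving the u/v gates.
    """
    inf: dict[str, np.ndarray] = {}
    tau: dict[str, np.ndarray] = {}

    # --- I_Na gates -------------------------------------------------------
    a_m = _safe_div(
        0.32 * (v + 47.13), 1.0 - np.exp(-0.1 * (v + 47.13)), 3.2
    )
    b_m = 0.08 * np.exp(-v / 11.0)
    inf["m"] = a_m / (a_m + b_m)
    tau["m"] = 1.0 / (a_m + b_m)

    dep = v >= -40.0
    a_h = np.where(dep, 0.0, 0.135 * np.exp(-(v + 80.0) / 6.8))
    b_h = np.where(
        dep,
        1.0 / (0.13 * (1.0 + np.exp(-(v + 10.66) / 11.1))),
        3.56 * np.exp(0.079 * v) + 3.1e5 * np.exp(0.35 * v),
    )
    inf["h"] = a_h / (a_h + b_h)
    tau["h"] = 1.0 / (a_h + b_h)

    a_j = np.where(
        dep,
        0.0,
        (-1.2714e5 * np.exp(0.2444 * v) - 3.474e-5 * np.exp(-0.04391 * v))
        * (v + 37.78)
        / (1.0 + np.exp(0.311 * (v + 79.23))),
    )
    b_j = np.where(
        dep,
        0.3 * np.exp(-2.535e-7 * v) / (1.0 + np.exp(-0.1 * (v + 32.0))),
        0.1212 * np.exp(-0.01052 * v) / (1.0 + np.exp(-0.1378 * (v + 40.14))),
    )
    inf["j"] = a_j / (a_j + b_j)
    tau["j"] = 1.0 / (a_j + b_j)

    # --- I_to gates -------------------------------------------------------
    a_oa = 0.65 / (np.exp(-(v + 10.0) / 8.5) + np.exp(-(v - 30.0) / 59.0))
    b_oa = 0.65 / (2.5 + np.exp((v + 82.0) / 17.0))
    tau["oa"] = 1.0 / ((a_oa + b_oa) * K_Q10)
    inf["oa"] = 1.0 / (1.0 + np.exp(-(v + 20.47) / 17.54))

    a_oi = 1.0 / (18.53 + np.exp((v + 113.7) / 10.95))
    b_oi = 1.0 / (35.56 + np.exp(-(v + 1.26) / 7.44))
    tau["oi"] = 1.0 / ((a_oi + b_oi) * K_Q10)
    inf["oi"] = 1.0 / (1.0 + np.exp((v + 43.1) / 5.3))

    # --- I_Kur gates ------------------------------------------------------
    a_ua = 0.65 / (np.exp(-(v + 10.0) / 8.5) + np.exp(-(v - 30.0) / 59.0))
    b_ua = 0.65 / (2.5 + np.exp((v + 82.0) / 17.0))
    tau["ua"] = 1.0 / ((a_ua + b_ua) * K_Q10)
    inf["ua"] = 1.0 / (1.0 + np.exp(-(v + 30.3) / 9.6))

    a_ui = 1.0 / (21.0 + np.exp(-(v - 185.0) / 28.0))
    b_ui = np.exp((v - 158.0) / 16.0)
    tau["ui"] = 1.0 / ((a_ui + b_ui) * K_Q10)
    inf["ui"] = 1.0 / (1.0 + np.exp((v - 99.45) / 27.48))

    # --- I_Kr / I_Ks gates ------------------------------------------------
    a_xr = _safe_div(
        0.0003 * (v + 14.1), 1.0 - np.exp(-(v + 14.1) / 5.0), 0.0015
    )
    b_xr = _safe_div(
        7.3898e-5 * (v - 3.3328),
        np.exp((v - 3.3328) / 5.1237) - 1.0,
        7.3898e-5 * 5.1237,
    )
    tau["xr"] = 1.0 / (a_xr + b_xr)
    inf["xr"] = 1.0 / (1.0 + np.exp(-(v + 14.1) / 6.5))

    a_xs = _safe_div(
        4e-5 * (v - 19.9), 1.0 - np.exp(-(v - 19.9) / 17.0), 4e-5 * 17.0
    )
    b_xs = _safe_div(
        3.5e-5 * (v - 19.9), np.exp((v - 19.9) / 9.0) - 1.0, 3.5e-5 * 9.0
    )
    tau["xs"] = 0.5 / (a_xs + b_xs)
    inf["xs"] = 1.0 / np.sqrt(1.0 + np.exp(-(v - 19.9) / 12.7))

    # --- I_CaL gates ------------------------------------------------------
    e1 = np.exp(-(v + 10.0) / 6.24)
    tau["d"] = _safe_div(
        1.0 - e1, 0.035 * (v + 10.0) * (1.0 + e1), 1.0 / (0.035 * 6.24 * 2.0)
    )
    inf["d"] = 1.0 / (1.0 + np.exp(-(v + 10.0) / 8.0))

    tau["f"] = 9.0 / (0.0197 * np.exp(-(0.0337 ** 2) * (v + 10.0) ** 2) + 0.02)
    inf["f"] = 1.0 / (1.0 + np.exp((v + 28.0) / 6.9))

    tau["fca"] = np.full_like(np.asarray(v, dtype=float), TAU_F_CA)
    inf["fca"] = 1.0 / (1.0 + cai / 0.00035)

    # --- SR release gates -------------------------------------------------
    tau["u"] = np.full_like(np.asarray(v, dtype=float), TAU_U)
    inf["u"] = 1.0 / (1.0 + np.exp(-(fn - 3.4175e-13) / 13.67e-16))

    tau["v"] = 1.91 + 2.09 / (1.0 + np.exp(-(fn - 3.4175e-13) / 13.67e-16))
    inf["v"] = 1.0 - 1.0 / (1.0 + np.exp(-(fn - 6.835e-14) / 13.67e-16))

    e2 = np.exp(-(v - 7.9) / 5.0)
    tau["w"] = _safe_div(
        6.0 * (1.0 - e2), (1.0 + 0.3 * e2) * (v - 7.9), 6.0 / (5.0 * 1.3)
    )
    inf["w"] = 1.0 - 1.0 / (1.0 + np.exp(-(v - 40.0) / 17.0))

    return inf, tau


def crn_currents(state: np.ndarray, scaling: IonChannelScaling | None = None):
    """All membrane and SR currents for one or more states.

    ``state`` has shape (21,) or (n, 21).  Returns a dict of named currents
    (pA for membrane currents, mM/ms for SR fluxes) with the scaling
    factors applied.
    """
    if scaling is None:
        scaling = neutral_profile()
    s = np.atleast_2d(np.asarray(state, dtype=float))
    v = s[:, 0]
    m, h, j_g, oa, oi, ua, ui, xr, xs, d, f_g, fca, u, v_g, w = (
        s[:, k] for k in range(1, 16)
    )
    nai, ki, cai, ca_up, ca_rel = (s[:, k] for k in range(16, 21))

    e_na = RTF * np.log(NA_O / nai)
    e_k = RTF * np.log(K_O / ki)
    e_ca = 0.5 * RTF * np.log(CA_O / cai)

    cur: dict[str, np.ndarray] = {}
    cur["i_na"] = scaling.f_na * CM * G_NA * m ** 3 * h * j_g * (v - e_na)
    cur["i_k1"] = (
        scaling.f_k1 * CM * G_K1 * (v - e_k) / (1.0 + np.exp(0.07 * (v + 80.0)))
    )
    cur["i_to"] = scaling.f_to * CM * G_TO * oa ** 3 * oi * (v - e_k)
    g_kur = 0.005 + 0.05 / (1.0 + np.exp(-(v - 15.0) / 13.0))
    cur["i_kur"] = scaling.f_kur * CM * g_kur * ua ** 3 * ui * (v - e_k)
    cur["i_kr"] = (
        CM * G_KR * xr * (v - e_k) / (1.0 + np.exp((v + 15.0) / 22.4))
    )
    cur["i_ks"] = CM * G_KS * xs ** 2 * (v - e_k)
    cur["i_cal"] = scaling.f_cal * CM * G_CAL * d * f_g * fca * (v - 65.0)

    f_nak = 1.0 / (
        1.0
        + 0.1245 * np.exp(-0.1 * v / RTF)
        + 0.0365 * SIGMA_NAK * np.exp(-v / RTF)
    )
    cur["i_nak"] = (
        CM
        * I_NAK_MAX
        * f_nak
        * (1.0 / (1.0 + (KM_NAI / nai) ** 1.5))
        * (K_O / (K_O + KM_KO))
    )
    cur["i_naca"] = (
        scaling.f_ncx
        * CM
        * I_NACA_MAX
        * (
            np.exp(GAMMA * v / RTF) * nai ** 3 * CA_O
            - np.exp((GAMMA - 1.0) * v / RTF) * NA_O ** 3 * cai
        )
        / (
            (KM_NA ** 3 + NA_O ** 3)
            * (KM_CA + CA_O)
            * (1.0 + K_SAT * np.exp((GAMMA - 1.0) * v / RTF))
        )
    )
    cur["i_bna"] = CM * G_B_NA * (v - e_na)
    cur["i_bca"] = CM * G_B_CA * (v - e_ca)
    cur["i_pca"] = CM * I_PCA_MAX * cai / (0.0005 + cai)

    cur["i_rel"] = K_REL * u ** 2 * v_g * w * (ca_rel - cai)
    cur["i_up"] = I_UP_MAX / (1.0 + K_UP / cai)
    cur["i_up_leak"] = I_UP_MAX * ca_up / CA_UP_MAX
    cur["i_tr"] = (ca_up - ca_rel) / TAU_TR

    if np.asarray(state).ndim == 1:
        cur = {k: val[0] for k, val in cur.items()}
    return cur


def crn_derivatives(
    state: np.ndarray,
    scaling: IonChannelScaling | None = None,
    i_stim: float = 0.0,
) -> np.ndarray:
    """Time derivative of the full CRN state (shape preserved).

    ``i_stim`` is the applied stimulus current in pA (negative =
    depolarizing, i.e. inward by convention of the total-current sum).
    """
    arr = np.asarray(state, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite state passed to crn_derivatives")
    if scaling is None:
        scaling = neutral_profile()
    s = np.atleast_2d(arr)
    v = s[:, 0]
    cai = s[:, 18]
    cur = crn_currents(s, scaling)
    i_rel = cur["i_rel"]
    fn = 1e3 * (
        1e-15 * V_REL * i_rel
        - 1e-15 / (2.0 * FARADAY) * (0.5 * cur["i_cal"] - 0.2 * cur["i_naca"])
    )
    inf, tau = _gate_inf_tau(v, cai, fn)

    d = np.empty_like(s)
    i_ion = (
        cur["i_na"] + cur["i_k1"] + cur["i_to"] + cur["i_kur"] + cur["i_kr"]
        + cur["i_ks"] + cur["i_cal"] + cur["i_nak"] + cur["i_naca"]
        + cur["i_bna"] + cur["i_bca"] + cur["i_pca"]
    )
    d[:, 0] = -(i_ion + i_stim) / CM
    for k, name in enumerate(STATE_NAMES[1:16], start=1):
        d[:, k] = (inf[name] - s[:, k]) / tau[name]

    d[:, 16] = (
        -3.0 * cur["i_nak"] - 3.0 * cur["i_naca"] - cur["i_bna"] - cur["i_na"]
    ) / (V_I * FARADAY)
    d[:, 17] = (
        2.0 * cur["i_nak"] - cur["i_k1"] - cur["i_to"] - cur["i_kur"]
        - cur["i_kr"] - cur["i_ks"]
    ) / (V_I * FARADAY)
    b1 = (
        2.0 * cur["i_naca"] - cur["i_pca"] - cur["i_cal"] - cur["i_bca"]
    ) / (2.0 * V_I * FARADAY) + (
        V_UP * (cur["i_up_leak"] - cur["i_up"]) + i_rel * V_REL
    ) / V_I
    b2 = (
        1.0
        + TRPN_MAX * KM_TRPN / (cai + KM_TRPN) ** 2
        + CMDN_MAX * KM_CMDN / (cai + KM_CMDN) ** 2
    )
    d[:, 18] = b1 / b2
    d[:, 19] = cur["i_up"] - cur["i_up_leak"] - cur["i_tr"] * V_REL / V_UP
    d[:, 20] = (cur["i_tr"] - i_rel) / (
        1.0 + CSQN_MAX * KM_CSQN / (s[:, 20] + KM_CSQN) ** 2
    )
    return d.reshape(arr.shape)


# ---------------------------------------------------------------------------
# Rush–Larsen stepper (numba route — shared with the tissue solver)
# ---------------------------------------------------------------------------

@njit(fastmath=False)
def rl_step(states, scal, istim, dt):  # pragma: no cover - exercised via wrappers
    """Advance every cell in ``states`` (n, 21) by one step of ``dt`` ms.

    ``scal`` is (n, 6) in order (Na, to, Kur, K1, CaL, NCX); ``istim`` is
    the per-cell stimulus in pA.  Gates use the Rush–Larsen exponential
    update; vm and concentrations use forward Euler.  Returns the maximum
    |dvm/dt| over cells (used by the adaptive time-step rule).
    """
    n = states.shape[0]
    max_dvdt = 0.0
    for i in range(n):
        v = states[i, 0]
        m = states[i, 1]; h = states[i, 2]; jg = states[i, 3]
        oa = states[i, 4]; oi = states[i, 5]
        ua = states[i, 6]; ui = states[i, 7]
        xr = states[i, 8]; xs = states[i, 9]
        dg = states[i, 10]; fg = states[i, 11]; fca = states[i, 12]
        ug = states[i, 13]; vg = states[i, 14]; wg = states[i, 15]
        nai = states[i, 16]; ki = states[i, 17]; cai = states[i, 18]
        ca_up = states[i, 19]; ca_rel = states[i, 20]

        f_na = scal[i, 0]; f_to = scal[i, 1]; f_kur = scal[i, 2]
        f_k1 = scal[i, 3]; f_cal = scal[i, 4]; f_ncx = scal[i, 5]

        e_na = RTF * np.log(NA_O / nai)
        e_k = RTF * np.log(K_O / ki)
        e_ca = 0.5 * RTF * np.log(CA_O / cai)

        i_na = f_na * CM * G_NA * m * m * m * h * jg * (v - e_na)
        i_k1 = f_k1 * CM * G_K1 * (v - e_k) / (1.0 + np.exp(0.07 * (v + 80.0)))
        i_to = f_to * CM * G_TO * oa * oa * oa * oi * (v - e_k)
        g_kur = 0.005 + 0.05 / (1.0 + np.exp(-(v - 15.0) / 13.0))
        i_kur = f_kur * CM * g_kur * ua * ua * ua * ui * (v - e_k)
        i_kr = CM * G_KR * xr * (v - e_k) / (1.0 + np.exp((v + 15.0) / 22.4))
        i_ks = CM * G_KS * xs * xs * (v - e_k)
        i_cal = f_cal * CM * G_CAL * dg * fg * fca * (v - 65.0)
        f_nak = 1.0 / (
            1.0
            + 0.1245 * np.exp(-0.1 * v / RTF)
            + 0.0365 * SIGMA_NAK * np.exp(-v / RTF)
        )
        i_nak = (
            CM * I_NAK_MAX * f_nak
            * (1.0 / (1.0 + (KM_NAI / nai) ** 1.5))
            * (K_O / (K_O + KM_KO))
        )
        ex1 = np.exp(GAMMA * v / RTF)
        ex2 = np.exp((GAMMA - 1.0) * v / RTF)
        i_naca = (
            f_ncx * CM * I_NACA_MAX
            * (ex1 * nai * nai * nai * CA_O - ex2 * NA_O ** 3 * cai)
            / ((KM_NA ** 3 + NA_O ** 3) * (KM_CA + CA_O) * (1.0 + K_SAT * ex2))
        )
        i_bna = CM * G_B_NA * (v - e_na)
        i_bca = CM * G_B_CA * (v - e_ca)
        i_pca = CM * I_PCA_MAX * cai / (0.0005 + cai)

        i_rel = K_REL * ug * ug * vg * wg * (ca_rel - cai)
        i_up = I_UP_MAX / (1.0 + K_UP / cai)
        i_up_leak = I_UP_MAX * ca_up / CA_UP_MAX
        i_tr = (ca_up - ca_rel) / TAU_TR

        fn = 1e3 * (
            1e-15 * V_REL * i_rel
            - 1e-15 / (2.0 * FARADAY) * (0.5 * i_cal - 0.2 * i_naca)
        )

        # --- gate kinetics (inf, tau) ---
        x = v + 47.13
        if abs(x) < 1e-10:
            a_m = 3.2
        else:
            a_m = 0.32 * x / (1.0 - np.exp(-0.1 * x))
        b_m = 0.08 * np.exp(-v / 11.0)
        tau_m = 1.0 / (a_m + b_m)
        inf_m = a_m * tau_m

        if v >= -40.0:
            a_h = 0.0
            b_h = 1.0 / (0.13 * (1.0 + np.exp(-(v + 10.66) / 11.1)))
            a_j = 0.0
            b_j = 0.3 * np.exp(-2.535e-7 * v) / (1.0 + np.exp(-0.1 * (v + 32.0)))
        else:
            a_h = 0.135 * np.exp(-(v + 80.0) / 6.8)
            b_h = 3.56 * np.exp(0.079 * v) + 3.1e5 * np.exp(0.35 * v)
            a_j = (
                (-1.2714e5 * np.exp(0.2444 * v) - 3.474e-5 * np.exp(-0.04391 * v))
                * (v + 37.78)
                / (1.0 + np.exp(0.311 * (v + 79.23)))
            )
            b_j = (
                0.1212 * np.exp(-0.01052 * v)
                / (1.0 + np.exp(-0.1378 * (v + 40.14)))
            )
        tau_h = 1.0 / (a_h + b_h)
        inf_h = a_h * tau_h
        tau_j = 1.0 / (a_j + b_j)
        inf_j = a_j * tau_j

        a_oa = 0.65 / (np.exp(-(v + 10.0) / 8.5) + np.exp(-(v - 30.0) / 59.0))
        b_oa = 0.65 / (2.5 + np.exp((v + 82.0) / 17.0))
        tau_oa = 1.0 / ((a_oa + b_oa) * K_Q10)
        inf_oa = 1.0 / (1.0 + np.exp(-(v + 20.47) / 17.54))
        a_oi = 1.0 / (18.53 + np.exp((v + 113.7) / 10.95))
        b_oi = 1.0 / (35.56 + np.exp(-(v + 1.26) / 7.44))
        tau_oi = 1.0 / ((a_oi + b_oi) * K_Q10)
        inf_oi = 1.0 / (1.0 + np.exp((v + 43.1) / 5.3))

        tau_ua = tau_oa
        inf_ua = 1.0 / (1.0 + np.exp(-(v + 30.3) / 9.6))
        a_ui = 1.0 / (21.0 + np.exp(-(v - 185.0) / 28.0))
        b_ui = np.exp((v - 158.0) / 16.0)
        tau_ui = 1.0 / ((a_ui + b_ui) * K_Q10)
        inf_ui = 1.0 / (1.0 + np.exp((v - 99.45) / 27.48))

        x = v + 14.1
        if abs(x) < 1e-10:
            a_xr = 0.0015
        else:
            a_xr = 0.0003 * x / (1.0 - np.exp(-x / 5.0))
        x = v - 3.3328
        if abs(x) < 1e-10:
            b_xr = 7.3898e-5 * 5.1237
        else:
            b_xr = 7.3898e-5 * x / (np.exp(x / 5.1237) - 1.0)
        tau_xr = 1.0 / (a_xr + b_xr)
        inf_xr = 1.0 / (1.0 + np.exp(-(v + 14.1) / 6.5))

        x = v - 19.9
        if abs(x) < 1e-10:
            a_xs = 4e-5 * 17.0
            b_xs = 3.5e-5 * 9.0
        else:
            a_xs = 4e-5 * x / (1.0 - np.exp(-x / 17.0))
            b_xs = 3.5e-5 * x / (np.exp(x / 9.0) - 1.0)
        tau_xs = 0.5 / (a_xs + b_xs)
        inf_xs = 1.0 / np.sqrt(1.0 + np.exp(-x / 12.7))

        x = v + 10.0
        e1 = np.exp(-x / 6.24)
        if abs(x) < 1e-10:
            tau_d = 1.0 / (0.035 * 6.24 * 2.0)
        else:
            tau_d = (1.0 - e1) / (0.035 * x * (1.0 + e1))
        inf_d = 1.0 / (1.0 + np.exp(-x / 8.0))
        tau_f = 9.0 / (0.0197 * np.exp(-(0.0337 ** 2) * x * x) + 0.02)
        inf_f = 1.0 / (1.0 + np.exp((v + 28.0) / 6.9))
        inf_fca = 1.0 / (1.0 + cai / 0.00035)

        inf_u = 1.0 / (1.0 + np.exp(-(fn - 3.4175e-13) / 13.67e-16))
        tau_v_g = 1.91 + 2.09 * inf_u
        inf_v = 1.0 - 1.0 / (1.0 + np.exp(-(fn - 6.835e-14) / 13.67e-16))
        x = v - 7.9
        e2 = np.exp(-x / 5.0)
        if abs(x) < 1e-10:
            tau_w = 6.0 / (5.0 * 1.3)
        else:
            tau_w = 6.0 * (1.0 - e2) / ((1.0 + 0.3 * e2) * x)
        inf_w = 1.0 - 1.0 / (1.0 + np.exp(-(v - 40.0) / 17.0))

        # --- Rush–Larsen gate update ---
        states[i, 1] = inf_m + (m - inf_m) * np.exp(-dt / tau_m)
        states[i, 2] = inf_h + (h - inf_h) * np.exp(-dt / tau_h)
        states[i, 3] = inf_j + (jg - inf_j) * np.exp(-dt / tau_j)
        states[i, 4] = inf_oa + (oa - inf_oa) * np.exp(-dt / tau_oa)
        states[i, 5] = inf_oi + (oi - inf_oi) * np.exp(-dt / tau_oi)
        states[i, 6] = inf_ua + (ua - inf_ua) * np.exp(-dt / tau_ua)
        states[i, 7] = inf_ui + (ui - inf_ui) * np.exp(-dt / tau_ui)
        states[i, 8] = inf_xr + (xr - inf_xr) * np.exp(-dt / tau_xr)
        states[i, 9] = inf_xs + (xs - inf_xs) * np.exp(-dt / tau_xs)
        states[i, 10] = inf_d + (dg - inf_d) * np.exp(-dt / tau_d)
        states[i, 11] = inf_f + (fg - inf_f) * np.exp(-dt / tau_f)
        states[i, 12] = inf_fca + (fca - inf_fca) * np.exp(-dt / TAU_F_CA)
        states[i, 13] = inf_u + (ug - inf_u) * np.exp(-dt / TAU_U)
        states[i, 14] = inf_v + (vg - inf_v) * np.exp(-dt / tau_v_g)
        states[i, 15] = inf_w + (wg - inf_w) * np.exp(-dt / tau_w)

        # --- concentrations (forward Euler) ---
        d_nai = (-3.0 * i_nak - 3.0 * i_naca - i_bna - i_na) / (V_I * FARADAY)
        d_ki = (
            2.0 * i_nak - i_k1 - i_to - i_kur - i_kr - i_ks
        ) / (V_I * FARADAY)
        b1 = (2.0 * i_naca - i_pca - i_cal - i_bca) / (2.0 * V_I * FARADAY) + (
            V_UP * (i_up_leak - i_up) + i_rel * V_REL
        ) / V_I
        b2 = (
            1.0
            + TRPN_MAX * KM_TRPN / ((cai + KM_TRPN) ** 2)
            + CMDN_MAX * KM_CMDN / ((cai + KM_CMDN) ** 2)
        )
        states[i, 16] = nai + dt * d_nai
        states[i, 17] = ki + dt * d_ki
        states[i, 18] = cai + dt * b1 / b2
        states[i, 19] = ca_up + dt * (i_up - i_up_leak - i_tr * V_REL / V_UP)
        states[i, 20] = ca_rel + dt * (i_tr - i_rel) / (
            1.0 + CSQN_MAX * KM_CSQN / ((ca_rel + KM_CSQN) ** 2)
        )

        i_ion = (
            i_na + i_k1 + i_to + i_kur + i_kr + i_ks + i_cal + i_nak
            + i_naca + i_bna + i_bca + i_pca
        )
        dvdt = -(i_ion + istim[i]) / CM
        states[i, 0] = v + dt * dvdt
        if abs(dvdt) > max_dvdt:
            max_dvdt = abs(dvdt)
    return max_dvdt


# ---------------------------------------------------------------------------
# Single-cell integration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StimulusTrain:
    """Rectangular pacing stimuli for a single cell.

    ``times`` are pulse onsets in ms; each pulse lasts ``duration`` ms with
    constant ``amplitude`` pA (negative = depolarizing).
    """

    times: tuple[float, ...]
    amplitude: float = STIM_AMPLITUDE
    duration: float = STIM_DURATION

    @classmethod
    def regular(
        cls, n_beats: int, cycle_length: float, start: float = 10.0, **kw
    ) -> "StimulusTrain":
        return cls(
            times=tuple(start + i * cycle_length for i in range(n_beats)), **kw
        )


@dataclass
class ActionPotentialTrace:
    """Sampled membrane-potential trace with the stimulus schedule."""

    times: np.ndarray          # ms
    vm: np.ndarray             # mV
    stimulus_times: np.ndarray  # ms
    final_state: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.vm = np.asarray(self.vm, dtype=float)
        self.stimulus_times = np.asarray(self.stimulus_times, dtype=float)
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("trace times must be strictly increasing")


class NumericalBlowupError(RuntimeError):
    """Raised when the integrator leaves the physical voltage range."""


def integrate_cell(
    initial: np.ndarray | CellState,
    scaling: IonChannelScaling,
    protocol: StimulusTrain | Sequence[float],
    duration: float,
    dt: float | None = None,
    output_interval: float = 0.2,
) -> ActionPotentialTrace:
    """Integrate one CRN cell under a pacing protocol.

    ``dt=None`` selects the adaptive rule (0.01 ms during fast upstrokes,
    0.1 ms otherwise); a fixed ``dt`` must lie within [0.01, 0.1] ms.
    Returns the trace sampled every ``output_interval`` ms; the final full
    state is attached for warm restarts.
    """
    if isinstance(initial, CellState):
        state0 = initial.vector
    else:
        state0 = np.asarray(initial, dtype=float)
    if state0.shape != (N_STATE,):
        raise ValueError("initial state must have 21 components")
    if not isinstance(protocol, StimulusTrain):
        protocol = StimulusTrain(times=tuple(float(t) for t in protocol))
    if dt is not None and not (DT_MIN - 1e-12 <= dt <= DT_MAX + 1e-12):
        raise ValueError(f"dt must lie in [{DT_MIN}, {DT_MAX}] ms")
    if duration < 0:
        raise ValueError("duration must be >= 0")

    stim_times = np.asarray(protocol.times, dtype=float)
    if duration == 0:
        return ActionPotentialTrace(
            times=np.empty(0),
            vm=np.empty(0),
            stimulus_times=stim_times,
            final_state=state0.copy(),
        )

    states = state0.copy().reshape(1, N_STATE)
    scal = scaling.as_array().reshape(1, 6)
    istim = np.zeros(1)

    # Event edges: every stimulus onset and offset, so steps never straddle
    # a discontinuity of the applied current.
    edges = np.unique(
        np.concatenate([stim_times, stim_times + protocol.duration])
    )
    edges = edges[(edges > 0) & (edges < duration)]

    n_out = int(np.floor(duration / output_interval)) + 1
    out_t = np.arange(n_out) * output_interval
    out_v = np.empty(n_out)
    out_v[0] = states[0, 0]

    t = 0.0
    k_out = 1
    edge_idx = 0
    dt_cur = dt if dt is not None else DT_MIN
    last_dvdt = 0.0
    while t < duration - 1e-9:
        if dt is None:
            dt_cur = DT_MIN if last_dvdt > UPSTROKE_DVDT else DT_MAX
        step = dt_cur
        while edge_idx < edges.size and edges[edge_idx] <= t + 1e-9:
            edge_idx += 1
        if edge_idx < edges.size:
            step = min(step, edges[edge_idx] - t)
        if k_out < n_out:
            step = min(step, out_t[k_out] - t)
        step = min(step, duration - t)

        active = np.any(
            (stim_times <= t + 1e-9) & (t < stim_times + protocol.duration - 1e-9)
        )
        istim[0] = protocol.amplitude if active else 0.0
        last_dvdt = rl_step(states, scal, istim, step)
        t += step
        vm_now = states[0, 0]
        if not np.isfinite(vm_now) or abs(vm_now) > 200.0:
            raise NumericalBlowupError(
                f"membrane potential blew up at t = {t:.3f} ms"
            )
        if k_out < n_out and t >= out_t[k_out] - 1e-9:
            out_v[k_out] = vm_now
            k_out += 1

    return ActionPotentialTrace(
        times=out_t[:k_out],
        vm=out_v[:k_out],
        stimulus_times=stim_times,
        final_state=states[0].copy(),
    )


# ---------------------------------------------------------------------------
# APD measurement
# ---------------------------------------------------------------------------

def compute_apd90(
    trace: ActionPotentialTrace, beat_index: int = -1, threshold_fraction: float = 0.9
) -> float:
    """Action-potential duration at 90 % repolarization, in ms.

    The beat is located from the trace's stimulus schedule; activation time
    is the instant of maximum dvm/dt within the beat, and APD90 the time
    from activation until vm first recovers 90 % of the beat amplitude
    toward the pre-beat diastolic level (linear interpolation between
    samples).
    """
    t, v = trace.times, trace.vm
    if t.size < 3:
        raise ValueError("trace too short for APD measurement")
    stim = np.sort(trace.stimulus_times)
    if stim.size:
        beats = list(stim[stim < t[-1]])
    else:
        beats = [t[0]]
    if not beats:
        raise ValueError("no beat inside the trace")
    try:
        t_beat = beats[beat_index]
    except IndexError as exc:
        raise ValueError(f"beat_index {beat_index} out of range") from exc
    idx = beat_index % len(beats)
    t_next = beats[idx + 1] if idx + 1 < len(beats) else t[-1]

    sel = (t >= t_beat) & (t <= t_next)
    if sel.sum() < 3:
        raise ValueError("requested beat not covered by the trace")
    tb, vb = t[sel], v[sel]

    dvdt = np.diff(vb) / np.diff(tb)
    if np.max(dvdt) <= 0.5:  # mV/ms — no upstroke
        raise ValueError("no upstroke found in the requested beat")
    k_act = int(np.argmax(dvdt))
    t_act = tb[k_act]

    # Diastolic reference: vm at the start of the beat window (pre-beat
    # diastolic level, before the stimulus artifact).
    v_rest = vb[0]
    k_peak = k_act + int(np.argmax(vb[k_act:]))
    v_peak = vb[k_peak]
    v_thr = v_peak - threshold_fraction * (v_peak - v_rest)

    below = np.nonzero(vb[k_peak:] <= v_thr)[0]
    if below.size == 0:
        raise ValueError("repolarization to 90% not reached before next beat")
    k2 = k_peak + below[0]
    k1 = k2 - 1
    if vb[k2] == vb[k1]:
        t_cross = tb[k2]
    else:
        t_cross = tb[k1] + (v_thr - vb[k1]) / (vb[k2] - vb[k1]) * (tb[k2] - tb[k1])
    return float(t_cross - t_act)
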
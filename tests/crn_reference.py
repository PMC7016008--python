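"""Independent reference implementation of the CRN atrial myocyte model.

Transcribed directly from the original model publication as a plain ODE
right-hand side (dictionary state, no Rush–Larsen, no numba) and
integrated with SciPy's LSODA.  Serves as the oracle for action-potential
morphology and APD in the ionic-model tests; deliberately kept separate
from the package implementation.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import solve_ivp

R = 8.3143
T = 310.0
F = 96.4867
CM = 100.0
VI = 13668.0
VUP = 1109.52
VREL = 96.48
NAO, KO, CAO = 140.0, 5.4, 1.8

ORDER = [
    "V", "m", "h", "j", "oa", "oi", "ua", "ui", "xr", "xs",
    "d", "f", "fca", "u", "v", "w", "Nai", "Ki", "Cai", "Caup", "Carel",
]

Y0 = {
    "V": -81.18, "m": 2.908e-3, "h": 9.649e-1, "j": 9.775e-1,
    "oa": 3.043e-2, "oi": 9.992e-1, "ua": 4.966e-3, "ui": 9.986e-1,
    "xr": 3.296e-5, "xs": 1.869e-2, "d": 1.367e-4, "f": 9.996e-1,
    "fca": 7.755e-1, "u": 0.0, "v": 1.0, "w": 9.992e-1,
    "Nai": 11.17, "Ki": 139.0, "Cai": 1.013e-4, "Caup": 1.488, "Carel": 1.488,
}


def _rhs(t, y, stim_fn, scale):
    s = dict(zip(ORDER, y))
    V = s["V"]
    rtf = R * T / F

    ena = rtf * np.log(NAO / s["Nai"])
    ek = rtf * np.log(KO / s["Ki"])
    eca = rtf / 2.0 * np.log(CAO / s["Cai"])

    ina = scale.get("na", 1.0) * CM * 7.8 * s["m"] ** 3 * s["h"] * s["j"] * (V - ena)
    ik1 = scale.get("k1", 1.0) * CM * 0.09 * (V - ek) / (1 + np.exp(0.07 * (V + 80)))
    ito = scale.get("to", 1.0) * CM * 0.1652 * s["oa"] ** 3 * s["oi"] * (V - ek)
    gkur = 0.005 + 0.05 / (1 + np.exp(-(V - 15) / 13))
    ikur = scale.get("kur", 1.0) * CM * gkur * s["ua"] ** 3 * s["ui"] * (V - ek)
    ikr = CM * 0.029411765 * s["xr"] * (V - ek) / (1 + np.exp((V + 15) / 22.4))
    iks = CM * 0.12941176 * s["xs"] ** 2 * (V - ek)
    ical = scale.get("cal", 1.0) * CM * 0.12375 * s["d"] * s["f"] * s["fca"] * (V - 65)
    sigma = (np.exp(NAO / 67.3) - 1) / 7
    fnak = 1.0 / (1 + 0.1245 * np.exp(-0.1 * F * V / (R * T))
                  + 0.0365 * sigma * np.exp(-F * V / (R * T)))
    inak = CM * 0.59933874 * fnak / (1 + (10.0 / s["Nai"]) ** 1.5) * KO / (KO + 1.5)
    g = 0.35
    inaca = scale.get("ncx", 1.0) * CM * 1600 * (
        np.exp(g * F * V / (R * T)) * s["Nai"] ** 3 * CAO
        - np.exp((g - 1) * F * V / (R * T)) * NAO ** 3 * s["Cai"]
    ) / ((87.5 ** 3 + NAO ** 3) * (1.38 + CAO)
         * (1 + 0.1 * np.exp((g - 1) * F * V / (R * T))))
    ibna = CM * 0.0006744375 * (V - ena)
    ibca = CM * 0.001131 * (V - eca)
    ipca = CM * 0.275 * s["Cai"] / (0.0005 + s["Cai"])

    irel = 30.0 * s["u"] ** 2 * s["v"] * s["w"] * (s["Carel"] - s["Cai"])
    iup = 0.005 / (1 + 0.00092 / s["Cai"])
    iupleak = 0.005 * s["Caup"] / 15.0
    itr = (s["Caup"] - s["Carel"]) / 180.0
    fn = 1e3 * (1e-15 * VREL * irel - 1e-15 / (2 * F) * (0.5 * ical - 0.2 * inaca))

    def rate(alpha, beta):
        return alpha + beta, alpha / (alpha + beta)

    # gate kinetics
    dy = {}
    am = 3.2 if abs(V + 47.13) < 1e-10 else \
        0.32 * (V + 47.13) / (1 - np.exp(-0.1 * (V + 47.13)))
    bm = 0.08 * np.exp(-V / 11)
    k, inf = rate(am, bm)
    dy["m"] = (inf - s["m"]) * k

    if V >= -40:
        ah, bh = 0.0, 1 / (0.13 * (1 + np.exp(-(V + 10.66) / 11.1)))
        aj = 0.0
        bj = 0.3 * np.exp(-2.535e-7 * V) / (1 + np.exp(-0.1 * (V + 32)))
    else:
        ah = 0.135 * np.exp(-(V + 80) / 6.8)
        bh = 3.56 * np.exp(0.079 * V) + 3.1e5 * np.exp(0.35 * V)
        aj = ((-1.2714e5 * np.exp(0.2444 * V) - 3.474e-5 * np.exp(-0.04391 * V))
              * (V + 37.78) / (1 + np.exp(0.311 * (V + 79.23))))
        bj = 0.1212 * np.exp(-0.01052 * V) / (1 + np.exp(-0.1378 * (V + 40.14)))
    dy["h"] = ah * (1 - s["h"]) - bh * s["h"]
    dy["j"] = aj * (1 - s["j"]) - bj * s["j"]

    kq10 = 3.0
    aoa = 0.65 / (np.exp(-(V + 10) / 8.5) + np.exp(-(V - 30) / 59))
    boa = 0.65 / (2.5 + np.exp((V + 82) / 17))
    dy["oa"] = (1 / (1 + np.exp(-(V + 20.47) / 17.54)) - s["oa"]) * (aoa + boa) * kq10
    aoi = 1 / (18.53 + np.exp((V + 113.7) / 10.95))
    boi = 1 / (35.56 + np.exp(-(V + 1.26) / 7.44))
    dy["oi"] = (1 / (1 + np.exp((V + 43.1) / 5.3)) - s["oi"]) * (aoi + boi) * kq10
    dy["ua"] = (1 / (1 + np.exp(-(V + 30.3) / 9.6)) - s["ua"]) * (aoa + boa) * kq10
    aui = 1 / (21 + np.exp(-(V - 185) / 28))
    bui = np.exp((V - 158) / 16)
    dy["ui"] = (1 / (1 + np.exp((V - 99.45) / 27.48)) - s["ui"]) * (aui + bui) * kq10

    axr = 0.0015 if abs(V + 14.1) < 1e-10 else \
        0.0003 * (V + 14.1) / (1 - np.exp(-(V + 14.1) / 5))
    bxr = 7.3898e-5 * 5.1237 if abs(V - 3.3328) < 1e-10 else \
        7.3898e-5 * (V - 3.3328) / (np.exp((V - 3.3328) / 5.1237) - 1)
    dy["xr"] = (1 / (1 + np.exp(-(V + 14.1) / 6.5)) - s["xr"]) * (axr + bxr)
    axs = 4e-5 * 17 if abs(V - 19.9) < 1e-10 else \
        4e-5 * (V - 19.9) / (1 - np.exp(-(V - 19.9) / 17))
    bxs = 3.5e-5 * 9 if abs(V - 19.9) < 1e-10 else \
        3.5e-5 * (V - 19.9) / (np.exp((V - 19.9) / 9) - 1)
    dy["xs"] = (1 / np.sqrt(1 + np.exp(-(V - 19.9) / 12.7)) - s["xs"]) * 2 * (axs + bxs)

    e1 = np.exp(-(V + 10) / 6.24)
    taud = 1 / (0.035 * 6.24 * 2) if abs(V + 10) < 1e-10 else \
        (1 - e1) / (0.035 * (V + 10) * (1 + e1))
    dy["d"] = (1 / (1 + np.exp(-(V + 10) / 8)) - s["d"]) / taud
    tauf = 9 / (0.0197 * np.exp(-0.0337 ** 2 * (V + 10) ** 2) + 0.02)
    dy["f"] = (1 / (1 + np.exp((V + 28) / 6.9)) - s["f"]) / tauf
    dy["fca"] = (1 / (1 + s["Cai"] / 0.00035) - s["fca"]) / 2.0

    uinf = 1 / (1 + np.exp(-(fn - 3.4175e-13) / 13.67e-16))
    dy["u"] = (uinf - s["u"]) / 8.0
    tauv = 1.91 + 2.09 * uinf
    dy["v"] = (1 - 1 / (1 + np.exp(-(fn - 6.835e-14) / 13.67e-16)) - s["v"]) / tauv
    e2 = np.exp(-(V - 7.9) / 5)
    tauw = 6 * 0.2 / 1.3 if abs(V - 7.9) < 1e-10 else \
        6 * (1 - e2) / ((1 + 0.3 * e2) * (V - 7.9))
    dy["w"] = (1 - 1 / (1 + np.exp(-(V - 40) / 17)) - s["w"]) / tauw

    ist = stim_fn(t)
    iion = (ina + ik1 + ito + ikur + ikr + iks + ical + inak + inaca
            + ibna + ibca + ipca)
    dy["V"] = -(iion + ist) / CM
    dy["Nai"] = (-3 * inak - 3 * inaca - ibna - ina) / (VI * F)
    dy["Ki"] = (2 * inak - ik1 - ito - ikur - ikr - iks) / (VI * F)
    b1 = (2 * inaca - ipca - ical - ibca) / (2 * VI * F) + \
        (VUP * (iupleak - iup) + irel * VREL) / VI
    b2 = 1 + 0.07 * 0.0005 / (s["Cai"] + 0.0005) ** 2 \
        + 0.05 * 0.00238 / (s["Cai"] + 0.00238) ** 2
    dy["Cai"] = b1 / b2
    dy["Caup"] = iup - iupleak - itr * VREL / VUP
    dy["Carel"] = (itr - irel) / (1 + 10 * 0.8 / (s["Carel"] + 0.8) ** 2)
    return [dy[name] for name in ORDER]


def simulate(
    duration_ms: float,
    stim_times=(10.0,),
    stim_amplitude: float = -2000.0,
    stim_duration: float = 2.0,
    scale: dict | None = None,
    output_dt: float = 0.2,
):
    """Integrate the reference model; returns (times, vm)."""
    scale = scale or {}
    stim_times = np.asarray(stim_times, dtype=float)

    def stim_fn(t):
        inside = (stim_times <= t) & (t < stim_times + stim_duration)
        return stim_amplitude if inside.any() else 0.0

    y0 = [Y0[name] for name in ORDER]
    t_eval = np.arange(0.0, duration_ms + 1e-9, output_dt)
    # integrate piecewise so LSODA never steps across a stimulus edge
    edges = np.unique(np.r_[0.0, stim_times, stim_times + stim_duration, duration_ms])
    edges = edges[(edges >= 0) & (edges <= duration_ms)]
    ts, vs = [], []
    for a, b in zip(edges[:-1], edges[1:]):
        seg_eval = t_eval[(t_eval >= a) & (t_eval <= b)]
        sol = solve_ivp(
            _rhs, (a, b), y0, method="LSODA", rtol=1e-8, atol=1e-10,
            t_eval=seg_eval if seg_eval.size else None,
            args=(stim_fn, scale), max_step=1.0,
        )
        y0 = sol.y[:, -1]
        if seg_eval.size:
            ts.append(sol.t)
            vs.append(sol.y[0])
    t = np.concatenate(ts)
    v = np.concatenate(vs)
    uniq = np.concatenate([[True], np.diff(t) > 1e-12])
    return t[uniq], v[uniq]
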
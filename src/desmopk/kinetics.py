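"""Concentration-time solutions of the dual-input two-compartment model.

The structural model of the sublingual lyophilisate: a fraction Bio of the
dose enters a first depot by zero-order release over a duration D1 and is
absorbed first-order (Ka1) into the central compartment; the remaining
1-Bio sits in a second depot that starts first-order release (Ka2) after a
lag time Tlag.  Disposition is two-compartmental with first-order
elimination from the central compartment.  All parameters are apparent
(scaled by the unknown absolute bioavailability F, fixed to 1).

The closed form superposes the bi-exponential disposition response
(eigenvalues lam1, lam2 of the micro-constant system k10 = CL/V1,
k12 = Q/V1, k21 = Q/V2) convolved with each input.  Near-degenerate
absorption rates (Ka within ~1e-8 of a disposition eigenvalue) switch to
the l'Hopital limit expressions, so no NaN is ever produced.

`concentration_profile` broadcasts over leading parameter axes: passing
arrays of shape (B,) for each parameter yields a (B, n_times) profile
matrix in a single vectorized call, which the estimation layer relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Mapping

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "StructuralParams",
    "StateAmounts",
    "PARAM_NAMES",
    "concentration_profile",
    "concentration_profile_ode",
    "amounts_ode",
    "disposition_eigenvalues",
    "PROFILE_FUNCTIONS",
    "STRUCTURAL_MODELS",
]

#: Parameter order of the dual-depot model (interface units: L, L/h, 1/h, h).
PARAM_NAMES = ("CL", "V1", "Q", "V2", "Ka1", "Ka2", "Bio", "Tlag", "D1")

_ML_PER_L = 1000.0


@dataclass(frozen=True)
class StructuralParams:
    """Individual-level kinetic parameters of the dual-depot model.

    CL, Q in L/h; V1, V2 in L; Ka1, Ka2 in 1/h; Bio dimensionless in (0,1);
    Tlag, D1 in h.  All apparent (per F = 1).
    """

    CL: float
    V1: float
    Q: float
    V2: float
    Ka1: float
    Ka2: float
    Bio: float
    Tlag: float
    D1: float

    def __post_init__(self):
        for name in ("CL", "V1", "Q", "V2", "Ka1", "Ka2", "Tlag", "D1"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if not 0 < self.Bio < 1:
            raise ValueError(f"Bio must be in (0,1), got {self.Bio}")

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class StateAmounts:
    """Compartment drug amounts (pg) along a time grid."""

    times: np.ndarray
    depot1: np.ndarray
    depot2: np.ndarray
    central: np.ndarray
    peripheral: np.ndarray
    eliminated: np.ndarray

    def total(self) -> np.ndarray:
        return self.depot1 + self.depot2 + self.central + self.peripheral + self.eliminated


def _param_arrays(params) -> dict:
    if isinstance(params, StructuralParams):
        params = params.as_dict()
    return {k: np.asarray(params[k], dtype=float) for k in PARAM_NAMES}


def disposition_eigenvalues(CL, V1, Q, V2):
    """Bi-exponential disposition rate constants (lam1 >= lam2 > 0)."""
    CL, V1, Q, V2 = (np.asarray(x, dtype=float) for x in (CL, V1, Q, V2))
    k10 = CL / V1
    k12 = Q / V1
    k21 = Q / V2
    s = k10 + k12 + k21
    disc = np.sqrt(np.maximum(s * s - 4.0 * k10 * k21, 0.0))
    # guard the (measure-zero) repeated-root case so c1/c2 stay finite
    disc = np.maximum(disc, 1e-12 * s)
    lam1 = 0.5 * (s + disc)
    lam2 = 0.5 * (s - disc)
    return lam1, lam2, k21


def _E(a, b, t):
    """(exp(-a t) - exp(-b t)) / (b - a), with the b->a limit t exp(-a t)."""
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        d = b - a
        scale = np.maximum(np.abs(a), np.abs(b))
        small = np.abs(d) < 1e-8 * scale
        safe = np.where(small, 1.0, d)
        base = (np.exp(-a * t) - np.exp(-b * t)) / safe
        m = 0.5 * (a + b)
        return np.where(small, t * np.exp(-m * t), base)


def _F(a, b, t):
    """Integral of _E from 0 to t; limit (1 - exp(-a t)(1 + a t)) / a^2."""
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        d = b - a
        scale = np.maximum(np.abs(a), np.abs(b))
        small = np.abs(d) < 1e-8 * scale
        safe = np.where(small, 1.0, d)
        ga = (1.0 - np.exp(-a * t)) / a
        gb = (1.0 - np.exp(-b * t)) / b
        base = (ga - gb) / safe
        m = 0.5 * (a + b)
        lim = (1.0 - np.exp(-m * t) * (1.0 + m * t)) / (m * m)
        return np.where(small, lim, base)


def concentration_profile(params, dose: float, times) -> np.ndarray:
    """Closed-form plasma concentration (pg/mL) of the dual-depot model.

    Parameters may be scalars, a :class:`StructuralParams`, or a mapping of
    broadcastable arrays; ``times`` is an increasing vector of hours since
    the dose.  Evaluation exactly at t = 0 returns 0 by convention.
    """
    p = _param_arrays(params)
    t = np.asarray(times, dtype=float)
    scalar_params = all(v.ndim == 0 for v in p.values())
    tcol = t[None, :] if t.ndim == 1 else t
    pa = {k: v[..., None] for k, v in p.items()}

    lam1, lam2, k21 = disposition_eigenvalues(pa["CL"], pa["V1"], pa["Q"], pa["V2"])
    denom = lam1 - lam2
    c1 = (lam1 - k21) / denom
    c2 = (k21 - lam2) / denom

    ka1, ka2 = pa["Ka1"], pa["Ka2"]
    bio, tlag, d1 = pa["Bio"], pa["Tlag"], pa["D1"]
    dose = np.asarray(dose, dtype=float)
    if dose.ndim:
        dose = dose[..., None]

    tt = np.maximum(tcol, 0.0)
    # zero-order release into depot1 on [0, D1): step-on minus step-off
    rate = bio * dose / d1

    def step(tau):
        return ka1 * (c1 * _F(lam1, ka1, tau) + c2 * _F(lam2, ka1, tau))

    central = rate * (step(tt) - step(np.maximum(tcol - d1, 0.0)))
    # lagged bolus of (1-Bio) dose into depot2, first-order Ka2 release
    tau2 = np.maximum(tcol - tlag, 0.0)
    central = central + (1.0 - bio) * dose * ka2 * (
        c1 * _E(lam1, ka2, tau2) + c2 * _E(lam2, ka2, tau2)
    )
    conc = central / (pa["V1"] * _ML_PER_L)
    conc = np.maximum(conc, 0.0)  # clip tiny negative round-off
    if scalar_params and t.ndim == 1:
        return conc[0] if conc.ndim == 2 and conc.shape[0] == 1 else conc
    return conc


def _one_compartment_bolus(params, dose, times) -> np.ndarray:
    """IV-bolus one-compartment profile (pg/mL); params CL (L/h), V1 (L)."""
    CL = np.asarray(params["CL"], dtype=float)
    V1 = np.asarray(params["V1"], dtype=float)
    scalar = CL.ndim == 0 and V1.ndim == 0
    t = np.asarray(times, dtype=float)[None, :]
    k = (CL / V1)[..., None] if CL.ndim else np.asarray(CL / V1)[None, None]
    v = V1[..., None] if V1.ndim else np.asarray(V1)[None, None]
    conc = dose * np.exp(-k * t) / (v * _ML_PER_L)
    return conc[0] if scalar else conc


def _dual_depot_profile(params, dose, times) -> np.ndarray:
    return concentration_profile(params, dose, times)


#: Registry of structural models usable by the hierarchical layer.
PROFILE_FUNCTIONS = {
    "dual_depot_two_compartment": _dual_depot_profile,
    "one_compartment_bolus": _one_compartment_bolus,
}

#: Parameter names per registered structural model.
STRUCTURAL_MODELS = {
    "dual_depot_two_compartment": PARAM_NAMES,
    "one_compartment_bolus": ("CL", "V1"),
}


# ---------------------------------------------------------------------------
# numerical oracle / fallback
# ---------------------------------------------------------------------------

def _integrate_segments(p: StructuralParams, dose: float, times: np.ndarray,
                        rtol: float) -> np.ndarray:
    """Integrate the four-state system piecewise across the D1/Tlag events.

    Returns the (n_times, 5) state matrix [depot1, depot2, central,
    peripheral, eliminated].
    """
    k10 = p.CL / p.V1
    k12 = p.Q / p.V1
    k21 = p.Q / p.V2
    rate0 = p.Bio * dose / p.D1

    def rhs(t, y, zero_order_on):
        a1, a2, ac, ap, ael = y
        r = rate0 if zero_order_on else 0.0
        da1 = r - p.Ka1 * a1
        da2 = -p.Ka2 * a2
        dac = p.Ka1 * a1 + p.Ka2 * a2 - (k10 + k12) * ac + k21 * ap
        dap = k12 * ac - k21 * ap
        dael = k10 * ac
        return (da1, da2, dac, dap, dael)

    times = np.asarray(times, dtype=float)
    t_end = float(times[-1]) if len(times) else 0.0
    breaks = sorted({0.0, p.D1, p.Tlag, max(t_end, p.D1, p.Tlag)})
    y = np.zeros(5)
    out = np.zeros((len(times), 5))
    done = np.zeros(len(times), dtype=bool)
    done |= np.isclose(times, 0.0)  # all-zero state at t = 0
    for a, b in zip(breaks[:-1], breaks[1:]):
        if np.isclose(a, p.Tlag):  # lagged bolus fills depot 2
            y = y.copy()
            y[1] += (1.0 - p.Bio) * dose
        mask = (~done) & (times > a + 1e-15) & (times <= b + 1e-12)
        t_eval = np.unique(np.append(times[mask], b))
        zero_on = a < p.D1 - 1e-15
        sol = solve_ivp(
            rhs, (a, b), y, args=(zero_on,), method="LSODA",
            rtol=rtol, atol=rtol * max(dose, 1.0) * 1e-6, t_eval=t_eval,
        )
        if not sol.success:
            raise RuntimeError(
                f"ODE integration failed on [{a}, {b}] for params {p}: {sol.message}"
            )
        states = sol.y.T  # rows follow t_eval exactly
        pos = np.searchsorted(sol.t, times[mask])
        out[mask] = states[np.clip(pos, 0, len(sol.t) - 1)]
        y = states[-1]
        done |= mask
    return out


def amounts_ode(params, dose: float, times, rtol: float = 1e-10) -> StateAmounts:
    """Numerically integrated compartment amounts (mass-balance oracle)."""
    p = params if isinstance(params, StructuralParams) else StructuralParams(**dict(params))
    times = np.asarray(times, dtype=float)
    states = _integrate_segments(p, dose, times, rtol)
    return StateAmounts(
        times=times,
        depot1=states[:, 0],
        depot2=states[:, 1],
        central=states[:, 2],
        peripheral=states[:, 3],
        eliminated=states[:, 4],
    )


def concentration_profile_ode(params, dose: float, times,
                              rtol: float = 1e-10) -> np.ndarray:
    """ODE-integrated concentration profile (pg/mL); oracle for the closed form."""
    if not 0 < rtol <= 1e-3:
        raise ValueError("rtol must be in (0, 1e-3]")
    p = params if isinstance(params, StructuralParams) else StructuralParams(**dict(params))
    st = amounts_ode(p, dose, times, rtol=rtol)
    return st.central / (p.V1 * _ML_PER_L)
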
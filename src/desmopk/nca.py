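"""Non-compartmental secondary parameters: lambda_z, half-life, AUC.

AUC(0->last) uses the logarithmic trapezoidal rule, exact for exponential
decline between samples; the tail beyond the last quantifiable sample is
C_last/lambda_z.  The terminal rate constant lambda_z is a log-linear
regression over a tail point set chosen by maximizing adjusted R^2 over all
candidate tails of >= 3 points strictly after the global maximum.

By default the package computes these on dense model-predicted individual
profiles from the posthoc (empirical Bayes) step; an observed-data mode
simply feeds sampled concentrations into the same functions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import kinetics

__all__ = [
    "NCAResult",
    "lambda_z",
    "auc_to_last",
    "auc_inf",
    "half_life",
    "nca_profile",
    "nca_from_individuals",
    "summarize_by_group",
]

#: Conventional QC flag: extrapolated tail above this % of AUC(0->inf).
EXTRAPOLATION_FLAG_PERCENT = 20.0


@dataclass
class NCAResult:
    """Secondary parameters of one concentration-time profile."""

    subject_id: object = None
    lambda_z: float | None = None
    n_lambda_points: int = 0
    adj_r_squared: float | None = None
    auc_last: float | None = None
    auc_tail: float | None = None
    auc_inf: float | None = None
    half_life: float | None = None
    extrapolated_percent: float | None = None
    extrapolation_flagged: bool = False


def lambda_z(times, concentrations) -> tuple[float | None, int, float | None]:
    """Terminal slope by best-adjusted-R^2 log-linear regression.

    Returns ``(lambda_z, n_points, adjusted_r2)``; ``(None, 0, None)`` when
    fewer than 3 positive post-peak concentrations are available or no tail
    yields a negative slope.
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(concentrations, dtype=float)
    pos = c > 0
    t, c = t[pos], c[pos]
    if len(t) < 3:
        return None, 0, None
    imax = int(np.argmax(c))
    t, c = t[imax + 1:], c[imax + 1:]
    if len(t) < 3:
        return None, 0, None
    logc = np.log(c)
    best = (None, 0, -np.inf)
    for start in range(0, len(t) - 2):
        tt, yy = t[start:], logc[start:]
        n = len(tt)
        slope, intercept = np.polyfit(tt, yy, 1)
        resid = yy - (slope * tt + intercept)
        ss_res = float(resid @ resid)
        ss_tot = float(np.sum((yy - yy.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
        if slope < 0 and adj > best[2] + 1e-12:
            best = (-slope, n, adj)
    if best[0] is None:
        return None, 0, None
    return float(best[0]), int(best[1]), float(best[2])


def auc_to_last(times, concentrations) -> float:
    """AUC to the last sample by the logarithmic trapezoidal method.

    Intervals with both ends positive and unequal use the log trapezoid
    (C1 - C2) dt / ln(C1/C2); equal or zero-bounded intervals fall back to
    the linear trapezoid.
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(concentrations, dtype=float)
    if len(t) < 2:
        raise ValueError("AUC needs at least 2 points")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    if np.any(c < 0):
        raise ValueError("concentrations must be >= 0")
    c1, c2 = c[:-1], c[1:]
    dt = np.diff(t)
    with np.errstate(divide="ignore", invalid="ignore"):
        logq = np.log(c1 / c2)
        log_seg = (c1 - c2) * dt / logq
    lin_seg = 0.5 * (c1 + c2) * dt
    use_log = (c1 > 0) & (c2 > 0) & ~np.isclose(c1, c2)
    return float(np.sum(np.where(use_log, log_seg, lin_seg)))


def auc_inf(times, concentrations, lz: float | None) -> tuple:
    """AUC(0->inf) and extrapolated percent; propagates a missing lambda_z.

    The tail uses the last measured (or predicted) concentration, not the
    regression-predicted one.  Returns ``(auc_inf, tail, extrapolated_%)``
    or ``(None, None, None)``.
    """
    if lz is None:
        return None, None, None
    if lz <= 0:
        raise ValueError("lambda_z must be > 0")
    auc_l = auc_to_last(times, concentrations)
    c = np.asarray(concentrations, dtype=float)
    pos = np.nonzero(c > 0)[0]
    c_last = float(c[pos[-1]]) if len(pos) else 0.0
    tail = c_last / lz
    total = auc_l + tail
    return float(total), float(tail), float(100.0 * tail / total)


def half_life(lz: float) -> float:
    """Terminal elimination half-life ln(2)/lambda_z, hours."""
    if not lz > 0:
        raise ValueError("lambda_z must be > 0")
    return float(np.log(2.0) / lz)


def nca_profile(times, concentrations, subject_id=None) -> NCAResult:
    """Full NCA of one profile; missing lambda_z leaves AUC(0->last) only."""
    lz, n, adj = lambda_z(times, concentrations)
    auc_l = auc_to_last(times, concentrations)
    res = NCAResult(subject_id=subject_id, lambda_z=lz, n_lambda_points=n,
                    adj_r_squared=adj, auc_last=auc_l)
    if lz is not None:
        total, tail, extr = auc_inf(times, concentrations, lz)
        res.auc_inf = total
        res.auc_tail = tail
        res.extrapolated_percent = extr
        res.half_life = half_life(lz)
        res.extrapolation_flagged = bool(extr > EXTRAPOLATION_FLAG_PERCENT)
    return res


def _dense_grid(t_end: float = 24.0, n: int = 2001) -> np.ndarray:
    # geometric spacing resolves the fast absorption phase
    return np.concatenate([[0.0], np.geomspace(1e-3, t_end, n - 1)])


def nca_from_individuals(individuals, dose: float,
                         structural: str = "dual_depot_two_compartment",
                         t_end: float = 24.0) -> pd.DataFrame:
    """Model-based NCA over posthoc individual parameter sets.

    ``individuals`` is an iterable of :class:`~desmopk.popmodel.IndividualParams`
    (the EBE output); each subject's noise-free predicted profile on a
    dense grid feeds the same NCA functions as observed data would.
    """
    profile = kinetics.PROFILE_FUNCTIONS[structural]
    grid = _dense_grid(t_end)
    rows = []
    for ind in individuals:
        conc = profile({k: np.asarray(v) for k, v in ind.params.items()},
                       dose, grid)
        res = nca_profile(grid, np.asarray(conc), subject_id=ind.subject_id)
        rows.append(vars(res))
    return pd.DataFrame(rows)


def summarize_by_group(table: pd.DataFrame, groups: pd.Series | dict
                       ) -> pd.DataFrame:
    """Mean +- SD of AUC(0->inf) and half-life per age group."""
    tab = table.copy()
    mapping = groups if isinstance(groups, dict) else dict(groups)
    tab["age_group"] = tab["subject_id"].map(mapping)
    out = tab.groupby("age_group", sort=False).agg(
        n=("subject_id", "size"),
        auc_inf_mean=("auc_inf", "mean"), auc_inf_sd=("auc_inf", "std"),
        half_life_mean=("half_life", "mean"), half_life_sd=("half_life", "std"),
    )
    return out.reset_index()
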
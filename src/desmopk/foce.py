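"""First-order conditional estimation (FOCE) for the population model.

The marginal likelihood of each subject's log-scale observations is
approximated by linearizing the model in the random effects around the
subject's conditional mode eta_hat (found by an inner Newton/Gauss-Newton
optimization).  With residual error additive on the log scale the
approximation carries no eta-interaction term in the residual variance, so
this is plain FOCE; on linear-Gaussian models it is exact.

Per-subject contribution to the objective (OFV = -2 log L, full 2*pi
constant included so exact-likelihood oracles match):

    V_i   = J_i Omega J_i' + sigma^2 I
    mu_i  = f_i(eta_hat) - J_i eta_hat
    OFV_i = n_i log(2 pi) + log|V_i| + (y_i - mu_i)' V_i^{-1} (y_i - mu_i)

with J_i the Jacobian of the log-scale predictions in eta at eta_hat.

The outer problem minimizes the summed OFV over the unconstrained
estimation scale (log for positive parameters, logit for Bio, identity for
covariate exponents, log-SD for the Omega diagonal and sigma) with L-BFGS-B
and finite-difference gradients.  The covariance step inverts a central
finite-difference Hessian of OFV/2 and maps standard errors to the
reporting scale by the delta method; random-effect entries are reported as
variances with the RSE on the SD scale.
"""

from __future__ import annotations

import time as _time
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logit

from .dataset_io import PKDataset
from .popmodel import PopulationModel, predictor, individual_parameters

__all__ = [
    "SubjectProblem",
    "FitResult",
    "foce_objective",
    "conditional_objective",
    "build_problems",
    "fit",
    "compute_ebes",
    "shrinkage",
    "rse",
    "rse_table",
    "condition_number",
    "condition_number_acceptable",
]

_INNER_MAXIT = 100
_FD_STEP = 1e-5  # eta-Jacobian forward-difference step


@dataclass
class SubjectProblem:
    """One subject's data and batched prediction function.

    ``predict`` maps an (B, K) eta matrix to (B, n) predicted log
    concentrations; ``y`` are the observed log concentrations.
    """

    key: object
    y: np.ndarray
    predict: Callable[[np.ndarray], np.ndarray]


class InnerOptimizationError(RuntimeError):
    pass


def _inner_mode(prob: SubjectProblem, omega_inv: np.ndarray, sigma2: float,
                eta0: np.ndarray):
    """Conditional mode of eta by Levenberg-Marquardt-damped Gauss-Newton.

    Returns (eta, f, J) with f and J evaluated at the mode, reused for the
    FOCE linearization.  The damping makes cold starts (eta far from the
    mode under a misspecified model) converge to the same mode as warm
    starts, which keeps the objective history-independent.
    """
    K = omega_inv.shape[0]
    eta = np.asarray(eta0, dtype=float).copy()
    y = prob.y
    eye = np.eye(K)

    def fj(e):
        batch = np.vstack([e, e + _FD_STEP * eye])
        F = prob.predict(batch)
        f = F[0]
        J = (F[1:] - f).T / _FD_STEP
        return f, J

    def penalized(e, f_at_e):
        return float(np.dot(y - f_at_e, y - f_at_e) / sigma2
                     + e @ omega_inv @ e)

    f, J = fj(eta)
    if not np.all(np.isfinite(f)):
        # a hopeless warm start: fall back to the prior mean
        eta = np.zeros(K)
        f, J = fj(eta)
    obj = penalized(eta, f)
    # in near-hopeless regions a short budget suffices: either the mode is
    # reachable in a few damped steps or its exact position is irrelevant
    maxit = _INNER_MAXIT if obj < 1e7 else 15
    lam = 0.0
    for _ in range(maxit):
        r = y - f
        grad = -2.0 * (J.T @ r) / sigma2 + 2.0 * omega_inv @ eta
        H = 2.0 * (J.T @ J / sigma2 + omega_inv)
        scale = max(float(np.trace(H)) / max(K, 1), 1e-12)
        accepted = False
        for _damp in range(12):
            try:
                delta = np.linalg.solve(H + lam * scale * eye, -grad)
            except np.linalg.LinAlgError as exc:
                raise InnerOptimizationError(
                    f"singular inner Hessian for subject {prob.key!r} at eta={eta}"
                ) from exc
            expected_gain = -float(grad @ delta) - 0.5 * float(
                delta @ (H @ delta))
            if lam == 0.0 and (np.max(np.abs(delta)) < 1e-9
                               or abs(expected_gain) < 1e-9):
                break  # converged up to the FD-Jacobian noise floor
            trial = eta + delta
            f_t = prob.predict(trial[None, :])[0]
            obj_t = penalized(trial, f_t) if np.all(np.isfinite(f_t)) else np.inf
            if obj_t < obj - 1e-13:
                accepted = True
                lam = lam / 3.0 if lam > 1e-8 else 0.0
                break
            lam = 10.0 * lam if lam > 0.0 else 1e-4
        if not accepted:
            break
        gain = obj - obj_t
        eta, obj = trial, obj_t
        f, J = fj(eta)
        if gain < 1e-10 and lam == 0.0:
            break
    if not np.all(np.isfinite(f)):
        raise InnerOptimizationError(
            f"non-finite prediction for subject {prob.key!r} at eta={eta}"
        )
    return eta, f, J, obj




def foce_objective(problems: Sequence[SubjectProblem], omega: np.ndarray,
                   sigma: float, eta_start: dict | None = None
                   ) -> tuple[float, dict]:
    """Summed FOCE objective over subjects; returns (OFV, eta modes).

    ``omega`` is the (K, K) IIV covariance of the *active* random effects
    (K may be 0, collapsing to a fixed-effects log-normal residual model).
    ``eta_start`` warm-starts the inner optimizations, keyed by subject.
    """
    omega = np.atleast_2d(np.asarray(omega, dtype=float)) if np.size(omega) else \
        np.zeros((0, 0))
    K = omega.shape[0]
    sigma2 = float(sigma) ** 2
    log2pi = np.log(2.0 * np.pi)
    total = 0.0
    modes = {}
    if K == 0:
        for prob in problems:
            f = prob.predict(np.zeros((1, 0)))[0]
            r = prob.y - f
            n = len(r)
            total += n * log2pi + n * np.log(sigma2) + float(r @ r) / sigma2
            modes[prob.key] = np.zeros(0)
        return total, modes
    omega_inv = np.linalg.inv(omega)
    for prob in problems:
        eta0 = (eta_start or {}).get(prob.key, np.zeros(K))
        eta, f, J, _ = _inner_mode(prob, omega_inv, sigma2, eta0)
        V = J @ omega @ J.T + sigma2 * np.eye(len(prob.y))
        resid = prob.y - (f - J @ eta)
        L = np.linalg.cholesky(V)
        z = np.linalg.solve(L, resid)
        logdet = 2.0 * np.sum(np.log(np.diag(L)))
        total += len(prob.y) * log2pi + logdet + float(z @ z)
        modes[prob.key] = eta
    return total, modes


def extract_subject_data(ds: PKDataset) -> list[dict]:
    """Static per-subject arrays (times, log-obs, dose, covariates).

    Separated from problem construction so repeated objective evaluations
    do not pay the table-slicing cost.
    """
    if not ds.log_scale:
        raise ValueError("dataset must be log-transformed before estimation")
    out = []
    for sid, sub in ds.records.groupby("id", sort=False):
        obs = sub[(sub["evid"] == 0) & (sub["mdv"] == 0)]
        if obs.empty:
            continue  # fully censored subject carries no likelihood
        out.append({
            "key": sid,
            "dose": float(sub.loc[sub["evid"] == 1, "amt"].iloc[0]),
            "covs": {c: sub.iloc[0][c] for c in ds.covariate_columns()},
            "times": obs["time"].to_numpy(dtype=float),
            "y": obs["dv"].to_numpy(dtype=float),
        })
    if not out:
        raise ValueError("no quantifiable observations in the dataset")
    return out


def _problems_from_data(model: PopulationModel, data: list[dict]) -> list[SubjectProblem]:
    return [
        SubjectProblem(
            key=d["key"], y=d["y"],
            predict=predictor(model, d["covs"], d["dose"], d["times"]))
        for d in data
    ]


def build_problems(model: PopulationModel, ds: PKDataset) -> list[SubjectProblem]:
    """Per-subject FOCE problems from a log-transformed, LOQ-filtered dataset."""
    return _problems_from_data(model, extract_subject_data(ds))


def conditional_objective(model: PopulationModel, ds: PKDataset,
                          at: np.ndarray | None = None) -> float:
    """FOCE objective of ``model`` (optionally at estimation-scale vector ``at``)."""
    spec = ParamSpec.from_model(model)
    m = spec.apply(model, at) if at is not None else model
    ofv, _ = foce_objective(build_problems(m, ds), m.omega_matrix(), m.sigma)
    return ofv


# ---------------------------------------------------------------------------
# estimation-scale parameter vector
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ParamEntry:
    kind: str       # theta | coveff | omega | sigma
    name: str       # parameter name, or "param:covariate" for coveff
    transform: str  # log | logit | identity | log_sd


@dataclass
class ParamSpec:
    entries: list

    @classmethod
    def from_model(cls, model: PopulationModel,
                   estimate_omega: bool = True,
                   estimate_sigma: bool = True) -> "ParamSpec":
        entries = []
        for p in model.param_names:
            if p not in model.theta_fixed:
                entries.append(ParamEntry("theta", p, model.transform(p)))
        for e in model.covariate_effects:
            if not e.fixed:
                entries.append(ParamEntry("coveff", f"{e.parameter}:{e.covariate}", "identity"))
        if estimate_omega:
            for p in model.eta_names:
                if p not in model.iiv_fixed:
                    entries.append(ParamEntry("omega", p, "log_sd"))
        if estimate_sigma and not model.sigma_fixed:
            entries.append(ParamEntry("sigma", "sigma", "log_sd"))
        return cls(entries)

    def __len__(self):
        return len(self.entries)

    def pack(self, model: PopulationModel) -> np.ndarray:
        x = []
        for e in self.entries:
            if e.kind == "theta":
                v = model.theta[e.name]
                x.append(np.log(v) if e.transform == "log" else logit(v))
            elif e.kind == "coveff":
                p, c = e.name.split(":")
                eff = next(f for f in model.covariate_effects
                           if f.parameter == p and f.covariate == c)
                x.append(eff.exponent)
            elif e.kind == "omega":
                x.append(0.5 * np.log(max(model.iiv[e.name], 1e-12)))
            else:
                x.append(np.log(model.sigma))
        return np.array(x, dtype=float)

    def apply(self, model: PopulationModel, x: np.ndarray) -> PopulationModel:
        from scipy.special import expit
        m = model.copy()
        for e, v in zip(self.entries, np.asarray(x, dtype=float)):
            if e.kind == "theta":
                m.theta[e.name] = float(np.exp(v)) if e.transform == "log" else float(expit(v))
            elif e.kind == "coveff":
                p, c = e.name.split(":")
                m.covariate_effects = [
                    CovE if not (CovE.parameter == p and CovE.covariate == c)
                    else type(CovE)(p, c, float(v), CovE.center, CovE.fixed)
                    for CovE in m.covariate_effects
                ]
            elif e.kind == "omega":
                m.iiv[e.name] = float(np.exp(2.0 * v))
            else:
                m.sigma = float(np.exp(v))
        return m

    def bounds(self, x0: np.ndarray, width: float = 6.0) -> list:
        """Wide boxes on the estimation scale; they only exclude regions
        where the hierarchy degenerates (random-effect SDs above 3 make the
        prior so flat that the subject-level problems turn multi-modal)."""
        out = []
        for e, v in zip(self.entries, x0):
            if e.transform == "identity":
                out.append((v - 6.0, v + 6.0))
            elif e.kind in ("omega", "sigma"):
                out.append((max(v - width, np.log(1e-4)), np.log(3.0)))
            else:
                out.append((v - width, v + width))
        return out


# ---------------------------------------------------------------------------
# fit, covariance step, EBEs
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """Estimates, objective, covariance-step outputs and EBEs of one fit."""

    model: PopulationModel
    spec: ParamSpec
    ofv: float
    aic: float
    n_free: int
    success: bool
    message: str
    nit: int
    nfev: int
    x: np.ndarray
    ebes: pd.DataFrame | None = None
    shrinkage: dict | None = None
    se_est: np.ndarray | None = None
    cov_est: np.ndarray | None = None
    se_report: dict | None = None
    rse_percent: dict | None = None
    condition_number: float | None = None
    runtime_s: float = 0.0

    def param_table(self) -> pd.DataFrame:
        rows = []
        for i, e in enumerate(self.spec.entries):
            if e.kind == "theta":
                est = self.model.theta[e.name]
                label = e.name
            elif e.kind == "coveff":
                p, c = e.name.split(":")
                est = next(f.exponent for f in self.model.covariate_effects
                           if f.parameter == p and f.covariate == c)
                label = f"{c} on {p}"
            elif e.kind == "omega":
                est = self.model.iiv[e.name]
                label = f"IIV {e.name}"
            else:
                est = self.model.sigma
                label = "sigma"
            rows.append({
                "parameter": label,
                "estimate": est,
                "se": None if self.se_report is None else self.se_report.get(label),
                "rse_percent": None if self.rse_percent is None else self.rse_percent.get(label),
                "shrinkage_percent": (self.shrinkage or {}).get(e.name)
                if e.kind == "omega" else None,
            })
        return pd.DataFrame(rows)


def _objective_factory(model, ds, spec, use_cache: bool = True):
    """Objective over the estimation-scale vector.

    With ``use_cache`` the per-subject conditional modes warm-start the
    next evaluation (fast, but the conditional-mode problem of a
    double-peak model is multi-modal, so values carry a small path
    dependence).  Without it every evaluation cold-starts from the prior
    mean and the objective is exactly deterministic.
    """
    data = extract_subject_data(ds)
    eta_cache: dict = {}
    ref = [None]  # first finite value; anchors the runaway compression

    def objective(x):
        m = spec.apply(model, x)
        problems = _problems_from_data(m, data)
        try:
            ofv, modes = foce_objective(
                problems, m.omega_matrix(), m.sigma,
                eta_start=eta_cache if use_cache else None)
        except (InnerOptimizationError, np.linalg.LinAlgError):
            ofv = np.inf
        if np.isnan(ofv):  # NaN would poison the quasi-Newton line search
            ofv = np.inf
        if np.isfinite(ofv) and use_cache:
            eta_cache.update(modes)
        if ref[0] is None and np.isfinite(ofv):
            ref[0] = ofv
        # compress catastrophic values (diverged conditional modes can reach
        # 1e9) so the quasi-Newton line search can still interpolate; the
        # transform is monotone, hence harmless to the argmin
        cap = (ref[0] if ref[0] is not None else 0.0) + 1e4
        if ofv > cap:
            ofv = cap + (np.log1p(ofv - cap) if np.isfinite(ofv) else 50.0)
        return float(ofv)

    return objective


def fit(model: PopulationModel, ds: PKDataset,
        estimate_omega: bool = True, estimate_sigma: bool = True,
        cov_step: bool = True, maxiter: int = 300,
        ftol: float = 1e-9, gtol: float = 1e-6,
        fd: str = "2-point", restarts: int = 0) -> FitResult:
    """FOCE fit of ``model`` to a log-transformed dataset.

    The starting values are the model's current values.  ``fd`` selects the
    outer finite-difference scheme ("2-point" is fast, "3-point" doubles
    the gradient cost for higher accuracy).  ``restarts`` re-launches the
    quasi-Newton search from the incumbent optimum until the OFV stops
    improving by more than 0.5 — useful on rough landscapes (e.g. base
    models badly misspecified for wide-covariate-range data) where a single
    L-BFGS-B run can stall.  Returns a :class:`FitResult`; if the optimizer
    fails, estimates are still returned with ``success=False`` and the
    covariance step is skipped.
    """
    t0 = _time.perf_counter()
    spec = ParamSpec.from_model(model, estimate_omega, estimate_sigma)
    if len(spec) == 0:
        raise ValueError("model has no free parameters to estimate")
    if any(e.kind == "omega" for e in spec.entries) and ds.n_subjects < 2:
        raise ValueError("estimating IIV needs at least 2 subjects")
    objective = _objective_factory(model, ds, spec)
    x0 = spec.pack(model)
    options = {"maxiter": maxiter, "ftol": ftol, "gtol": gtol}
    if fd == "2-point":
        jac = None
        options["eps"] = 1e-5
    else:
        jac = fd
    bounds = spec.bounds(x0)
    res = None
    x_start = x0
    total_nit = total_nfev = 0
    for _round in range(restarts + 1):
        attempt = minimize(objective, x_start, method="L-BFGS-B", jac=jac,
                           bounds=bounds, options=options)
        total_nit += int(attempt.nit)
        total_nfev += int(attempt.nfev)
        improved = res is None or attempt.fun < res.fun
        stalled = res is not None and res.fun - attempt.fun < 0.5
        if improved:
            res = attempt
        if stalled:
            break
        x_start = attempt.x
    if np.max(np.abs(res.x - x0)) < 5e-3 and len(spec) > 1:
        # frozen at (or microscopically near) the start: the warm-start
        # cache was poisoned by a line-search excursion into another
        # conditional-mode basin.  First try a cheap rescue: a fresh warm
        # objective started from a small deterministic step along the
        # descent direction; fall back to the deterministic cold-start
        # objective if that freezes too.
        rescued = False
        for step in (0.05, 0.2):
            warm2 = _objective_factory(model, ds, spec, use_cache=True)
            f0 = warm2(x0)
            g = np.array([(warm2(x0 + 1e-5 * np.eye(len(x0))[i]) - f0) / 1e-5
                          for i in range(len(x0))])
            gnorm = np.linalg.norm(g)
            x_j = x0 - step * g / gnorm if gnorm > 0 else x0
            x_j = np.clip(x_j, [b[0] for b in bounds], [b[1] for b in bounds])
            attempt = minimize(warm2, x_j, method="L-BFGS-B", jac=jac,
                               bounds=bounds, options=options)
            total_nit += int(attempt.nit)
            total_nfev += int(attempt.nfev)
            if attempt.fun < f0 and np.max(np.abs(attempt.x - x0)) > 5e-3:
                res = attempt
                rescued = True
                break
        if not rescued:
            cold = _objective_factory(model, ds, spec, use_cache=False)
            attempt = minimize(cold, x0, method="L-BFGS-B", jac=jac,
                               bounds=bounds,
                               options={**options, "maxiter": min(maxiter, 150)})
            total_nit += int(attempt.nit)
            total_nfev += int(attempt.nfev)
            res = attempt
    res.nit, res.nfev = total_nit, total_nfev
    final = spec.apply(model, res.x)
    # report the history-free OFV at the optimum (cold conditional modes),
    # so Delta-OFV between separately fitted models is well-defined
    ofv_det = _objective_factory(model, ds, spec, use_cache=False)(res.x)
    ofv = float(ofv_det) if np.isfinite(ofv_det) else float(res.fun)
    n_free = len(spec)
    ebes, ipars = compute_ebes(final, ds)
    shr = shrinkage(ebes, final)
    result = FitResult(
        model=final, spec=spec, ofv=ofv, aic=ofv + 2.0 * n_free, n_free=n_free,
        success=bool(res.success), message=str(res.message),
        nit=int(res.nit), nfev=int(res.nfev), x=np.asarray(res.x),
        ebes=ebes, shrinkage=shr,
        runtime_s=_time.perf_counter() - t0,
    )
    if cov_step and res.success:
        try:
            _covariance_step(result, objective)
        except np.linalg.LinAlgError:
            pass  # estimates stand; SEs unavailable
    result.runtime_s = _time.perf_counter() - t0
    return result


def _numeric_hessian(fun, x, step=5e-4):
    n = len(x)
    H = np.zeros((n, n))
    f0 = fun(x)
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = step
            ej = np.zeros(n); ej[j] = step
            if i == j:
                H[i, i] = (fun(x + ei) - 2 * f0 + fun(x - ei)) / step**2
            else:
                H[i, j] = H[j, i] = (
                    fun(x + ei + ej) - fun(x + ei - ej)
                    - fun(x - ei + ej) + fun(x - ei - ej)
                ) / (4 * step**2)
    return H


def _covariance_step(result: FitResult, objective) -> None:
    """SEs from the inverse Hessian of OFV/2, delta method to report scale."""
    H = _numeric_hessian(objective, result.x) / 2.0
    cov = np.linalg.inv(H)
    d = np.diag(cov)
    if np.any(d <= 0):
        raise np.linalg.LinAlgError("non-positive-definite covariance")
    result.cov_est = cov
    result.se_est = np.sqrt(d)
    result.condition_number = condition_number(cov)
    se_rep, rse_rep = {}, {}
    m = result.model
    for i, e in enumerate(result.spec.entries):
        se = result.se_est[i]
        if e.kind == "theta":
            v = m.theta[e.name]
            se_nat = v * se if e.transform == "log" else v * (1 - v) * se
            label = e.name
            est = v
        elif e.kind == "coveff":
            p, c = e.name.split(":")
            est = next(f.exponent for f in m.covariate_effects
                       if f.parameter == p and f.covariate == c)
            se_nat = se
            label = f"{c} on {p}"
        elif e.kind == "omega":
            var = m.iiv[e.name]
            se_nat = 2.0 * var * se  # d(omega^2)/d(log omega) = 2 omega^2
            label = f"IIV {e.name}"
            est = var
        else:
            est = m.sigma
            se_nat = est * se
            label = "sigma"
        se_rep[label] = se_nat
        kind = {"theta": "fixed", "coveff": "fixed", "omega": "variance",
                "sigma": "sigma"}[e.kind]
        rse_rep[label] = rse(est, se_nat, kind)
    result.se_report = se_rep
    result.rse_percent = rse_rep


def compute_ebes(model: PopulationModel, ds: PKDataset
                 ) -> tuple[pd.DataFrame, list]:
    """Posthoc step: conditional eta modes and realized individual parameters."""
    problems = build_problems(model, ds)
    omega = model.omega_matrix()
    names = model.eta_names
    K = len(names)
    rows, ipars = [], []
    if K:
        omega_inv = np.linalg.inv(omega)
    for prob in problems:
        if K == 0:
            eta = np.zeros(0)
        else:
            eta, _, _, _ = _inner_mode(prob, omega_inv, model.sigma ** 2,
                                       np.zeros(K))
        covs = ds.subject_covariates(prob.key)
        ind = individual_parameters(model, covs, eta, subject_id=prob.key)
        ipars.append(ind)
        rows.append({"id": prob.key,
                     **{f"eta_{p}": eta[i] for i, p in enumerate(names)},
                     **{f"param_{k}": v for k, v in ind.params.items()}})
    return pd.DataFrame(rows), ipars


def shrinkage(ebes: pd.DataFrame, model_or_omega) -> dict:
    """Eta-shrinkage per IIV element: 100 (1 - SD(eta_hat)/omega).

    Sample SD uses the n-1 denominator.  Elements fixed to zero are
    reported as None (not applicable).
    """
    if isinstance(model_or_omega, PopulationModel):
        model = model_or_omega
        pairs = [(p, model.iiv[p]) for p in model.eta_names]
        fixed_zero = [p for p in model.iiv_fixed if model.iiv.get(p, 0.0) == 0.0]
    else:
        pairs = list(model_or_omega.items())
        fixed_zero = []
    out = {p: None for p in fixed_zero}
    for p, var in pairs:
        col = f"eta_{p}" if f"eta_{p}" in ebes.columns else p
        if var <= 0 or col not in ebes.columns or len(ebes) < 2:
            out[p] = None
            continue
        sd = float(ebes[col].std(ddof=1))
        out[p] = 100.0 * (1.0 - sd / np.sqrt(var))
    return out


def rse(estimate: float, se: float, kind: str = "fixed") -> float:
    """Relative standard error in percent, per reporting convention.

    ``fixed`` effects and the residual SD: 100*SE/estimate.  Random-effect
    entries reported as variances (``kind="variance"``): 100*SE/(2*estimate),
    the RSE of the SD obtained by the delta method.
    """
    if estimate == 0:
        if se == 0:
            return 0.0
        raise ZeroDivisionError("RSE undefined for a zero estimate")
    if kind == "variance":
        return 100.0 * se / (2.0 * abs(estimate))
    return 100.0 * se / abs(estimate)


def rse_table(rows: Sequence[tuple]) -> pd.DataFrame:
    """%RSE for (name, estimate, SE, kind) tuples; kind in fixed|variance|sigma."""
    out = []
    for name, est, se, kind in rows:
        out.append({"parameter": name, "estimate": est, "se": se,
                    "rse_percent": rse(est, se, kind)})
    return pd.DataFrame(out)


def condition_number_acceptable(cn: float, threshold: float = 1000.0) -> bool:
    """Conventional ill-conditioning alarm: CN below the threshold passes."""
    return bool(cn < threshold)


def condition_number(cov: np.ndarray) -> float:
    """Eigenvalue ratio of the correlation matrix of the estimates.

    Returns inf when the matrix is not positive definite (the covariance
    step is then reported as failed).
    """
    cov = np.atleast_2d(np.asarray(cov, dtype=float))
    d = np.sqrt(np.diag(cov))
    if np.any(d <= 0):
        return np.inf
    corr = cov / np.outer(d, d)
    w = np.linalg.eigvalsh(corr)
    if w[0] <= 0:
        return np.inf
    return float(w[-1] / w[0])
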
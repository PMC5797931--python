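"""Goodness-of-fit quantities and the visual predictive check.

CWRES follows the literature-standard FOCE linearization: with J_i the
Jacobian of the log-scale predictions in eta at the conditional mode
eta_hat_i,

    mean_i  = f_i(eta_hat_i) - J_i eta_hat_i
    cov_i   = J_i Omega J_i' + sigma^2 I
    CWRES_i = cov_i^(-1/2) (y_i - mean_i)

computed on the log-concentration (estimation) scale.  For a correctly
specified linear-Gaussian model CWRES is exactly standard normal.

The VPC simulates replicate datasets under the model with the original
design, bins by exact nominal time (the study shares nominal times across
subjects), and reports observed percentiles next to the simulation median
and confidence band of each percentile.  No smoothing is applied; the
artifact emits tables, plotting is a thin optional layer.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .dataset_io import PKDataset
from .popmodel import PopulationModel, simulate_population
from . import foce

__all__ = ["cwres", "gof_table", "vpc", "plot_vpc"]


def _linearization(model: PopulationModel, ds: PKDataset,
                   ebes: pd.DataFrame | None):
    """Per-subject (y, f, J, eta_hat) at the conditional modes."""
    data = foce.extract_subject_data(ds)
    names = model.eta_names
    K = len(names)
    omega = model.omega_matrix()
    if ebes is None:
        ebes, _ = foce.compute_ebes(model, ds)
    eta_by_id = {
        row["id"]: np.array([row.get(f"eta_{p}", 0.0) for p in names])
        for _, row in ebes.iterrows()
    }
    out = []
    for d in data:
        prob = foce._problems_from_data(model, [d])[0]
        eta = eta_by_id.get(d["key"], np.zeros(K))
        batch = np.vstack([eta, eta + 1e-5 * np.eye(K)]) if K else eta[None, :]
        F = prob.predict(batch)
        f = F[0]
        J = (F[1:] - f).T / 1e-5 if K else np.zeros((len(f), 0))
        out.append((d, f, J, eta))
    return out, omega


def cwres(model: PopulationModel, ds: PKDataset,
          ebes: pd.DataFrame | None = None) -> np.ndarray:
    """Conditional weighted residuals, ordered as the retained observations."""
    lin, omega = _linearization(model, ds, ebes)
    sigma2 = model.sigma ** 2
    out = []
    for d, f, J, eta in lin:
        V = J @ omega @ J.T + sigma2 * np.eye(len(f))
        w, U = np.linalg.eigh(V)
        if np.any(w <= 0):
            raise np.linalg.LinAlgError(
                f"singular CWRES covariance for subject {d['key']!r}")
        inv_sqrt = U @ np.diag(1.0 / np.sqrt(w)) @ U.T
        resid = d["y"] - (f - J @ eta)
        out.append(inv_sqrt @ resid)
    return np.concatenate(out)


def gof_table(model: PopulationModel, ds: PKDataset,
              ebes: pd.DataFrame | None = None) -> pd.DataFrame:
    """Observed, PRED (eta=0), IPRED (eta=eta_hat) and CWRES per observation.

    Log-scale columns carry the estimation-scale quantities; natural-scale
    concentrations are exp of those.
    """
    lin, omega = _linearization(model, ds, ebes)
    sigma2 = model.sigma ** 2
    rows = []
    for d, f, J, eta in lin:
        K = len(eta)
        prob = foce._problems_from_data(model, [d])[0]
        pred = prob.predict(np.zeros((1, K)))[0]
        V = J @ omega @ J.T + sigma2 * np.eye(len(f))
        w, U = np.linalg.eigh(V)
        inv_sqrt = U @ np.diag(1.0 / np.sqrt(w)) @ U.T
        res = inv_sqrt @ (d["y"] - (f - J @ eta))
        for i, t in enumerate(d["times"]):
            rows.append({"id": d["key"], "time": t, "obs_log": d["y"][i],
                         "pred_log": pred[i], "ipred_log": f[i],
                         "cwres": res[i]})
    tab = pd.DataFrame(rows)
    tab["obs"] = np.exp(tab["obs_log"])
    tab["pred"] = np.exp(tab["pred_log"])
    tab["ipred"] = np.exp(tab["ipred_log"])
    return tab


def vpc(model: PopulationModel, ds: PKDataset, n_simulations: int = 1000,
        percentiles: tuple = (5, 50, 95), ci_level: float = 95.0,
        seed: int | None = None, apply_loq: bool = True) -> pd.DataFrame:
    """Visual-predictive-check table from replicate simulations of the design.

    Defaults mirror the study evaluation: 1,000 simulations, 5th/50th/95th
    percentiles (a 90% inter-percentile range) with a 95% confidence band
    on each simulated percentile.  ``ds`` supplies the design: subjects,
    covariates, dose, and the nominal times (its observation times).  When
    ``apply_loq`` is set, simulated records below the dataset LOQ are
    excluded before percentile computation, mirroring the construction of
    the analysis dataset.
    """
    if n_simulations < 100:
        raise ValueError("n_simulations must be >= 100")
    if ds.log_scale:
        raise ValueError("vpc expects concentrations on the natural scale")
    rng = np.random.default_rng(seed)
    percentiles = tuple(sorted(percentiles))
    obs = ds.observations
    nominal = np.array(sorted(obs["time"].unique()))
    cohort = ds.subject_table().drop(columns=["dose"])
    dose = float(ds.doses["amt"].iloc[0])

    def perc_by_time(frame: pd.DataFrame) -> np.ndarray:
        out = np.full((len(nominal), len(percentiles)), np.nan)
        for i, t in enumerate(nominal):
            vals = frame.loc[np.isclose(frame["time"], t), "dv"].to_numpy()
            if len(vals):
                out[i] = np.percentile(vals, percentiles)
        return out

    obs_p = perc_by_time(obs)
    sims = np.full((n_simulations, len(nominal), len(percentiles)), np.nan)
    for s in range(n_simulations):
        sim_ds, _ = simulate_population(
            model, cohort, nominal, dose, rng=rng, loq=ds.loq,
            censor="drop" if apply_loq else "none", predose_record=False)
        sims[s] = perc_by_time(sim_ds.observations)
    lo = (100.0 - ci_level) / 2.0
    hi = 100.0 - lo
    rows = []
    for i, t in enumerate(nominal):
        row = {"time": t,
               "n_obs": int(np.isclose(obs["time"], t).sum()),
               "n_simulations": n_simulations}
        for j, p in enumerate(percentiles):
            col = sims[:, i, j]
            col = col[np.isfinite(col)]
            row[f"obs_p{p}"] = obs_p[i, j]
            row[f"sim_p{p}"] = np.median(col) if len(col) else np.nan
            row[f"sim_p{p}_lo"] = np.percentile(col, lo) if len(col) else np.nan
            row[f"sim_p{p}_hi"] = np.percentile(col, hi) if len(col) else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def plot_vpc(table: pd.DataFrame, path, percentiles=(5, 50, 95),
             log_y: bool = True) -> None:
    """Render a VPC table (ribbons + observed percentiles) to an image file."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    t = table["time"]
    for p in percentiles:
        ax.fill_between(t, table[f"sim_p{p}_lo"], table[f"sim_p{p}_hi"],
                        alpha=0.25, label=f"sim {p}th 95% CI")
        ax.plot(t, table[f"obs_p{p}"], "o-", ms=3,
                label=f"observed {p}th")
    if log_y:
        ax.set_yscale("log")
    ax.set_xlabel("time after dose (h)")
    ax.set_ylabel("concentration (pg/mL)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
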
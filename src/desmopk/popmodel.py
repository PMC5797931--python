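"""Hierarchical population layer over the structural kinetics.

A :class:`PopulationModel` bundles fixed effects (typical values), centered
power covariate effects, a diagonal inter-individual variability (IIV)
matrix on the log scale (logit scale for the depot-split fraction Bio), and
a residual SD sigma additive on the log-concentration scale (exponential /
proportional error in the natural domain).

Individual parameters follow the usual NLME construction, e.g. for
clearance with a body-weight effect centered at 10 kg:

    CL_i = theta_CL * (BW_i / 10)^theta_BW,CL * exp(eta_CL,i)

Bio is kept in (0,1) by placing its random effect on the logit scale.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit, logit

from . import kinetics
from .dataset_io import PKDataset, from_records, DEFAULT_LOQ

__all__ = [
    "CovariateEffect",
    "PopulationModel",
    "IndividualParams",
    "piglet_model",
    "individual_parameters",
    "simulate_individual",
    "simulate_population",
]


@dataclass(frozen=True)
class CovariateEffect:
    """Centered power covariate effect: factor (cov/center)^exponent."""

    parameter: str
    covariate: str
    exponent: float
    center: float
    fixed: bool = False

    def __post_init__(self):
        if not self.center > 0:
            raise ValueError("centering constant must be > 0")


@dataclass
class PopulationModel:
    """Fixed effects, covariate map, IIV and residual model.

    ``theta`` holds the typical values on the reporting scale (L, L/h, 1/h,
    h; Bio as a fraction).  ``iiv`` holds diagonal Omega *variances* keyed
    by parameter; entries listed in ``iiv_fixed`` are never updated by
    estimation (the study fixes the IIV of Q, Ka2 and Tlag to zero).
    """

    theta: dict
    iiv: dict = field(default_factory=dict)
    iiv_fixed: frozenset | set = field(default_factory=set)
    sigma: float = 0.228
    covariate_effects: list = field(default_factory=list)
    theta_fixed: frozenset | set = field(default_factory=set)
    sigma_fixed: bool = False
    structural: str = "dual_depot_two_compartment"

    def __post_init__(self):
        names = kinetics.STRUCTURAL_MODELS[self.structural]
        unknown = set(self.theta) - set(names)
        if unknown:
            raise ValueError(f"theta names {unknown} not in structural model {self.structural}")
        for p, v in self.iiv.items():
            if v < 0:
                raise ValueError(f"IIV variance for {p} must be >= 0")
        if not self.sigma > 0:
            raise ValueError("sigma must be > 0")

    # -- structure ---------------------------------------------------------
    @property
    def param_names(self) -> tuple:
        return tuple(kinetics.STRUCTURAL_MODELS[self.structural])

    @property
    def eta_names(self) -> tuple:
        """Parameters with an active (non fixed-to-zero) random effect."""
        return tuple(
            p for p in self.param_names
            if p in self.iiv and not (p in self.iiv_fixed and self.iiv[p] == 0.0)
        )

    def omega_matrix(self) -> np.ndarray:
        return np.diag([self.iiv[p] for p in self.eta_names])

    def transform(self, name: str) -> str:
        return "logit" if name == "Bio" else "log"

    def effects_on(self, parameter: str) -> list:
        return [e for e in self.covariate_effects if e.parameter == parameter]

    def with_effect(self, effect: CovariateEffect) -> "PopulationModel":
        out = copy.deepcopy(self)
        out.covariate_effects = out.covariate_effects + [effect]
        return out

    def without_effect(self, parameter: str, covariate: str) -> "PopulationModel":
        out = copy.deepcopy(self)
        out.covariate_effects = [
            e for e in out.covariate_effects
            if not (e.parameter == parameter and e.covariate == covariate)
        ]
        return out

    def copy(self) -> "PopulationModel":
        return copy.deepcopy(self)

    # -- serialization -----------------------------------------------------
    def to_yaml(self, path=None) -> str:
        doc = {
            "structural": self.structural,
            "theta": {k: float(v) for k, v in self.theta.items()},
            "theta_fixed": sorted(self.theta_fixed),
            "iiv": {k: float(v) for k, v in self.iiv.items()},
            "iiv_fixed": sorted(self.iiv_fixed),
            "sigma": float(self.sigma),
            "sigma_fixed": bool(self.sigma_fixed),
            "covariate_effects": [
                {"parameter": e.parameter, "covariate": e.covariate,
                 "exponent": float(e.exponent), "center": float(e.center),
                 "fixed": bool(e.fixed)}
                for e in self.covariate_effects
            ],
        }
        text = yaml.safe_dump(doc, sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "PopulationModel":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        doc = yaml.safe_load(text)
        return cls(
            structural=doc.get("structural", "dual_depot_two_compartment"),
            theta=dict(doc["theta"]),
            theta_fixed=set(doc.get("theta_fixed", [])),
            iiv=dict(doc.get("iiv", {})),
            iiv_fixed=set(doc.get("iiv_fixed", [])),
            sigma=float(doc.get("sigma", 0.228)),
            sigma_fixed=bool(doc.get("sigma_fixed", False)),
            covariate_effects=[CovariateEffect(**e) for e in doc.get("covariate_effects", [])],
        )


@dataclass
class IndividualParams:
    """Realized structural parameters for one subject."""

    subject_id: object
    params: dict
    eta: dict

    def structural(self) -> kinetics.StructuralParams:
        return kinetics.StructuralParams(**self.params)


def piglet_model() -> PopulationModel:
    """The final piglet population model (typical values, BW effects on CL
    and V1 centered at 10 kg, six active IIV terms, 22.8% CV residual)."""
    return PopulationModel(
        theta={
            "CL": 395.0, "V1": 131.0, "Ka1": 0.275, "Q": 32.0, "V2": 436.0,
            "D1": 0.16, "Ka2": 0.399, "Bio": 0.86, "Tlag": 1.0,
        },
        iiv={
            "CL": 0.175, "V1": 0.641, "Q": 0.0, "Ka1": 0.0903, "Ka2": 0.0,
            "V2": 0.634, "D1": 0.485, "Bio": 0.627, "Tlag": 0.0,
        },
        iiv_fixed={"Q", "Ka2", "Tlag"},
        sigma=0.228,
        covariate_effects=[
            CovariateEffect("CL", "BW", 1.03, 10.0),
            CovariateEffect("V1", "BW", 0.691, 10.0),
        ],
    )


def _covariate_factor(model: PopulationModel, parameter: str,
                      covariates: Mapping) -> float:
    fac = 1.0
    for e in model.effects_on(parameter):
        if e.covariate not in covariates or pd.isna(covariates[e.covariate]):
            raise KeyError(
                f"covariate {e.covariate!r} required for parameter {parameter!r} "
                f"is missing for this subject"
            )
        fac *= (float(covariates[e.covariate]) / e.center) ** e.exponent
    return fac


def individual_params_batch(model: PopulationModel, covariates: Mapping,
                            eta: np.ndarray) -> dict:
    """Vectorized individual parameters for a batch of eta vectors.

    ``eta`` has shape (B, n_eta) ordered as ``model.eta_names``; returns a
    dict of (B,) arrays on the natural scale.
    """
    eta = np.atleast_2d(np.asarray(eta, dtype=float))
    names = model.eta_names
    if eta.shape[1] != len(names):
        raise ValueError(f"eta has {eta.shape[1]} columns, model has {len(names)} random effects")
    cols = {p: eta[:, i] for i, p in enumerate(names)}
    B = eta.shape[0]
    out = {}
    for p in model.param_names:
        base = model.theta[p] * _covariate_factor(model, p, covariates)
        if p in cols:
            if model.transform(p) == "logit":
                out[p] = expit(logit(base) + cols[p])
            else:
                out[p] = base * np.exp(cols[p])
        else:
            out[p] = np.full(B, float(base))
    return out


def individual_parameters(model: PopulationModel, covariates: Mapping,
                          eta: Mapping | Sequence | np.ndarray,
                          subject_id=None) -> IndividualParams:
    """Realize one subject's structural parameters from covariates and eta."""
    names = model.eta_names
    if isinstance(eta, Mapping):
        vec = np.array([float(eta.get(p, 0.0)) for p in names])
    else:
        vec = np.asarray(eta, dtype=float).reshape(-1)
        if vec.size != len(names):
            raise ValueError(f"expected {len(names)} eta values ({names}), got {vec.size}")
    batch = individual_params_batch(model, covariates, vec[None, :])
    return IndividualParams(
        subject_id=subject_id,
        params={k: float(v[0]) for k, v in batch.items()},
        eta={p: float(vec[i]) for i, p in enumerate(names)},
    )


def predictor(model: PopulationModel, covariates: Mapping, dose: float, times):
    """Batched log-concentration prediction function eta (B,K) -> (B,T).

    Concentrations are floored at 1e-12 pg/mL before the log so pathological
    parameter proposals yield a large finite objective instead of -inf.
    """
    times = np.asarray(times, dtype=float)
    profile = kinetics.PROFILE_FUNCTIONS[model.structural]

    def predict(eta_batch: np.ndarray) -> np.ndarray:
        params = individual_params_batch(model, covariates, eta_batch)
        conc = profile(params, dose, times)
        return np.log(np.maximum(conc, 1e-12))

    return predict


def simulate_individual(model: PopulationModel, covariates: Mapping,
                        times, dose: float,
                        rng: np.random.Generator | int | None = None,
                        subject_id=None) -> tuple[np.ndarray, IndividualParams]:
    """Simulate one subject's observations C_obs = C_pred * exp(eps).

    Draws eta ~ N(0, Omega) and eps ~ N(0, sigma^2) per sample; returns the
    concentration vector (pg/mL) and the realized individual parameters.
    """
    rng = np.random.default_rng(rng)
    names = model.eta_names
    sds = np.sqrt([model.iiv[p] for p in names])
    eta = rng.standard_normal(len(names)) * sds
    ind = individual_parameters(model, covariates, eta, subject_id=subject_id)
    profile = kinetics.PROFILE_FUNCTIONS[model.structural]
    pred = profile({k: np.asarray(v) for k, v in ind.params.items()}, dose,
                   np.asarray(times, dtype=float))
    eps = rng.standard_normal(len(np.atleast_1d(pred))) * model.sigma
    return np.asarray(pred) * np.exp(eps), ind


def simulate_population(model: PopulationModel, cohort: pd.DataFrame,
                        times, dose: float,
                        rng: np.random.Generator | int | None = None,
                        loq: float = DEFAULT_LOQ,
                        censor: str = "none",
                        predose_record: bool = True,
                        ) -> tuple[PKDataset, pd.DataFrame]:
    """Simulate a full study dataset over a cohort covariate table.

    ``cohort`` needs an ``id`` column plus the covariates the model uses;
    ``censor`` is one of ``"none"`` (keep everything), ``"flag"`` (keep,
    LOQ retrievable via ``PKDataset.below_loq``) or ``"drop"`` (apply the
    exclusion exactly as ``apply_loq_filter`` would).  Returns the dataset
    and a per-subject truth table of the eta draws.
    """
    if cohort.empty:
        raise ValueError("cohort is empty")
    if censor not in {"none", "flag", "drop"}:
        raise ValueError(f"unknown censor policy {censor!r}")
    rng = np.random.default_rng(rng)
    times = np.asarray(times, dtype=float)
    cov_cols = [c for c in cohort.columns if c != "id"]
    rows = []
    truth = []
    for _, subj in cohort.iterrows():
        sid = subj["id"]
        covs = {c: subj[c] for c in cov_cols}
        conc, ind = simulate_individual(model, covs, times, dose, rng=rng,
                                        subject_id=sid)
        base = {"id": sid, **{c: subj[c] for c in cov_cols}}
        rows.append({**base, "time": 0.0, "amt": dose, "dv": np.nan,
                     "evid": 1, "mdv": 1})
        if predose_record:
            rows.append({**base, "time": 0.0, "amt": np.nan, "dv": np.nan,
                         "evid": 0, "mdv": 1})
        for t, c in zip(times, conc):
            if censor == "drop" and c < loq:
                continue
            rows.append({**base, "time": float(t), "amt": np.nan,
                         "dv": float(c), "evid": 0, "mdv": 0})
        truth.append({"id": sid, **{f"eta_{k}": v for k, v in ind.eta.items()},
                      **{f"param_{k}": v for k, v in ind.params.items()}})
    df = pd.DataFrame(rows)
    ds = from_records(df, loq=loq, provenance="simulate_population")
    return ds, pd.DataFrame(truth)
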
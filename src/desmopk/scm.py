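"""Stepwise covariate modeling: forward inclusion, backward elimination.

Candidate effects are centered power relations added one at a time to a
base model.  A candidate enters during forward selection when it drops the
objective by more than the chi-squared df=1 quantile at p < 0.01 (6.635);
during backward elimination an included effect is retained only when its
removal worsens the objective by more than the p < 0.001 quantile (10.828).
Forward steps take the largest qualifying drop; ties break by candidate
declaration order, so a run is deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .dataset_io import PKDataset
from .popmodel import PopulationModel, CovariateEffect
from . import foce

__all__ = [
    "CovariateCandidate",
    "SCMStep",
    "SCMTrace",
    "lrt_threshold",
    "FORWARD_P",
    "BACKWARD_P",
    "evaluate_candidate",
    "run_scm",
]

FORWARD_P = 0.01
BACKWARD_P = 0.001


def lrt_threshold(p: float, df: int = 1) -> float:
    """Chi-squared quantile used as a likelihood-ratio OFV threshold."""
    return float(chi2.ppf(1.0 - p, df))


@dataclass(frozen=True)
class CovariateCandidate:
    """A centered power covariate effect proposed for one parameter."""

    parameter: str
    covariate: str
    center: float | None = None  # None: dataset median of the covariate
    exponent_init: float = 0.0

    def label(self) -> str:
        return f"{self.covariate} on {self.parameter}"

    def effect(self, ds: PKDataset) -> CovariateEffect:
        center = self.center
        if center is None:
            center = float(ds.records.drop_duplicates("id")[self.covariate].median())
        return CovariateEffect(self.parameter, self.covariate,
                               self.exponent_init, center)


@dataclass
class SCMStep:
    stage: str          # forward | backward
    candidate: str
    delta_ofv: float
    threshold: float
    decision: str       # included | rejected | removed | retained | skipped


@dataclass
class SCMTrace:
    steps: list = field(default_factory=list)
    final_model: PopulationModel | None = None
    final_fit: foce.FitResult | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(s) for s in self.steps])


def _validate_candidate(c: CovariateCandidate, model: PopulationModel,
                        ds: PKDataset) -> None:
    if c.parameter not in model.param_names:
        raise ValueError(f"candidate targets unknown parameter {c.parameter!r}")
    if c.covariate not in ds.records.columns:
        raise ValueError(f"covariate {c.covariate!r} not present in the dataset")


def evaluate_candidate(base_fit: foce.FitResult, candidate: CovariateCandidate,
                       ds: PKDataset, threshold: float | None = None,
                       **fit_kwargs) -> tuple[float, bool, foce.FitResult | None]:
    """Fit base+candidate; return (delta OFV, qualifies, extended fit).

    delta OFV = OFV(base) - OFV(extended); a positive value is an
    improvement.  A non-converged extended fit is skipped (returns
    ``(nan, False, None)``) rather than aborting the search.
    """
    threshold = lrt_threshold(FORWARD_P) if threshold is None else threshold
    _validate_candidate(candidate, base_fit.model, ds)
    extended = base_fit.model.with_effect(candidate.effect(ds))
    fit_kwargs.setdefault("cov_step", False)
    fit_kwargs.setdefault("restarts", 2)
    try:
        ext_fit = foce.fit(extended, ds, **fit_kwargs)
    except (foce.InnerOptimizationError, np.linalg.LinAlgError) as exc:
        warnings.warn(f"candidate {candidate.label()} skipped: {exc}")
        return float("nan"), False, None
    if not np.isfinite(ext_fit.ofv):
        warnings.warn(f"candidate {candidate.label()} skipped: {ext_fit.message}")
        return float("nan"), False, None
    if not ext_fit.success:
        warnings.warn(f"candidate {candidate.label()} did not formally "
                      f"converge ({ext_fit.message}); using best OFV found")
    delta = base_fit.ofv - ext_fit.ofv
    return delta, bool(delta > threshold), ext_fit


def run_scm(model: PopulationModel, ds: PKDataset,
            candidates: list[CovariateCandidate],
            forward_threshold: float | None = None,
            backward_threshold: float | None = None,
            **fit_kwargs) -> tuple[PopulationModel, SCMTrace]:
    """Forward-inclusion / backward-elimination covariate search.

    Every step re-fits all non-fixed parameters.  Returns the final model
    and the full decision trace.
    """
    fwd = lrt_threshold(FORWARD_P) if forward_threshold is None else forward_threshold
    bwd = lrt_threshold(BACKWARD_P) if backward_threshold is None else backward_threshold
    trace = SCMTrace()
    fit_kwargs.setdefault("cov_step", False)
    fit_kwargs.setdefault("restarts", 2)
    current_fit = foce.fit(model, ds, **fit_kwargs)
    if not candidates:
        trace.final_model = current_fit.model
        trace.final_fit = current_fit
        return current_fit.model, trace

    remaining = list(candidates)
    included: list[CovariateCandidate] = []
    # ---- forward selection ----
    while remaining:
        results = []
        for c in remaining:
            delta, ok, ext = evaluate_candidate(current_fit, c, ds, fwd, **fit_kwargs)
            if ext is None:
                trace.steps.append(SCMStep("forward", c.label(), delta, fwd, "skipped"))
                continue
            results.append((delta, c, ext))
        qualifying = [r for r in results if r[0] > fwd]
        if not qualifying:
            for delta, c, _ in results:
                trace.steps.append(SCMStep("forward", c.label(), delta, fwd, "rejected"))
            break
        best = max(qualifying, key=lambda r: r[0])  # ties: first wins (stable max)
        for delta, c, _ in results:
            if c is not best[1]:
                trace.steps.append(SCMStep("forward", c.label(), delta, fwd, "rejected"))
        trace.steps.append(SCMStep("forward", best[1].label(), best[0], fwd, "included"))
        current_fit = best[2]
        included.append(best[1])
        remaining = [c for c in remaining if c is not best[1]]

    # ---- backward elimination ----
    while included:
        results = []
        for c in included:
            reduced = current_fit.model.without_effect(c.parameter, c.covariate)
            try:
                red_fit = foce.fit(reduced, ds, **fit_kwargs)
            except (foce.InnerOptimizationError, np.linalg.LinAlgError) as exc:
                warnings.warn(f"removal of {c.label()} skipped: {exc}")
                continue
            worsening = red_fit.ofv - current_fit.ofv
            results.append((worsening, c, red_fit))
        if not results:
            break
        worst, cand, red_fit = min(results, key=lambda r: r[0])
        if worst > bwd:
            for w, c, _ in results:
                trace.steps.append(SCMStep("backward", c.label(), w, bwd, "retained"))
            break
        trace.steps.append(SCMStep("backward", cand.label(), worst, bwd, "removed"))
        current_fit = red_fit
        included = [c for c in included if c is not cand]

    trace.final_model = current_fit.model
    trace.final_fit = current_fit
    return current_fit.model, trace
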
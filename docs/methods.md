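# Methods

## The model

`desmopk` implements a population pharmacokinetic analysis of a single
120 µg sublingual desmopressin lyophilisate given to growing piglets in
four age groups (8 days, 4 weeks, 7 weeks, 6 months; 8 animals each).
Because part of a fast-dissolving sublingual tablet is absorbed through the
buccal mucosa and part is swallowed, plasma profiles show a double peak.
The structural model therefore uses a dual input into a two-compartment
disposition system:

* a fraction `Bio` of the dose enters depot 1 by **zero-order release over a
  duration `D1`** and is absorbed **first-order (`Ka1`)** into the central
  compartment (buccal route, no lag);
* the remaining `1 − Bio` sits in depot 2 and starts **first-order release
  (`Ka2`) after a lag time `Tlag`** (gastrointestinal route). When depot 2
  is filled is not observable; we treat it as a lagged bolus — equivalent
  to any filling schedule that completes before `Tlag`;
* disposition is linear two-compartmental with micro-constants
  `k10 = CL/V1`, `k12 = Q/V1`, `k21 = Q/V2`, and plasma concentration
  `C = A_central / V1`.

All parameters are *apparent* (scaled by the unknown absolute
bioavailability `F ≡ 1`): `CL/F` (L/h), `V1/F` (L), `Q/F` (L/h), `V2/F`
(L), `Ka1`, `Ka2` (1/h), `Bio` ∈ (0,1), `Tlag`, `D1` (h). Internal units
are h, pg, mL and pg/mL; the dose is stored as 1.2×10⁸ pg, and L-based
interface values are converted at the boundary so `C = A/V` can never mix
units.

The closed form superposes, per input, the convolution of the
bi-exponential disposition response (eigenvalues `λ1, λ2` from the sum and
product of the micro-constants) with the input profile; the zero-order
phase is written as a step-on minus step-off superposition so the profile
is continuous at `t = D1` and `t = Tlag`. Near-degenerate cases
(`|Ka − λ| < 1e-8·λ`) switch to the l'Hôpital limit expressions. A
stiff-capable ODE integration of the four-state system (`solve_ivp`,
LSODA, segment breaks at `D1` and `Tlag`) serves as the numerical oracle
and fallback; closed form and ODE agree to ≤1e-6 relative over random
parameter draws, mass balance closes to ≤1e-8, and `AUC₀→∞ = dose/CL`
holds independently of the absorption parameters (linear system, complete
absorption of both depot fractions).

## Hierarchical layer

Typical values are modified by centered power covariate effects
(`CL = θ_CL · (BW/10)^θ_BW,CL · e^η`; body weight centered at 10 kg,
configurable) and log-normal inter-individual variability (IIV) with a
diagonal Ω. The IIV of `Q`, `Ka2` and `Tlag` is fixed to zero, mirroring
the study's finding that these could not be estimated. `Bio` carries its
random effect on the **logit** scale: an exponential effect with the
reported variance 0.627 on a fraction of 0.86 would routinely exceed 1,
whereas the logit keeps realized fractions in (0,1). Residual error is
additive on the log-concentration scale (log-transform-both-sides, i.e. a
proportional error in the natural domain); σ is stored as the log-scale SD
and reported as `% CV = 100·σ` (0.228 ↔ 22.8% CV, which exactly reproduces
the printed residual RSE 0.0291/0.228 = 12.76%).

## Estimation (FOCE)

The marginal likelihood is approximated by first-order conditional
estimation: per subject an inner Levenberg–Marquardt-damped Gauss–Newton
finds the conditional mode `η̂ᵢ` (finite-difference Jacobian,
objective-change convergence at 1e-10 with a quadratic-model noise-floor
guard, max 100 iterations); the
model is then linearized in η around `η̂ᵢ`, giving the per-subject
contribution `nᵢ log 2π + log|Vᵢ| + rᵢᵀVᵢ⁻¹rᵢ` with
`Vᵢ = JᵢΩJᵢᵀ + σ²I` and `rᵢ = yᵢ − (f(η̂ᵢ) − Jᵢη̂ᵢ)`. Because the
residual is additive on the log scale no η-interaction term arises, and
on linear-Gaussian models the objective equals the exact −2 log marginal
likelihood. The full `2π` constant is included so exact-likelihood and
quadrature oracles match; ΔOFV between nested models is unaffected by the
convention.

The outer problem is minimized with L-BFGS-B on an unconstrained
estimation scale (log for positive parameters, logit for `Bio`, identity
for covariate exponents, log-SD for Ω entries and σ) with finite-difference
gradients (absolute step 1e-5 by default; an optional central-difference
mode doubles the cost for higher accuracy). Conditional modes are
warm-started across objective evaluations for speed. Because the
conditional-mode problem of a double-peak model is multi-modal, a
warm-started mode can occasionally land in a different basin than a
prior-mean start would, giving the objective a small path dependence.
Two safeguards keep this harmless: the OFV reported for a finished fit is
always recomputed with deterministic prior-mean (cold) conditional modes,
so ΔOFV between separately fitted models is well-defined; and a fit whose
optimizer never meaningfully leaves the starting vector — the signature
of a warm-start cache poisoned by a line-search excursion — is
automatically redone, first from small deterministic steps along the
descent direction with a fresh cache, then against the cold-start
objective if that still freezes. Wide box bounds (±6 log units
for fixed effects; random-effect SDs capped at 3) exclude only the region
where the hierarchy degenerates — with an IIV SD above ~3 the prior is so
flat that the subject-level problems turn multi-modal and the typical
values become unidentified. An optional restart chain re-launches the
search from the incumbent optimum until the OFV improves by less than
0.5, which rescues runs that stall on rough landscapes (e.g. a
no-covariate base model fitted to data spanning a 50-fold body-weight
range, as every covariate-search step must do). The covariance step
inverts a central
finite-difference Hessian of OFV/2 (step 5e-4) and maps SEs to the
reporting scale by the delta method; Ω entries are reported as variances
with the RSE on the SD scale (`100·SE/(2·estimate)`), which is the
convention the published table's arithmetic implies. The condition number
is the eigenvalue ratio of the correlation matrix of the estimates
(alarm threshold 1000). Eta shrinkage is `100·(1 − SD(η̂)/ω)` with the
n−1 sample SD. `AIC = OFV + 2·(free parameters)`.

Fully censored subjects (no quantifiable observations) drop out of the
likelihood. Predicted concentrations are floored at 1e-12 pg/mL before the
log so pathological proposals yield a large finite objective rather than
NaN.

## Covariate selection

Stepwise covariate modeling adds centered power effects one at a time:
forward inclusion requires ΔOFV > 6.635 (χ², df = 1, p < 0.01), backward
retention requires that removal worsens the OFV by > 10.828 (p < 0.001).
The largest qualifying drop wins each forward step (ties by declaration
order); every step re-fits all non-fixed parameters. Non-converged
candidate fits are skipped with a warning and recorded in the trace.
Only power forms are scanned.

## Diagnostics

CWRES uses the standard FOCE linearization at the conditional mode on the
log scale, with the inverse matrix square root of `JΩJᵀ + σ²I`; for a
correctly specified linear-Gaussian model it is exactly standard normal,
which the suite uses as an oracle. The VPC simulates replicate datasets
under the fitted model with the original design (subjects, covariates,
dose, nominal times), applies the LOQ exclusion to the simulated data by
default (mirroring how the analysis dataset is built; switchable), bins by
exact nominal time, and reports observed 5th/50th/95th percentiles next to
the simulation median and 95% confidence band of each percentile. Defaults
are 1,000 simulations; no smoothing is computed — the artifact emits
tables, plotting is a thin optional layer.

## Secondary parameters (NCA)

`AUC₀→last` uses the logarithmic trapezoid (linear trapezoid on equal or
zero-bounded segments), the tail is `C_last/λz`, and `T½ = ln 2/λz`. The
terminal slope λz is a log-linear regression over the tail point set with
the best adjusted R² among all candidate tails of ≥3 points strictly after
the global maximum; fewer than 3 usable points yields a no-estimate result
with `AUC₀→last` still reported. Extrapolated fractions above 20% are
flagged (flag only, no exclusion). By default NCA runs on dense noise-free
individual profiles realized from the empirical Bayes estimates (the
posthoc step); an observed-data mode feeds sampled concentrations into the
same functions. Note that within the 24 h schedule the absorption rates
(0.275/0.399 1/h) still feed the curve at 10–24 h, so the apparent λz is a
blend and exceeds the smallest disposition eigenvalue (~0.068 1/h); the
eigenvalue identity only emerges when sampling extends far past the
absorption phase.

## Synthetic studies

The generator emulates the study design: 4 groups × 8 piglets, the
published BW/BSA/GFR group statistics, a single 1.2×10⁸ pg dose, nominal
samples at 5/15/30/60 min and 1.5/2/3/4/6/8/10/12/24 h plus a pre-dose
placeholder record, and LOQ exclusion at 4 pg/mL (the analysis threshold;
the assay LOQ is 4.2 pg/mL — both are configurable). Body weight is a
truncated normal on the published group range whose parent location is
solved so the truncated mean matches the published mean exactly; the
published SD is used as the parent scale. (The published SDs are not
jointly attainable with truncation at the observed ranges — an 8-animal
range understates the population spread — so realized SDs are somewhat
smaller.) BSA and GFR are allometric functions of BW (`BSA ∝ BW^(2/3)`,
`GFR ∝ BW^0.3`, per-group coefficients matched to the published means)
with mean-one lognormal noise sized from the published residual spread.
Tying the covariates to BW reproduces the collinearity that makes
covariate selection non-trivial. An alternative 7-week preset ships with
the other BW statistics printed for that group (13.9 ± 2.74 kg).

Every study returns a truth sidecar (generating model, per-subject
covariates and η draws, seed, BLOQ fractions) so recovery experiments can
compare estimates against the exact generating values. Simulated datasets
from the final model typically lose ~25–30% of observations to the
4 pg/mL exclusion, dominated by the 6-month group whose exposures fall
below the LOQ early — the generator's BLOQ exclusion is what the analysis
prescribes, not a tuning knob.

What the generator does **not** emulate: assay error structure beyond a
lognormal CV, actual (vs nominal) sampling times, pre-dose endogenous
signal, dropout, or any pharmacodynamic response. Passing recovery tests
therefore demonstrate correctness of the estimation machinery under the
model's own assumptions, not robustness to real-data misspecification.

## Problem sizes and experiment design

Replicate recovery experiments use 5 replicates of the full 32-subject
design; medians across replicates are compared with the generating values.
Recovery fits start at the generating values (the experiment measures
noise-driven displacement, not basin-finding) and skip the covariance
step. The covariate-selection calibration experiments run on a
one-compartment bolus model with the same cohort, covariate structure and
variability magnitudes — a full dual-depot stepwise search over replicates
would cost hundreds of NLME fits without changing what the experiment
measures (threshold behaviour of ΔOFV under the χ² calibration).

## Known limitations

* Below-LOQ records are excluded (as the analysis prescribes), not
  integrated into the likelihood (no M3); with ~30% exclusion this leaves
  a small downward bias in clearance-related estimates, visible in the
  recovery medians but within the stated bands.
* Ω is diagonal; no inter-occasion variability; single dose only.
* The inner/outer optimization uses finite differences throughout; the
  covariance step can fail on ill-conditioned fits, in which case
  estimates are returned without SEs.
* Absolute OFV values are convention-dependent (full constant included);
  only ΔOFV is comparable across software.
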
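# Methods

## Model

The simulator integrates a three-compartment ordinary-differential-
equation model of a disseminated tumor under two interacting therapies.
Non-irradiated tumor cells `NT` grow exponentially with net rate ρ
(birth minus death); there is no carrying capacity, which is adequate
for preclinical time scales where burden stays far from a plateau but
overestimates late-time growth of slow clinical tumors. CAR-T cells
`NC` kill tumor cells in either compartment by mass action (rate
constant k1 per CAR-T cell), change number on tumor contact at net rate
k2 (proliferation when positive dominates exhaustion) and die at rate
θ. Cells hit by the radiotherapeutic move into an irradiated
compartment `NR` that no longer proliferates and clears at rate k_cl.
Both therapies are assumed well mixed with the tumor — reasonable for a
disseminated disease, wrong for solid lesions with heterogeneous
uptake.

The irradiation rate uses the linear-quadratic cell-kill model with the
Lea–Catcheside protraction factor for a mono-exponentially decaying
dose rate: `k_Rx(s) = α·R0·e^(−λs)` plus a quadratic term
`[2βR0²/((γ−λ)γλ)]·(e^(−2λs) − e^(−(λ+γ)s))`, where s is time since
injection, `R0 = η·A0`, λ the effective (physical + biological) decay
constant and γ the sublethal-damage repair rate. The printed form of
the protraction term in the source literature is typographically
ambiguous about grouping; the implementation follows the standard
bi-exponential Lea–Catcheside form shown above. For alpha-particle
therapy β = 0 (high-LET damage has no sublethal component) and the
quadratic term vanishes; γ is therefore only required — and only
validated — when β > 0. γ = λ is a removable singularity of the
quadratic coefficient; the implementation rejects it with an explicit
error rather than silently substituting the limit.

**Decay clock.** Each TRT injection's dose rate is maximal at its own
injection time: the exponential factors are evaluated at
`s = t − τ_TRT` of that injection, and multiple injections sum their
kernels. (Evaluating the decay at absolute time t instead would make a
day-7 injection arrive pre-decayed by ~39% and is inconsistent with the
endpoint values this model class reports.)

**Administrations.** CAR-T boluses are instantaneous state jumps, not
source terms. Integration is split at every administration time so the
solver never steps across a discontinuity. Heaviside convention:
`H(t−τ) = 1` for `t ≥ τ`.

## Parameters

| symbol | meaning | unit | default |
|---|---|---|---|
| ρ | net tumor proliferation rate | 1/day | 0.27 |
| k1 | CAR-T killing rate | 1/day/cell | 4.49×10⁻⁷ |
| k2 | CAR-T stimulation/exhaustion rate | 1/day/cell | 3.6×10⁻¹³ |
| θ | CAR-T death rate | 1/day | 0.042 |
| k_cl | irradiated-cell clearance | 1/day | 0.5 |
| λ | effective decay constant | 1/day | 0.07 |
| α_T, α_C | tumor / CAR-T radiosensitivity | 1/Gy | 1.5 |
| β | quadratic radiosensitivity | 1/Gy² | 0 |
| γ | tissue repair rate | 1/day | unset (needed iff β > 0) |
| η | activity → dose rate | Gy/day/µCi | 3.48 |

Defaults are the experimentally derived reference set for an MM1S
multiple-myeloma xenograft treated with CS1 CAR-T cells and an Ac-225
antibody conjugate. Activities are stored in µCi internally; the CLI
and schedule builders accept nCi (100 nCi = 0.1 µCi). Reference
protocol: 5×10⁶ tumor cells at t = 0, first therapy day 7, 100 nCi TRT,
10⁶ CAR-T cells, lethal threshold 10¹¹ cells, horizon 150 days.

## Numerics

LSODA (stiff-capable, adaptive) with rtol 10⁻⁸ and atol 10⁻² cells,
dense output per inter-administration segment. The tolerance choice is
driven by endpoint stability: threshold-crossing times must be stable
to well under 0.05 day, and under a 10× tolerance refinement the
computed PFS/OS shift by < 5×10⁻⁵ day. Pointwise *global* relative
error of the trajectory plateaus near 10⁻⁴–10⁻⁵ (local tolerance does
not bound global error for a multi-scale stiff system); the convergence
test therefore asserts endpoint stability and a 10⁻³ burden band rather
than the raw integrator tolerance. State inputs to the right-hand side
are clamped at zero: the clearance and kill terms can drive tiny
negative excursions at sharp transients.

Endpoint location: crossings are bracketed on a 0.05-day scan of the
dense trajectory and refined by Brent root finding (crossings) or
bounded scalar minimization (nadir), then rounded half-up to whole days
to match the convention of the published response tables.

**Search window.** PFS and nadir are searched over
`first_therapy_day ≤ t ≤ OS`. This matters: the mass-action k1/k2
coupling admits predator-prey rebounds, and with a 150-day horizon the
CAR-T-only regimen develops a *second, deeper* burden minimum around
day 124 — after the lethal 10¹¹ crossing at day 74, i.e. in a regime
with no biological meaning. Windowing at OS restores the intended
endpoint ordering t_nadir ≤ PFS ≤ OS.

## Regimen analysis

Five regimens: control, TRT-only, CAR-T-only (first therapy day 7) and
the two combination orderings. The second therapy day is swept over
14–80 in 1-day steps; per metric the sweep reports the maximum and the
smallest interval achieving it (OS is flat near its optimum over a wide
interval range, so ties are real; the full plateau is also recorded).
The response-summary table reports combination columns as per-metric
maxima over the sweep, with the fixed 7-day-interval values alongside:
at a 7-day interval the TRT-before-CAR-T ordering actually
*underperforms* CAR-T monotherapy on OS (the decaying radionuclide
kills the incoming CAR-T cells), so the additivity of the combination
is a statement about well-chosen intervals, not all intervals.

## Sensitivity analysis

One-at-a-time ±50% perturbations of nine quantities (TRT activity,
CAR-T dose, initial burden, ρ, k1, k2, θ, α_C, λ) around the fixed
CAR-T(day 7) → TRT(day 14) regimen; λ only +50% because its reference
value already contains the physical decay constant, which cannot
decrease. Outcomes use unrounded crossing times so sub-day effects are
visible. Quantities are ranked by the largest |ΔPFS| or |ΔOS| they
induce; classification into direct/inverse uses the metric with the
larger swing, with a 1-day deadband flagging weak effects (k2's fitted
value is so small its influence is fractions of a day). A flag-free
fixed-interval design was chosen over re-optimizing the interval per
perturbation because the perturbation study is defined around the
fixed-schedule regimen; `run_sensitivity` accepts any base spec if the
re-optimized variant is wanted.

## Calibration

ρ is the ordinary-least-squares slope of log signal vs. day on control
series (BLI radiance is proportional to cell number, so the slope is
scale-free). Radiance is converted to cells by back-extrapolating the
fitted exponential to the inoculation day and anchoring it to the known
inoculum; for *treated* series only pre-therapy observations follow the
untreated exponential, so the anchor is restricted to days ≤ therapy
day (`anchor_max_day`) — without this restriction the therapy dip
biases the scale and wrecks downstream estimates of θ.

(k1, k2, θ) minimize squared residuals of log total burden at the
observation days plus one residual matching the day-28 CAR-T:tumor
fraction on the log-odds scale (weight 1 residual unit, configurable).
Log-burden residuals equalize relative error across a signal spanning
decades. The search runs in log10 parameter space over wide bounds
(k1 ∈ [10⁻⁹,10⁻⁵], k2 ∈ [10⁻¹⁵,10⁻¹⁰], θ ∈ [10⁻³,1]): 16 log-uniform
starting points (seeded) are scored on their initial objective and the
best 4 polished with bounded trust-region least squares — a standard
multi-start triage; polishing all 16 reproduces the same optima at
three times the cost. k2 is weakly identifiable from these data (its
reference value is so small that the burden curve barely responds
within its bounds); recovery tests hold it to order of magnitude only,
while k1 and θ are recovered to a few percent from noiseless data.

## Synthetic data

The generator emulates the calibration's data-generating process:
per-animal control series `N0·e^(ρ·day)` and treated series from the
simulated CAR-T trajectory, both times multiplicative lognormal noise
(σ = 0.2 log units by default — a typical whole-animal BLI
repeat-measurement spread; the true measurement noise of any given
study is unknown, so σ is a declared default, not an estimate) and an
arbitrary radiance-per-cell scale. Cohort sizes default to 7 control
and 3 treated animals; the imaging grid is every 3 days from day 0 to
28, a typical preclinical BLI cadence. Day-28 ratio observations are
the noiseless model ratio perturbed by the same noise, mimicking a
terminal flow-cytometry readout. Everything is deterministic under the
seed. Not modeled: imaging physics (depth attenuation, scatter),
animal-level parameter heterogeneity, censoring/dropout — so passing
recovery tests demonstrate estimator correctness under the assumed
noise model, not robustness to real-world BLI artifacts.

## Known limitations

- Exponential growth only; no logistic/Gompertz option.
- Monoexponential CAR-T decay (appropriate for marrow-resident CAR-T
  measurements; blood kinetics are often biexponential).
- No toxicity, cytokine-release or radiation-immune-stimulation terms;
  no organ-level pharmacokinetics or daughter-nuclide redistribution;
  absorbed fraction assumed unity (alpha emitters).
- The untreated-control OS at the reference inoculum (5×10⁶ cells)
  computes to 37 days analytically and numerically; published tables
  for this model class sometimes quote a control OS consistent with a
  1×10⁶ inoculum instead (≈ 43 days). The inoculum is an explicit
  argument everywhere for this reason.
- Mass-action CAR-T kinetics admit oscillatory (predator-prey)
  solutions; at the reference parameters these appear only past the
  lethal-burden crossing and are excluded from endpoints by the OS
  search window.
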
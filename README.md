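# trtcart

Simulator for combination therapy with an alpha-emitting **targeted
radionuclide therapeutic (TRT)** and **CAR-T cell immunotherapy**, built
around a three-compartment tumor-dynamics model for a disseminated
(multiple-myeloma-style) disease setting. It answers scheduling
questions that are hard to test exhaustively in the lab: given fixed
doses of each agent, *in which order and how far apart* should the two
therapies be given to maximize tumor control?

Intended users are mathematical-oncology and radiopharmaceutical
modelers who want a reproducible, scriptable implementation of this
model class — including endpoint computation, interval optimization,
sensitivity analysis and calibration to bioluminescence-imaging (BLI)
burden data.

## The model

Three coupled compartments: non-irradiated tumor cells `NT`, lethally
irradiated tumor cells `NR` (total burden `T = NT + NR`) and CAR-T
cells `NC`:

```
dNT/dt = ρ·NT − H(t−τ_TRT)·k_Rx,T·NT − k1·NT·NC
dNR/dt = H(t−τ_TRT)·k_Rx,T·NT − k1·NR·NC − k_cl·NR
dNC/dt = k2·(NT+NR)·NC − H(t−τ_TRT)·k_Rx,C·NC − θ·NC
```

Tumor cells proliferate exponentially at net rate ρ; CAR-T cells kill
by mass action (k1), are stimulated to proliferate or exhaust on tumor
contact (k2) and die at rate θ; irradiated cells do not proliferate and
clear at rate k_cl. The irradiation rate follows the linear-quadratic
model with the Lea–Catcheside protraction factor for an exponentially
decaying dose rate,

```
k_Rx(s) = α·R0·e^(−λs) + [2β·R0²/((γ−λ)γλ)]·(e^(−2λs) − e^(−(λ+γ)s))
```

with `R0 = η·A0` the initial dose rate of injected activity `A0` and
`s` the time since injection. For alpha emitters (e.g. Ac-225
conjugates) β = 0 and only the linear term survives. CAR-T boluses are
instantaneous jumps in `NC`; the Heaviside factors switch the TRT terms
on at the injection time.

Endpoints per simulated regimen, in days from tumor initiation:
**PFS** (burden regains its pre-therapy baseline), **OS** (burden
reaches 10¹¹ cells) and **time to nadir** (post-therapy burden
minimum).

## Worked example

Default parameters are the experimentally derived reference set
(ρ = 0.27/day, k1 = 4.49×10⁻⁷, k2 = 3.6×10⁻¹³, θ = 0.042/day,
k_cl = 0.5/day, λ = 0.07/day, α_T = α_C = 1.5/Gy, η = 3.48 Gy/day/µCi)
with the reference protocol: 5×10⁶ tumor cells at t = 0, first therapy
at day 7, 100 nCi TRT, 10⁶ CAR-T cells.

```
$ trtcart simulate --regimen cart_then_trt
      regimen  pfs_days  os_days  t_nadir_days  nadir_burden  baseline_burden
cart_then_trt      43.0     77.0          26.0  4.113997e+06     3.309684e+07
```

CAR-T at day 7 followed by TRT at day 14 keeps the tumor below its
pre-therapy baseline (3.3×10⁷ cells) until day 43, drives the burden
minimum to 4.1×10⁶ cells at day 26, and delays the lethal 10¹¹-cell
crossing to day 77 — versus day 37 untreated.

The full response summary (monotherapies at day 7; combination columns
report the maxima attainable over a day-14–80 second-therapy sweep,
with the fixed 7-day-interval values below):

```
$ trtcart summary
                          control  trt_only  cart_only  cart_then_trt  trt_then_cart
pfs_days                      NaN      27.0       34.0           56.0           43.0
os_days                      37.0      64.0       74.0           98.0           98.0
t_nadir_days                  NaN      19.0       19.0           44.0           34.0
optimal_interval_pfs          NaN       NaN        NaN           25.0           20.0
pfs_days_7d_interval          NaN       NaN        NaN           43.0           36.0
os_days_7d_interval           NaN       NaN        NaN           77.0           70.0
t_nadir_days_7d_interval      NaN       NaN        NaN           26.0           21.0
```

Reading it: either ordering of the combination beats both monotherapies
when the interval is chosen well, and giving CAR-T cells *before* TRT
is the better sequence (max PFS 56 vs 43 days) because the
still-decaying radionuclide kills CAR-T cells given after it. The
PFS-optimal gap between therapies is ~25 days for CAR-T-first.

Other subcommands: `trtcart sweep --regimen cart_then_trt` (per-interval
endpoint table), `trtcart sensitivity` (±50% one-at-a-time design;
ranks tumor proliferation rate ρ as the most influential quantity and
k2 as the least), `trtcart make-fixtures` / `trtcart fit` (synthetic
BLI-style cohorts and the calibration pipeline that recovers ρ from
control animals and k1, k2, θ from treated animals plus a day-28
CAR-T:tumor flow-cytometry datum).

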
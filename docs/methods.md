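# Methods

## Dose-response model and fitting

Single-agent cytotoxicity is modeled by the median-effect equation
`fa/fu = (D/Dm)^m`. The default estimator is ordinary least squares on the
linearized median-effect plot, `log10(fa/fu)` against `log10 D`, over the
nonzero doses; `m` is the slope, `Dm = 10^(−intercept/m)`, and the reported
R² is that of the linearized fit — the classic presentation, and the one
whose R² matches what synergy studies conventionally print. Replicates
enter as individual regression points by default (`pooling=
"pooled-replicates"`); per-dose means are available. Points are
unweighted.

The linearization amplifies noise where fa is near 0 or 1 (the variance of
`log10(fa/fu)` grows like `1/(fa·fu)²`), so the package also offers
`refine=True`: nonlinear least squares on fa itself, initialized at the
OLS solution and log-parameterized in (Dm, m). Under additive absorbance
noise this is the efficient estimator and is the recommended mode when the
goal is parameter recovery rather than matching the printed-fit
convention; the linearized R² and residuals are still reported.

A fitted slope ≤ 0 raises a non-monotone-response error; a slope below
0.01 is returned with a warning (Dm is then poorly determined). Fits
require at least two distinct nonzero doses.

## Normalization

The fraction unaffected is viability relative to untreated control:
`fu = OD_treated / mean(OD_control)` using reference-corrected OD
(570 nm − 650 nm) at the same readout time. Control wells are those with
both doses zero; their mean is pooled over replicates by default, with
per-replicate pairing as an option. fa = 1 − fu is clipped into
[ε, 1 − ε], ε = 0.005 by default, because the log transform is undefined
at fa ∈ {0, 1}; the zero-dose row is retained in the table but excluded
from fits. Negative corrected OD (possible by measurement noise at full
kill — the formazan signal itself cannot be negative) is flagged and
floors at fu = ε. Normalization is scale-invariant: multiplying all
corrected ODs at a time point by a positive constant leaves every fa
unchanged. Baseline-anchored normalization against the 0 h plate is
deliberately not the default; the 0 h readout is retained in generated
data but the default analysis uses the 72 h slice (configurable via
`--time-h`).

## Combination index

The CI uses the two-term (mutually exclusive) Chou–Talalay form without
the third product term; this choice reproduces the published CI values in
the packaged fixture from their printed parameters, which the three-term
form does not. The combination's dose axis is the compound-1
concentration, so its fitted Dm is in compound-1 units and `D2 = r·D1`
with r = 0.1 in the reference design. The reference effect level defaults
to fa = 0.5, where `CI = Dm_c/Dm_1 + r·Dm_c/Dm_2` and the combination's
fitted slope cancels. Classification uses strict inequalities by default
(band 0); a configurable band widens the "additive" verdict for practical
use. Analytic invariants: sham self-combinations give CI = 1 at every fa,
ratio and slope; `CI = 1/DRI1 + 1/DRI2` holds identically; CI is invariant
to a common rescaling of all doses.

## Packaged fixture and its two flagged rows

The fixture transcribes two published summary tables: 11 single-agent
rows plus doxorubicin singles, and 13 combination rows.
Recomputing each combination's CI from printed parameters reproduces the
printed CI within ±0.02 for 11 of 13 rows. Two rows (A204 M344+Tam,
printed 0.19 vs recomputed 0.044; G401 SAHA+Tam, printed 0.06 vs
recomputed 0.090) disagree beyond rounding — most plausibly the published
CIs were computed from unrounded fits. The consistency check reports both
values and flags the discrepancy rather than guessing intent.

## Synthetic plates

`simulate_single_agent` draws wells as
`a570 = 0.05 + od_bg + od_max·fu(D, t) + N(0, noise_sd)` and
`a650 = 0.05 + N(0, noise_sd/5)`, so the corrected OD is
`od_bg + od_max·fu` plus noise and equals it exactly at `noise_sd = 0`.
Defaults: `od_max = 1.0` OD (a typical MTT control plateau),
`noise_sd = 0.02` OD, `od_bg = 0` — ratio normalization implicitly
assumes the 650 nm reference removes plate background, so a nonzero
background is exposed only as a robustness knob. Potency grows with
exposure time as `Dm(t) = dm·(1 + h/t)` with `h = 2 h` by default
(`Dm(72 h) = 1.028·dm`; no effect at t = 0); recovery tests therefore
compare fitted Dm against the *effective* Dm at the analyzed time, the
generator's actual truth there.

`simulate_combination` carries a true combination index ψ: at each
compound-1 dose D the achieved fa solves `D/Dx1(fa) + rD/Dx2(fa) = ψ` by
Brent root-finding bracketed in (10⁻¹², 1 − 10⁻¹²) — the left side falls
monotonically from +∞ to 0 in fa, so the root always exists. When the two
agents share a slope m the ray is itself exactly median-effect with
`Dm_c = ψ/(1/Dm1 + r/Dm2)` and the same m; with unequal slopes the ray is
only approximately median-effect and a noise-free fitted CI deviates from
ψ by the linearization error (a few percent), which is a property of the
method, not the generator.

What the generator does *not* emulate: plate-geometry effects (edge wells,
drift), growth kinetics or incubation chemistry, non-Gaussian or
signal-dependent noise, and inter-plate batch effects. Passing recovery
tests therefore validate the estimators under the assumed noise model,
not robustness to those artifacts.

## Flow-cytometry summaries

Annexin-V/PI events are a three-component bivariate log-normal mixture
(surviving both-low at log10 1.8; early apoptotic annexin-high 3.0 / PI-low;
late apoptotic both-high; common log10 sd 0.25). Gating thresholds are
explicit inputs (default 10^2.4 on both channels, midway between the
component means); there is no auto-gating. Events exactly on a cut count
as positive. With the default separation (≈4.8 sd between components)
misclassification across a cut is below one percentage point per
boundary.

DNA content is a mixture of Gaussian G1 (mean c, default 50 channel units,
CV 5%), Gaussian G2/M constrained to mean 2c (CV 4%), and S phase modeled
as uniform on (c, 2c) convolved with the G1 width — a Dean–Jett–Fox-style
simplification. The fit is a generalized EM: the E-step and the weight
update are exact; (c, s1, s2) are updated from closed-form Gaussian
candidates accepted through a backtracking line search on the observed
log-likelihood (the S component's density depends on c and s1, so the
naive closed form is not guaranteed monotone — the safeguard restores the
EM monotonicity guarantee at negligible cost). Initialization: c at the
histogram mode (128 bins), 6% CV widths, equal weights; cap 500
iterations, tolerance 10⁻⁸ on the log-likelihood, with an error carrying
the last iterate on non-convergence. Reported fractions are the fitted
mixture weights (equal to mean posterior masses). Doublets, debris,
compensation and binary FCS parsing are out of scope; events are CSV.

## Problem sizes used in validation

Recovery studies run at the experimental design's own scale: 6-dose
plates, 3 replicates, 0.02 OD noise, 50 seeds per ψ ∈ {0.1, 0.3, 1.0}
with published-fit-like agents (Dm 8.39 µM/m 0.64 and Dm 2.09 µM/m 0.75,
ratio 0.1), using the refined estimator; cytometry recovery uses 100
seeds at 20,000 events per draw. Median recovered CI sits within ±0.05 of
ψ and median relative Dm error under 5%; quadrant and phase fractions
recover within 2 percentage points.

## Command-line interface

`ctsynergy simulate|synergy|check-fixture|cytometry` is a thin layer over
the library: YAML-configurable simulation, plate-CSV synergy analysis with
plots (median-effect plot; fa–CI curve over fa ∈ [0.05, 0.95]), the
fixture consistency report, and flow-event summaries. Every command logs
its seed and a SHA-256 hash of its effective configuration to stderr.
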
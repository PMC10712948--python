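# Methods

## Cell model

The biophysical substrate is the O'Hara–Rudy (2011) dynamic model of the
human endocardial ventricular myocyte (41 states), with six maximal
conductances/permeabilities rescaled once at construction: GKs ×8.09,
GKr ×1.17, PCa ×3.57, PNaCa ×3.05, PNaK ×1.91, GNaL ×1.7. This baseline
rescaling biases the model toward long-QT-like dynamics so that early
afterdepolarizations (EADs) are reachable inside the studied parameter
domain. On top of it, each virtual cell multiplies PCa (ICaL), GKr, GNaL
and GKs by dimensionless factors g; the analysis space is X = ln g, with
the study domain |X| ≤ 3 per channel (multipliers 0.05–20).

Pacing: 1 Hz, stimulus current −70 µA/µF for 0.5 ms. The source
description of the stimulus is ambiguous about units ("−70 mV"); the ORd
formulation has no voltage-clamp stimulus, so it is implemented as a
current of that amplitude, configurable in `PacingProtocol`. Cells are
equilibrated for 1000 beats (default; configurable) and the final four
beats are recorded at 1 ms resolution.

Two integrators share one derivative kernel (numba-compiled):

* **lsoda** — adaptive stiff integration (scipy), AbsTol 1e-3 / RelTol
  1e-6 by default, integrating each beat in a stimulus-on/stimulus-off
  pair so the 0.5 ms pulse is never stepped over.
* **rush-larsen** (default) — fixed-step hybrid: exponential (Rush–Larsen)
  updates for the 31 gating-type states, forward Euler for voltage,
  concentrations and CaMK; step 0.005 ms for the first 20 ms of each beat
  (stimulus + upstroke), 0.02 ms thereafter. Roughly 45 ms of CPU per
  beat; bitwise deterministic.

The two solvers agree at baseline to ~0.01 mV mean absolute voltage
difference, with discrepancies confined to the single sample spanning the
upstroke. An external reference implementation is not bundled, so this
dual-route agreement plus morphology checks (resting potential −88.3 mV,
peak ~+45 mV, APD90 ≈ 264 ms, stable periodicity after equilibration)
stand as the model's verification. Non-finite states (extreme parameter
corners) raise `SimulationError` carrying the offending multipliers;
population drivers can drop such cells.

## EAD detection and labelling

Peaks are local maxima with ≥1 mV prominence (a numerical-ripple floor,
not a study-prescribed value; configurable). A beat is flagged when a
non-primary peak rises *above* −50 mV (strict) and lies ≥100 ms
(inclusive) from **every** other detected peak in the same beat — the
within-beat reading of the separation rule, which correctly rejects
spike-and-dome morphologies whose dome peak rides within ~30 ms of the
upstroke. Beats are half-open windows delimited by stimulus onsets. Four
successive beats are analysed to accommodate alternans; the cell is
*ectopic* if any beat is flagged, else *benign*.

## Populations

Axis identification samples X i.i.d. uniform on [−3, 3]⁴; the natural
population samples X i.i.d. normal with μ = −0.112, σ = 0.472 per channel,
i.e. log-normal multipliers with arithmetic mean 1 and SD 0.5 via
σ² = ln(1 + sd²/mean²), μ = ln(mean) − σ²/2. (Two printed signs for μ
circulate; only the negative one satisfies the moment equations, and it is
used throughout.) Channels are independent; only the four analysis
channels vary.

## Axis fit

Unpenalized maximum-likelihood logistic regression (statsmodels Logit,
Newton, gradient tolerance 1e-8) of the ectopic label on the four
coordinates with intercept; standard errors from the MLE information
matrix; the model-vs-null likelihood-ratio statistic is reported.
Complete separation or non-convergence raises `AxisFitError` — this
matters for surrogate-generated populations, whose labels must be drawn
from a soft (Bernoulli) boundary to keep the fit well-posed. The published
coefficients β₀ = −6.416, B = (2.509, −2.471, 0.847, −1.724) ship as the
default `AxisModel`, so scoring never requires simulation.

The logistic convention is p = 1/(1 + e^(−x)) everywhere. (One printed
form of the a-priori-probability equation has the opposite sign in the
exponent; it is inconsistent with the regression equation and with every
published population fraction, all of which the standard form reproduces.)

## Drug response

δ = IC50^h/(IC50^h + C^h) with h = 1 throughout (no evidence of
cooperative binding; overriding h is possible but non-canonical).
Concentrations are normalised to EFTPC, so dose tables may carry absolute
nM or Cmax multiples. Channels without an IC50 are unblocked (δ = 1,
α = 0) and contribute exactly zero to every score. The dose-table CSV
schema carries seven channels (Kr, Na, NaL, CaL, Ks, K1, to); Na, K1 and
to are parsed and preserved on round trip but excluded from the 4-channel
metric. Measured G*Scale values in a table take precedence over Hill
reconstruction at matching doses.

A note on dose dependence: with h = 1 the log-action ratio of a potent to
a weak channel decreases monotonically from IC50_weak/IC50_potent toward 1
as dose grows — the action direction rotates, which is why multi-channel
paths in action space are curvilinear and risk scores dose-dependent.

## Risk metric and susceptibility

risk = A·B/‖B‖ (natural-log units along the axis; linear in A). The
susceptible fraction shifts the natural population by r along the axis and
integrates it against the a-priori probability of ectopy:

P(r) = ∫ φ(s; 0, σ) · logistic(x_O + ‖B‖(s + r)) ds,  x_O = β₀ + μ Σβᵢ.

The 4-D → 1-D reduction is exact because the logit is linear (orthogonal
components integrate out); the equivalence is tested directly against 4-D
Monte-Carlo. Quadrature: Gauss–Hermite, 128 nodes, confirmed against 256
nodes at 1e-6 relative tolerance with an adaptive (scipy `quad`) fallback
on disagreement; σ = 0 degenerates to a single logistic evaluation.
Reproduced published fractions agree to well within 2%; the residuals
(e.g. 0.923% vs the printed 0.93% baseline) trace to the 3-dp rounding of
the published coefficients and 2-dp rounding of displacements, not to the
integral.

Classification: unsafe iff score > θ (strict; default θ = 0.195, the
optimised 25×-dose threshold). Clinical classes lump 1–2 unsafe vs 3–4
safe. ROC sweeps thresholds over midpoints of consecutive sorted scores
with ±∞ sentinels; AUROC by trapezoid; threshold optimisation breaks
accuracy ties toward the larger θ (fewer positive calls).

## Surrogate model and fixtures

The surrogate generator exists so the full pipeline (simulate → detect →
fit → score) is testable in seconds. It emits a stereotyped AP (rest
−88 mV, peak +34 mV, APD ≈ 300 ms) and inserts a Gaussian EAD bump
(+12 mV at 240 ms, satisfying the detector's definition) according to a
configurable linear rule in X — by default the published axis itself, with
an optional Bernoulli temperature so refits are well-posed and recover the
configured coefficients. What surrogate-based tests demonstrate is the
correctness of the *pipeline machinery* (detector, sampler, fit, scoring),
not the biophysics; biophysical claims rest on the direct ORd tests and
the replication script.

Synthetic drug fixtures are labelled synthetic (`SYN-*` compounds) and are
built so hERG-dominant records score positive and CaL-dominant negative at
every dose, with scores known in closed form.

## Problem sizes

Default test-suite sizes: logistic recovery on 50,000 points; population
statistics on 10⁵–10⁶ draws; Monte-Carlo oracles at 10⁶ (1-D) and 4×10⁵
(4-D) draws; surrogate populations of 3,000–8,000 cells; direct ORd runs
of a handful of cells at 20–150-beat equilibration. Axis regeneration at
full fidelity (100,000 cells × 1000 beats) is a sharded batch job
(`scripts/replicate_axis.py`); reduced runs of a few hundred to a few
thousand cells reproduce the coefficient signs and the near-unity
|β_CaL/β_Kr| ratio with attenuated magnitudes.

## Known limitations

* Endocardial cell type and 1 Hz pacing only; other rates/cell types are
  configurable but unvalidated, and would yield a different axis.
* No drug-binding kinetics (state-dependent block) and no Hill
  cooperativity; potency enters only through equilibrium IC50s.
* The natural-population spread (SD 0.5) is an assumption, not a fitted
  quantity; susceptibility percentages inherit it.
* Channel independence is assumed in both sampling regimes; correlated
  co-expression would change population fractions.
* Points near the decision boundary (|a-priori p − 0.5| small) can flip
  label between implementations of the same cell model; only the
  boundary's *location and orientation* in aggregate is meaningful.
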
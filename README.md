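# arraxis

Torsadogenic drug risk from multi-channel ion-block profiles, via the
**axis of arrhythmia** in cardiomyocyte log-conductance space.

Many drugs trigger Torsades de Pointes by disturbing the balance of four
ventricular ion currents — I<sub>CaL</sub>, I<sub>Kr</sub>, I<sub>NaL</sub>,
I<sub>Ks</sub>. Conventional in-silico safety assays simulate each candidate
drug in populations of virtual cardiomyocytes, which is computationally
heavy and demands simulation expertise. This package implements the inverse
approach: the expensive simulations are done **once, drug-free**, to map
where in conductance space myocytes become ectopic (exhibit early
afterdepolarizations, EADs); any drug can then be scored with pen-and-paper
arithmetic from its patch-clamp block profile alone.

## The method

Phenotypic diversity and drug block act on the same quantities — channel
conductances — multiplicatively, so both are *additive* in logarithmic
coordinates X = ln G. A logistic regression on a population of simulated
myocytes (an O'Hara–Rudy endocardial variant rescaled toward long-QT
behaviour, conductances sampled log-uniformly over e<sup>±3</sup>) gives the
log-odds of ectopy,

    ln(p/(1−p)) = β₀ + β_CaL·X_CaL + β_Kr·X_Kr + β_NaL·X_NaL + β_Ks·X_Ks.

The slope vector **B** = (β_CaL, β_Kr, β_NaL, β_Ks) — packaged as
(2.509, −2.471, 0.847, −1.724) with β₀ = −6.416, ‖**B**‖ = 4.01 — is the
*axis of arrhythmia*: the steepest direction from benign to ectopic
electrophysiology. A drug with fractional conductances δ (from the Hill
equation, δ = IC50/(IC50 + C), h = 1) has action vector
**A** = ln δ per channel, and its risk is the projection

    risk = A · B / ‖B‖.

Positive scores push toward ectopy (IKr block), negative away (ICaL block).
Assuming natural conductance variation is log-normal (multiplier mean 1,
SD 0.5, hence μ = −0.112, σ = 0.472 in log space), the fraction of the
population rendered susceptible by a drug at displacement r is the
logistic-normal integral

    P(r) = ∫ φ(s; 0, σ) · logistic(x_O + ‖B‖(s + r)) ds,

evaluated by Gauss–Hermite quadrature (x_O is the logit at the population
centre). Scoring a drug therefore needs **no simulation at all**; the
package also contains everything required to regenerate the axis from
scratch (cell model, EAD detector, population sampler, logistic fit).

## Worked example

Ajmaline (known torsadogenic risk) and Linezolid (no clinical evidence of
risk) both block IKr, but with nearly opposite balance against ICaL. At 25×
therapeutic dose their fractional conductances are δ = (0.654, 0.0986) and
(0.067, 0.437) for (CaL, Kr):

```sh
$ arraxis score-drugs --drugs two_drugs.csv --dose 25
DrugID,Compound,Class,dose,risk_score,susceptible_pct,predicted_label
1,Ajmaline,1,25.0,1.1614906768912983,25.793222460322124,unsafe
2,Linezolid,4,25.0,-1.180774035551019,0.009427461233573162,safe
```

Ajmaline scores +1.16 — it shifts the population 1.16 log-units toward
ectopy, making ~26% of the natural population susceptible — while Linezolid
scores −1.18, *reducing* susceptibility to 0.009% against a drug-free
baseline of 0.92%:

```sh
$ arraxis susceptibility --score 0 --score 1.44
0,0.923329
1.44,41.5324
```

(the second line is the 10× Ibutilide displacement: 41.5% susceptible).

In Python:

```python
from arraxis import PUBLISHED_AXIS, risk_score, susceptible_fraction
score = risk_score([-0.425, -2.32, 0.0, 0.0], PUBLISHED_AXIS)  # 1.16
pct = 100 * susceptible_fraction(score, PUBLISHED_AXIS)        # 25.9
```

Other entry points: `arraxis simulate-population` (surrogate or
biophysical), `fit-axis`, `classify`, `evaluate`, `make-fixtures`; and
`scripts/replicate_axis.py` to regenerate the axis from O'Hara–Rudy
simulations (the production 100,000-cell run is a sharded batch job).

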
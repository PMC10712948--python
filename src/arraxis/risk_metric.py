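"""Risk scoring along the axis of arrhythmia and population susceptibility.

The arrhythmogenic component of a drug is the projection of its action
vector A onto the axis basis vector B:

    risk = (A . B) / ||B||          (natural-log units along the axis)

Positive scores push the electrophysiology toward ectopy, negative away.

Susceptibility of the natural population follows from shifting the
log-normal population density along the axis by the risk score r and
integrating it against the a-priori probability of ectopy,

    P(r) = int phi(s; 0, sigma) * logistic(x_O + ||B|| (s + r)) ds,

where x_O = beta0 + mu * sum(beta_i) is the logit at the drug-free
population centre O = (mu, mu, mu, mu). The reduction from four dimensions
to one is exact because the logit is linear: components of the population
density orthogonal to B integrate out. The integral is evaluated with
Gauss-Hermite quadrature (the integrand is a bounded logistic times a
Gaussian), with an adaptive fallback when two node counts disagree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import integrate

from .axis_model import AxisModel
from .drug_response import ChannelBlock, action_vector
from .population import NATURAL_MU, NATURAL_SIGMA, PopulationSpec


def _logistic(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def risk_score(A: np.ndarray | ChannelBlock | Sequence[float], axis: AxisModel) -> float:
    """Projection of the drug action onto the axis: (A.B)/||B||."""
    if isinstance(A, ChannelBlock):
        A = action_vector(A)
    A = np.asarray(A, dtype=float)
    return float(A @ axis.B / axis.norm)


def population_centre_logit(
    axis: AxisModel, mu: float = NATURAL_MU
) -> float:
    """Logit of ectopy at the natural-population centre O = (mu, mu, mu, mu)."""
    return float(axis.beta0 + mu * axis.B.sum())


def susceptible_fraction(
    score: float,
    axis: AxisModel,
    mu: float = NATURAL_MU,
    sigma: float = NATURAL_SIGMA,
    nodes: int = 128,
    rtol: float = 1e-6,
) -> float:
    """Fraction of the natural population ectopic after a shift of ``score``.

    Deterministic Gauss-Hermite quadrature of the logistic-normal integral;
    if doubling the node count changes the result by more than ``rtol``
    (relative), an adaptive quadrature takes over.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    x0 = population_centre_logit(axis, mu)
    norm = axis.norm
    if sigma == 0.0:
        return float(_logistic(np.array(x0 + norm * score)))

    def gh(n: int) -> float:
        t, w = np.polynomial.hermite.hermgauss(n)
        s = np.sqrt(2.0) * sigma * t
        return float(w @ _logistic(x0 + norm * (s + score)) / np.sqrt(np.pi))

    p1, p2 = gh(nodes), gh(2 * nodes)
    if abs(p2 - p1) <= rtol * max(abs(p2), 1e-300):
        return p2
    val, err = integrate.quad(
        lambda s: np.exp(-0.5 * (s / sigma) ** 2)
        / (sigma * np.sqrt(2 * np.pi))
        * _logistic(np.array(x0 + norm * (s + score))),
        -np.inf,
        np.inf,
        epsrel=rtol,
        limit=200,
    )
    if not np.isfinite(val):
        raise ArithmeticError("susceptibility quadrature did not converge")
    return float(val)


@dataclass(frozen=True)
class RiskResult:
    """Risk assessment for one drug at one dose."""

    drug_id: int
    compound: str
    clinical_class: int | None
    dose: float
    score: float
    susceptible: float  # fraction in [0, 1]

    def predicted_unsafe(self, theta: float) -> bool:
        return self.score > theta


def assess(
    drug,
    axis: AxisModel,
    dose: float,
    mu: float = NATURAL_MU,
    sigma: float = NATURAL_SIGMA,
) -> RiskResult:
    """Score one :class:`~arraxis.drug_response.DrugRecord` at a dose."""
    A = drug.action_at(dose)
    r = risk_score(A, axis)
    return RiskResult(
        drug_id=drug.drug_id,
        compound=drug.compound,
        clinical_class=drug.clinical_class,
        dose=dose,
        score=r,
        susceptible=susceptible_fraction(r, axis, mu=mu, sigma=sigma),
    )


def classify_drug(result: RiskResult | float, theta: float) -> str:
    """'unsafe' iff the score strictly exceeds the threshold, else 'safe'."""
    score = result.score if isinstance(result, RiskResult) else float(result)
    return "unsafe" if score > theta else "safe"


def lump_classes(classes: Sequence[int]) -> np.ndarray:
    """Clinical classes 1-2 lump to unsafe (True); 3-4 to safe (False)."""
    c = np.asarray(classes, dtype=int)
    if np.any((c < 1) | (c > 4)):
        raise ValueError("clinical classes must be in 1..4")
    return c <= 2


@dataclass(frozen=True)
class EvaluationReport:
    """Classification performance of risk scores against clinical labels."""

    theta: float
    accuracy: float
    tpr: float
    fpr: float
    auroc: float
    roc: tuple = field(repr=False, default=())  # ((fpr, tpr, theta), ...)

    def to_dict(self) -> dict:
        return {
            "theta": self.theta,
            "accuracy": self.accuracy,
            "tpr": self.tpr,
            "fpr": self.fpr,
            "auroc": self.auroc,
            "roc": [list(p) for p in self.roc],
        }


def _threshold_grid(scores: np.ndarray) -> np.ndarray:
    s = np.unique(scores)
    mids = (s[:-1] + s[1:]) / 2.0 if len(s) > 1 else np.empty(0)
    return np.concatenate(([-np.inf], mids, [np.inf]))


def _rates(scores: np.ndarray, unsafe: np.ndarray, theta: float):
    pred = scores > theta
    tp = np.sum(pred & unsafe)
    fp = np.sum(pred & ~unsafe)
    tpr = tp / unsafe.sum()
    fpr = fp / (~unsafe).sum()
    acc = np.mean(pred == unsafe)
    return float(acc), float(tpr), float(fpr)


def optimize_threshold(scores: Sequence[float], classes: Sequence[int]) -> float:
    """Threshold maximising accuracy; ties resolve toward the larger theta
    (fewer positive calls)."""
    scores = np.asarray(scores, dtype=float)
    unsafe = lump_classes(classes)
    best_theta, best_acc = np.inf, -1.0
    for theta in _threshold_grid(scores):
        acc, _, _ = _rates(scores, unsafe, theta)
        if acc > best_acc or (acc == best_acc and theta > best_theta):
            best_acc, best_theta = acc, theta
    return float(best_theta)


def evaluate(
    scores: Sequence[float],
    classes: Sequence[int],
    theta: float | None = None,
) -> EvaluationReport:
    """ROC analysis of risk scores against lumped clinical labels.

    Sweeps the threshold over midpoints of consecutive sorted scores (with
    infinite sentinels), computes the ROC and its trapezoidal area, and
    reports accuracy/TPR/FPR at ``theta`` (optimised for accuracy when not
    given).
    """
    scores = np.asarray(scores, dtype=float)
    unsafe = lump_classes(classes)
    if unsafe.all() or not unsafe.any():
        raise ValueError("evaluation needs at least one drug of each lumped class")
    grid = _threshold_grid(scores)
    roc = []
    for t in grid:
        acc, tpr, fpr = _rates(scores, unsafe, t)
        roc.append((fpr, tpr, float(t)))
    roc.sort(key=lambda p: (p[0], p[1]))
    fprs = np.array([p[0] for p in roc])
    tprs = np.array([p[1] for p in roc])
    auroc = float(np.trapezoid(tprs, fprs))
    if theta is None:
        theta = optimize_threshold(scores, classes)
    acc, tpr, fpr = _rates(scores, unsafe, theta)
    return EvaluationReport(
        theta=float(theta), accuracy=acc, tpr=tpr, fpr=fpr, auroc=auroc,
        roc=tuple(roc),
    )
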
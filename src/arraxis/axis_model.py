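"""The axis of arrhythmia: a logistic decision boundary in log-conductance space.

A multivariate logistic regression of the benign/ectopic label on the four
log-conductance coordinates X = (X_CaL, X_Kr, X_NaL, X_Ks) defines the
log-odds of ectopy,

    ln(p / (1 - p)) = beta0 + B . X,

where B = (beta_CaL, beta_Kr, beta_NaL, beta_Ks) is the slope vector. The
decision boundary is the hyperplane where p = 0.5; the *axis of arrhythmia*
is the line through that boundary along B — the steepest direction from
benign to ectopic electrophysiology. The slope vector and its Euclidean
norm ||B|| are the yardstick against which drug block profiles are scored.

The coefficients estimated from a 100,000-myocyte population of the
rescaled O'Hara-Rudy endocardial model ship as :data:`PUBLISHED_AXIS`, so
drugs can be scored without re-running any simulation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .population import CHANNELS, LabelledPopulation


class AxisFitError(RuntimeError):
    """Logistic fit failed (separation or non-convergence)."""


@dataclass(frozen=True)
class AxisModel:
    """Fitted logistic boundary: intercept, slopes, and the axis basis vector."""

    beta0: float
    beta: tuple[float, float, float, float]  # CaL, Kr, NaL, Ks
    se_beta0: float | None = None
    se_beta: tuple[float, float, float, float] | None = None
    llr_stat: float | None = None
    provenance: str = "unspecified"

    def __post_init__(self) -> None:
        if len(self.beta) != 4:
            raise ValueError("beta must have 4 components (CaL, Kr, NaL, Ks)")

    @property
    def B(self) -> np.ndarray:
        """Basis vector of the axis of arrhythmia."""
        return np.asarray(self.beta, dtype=float)

    @property
    def norm(self) -> float:
        """Euclidean length ||B|| of the basis vector."""
        n = float(np.linalg.norm(self.B))
        if n == 0.0:
            raise ValueError("degenerate axis: ||B|| = 0")
        return n

    def logit(self, X: Sequence[float] | np.ndarray) -> np.ndarray | float:
        """Log-odds beta0 + B.X; X has the channel order CaL, Kr, NaL, Ks."""
        X = np.asarray(X, dtype=float)
        return self.beta0 + X @ self.B

    def predict_probability(self, X: Sequence[float] | np.ndarray) -> np.ndarray | float:
        """A-priori probability of ectopy, p = 1 / (1 + exp(-(beta0 + B.X)))."""
        x = np.asarray(self.logit(X), dtype=float)
        out = np.empty_like(x)
        pos = x >= 0
        out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
        ex = np.exp(x[~pos])
        out[~pos] = ex / (1.0 + ex)
        return float(out) if out.ndim == 0 else out

    def to_dict(self) -> dict:
        return {
            "beta0": self.beta0,
            "beta": list(self.beta),
            "se": None if self.se_beta is None else list(self.se_beta),
            "se_beta0": self.se_beta0,
            "llr_stat": self.llr_stat,
            "norm": self.norm,
            "channels": list(CHANNELS),
            "provenance": self.provenance,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_dict(cls, d: dict) -> "AxisModel":
        return cls(
            beta0=float(d["beta0"]),
            beta=tuple(float(b) for b in d["beta"]),
            se_beta0=d.get("se_beta0"),
            se_beta=None if d.get("se") is None else tuple(d["se"]),
            llr_stat=d.get("llr_stat"),
            provenance=d.get("provenance", "unspecified"),
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "AxisModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


#: Coefficients estimated from the 100,000-cell O'Hara-Rudy population.
PUBLISHED_AXIS = AxisModel(
    beta0=-6.416,
    beta=(2.509, -2.471, 0.847, -1.724),
    se_beta0=0.059,
    se_beta=(0.024, 0.024, 0.012, 0.018),
    provenance="published",
)


def axis_norm(axis: AxisModel) -> float:
    """Euclidean norm ||B|| of the axis basis vector."""
    return axis.norm


def fit_logistic(population: LabelledPopulation, gtol: float = 1e-8) -> AxisModel:
    """Maximum-likelihood logistic fit of the ectopic label on log-conductances.

    Unpenalized Newton-type MLE with intercept. Raises :class:`AxisFitError`
    on complete separation or non-convergence, and ``ValueError`` when only
    one class is present.
    """
    y = population.labels.astype(float)
    if y.min() == y.max():
        raise ValueError("population contains a single class; cannot fit a boundary")
    Xd = sm.add_constant(population.X, prepend=True)
    model = sm.Logit(y, Xd)
    try:
        res = model.fit(method="newton", maxiter=200, tol=gtol, disp=False)
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        raise AxisFitError(f"logistic fit failed: {exc}") from exc
    if not res.mle_retvals.get("converged", False):
        raise AxisFitError("logistic fit did not converge")
    params = np.asarray(res.params, dtype=float)
    if not np.all(np.isfinite(params)) or np.abs(params).max() > 1e3:
        raise AxisFitError("logistic fit diverged (likely complete separation)")
    se = np.asarray(res.bse, dtype=float)
    return AxisModel(
        beta0=float(params[0]),
        beta=tuple(params[1:5]),
        se_beta0=float(se[0]),
        se_beta=tuple(se[1:5]),
        llr_stat=float(res.llr),
        provenance=str(population.provenance.get("id", "fitted")),
    )


def predict_probability(X, axis: AxisModel):
    """Module-level convenience alias for :meth:`AxisModel.predict_probability`."""
    return axis.predict_probability(X)
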
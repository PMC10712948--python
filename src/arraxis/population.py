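"""Cohorts of conductance multipliers for virtual-myocyte populations.

Two sampling regimes are used. Axis identification samples the four
log-conductance coordinates uniformly over a symmetric box (by default
``[-3, 3]`` in natural-log units, i.e. multipliers between roughly 0.05 and
20) so that the ectopic region is well covered. The *natural* population,
used for susceptibility estimates, draws each multiplier from a log-normal
distribution whose parameters are moment-matched to an arithmetic mean of 1
and standard deviation of 0.5 across cells.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

CHANNELS = ("CaL", "Kr", "NaL", "Ks")
LOG_COLUMNS = tuple(f"lnG{c}" for c in CHANNELS)

#: Log-normal parameters matching multiplier mean 1 and SD 0.5.
NATURAL_MU = -0.112
NATURAL_SIGMA = 0.472

#: Half-width of the axis-identification domain in natural-log units.
DOMAIN_HALF_WIDTH = 3.0


def moment_match(mean: float, sd: float) -> tuple[float, float]:
    """Log-normal (mu, sigma) giving the requested arithmetic mean and SD.

    Solves ``sigma^2 = ln(1 + sd^2/mean^2)`` and
    ``mu = ln(mean) - sigma^2/2``; with mean 1 and SD 0.5 this yields
    ``(-0.112, 0.472)`` to three decimals.
    """
    if mean <= 0 or sd < 0:
        raise ValueError(f"mean must be > 0 and sd >= 0, got mean={mean}, sd={sd}")
    sigma2 = math.log1p((sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


@dataclass(frozen=True)
class PopulationSpec:
    """Configuration of a cohort of conductance multipliers.

    ``mode='axis-domain'`` samples ln-multipliers uniformly on
    ``[-half_width, half_width]`` per channel; ``mode='natural'`` samples
    them normally with mean ``mu`` and SD ``sigma`` (log-normal multipliers).
    Channels are independent in both modes.
    """

    n: int
    mode: Literal["axis-domain", "natural"] = "axis-domain"
    mu: float = NATURAL_MU
    sigma: float = NATURAL_SIGMA
    half_width: float = DOMAIN_HALF_WIDTH
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"population size must be >= 1, got {self.n}")
        if self.mode not in ("axis-domain", "natural"):
            raise ValueError(f"unknown sampling mode {self.mode!r}")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.half_width <= 0:
            raise ValueError("half_width must be > 0")

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "mode": self.mode,
            "mu": self.mu,
            "sigma": self.sigma,
            "half_width": self.half_width,
            "seed": self.seed,
        }


def sample_axis_domain(spec: PopulationSpec) -> np.ndarray:
    """Draw an (n, 4) matrix of log-multipliers uniform on the study domain."""
    if spec.mode != "axis-domain":
        raise ValueError("spec.mode must be 'axis-domain'")
    rng = np.random.default_rng(spec.seed)
    return rng.uniform(-spec.half_width, spec.half_width, size=(spec.n, 4))


def sample_natural(spec: PopulationSpec) -> np.ndarray:
    """Draw an (n, 4) matrix of log-multipliers from the natural population."""
    if spec.mode != "natural":
        raise ValueError("spec.mode must be 'natural'")
    rng = np.random.default_rng(spec.seed)
    return rng.normal(spec.mu, spec.sigma, size=(spec.n, 4))


def sample(spec: PopulationSpec) -> np.ndarray:
    if spec.mode == "axis-domain":
        return sample_axis_domain(spec)
    return sample_natural(spec)


@dataclass
class LabelledPopulation:
    """Log-multiplier matrix with benign/ectopic labels and provenance."""

    X: np.ndarray  # (n, 4) log-multipliers, columns CaL, Kr, NaL, Ks
    labels: np.ndarray  # (n,) bool, True = ectopic
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.labels = np.asarray(self.labels, dtype=bool)
        if self.X.ndim != 2 or self.X.shape[1] != 4:
            raise ValueError(f"X must be (n, 4), got {self.X.shape}")
        if self.labels.shape != (self.X.shape[0],):
            raise ValueError("labels length must match X rows")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def n_ectopic(self) -> int:
        return int(self.labels.sum())

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=list(LOG_COLUMNS))
        df.insert(0, "cell_id", np.arange(self.n))
        df["label"] = np.where(self.labels, "ectopic", "benign")
        return df

    def to_csv(self, path: str | Path) -> None:
        """Write the population as CSV plus a JSON sidecar with provenance."""
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(json.dumps(self.provenance, indent=2, default=str))

    @classmethod
    def from_csv(cls, path: str | Path) -> "LabelledPopulation":
        path = Path(path)
        df = pd.read_csv(path)
        missing = [c for c in LOG_COLUMNS + ("label",) if c not in df.columns]
        if missing:
            raise ValueError(f"population file {path} lacks columns {missing}")
        provenance: dict = {}
        sidecar = path.with_suffix(path.suffix + ".json")
        if sidecar.exists():
            provenance = json.loads(sidecar.read_text())
        return cls(
            X=df[list(LOG_COLUMNS)].to_numpy(),
            labels=(df["label"].astype(str) == "ectopic").to_numpy(),
            provenance=provenance,
        )
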
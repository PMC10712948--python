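"""End-to-end orchestration: populate, fit, score, evaluate.

Stages run in dependency order and every artifact carries provenance
(config echo, seed, package version). Re-running with an identical config
reproduces identical scoring outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .axis_model import PUBLISHED_AXIS, AxisModel, fit_logistic
from .cell_model import PacingProtocol, SolverSettings, SurrogateSpec
from .drug_response import read_drug_table
from .fixtures import FixtureSpec, make_drug_fixtures, simulate_population
from .population import NATURAL_MU, NATURAL_SIGMA, PopulationSpec
from .risk_metric import assess, classify_drug, evaluate


class PipelineError(RuntimeError):
    """A stage is missing an upstream artifact."""


@dataclass
class PipelineConfig:
    """What to run and where artifacts live."""

    out_dir: Path = Path(".")
    drugs_csv: Path | None = None
    axis_json: Path | None = None
    population_csv: Path | None = None
    population: PopulationSpec | None = None
    model: str = "surrogate"
    doses: tuple[float, ...] = (1.0, 5.0, 10.0, 25.0, 30.0, 32.0)
    theta: float = 0.195
    mu: float = NATURAL_MU
    sigma: float = NATURAL_SIGMA
    seed: int | None = None
    stages: tuple[str, ...] = ("score", "evaluate")

    def digest(self) -> str:
        blob = json.dumps(
            {k: str(v) for k, v in vars(self).items()}, sort_keys=True
        ).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _provenance(config: PipelineConfig) -> dict:
    return {
        "package_version": __version__,
        "config_hash": config.digest(),
        "seed": config.seed,
    }


def score_drug_table(
    records,
    axis: AxisModel,
    doses,
    theta: float,
    mu: float = NATURAL_MU,
    sigma: float = NATURAL_SIGMA,
) -> pd.DataFrame:
    """Score every record at every dose; one row per (drug, dose)."""
    rows = []
    for rec in records:
        for dose in doses:
            res = assess(rec, axis, dose, mu=mu, sigma=sigma)
            rows.append(
                {
                    "DrugID": res.drug_id,
                    "Compound": res.compound,
                    "Class": res.clinical_class,
                    "dose": dose,
                    "risk_score": res.score,
                    "susceptible_pct": 100.0 * res.susceptible,
                    "predicted_label": classify_drug(res, theta),
                }
            )
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the requested stages; returns a map of artifact paths."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    axis = PUBLISHED_AXIS
    if "fit-axis" in config.stages:
        if config.population is None and config.population_csv is None:
            raise PipelineError("fit-axis stage needs a population spec or CSV")
        if config.population_csv is not None:
            from .population import LabelledPopulation

            pop = LabelledPopulation.from_csv(config.population_csv)
        else:
            pop = simulate_population(config.population, model=config.model)
        axis = fit_logistic(pop)
        path = out_dir / "axis.json"
        axis.to_json(path)
        artifacts["axis"] = path
    elif config.axis_json is not None:
        axis = AxisModel.from_json(config.axis_json)

    if "score" in config.stages or "evaluate" in config.stages:
        if config.drugs_csv is None:
            raise PipelineError("score stage needs a drug table (drugs_csv)")
        records = read_drug_table(config.drugs_csv)
        scored = score_drug_table(
            records, axis, config.doses, config.theta, config.mu, config.sigma
        )
        path = out_dir / "scores.csv"
        scored.to_csv(path, index=False)
        artifacts["scores"] = path

        if "evaluate" in config.stages:
            reports = {}
            for dose in config.doses:
                sub = scored[scored["dose"] == dose]
                rep = evaluate(sub["risk_score"], sub["Class"])
                reports[str(dose)] = rep.to_dict()
            path = out_dir / "evaluation.json"
            path.write_text(
                json.dumps({"provenance": _provenance(config), **reports}, indent=2)
            )
            artifacts["evaluation"] = path

    prov = out_dir / "provenance.json"
    prov.write_text(json.dumps(_provenance(config), indent=2))
    artifacts["provenance"] = prov
    return artifacts
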
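"""Drug block profiles: Hill reconstruction, log-actions, and the dose-table CSV.

A drug attenuates each channel conductance multiplicatively,
``G_drug = delta * G``, with fractional conductance ``delta`` in (0, 1].
The saturating dose-response is the Hill equation

    delta = IC50^h / (IC50^h + C^h),

with the Hill coefficient fixed at h = 1 by default (no evidence of
cooperative binding in the curated potency data). In log-conductance space
block becomes additive: the *action vector* A = (ln dCaL, ln dKr, ln dNaL,
ln dKs) is the displacement a drug imposes on every myocyte, and is what
gets projected onto the axis of arrhythmia. Channels with no measured IC50
are treated as unblocked (delta = 1, alpha = 0).

Concentrations are normalised internally to multiples of the effective free
therapeutic plasma concentration (EFTPC), so 1x means the therapeutic dose.

Dose tables are read and written in a wide CSV schema, one row per
(drug, dose), with fractional-conductance columns ``G<ch>Scale`` and their
logs ``LogG<ch>Scale`` for the seven channels Kr, Na, NaL, CaL, Ks, K1, to.
The Na, K1, and to columns are parsed and preserved on round trip but are
not part of the 4-channel metric.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Channels of the 4-channel risk metric, in axis order.
CHANNELS = ("CaL", "Kr", "NaL", "Ks")
#: Channels carried in the dataset schema but excluded from the metric.
EXTRA_CHANNELS = ("Na", "K1", "to")
#: Column order of the schema for the seven G*Scale columns.
SCALE_CHANNELS = ("Kr", "Na", "NaL", "CaL", "Ks", "K1", "to")

TABLE_COLUMNS = (
    ["DrugID", "Compound", "Class", "EFTPC", "Cmax", "Conc"]
    + [f"G{c}Scale" for c in SCALE_CHANNELS]
    + [f"LogG{c}Scale" for c in SCALE_CHANNELS]
    + ["Score"]
)

RAW_COLUMNS = ("Compound", "Class", "EFTPC_nM")


class DrugTableError(ValueError):
    """Malformed drug table (missing columns, bad cells)."""


def hill_block(ic50: float, conc: float, h: float = 1.0) -> float:
    """Fractional conductance delta = IC50^h / (IC50^h + C^h).

    ``ic50`` and ``conc`` must share units (the package uses multiples of
    EFTPC internally, but any common unit works since the ratio is all that
    matters at h = 1).
    """
    if ic50 <= 0:
        raise ValueError(f"IC50 must be > 0, got {ic50}")
    if conc < 0:
        raise ValueError(f"concentration must be >= 0, got {conc}")
    if h <= 0:
        raise ValueError(f"Hill coefficient must be > 0, got {h}")
    if conc == 0.0:
        return 1.0
    # work in logs to stay stable for extreme potency ratios
    r = math.exp(h * (math.log(conc) - math.log(ic50)))
    return 1.0 / (1.0 + r)


@dataclass(frozen=True)
class ChannelBlock:
    """Per-channel fractional conductances at one dose (Cmax multiple)."""

    dose: float
    delta: tuple[float, float, float, float]  # CaL, Kr, NaL, Ks
    extra: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        for name, d in zip(CHANNELS, self.delta):
            if not (0.0 < d <= 1.0):
                raise ValueError(
                    f"delta_{name} = {d} outside (0, 1]; potency out of range"
                )


def action_vector(block: ChannelBlock | Sequence[float]) -> np.ndarray:
    """Log-action A = ln(delta) per channel; zero for unblocked channels."""
    delta = np.asarray(block.delta if isinstance(block, ChannelBlock) else block, float)
    if np.any(delta <= 0.0) or np.any(delta > 1.0):
        raise ValueError("delta values must lie in (0, 1]; potency out of range")
    return np.log(delta)


@dataclass
class DrugRecord:
    """One compound: potency data, clinical risk class, and optional dose rows.

    ``ic50`` maps channel name to IC50 in nM; absent channels are unblocked.
    ``blocks`` optionally holds measured fractional conductances per dose
    (rows of the dose-table schema), which take precedence over the Hill
    reconstruction when a requested dose is present.
    """

    drug_id: int
    compound: str
    clinical_class: int
    eftpc: float  # nM
    ic50: dict = field(default_factory=dict)
    hill: dict = field(default_factory=dict)  # per-channel h; default 1
    blocks: pd.DataFrame | None = None  # columns: Cmax + G<c>Scale

    def __post_init__(self) -> None:
        if self.eftpc <= 0:
            raise ValueError(f"{self.compound}: EFTPC must be > 0, got {self.eftpc}")
        if self.clinical_class not in (1, 2, 3, 4):
            raise ValueError(
                f"{self.compound}: clinical class must be 1-4, got {self.clinical_class}"
            )
        for ch, v in self.ic50.items():
            if v <= 0:
                raise ValueError(f"{self.compound}: IC50[{ch}] must be > 0, got {v}")

    def block_at(self, dose: float) -> ChannelBlock:
        """Channel block at ``dose`` (multiple of EFTPC).

        Uses a stored measured row when one matches the dose (relative
        tolerance 1e-9), otherwise evaluates the Hill equation per channel.
        """
        if self.blocks is not None and len(self.blocks):
            match = self.blocks[np.isclose(self.blocks["Cmax"], dose, rtol=1e-9)]
            if len(match):
                row = match.iloc[0]
                delta = tuple(
                    float(row.get(f"G{c}Scale", 1.0)) for c in CHANNELS
                )
                extra = {
                    c: float(row.get(f"G{c}Scale", 1.0)) for c in EXTRA_CHANNELS
                }
                return ChannelBlock(dose=dose, delta=delta, extra=extra)
        conc_nm = dose * self.eftpc
        delta = tuple(
            hill_block(self.ic50[c], conc_nm, self.hill.get(c, 1.0))
            if c in self.ic50
            else 1.0
            for c in CHANNELS
        )
        extra = {
            c: hill_block(self.ic50[c], conc_nm, self.hill.get(c, 1.0))
            if c in self.ic50
            else 1.0
            for c in EXTRA_CHANNELS
        }
        return ChannelBlock(dose=dose, delta=delta, extra=extra)

    def action_at(self, dose: float) -> np.ndarray:
        return action_vector(self.block_at(dose))


def dose_sweep(
    drug: DrugRecord, doses: Iterable[float]
) -> list[tuple[float, ChannelBlock, np.ndarray]]:
    """Evaluate the block and log-action of a drug over a list of doses.

    The path traced in action space is a straight ray through the origin
    when every blocked channel shares one IC50, and curvilinear otherwise
    (channels saturate at different rates).
    """
    out = []
    for dose in doses:
        if dose < 0:
            raise ValueError(f"dose must be >= 0, got {dose}")
        blk = drug.block_at(dose)
        out.append((dose, blk, action_vector(blk)))
    return out


# ---------------------------------------------------------------------------
# CSV schemas


def _is_table_schema(columns: Sequence[str]) -> bool:
    return {"DrugID", "Compound", "Class", "EFTPC", "Cmax"}.issubset(columns)


def _is_raw_schema(columns: Sequence[str]) -> bool:
    return set(RAW_COLUMNS).issubset(columns)


def read_drug_table(path: str | Path) -> list[DrugRecord]:
    """Read a drug table (dose-table schema or raw IC50 schema) into records.

    Unknown columns raise a warning-level message via ``DrugTableError`` only
    when mandatory columns are missing; otherwise they are preserved where
    possible. Blank IC50 or scale cells mean "channel unblocked".
    """
    path = Path(path)
    df = pd.read_csv(path)
    if _is_table_schema(df.columns):
        return _records_from_table(df, path)
    if _is_raw_schema(df.columns):
        return _records_from_raw(df, path)
    raise DrugTableError(
        f"{path}: header matches neither the dose-table schema "
        f"(DrugID, Compound, Class, EFTPC, Cmax, ...) nor the raw IC50 schema "
        f"(Compound, Class, EFTPC_nM, IC50_*)"
    )


def _records_from_table(df: pd.DataFrame, path: Path) -> list[DrugRecord]:
    records = []
    for drug_id, grp in df.groupby("DrugID", sort=True):
        first = grp.iloc[0]
        blocks = grp.copy().reset_index(drop=True)
        for c in SCALE_CHANNELS:
            col = f"G{c}Scale"
            if col in blocks.columns:
                blocks[col] = blocks[col].fillna(1.0)
                bad = blocks.index[(blocks[col] <= 0) | (blocks[col] > 1.0)]
                if len(bad):
                    raise DrugTableError(
                        f"{path}: {col} outside (0, 1] in row {int(bad[0]) + 2} "
                        f"of drug {first['Compound']}"
                    )
            else:
                blocks[col] = 1.0
        try:
            rec = DrugRecord(
                drug_id=int(drug_id),
                compound=str(first["Compound"]),
                clinical_class=int(first["Class"]),
                eftpc=float(first["EFTPC"]),
                blocks=blocks,
            )
        except (TypeError, ValueError) as exc:
            raise DrugTableError(f"{path}: invalid record for DrugID {drug_id}: {exc}")
        records.append(rec)
    return records


def _records_from_raw(df: pd.DataFrame, path: Path) -> list[DrugRecord]:
    records = []
    for i, row in df.iterrows():
        ic50 = {}
        for c in CHANNELS + EXTRA_CHANNELS:
            col = f"IC50_{c}"
            if col in df.columns and pd.notna(row[col]):
                ic50[c] = float(row[col])
        try:
            rec = DrugRecord(
                drug_id=int(row["DrugID"]) if "DrugID" in df.columns else i + 1,
                compound=str(row["Compound"]),
                clinical_class=int(row["Class"]),
                eftpc=float(row["EFTPC_nM"]),
                ic50=ic50,
            )
        except (TypeError, ValueError) as exc:
            raise DrugTableError(f"{path}: row {i + 2}: {exc}")
        records.append(rec)
    return records


def write_drug_table(
    records: Iterable[DrugRecord],
    path: str | Path,
    doses: Sequence[float] | None = None,
    scores: dict | None = None,
) -> pd.DataFrame:
    """Write records to the dose-table CSV schema; returns the DataFrame.

    Records with stored dose rows emit those rows verbatim (round-trip
    identity); records with IC50 data are expanded over ``doses``
    (default 1x-32x integer doses). ``scores`` optionally maps
    ``(drug_id, dose)`` to a risk score for the Score column.
    """
    doses = list(doses) if doses is not None else list(range(1, 33))
    rows = []
    for rec in records:
        if rec.blocks is not None and len(rec.blocks):
            for _, brow in rec.blocks.iterrows():
                rows.append(_table_row(rec, float(brow["Cmax"]), brow, scores))
        else:
            for dose in doses:
                blk = rec.block_at(dose)
                vals = {f"G{c}Scale": blk.delta[CHANNELS.index(c)] for c in CHANNELS}
                vals.update({f"G{c}Scale": blk.extra[c] for c in EXTRA_CHANNELS})
                rows.append(_table_row(rec, dose, vals, scores))
    df = pd.DataFrame(rows, columns=TABLE_COLUMNS)
    df.to_csv(path, index=False)
    return df


def _table_row(rec: DrugRecord, dose: float, vals, scores: dict | None) -> dict:
    row = {
        "DrugID": int(rec.drug_id),
        "Compound": rec.compound,
        "Class": int(rec.clinical_class),
        "EFTPC": float(rec.eftpc),
        "Cmax": float(dose),
        "Conc": float(dose * rec.eftpc),
    }
    for c in SCALE_CHANNELS:
        delta = float(vals[f"G{c}Scale"]) if f"G{c}Scale" in vals else 1.0
        row[f"G{c}Scale"] = delta
        row[f"LogG{c}Scale"] = math.log(delta)
    row["Score"] = (
        scores.get((rec.drug_id, dose), np.nan) if scores is not None else np.nan
    )
    return row
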
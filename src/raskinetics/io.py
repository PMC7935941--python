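"""File formats: curve tables (CSV) and run configuration documents.

A curve table is a flat CSV with columns exactly ``curve_id, time_s,
signal`` (times strictly increasing within each curve). Configuration
documents are JSON or YAML with the generator truth, suite choices,
noise model, fit options and turnover parameters; every pipeline run
embeds the resolved configuration in its output for provenance.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .mechanism import KineticParameters, ProgressCurve
from .synthetic import NoiseModel
from .turnover import TurnoverParameters

__all__ = [
    "CurveTableError",
    "read_curves",
    "write_curves",
    "curves_to_table",
    "RecoveryConfig",
    "load_config",
    "save_config",
]

CURVE_COLUMNS = ["curve_id", "time_s", "signal"]


class CurveTableError(ValueError):
    """A curve-table file violates the schema."""


def write_curves(table: pd.DataFrame, path) -> None:
    """Write a curve table to CSV with full float precision."""
    _validate_table(table, where=str(path))
    table.to_csv(path, index=False, float_format="%.17g")


def read_curves(path) -> pd.DataFrame:
    """Read and validate a curve-table CSV."""
    try:
        table = pd.read_csv(path, dtype={"curve_id": str})
    except Exception as exc:
        raise CurveTableError(f"{path}: cannot parse CSV: {exc}") from exc
    return _validate_table(table, where=str(path))


def _validate_table(table: pd.DataFrame, where: str = "<table>") -> pd.DataFrame:
    if list(table.columns) != CURVE_COLUMNS:
        raise CurveTableError(
            f"{where}: columns must be exactly {CURVE_COLUMNS}, "
            f"got {list(table.columns)}")
    if table.isna().any().any():
        row = int(table.isna().any(axis=1).idxmax())
        raise CurveTableError(f"{where}: missing cell at row {row}")
    for col in ("time_s", "signal"):
        coerced = pd.to_numeric(table[col], errors="coerce")
        if coerced.isna().any():
            row = int(coerced.isna().idxmax())
            raise CurveTableError(f"{where}: non-numeric {col!r} at row {row}")
        table[col] = coerced.astype(float)
    for cid, grp in table.groupby("curve_id", sort=False):
        dt = np.diff(grp["time_s"].to_numpy())
        if np.any(dt <= 0):
            bad = grp.index[1:][dt <= 0][0]
            raise CurveTableError(
                f"{where}: times not strictly increasing in curve "
                f"{cid!r} at row {int(bad)}")
    return table


def curves_to_table(curves: list[ProgressCurve],
                    ids: list[str] | None = None) -> pd.DataFrame:
    """Flatten progress curves into the curve-table schema."""
    ids = ids or [f"curve_{i:02d}" for i in range(len(curves))]
    frames = [pd.DataFrame({"curve_id": cid, "time_s": c.time,
                            "signal": c.amc})
              for cid, c in zip(ids, curves)]
    return pd.concat(frames, ignore_index=True)


@dataclass
class RecoveryConfig:
    """Configuration of a generate→fit→compare recovery study."""

    variant: str = "I"                  # protease variant label: I | N
    truth_active: dict = field(default_factory=dict)    # KineticParameters fields
    truth_inactive: dict = field(default_factory=dict)
    noise_sigma: float = 0.01
    seed: int = 0
    n_starts: int = 20
    tolerance_rel: float = 0.05         # pass/fail bound on k_2/K_S recovery
    fit_kp_from_r1_suite: bool = True
    turnover: dict = field(default_factory=dict)  # TurnoverParameters fields

    def kinetic_truth(self, form: str) -> KineticParameters:
        d = self.truth_active if form == "active" else self.truth_inactive
        return KineticParameters(**d)

    def noise_model(self, seed_offset: int = 0) -> NoiseModel:
        return NoiseModel(sigma=self.noise_sigma, seed=self.seed + seed_offset)

    def turnover_params(self) -> TurnoverParameters:
        return TurnoverParameters(**self.turnover)

    def to_dict(self) -> dict:
        return asdict(self)


_REQUIRED_TRUTH_KEYS = {"K_S", "k_2", "K_P", "k_rep"}


def load_config(path) -> RecoveryConfig:
    """Load a JSON or YAML configuration document and validate the schema."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config root must be a mapping")
    known = {f for f in RecoveryConfig.__dataclass_fields__}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    cfg = RecoveryConfig(**data)
    for name, d in (("truth_active", cfg.truth_active),
                    ("truth_inactive", cfg.truth_inactive)):
        if d and not _REQUIRED_TRUTH_KEYS.issubset(d):
            missing = _REQUIRED_TRUTH_KEYS - set(d)
            raise ValueError(f"{path}: {name} missing keys {sorted(missing)}")
    return cfg


def save_config(cfg: RecoveryConfig, path) -> None:
    path = Path(path)
    data = cfg.to_dict()
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))
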
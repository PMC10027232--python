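"""Manual-vs-system agreement statistics.

For paired measurements (v_l manual, v'_l system, l = 1..m) the package
reports

    R^2  = 1 - sum (v_l - v'_l)^2 / sum (v_l - vbar)^2
    RMSE = sqrt( (1/m) sum (v_l - v'_l)^2 )

together with mean absolute error and per-item relative errors
100 |v_l - v'_l| / v_l. The squared Pearson correlation is reported as a
supplementary statistic because regression software commonly labels that
quantity R^2; the two differ whenever the system is biased.

A transcribed field validation table (plant height, two dates, three
planting-density groups of five plants each) ships with the package as the
only real data available; :func:`load_plant_height_table` returns it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

PLANT_HEIGHT_TABLE = "table3_plant_height.csv"


@dataclass
class PairedMeasurements:
    """Aligned manual and system measurement vectors (cm) with a group label."""

    manual: np.ndarray
    system: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.manual = np.asarray(self.manual, dtype=np.float64).reshape(-1)
        self.system = np.asarray(self.system, dtype=np.float64).reshape(-1)
        if self.manual.shape != self.system.shape:
            raise ValueError("manual and system vectors differ in length")
        if len(self.manual) < 1:
            raise ValueError("at least one measurement pair is required")

    @property
    def m(self) -> int:
        return len(self.manual)


@dataclass
class EvalReport:
    """Agreement summary for one group of paired measurements."""

    label: str
    m: int
    r2: float
    rmse_cm: float
    mae_cm: float
    pearson_r2: float
    relative_errors_pct: np.ndarray = field(repr=False)
    max_rel_pct: float = 0.0
    min_rel_pct: float = 0.0
    mean_rel_pct: float = 0.0

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "m": self.m,
            "r2": self.r2,
            "rmse_cm": self.rmse_cm,
            "mae_cm": self.mae_cm,
            "pearson_r2": self.pearson_r2,
            "max_rel_pct": self.max_rel_pct,
            "min_rel_pct": self.min_rel_pct,
            "mean_rel_pct": self.mean_rel_pct,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    def to_markdown(self) -> str:
        return (
            f"| {self.label} | {self.m} | {self.r2:.4f} | {self.rmse_cm:.2f} | "
            f"{self.mae_cm:.3f} | {self.max_rel_pct:.2f} | {self.min_rel_pct:.2f} | "
            f"{self.mean_rel_pct:.2f} |"
        )


def rmse(pairs: PairedMeasurements) -> float:
    """Root mean square error between manual and system values, in cm."""
    d = pairs.manual - pairs.system
    return float(np.sqrt(np.mean(d**2)))


def r_squared(pairs: PairedMeasurements) -> float:
    """Coefficient of determination of the system values against the
    manual values (1 - residual SS / total SS about the manual mean)."""
    if pairs.m < 2:
        raise ValueError("R^2 requires at least 2 pairs")
    tot = np.sum((pairs.manual - pairs.manual.mean()) ** 2)
    if tot == 0:
        raise ValueError("R^2 undefined: manual values are all equal")
    res = np.sum((pairs.manual - pairs.system) ** 2)
    return float(1.0 - res / tot)


def pearson_r_squared(pairs: PairedMeasurements) -> float:
    """Squared Pearson correlation (the regression-fit R^2)."""
    if pairs.m < 2:
        raise ValueError("correlation requires at least 2 pairs")
    r = np.corrcoef(pairs.manual, pairs.system)[0, 1]
    return float(r**2)


def relative_errors(
    pairs: PairedMeasurements,
) -> tuple[np.ndarray, float, float, float]:
    """Per-item relative errors (%) plus their max, min and mean.

    Relative error of pair l is 100 |v_l - v'_l| / v_l (manual value as
    denominator).
    """
    if np.any(pairs.manual <= 0):
        raise ValueError("relative errors require positive manual values")
    rel = 100.0 * np.abs(pairs.manual - pairs.system) / pairs.manual
    return rel, float(rel.max()), float(rel.min()), float(rel.mean())


def group_summary(pairs: PairedMeasurements) -> tuple[float, float, float]:
    """(manual mean, system mean, mean absolute error), as in the printed
    Average rows of the field validation table."""
    mae = float(np.mean(np.abs(pairs.manual - pairs.system)))
    return float(pairs.manual.mean()), float(pairs.system.mean()), mae


def evaluate_pairs(pairs: PairedMeasurements) -> EvalReport:
    """Full agreement report for one group."""
    rel, mx, mn, mean = relative_errors(pairs)
    return EvalReport(
        label=pairs.label,
        m=pairs.m,
        r2=r_squared(pairs) if pairs.m >= 2 else float("nan"),
        rmse_cm=rmse(pairs),
        mae_cm=group_summary(pairs)[2],
        pearson_r2=pearson_r_squared(pairs) if pairs.m >= 2 else float("nan"),
        relative_errors_pct=rel,
        max_rel_pct=mx,
        min_rel_pct=mn,
        mean_rel_pct=mean,
    )


def load_plant_height_table() -> pd.DataFrame:
    """The bundled plant-height validation table (30 pairs: two dates,
    three planting-density groups of five plants each, variety AD268)."""
    with resources.files("canopy_pheno.data").joinpath(PLANT_HEIGHT_TABLE).open() as fh:
        return pd.read_csv(fh)


def pairs_from_frame(
    frame: pd.DataFrame, group_by: list[str] | None = None
) -> list[PairedMeasurements]:
    """Split a pairs table (columns manual_cm, system_cm and any grouping
    columns) into PairedMeasurements, one per group."""
    if group_by:
        out = []
        for key, sub in frame.groupby(group_by, sort=False):
            key = key if isinstance(key, tuple) else (key,)
            out.append(
                PairedMeasurements(
                    manual=sub["manual_cm"].to_numpy(),
                    system=sub["system_cm"].to_numpy(),
                    label="/".join(str(k) for k in key),
                )
            )
        return out
    return [
        PairedMeasurements(
            manual=frame["manual_cm"].to_numpy(),
            system=frame["system_cm"].to_numpy(),
            label="all",
        )
    ]
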
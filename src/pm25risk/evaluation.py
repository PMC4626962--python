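"""Validation statistics for predicted-vs-observed concentration series.

Four statistics, computed on the concentration scale:

* Pearson correlation coefficient r;
* Willmott-style index of agreement,
  IA = 1 - sum (S_i - O_i)^2 / sum (|S_i - O_ave| + |O_i - O_ave|)^2,
  dimensionless in [0, 1] with IA = 1 iff the series agree elementwise;
* mean bias error MBE = mean(S_i - O_i), positive when the model
  over-forecasts;
* root mean square error RMSE = sqrt(mean (S_i - O_i)^2), which always
  satisfies RMSE >= |MBE|.

Statistics that are undefined for an input (zero variance, zero
denominator) are returned as NaN and rendered as the explicit string
``undefined`` in report files, never silently as 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "pearson_r",
    "index_of_agreement",
    "mean_bias_error",
    "rmse",
    "EvalReport",
    "evaluate_station",
    "write_report_csv",
]

REPORT_COLUMNS = ["station_id", "n", "r", "ia", "mbe", "rmse"]


def _pair(S, O, min_len: int) -> tuple[np.ndarray, np.ndarray]:
    S = np.asarray(S, dtype=float).ravel()
    O = np.asarray(O, dtype=float).ravel()
    if S.shape != O.shape:
        raise ValueError(f"length mismatch: {S.shape} vs {O.shape}")
    if len(S) < min_len:
        raise ValueError(f"need at least {min_len} samples, got {len(S)}")
    if not (np.all(np.isfinite(S)) and np.all(np.isfinite(O))):
        raise ValueError("series must be finite")
    return S, O


def pearson_r(S, O) -> float:
    """Pearson correlation; NaN (undefined) if either series is constant."""
    S, O = _pair(S, O, 2)
    ds, do = S - S.mean(), O - O.mean()
    denom = math.sqrt(float(ds @ ds) * float(do @ do))
    if denom == 0.0:
        return math.nan
    return float(ds @ do) / denom


def index_of_agreement(S, O) -> float:
    """Index of agreement in [0, 1]; NaN when the denominator vanishes."""
    S, O = _pair(S, O, 1)
    o_ave = O.mean()
    denom = float(np.sum((np.abs(S - o_ave) + np.abs(O - o_ave)) ** 2))
    if denom == 0.0:
        return math.nan
    ia = 1.0 - float(np.sum((S - O) ** 2)) / denom
    # exact arithmetic keeps IA in [0, 1]; guard the floating-point edges
    return min(max(ia, 0.0), 1.0)


def mean_bias_error(S, O) -> float:
    S, O = _pair(S, O, 1)
    return float(np.mean(S - O))


def rmse(S, O) -> float:
    S, O = _pair(S, O, 1)
    return float(np.sqrt(np.mean((S - O) ** 2)))


@dataclass
class EvalReport:
    """Per-station bundle of the four statistics.

    ``scale`` records the scale the statistics were computed on;
    concentration units (ug/m3) unless stated otherwise.
    """

    station_id: str
    n: int
    r: float
    ia: float
    mbe: float
    rmse: float
    scale: str = "concentration"

    def to_row(self) -> dict:
        def fmt(v):
            return "undefined" if isinstance(v, float) and math.isnan(v) else v

        return {
            "station_id": self.station_id,
            "n": self.n,
            "r": fmt(self.r),
            "ia": fmt(self.ia),
            "mbe": fmt(self.mbe),
            "rmse": fmt(self.rmse),
        }


def evaluate_station(predictions, observations, station_id: str) -> EvalReport:
    S, O = _pair(predictions, observations, 1)
    return EvalReport(
        station_id=station_id,
        n=len(S),
        r=pearson_r(S, O) if len(S) >= 2 else math.nan,
        ia=index_of_agreement(S, O),
        mbe=mean_bias_error(S, O),
        rmse=rmse(S, O),
    )


def write_report_csv(reports: list[EvalReport], path) -> None:
    pd.DataFrame([r.to_row() for r in reports], columns=REPORT_COLUMNS).to_csv(
        path, index=False
    )
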
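"""File I/O, the bundled software-failure fixture and synthetic data.

The tabular format is a two-column CSV ``time,value``; results are JSON.
The Tandem Computers Release #1 failure counts (20 weekly cumulative defect
totals) ship as an in-memory fixture; epidemic-style series are emulated by
the synthetic generator, which adds homoscedastic Gaussian noise to a model
curve (the fitting procedures minimise unweighted squared residuals, which
matches that noise model).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .errors import ParameterError
from .fitting import TimeSeries, predict_curve

__all__ = [
    "RunConfig",
    "read_timeseries_csv",
    "write_timeseries_csv",
    "tandem_fixture",
    "TANDEM_DEFECTS",
    "synthetic_growth_data",
]

#: Cumulative defects found in 20 consecutive weeks of testing of the
#: Tandem Computers Release #1 software product.
TANDEM_DEFECTS = (
    16, 24, 27, 33, 41, 49, 54, 58, 69, 75,
    81, 86, 90, 93, 96, 98, 99, 100, 100, 100,
)


@dataclass(frozen=True)
class RunConfig:
    """Serializable description of one CLI invocation."""

    command: str
    model: str = ""
    params: tuple = ()
    seed: Optional[int] = None
    input_path: str = ""
    output_path: str = ""
    options: dict = field(default_factory=dict)

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["params"] = list(d["params"])
        return json.dumps(d, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        d = json.loads(text)
        d["params"] = tuple(d.get("params", ()))
        return cls(**d)


def read_timeseries_csv(path: Union[str, Path], label: str = "") -> TimeSeries:
    """Strictly parse a ``time,value`` CSV into a :class:`TimeSeries`.

    Raises :class:`ParameterError` naming the offending row for missing
    columns, non-numeric cells or non-increasing times.
    """
    df = pd.read_csv(path)
    missing = {"time", "value"} - set(df.columns)
    if missing:
        raise ParameterError(
            f"{path}: missing column(s) {sorted(missing)}; expected header "
            "'time,value'"
        )
    for col in ("time", "value"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = np.nonzero(coerced.isna().to_numpy() & df[col].notna().to_numpy())[0]
        if df[col].isna().any() or bad.size:
            row = int((bad[0] if bad.size else df[col].isna().idxmax())) + 2
            raise ParameterError(f"{path}: non-numeric {col!r} at row {row}")
        df[col] = coerced
    times = df["time"].to_numpy(dtype=float)
    steps = np.diff(times)
    if np.any(steps <= 0):
        row = int(np.argmax(steps <= 0)) + 3  # +1 header, +1 one-based, +1 diff
        raise ParameterError(f"{path}: times not strictly increasing at row {row}")
    return TimeSeries(times, df["value"].to_numpy(dtype=float),
                      label=label or str(path))


def write_timeseries_csv(series: TimeSeries, path: Union[str, Path]) -> None:
    """Write a series as ``time,value`` with full float precision."""
    df = pd.DataFrame({"time": series.times, "value": series.values})
    df.to_csv(path, index=False)  # pandas writes shortest round-trip floats


def tandem_fixture() -> TimeSeries:
    """The Tandem Computers weekly cumulative defect counts (weeks 1-20)."""
    return TimeSeries(
        np.arange(1, 21, dtype=float),
        np.asarray(TANDEM_DEFECTS, dtype=float),
        label="tandem-release1-defects",
    )


def synthetic_growth_data(
    kind: str,
    params: Sequence[float],
    times: Sequence[float],
    noise_sd: float = 0.0,
    seed: Optional[int] = None,
    label: str = "",
) -> TimeSeries:
    """Model curve plus independent Gaussian observation noise.

    Emulates cumulative surveillance counts read off a growth curve; the
    noise is additive on the size scale and the result is clipped at zero
    (counts cannot be negative).  Deterministic under ``seed``.
    """
    if noise_sd < 0:
        raise ParameterError("noise_sd must be >= 0")
    times = np.asarray(times, dtype=float)
    values = predict_curve(kind, params, times)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        values = values + rng.normal(0.0, noise_sd, size=values.shape)
        values = np.clip(values, 0.0, None)
    return TimeSeries(times, values, label=label or f"synthetic-{kind}")
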
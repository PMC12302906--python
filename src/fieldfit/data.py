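"""Core data containers shared across the package.

The modeling code works on three kinds of objects:

* :class:`EnvSeries` — a regularly sampled environmental trace (temperature
  and irradiance against hours since the series start).
* :class:`EnvStack` — several traces concatenated into flat arrays so that
  windowed look-back means can be computed for many samples in one shot.
* :class:`SampleSet` — per-sample covariates (clock time, plant age) together
  with a pointer into an :class:`EnvStack` saying which trace and which grid
  position each sample was taken at.
* :class:`ExpressionStudy` — a genes x samples matrix of log2(rpm+1) values
  plus per-sample metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

#: Hours of meteorological history a model may look back over.
LOOKBACK_H = 72.0


@dataclass(frozen=True)
class EnvSeries:
    """A uniformly sampled environmental trace.

    Parameters
    ----------
    t : ndarray
        Hours since the series start; strictly increasing uniform grid with
        step ``dt <= 0.5`` h.
    temperature : ndarray
        Air temperature in deg C.
    irradiance : ndarray
        Irradiance in arbitrary flux units, non-negative.
    clock0 : float
        Clock time (hours-of-day) of the first grid point.
    """

    t: np.ndarray
    temperature: np.ndarray
    irradiance: np.ndarray
    clock0: float = 0.0

    def __post_init__(self):
        t = np.asarray(self.t, dtype=float)
        temp = np.asarray(self.temperature, dtype=float)
        irr = np.asarray(self.irradiance, dtype=float)
        if t.ndim != 1 or len(t) < 2:
            raise ValueError("EnvSeries needs a 1-d time grid with >= 2 points")
        steps = np.diff(t)
        if not np.allclose(steps, steps[0], rtol=0, atol=1e-9) or steps[0] <= 0:
            raise ValueError("EnvSeries time grid must be uniform and increasing")
        if steps[0] > 0.5 + 1e-12:
            raise ValueError("EnvSeries grid step must be <= 0.5 h")
        if temp.shape != t.shape or irr.shape != t.shape:
            raise ValueError("temperature/irradiance must match the time grid")
        if np.any(irr < 0):
            raise ValueError("irradiance must be non-negative")
        if not (np.all(np.isfinite(temp)) and np.all(np.isfinite(irr))):
            raise ValueError("environmental values must be finite")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "temperature", temp)
        object.__setattr__(self, "irradiance", irr)

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    @property
    def clock_time(self) -> np.ndarray:
        """Hours-of-day in [0, 24) for every grid point."""
        return (self.clock0 + self.t) % 24.0

    @property
    def span_h(self) -> float:
        return float(self.t[-1] - self.t[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_h": self.t,
                "clock_time_h": self.clock_time,
                "temperature_C": self.temperature,
                "irradiance": self.irradiance,
            }
        )


class EnvStack:
    """Several :class:`EnvSeries` concatenated into flat arrays.

    Window means over ``[t - D - T, t - D)`` are computed with prefix sums
    over the concatenated arrays; windows never cross trace boundaries
    because callers are required to keep ``T + D`` within each sample's
    available history.
    """

    def __init__(self, series: Sequence[EnvSeries]):
        if not series:
            raise ValueError("EnvStack needs at least one EnvSeries")
        dts = {round(s.dt, 9) for s in series}
        if len(dts) > 1:
            raise ValueError("all EnvSeries in a stack must share the grid step")
        self.dt = series[0].dt
        self.series = list(series)
        self.lengths = np.array([len(s.t) for s in series], dtype=np.int64)
        self.offsets = np.concatenate([[0], np.cumsum(self.lengths)[:-1]])
        self.n_total = int(self.lengths.sum())
        self.temperature = np.concatenate([s.temperature for s in series])
        self.irradiance = np.concatenate([s.irradiance for s in series])
        self.clock = np.concatenate([s.clock_time for s in series])

    def variable(self, name: str) -> np.ndarray:
        if name == "temperature":
            return self.temperature
        if name == "radiation":
            return self.irradiance
        raise ValueError(f"unknown environmental variable {name!r}")

    @staticmethod
    def concat(stacks: Sequence["EnvStack"]) -> "EnvStack":
        series: list[EnvSeries] = []
        for st in stacks:
            series.extend(st.series)
        return EnvStack(series)


class SampleSet:
    """Samples with covariates, anchored to traces of an :class:`EnvStack`.

    Parameters
    ----------
    stack : EnvStack
    trace : ndarray of int
        Index of the trace each sample belongs to.
    time_h : ndarray
        Hours since the start of the sample's own trace; must sit on the
        trace's grid and leave at least ``LOOKBACK_H`` hours of history.
    clock : ndarray
        Hours-of-day of each sample.
    age : ndarray
        Plant age in days at sampling.
    """

    def __init__(self, stack: EnvStack, trace, time_h, clock, age):
        self.stack = stack
        self.trace = np.asarray(trace, dtype=np.int64)
        self.time_h = np.asarray(time_h, dtype=float)
        self.clock = np.asarray(clock, dtype=float)
        self.age = np.asarray(age, dtype=float)
        n = len(self.trace)
        if not (len(self.time_h) == len(self.clock) == len(self.age) == n):
            raise ValueError("sample covariate arrays must have equal length")
        if np.any(self.trace < 0) or np.any(self.trace >= len(stack.lengths)):
            raise ValueError("trace index out of range")
        k = self.time_h / stack.dt
        ki = np.rint(k).astype(np.int64)
        if not np.allclose(k, ki, atol=1e-6):
            raise ValueError("sample times must sit on the environmental grid")
        if np.any(ki >= stack.lengths[self.trace]):
            raise ValueError("sample time beyond the end of its trace")
        short = self.time_h < LOOKBACK_H
        if np.any(short):
            earliest = LOOKBACK_H
            raise ValueError(
                f"insufficient environmental history for {int(short.sum())} "
                f"sample(s); earliest valid time is {earliest:.1f} h into a trace"
            )
        #: global grid index of each sample in the concatenated stack
        self.pos = stack.offsets[self.trace] + ki

    def __len__(self) -> int:
        return len(self.pos)

    def subset(self, idx) -> "SampleSet":
        out = SampleSet.__new__(SampleSet)
        out.stack = self.stack
        out.trace = self.trace[idx]
        out.time_h = self.time_h[idx]
        out.clock = self.clock[idx]
        out.age = self.age[idx]
        out.pos = self.pos[idx]
        return out

    @staticmethod
    def concat(parts: Sequence["SampleSet"]) -> "SampleSet":
        """Concatenate sample sets; their stacks are merged in order."""
        stack = EnvStack.concat([p.stack for p in parts])
        trace, time_h, clock, age = [], [], [], []
        shift = 0
        for p in parts:
            trace.append(p.trace + shift)
            time_h.append(p.time_h)
            clock.append(p.clock)
            age.append(p.age)
            shift += len(p.stack.lengths)
        return SampleSet(
            stack,
            np.concatenate(trace),
            np.concatenate(time_h),
            np.concatenate(clock),
            np.concatenate(age),
        )


META_COLUMNS = [
    "sample_id",
    "cultivar",
    "condition_id",
    "plate_id",
    "clock_time_h",
    "age_days",
    "sampling_time_index",
]


@dataclass
class ExpressionStudy:
    """A genes x samples matrix of log2(rpm+1) values plus sample metadata.

    ``matrix`` is a DataFrame indexed by gene_id with sample_ids as columns;
    ``meta`` is indexed by sample_id.  ``truth`` optionally carries
    generator-side ground truth (e.g. the temperature actually used to
    simulate each sample) and is never touched by annotation edits such as
    plate-swap injection.
    """

    matrix: pd.DataFrame
    meta: pd.DataFrame
    truth: pd.DataFrame | None = None
    swap_log: list = field(default_factory=list)

    def __post_init__(self):
        if self.meta.index.name != "sample_id":
            if "sample_id" in self.meta.columns:
                self.meta = self.meta.set_index("sample_id")
            else:
                self.meta = self.meta.rename_axis("sample_id")
        if self.meta.index.duplicated().any():
            dup = self.meta.index[self.meta.index.duplicated()][0]
            raise ValueError(f"duplicate sample_id {dup!r} in metadata")
        missing = [c for c in self.matrix.columns if c not in self.meta.index]
        if missing:
            raise ValueError(f"samples without metadata: {missing[:5]}")
        if not np.all(np.isfinite(self.matrix.to_numpy())):
            raise ValueError("expression matrix contains non-finite values")
        # align metadata rows to matrix column order
        self.meta = self.meta.loc[list(self.matrix.columns)]

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[1]

    def copy(self) -> "ExpressionStudy":
        return ExpressionStudy(
            self.matrix.copy(),
            self.meta.copy(),
            None if self.truth is None else self.truth.copy(),
            list(self.swap_log),
        )
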
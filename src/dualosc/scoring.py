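"""Oscillation-damping evaluation of fluorescence time courses.

A trace is smoothed with a short moving average and its local minima
("bottoms") with sufficient range-relative prominence are counted; a trace
with three or more bottoms is scored as oscillating.  The per-condition
fraction of such traces (the relative bottom count) and the cumulative
relative-frequency distribution of bottom counts summarise each inducer
condition; summaries are laid out on the inducer grid as a heat-map matrix.

Because prominence is measured relative to the post-smoothing range,
scoring is invariant to multiplying a trace by a positive constant.  Within
a 3-h observation window a trace needs roughly three full periods to pass
the >= 3 bottom rule, so slow oscillators are conservatively scored as
non-oscillating.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from dualosc.params import InducerCondition
from dualosc.sweep import GridSpec

#: bottoms required to call a trace oscillating
OSCILLATION_BOTTOM_RULE = 3


@dataclass
class FluorescenceTrace:
    """One per-colony GFP intensity time course."""

    times: np.ndarray           # min, uniformly sampled
    intensity: np.ndarray       # arbitrary units
    condition: InducerCondition
    trace_id: str = ""
    source: str = "synthetic"   # {"synthetic", "measured"}

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.times.size < 2:
            raise ValueError("a trace needs at least 2 samples")
        if self.times.size != self.intensity.size:
            raise ValueError("times and intensity length mismatch")
        steps = np.diff(self.times)
        if np.any(steps <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.allclose(steps, steps[0], rtol=1e-6):
            raise ValueError("sampling interval must be uniform")
        self.sampling_interval = float(steps[0])
        if self.source not in ("synthetic", "measured"):
            raise ValueError(f"unknown source tag {self.source!r}")


def _smooth(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return x.astype(float)
    return (
        pd.Series(x).rolling(window, center=True, min_periods=1).mean().to_numpy()
    )


def detect_bottoms(
    trace: FluorescenceTrace,
    smooth_window: int = 3,
    min_prominence_fraction: float = 0.3,
    min_width_samples: int = 6,
) -> np.ndarray:
    """Indices of oscillation bottoms (local minima) in a trace.

    The intensity is moving-average smoothed over ``smooth_window`` samples,
    then local minima are kept when (i) their prominence is at least
    ``min_prominence_fraction`` times the post-smoothing range and (ii) the
    trough is at least ``min_width_samples`` wide at half prominence.
    Endpoints are never counted; a flat trace has zero bottoms.

    Both criteria are relative to the trace itself (range-relative
    prominence, duration-based width), so scoring is invariant to positive
    rescaling of the intensity.  The width criterion is what separates
    genuine oscillation troughs (wide, at the 3-min frame interval roughly
    a quarter period) from the narrow dips that uncorrelated multiplicative
    measurement noise produces at any noise scale.
    """
    if smooth_window < 1:
        raise ValueError("smooth_window must cover at least 1 sample")
    if not 0 < min_prominence_fraction < 1:
        raise ValueError("min_prominence_fraction must lie in (0, 1)")
    smoothed = _smooth(trace.intensity, smooth_window)
    rng = float(smoothed.max() - smoothed.min())
    if rng == 0.0:
        return np.array([], dtype=int)
    idx, _ = find_peaks(
        -smoothed,
        prominence=min_prominence_fraction * rng,
        width=min_width_samples,
    )
    return idx


@dataclass
class BottomCountSummary:
    """Per-condition bottom-count statistics.

    ``relative_bottom_count`` is the fraction of traces with at least three
    bottoms.  ``counts_descending`` and ``cumulative_frequency`` give the
    cumulative relative-frequency distribution: traces sorted by bottom
    count in descending order against the cumulative fraction of traces.
    """

    condition: InducerCondition
    bottom_counts: np.ndarray
    relative_bottom_count: float
    counts_descending: np.ndarray
    cumulative_frequency: np.ndarray
    n_traces: int
    scoring_params: dict = field(default_factory=dict)


def score_condition(
    traces: list[FluorescenceTrace],
    smooth_window: int = 3,
    min_prominence_fraction: float = 0.3,
    min_width_samples: int = 6,
) -> BottomCountSummary:
    """Score all traces of one inducer condition."""
    if not traces:
        raise ValueError("at least one trace is required")
    cond = traces[0].condition
    if any(t.condition != cond for t in traces):
        raise ValueError("all traces must share one inducer condition")
    counts = np.array(
        [detect_bottoms(t, smooth_window, min_prominence_fraction,
                        min_width_samples).size
         for t in traces]
    )
    desc = np.sort(counts)[::-1]
    return BottomCountSummary(
        condition=cond,
        bottom_counts=counts,
        relative_bottom_count=float(
            np.mean(counts >= OSCILLATION_BOTTOM_RULE)
        ),
        counts_descending=desc,
        cumulative_frequency=np.arange(1, counts.size + 1) / counts.size,
        n_traces=counts.size,
        scoring_params={
            "smooth_window": smooth_window,
            "min_prominence_fraction": min_prominence_fraction,
            "min_width_samples": min_width_samples,
        },
    )


def condition_heatmap(
    summaries: dict[InducerCondition, BottomCountSummary] | list[BottomCountSummary],
    grid: GridSpec,
) -> np.ndarray:
    """Relative bottom counts laid out on the inducer grid.

    Missing cells are NaN (absent, not zero); a summary whose condition is
    not a grid point is rejected.
    """
    if isinstance(summaries, dict):
        summaries = list(summaries.values())
    mat = np.full(grid.shape, np.nan)
    ara, iptg = grid.ara_values, grid.iptg_values
    for s in summaries:
        ia = np.flatnonzero(np.isclose(ara, s.condition.arabinose, rtol=1e-9))
        ji = np.flatnonzero(np.isclose(iptg, s.condition.iptg, rtol=1e-9))
        if ia.size != 1 or ji.size != 1:
            raise ValueError(
                f"condition (ara={s.condition.arabinose}, "
                f"iptg={s.condition.iptg}) is not on the grid"
            )
        mat[ia[0], ji[0]] = s.relative_bottom_count
    return mat


# -- long-format trace table IO ------------------------------------------

_COLUMNS = ["trace_id", "time_min", "intensity", "arabinose_pct", "iptg_mM"]


def write_traces(traces: list[FluorescenceTrace], path) -> None:
    """Long-format delimited text (trace id, time, intensity, inducers)."""
    frames = [
        pd.DataFrame({
            "trace_id": t.trace_id,
            "time_min": t.times,
            "intensity": t.intensity,
            "arabinose_pct": t.condition.arabinose,
            "iptg_mM": t.condition.iptg,
        })
        for t in traces
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_traces(path, source: str = "measured") -> list[FluorescenceTrace]:
    df = pd.read_csv(Path(path), sep="\t")
    missing = set(_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trace table misses columns: {sorted(missing)}")
    traces = []
    for tid, sub in df.groupby("trace_id", sort=False):
        sub = sub.sort_values("time_min")
        traces.append(
            FluorescenceTrace(
                times=sub["time_min"].to_numpy(),
                intensity=sub["intensity"].to_numpy(),
                condition=InducerCondition(
                    arabinose=float(sub["arabinose_pct"].iloc[0]),
                    iptg=float(sub["iptg_mM"].iloc[0]),
                ),
                trace_id=str(tid),
                source=source,
            )
        )
    return traces
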
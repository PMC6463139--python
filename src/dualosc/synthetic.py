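"""Synthetic microscopy-trace generator.

Emulates per-colony GFP fluorescence sampled every 3 min for 3 h: a
(possibly damped) sinusoid on a baseline with slow drift, multiplicative
measurement noise and guaranteed positivity.  Used to validate the trace
scorer and to bridge model trajectories to the scoring pipeline; it does
not emulate cell growth, lineage structure or photobleaching.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from dualosc.params import InducerCondition
from dualosc.scoring import FluorescenceTrace
from dualosc.sweep import GridSpec
from dualosc.timecourse import Trajectory

_MIN_INTENSITY = 1e-9


@dataclass(frozen=True)
class TraceGenSpec:
    """Generator settings for one synthetic fluorescence trace.

    ``intensity(t) = (baseline + drift*t + amplitude * exp(-damping*t)
    * sin(2*pi*t/period)) * (1 + noise)`` with i.i.d. zero-mean Gaussian
    multiplicative noise of scale ``noise_scale``, clipped to stay
    positive.  The seed fixes the full output.
    """

    duration: float = 180.0          # min (3-h observation window)
    interval: float = 3.0            # min between frames
    baseline: float = 100.0          # a.u.
    amplitude: float = 40.0          # a.u.
    period: float = 40.0             # min
    damping: float = 0.0             # per min
    noise_scale: float = 0.05
    drift: float = 0.0               # a.u. per min
    seed: int = 0

    def __post_init__(self):
        if self.duration <= 0 or self.interval <= 0:
            raise ValueError("duration and interval must be positive")
        if self.noise_scale < 0:
            raise ValueError("noise scale must be nonnegative")
        if self.period <= 0:
            raise ValueError("period must be positive")


def generate_trace(
    spec: TraceGenSpec,
    condition: InducerCondition = InducerCondition(0.0, 0.0),
    trace_id: str = "synthetic-0",
) -> FluorescenceTrace:
    """One deterministic-per-seed synthetic trace.

    Rejects parameter combinations whose noise-free signal is not strictly
    positive somewhere in the window.
    """
    times = np.arange(0.0, spec.duration + 0.5 * spec.interval, spec.interval)
    clean = (
        spec.baseline
        + spec.drift * times
        + spec.amplitude
        * np.exp(-spec.damping * times)
        * np.sin(2.0 * np.pi * times / spec.period)
    )
    if np.any(clean <= 0):
        raise ValueError(
            "generator parameters force nonpositive intensity "
            f"(min {clean.min():.3g})"
        )
    rng = np.random.default_rng(spec.seed)
    noise = rng.normal(0.0, spec.noise_scale, times.size)
    intensity = np.maximum(clean * (1.0 + noise), _MIN_INTENSITY)
    return FluorescenceTrace(
        times=times, intensity=intensity, condition=condition,
        trace_id=trace_id, source="synthetic",
    )


def _derive_seed(master_seed: int, *key: int) -> int:
    """Stable per-trace seed from (master seed, cell indices, replicate)."""
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=tuple(key))
    return int(ss.generate_state(1)[0] % (2**31))


def generate_panel(
    grid: GridSpec,
    regime_map,
    n_traces_per_cell: int,
    seed: int = 0,
) -> list[FluorescenceTrace]:
    """Synthetic trace panel over an inducer grid.

    ``regime_map`` assigns a :class:`TraceGenSpec` template to each cell:
    either a mapping keyed by ``(i_ara, i_iptg)`` or a callable
    ``(i_ara, i_iptg, arabinose, iptg) -> TraceGenSpec``.  Per-trace seeds
    are derived from the master seed and the cell/replicate indices, so a
    panel is reproducible under partial regeneration.
    """
    if n_traces_per_cell < 1:
        raise ValueError("n_traces_per_cell must be at least 1")
    ara, iptg = grid.ara_values, grid.iptg_values
    traces: list[FluorescenceTrace] = []
    for i, a in enumerate(ara):
        for j, p in enumerate(iptg):
            template = (
                regime_map[(i, j)] if hasattr(regime_map, "__getitem__")
                else regime_map(i, j, float(a), float(p))
            )
            cond = InducerCondition(float(a), float(p))
            for r in range(n_traces_per_cell):
                spec = replace(template, seed=_derive_seed(seed, i, j, r))
                traces.append(
                    generate_trace(
                        spec, cond, trace_id=f"cell{i}-{j}_rep{r}"
                    )
                )
    return traces


def traces_from_model(
    traj: Trajectory,
    noise_scale: float = 0.05,
    n: int = 1,
    seed: int = 0,
    duration: float = 180.0,
    interval: float = 3.0,
    start: float | None = None,
    species: str = "gfp",
) -> list[FluorescenceTrace]:
    """Noisy microscopy-like replicates resampled from a model trajectory.

    The ``species`` variable (free GFP by default) is resampled at the
    microscopy interval over a ``duration`` window starting at ``start``
    (default: the final window, past the transient); each of the ``n``
    replicates gets its own multiplicative-noise realisation.
    """
    if species not in traj.names:
        raise ValueError(f"trajectory has no {species!r} variable")
    if n < 1:
        raise ValueError("n must be at least 1")
    span = traj.times[-1] - traj.times[0]
    if span < duration:
        raise ValueError(
            f"trajectory ({span:.0f} min) shorter than the "
            f"{duration:.0f}-min sampling window"
        )
    if start is None:
        start = traj.times[-1] - duration
    if start < traj.times[0] or start + duration > traj.times[-1] + 1e-9:
        raise ValueError("sampling window outside the trajectory")
    times = np.arange(0.0, duration + 0.5 * interval, interval)
    signal = np.interp(start + times, traj.times, traj.series(species))
    cond = InducerCondition(
        float(traj.metadata.get("arabinose", 0.0)),
        float(traj.metadata.get("iptg", 0.0)),
    )
    out = []
    for r in range(n):
        rng = np.random.default_rng(_derive_seed(seed, r))
        noise = rng.normal(0.0, noise_scale, times.size) if noise_scale else 0.0
        intensity = np.maximum(signal * (1.0 + noise), _MIN_INTENSITY)
        out.append(
            FluorescenceTrace(
                times=times, intensity=intensity, condition=cond,
                trace_id=f"model_rep{r}", source="synthetic",
            )
        )
    return out
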
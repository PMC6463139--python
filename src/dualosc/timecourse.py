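"""Stiff integration of the circuit ODEs and oscillation metrics.

A :class:`Trajectory` is the dense-sampled solution of one circuit at one
inducer condition; :func:`extract_oscillation_metrics` discards a transient
window, detects peaks and troughs and decides fixed-point versus sustained
oscillation.  Amplitude is peak-to-trough (max minus min over the last full
cycles) and the period is the mean inter-peak interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.signal import find_peaks


class IntegrationError(RuntimeError):
    """Raised when the ODE solver fails; carries the partial solution."""

    def __init__(self, message: str, partial: "Trajectory | None" = None):
        super().__init__(message)
        self.partial = partial


@dataclass
class Trajectory:
    """Dense ODE solution: times (min) by state-variable values."""

    times: np.ndarray
    values: np.ndarray          # shape (n_times, n_states)
    names: list[str]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.times.size, len(self.names)):
            raise ValueError("trajectory shape mismatch")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def series(self, name: str) -> np.ndarray:
        return self.values[:, self.names.index(name)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.names)
        df.insert(0, "time_min", self.times)
        return df

    def write(self, path) -> None:
        """Wide-format delimited text: time plus one column per variable."""
        self.to_frame().to_csv(path, sep="\t", index=False)


def integrate(
    system,
    initial,
    t_end: float,
    sample_interval: float = 1.0,
    method: str = "LSODA",
    rtol: float = 1e-7,
    atol: float = 1e-8,
) -> Trajectory:
    """Integrate ``system`` from ``initial`` over [0, t_end].

    Uses a stiff-capable solver with the system's analytic Jacobian when it
    exposes one; output is sampled on a uniform grid of ``sample_interval``
    minutes and the solver settings are recorded in the metadata.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    initial = np.asarray(initial, dtype=float)
    t_eval = np.arange(0.0, t_end + 0.5 * sample_interval, sample_interval)
    kwargs = {}
    if hasattr(system, "jacobian") and method in ("LSODA", "BDF", "Radau"):
        kwargs["jac"] = system.jacobian
    sol = solve_ivp(
        system.rhs if hasattr(system, "rhs") else system,
        (0.0, t_end),
        initial,
        method=method,
        t_eval=t_eval,
        rtol=rtol,
        atol=atol,
        **kwargs,
    )
    names = (list(system.state_names) if hasattr(system, "state_names")
             else [f"x{i}" for i in range(initial.size)])
    meta = {
        "method": method, "rtol": rtol, "atol": atol,
        "sample_interval": sample_interval, "t_end": t_end,
    }
    if hasattr(system, "config"):
        meta["reporter_kind"] = system.config.reporter_kind
        meta["retroactivity_on"] = system.config.retroactivity_on
        meta["protease_sharing_on"] = system.config.protease_sharing_on
    if hasattr(system, "condition"):
        meta["arabinose"] = system.condition.arabinose
        meta["iptg"] = system.condition.iptg
    if not sol.success:
        partial = None
        if sol.t.size:
            partial = Trajectory(sol.t, sol.y.T, names, meta)
        raise IntegrationError(
            f"ODE integration failed at t={sol.t[-1] if sol.t.size else 0}: "
            f"{sol.message}",
            partial=partial,
        )
    return Trajectory(sol.t, sol.y.T, names, meta)


@dataclass
class OscillationMetrics:
    """Fixed-versus-oscillatory verdict with amplitude and period."""

    classification: str                      # "fixed" | "oscillatory"
    amplitude: dict                          # species -> max-min, last cycles
    period: float | None                     # min; None when fixed
    peak_times: np.ndarray
    trough_times: np.ndarray
    reference: str

    @property
    def oscillatory(self) -> bool:
        return self.classification == "oscillatory"


def _peaks(signal: np.ndarray, times: np.ndarray, prominence: float):
    idx, _ = find_peaks(signal, prominence=prominence)
    if idx.size >= 3:
        # refine with a minimum separation of 1/4 of the running period
        period_est = float(np.median(np.diff(times[idx])))
        dt = times[1] - times[0]
        dist = max(1, int(round(period_est / 4.0 / dt)))
        idx, _ = find_peaks(signal, prominence=prominence, distance=dist)
    return idx


def extract_oscillation_metrics(
    traj: Trajectory,
    transient_fraction: float = 0.5,
    amp_threshold: float = 1.0,
    reference: str | None = None,
    species: list[str] | None = None,
) -> OscillationMetrics:
    """Classify a trajectory and measure amplitude and period.

    The first ``transient_fraction`` of the horizon is discarded.  The
    reference species (free LacI when present) is scanned for peaks and
    troughs; the trajectory is oscillatory iff at least two full periods
    are seen (>= 3 peaks) and the peak-to-trough amplitude over the last
    full cycles exceeds ``amp_threshold`` (default 1 molecule/cell:
    sub-molecule swings are not called oscillations).  Amplitudes are
    reported for every requested species over the same window.
    """
    if not 0 <= transient_fraction < 1:
        raise ValueError("transient_fraction must lie in [0, 1)")
    t_cut = traj.times[0] + transient_fraction * (traj.times[-1] - traj.times[0])
    keep = traj.times >= t_cut
    if keep.sum() < 4:
        raise ValueError("trajectory shorter than the transient window")
    times = traj.times[keep]

    if reference is None:
        reference = "laci_free" if "laci_free" in traj.names else traj.names[0]
    if species is None:
        species = [n for n in ("laci_free", "arac_free", "gfp")
                   if n in traj.names]
        if reference not in species:
            species = [reference] + species

    ref = traj.series(reference)[keep]
    rng = float(ref.max() - ref.min())
    prominence = max(amp_threshold / 2.0, 1e-3 * rng)
    p_idx = _peaks(ref, times, prominence)
    t_idx = _peaks(-ref, times, prominence)

    oscillatory = False
    period = None
    window = slice(None)
    if p_idx.size >= 3:
        period = float(np.mean(np.diff(times[p_idx])))
        # last full cycles: from the antepenultimate peak onwards
        window = slice(int(p_idx[-3]), None)
        last_amp = float(ref[window].max() - ref[window].min())
        if last_amp > amp_threshold:
            oscillatory = True
    if not oscillatory:
        period = None
        window = slice(None)

    amplitude = {
        name: float(traj.series(name)[keep][window].max()
                    - traj.series(name)[keep][window].min())
        for name in species
    }
    return OscillationMetrics(
        classification="oscillatory" if oscillatory else "fixed",
        amplitude=amplitude,
        period=period,
        peak_times=times[p_idx],
        trough_times=times[t_idx],
        reference=reference,
    )
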
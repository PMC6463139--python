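"""Two-inducer phase-diagram sweeps.

Every grid cell (arabinose, IPTG pair) is classified by linear stability
analysis first: Newton-Raphson equilibria and Jacobian eigenvalues on the
conservation manifold.  Cells with a stable equilibrium are stable fixed
points (the phase diagram's black region); only cells without one are
integrated, and carry the LacI/GFP peak-to-trough amplitudes and the
period of the resulting oscillation.  Deciding by asymptotic stability
rather than by a finite trajectory keeps weakly damped spirals -- whose
transients can ring for thousands of minutes -- out of the oscillatory
set.
"""

from __future__ import annotations

import hashlib
import json
from concurrent.futures import ProcessPoolExecutor
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from dualosc.odes import assemble_odes
from dualosc.params import CircuitConfig, InducerCondition, ParameterSet
from dualosc.stability import find_equilibria
from dualosc.timecourse import (
    IntegrationError,
    extract_oscillation_metrics,
    integrate,
)


@dataclass(frozen=True)
class GridSpec:
    """Log-spaced inducer grid; defaults reproduce the full study grid
    (21 arabinose points on [0.01, 1.0] % and 46 IPTG points on
    [0.001, 31.6] mM)."""

    n_ara: int = 21
    ara_min: float = 0.01
    ara_max: float = 1.0
    n_iptg: int = 46
    iptg_min: float = 0.001
    iptg_max: float = 31.6

    def __post_init__(self):
        for lo, hi, n, label in (
            (self.ara_min, self.ara_max, self.n_ara, "arabinose"),
            (self.iptg_min, self.iptg_max, self.n_iptg, "IPTG"),
        ):
            if lo <= 0 or hi <= 0:
                raise ValueError(f"{label} bounds must be positive")
            if hi <= lo:
                raise ValueError(f"{label} axis must be increasing")
            if n < 2:
                raise ValueError(f"{label} axis needs at least 2 points")

    @property
    def ara_values(self) -> np.ndarray:
        return np.geomspace(self.ara_min, self.ara_max, self.n_ara)

    @property
    def iptg_values(self) -> np.ndarray:
        return np.geomspace(self.iptg_min, self.iptg_max, self.n_iptg)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_ara, self.n_iptg)


def make_grid(spec: GridSpec) -> list[InducerCondition]:
    """All grid conditions in row-major order (arabinose outer, IPTG inner);
    endpoints are exact."""
    return [
        InducerCondition(arabinose=float(a), iptg=float(i))
        for a in spec.ara_values
        for i in spec.iptg_values
    ]


@dataclass
class SweepResult:
    """Per-cell classification and oscillation measures on a GridSpec.

    ``classification`` holds ``"oscillatory"`` / ``"stable_fixed"`` (or
    ``"failed"``); amplitude and period matrices are NaN outside
    oscillatory cells.
    """

    grid: GridSpec
    classification: np.ndarray          # (n_ara, n_iptg) of str
    laci_amplitude: np.ndarray
    gfp_amplitude: np.ndarray
    period: np.ndarray
    coexistence: np.ndarray             # bool: stable eq + sustained cycle
    fingerprint: str
    failures: list = field(default_factory=list)

    @property
    def oscillatory_mask(self) -> np.ndarray:
        return self.classification == "oscillatory"

    @property
    def oscillation_area(self) -> int:
        """Number of oscillatory grid cells."""
        return int(self.oscillatory_mask.sum())

    def write(self, out_dir) -> None:
        """One delimited matrix file per quantity plus a metadata sidecar."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        header = "\t".join(["arabinose_pct\\iptg_mM"]
                           + [f"{v:.6g}" for v in self.grid.iptg_values])
        for name, mat in (
            ("classification", self.classification),
            ("laci_amplitude", self.laci_amplitude),
            ("gfp_amplitude", self.gfp_amplitude),
            ("period", self.period),
        ):
            lines = [header]
            for i, a in enumerate(self.grid.ara_values):
                cells = [f"{a:.6g}"] + [
                    (str(x) if mat.dtype.kind in "US" else f"{x:.8g}")
                    for x in mat[i]
                ]
                lines.append("\t".join(cells))
            (out / f"{name}.tsv").write_text("\n".join(lines) + "\n")
        meta = {"grid": asdict(self.grid), "fingerprint": self.fingerprint,
                "oscillation_area": self.oscillation_area,
                "failures": self.failures}
        (out / "sweep_meta.json").write_text(json.dumps(meta, indent=2))

    def plot(self, path, quantity: str = "laci_amplitude") -> None:
        """Render the phase diagram to an image file.

        Stable-fixed cells are black; oscillatory cells are colored by the
        requested quantity (amplitude or period).
        """
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        mat = np.ma.masked_invalid(getattr(self, quantity))
        fig, ax = plt.subplots(figsize=(5.2, 4.2))
        cmap = plt.get_cmap("jet").copy()
        cmap.set_bad("black")
        pcm = ax.pcolormesh(self.grid.iptg_values, self.grid.ara_values,
                            mat, cmap=cmap, shading="nearest")
        ax.set_xscale("log")
        ax.set_yscale("log")
        ax.set_xlabel("IPTG (mM)")
        ax.set_ylabel("arabinose (% w/v)")
        fig.colorbar(pcm, ax=ax, label=quantity.replace("_", " "))
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)


def _fingerprint(config: CircuitConfig, params: ParameterSet,
                 spec: GridSpec) -> str:
    payload = json.dumps(
        [asdict(config), asdict(params), asdict(spec)], sort_keys=True
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


#: protein levels of the Newton seeding lattice (free AraC, free LacI)
_GUESS_LATTICE = ((1.0, 1.0), (300.0, 30.0), (30.0, 300.0), (300.0, 300.0))


def equilibrium_guesses(system, burn_in: float = 300.0,
                        rtol: float = 1e-6, atol: float = 1e-6):
    """Newton-Raphson seeds: a lattice of low/mid/high protein levels plus
    the endpoint of a short ODE burn-in from the standard initial state."""
    guesses = [system.initial_state()]
    for a0, l0 in _GUESS_LATTICE:
        y = system.initial_state(a0, l0)
        if system.has_reporter:
            y[system.i_g] = 10.0 * (a0 + l0)
        guesses.append(y)
    traj = integrate(system, system.initial_state(), burn_in,
                     sample_interval=burn_in / 8, rtol=rtol, atol=atol)
    guesses.append(traj.values[-1])
    return guesses


def classify_cell(
    config: CircuitConfig,
    params: ParameterSet,
    condition: InducerCondition,
    t_end: float = 1500.0,
    sample_interval: float = 1.0,
    amp_threshold: float = 1.0,
    rtol: float = 1e-6,
    atol: float = 1e-6,
):
    """Classify one inducer condition, stability analysis first.

    Equilibria are located by Newton-Raphson from a fixed seeding (lattice
    plus burn-in endpoint) and classified by Jacobian eigenvalues on the
    conservation manifold.  A cell with a stable equilibrium is a stable
    fixed point -- even when a limit cycle coexists, which matches the
    equilibrium-based phase diagrams this pipeline reproduces; coexistence
    is detectable downstream through the flag.  Only cells without a
    stable equilibrium are integrated, to measure amplitude and period of
    the oscillation.
    """
    system = assemble_odes(config, params, condition)
    try:
        reports = find_equilibria(
            system, equilibrium_guesses(system, rtol=rtol, atol=atol),
            tol=1e-7,
        )
    except IntegrationError:
        reports = []
    stable_eq = any(r.converged and r.stable and r.physical for r in reports)
    any_root = any(r.converged and r.physical for r in reports)
    if stable_eq:
        return {
            "classification": "stable_fixed",
            "laci_amplitude": np.nan, "gfp_amplitude": np.nan,
            "period": np.nan, "coexistence": False,
            "newton_root_found": True,
        }
    traj = integrate(system, system.initial_state(), t_end,
                     sample_interval=sample_interval, rtol=rtol, atol=atol)
    metrics = extract_oscillation_metrics(traj, amp_threshold=amp_threshold)
    oscillatory = metrics.oscillatory
    return {
        "classification": "oscillatory" if oscillatory else "stable_fixed",
        "laci_amplitude": metrics.amplitude.get("laci_free", np.nan)
        if oscillatory else np.nan,
        "gfp_amplitude": metrics.amplitude.get("gfp", np.nan)
        if oscillatory else np.nan,
        "period": metrics.period if oscillatory else np.nan,
        "coexistence": False,
        "newton_root_found": any_root,
    }


def _cell_job(args):
    config, params, condition, opts = args
    try:
        return classify_cell(config, params, condition, **opts)
    except (IntegrationError, ValueError) as exc:
        return {"classification": "failed", "laci_amplitude": np.nan,
                "gfp_amplitude": np.nan, "period": np.nan,
                "coexistence": False, "error": str(exc)}


def run_sweep(
    config: CircuitConfig,
    params: ParameterSet,
    spec: GridSpec,
    t_end: float = 1500.0,
    sample_interval: float = 1.0,
    amp_threshold: float = 1.0,
    rtol: float = 1e-6,
    atol: float = 1e-6,
    n_workers: int = 1,
) -> SweepResult:
    """Classify every cell of the inducer grid.

    Deterministic given (config, params, spec); cells are independent and
    can be distributed over ``n_workers`` processes.  Per-cell failures are
    recorded in the result, never aborting the grid.
    """
    conditions = make_grid(spec)
    opts = {"t_end": t_end, "sample_interval": sample_interval,
            "amp_threshold": amp_threshold, "rtol": rtol, "atol": atol}
    jobs = [(config, params, c, opts) for c in conditions]
    if n_workers > 1:
        with ProcessPoolExecutor(max_workers=n_workers) as pool:
            results = list(pool.map(_cell_job, jobs, chunksize=4))
    else:
        results = [_cell_job(j) for j in jobs]

    shape = spec.shape
    classification = np.empty(shape, dtype=object)
    laci = np.full(shape, np.nan)
    gfp = np.full(shape, np.nan)
    period = np.full(shape, np.nan)
    coex = np.zeros(shape, dtype=bool)
    failures = []
    for flat, (cond, res) in enumerate(zip(conditions, results)):
        i, j = divmod(flat, spec.n_iptg)
        classification[i, j] = res["classification"]
        laci[i, j] = res["laci_amplitude"]
        gfp[i, j] = res["gfp_amplitude"]
        period[i, j] = res["period"]
        coex[i, j] = res["coexistence"]
        if res["classification"] == "failed":
            failures.append({"arabinose": cond.arabinose, "iptg": cond.iptg,
                             "error": res.get("error", "")})
    return SweepResult(
        grid=spec,
        classification=classification.astype(str),
        laci_amplitude=laci,
        gfp_amplitude=gfp,
        period=period,
        coexistence=coex,
        fingerprint=_fingerprint(config, params, spec),
        failures=failures,
    )


def compare_sweeps(a: SweepResult, b: SweepResult) -> dict:
    """Set relations and amplitude deltas between two sweeps on one grid."""
    if a.grid != b.grid:
        raise ValueError("sweeps use different grids")
    osc_a, osc_b = a.oscillatory_mask, b.oscillatory_mask
    both = osc_a & osc_b
    deltas = np.abs(a.laci_amplitude - b.laci_amplitude)[both]
    return {
        "area_a": int(osc_a.sum()),
        "area_b": int(osc_b.sum()),
        "intersection": int(both.sum()),
        "only_a": int((osc_a & ~osc_b).sum()),
        "only_b": int((~osc_a & osc_b).sum()),
        "symmetric_difference": int((osc_a ^ osc_b).sum()),
        "max_laci_amplitude_delta": float(deltas.max()) if deltas.size else 0.0,
        "mean_laci_amplitude_delta": float(deltas.mean()) if deltas.size else 0.0,
    }
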
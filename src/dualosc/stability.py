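"""Equilibrium finding and linear stability classification.

Equilibria of the assembled ODE system are located with a damped
Newton-Raphson iteration; each converged root is classified by the real
parts of the Jacobian eigenvalues (an equilibrium is stable iff every real
part is negative).  A Routh-Hurwitz test on the characteristic polynomial
runs as an independent cross-check on small systems, where the polynomial
coefficients are well conditioned; the eigenvalue decision is always
primary and any disagreement is surfaced as a warning flag, never silently
resolved.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

#: scaled half-width of the band around zero inside which an eigenvalue
#: real part is treated as marginal rather than decisive
MARGINAL_BAND = 1e-8

#: dimension up to which the Routh-Hurwitz cross-check runs inside
#: classify_stability (characteristic-polynomial coefficients lose accuracy
#: rapidly with dimension)
ROUTH_MAX_DIM = 12


@dataclass
class EquilibriumReport:
    """One candidate equilibrium with its stability verdict."""

    point: np.ndarray
    residual_norm: float
    converged: bool
    eigenvalues: np.ndarray | None = None
    stable: bool | None = None
    marginal: bool = False
    physical: bool = True       # all coordinates nonnegative (within rounding)
    method_flags: dict = field(default_factory=dict)
    message: str = ""


def jacobian_at(system, point, method: str = "auto", rel_step: float = 1e-6):
    """Jacobian of ``system.rhs`` at ``point``.

    ``method="auto"`` uses the system's analytic Jacobian when it provides
    one and falls back to central finite differences otherwise;
    ``"fd"`` forces finite differences (step chosen relative to the state
    scale), ``"analytic"`` requires the analytic route.
    """
    point = np.asarray(point, dtype=float)
    has_analytic = hasattr(system, "jacobian")
    if method == "analytic" or (method == "auto" and has_analytic):
        if not has_analytic:
            raise ValueError("system provides no analytic jacobian")
        return np.asarray(system.jacobian(0.0, point))
    if method not in ("auto", "fd"):
        raise ValueError(f"unknown jacobian method {method!r}")
    rhs = system.rhs if hasattr(system, "rhs") else system
    n = point.size
    J = np.empty((n, n))
    for j in range(n):
        h = rel_step * max(1.0, abs(point[j]))
        e = np.zeros(n)
        e[j] = h
        J[:, j] = (np.asarray(rhs(0.0, point + e))
                   - np.asarray(rhs(0.0, point - e))) / (2.0 * h)
    return J


def routh_hurwitz_stable(coeffs) -> bool:
    """Routh-Hurwitz test: do all roots of the polynomial lie in Re(s)<0?

    ``coeffs`` are characteristic-polynomial coefficients, highest order
    first.  A zero first-column pivot is handled with the standard epsilon
    substitution; an all-zero row (symmetric root constellations, e.g. pure
    imaginary pairs) is replaced by the derivative of its auxiliary
    polynomial and the case is reported unstable/marginal (not strictly
    Hurwitz), which is correct for the strict test used here.
    """
    c = np.asarray(coeffs, dtype=float)
    c = np.trim_zeros(c, "f")
    if c.size == 0:
        raise ValueError("empty polynomial")
    if c[0] < 0:
        c = -c
    n = c.size - 1
    if n == 0:
        return True
    # necessary condition: all coefficients strictly positive
    if np.any(c <= 0):
        return False
    width = (n + 2) // 2
    rows = np.zeros((n + 1, width + 1))
    rows[0, : c[0::2].size] = c[0::2]
    rows[1, : c[1::2].size] = c[1::2]
    eps = 1e-12 * np.max(np.abs(c))
    for i in range(2, n + 1):
        prev, prev2 = rows[i - 1], rows[i - 2]
        if np.all(np.abs(prev) < eps):
            # auxiliary polynomial derivative (marginal constellation)
            order = n - (i - 2)
            aux = prev2[: (order // 2) + 1]
            powers = np.arange(order, -1, -2)[: aux.size]
            rows[i - 1, : aux.size] = aux * powers
            prev = rows[i - 1]
            if np.all(np.abs(prev) < eps):
                return False
        pivot = prev[0] if abs(prev[0]) > eps else eps
        for j in range(width):
            rows[i, j] = (pivot * prev2[j + 1] - prev2[0] * prev[j + 1]) / pivot
    first = rows[: n + 1, 0]
    first = np.where(np.abs(first) < eps, eps, first)
    return bool(np.all(first > 0))


def classify_stability(jacobian, marginal_band: float = MARGINAL_BAND,
                       constraints=None):
    """Classify an equilibrium from its Jacobian.

    Returns ``(label, eigenvalues, flags)`` with label in
    ``{"stable", "unstable", "marginal"}``.  The decision comes from the
    numerically computed eigenvalue real parts; on systems of dimension
    <= ``ROUTH_MAX_DIM`` a Routh-Hurwitz test on the characteristic
    polynomial cross-validates it and a disagreement raises a warning and
    is recorded in the flags.

    ``constraints`` is an optional matrix of exact linear invariants of the
    flow (rows ``c`` with ``c @ rhs == 0`` identically, e.g. promoter-copy
    conservation).  Each invariant contributes a structural zero eigenvalue
    that says nothing about stability on the invariant manifold, so the
    Jacobian is restricted to the manifold's tangent space (an invariant
    subspace) before the eigenvalues are read.
    """
    J = np.asarray(jacobian, dtype=float)
    if J.ndim != 2 or J.shape[0] != J.shape[1]:
        raise ValueError(f"jacobian must be square, got shape {J.shape}")
    if not np.all(np.isfinite(J)):
        raise ValueError("jacobian contains non-finite entries")
    if constraints is not None and np.size(constraints):
        from scipy.linalg import null_space

        B = null_space(np.atleast_2d(np.asarray(constraints, dtype=float)))
        J = B.T @ J @ B
    eig = np.linalg.eigvals(J)
    scale = max(1.0, float(np.max(np.abs(eig))) if eig.size else 1.0)
    max_re = float(np.max(eig.real))
    flags = {"decided_by": "eigenvalues"}
    if abs(max_re) < marginal_band * scale:
        return "marginal", eig, flags
    label = "stable" if max_re < 0 else "unstable"
    if J.shape[0] <= ROUTH_MAX_DIM:
        coeffs = np.poly(J)
        routh = routh_hurwitz_stable(coeffs)
        flags["routh_stable"] = routh
        if routh != (label == "stable"):
            flags["routh_disagrees"] = True
            warnings.warn(
                "Routh-Hurwitz cross-check disagrees with eigenvalue "
                f"classification ({label}); eigenvalue decision kept",
                RuntimeWarning,
            )
    return label, eig, flags


def _newton(system, guess, tol, max_iter, constraints=None):
    """Damped Newton-Raphson on system.rhs; returns (x, residual, ok, msg).

    With ``constraints`` (exact linear invariants), the Jacobian is
    structurally singular; the step is then the least-squares solution of
    the stacked system [J; C] s = [-f; 0], which keeps the iterate on the
    invariant manifold.
    """
    x = np.asarray(guess, dtype=float).copy()
    f = system.rhs(0.0, x)
    res = np.linalg.norm(f)
    for _ in range(max_iter):
        if res <= tol:
            return x, res, True, ""
        J = jacobian_at(system, x)
        try:
            if constraints is None:
                step = np.linalg.solve(J, -f)
            else:
                C = np.atleast_2d(constraints)
                A = np.vstack([J, C])
                rhs_vec = np.concatenate([-f, np.zeros(C.shape[0])])
                step, *_ = np.linalg.lstsq(A, rhs_vec, rcond=None)
        except np.linalg.LinAlgError:
            return x, res, False, "singular Jacobian during Newton iteration"
        lam, improved = 1.0, False
        for _bt in range(30):
            xn = x + lam * step
            fn = system.rhs(0.0, xn)
            rn = np.linalg.norm(fn)
            if rn < res:
                x, f, res, improved = xn, fn, rn, True
                break
            lam *= 0.5
        if not improved:
            return x, res, False, "line search stalled"
    ok = res <= tol
    return x, res, ok, "" if ok else "max iterations reached"


def find_equilibria(
    system,
    initial_guesses,
    tol: float = 1e-8,
    max_iter: int = 60,
    dedup_rtol: float = 1e-6,
) -> list[EquilibriumReport]:
    """Newton-Raphson roots of the RHS from a list of initial guesses.

    Converged roots are deduplicated (relative distance ``dedup_rtol``) and
    classified; guesses that fail to converge are returned as unconverged
    reports with a diagnostic message rather than dropped.

    When the system exposes a ``conservation_matrix`` (exact linear
    invariants such as promoter-copy sums), the Newton step respects the
    invariant manifold and stability is classified on it, discarding the
    structural zero eigenvalues.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    guesses = list(initial_guesses)
    if not guesses:
        raise ValueError("at least one initial guess is required")
    constraints = getattr(system, "conservation_matrix", None)
    roots: list[EquilibriumReport] = []
    failures: list[EquilibriumReport] = []
    for guess in guesses:
        x, res, ok, msg = _newton(system, guess, tol, max_iter,
                                  constraints=constraints)
        if not ok:
            failures.append(
                EquilibriumReport(point=x, residual_norm=res,
                                  converged=False, message=msg)
            )
            continue
        scale = max(1.0, float(np.linalg.norm(x)))
        if any(
            np.linalg.norm(x - r.point) <= dedup_rtol * scale for r in roots
        ):
            continue
        J = jacobian_at(system, x)
        label, eig, flags = classify_stability(J, constraints=constraints)
        # a state-space root with negative molecule counts is a formal
        # solution of the rate equations, never a biological steady state
        physical = bool(x.min() >= -1e-6 * max(1.0, float(np.abs(x).max())))
        roots.append(
            EquilibriumReport(
                point=x,
                residual_norm=res,
                converged=True,
                eigenvalues=eig,
                stable=(label == "stable"),
                marginal=(label == "marginal"),
                physical=physical,
                method_flags=flags,
            )
        )
    return roots + failures


def equilibria_to_frame(reports: list[EquilibriumReport], state_names=None):
    """Tabular summary (one row per report) for serialization."""
    import pandas as pd

    rows = []
    for r in reports:
        row = {
            "converged": r.converged,
            "residual_norm": r.residual_norm,
            "stable": r.stable,
            "marginal": r.marginal,
            "max_re_eig": (float(np.max(r.eigenvalues.real))
                           if r.eigenvalues is not None else np.nan),
            "message": r.message,
        }
        names = (state_names if state_names is not None
                 else [f"x{i}" for i in range(r.point.size)])
        row.update({n: v for n, v in zip(names, r.point)})
        rows.append(row)
    return pd.DataFrame(rows)
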
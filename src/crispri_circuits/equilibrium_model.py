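"""Steady-state mass-action model of dCas9:sgRNA:promoter binding.

The CRISPRi repressor forms in two reversible steps: dCas9 (``C``) binds an
sgRNA (``g``) with dissociation constant ``K1`` to give the complex ``C:g``,
which then binds the free target promoter DNA (``D``) with dissociation
constant ``K2`` to give the transcriptionally silent ``C:g:D``.  Binding is
assumed fast relative to synthesis, degradation and dilution, so at steady
state the free concentrations satisfy the implicit system

.. math::

    C = \\frac{C_{tot}}{1 + g/K_1 + g D/(K_1 K_2)}, \\qquad
    g = \\frac{g_{tot}}{1 + C/K_1 + C D/(K_1 K_2)}, \\qquad
    D = \\frac{D_{tot}}{1 + g C/(K_1 K_2)},

with reporter output ``R = theta * D`` (the repressed promoter is assumed
fully silent).  All concentrations are in nM; in E. coli 1 nM corresponds to
roughly one molecule per cell, so plasmid copy number maps directly onto
``Dtot``.

Two independent solvers are provided: a damped sequential fixed-point
iteration (:func:`solve_equilibrium`) and a nested-bisection root finder on
the equivalent two-unknown polynomial system (:func:`solve_equilibrium_oracle`)
that serves as ground truth in tests.  The explicit Michaelis-Menten-style
limit valid for ``g >> C >> D`` is :func:`explicit_output`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "BindingParams",
    "SpeciesTotals",
    "EquilibriumState",
    "TransferCurve",
    "solve_equilibrium",
    "solve_equilibrium_oracle",
    "explicit_output",
    "sweep_transfer_curve",
    "switch_point",
]


def _require_finite_nonneg(name: str, value: float, strict: bool = False) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value!r}")
    if strict and value <= 0:
        raise ValueError(f"{name} must be > 0, got {value!r}")
    if value < 0:
        raise ValueError(f"{name} must be >= 0, got {value!r}")
    return value


@dataclass(frozen=True)
class BindingParams:
    """Dissociation constants and output gain of the binding model.

    Parameters
    ----------
    K1 : float
        Dissociation constant of dCas9 + sgRNA binding, nM.
    K2 : float
        Dissociation constant of complex + promoter DNA binding, nM.
    theta : float, default 1.0
        Lumped gain mapping free promoter DNA (nM) to reporter output (AU),
        absorbing transcription, translation, maturation, degradation and
        dilution.  With the default 1.0 the output equals free DNA.
    """

    K1: float
    K2: float
    theta: float = 1.0

    def __post_init__(self) -> None:
        _require_finite_nonneg("K1", self.K1, strict=True)
        _require_finite_nonneg("K2", self.K2, strict=True)
        _require_finite_nonneg("theta", self.theta)


@dataclass(frozen=True)
class SpeciesTotals:
    """Total intracellular concentrations of the three species, nM."""

    Ctot: float
    gtot: float
    Dtot: float

    def __post_init__(self) -> None:
        _require_finite_nonneg("Ctot", self.Ctot)
        _require_finite_nonneg("gtot", self.gtot)
        _require_finite_nonneg("Dtot", self.Dtot)


@dataclass(frozen=True)
class EquilibriumState:
    """Free and bound concentrations (nM) at binding equilibrium.

    ``C + Cg + CgD == Ctot``, ``g + Cg + CgD == gtot`` and
    ``D + CgD == Dtot`` hold to the solver tolerance, as do the mass-action
    relations ``K1*Cg == C*g`` and ``K2*CgD == Cg*D``.  ``R = theta * D``.
    """

    C: float
    g: float
    D: float
    Cg: float
    CgD: float
    R: float
    converged: bool = True
    iterations: int = 0

    def conservation_residuals(self, totals: SpeciesTotals) -> tuple[float, float, float]:
        """Relative residuals of the three conservation laws."""
        rC = abs(self.C + self.Cg + self.CgD - totals.Ctot) / max(1.0, totals.Ctot)
        rg = abs(self.g + self.Cg + self.CgD - totals.gtot) / max(1.0, totals.gtot)
        rD = abs(self.D + self.CgD - totals.Dtot) / max(1.0, totals.Dtot)
        return rC, rg, rD

    def mass_action_residuals(self, params: BindingParams) -> tuple[float, float]:
        """Relative residuals of the two dissociation relations."""
        r1 = abs(params.K1 * self.Cg - self.C * self.g) / max(1.0, params.K1 * self.Cg)
        r2 = abs(params.K2 * self.CgD - self.Cg * self.D) / max(1.0, params.K2 * self.CgD)
        return r1, r2


@dataclass
class TransferCurve:
    """An input grid with aligned steady-state outputs.

    The common currency between the equilibrium model, Hill fitting and the
    synthetic-data generator: ``input_values`` must be strictly increasing
    and aligned with ``output_values``.  For ``output_name='D_over_Dtot'``
    outputs lie in [0, 1].
    """

    input_name: str
    input_values: np.ndarray
    output_name: str
    output_values: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.input_values = np.asarray(self.input_values, dtype=float)
        self.output_values = np.asarray(self.output_values, dtype=float)
        if self.input_values.shape != self.output_values.shape:
            raise ValueError("input and output grids must be aligned")
        if self.input_values.ndim != 1 or self.input_values.size < 2:
            raise ValueError("need a 1-D grid of at least 2 points")
        if np.any(np.diff(self.input_values) <= 0):
            raise ValueError("input grid must be strictly increasing")


def _state_from_free(
    params: BindingParams, C: float, g: float, D: float, converged: bool, iterations: int
) -> EquilibriumState:
    Cg = C * g / params.K1
    CgD = Cg * D / params.K2
    return EquilibriumState(
        C=C, g=g, D=D, Cg=Cg, CgD=CgD, R=params.theta * D,
        converged=converged, iterations=iterations,
    )


def _single_binding_complex(K: float, Atot: float, Btot: float) -> float:
    """Smaller root of x^2 - (Atot+Btot+K) x + Atot*Btot = 0.

    Equilibrium complex concentration for a single reversible binding step.
    Written in the product form to stay accurate when the root is tiny.
    """
    s = Atot + Btot + K
    disc = math.sqrt(max(s * s - 4.0 * Atot * Btot, 0.0))
    return 2.0 * Atot * Btot / (s + disc)


def _trivial_state(params: BindingParams, totals: SpeciesTotals) -> EquilibriumState | None:
    """Analytic solutions for boundary cases, avoiding 0/0 in the iteration."""
    Ctot, gtot, Dtot = totals.Ctot, totals.gtot, totals.Dtot
    if Ctot == 0.0 or gtot == 0.0:
        return _state_from_free(params, Ctot, gtot, Dtot, True, 0)
    if Dtot == 0.0:
        Cg = _single_binding_complex(params.K1, Ctot, gtot)
        return _state_from_free(params, Ctot - Cg, gtot - Cg, 0.0, True, 0)
    return None


def solve_equilibrium(
    params: BindingParams,
    totals: SpeciesTotals,
    tol: float = 1e-9,
    max_iter: int = 100_000,
) -> EquilibriumState:
    """Solve the implicit steady-state system by damped fixed-point iteration.

    The three update equations are applied sequentially in the order C, g, D,
    each using the latest values, starting from the all-free state
    ``(Ctot, gtot, Dtot)``.  If the undamped iteration oscillates, a damping
    factor of 0.5 is switched on automatically.  Convergence is declared when
    the maximum relative change across (C, g, D) drops below ``tol``.  If the
    iteration does not converge within ``max_iter`` steps the nested-bisection
    oracle result is returned with ``converged=False`` and a logged warning.

    Parameters
    ----------
    params : BindingParams
    totals : SpeciesTotals
    tol : float
        Relative convergence tolerance, > 0.
    max_iter : int
        Iteration budget before falling back to the oracle.
    """
    if tol <= 0:
        raise ValueError("tol must be > 0")
    shortcut = _trivial_state(params, totals)
    if shortcut is not None:
        return shortcut

    K1, K2 = params.K1, params.K2
    Ctot, gtot, Dtot = totals.Ctot, totals.gtot, totals.Dtot
    C, g, D = Ctot, gtot, Dtot
    damping = 1.0
    prev_delta = math.inf
    for it in range(1, max_iter + 1):
        C_old, g_old, D_old = C, g, D
        C = damping * (Ctot / (1.0 + g / K1 + g * D / (K1 * K2))) + (1.0 - damping) * C
        g = damping * (gtot / (1.0 + C / K1 + C * D / (K1 * K2))) + (1.0 - damping) * g
        D = damping * (Dtot / (1.0 + g * C / (K1 * K2))) + (1.0 - damping) * D
        delta = max(
            abs(C - C_old) / max(C, 1e-300),
            abs(g - g_old) / max(g, 1e-300),
            abs(D - D_old) / max(D, 1e-300),
        )
        if delta < tol:
            return _state_from_free(params, C, g, D, True, it)
        # growing step size signals oscillation around the root
        if damping == 1.0 and delta > prev_delta and it > 10:
            damping = 0.5
        prev_delta = delta

    logger.warning(
        "fixed-point iteration did not converge in %d steps for totals=%s; "
        "falling back to nested-bisection solve", max_iter, totals,
    )
    oracle = solve_equilibrium_oracle(params, totals)
    return EquilibriumState(
        C=oracle.C, g=oracle.g, D=oracle.D, Cg=oracle.Cg, CgD=oracle.CgD,
        R=oracle.R, converged=False, iterations=max_iter,
    )


def solve_equilibrium_oracle(
    params: BindingParams, totals: SpeciesTotals
) -> EquilibriumState:
    """Solve the same equilibrium via nested bisection on the polynomial form.

    With ``x = Cg`` and ``y = CgD`` the system reduces to

    ``K1*x = (Ctot - x - y)(gtot - x - y)`` and ``K2*y = x*(Dtot - y)``.

    For fixed ``y`` the first equation is a quadratic in ``x`` solved in
    closed form (smaller root); the outer residual ``K2*y - x(y)*(Dtot - y)``
    is strictly increasing on ``y in [0, min(Ctot, gtot, Dtot)]`` and is
    bisected to machine precision.  Independent of the fixed-point path, this
    serves as ground truth in tests and as the non-convergence fallback.
    """
    shortcut = _trivial_state(params, totals)
    if shortcut is not None:
        return shortcut

    K1, K2 = params.K1, params.K2
    Ctot, gtot, Dtot = totals.Ctot, totals.gtot, totals.Dtot

    def x_of_y(y: float) -> float:
        return _single_binding_complex(K1, Ctot - y, gtot - y)

    def resid(y: float) -> float:
        return K2 * y - x_of_y(y) * (Dtot - y)

    lo, hi = 0.0, min(Ctot, gtot, Dtot)
    # resid(lo) <= 0 and resid(hi) >= 0; bisect until the interval collapses
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if mid == lo or mid == hi:
            break
        if resid(mid) < 0.0:
            lo = mid
        else:
            hi = mid
    y = 0.5 * (lo + hi)
    x = x_of_y(y)
    return EquilibriumState(
        C=Ctot - x - y, g=gtot - x - y, D=Dtot - y, Cg=x, CgD=y,
        R=params.theta * (Dtot - y), converged=True, iterations=0,
    )


def explicit_output(params: BindingParams, totals: SpeciesTotals) -> float:
    """Explicit reporter output under the ``g >> C >> D`` abundance regime.

    .. math::

        R = \\frac{\\theta D_{tot}}{1 + \\dfrac{C_{tot}/K_2}{1 + 1/(g_{tot}/K_1)}}

    evaluated in the equivalent form
    ``theta*Dtot / (1 + Ctot*gtot / (K2*(K1 + gtot)))`` which is finite at
    ``gtot = 0`` (where it reduces to ``theta*Dtot``).  Only valid when sgRNA
    is abundant over dCas9 and dCas9 over DNA; outside that regime use
    :func:`solve_equilibrium`.
    """
    repression = totals.Ctot * totals.gtot / (params.K2 * (params.K1 + totals.gtot))
    return params.theta * totals.Dtot / (1.0 + repression)


def sweep_transfer_curve(
    params: BindingParams,
    fixed: SpeciesTotals,
    sweep_field: Literal["Ctot", "gtot", "Dtot"],
    grid: np.ndarray,
    solver=solve_equilibrium,
) -> TransferCurve:
    """Sweep one total concentration over a grid, solving at each point.

    Returns a :class:`TransferCurve` of the free-DNA fraction ``D/Dtot``
    (the quantity plotted in repression-curve panels).  The full state at
    each grid point is kept in ``metadata['states']``.
    """
    if sweep_field not in ("Ctot", "gtot", "Dtot"):
        raise ValueError(f"unknown sweep field {sweep_field!r}")
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size < 2 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be 1-D, strictly increasing, >= 2 points")

    states: list[EquilibriumState] = []
    fractions = np.empty_like(grid)
    for i, value in enumerate(grid):
        kwargs = {"Ctot": fixed.Ctot, "gtot": fixed.gtot, "Dtot": fixed.Dtot}
        kwargs[sweep_field] = float(value)
        totals = SpeciesTotals(**kwargs)
        try:
            state = solver(params, totals)
        except Exception as exc:  # identify the offending grid point
            raise RuntimeError(
                f"equilibrium solve failed at {sweep_field}={value:g} nM"
            ) from exc
        states.append(state)
        fractions[i] = state.D / totals.Dtot if totals.Dtot > 0 else 1.0

    return TransferCurve(
        input_name=sweep_field,
        input_values=grid,
        output_name="D_over_Dtot",
        output_values=fractions,
        metadata={
            "params": params,
            "fixed": fixed,
            "states": states,
        },
    )


@dataclass(frozen=True)
class SwitchPoint:
    """Result of a switch-point search; ``value`` is None when no crossing."""

    value: float | None
    level: float

    @property
    def found(self) -> bool:
        return self.value is not None


def switch_point(curve: TransferCurve, level: float = 0.5) -> SwitchPoint:
    """Input value at which a normalized repression curve crosses ``level``.

    Scans the curve for the first pair of adjacent grid points bracketing
    ``level`` and interpolates linearly in log10 of the input (transfer
    curves are read on log-input axes).  Grid points exactly at ``level``
    are returned as-is.  If the curve never crosses, a
    :class:`SwitchPoint` with ``value=None`` is returned — an explicit
    no-crossing result rather than an exception or a fake number.
    """
    x = curve.input_values
    y = curve.output_values
    for i in range(len(x) - 1):
        y0, y1 = y[i], y[i + 1]
        if y0 == level:
            return SwitchPoint(float(x[i]), level)
        if (y0 - level) * (y1 - level) < 0:
            if x[i] <= 0:  # cannot take log of a zero input; fall back to linear
                frac = (level - y0) / (y1 - y0)
                return SwitchPoint(float(x[i] + frac * (x[i + 1] - x[i])), level)
            lx0, lx1 = math.log10(x[i]), math.log10(x[i + 1])
            frac = (level - y0) / (y1 - y0)
            return SwitchPoint(float(10.0 ** (lx0 + frac * (lx1 - lx0))), level)
    if y[-1] == level:
        return SwitchPoint(float(x[-1]), level)
    return SwitchPoint(None, level)
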
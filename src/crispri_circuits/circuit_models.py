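"""Hill-equation circuit stages and their composition into logic gates.

Each regulatory stage — an inducible expression device or a transcriptional
repression — is modelled by a four-parameter Hill function:

* activation:  ``y = basal + range * x^n / (Km^n + x^n)``
* repression:  ``y = basal + range / (1 + (x/Km)^n)``

Stages compose by feeding one stage's output into the next (transcriptional
cascades), by mapping an inducer onto sgRNA level and handing repression to
the mass-action equilibrium model (a CRISPRi NOT gate), or by two repressors
acting on one promoter with mutually exclusive binding, giving the
multiplicative NOR composition

``y(a, b) = basal + range * f1(a) * f2(b)`` with
``fi(x) = 1 / (1 + (x/Km_i)^{n_i})``.

Stage parameters are estimated component-wise from individual transfer
curves (:func:`fit_stage`), by least squares on the log of the output —
outputs span decades — with a deterministic multi-start grid.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import least_squares

from crispri_circuits.equilibrium_model import (
    BindingParams,
    SpeciesTotals,
    TransferCurve,
    solve_equilibrium,
)

__all__ = [
    "HillStage",
    "CrispriStage",
    "CircuitModel",
    "FitResult",
    "hill_eval",
    "cascade_predict",
    "crispri_not_predict",
    "nor_predict",
    "fit_stage",
    "fit_cascade",
]

StageKind = Literal["activation", "repression"]


@dataclass(frozen=True)
class HillStage:
    """One Hill-type input/output stage.

    Parameters
    ----------
    kind : {'activation', 'repression'}
    basal : float
        Output floor, AU (>= 0).
    range : float
        Output span above the floor, AU (>= 0).
    Km : float
        Half-effect input concentration, input units (> 0).
    n : float
        Hill coefficient (> 0).
    """

    kind: StageKind
    basal: float
    range: float
    Km: float
    n: float

    def __post_init__(self) -> None:
        if self.kind not in ("activation", "repression"):
            raise ValueError(f"unknown stage kind {self.kind!r}")
        if self.basal < 0 or self.range < 0:
            raise ValueError("basal and range must be >= 0")
        if not (self.Km > 0 and self.n > 0):
            raise ValueError("Km and n must be > 0")


@dataclass(frozen=True)
class CrispriStage:
    """An inducer→sgRNA activation stage wired into the equilibrium model.

    ``activation`` maps inducer concentration to total sgRNA (gtot, nM);
    the repression of the target promoter is then computed mechanistically
    by :func:`~crispri_circuits.equilibrium_model.solve_equilibrium` with
    ``params``/``totals`` (the ``gtot`` field of ``totals`` is overridden).
    """

    activation: HillStage
    params: BindingParams
    totals: SpeciesTotals

    def __post_init__(self) -> None:
        if self.activation.kind != "activation":
            raise ValueError("CRISPRi stage needs an activation Hill stage for sgRNA")


@dataclass
class CircuitModel:
    """An ordered cascade of stages, or a 2-input NOR configuration.

    ``topology='cascade'``: ``stages`` are applied input→output in order.
    ``topology='nor'``: exactly two parallel repression stages act on one
    promoter; ``basal``/``range`` give the shared output scale.
    ``crispri_stage``, when present, replaces the *first* cascade stage by a
    mechanistic CRISPRi inverter.
    """

    topology: Literal["cascade", "nor"]
    stages: list[HillStage] = field(default_factory=list)
    crispri_stage: CrispriStage | None = None
    basal: float = 0.0
    range: float = 1.0

    def __post_init__(self) -> None:
        if self.topology == "nor":
            if len(self.stages) != 2:
                raise ValueError("NOR gate needs exactly 2 parallel input stages")
            if any(s.kind != "repression" for s in self.stages):
                raise ValueError("NOR inputs must be repression stages")
        elif self.topology == "cascade":
            if not self.stages and self.crispri_stage is None:
                raise ValueError("cascade needs at least one stage")
        else:
            raise ValueError(f"unknown topology {self.topology!r}")

    # -- serialization --------------------------------------------------
    SCHEMA_VERSION = 1

    def to_dict(self) -> dict:
        d: dict = {
            "schema_version": self.SCHEMA_VERSION,
            "topology": self.topology,
            "stages": [vars(s) | {} for s in self.stages],
            "basal": self.basal,
            "range": self.range,
        }
        if self.crispri_stage is not None:
            cs = self.crispri_stage
            d["crispri_stage"] = {
                "activation": dict(vars(cs.activation)),
                "params": dict(vars(cs.params)),
                "totals": dict(vars(cs.totals)),
            }
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "CircuitModel":
        if d.get("schema_version") != cls.SCHEMA_VERSION:
            raise ValueError("unsupported model schema version")
        crispri = None
        if "crispri_stage" in d:
            cs = d["crispri_stage"]
            crispri = CrispriStage(
                activation=HillStage(**cs["activation"]),
                params=BindingParams(**cs["params"]),
                totals=SpeciesTotals(**cs["totals"]),
            )
        return cls(
            topology=d["topology"],
            stages=[HillStage(**s) for s in d["stages"]],
            crispri_stage=crispri,
            basal=d.get("basal", 0.0),
            range=d.get("range", 1.0),
        )

    @classmethod
    def from_json(cls, path) -> "CircuitModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class FitResult:
    """Outcome of a stage fit: estimates, residual and convergence flag."""

    estimates: dict[str, float]
    residual_norm: float
    n_points: int
    converged: bool

    @property
    def stage(self) -> HillStage:
        return HillStage(kind=self.estimates["kind"], **{
            k: v for k, v in self.estimates.items() if k != "kind"
        })


def hill_eval(stage: HillStage, x) -> np.ndarray | float:
    """Evaluate a Hill stage at input ``x`` (scalar or array, >= 0)."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("inputs must be >= 0")
    ratio = (x / stage.Km) ** stage.n
    if stage.kind == "activation":
        out = stage.basal + stage.range * ratio / (1.0 + ratio)
    else:
        out = stage.basal + stage.range / (1.0 + ratio)
    return out if out.ndim else float(out)


def cascade_predict(model: CircuitModel, inducer) -> np.ndarray | float:
    """Output of a cascade: each stage's output feeds the next stage.

    If a ``crispri_stage`` is present it acts as the first stage: inducer →
    sgRNA level → mechanistic repression output; any remaining Hill stages
    are applied downstream.  Two sequential repressions make the overall
    response increase with the inducer (an inverter of an inverter).
    """
    if model.topology != "cascade":
        raise ValueError("cascade_predict requires a cascade model")
    scalar = np.isscalar(inducer) or np.ndim(inducer) == 0
    signal = np.atleast_1d(np.asarray(inducer, dtype=float))
    stages = list(model.stages)
    if model.crispri_stage is not None:
        signal = np.atleast_1d(crispri_not_predict(model, signal))
    elif not stages:
        raise ValueError("empty cascade")
    for stage in stages:
        signal = np.atleast_1d(hill_eval(stage, signal))
    return float(signal[0]) if scalar else signal


def crispri_not_predict(model: CircuitModel, inducer) -> np.ndarray | float:
    """CRISPRi NOT gate: inducer → sgRNA (Hill activation) → equilibrium R.

    The activation stage sets ``gtot``; the binding equilibrium with the
    stage's dCas9/DNA totals then determines free promoter DNA and the
    reporter output ``R = theta * D``.
    """
    cs = model.crispri_stage
    if cs is None:
        raise ValueError("model has no CRISPRi stage")
    scalar = np.isscalar(inducer) or np.ndim(inducer) == 0
    inducer = np.atleast_1d(np.asarray(inducer, dtype=float))
    gtot = np.atleast_1d(hill_eval(cs.activation, inducer))
    out = np.empty_like(gtot)
    for i, g in enumerate(gtot):
        totals = SpeciesTotals(Ctot=cs.totals.Ctot, gtot=float(g), Dtot=cs.totals.Dtot)
        out[i] = solve_equilibrium(cs.params, totals).R
    return float(out[0]) if scalar else out


def nor_predict(model: CircuitModel, in1, in2) -> np.ndarray | float:
    """2-input NOR output: high only when both inputs are low.

    Mutually exclusive binding of the two repressors on one promoter gives
    the multiplicative composition
    ``basal + range * f1(in1) * f2(in2)`` with normalized repression terms
    ``fi(x) = 1 / (1 + (x/Km_i)^{n_i})``.
    """
    if model.topology != "nor":
        raise ValueError("nor_predict requires a NOR model")
    s1, s2 = model.stages

    def f(stage: HillStage, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return 1.0 / (1.0 + (x / stage.Km) ** stage.n)

    out = model.basal + model.range * f(s1, in1) * f(s2, in2)
    out = np.asarray(out)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# fitting


def _hill_model(kind: StageKind, x: np.ndarray, p: np.ndarray) -> np.ndarray:
    basal, rng, Km, n = p
    ratio = (x / Km) ** n
    if kind == "activation":
        return basal + rng * ratio / (1.0 + ratio)
    return basal + rng / (1.0 + ratio)


def fit_stage(
    data: TransferCurve,
    kind: StageKind,
    bounds: dict[str, tuple[float, float]] | None = None,
    replicate_outputs: Sequence[np.ndarray] | None = None,
) -> FitResult:
    """Fit a four-parameter Hill stage to a transfer curve.

    Least squares is performed on ``log(output + eps)`` with
    ``eps = 1e-6 * max(output)`` and uniform weights, since measured outputs
    span decades.  Optimization restarts from 8 deterministic initial
    guesses — Km placed at four log-spaced positions across the non-zero
    input range crossed with Hill coefficients {1, 3} — and the best
    residual wins, ties broken toward the smaller fitted ``n``.

    ``replicate_outputs`` may supply additional aligned output vectors
    (replicate measurements); all replicates enter the residual jointly.
    Requires at least 4 distinct input values (the model has 4 free
    parameters); all-zero outputs are rejected.
    """
    x = np.asarray(data.input_values, dtype=float)
    y_sets = [np.asarray(data.output_values, dtype=float)]
    if replicate_outputs is not None:
        y_sets += [np.asarray(y, dtype=float) for y in replicate_outputs]
    if len(np.unique(x)) < 4:
        raise ValueError("need >= 4 distinct input values for a 4-parameter fit")
    y_all = np.concatenate(y_sets)
    if not np.any(y_all > 0):
        raise ValueError("all outputs are zero; nothing to fit")

    eps = 1e-6 * y_all.max()
    log_targets = [np.log(np.clip(y, 0.0, None) + eps) for y in y_sets]

    x_pos = x[x > 0]
    lo_b = {"basal": 0.0, "range": 0.0, "Km": x_pos.min() * 1e-3, "n": 0.05}
    hi_b = {
        "basal": y_all.max(),
        "range": 10.0 * y_all.max(),
        "Km": x_pos.max() * 1e3,
        "n": 8.0,
    }
    if bounds:
        for k, (lo, hi) in bounds.items():
            lo_b[k], hi_b[k] = lo, hi
    lb = np.array([lo_b[k] for k in ("basal", "range", "Km", "n")])
    ub = np.array([hi_b[k] for k in ("basal", "range", "Km", "n")])

    def residuals(p: np.ndarray) -> np.ndarray:
        pred = np.log(np.clip(_hill_model(kind, x, p), 0.0, None) + eps)
        return np.concatenate([pred - t for t in log_targets])

    y_mean = np.mean(y_sets, axis=0)
    basal0 = max(float(y_mean.min()), eps)
    range0 = max(float(y_mean.max() - y_mean.min()), eps)
    km_grid = np.geomspace(x_pos.min(), x_pos.max(), 4)
    best: tuple[float, float, np.ndarray] | None = None  # (cost, n, params)
    converged = False
    for km0 in km_grid:
        for n0 in (1.0, 3.0):
            p0 = np.clip(np.array([basal0, range0, km0, n0]), lb, ub)
            sol = least_squares(residuals, p0, bounds=(lb, ub), method="trf")
            key = (sol.cost, sol.x[3])
            if best is None or key < (best[0], best[1]):
                best = (sol.cost, sol.x[3], sol.x)
                converged = bool(sol.success)
    assert best is not None
    p = best[2]
    return FitResult(
        estimates={
            "kind": kind,
            "basal": float(p[0]),
            "range": float(p[1]),
            "Km": float(p[2]),
            "n": float(p[3]),
        },
        residual_norm=float(2.0 * best[0]),
        n_points=int(x.size * len(y_sets)),
        converged=converged,
    )


def fit_cascade(
    stage_datasets: Sequence[TransferCurve],
    topology: Sequence[StageKind] | Literal["nor"],
    bounds: dict[str, tuple[float, float]] | None = None,
) -> CircuitModel:
    """Fit each stage to its own transfer curve, then compose.

    Stages are estimated independently (component-wise) and assembled
    without a joint refit.  ``topology`` is either a sequence of stage
    kinds, one per dataset and ordered input→output, or the string
    ``'nor'`` for two parallel repression datasets; in the NOR case the
    shared output scale is taken from the first fitted stage
    (``basal``, ``range``) and both stages are normalized.
    """
    if topology == "nor":
        if len(stage_datasets) != 2:
            raise ValueError("NOR topology needs exactly 2 stage datasets")
        fits = [fit_stage(d, "repression", bounds=bounds) for d in stage_datasets]
        scale = fits[0].estimates
        return CircuitModel(
            topology="nor",
            stages=[f.stage for f in fits],
            basal=scale["basal"],
            range=scale["range"],
        )
    kinds = list(topology)
    if len(kinds) != len(stage_datasets):
        raise ValueError(
            f"{len(kinds)} stage kinds but {len(stage_datasets)} datasets"
        )
    fits = [fit_stage(d, k, bounds=bounds) for d, k in zip(stage_datasets, kinds)]
    return CircuitModel(topology="cascade", stages=[f.stage for f in fits])
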
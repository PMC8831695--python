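"""Ground-truth generators for plate kinetics and transfer curves.

No raw measurements ship with the package; every pipeline stage is instead
exercised on synthetic data whose generating parameters are known exactly
and written alongside the data.  Two generators are provided:

* :func:`generate_plate` emulates a 96-well kinetic assay: logistic growth
  with lag, fluorescence accumulating in proportion to biomass at a constant
  true per-cell synthesis rate, additive instrument background, and
  multiplicative lognormal read noise.  Blank-medium, autofluorescence-
  control and reference wells are always included so the plate-kinetics
  reduction runs end to end.
* :func:`generate_curve` evaluates either a Hill stage or an equilibrium-
  model sweep on an inducer/sgRNA grid and adds per-replicate lognormal
  noise, producing the tidy curve CSV consumed by the fitting routines.

Identical seed and configuration give byte-identical output files.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from crispri_circuits.circuit_models import HillStage, hill_eval
from crispri_circuits.equilibrium_model import (
    BindingParams,
    SpeciesTotals,
    TransferCurve,
    sweep_transfer_curve,
)

__all__ = [
    "WellTruth",
    "PlateTruth",
    "CurveTruth",
    "generate_plate",
    "generate_curve",
    "default_hsl_grid",
    "default_iptg_grid",
]

#: default inducer grids matching the assay ranges: HSL 0.1–500 nM and
#: IPTG 0.1–100 µM (stored in nM), each preceded by a zero point.
def default_hsl_grid(points: int = 8) -> np.ndarray:
    return np.concatenate([[0.0], np.geomspace(0.1, 500.0, points)])


def default_iptg_grid(points: int = 8) -> np.ndarray:
    return np.concatenate([[0.0], np.geomspace(100.0, 100_000.0, points)])


@dataclass(frozen=True)
class WellTruth:
    """Generating parameters of one sample/reference well."""

    strain: str
    role: str = "sample"                      # sample | reference
    mu_true: float = 0.7                      # 1/h
    carrying_capacity: float = 1.0            # OD600
    od0: float = 0.002                        # inoculum OD above background
    lag_min: float = 60.0
    s_true: dict[str, float] = field(
        default_factory=lambda: {"RFP": 50.0, "GFP": 30.0}
    )                                         # AU·OD⁻¹·min⁻¹
    inducer: str = ""
    conc_nM: float = 0.0

    def __post_init__(self) -> None:
        if self.mu_true < 0 or self.carrying_capacity <= 0 or self.od0 <= 0:
            raise ValueError("growth parameters must be positive")
        if any(s < 0 for s in self.s_true.values()):
            raise ValueError("synthesis rates must be >= 0")


@dataclass(frozen=True)
class PlateTruth:
    """Plate-level generating configuration.

    ``autofluo_per_od`` is the strain-independent autofluorescence emitted
    per unit biomass in each channel; the autofluorescence-control wells
    carry exactly this signal and nothing else, so the OD-matched correction
    can remove it from every sample.  It defaults to zero — the base signal
    model is fluorescence accumulating from synthesis plus a constant
    instrument background — and the OD-matched correction is only exact
    when control and sample share growth kinetics, so enable it
    deliberately when exercising that pathway.
    """

    wells: dict[str, WellTruth]
    background_od: float = 0.04
    background_fluo: dict[str, float] = field(
        default_factory=lambda: {"RFP": 120.0, "GFP": 200.0}
    )
    autofluo_per_od: dict[str, float] = field(
        default_factory=lambda: {"RFP": 0.0, "GFP": 0.0}
    )
    noise_cv: float = 0.0
    seed: int = 0
    n_blanks: int = 3
    n_autofluor: int = 3

    def __post_init__(self) -> None:
        if not 0.0 <= self.noise_cv <= 0.2:
            raise ValueError("noise_cv must be in [0, 0.2]")
        if not self.wells:
            raise ValueError("plate needs at least one sample well")


def _logistic_od(t_min: np.ndarray, w: WellTruth) -> np.ndarray:
    """Three-parameter logistic growth with a lag offset, OD above background."""
    te = np.clip(t_min - w.lag_min, 0.0, None) / 60.0  # effective hours
    K, x0 = w.carrying_capacity, w.od0
    growth = np.exp(w.mu_true * te)
    return K * x0 * growth / (K - x0 + x0 * growth)


def _lognormal_factor(rng: np.random.Generator, cv: float, shape) -> np.ndarray:
    if cv == 0.0:
        return np.ones(shape)
    sigma = np.sqrt(np.log(1.0 + cv**2))
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=shape)


def generate_plate(
    truth: PlateTruth,
    duration_min: float = 1080.0,
    sample_min: float = 5.0,
    out_dir: str | Path | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Simulate a kinetic plate read; optionally write the three artifacts.

    Per well: ``OD_raw(t) = OD_true(t) + background_od``, noised;
    ``F_raw(t)`` integrates ``(s_true + autofluo_per_od)·OD_true`` by the
    trapezoidal rule, plus the constant instrument background, noised.
    Control wells are appended automatically: blank-medium wells carry
    backgrounds only; autofluorescence-control wells grow like a median
    sample but express no fluorophore beyond autofluorescence.

    Returns ``(plate, wellmap, truth_record)`` — the two tidy DataFrames in
    the CSV dialects consumed by :mod:`~crispri_circuits.plate_kinetics`
    plus a JSON-serializable record of every generating parameter.  With
    ``out_dir`` set, writes ``plate.csv``, ``wellmap.csv``, ``truth.json``.
    """
    if duration_min < 360.0:
        raise ValueError("simulate at least 6 h of growth")
    rng = np.random.default_rng(truth.seed)
    t = np.arange(0.0, duration_min + 0.5 * sample_min, sample_min)
    channels = sorted(truth.background_fluo)

    rows = []
    map_rows = []

    def emit(well_id: str, role: str, strain: str, od_true: np.ndarray,
             s_per_od: dict[str, float], inducer: str = "", conc: float = 0.0) -> None:
        # multiplicative noise perturbs the biological signal; the additive
        # instrument background is a stable offset removed exactly by blanks
        od_raw = od_true * _lognormal_factor(
            rng, truth.noise_cv, t.shape
        ) + truth.background_od
        series = {"OD600": od_raw}
        for ch in channels:
            rate = (s_per_od.get(ch, 0.0) + truth.autofluo_per_od.get(ch, 0.0)) * od_true
            f_true = np.concatenate(
                [[0.0], np.cumsum(0.5 * (rate[1:] + rate[:-1]) * np.diff(t))]
            )
            series[ch] = f_true * _lognormal_factor(
                rng, truth.noise_cv, t.shape
            ) + truth.background_fluo[ch]
        for ch, values in series.items():
            for ti, v in zip(t, values):
                rows.append((ti, well_id, ch, v))
        map_rows.append((well_id, strain, role, inducer, conc))

    for well_id, w in sorted(truth.wells.items()):
        od_true = _logistic_od(t, w)
        emit(well_id, w.role, w.strain, od_true, w.s_true, w.inducer, w.conc_nM)

    # control wells appended after samples, labelled by row "X"
    median_truth = WellTruth(strain="autofluor")
    od_ctrl = _logistic_od(t, median_truth)
    for i in range(truth.n_autofluor):
        emit(f"X{i + 1}", "autofluorescence_control", "TOP10", od_ctrl, {})
    zeros = np.zeros_like(t)
    for i in range(truth.n_blanks):
        emit(f"X{truth.n_autofluor + i + 1}", "blank_medium", "none", zeros, {})

    plate = pd.DataFrame(rows, columns=["time_min", "well", "channel", "value"])
    wellmap = pd.DataFrame(
        map_rows, columns=["well", "strain", "role", "inducer", "conc_nM"]
    )
    truth_record = {
        "plate": {
            k: v for k, v in dataclasses.asdict(truth).items() if k != "wells"
        },
        "wells": {wid: dataclasses.asdict(w) for wid, w in truth.wells.items()},
        "duration_min": duration_min,
        "sample_min": sample_min,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        plate.to_csv(out / "plate.csv", index=False)
        wellmap.to_csv(out / "wellmap.csv", index=False)
        with open(out / "truth.json", "w") as fh:
            json.dump(truth_record, fh, indent=2, sort_keys=True)
    return plate, wellmap, truth_record


@dataclass(frozen=True)
class CurveTruth:
    """Generating configuration for a noisy transfer curve.

    ``generator='hill'`` evaluates ``hill_stage`` on the grid;
    ``generator='equilibrium'`` sweeps ``sweep_field`` of the binding model.
    Noise is multiplicative lognormal with coefficient of variation
    ``noise_cv``, independent per replicate and grid point.
    """

    generator: str                               # "hill" | "equilibrium"
    hill_stage: HillStage | None = None
    binding: BindingParams | None = None
    totals: SpeciesTotals | None = None
    sweep_field: str = "gtot"
    noise_cv: float = 0.0
    replicates: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.generator == "hill" and self.hill_stage is None:
            raise ValueError("hill generator needs hill_stage")
        if self.generator == "equilibrium" and (
            self.binding is None or self.totals is None
        ):
            raise ValueError("equilibrium generator needs binding params and totals")
        if self.generator not in ("hill", "equilibrium"):
            raise ValueError(f"unknown generator {self.generator!r}")
        if not 0.0 <= self.noise_cv <= 0.2:
            raise ValueError("noise_cv must be in [0, 0.2]")
        if self.replicates < 1:
            raise ValueError("need >= 1 replicate")


def generate_curve(
    truth: CurveTruth,
    grid: np.ndarray,
    out_dir: str | Path | None = None,
) -> tuple[pd.DataFrame, TransferCurve, dict]:
    """Evaluate the chosen generator on ``grid`` and add replicate noise.

    Returns ``(data, clean_curve, truth_record)`` where ``data`` is the tidy
    long-format table (input_value, output_value, replicate) and
    ``clean_curve`` the noise-free :class:`TransferCurve`.  With ``out_dir``
    set, writes ``curve.csv`` and ``truth.json``.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size < 2 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be 1-D, strictly increasing, >= 2 points")
    rng = np.random.default_rng(truth.seed)

    if truth.generator == "hill":
        clean_out = np.asarray(hill_eval(truth.hill_stage, grid), dtype=float)
        clean = TransferCurve(
            input_name="inducer", input_values=grid,
            output_name="output", output_values=clean_out,
            metadata={"generator": "hill"},
        )
    else:
        clean = sweep_transfer_curve(
            truth.binding, truth.totals, truth.sweep_field, grid
        )
        clean_out = clean.output_values

    rows = []
    for rep in range(1, truth.replicates + 1):
        noisy = clean_out * _lognormal_factor(rng, truth.noise_cv, grid.shape)
        for x, y in zip(grid, noisy):
            rows.append((x, y, rep))
    data = pd.DataFrame(rows, columns=["input_value", "output_value", "replicate"])

    record: dict = {
        "generator": truth.generator,
        "noise_cv": truth.noise_cv,
        "replicates": truth.replicates,
        "seed": truth.seed,
        "grid": grid.tolist(),
    }
    if truth.hill_stage is not None:
        record["hill_stage"] = dataclasses.asdict(truth.hill_stage)
    if truth.binding is not None:
        record["binding"] = dataclasses.asdict(truth.binding)
        record["totals"] = dataclasses.asdict(truth.totals)
        record["sweep_field"] = truth.sweep_field

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        data.to_csv(out / "curve.csv", index=False)
        with open(out / "truth.json", "w") as fh:
            json.dump(record, fh, indent=2, sort_keys=True)
    return data, clean, record
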
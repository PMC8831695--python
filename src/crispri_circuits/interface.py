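"""Command-line entry point, config validation, and figure rendering.

Subcommands
-----------
``simulate``       one equilibrium solve, state printed as JSON
``sweep``          grid sweep of the binding model → CSV (+ optional panel figure)
``process-plate``  plate.csv + wellmap.csv → kinetics.csv
``fit``            transfer-curve CSV → Hill fit JSON
``predict``        model JSON + input grid → predicted curve CSV
``synth``          synthetic plate or curve from a YAML truth config

Configs are YAML validated by pydantic models with unknown keys rejected;
every run writes a small manifest (config hash, package version, inputs and
outputs) next to its artifacts so any figure can be regenerated from the
CSVs alone.  Figures are always rendered from the written CSV, never from
in-memory state.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from pathlib import Path

import click
import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, ValidationError

import crispri_circuits
from crispri_circuits.circuit_models import (
    CircuitModel,
    HillStage,
    cascade_predict,
    fit_stage,
    nor_predict,
)
from crispri_circuits.equilibrium_model import (
    BindingParams,
    SpeciesTotals,
    solve_equilibrium,
    sweep_transfer_curve,
)
from crispri_circuits.plate_kinetics import load_plate, process_plate
from crispri_circuits.synthetic_data import (
    CurveTruth,
    PlateTruth,
    WellTruth,
    generate_curve,
    generate_plate,
)

logger = logging.getLogger("crispri_circuits")


class SweepBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    field: str = "gtot"
    min: float = 1e-2
    max: float = 1e4
    points: int = 61


class ModelConfig(BaseModel):
    """Binding-model block of the run config (concentrations in nM)."""

    model_config = ConfigDict(extra="forbid")
    K1: float = 0.3
    K2: float = 2.0
    theta: float = 1.0
    Ctot: float = 100.0
    gtot: float = 10.0
    Dtot: float = 10.0
    sweep: SweepBlock = SweepBlock()


def load_config(path: str | Path) -> ModelConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return ModelConfig.model_validate(raw)


def write_manifest(out_dir: Path, config: dict, inputs: list[str], outputs: list[str]) -> None:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    manifest = {
        "package_version": crispri_circuits.__version__,
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "config": config,
        "inputs": inputs,
        "outputs": outputs,
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)


@click.group()
@click.option("--log-level", default="INFO", show_default=True)
def main(log_level: str) -> None:
    """CRISPRi logic-inverter modelling toolkit."""
    logging.basicConfig(level=log_level.upper(), stream=sys.stderr,
                        format="%(levelname)s %(name)s: %(message)s")


def _config_option(f):
    return click.option(
        "--config", "config_path", type=click.Path(exists=True),
        help="YAML config; flags override its values.",
    )(f)


def _load_or_default(config_path: str | None) -> ModelConfig:
    try:
        return load_config(config_path) if config_path else ModelConfig()
    except ValidationError as exc:
        raise click.exceptions.UsageError(f"invalid config:\n{exc}") from exc


@main.command()
@_config_option
@click.option("--k1", type=float, default=None, help="K1, nM")
@click.option("--k2", type=float, default=None, help="K2, nM")
@click.option("--theta", type=float, default=None)
@click.option("--ctot", type=float, default=None, help="total dCas9, nM")
@click.option("--gtot", type=float, default=None, help="total sgRNA, nM")
@click.option("--dtot", type=float, default=None, help="total promoter DNA, nM")
def simulate(config_path, k1, k2, theta, ctot, gtot, dtot) -> None:
    """Solve one binding equilibrium and print the state as JSON."""
    cfg = _load_or_default(config_path)
    params = BindingParams(
        K1=k1 if k1 is not None else cfg.K1,
        K2=k2 if k2 is not None else cfg.K2,
        theta=theta if theta is not None else cfg.theta,
    )
    totals = SpeciesTotals(
        Ctot=ctot if ctot is not None else cfg.Ctot,
        gtot=gtot if gtot is not None else cfg.gtot,
        Dtot=dtot if dtot is not None else cfg.Dtot,
    )
    state = solve_equilibrium(params, totals)
    click.echo(json.dumps(vars(state), indent=2))


@main.command()
@_config_option
@click.option("--out", "out_path", type=click.Path(), default="sweep.csv",
              show_default=True)
@click.option("--figure", type=click.Path(), default=None,
              help="Optional PNG: repression-curve panel grid.")
def sweep(config_path, out_path, figure) -> None:
    """Sweep one total concentration over a log grid; write the CSV."""
    cfg = _load_or_default(config_path)
    params = BindingParams(K1=cfg.K1, K2=cfg.K2, theta=cfg.theta)
    fixed = SpeciesTotals(Ctot=cfg.Ctot, gtot=cfg.gtot, Dtot=cfg.Dtot)
    grid = np.geomspace(cfg.sweep.min, cfg.sweep.max, cfg.sweep.points)
    curve = sweep_transfer_curve(params, fixed, cfg.sweep.field, grid)
    states = curve.metadata["states"]
    df = pd.DataFrame(
        {
            "input_value": curve.input_values,
            "C": [s.C for s in states],
            "g": [s.g for s in states],
            "D": [s.D for s in states],
            "Cg": [s.Cg for s in states],
            "CgD": [s.CgD for s in states],
            "D_over_Dtot": curve.output_values,
            "R": [s.R for s in states],
        }
    )
    out = Path(out_path)
    df.to_csv(out, index=False)
    write_manifest(out.parent if out.parent != Path("") else Path("."),
                   cfg.model_dump(), [], [str(out)])
    if figure:
        render_sweep_panels(out, Path(figure), params)
    click.echo(f"wrote {out}")


def render_sweep_panels(
    sweep_csv: Path,
    figure_path: Path,
    params: BindingParams,
    ctot_values=(1.0, 10.0, 100.0, 1000.0),
    dtot_values=(1.0, 10.0, 100.0),
) -> None:
    """Render a repression-curve panel grid (Dtot rows × Ctot columns).

    The swept input grid is read back from the written CSV; each panel
    re-solves with its own (Ctot, Dtot) so the figure shows how the switch
    point moves with DNA copy number and dCas9 level.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    grid = pd.read_csv(sweep_csv)["input_value"].to_numpy()
    fig, axes = plt.subplots(
        len(dtot_values), len(ctot_values),
        figsize=(3 * len(ctot_values), 2.4 * len(dtot_values)),
        sharex=True, sharey=True, squeeze=False,
    )
    for i, dtot in enumerate(dtot_values):
        for j, ctot in enumerate(ctot_values):
            fixed = SpeciesTotals(Ctot=ctot, gtot=0.0, Dtot=dtot)
            curve = sweep_transfer_curve(params, fixed, "gtot", grid)
            ax = axes[i][j]
            ax.semilogx(curve.input_values, curve.output_values)
            ax.set_title(f"Ctot={ctot:g}, Dtot={dtot:g} nM", fontsize=8)
            ax.set_ylim(-0.05, 1.05)
    for ax in axes[-1]:
        ax.set_xlabel("gtot (nM)")
    for row in axes:
        row[0].set_ylabel("D / Dtot")
    fig.tight_layout()
    fig.savefig(figure_path, dpi=150)
    plt.close(fig)


@main.command("process-plate")
@click.option("--plate", "plate_csv", type=click.Path(exists=True), required=True)
@click.option("--map", "map_csv", type=click.Path(exists=True), required=True)
@click.option("--out", "out_path", type=click.Path(), default="kinetics.csv",
              show_default=True)
@click.option("--no-autofluor", is_flag=True, help="Skip autofluorescence correction.")
@click.option("--smooth", type=int, default=None,
              help="Odd moving-window width for fluorescence smoothing.")
def process_plate_cmd(plate_csv, map_csv, out_path, no_autofluor, smooth) -> None:
    """Reduce a kinetic plate read to growth and synthesis rates."""
    wells = load_plate(plate_csv, map_csv)
    df = process_plate(
        wells, use_autofluorescence=not no_autofluor, smooth=smooth
    )
    out = Path(out_path)
    df.to_csv(out, index=False)
    write_manifest(out.parent if out.parent != Path("") else Path("."),
                   {"plate": plate_csv, "map": map_csv,
                    "no_autofluor": no_autofluor, "smooth": smooth},
                   [plate_csv, map_csv], [str(out)])
    click.echo(f"wrote {out} ({len(df)} wells reduced)")


@main.command()
@click.option("--data", "data_csv", type=click.Path(exists=True), required=True,
              help="Tidy curve CSV: input_value, output_value[, replicate].")
@click.option("--kind", type=click.Choice(["activation", "repression"]),
              required=True)
@click.option("--out", "out_path", type=click.Path(), default="fit.json",
              show_default=True)
def fit(data_csv, kind, out_path) -> None:
    """Fit a four-parameter Hill stage to a transfer curve."""
    df = pd.read_csv(data_csv)
    from crispri_circuits.equilibrium_model import TransferCurve

    reps = None
    if "replicate" in df.columns and df["replicate"].nunique() > 1:
        wide = df.pivot_table(index="input_value", columns="replicate",
                              values="output_value").sort_index()
        x = wide.index.to_numpy()
        cols = list(wide.columns)
        base = wide[cols[0]].to_numpy()
        reps = [wide[c].to_numpy() for c in cols[1:]]
    else:
        grp = df.groupby("input_value")["output_value"].mean().sort_index()
        x, base = grp.index.to_numpy(), grp.to_numpy()
    curve = TransferCurve("input", x, "output", base)
    result = fit_stage(curve, kind, replicate_outputs=reps)
    with open(out_path, "w") as fh:
        json.dump(
            {"estimates": result.estimates, "residual_norm": result.residual_norm,
             "n_points": result.n_points, "converged": result.converged},
            fh, indent=2,
        )
    click.echo(f"wrote {out_path}")


@main.command()
@click.option("--model", "model_json", type=click.Path(exists=True), required=True)
@click.option("--grid-min", type=float, default=0.1, show_default=True)
@click.option("--grid-max", type=float, default=500.0, show_default=True)
@click.option("--points", type=int, default=25, show_default=True)
@click.option("--in2", type=float, default=0.0,
              help="Second input level for NOR models.")
@click.option("--out", "out_path", type=click.Path(), default="prediction.csv",
              show_default=True)
def predict(model_json, grid_min, grid_max, points, in2, out_path) -> None:
    """Predict a circuit response over a log-spaced input grid."""
    model = CircuitModel.from_json(model_json)
    grid = np.geomspace(grid_min, grid_max, points)
    if model.topology == "nor":
        out = np.array([nor_predict(model, x, in2) for x in grid])
    else:
        out = np.atleast_1d(cascade_predict(model, grid))
    pd.DataFrame({"input_value": grid, "output_value": out}).to_csv(
        out_path, index=False
    )
    click.echo(f"wrote {out_path}")


class SynthPlateConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    kind: str = "plate"
    seed: int = 0
    noise_cv: float = 0.0
    duration_min: float = 1080.0
    n_samples: int = 4
    mu_range: tuple[float, float] = (0.5, 0.9)
    s_rfp_range: tuple[float, float] = (20.0, 120.0)
    s_gfp_range: tuple[float, float] = (10.0, 60.0)


class SynthCurveConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    kind: str = "curve"
    seed: int = 0
    noise_cv: float = 0.1
    replicates: int = 3
    stage_kind: str = "repression"
    basal: float = 10.0
    range: float = 100.0
    Km: float = 5.0
    n: float = 2.0
    grid_min: float = 0.1
    grid_max: float = 500.0
    points: int = 8


def build_demo_plate(cfg: SynthPlateConfig) -> PlateTruth:
    """A small plate with varied sample wells plus RFP/GFP reference strains."""
    rng = np.random.default_rng(cfg.seed)
    wells: dict[str, WellTruth] = {
        "A1": WellTruth(strain="J101R", role="reference",
                        s_true={"RFP": 80.0, "GFP": 5.0}),
        "A2": WellTruth(strain="J101G", role="reference",
                        s_true={"RFP": 5.0, "GFP": 40.0}),
    }
    for i in range(cfg.n_samples):
        wells[f"B{i + 1}"] = WellTruth(
            strain=f"sample{i + 1}",
            mu_true=float(rng.uniform(*cfg.mu_range)),
            s_true={
                "RFP": float(rng.uniform(*cfg.s_rfp_range)),
                "GFP": float(rng.uniform(*cfg.s_gfp_range)),
            },
        )
    return PlateTruth(wells=wells, noise_cv=cfg.noise_cv, seed=cfg.seed)


@main.command()
@click.option("--config", "config_path", type=click.Path(exists=True),
              required=True, help="YAML truth config with a 'kind' key.")
@click.option("--out", "out_dir", type=click.Path(), required=True)
def synth(config_path, out_dir) -> None:
    """Generate a synthetic plate or transfer curve with known truth."""
    with open(config_path) as fh:
        raw = yaml.safe_load(fh) or {}
    kind = raw.get("kind", "plate")
    out = Path(out_dir)
    try:
        if kind == "plate":
            cfg = SynthPlateConfig.model_validate(raw)
            truth = build_demo_plate(cfg)
            generate_plate(truth, duration_min=cfg.duration_min, out_dir=out)
            outputs = ["plate.csv", "wellmap.csv", "truth.json"]
        elif kind == "curve":
            cfg = SynthCurveConfig.model_validate(raw)
            stage = HillStage(kind=cfg.stage_kind, basal=cfg.basal,
                              range=cfg.range, Km=cfg.Km, n=cfg.n)
            truth = CurveTruth(generator="hill", hill_stage=stage,
                               noise_cv=cfg.noise_cv, replicates=cfg.replicates,
                               seed=cfg.seed)
            grid = np.concatenate(
                [[0.0], np.geomspace(cfg.grid_min, cfg.grid_max, cfg.points - 1)]
            )
            generate_curve(truth, grid, out_dir=out)
            outputs = ["curve.csv", "truth.json"]
        else:
            raise click.exceptions.UsageError(f"unknown synth kind {kind!r}")
    except ValidationError as exc:
        raise click.exceptions.UsageError(f"invalid config:\n{exc}") from exc
    write_manifest(out, raw, [config_path], outputs)
    click.echo(f"wrote {', '.join(outputs)} in {out}")


if __name__ == "__main__":
    main()
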
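"""Reduction of microplate kinetic reads to per-cell synthesis rates.

A 96-well kinetic assay yields, per well, aligned time series of OD600 and
one or more fluorescence channels (here GFP and RFP) sampled every few
minutes.  The reduction implemented here is the standard one for promoter
activity quantification:

1. background-correct OD and fluorescence using blank-medium wells and,
   optionally, an autofluorescence control strain matched by OD;
2. locate the exponential growth phase from the corrected OD;
3. fit the growth rate ``mu`` by ordinary least squares on ln(OD) vs time;
4. compute the per-biomass synthesis rate ``S(t) = dF/dt / OD600`` by
   numerical differentiation, average it over the exponential window
   (``S_ave``), and normalize by a reference strain measured on the same
   plate to obtain the dimensionless per-cell rate ``S_cell``.

Time is in minutes on input; ``mu`` is reported per hour; ``S_ave`` is in
AU·OD⁻¹·min⁻¹ (units cancel in ``S_cell``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "PlateWell",
    "KineticResult",
    "load_plate",
    "subtract_background",
    "exponential_window",
    "growth_rate",
    "synthesis_rate",
    "s_cell",
    "process_plate",
]

FLUOR_CHANNELS = ("GFP", "RFP")
OD_CHANNEL = "OD600"

#: minimum OD600 used when dividing dF/dt by biomass
OD_FLOOR = 0.001


@dataclass
class PlateWell:
    """One well: aligned raw (or corrected) time series per channel.

    ``role`` is one of ``sample``, ``blank_medium``,
    ``autofluorescence_control`` or ``reference``; reference wells carry the
    strain used for ``S_cell`` normalization of one fluorescence channel.
    """

    well_id: str
    strain: str
    role: str
    time_min: np.ndarray
    channels: dict[str, np.ndarray]
    inducers: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_min = np.asarray(self.time_min, dtype=float)
        if np.any(np.diff(self.time_min) <= 0):
            raise ValueError(f"well {self.well_id}: time must be strictly increasing")
        for name, series in self.channels.items():
            series = np.asarray(series, dtype=float)
            if series.shape != self.time_min.shape:
                raise ValueError(
                    f"well {self.well_id}: channel {name} not aligned with time grid"
                )
            if not np.all(np.isfinite(series)):
                raise ValueError(f"well {self.well_id}: non-finite values in {name}")
            self.channels[name] = series


@dataclass
class KineticResult:
    """Per-well reduction: growth rate, window, and synthesis rates."""

    well_id: str
    strain: str
    mu: float                      # 1/h
    r_squared: float
    window: tuple[float, float]    # minutes
    S_ave: dict[str, float]        # channel -> AU·OD⁻¹·min⁻¹
    S_cell: dict[str, float] = field(default_factory=dict)
    inducers: dict[str, float] = field(default_factory=dict)


def load_plate(plate_csv, wellmap_csv) -> list[PlateWell]:
    """Read the tidy plate CSV and well map into :class:`PlateWell` objects.

    ``plate.csv`` columns: time_min, well, channel, value.
    ``wellmap.csv`` columns: well, strain, role, inducer, conc_nM (inducer
    may be empty for uninduced wells).
    """
    plate = pd.read_csv(plate_csv)
    wellmap = pd.read_csv(wellmap_csv)
    required = {"time_min", "well", "channel", "value"}
    if not required.issubset(plate.columns):
        raise ValueError(f"plate CSV must have columns {sorted(required)}")

    meta = wellmap.set_index("well")
    wells = []
    for well_id, grp in plate.groupby("well", sort=True):
        if well_id not in meta.index:
            raise ValueError(f"well {well_id} missing from well map")
        pivot = grp.pivot_table(index="time_min", columns="channel", values="value")
        pivot = pivot.sort_index()
        row = meta.loc[well_id]
        inducers = {}
        if "inducer" in row and isinstance(row["inducer"], str) and row["inducer"]:
            inducers[row["inducer"]] = float(row.get("conc_nM", 0.0))
        wells.append(
            PlateWell(
                well_id=str(well_id),
                strain=str(row["strain"]),
                role=str(row["role"]),
                time_min=pivot.index.to_numpy(),
                channels={c: pivot[c].to_numpy() for c in pivot.columns},
                inducers=inducers,
            )
        )
    return wells


def _timewise_mean(wells: list[PlateWell], channel: str) -> np.ndarray:
    return np.mean([w.channels[channel] for w in wells], axis=0)


def subtract_background(
    wells: list[PlateWell], use_autofluorescence: bool = True
) -> list[PlateWell]:
    """Blank- and autofluorescence-correct all wells of a plate.

    OD600 has the time-pointwise mean of the blank-medium wells subtracted.
    Fluorescence channels are first blank-subtracted; then, if
    autofluorescence-control wells are present and ``use_autofluorescence``,
    the control strain's fluorescence is interpolated as a function of its
    corrected OD600 and subtracted from each well at the well's own OD —
    OD-matched rather than time-matched, so differing growth timing between
    control and sample does not bias the correction.  Sample OD outside the
    control's OD range is clamped to the nearest covered value (logged).
    Negative corrected values are clipped to zero and counted.
    """
    blanks = [w for w in wells if w.role == "blank_medium"]
    if not blanks:
        raise ValueError("no blank_medium wells on the plate")
    od_blank = _timewise_mean(blanks, OD_CHANNEL)
    fluo_blank = {
        ch: _timewise_mean(blanks, ch)
        for ch in FLUOR_CHANNELS
        if all(ch in w.channels for w in blanks)
    }

    corrected: list[PlateWell] = []
    n_clipped = 0
    for well in wells:
        new_channels: dict[str, np.ndarray] = {}
        od = well.channels[OD_CHANNEL] - od_blank
        n_clipped += int(np.sum(od < 0))
        new_channels[OD_CHANNEL] = np.clip(od, 0.0, None)
        for ch in well.channels:
            if ch == OD_CHANNEL:
                continue
            f = well.channels[ch] - fluo_blank.get(ch, 0.0)
            n_clipped += int(np.sum(f < 0))
            new_channels[ch] = np.clip(f, 0.0, None)
        corrected.append(replace(well, channels=new_channels))

    controls = [w for w in corrected if w.role == "autofluorescence_control"]
    if use_autofluorescence and controls:
        ctrl_od = np.concatenate([w.channels[OD_CHANNEL] for w in controls])
        order = np.argsort(ctrl_od)
        ctrl_od = ctrl_od[order]
        for ch in FLUOR_CHANNELS:
            if not all(ch in w.channels for w in controls):
                continue
            ctrl_f = np.concatenate([w.channels[ch] for w in controls])[order]
            for well in corrected:
                if well.role in ("blank_medium", "autofluorescence_control"):
                    continue
                if ch not in well.channels:
                    continue
                od = well.channels[OD_CHANNEL]
                if od.max() > 1.05 * ctrl_od.max():
                    logger.warning(
                        "well %s OD range extends beyond autofluorescence control; "
                        "clamping to control range", well.well_id,
                    )
                autofluo = np.interp(od, ctrl_od, ctrl_f)
                f = well.channels[ch] - autofluo
                n_clipped += int(np.sum(f < 0))
                well.channels[ch] = np.clip(f, 0.0, None)

    if n_clipped:
        logger.info("background subtraction clipped %d negative values to 0", n_clipped)
    return corrected


@dataclass(frozen=True)
class WindowSearchFailure(Exception):
    """No OD window met the exponential-phase criteria."""

    best_r_squared: float

    def __str__(self) -> str:
        return (
            "no exponential window found "
            f"(best log-linear R² over candidate windows: {self.best_r_squared:.4f})"
        )


def _loglinear_fit(t_min: np.ndarray, od: np.ndarray) -> tuple[float, float]:
    """Slope (1/h) and R² of ln(OD) vs time in hours."""
    res = stats.linregress(t_min / 60.0, np.log(od))
    return float(res.slope), float(res.rvalue**2)


def exponential_window(
    time_min: np.ndarray,
    od: np.ndarray,
    od_min_frac: float = 0.003,
    od_max_frac: float = 0.015,
    min_points: int = 5,
    r2_threshold: float = 0.99,
) -> tuple[float, float]:
    """Locate the exponential growth phase of a corrected OD600 series.

    Candidate points are those with OD within
    ``[od_min_frac, od_max_frac] * max(OD)``; the longest contiguous run
    whose log-linear fit achieves ``R² >= r2_threshold`` with at least
    ``min_points`` points wins, ties broken toward earlier windows.  The
    band's lower edge keeps lag-phase and detection-floor reads out; the
    upper edge is deliberately far below the carrying capacity, because on
    a logistic growth curve the apparent log-linear rate at OD equal to a
    fraction ``f`` of capacity is already depressed by about ``f`` — a
    window reaching half-saturation underestimates ``mu`` by ~20%, while
    this band keeps the curvature bias under about 1%.

    Raises :class:`WindowSearchFailure` (carrying the best R² seen) when no
    window qualifies.
    """
    time_min = np.asarray(time_min, dtype=float)
    od = np.asarray(od, dtype=float)
    above = od > 0
    if int(above.sum()) < 8:
        raise WindowSearchFailure(best_r_squared=float("nan"))
    od_max = od.max()
    in_band = (od >= od_min_frac * od_max) & (od <= od_max_frac * od_max) & above

    # contiguous runs of in-band points
    runs: list[tuple[int, int]] = []
    start = None
    for i, ok in enumerate(in_band):
        if ok and start is None:
            start = i
        elif not ok and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(od)))

    best: tuple[int, int] | None = None
    best_r2 = -np.inf
    max_len = max((hi - lo for lo, hi in runs), default=0)
    for length in range(max_len, min_points - 1, -1):
        for lo, hi in runs:
            for start in range(lo, hi - length + 1):
                _, r2 = _loglinear_fit(
                    time_min[start : start + length], od[start : start + length]
                )
                best_r2 = max(best_r2, r2)
                if r2 >= r2_threshold:
                    best = (start, start + length)
                    break
            if best is not None:
                break
        if best is not None:
            break
    if best is None:
        raise WindowSearchFailure(best_r_squared=float(best_r2))
    return float(time_min[best[0]]), float(time_min[best[1] - 1])


def growth_rate(
    time_min: np.ndarray, od: np.ndarray, window: tuple[float, float]
) -> tuple[float, float]:
    """OLS growth rate ``mu`` (1/h) and R² of ln(OD) vs time inside a window."""
    time_min = np.asarray(time_min, dtype=float)
    od = np.asarray(od, dtype=float)
    mask = (time_min >= window[0]) & (time_min <= window[1])
    if int(mask.sum()) < 3:
        raise ValueError("growth window must contain at least 3 points")
    if np.any(od[mask] <= 0):
        raise ValueError(
            "non-positive OD inside the growth window "
            "(background over-subtraction upstream?)"
        )
    return _loglinear_fit(time_min[mask], od[mask])


def synthesis_rate(
    time_min: np.ndarray,
    fluo: np.ndarray,
    od: np.ndarray,
    od_floor: float = OD_FLOOR,
) -> np.ma.MaskedArray:
    """Per-biomass synthesis rate ``S(t) = dF/dt / OD600``.

    The derivative uses central differences at interior points and one-sided
    differences at the ends (``numpy.gradient``).  Points with OD below
    ``od_floor`` are masked rather than amplified into noise.
    """
    time_min = np.asarray(time_min, dtype=float)
    fluo = np.asarray(fluo, dtype=float)
    od = np.asarray(od, dtype=float)
    dfdt = np.gradient(fluo, time_min)
    mask = od < od_floor
    if mask.all():
        raise ValueError("all points below the OD floor; no usable signal")
    s = np.ma.masked_array(
        np.divide(dfdt, od, out=np.zeros_like(dfdt), where=~mask), mask=mask
    )
    return s


def s_cell(S_ave: float, S_ave_ref: float) -> float:
    """Reference-normalized per-cell synthesis rate ``S_ave / S_ave_ref``.

    The reference must be the channel-matched reference strain (distinct
    strains calibrate RFP and GFP).
    """
    if not S_ave_ref > 0:
        raise ValueError("reference S_ave must be > 0")
    if S_ave < 0:
        raise ValueError("S_ave must be >= 0")
    return S_ave / S_ave_ref


def _reduce_well(well: PlateWell, smooth: int | None = None) -> KineticResult:
    t = well.time_min
    od = well.channels[OD_CHANNEL]
    window = exponential_window(t, od)
    mu, r2 = growth_rate(t, od, window)
    in_window = (t >= window[0]) & (t <= window[1])
    S_ave: dict[str, float] = {}
    for ch in FLUOR_CHANNELS:
        if ch not in well.channels:
            continue
        fluo = well.channels[ch]
        if smooth and smooth >= 3:
            if smooth % 2 == 0:
                raise ValueError("smoothing window must be odd")
            from scipy.signal import savgol_filter

            fluo = savgol_filter(fluo, smooth, 2)
        s = synthesis_rate(t, fluo, od)
        S_ave[ch] = float(s[in_window].mean())
    return KineticResult(
        well_id=well.well_id,
        strain=well.strain,
        mu=mu,
        r_squared=r2,
        window=window,
        S_ave=S_ave,
        inducers=dict(well.inducers),
    )


def process_plate(
    wells: list[PlateWell],
    reference_strains: dict[str, str] | None = None,
    use_autofluorescence: bool = True,
    smooth: int | None = None,
) -> pd.DataFrame:
    """Full plate reduction: background, windows, mu, S_ave and S_cell.

    ``reference_strains`` maps channel name to the strain whose wells
    provide ``S_ave,ref`` for that channel; by default the wells with role
    ``reference`` are grouped by strain and each strain calibrates the
    channel in which its mean ``S_ave`` is largest (the RFP and GFP
    references are distinct strains).  Returns a tidy DataFrame, one row per
    non-control well.
    """
    corrected = subtract_background(wells, use_autofluorescence=use_autofluorescence)
    measurable = [
        w for w in corrected if w.role not in ("blank_medium",)
    ]
    results: dict[str, KineticResult] = {}
    failures: dict[str, str] = {}
    for well in measurable:
        if well.role == "autofluorescence_control":
            continue
        try:
            results[well.well_id] = _reduce_well(well, smooth=smooth)
        except (WindowSearchFailure, ValueError) as exc:
            failures[well.well_id] = str(exc)
            logger.warning("well %s skipped: %s", well.well_id, exc)

    ref_wells = [w for w in corrected if w.role == "reference"]
    ref_S: dict[str, float] = {}
    if ref_wells:
        by_strain: dict[str, list[KineticResult]] = {}
        for w in ref_wells:
            if w.well_id in results:
                by_strain.setdefault(w.strain, []).append(results[w.well_id])
        if reference_strains is None:
            reference_strains = {}
            for strain, res_list in by_strain.items():
                means = {
                    ch: float(np.mean([r.S_ave[ch] for r in res_list]))
                    for ch in FLUOR_CHANNELS
                    if all(ch in r.S_ave for r in res_list)
                }
                if means:
                    best_ch = max(means, key=means.get)
                    reference_strains.setdefault(best_ch, strain)
        for ch, strain in reference_strains.items():
            if strain in by_strain:
                ref_S[ch] = float(np.mean([r.S_ave[ch] for r in by_strain[strain]]))

    rows = []
    for res in results.values():
        for ch, ref in ref_S.items():
            if ch in res.S_ave:
                res.S_cell[ch] = s_cell(res.S_ave[ch], ref)
        inducer = next(iter(res.inducers), "")
        rows.append(
            {
                "well": res.well_id,
                "strain": res.strain,
                "inducer": inducer,
                "conc_nM": res.inducers.get(inducer, 0.0),
                "mu_per_h": res.mu,
                "r_squared": res.r_squared,
                "window_start_min": res.window[0],
                "window_end_min": res.window[1],
                "S_ave_RFP": res.S_ave.get("RFP", np.nan),
                "S_ave_GFP": res.S_ave.get("GFP", np.nan),
                "S_cell_RFP": res.S_cell.get("RFP", np.nan),
                "S_cell_GFP": res.S_cell.get("GFP", np.nan),
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["failures"] = failures
    return df
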
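"""Growth-curve phenotyping: maximum specific growth rates and derived fitness statistics.

The maximum specific growth rate mu_max (h^-1) is the slope of a linear
regression of ln(OD600) versus time over the exponential (log) growth phase,
after blank subtraction.  The log phase is located automatically by scanning
all contiguous windows of the blank-corrected series; see :func:`fit_mu_max`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "GrowthCurve",
    "GrowthFit",
    "GrowthFitConfig",
    "FitnessRecord",
    "AssayParams",
    "fit_mu_max",
    "fit_plate",
    "aggregate_fitness",
    "relative_fitness",
    "normalized_relative_fitness",
    "percent_relative_inhibition",
    "tolerance_improvement",
    "percent_change",
    "specific_fluorescence",
    "mdh_activity",
    "read_plate_csv",
    "read_plate_map",
]


@dataclass(frozen=True)
class GrowthCurve:
    """One well's OD600 time series.

    Parameters
    ----------
    well : str
        Well identifier (e.g. ``"A1"``).
    time_h : array
        Time points in hours, strictly increasing and nonnegative.
    od600 : array
        Raw absorbance readings, same length as ``time_h``.
    blank : float, optional
        Blank absorbance to subtract.  If ``None``, the caller must supply a
        plate-level blank (see :func:`fit_plate`).
    """

    well: str
    time_h: np.ndarray
    od600: np.ndarray
    blank: float | None = None

    def __post_init__(self):
        t = np.asarray(self.time_h, dtype=float)
        y = np.asarray(self.od600, dtype=float)
        object.__setattr__(self, "time_h", t)
        object.__setattr__(self, "od600", y)
        if t.ndim != 1 or y.ndim != 1 or len(t) != len(y):
            raise ValueError("time_h and od600 must be 1-D arrays of equal length")
        if len(t) < 10:
            raise ValueError("a growth curve needs at least 10 time points")
        if np.any(t < 0):
            raise ValueError("times must be nonnegative")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")


@dataclass(frozen=True)
class GrowthFit:
    """Result of a mu_max fit.

    ``mu_max`` is 0 and ``no_growth`` is True when no window qualified.
    ``window`` holds the (first, last) index into the original series of the
    selected regression window.
    """

    well: str
    mu_max: float
    window: tuple[int, int] | None
    r_squared: float
    od_max: float
    n_points: int
    se: float = float("nan")
    no_growth: bool = False


@dataclass(frozen=True)
class GrowthFitConfig:
    """Settings for log-phase window selection.

    min_points
        Minimum regression window length (points).
    r2_min
        Minimum R^2 of ln(OD) vs time within a window.
    min_ln_range
        Minimum fitted ln(OD) span (slope x time span) a window must cover;
        one natural-log unit ~ 1.44 doublings.  Guards against short windows
        that only track noise.
    z
        With ``selection="lcb"``, windows are ranked by
        ``slope - z * SE_model`` where SE_model is the slope standard error
        predicted from a heteroscedastic noise model (additive OD noise of
        magnitude ``noise_sd``, so ln-noise ~ noise_sd / OD).  ``z`` trades
        off precision against upward selection bias.
    selection
        ``"lcb"`` (default) or ``"slope"`` (rank by raw slope; the classical
        rule, noise-sensitive).
    floor
        Positivity floor: blank-subtracted ODs at or below
        ``max(floor, 3 * noise_sd)`` are excluded from the log regression.
    noise_sd
        Additive OD noise magnitude.  ``None`` = estimate from the final
        readings of the curve (successive differences of the last 31 points).
    """

    min_points: int = 6
    r2_min: float = 0.98
    min_ln_range: float = 1.0
    z: float = 4.0
    selection: str = "lcb"
    floor: float = 1e-4
    noise_sd: float | None = None


@dataclass(frozen=True)
class FitnessRecord:
    """Per strain x condition mu_max with uncertainty over replicate wells."""

    strain: str
    condition: str
    mu_max: float
    se: float
    n_replicates: int

    def __post_init__(self):
        if not (self.se >= 0 or math.isnan(self.se)):
            raise ValueError("SE must be nonnegative")


@dataclass(frozen=True)
class AssayParams:
    """Spectrophotometric assay constants for NADH-linked enzyme activity.

    epsilon_340 : NADH molar extinction coefficient at 340 nm (mM^-1 cm^-1).
    path_length : optical path length (cm).
    cell_mass   : g wet cells per reaction.
    """

    epsilon_340: float = 6.22
    path_length: float = 1.0
    cell_mass: float = 0.0045

    def __post_init__(self):
        if min(self.epsilon_340, self.path_length, self.cell_mass) <= 0:
            raise ValueError("assay parameters must be positive")


def _estimate_noise_sd(od: np.ndarray) -> float:
    """Estimate additive OD noise from successive differences of the tail."""
    tail = np.asarray(od[-31:], dtype=float)
    if len(tail) < 3:
        return 0.0
    d = np.diff(tail)
    return float(np.std(d) / np.sqrt(2.0))


def _window_stats(t: np.ndarray, ln_y: np.ndarray, inv_y2: np.ndarray, L: int):
    """OLS slope, R^2 and model-based slope variance for every window of length L.

    Uses rolling sums; the model-based slope variance assumes independent
    ln-noise with variance proportional to 1/OD^2 (unit additive-OD noise).
    """
    def roll(a):
        c = np.concatenate(([0.0], np.cumsum(a)))
        return c[L:] - c[:-L]

    St, Sy = roll(t), roll(ln_y)
    Stt, Sty, Syy = roll(t * t), roll(t * ln_y), roll(ln_y * ln_y)
    Sw, Stw, Sttw = roll(inv_y2), roll(t * inv_y2), roll(t * t * inv_y2)
    tbar = St / L
    sxx = Stt - St * St / L
    sxy = Sty - St * Sy / L
    syy = Syy - Sy * Sy / L
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = sxy / sxx
        intercept = (Sy - slope * St) / L
        ssr = np.maximum(syy - sxy * sxy / sxx, 0.0)
        r2 = np.where(syy > 0, 1.0 - ssr / syy, 1.0)
        # var(slope) = sum c_i^2 sigma_i^2, c_i = (t_i - tbar)/sxx, sigma_i ~ 1/y_i
        unit_var = (Sttw - 2.0 * tbar * Stw + tbar * tbar * Sw) / (sxx * sxx)
    return slope, intercept, r2, np.maximum(unit_var, 0.0), sxx


def fit_mu_max(curve: GrowthCurve, cfg: GrowthFitConfig = GrowthFitConfig(),
               blank: float | None = None) -> GrowthFit:
    """Fit the maximum specific growth rate of one well.

    Subtracts the blank, excludes points at or below the positivity floor,
    and scans all contiguous windows of the remaining points with length >=
    ``cfg.min_points``.  A window qualifies if its ln-OD regression has
    R^2 >= ``cfg.r2_min`` and its fitted ln-range spans >=
    ``cfg.min_ln_range``.  Among qualifying windows the one maximizing the
    selection score (see :class:`GrowthFitConfig`) is returned; ties go to
    the longer, then earlier, window.

    Returns a flagged no-growth result (mu_max = 0) when no window qualifies.
    """
    b = blank if blank is not None else (curve.blank or 0.0)
    y = curve.od600 - b
    sigma = cfg.noise_sd if cfg.noise_sd is not None else _estimate_noise_sd(curve.od600)
    floor = max(cfg.floor, 3.0 * sigma)
    mask = y > floor
    idx = np.nonzero(mask)[0]
    od_max = float(np.max(y)) if len(y) else float("nan")
    no_growth = GrowthFit(curve.well, 0.0, None, float("nan"), od_max, 0, no_growth=True)
    if len(idx) < cfg.min_points:
        return no_growth

    tv = curve.time_h[mask]
    yv = y[mask]
    ln_y = np.log(yv)
    inv_y2 = 1.0 / (yv * yv)
    n = len(tv)

    best = None  # (score, L, start, slope, r2, se)
    for L in range(cfg.min_points, n + 1):
        slope, _inter, r2, unit_var, _sxx = _window_stats(tv, ln_y, inv_y2, L)
        span = tv[L - 1:] - tv[: n - L + 1]
        se = sigma * np.sqrt(unit_var)
        qualifies = (r2 >= cfg.r2_min) & (slope * span >= cfg.min_ln_range)
        if not qualifies.any():
            continue
        if cfg.selection == "lcb":
            score = slope - cfg.z * se
        elif cfg.selection == "slope":
            score = slope.copy()
        else:
            raise ValueError(f"unknown selection rule {cfg.selection!r}")
        score = np.where(qualifies, score, -np.inf)
        i = int(np.argmax(score))
        cand = (float(score[i]), L, i, float(slope[i]), float(r2[i]), float(se[i]))
        if best is None or cand[0] > best[0] + 1e-15 or (
            abs(cand[0] - best[0]) <= 1e-15 and (L, -i) > (best[1], -best[2])
        ):
            best = cand
    if best is None:
        return no_growth
    _score, L, start, slope, r2, se = best
    window = (int(idx[start]), int(idx[start + L - 1]))
    return GrowthFit(curve.well, slope, window, r2, od_max, L, se=se)


def fit_plate(plate: pd.DataFrame, plate_map: pd.DataFrame,
              cfg: GrowthFitConfig = GrowthFitConfig()) -> pd.DataFrame:
    """Fit every non-blank well of a long-format plate.

    ``plate`` columns: well, time_h, od600.  ``plate_map`` columns: well,
    strain, condition, blank (bool).  The blank value per well is the
    plate-level median OD of the designated blank wells (all time points);
    wells with no designated blanks are fitted with blank 0.

    Returns a tidy table of fits (one row per well).
    """
    blank_wells = set(plate_map.loc[plate_map["blank"].astype(bool), "well"])
    if blank_wells:
        blank_val = float(plate.loc[plate["well"].isin(blank_wells), "od600"].median())
    else:
        blank_val = 0.0
    rows = []
    annot = plate_map.set_index("well")
    for well, grp in plate.groupby("well", sort=True):
        if well in blank_wells:
            continue
        grp = grp.sort_values("time_h")
        curve = GrowthCurve(str(well), grp["time_h"].to_numpy(), grp["od600"].to_numpy())
        fit = fit_mu_max(curve, cfg, blank=blank_val)
        rows.append({
            "well": well,
            "strain": annot.loc[well, "strain"] if well in annot.index else "",
            "condition": annot.loc[well, "condition"] if well in annot.index else "",
            "mu_max": fit.mu_max,
            "r_squared": fit.r_squared,
            "od_max": fit.od_max,
            "n_points": fit.n_points,
            "no_growth": fit.no_growth,
        })
    return pd.DataFrame(rows)


def aggregate_fitness(fits: pd.DataFrame) -> list[FitnessRecord]:
    """Aggregate per-well fits into strain x condition records.

    mu_max is the mean over replicate wells; SE is the sample standard error
    (NaN with a single replicate).
    """
    records = []
    for (strain, cond), grp in fits.groupby(["strain", "condition"], sort=True):
        mus = grp["mu_max"].to_numpy(dtype=float)
        n = len(mus)
        se = float(np.std(mus, ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
        records.append(FitnessRecord(str(strain), str(cond), float(np.mean(mus)), se, n))
    return records


# --- scalar fitness statistics -------------------------------------------------

def relative_fitness(mu_mut: float, mu_ref: float) -> float:
    """Mutant growth rate divided by the reference strain's rate (same condition)."""
    if mu_ref <= 0:
        return float("nan")
    return mu_mut / mu_ref


def normalized_relative_fitness(rf: float, rf_at_zero: float) -> float:
    """Relative fitness divided by the relative fitness at 0% stressor."""
    if rf_at_zero <= 0 or math.isnan(rf_at_zero):
        return float("nan")
    return rf / rf_at_zero


def percent_relative_inhibition(mu_wt: float, mu_mut: float) -> float:
    """Percent relative inhibition of the reference (WT) strain vs a mutant.

    Convention: 100 * (mu_mut - mu_wt) / mu_mut -- positive when the mutant
    outgrows the reference, i.e. when the stressor inhibits the reference
    more.  Equals 0 for equal rates.
    """
    if mu_mut <= 0:
        return float("nan")
    return 100.0 * (mu_mut - mu_wt) / mu_mut


def tolerance_improvement(conc_tolerated: float, conc_ref: float) -> float:
    """Percent improvement of the tolerated stressor concentration over a reference."""
    if conc_ref <= 0:
        raise ValueError("reference concentration must be positive")
    return 100.0 * (conc_tolerated - conc_ref) / conc_ref


def percent_change(value_mut: float, value_ref: float) -> float:
    """Percent change of a mutant's value relative to a positive reference value."""
    if value_ref <= 0:
        raise ValueError("reference value must be positive")
    return 100.0 * (value_mut - value_ref) / value_ref


def specific_fluorescence(fluorescence: float, od600: float) -> float:
    """Fluorescence normalized by culture density (AU per OD600 unit)."""
    if od600 <= 0:
        return float("nan")
    return fluorescence / od600


def mdh_activity(dA340_per_min: float, params: AssayParams = AssayParams()) -> float:
    """Malate dehydrogenase activity in Units per g wet cells.

    ``dA340_per_min`` is the background-corrected rate of change in 340 nm
    absorbance (AU/min); activity = dA/min / (epsilon_340 * l * c).
    """
    return dA340_per_min / (params.epsilon_340 * params.path_length * params.cell_mass)


# --- plate I/O -----------------------------------------------------------------

def read_plate_csv(path, layout: str = "long") -> pd.DataFrame:
    """Read a plate-reader CSV.

    ``layout="long"``: columns well, time_h, od600.  ``layout="wide"``: a
    time_h column plus one column per well; melted to long format.
    """
    df = pd.read_csv(path)
    if layout == "long":
        missing = {"well", "time_h", "od600"} - set(df.columns)
        if missing:
            raise ValueError(f"long plate CSV missing columns: {sorted(missing)}")
        return df
    if layout == "wide":
        if "time_h" not in df.columns:
            raise ValueError("wide plate CSV needs a time_h column")
        return df.melt(id_vars="time_h", var_name="well", value_name="od600")[
            ["well", "time_h", "od600"]
        ]
    raise ValueError(f"unknown layout {layout!r}")


def read_plate_map(path) -> pd.DataFrame:
    """Read a plate map CSV with columns well, strain, condition, blank."""
    df = pd.read_csv(path)
    missing = {"well", "strain", "condition", "blank"} - set(df.columns)
    if missing:
        raise ValueError(f"plate map missing columns: {sorted(missing)}")
    return df
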
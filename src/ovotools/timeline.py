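"""Developmental-timeline estimation and standard growth curves.

Egg chambers progress through stages 2-14 along an ovariole. Under steady-state
egg production, the time a chamber spends in a stage is proportional to the
frequency with which that stage is observed in fixed samples: an ovariole
produces EPR = E/O eggs per day (E = eggs laid per female per day, O = ovarioles
per female), so a chamber traverses the whole ovariole (EO chambers) in
G = EO/EPR days, and a stage observed with frequency f_s lasts Gs = f_s * G.

Chamber size is summarised by the midsection area A (um^2), which grows
exponentially: A(t) = A0 * exp(k*t). The same functional form describes the
fraction of the midsection occupied by the oocyte during vitellogenesis
(stages 8-11); its time origin is the onset of stage 9, where the oocyte
occupies ~30% of the chamber.

All intermediate values are carried at full precision; rounding happens only
in the reporting helpers (``format_report``), because e.g. Gs for stage 8 is
reproducible only from the unrounded total duration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

STAGES: tuple[int, ...] = tuple(range(2, 15))
HOURS_PER_DAY = 24.0

__all__ = [
    "STAGES",
    "FixedSurvey",
    "StageTimeline",
    "GrowthCurve",
    "compute_epr",
    "compute_total_duration",
    "stage_frequencies",
    "stage_durations",
    "fit_growth_curve",
    "fit_survey_area_curve",
    "fit_survey_oocyte_curve",
    "predict",
    "invert_time",
    "area_oocyte_correlation",
    "survey_means",
    "estimate_timeline",
    "format_report",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class FixedSurvey:
    """Fixed-sample observations feeding the timeline estimate.

    Parameters
    ----------
    females : pandas.DataFrame
        One row per female with columns ``ovariole_count`` and ``eggs_24h``.
    chambers : pandas.DataFrame
        One row per staged egg chamber with columns ``ovariole_id``, ``stage``
        (2-14), ``midsection_area_um2`` and ``oocyte_fraction`` (NaN when the
        oocyte was not measurable, i.e. pre-vitellogenic chambers). Synthetic
        surveys additionally carry ground-truth ``true_age_h``.
    """

    females: pd.DataFrame
    chambers: pd.DataFrame

    def __post_init__(self) -> None:
        st = self.chambers["stage"]
        if len(st) and not st.between(STAGES[0], STAGES[-1]).all():
            raise ValueError("chamber stages must lie in 2..14")
        area = self.chambers["midsection_area_um2"]
        if len(area) and not (area > 0).all():
            raise ValueError("midsection areas must be positive")
        frac = self.chambers["oocyte_fraction"].dropna()
        if len(frac) and not frac.between(0.0, 1.0).all():
            raise ValueError("oocyte fractions must lie in [0, 1]")

    @property
    def ovarioles(self) -> list[list[int]]:
        """Per-ovariole lists of chamber stage calls."""
        return [
            list(g["stage"])
            for _, g in self.chambers.groupby("ovariole_id", sort=True)
        ]


@dataclass(frozen=True)
class StageTimeline:
    """Per-stage schedule inferred from stage frequencies.

    ``durations[s] = frequencies[s] * total_duration_h`` and
    ``cumulative_start[s]`` is the age (hours, stage 2 starts at 0) at which
    stage ``s`` begins.
    """

    frequencies: dict[int, float]
    total_duration_h: float
    durations: dict[int, float] = field(init=False)
    cumulative_start: dict[int, float] = field(init=False)

    def __post_init__(self) -> None:
        total = sum(self.frequencies.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"stage frequencies sum to {total}, expected 1")
        durations = {
            s: self.frequencies.get(s, 0.0) * self.total_duration_h
            for s in STAGES
        }
        starts, t = {}, 0.0
        for s in STAGES:
            starts[s] = t
            t += durations[s]
        object.__setattr__(self, "durations", durations)
        object.__setattr__(self, "cumulative_start", starts)

    def midpoint_age(self, stage: int) -> float:
        """Age at the midpoint of ``stage`` (hours since stage-2 onset)."""
        return self.cumulative_start[stage] + 0.5 * self.durations[stage]


@dataclass(frozen=True)
class GrowthCurve:
    """Two-parameter exponential law ``value(t) = amplitude * exp(rate * t)``.

    ``kind`` records what the value is: a midsection area in um^2 (time axis:
    hours since stage-2 onset) or an oocyte percent, i.e. dimensionless
    fraction (time axis: hours since stage-9 onset).
    """

    amplitude: float
    rate: float
    kind: Literal["area", "oocyte_percent"] = "area"

    def __post_init__(self) -> None:
        if not self.amplitude > 0:
            raise ValueError("amplitude must be positive")
        if not self.rate > 0:
            raise ValueError("rate must be positive")


#: Standard area growth curve, A = 273 * exp(0.06 t) um^2.
STANDARD_AREA_CURVE = GrowthCurve(273.0, 0.06, "area")
#: Standard oocyte-percent curve, O = 0.318 * exp(0.07 t).
STANDARD_OOCYTE_CURVE = GrowthCurve(0.318, 0.07, "oocyte_percent")


# ---------------------------------------------------------------------------
# stage-duration inference
# ---------------------------------------------------------------------------

def compute_epr(mean_eggs_per_day: float, mean_ovarioles: float) -> float:
    """Egg production rate per ovariole per day, EPR = E / O."""
    if not mean_ovarioles > 0:
        raise ValueError("mean_ovarioles must be positive")
    if mean_eggs_per_day < 0:
        raise ValueError("mean_eggs_per_day must be non-negative")
    return mean_eggs_per_day / mean_ovarioles


def compute_total_duration(
    mean_chambers_per_ovariole: float, epr: float
) -> float:
    """Total stage 2 -> 14 transit time G = EO / EPR, in hours.

    EPR has units eggs/ovariole/day, so EO/EPR is in days; the result is
    converted to hours.
    """
    if not epr > 0:
        raise ValueError("epr must be positive")
    if not mean_chambers_per_ovariole > 0:
        raise ValueError("mean_chambers_per_ovariole must be positive")
    return mean_chambers_per_ovariole / epr * HOURS_PER_DAY


def stage_frequencies(survey: FixedSurvey) -> dict[int, float]:
    """Empirical stage-frequency distribution over all staged chambers."""
    n = len(survey.chambers)
    if n == 0:
        raise ValueError("survey contains no staged chambers")
    counts = survey.chambers["stage"].value_counts()
    return {s: float(counts.get(s, 0)) / n for s in STAGES}


def stage_durations(
    frequencies: Mapping[int, float], total_duration_h: float
) -> StageTimeline:
    """Convert stage frequencies into per-stage durations, Gs = f_s * G."""
    return StageTimeline(dict(frequencies), total_duration_h)


def survey_means(survey: FixedSurvey) -> tuple[float, float, float]:
    """(E, O, EO): eggs/female/day, ovarioles/female, chambers/ovariole."""
    e = float(survey.females["eggs_24h"].mean())
    o = float(survey.females["ovariole_count"].mean())
    eo = float(survey.chambers.groupby("ovariole_id").size().mean())
    return e, o, eo


def estimate_timeline(survey: FixedSurvey) -> StageTimeline:
    """Full chain: survey -> EPR -> G -> stage frequencies -> timeline."""
    e, o, eo = survey_means(survey)
    g = compute_total_duration(eo, compute_epr(e, o))
    return stage_durations(stage_frequencies(survey), g)


# ---------------------------------------------------------------------------
# growth curves
# ---------------------------------------------------------------------------

def fit_growth_curve(
    points: Sequence[tuple[float, float]] | np.ndarray,
    kind: Literal["area", "oocyte_percent"] = "area",
) -> GrowthCurve:
    """Least-squares fit of an exponential growth law to (age, value) points.

    The fit is log-linear: ordinary least squares of ln(value) against age,
    which corresponds to a multiplicative (lognormal) error model and is
    deterministic. ``amplitude = exp(intercept)``, ``rate = slope``.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise ValueError("need at least two (age, value) points")
    ages, values = pts[:, 0], pts[:, 1]
    if not np.all(values > 0):
        raise ValueError("values must be positive for a log-linear fit")
    if np.ptp(ages) == 0:
        raise ValueError("ages are degenerate (all identical)")
    slope, intercept = np.polyfit(ages, np.log(values), 1)
    return GrowthCurve(float(np.exp(intercept)), float(slope), kind)


def fit_survey_area_curve(
    survey: FixedSurvey, tl: StageTimeline | None = None
) -> GrowthCurve:
    """Standard area growth curve from a fixed-sample survey.

    Each chamber contributes one (age, area) point, the age being the
    midpoint of its stage under the survey-estimated timeline (an unbiased
    within-stage placement given only the stage call).
    """
    if tl is None:
        tl = estimate_timeline(survey)
    ch = survey.chambers
    pts = np.column_stack(
        [
            [tl.midpoint_age(int(s)) for s in ch["stage"]],
            ch["midsection_area_um2"].to_numpy(dtype=float),
        ]
    )
    return fit_growth_curve(pts, "area")


def fit_survey_oocyte_curve(
    survey: FixedSurvey, tl: StageTimeline | None = None
) -> GrowthCurve:
    """Oocyte-percent growth curve from vitellogenic chambers (stages 8-11).

    Ages are measured from stage-9 onset (where the oocyte reaches ~30% of
    the midsection); only chambers with a measured oocyte fraction enter.
    Near-saturated fractions (>= 0.9) are excluded: once the oocyte fills the
    midsection the percent plateaus and no longer follows the exponential.
    """
    if tl is None:
        tl = estimate_timeline(survey)
    ch = survey.chambers
    sel = ch[(ch["stage"] >= 8) & (ch["stage"] <= 11)].dropna(
        subset=["oocyte_fraction"]
    )
    sel = sel[sel["oocyte_fraction"] < 0.9]
    if len(sel) < 2:
        raise ValueError("need at least 2 vitellogenic chambers with oocyte fraction")
    t9 = tl.cumulative_start[9]
    pts = np.column_stack(
        [
            [tl.midpoint_age(int(s)) - t9 for s in sel["stage"]],
            sel["oocyte_fraction"].to_numpy(dtype=float),
        ]
    )
    return fit_growth_curve(pts, "oocyte_percent")


def predict(curve: GrowthCurve, t: float | np.ndarray) -> float | np.ndarray:
    """Curve value at age ``t`` hours: amplitude * exp(rate * t)."""
    out = curve.amplitude * np.exp(curve.rate * np.asarray(t, dtype=float))
    return float(out) if out.ndim == 0 else out


def invert_time(
    curve: GrowthCurve, value: float | np.ndarray
) -> float | np.ndarray:
    """Age at which the curve reaches ``value``: ln(value/amplitude)/rate.

    Used to assign the initial age t0 of a live-imaged chamber from its first
    measured area (or oocyte percent).
    """
    v = np.asarray(value, dtype=float)
    if np.any(v <= 0):
        raise ValueError("value must be positive")
    out = np.log(v / curve.amplitude) / curve.rate
    return float(out) if out.ndim == 0 else out


def area_oocyte_correlation(chambers: pd.DataFrame) -> tuple[float, int]:
    """Pearson correlation of ln(area) vs ln(oocyte fraction).

    Only chambers with both quantities present contribute. Returns the
    coefficient and the number of chambers used.
    """
    both = chambers.dropna(subset=["midsection_area_um2", "oocyte_fraction"])
    both = both[both["oocyte_fraction"] > 0]
    n = len(both)
    if n < 3:
        raise ValueError("need at least 3 chambers with area and oocyte fraction")
    r, _ = stats.pearsonr(
        np.log(both["midsection_area_um2"]), np.log(both["oocyte_fraction"])
    )
    return float(r), n


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

def format_report(
    e: float, o: float, eo: float, frequencies: Mapping[int, float]
) -> str:
    """Human-readable timeline report with display rounding.

    Rounding (EPR to 2 decimals, G to whole hours, Gs to 2 decimals) is applied
    here only; the computation chain underneath is unrounded.
    """
    epr = compute_epr(e, o)
    g = compute_total_duration(eo, epr)
    tl = stage_durations(frequencies, g)
    lines = [
        f"eggs/female/day (E)        = {e:g}",
        f"ovarioles/female (O)       = {o:g}",
        f"chambers/ovariole (EO)     = {eo:g}",
        f"egg production rate (EPR)  = {epr:.2f} eggs/ovariole/day",
        f"total duration (G)         = {g:.0f} h",
        "stage  freq    Gs (h)  start (h)",
    ]
    for s in STAGES:
        lines.append(
            f"  {s:>2}   {tl.frequencies.get(s, 0.0):.3f}  {tl.durations[s]:6.2f}"
            f"   {tl.cumulative_start[s]:7.2f}"
        )
    return "\n".join(lines)
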
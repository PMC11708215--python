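"""Alignment of live egg-chamber growth traces to the standard growth curve.

A live-imaged chamber enters the session at an unknown developmental age. The
first measured size fixes that age: t0 = invert_time(curve, first value), and
subsequent samples sit at t0 + elapsed imaging time. Growth relative to
expectation is then observed / predicted at each absolute age; values below 1
quantify the growth slow-down under restraint and anesthesia.

Pre-vitellogenic chambers align by midsection area; once the oocyte reaches
~30% of the midsection (stage-8 completion), growth is yolk-driven and the
oocyte-percent curve gives the more reliable age, so ``by='auto'`` switches
on oocyte_fraction >= 0.30.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .timeline import GrowthCurve, invert_time, predict

__all__ = [
    "EggChamberTrace",
    "align_trace",
    "choose_alignment_quantity",
    "percent_of_expected",
    "cohort_percent_of_expected",
    "VITELLOGENIC_OOCYTE_FRACTION",
]

#: oocyte fraction marking stage-8 completion: the boundary for auto-switching
#: from area-based to oocyte-percent-based alignment.
VITELLOGENIC_OOCYTE_FRACTION = 0.30


@dataclass
class EggChamberTrace:
    """Midsection-area samples of one live-imaged chamber.

    ``samples`` has columns ``elapsed_h`` (strictly increasing, 0 at the first
    frame), ``area_um2`` and optionally ``oocyte_fraction``. ``t0_h`` is the
    assigned age at the first frame (NaN until aligned). For oocyte-percent
    alignment, ages are on the oocyte curve's own axis (stage-9 onset = 0).
    """

    chamber_id: str
    samples: pd.DataFrame
    t0_h: float = float("nan")

    def __post_init__(self) -> None:
        el = self.samples["elapsed_h"].to_numpy()
        if len(el) == 0:
            raise ValueError("trace has no samples")
        if len(el) > 1 and not np.all(np.diff(el) > 0):
            raise ValueError("elapsed times must be strictly increasing")
        if not (self.samples["area_um2"] > 0).all():
            raise ValueError("areas must be positive")

    @property
    def aligned(self) -> bool:
        return np.isfinite(self.t0_h)

    @property
    def ages_h(self) -> np.ndarray:
        if not self.aligned:
            raise ValueError("trace is not aligned (t0 unknown)")
        return self.t0_h + self.samples["elapsed_h"].to_numpy()


def choose_alignment_quantity(trace: EggChamberTrace) -> str:
    """'oocyte_percent' for vitellogenic first frames, else 'area'."""
    first = trace.samples.iloc[0]
    frac = first.get("oocyte_fraction", np.nan)
    if np.isfinite(frac) and frac >= VITELLOGENIC_OOCYTE_FRACTION:
        return "oocyte_percent"
    return "area"


def align_trace(
    trace: EggChamberTrace, curve: GrowthCurve, by: str = "area"
) -> EggChamberTrace:
    """Assign the initial age from the first sample's size.

    ``by`` is 'area', 'oocyte_percent' or 'auto'; the named quantity of the
    first sample is inverted through the curve to give t0. The elapsed-time
    column is untouched: alignment is a pure translation of the time axis.
    """
    if by == "auto":
        by = choose_alignment_quantity(trace)
    first = trace.samples.iloc[0]
    if by == "area":
        value = first["area_um2"]
    elif by == "oocyte_percent":
        value = first.get("oocyte_fraction", np.nan)
        if not np.isfinite(value):
            raise ValueError(
                f"trace {trace.chamber_id}: first sample has no oocyte "
                "fraction to align by"
            )
    else:
        raise ValueError(f"unknown alignment quantity {by!r}")
    if curve.kind != ("area" if by == "area" else "oocyte_percent"):
        raise ValueError(f"curve kind {curve.kind!r} does not match by={by!r}")
    return replace(trace, t0_h=float(invert_time(curve, float(value))))


def percent_of_expected(
    trace: EggChamberTrace, curve: GrowthCurve
) -> pd.DataFrame:
    """Observed area / curve-predicted area at each sample of an aligned trace.

    Columns: elapsed_h, age_h, observed_um2, expected_um2, fraction.
    """
    if not trace.aligned:
        raise ValueError("align the trace before computing percent of expected")
    ages = trace.ages_h
    observed = trace.samples["area_um2"].to_numpy(dtype=float)
    expected = predict(curve, ages)
    return pd.DataFrame(
        {
            "elapsed_h": trace.samples["elapsed_h"].to_numpy(),
            "age_h": ages,
            "observed_um2": observed,
            "expected_um2": expected,
            "fraction": observed / expected,
        }
    )


def cohort_percent_of_expected(
    traces: list[EggChamberTrace],
    curve: GrowthCurve,
    elapsed_times: np.ndarray | list[float],
) -> pd.DataFrame:
    """Cohort-mean fraction of expected size at chosen elapsed times.

    Each trace's fraction series is linearly interpolated in elapsed time;
    traces whose sampling does not cover an elapsed time are excluded there.
    Columns: elapsed_h, mean_fraction, n_traces.
    """
    elapsed_times = np.asarray(elapsed_times, dtype=float)
    rows = []
    per_trace = [percent_of_expected(t, curve) for t in traces]
    for e in elapsed_times:
        vals = [
            float(np.interp(e, pt["elapsed_h"], pt["fraction"]))
            for pt in per_trace
            if pt["elapsed_h"].iloc[0] <= e <= pt["elapsed_h"].iloc[-1]
        ]
        rows.append(
            {
                "elapsed_h": e,
                "mean_fraction": float(np.mean(vals)) if vals else np.nan,
                "n_traces": len(vals),
            }
        )
    return pd.DataFrame(rows)
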
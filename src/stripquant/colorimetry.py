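"""Time courses, the per-channel intensity-drop score, and replicate stats.

The enzymatic reaction turns the spot from the pale paper tone toward
indigo, so every channel darkens over time.  The assay score of a spot
is the signed intensity drop

    dI_c = I_c(0) - I_c(t_end)      for c in {R, G, B},

positive when the spot darkened.  Scores are computed per replicate and
then summarized, so replicate scatter propagates into the reported
standard deviations rather than being averaged away at the reading
stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError, InsufficientReplicatesError
from .imaging import ColorReading

__all__ = [
    "TimeCourse",
    "DeltaIntensity",
    "ReplicateSet",
    "delta_intensity",
    "replicate_stats",
    "control_change_test",
    "select_endpoint",
    "time_courses_from_frame",
    "delta_frame",
    "summarize_deltas",
]

CHANNELS = ("R", "G", "B")
_CHANNEL_COLUMN = {"R": "r", "G": "g", "B": "b"}


@dataclass(frozen=True)
class TimeCourse:
    """Readings of one spot over the capture schedule.

    ``times`` must be strictly increasing and start at 0 because the
    score is defined against the t = 0 photograph.
    """

    label: str
    times: tuple
    readings: tuple
    replicate: int = 0

    def __post_init__(self):
        times = tuple(float(t) for t in self.times)
        readings = tuple(self.readings)
        if len(times) != len(readings):
            raise InputError("times and readings must have equal length")
        if not times or times[0] != 0:
            raise InputError("a time course must start at t = 0 min")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise InputError("times must be strictly increasing")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "readings", readings)

    def at(self, t: float) -> ColorReading:
        for ti, rd in zip(self.times, self.readings):
            if ti == t:
                return rd
        raise LookupError(f"no reading at t = {t} min for {self.label!r}")

    def channel_series(self, channel: str) -> np.ndarray:
        return np.array([rd.channel(channel) for rd in self.readings], dtype=float)


@dataclass(frozen=True)
class DeltaIntensity:
    """Per-channel intensity drop of one spot between t = 0 and t_end."""

    label: str
    t_end: float
    d_r: float
    d_g: float
    d_b: float
    replicate: int = 0

    def channel(self, name: str) -> float:
        return {"R": self.d_r, "G": self.d_g, "B": self.d_b}[name.upper()]


@dataclass(frozen=True)
class ReplicateSet:
    """Replicate values of one condition with mean and sample SD (n-1)."""

    label: str
    values: tuple
    mean: float = field(init=False)
    sd: float = field(init=False)

    def __post_init__(self):
        vals = tuple(float(v) for v in self.values)
        if len(vals) < 2:
            raise InsufficientReplicatesError(
                f"need >= 2 replicate values for {self.label!r}, got {len(vals)}"
            )
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "mean", float(np.mean(vals)))
        object.__setattr__(self, "sd", float(np.std(vals, ddof=1)))

    @property
    def n(self) -> int:
        return len(self.values)


def delta_intensity(tc: TimeCourse, t_end: float) -> DeltaIntensity:
    """Score one time course: ``I(0) - I(t_end)`` per channel."""
    if t_end <= 0:
        raise InputError(f"t_end must be > 0, got {t_end}")
    start = tc.at(0.0)
    end = tc.at(float(t_end))
    return DeltaIntensity(
        label=tc.label,
        t_end=float(t_end),
        d_r=float(start.r - end.r),
        d_g=float(start.g - end.g),
        d_b=float(start.b - end.b),
        replicate=tc.replicate,
    )


def replicate_stats(values, label: str = "") -> ReplicateSet:
    """Mean and sample standard deviation of replicate measurements."""
    return ReplicateSet(label=label, values=tuple(values))


def control_change_test(groups) -> tuple[float, float]:
    """One-way fixed-effects ANOVA across time points.

    Used to confirm that untreated control strips show no color change
    over the capture schedule: the control passes when p > 0.05.
    Identical constant groups are the no-signal limit and return
    (F, p) = (0, 1).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise InputError("need >= 2 groups (time points)")
    for g in groups:
        if len(g) < 2:
            raise InsufficientReplicatesError(
                "every time point needs >= 2 replicate values"
            )
    allvals = np.concatenate(groups)
    if np.ptp(allvals) == 0:
        return 0.0, 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f, p = stats.f_oneway(*groups)
    return float(f), float(p)


def select_endpoint(
    tc_set,
    channel: str = "R",
    plateau_fraction: float = 0.05,
) -> float:
    """Choose the capture time at which the coloration has plateaued.

    Returns the earliest recorded time t with mean remaining change
    ``|I(t) - I(t_max)| <= plateau_fraction * |I(0) - I(t_max)|``
    (averaged over the supplied time courses).  With the default 5%
    threshold the reaction kinetics observed for undiluted plasma put
    the endpoint at 30 min.  A flat series returns t_max with a warning.
    """
    tc_set = list(tc_set)
    if not tc_set:
        raise InputError("need at least one time course")
    times = tc_set[0].times
    if len(times) < 3:
        raise InputError("need >= 3 time points to locate a plateau")
    for tc in tc_set[1:]:
        if tc.times != times:
            raise InputError("all time courses must share one time grid")
    series = np.vstack([tc.channel_series(channel) for tc in tc_set])
    mean = series.mean(axis=0)
    total = abs(mean[0] - mean[-1])
    if total == 0:
        warnings.warn(
            "flat series: no net color change; returning the final time",
            stacklevel=2,
        )
        return float(times[-1])
    remaining = np.abs(mean - mean[-1]) / total
    idx = int(np.argmax(remaining <= plateau_fraction))
    return float(times[idx])


# ---------------------------------------------------------------------------
# DataFrame plumbing over the shared readings table


def time_courses_from_frame(frame: pd.DataFrame) -> list[TimeCourse]:
    """Group a readings table into one TimeCourse per (label, replicate)."""
    if "replicate" not in frame.columns:
        frame = frame.assign(replicate=0)
    courses = []
    for (label, rep), grp in frame.groupby(["label", "replicate"], sort=True):
        grp = grp.sort_values("time_min")
        readings = tuple(
            ColorReading(
                r=int(row.r), g=int(row.g), b=int(row.b),
                time_min=float(row.time_min), label=str(label),
            )
            for row in grp.itertuples()
        )
        courses.append(
            TimeCourse(
                label=str(label),
                times=tuple(grp["time_min"]),
                readings=readings,
                replicate=int(rep),
            )
        )
    return courses


def delta_frame(frame: pd.DataFrame, t_end: float) -> pd.DataFrame:
    """Per-replicate intensity-drop scores from a readings table."""
    rows = []
    for tc in time_courses_from_frame(frame):
        d = delta_intensity(tc, t_end)
        rows.append(
            {
                "label": d.label,
                "replicate": d.replicate,
                "t_end": d.t_end,
                "d_r": d.d_r,
                "d_g": d.d_g,
                "d_b": d.d_b,
            }
        )
    return pd.DataFrame(rows)


def summarize_deltas(deltas: pd.DataFrame) -> pd.DataFrame:
    """Replicate mean, SD and n of each channel score per sample label."""
    out = []
    for label, grp in deltas.groupby("label", sort=True):
        row = {"label": label, "t_end": grp["t_end"].iloc[0], "n": len(grp)}
        for ch in CHANNELS:
            col = "d_" + _CHANNEL_COLUMN[ch]
            vals = grp[col].to_numpy(dtype=float)
            row["mean_" + col] = float(vals.mean())
            row["sd_" + col] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        out.append(row)
    return pd.DataFrame(out)
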
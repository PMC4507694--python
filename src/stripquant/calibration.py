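"""Boltzmann calibration of intensity-drop scores against enzyme activity.

The calibration curve is the four-parameter Boltzmann sigmoid

    y(x) = a2 + (a1 - a2) / (1 + exp((x - x0) / dx)),

with x the enzyme activity (kat/mL, linear scale by default), y the
channel score dI, a1 the blank (low-activity) asymptote, a2 the
saturation asymptote, x0 the activity at half transition and dx > 0 the
transition width.  The closed-form inverse

    x(y) = x0 + dx * ln((y - a1) / (a2 - y)),   a1 < y < a2,

turns a measured score into an activity estimate.  The limit of
detection follows the S/N = 3 convention: the activity whose predicted
signal exceeds the blank mean by three blank standard deviations.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .errors import (
    CalibrationRangeError,
    FitError,
    InputError,
    InsufficientReplicatesError,
    LODUndefinedError,
)

__all__ = [
    "BoltzmannCalibration",
    "LODEstimate",
    "boltzmann",
    "fit_boltzmann",
    "invert",
    "lod_sn3",
    "rank_channels",
    "save_calibration",
    "load_calibration",
]

CHANNELS = ("R", "G", "B")

# Fixed fit settings, recorded for reproducibility.
FIT_MAXFEV = 10000
FIT_XTOL = 1e-8


def boltzmann(x, a1, a2, x0, dx):
    """Four-parameter Boltzmann sigmoid, increasing from a1 to a2."""
    x = np.asarray(x, dtype=float)
    return a2 + (a1 - a2) / (1.0 + np.exp((x - x0) / dx))


@dataclass(frozen=True)
class BoltzmannCalibration:
    """Fitted sigmoid linking a channel's score to enzyme activity."""

    channel: str
    a1: float
    a2: float
    x0: float
    dx: float
    r_squared: float
    n_points: int = 0
    log_activity: bool = False

    def __post_init__(self):
        if self.dx <= 0:
            raise InputError(f"transition width dx must be > 0, got {self.dx}")

    @property
    def dynamic_range(self) -> float:
        return self.a2 - self.a1

    def _x(self, activity):
        return np.log10(activity) if self.log_activity else activity

    def predict(self, activity):
        """Predicted score at an activity (kat/mL)."""
        return boltzmann(self._x(activity), self.a1, self.a2, self.x0, self.dx)

    def slope_at_zero(self) -> float:
        """Derivative of the curve with respect to activity at activity 0.

        Only meaningful for the linear-activity parameterization."""
        if self.log_activity:
            raise InputError("low-end slope undefined for log-activity fits")
        e = math.exp((0.0 - self.x0) / self.dx)
        return (self.a2 - self.a1) * e / (self.dx * (1.0 + e) ** 2)


@dataclass(frozen=True)
class LODEstimate:
    """S/N = 3 limit of detection derived from blank replicates."""

    channel: str
    blank_mean: float
    blank_sd: float
    lod: float
    method: str = "invert"  # "invert" | "slope" | "degenerate"

    @property
    def degenerate(self) -> bool:
        return self.method == "degenerate"


def fit_boltzmann(
    activities,
    delta_i,
    channel: str = "R",
    log_activity: bool = False,
) -> BoltzmannCalibration:
    """Unweighted least-squares fit of the Boltzmann curve.

    Requires at least 5 distinct activity levels, one of them a blank
    (activity 0) on the linear scale so the low asymptote is anchored.
    Initialization: a1 = min(y), a2 = max(y), x0 = median(x),
    dx = range(x)/4; relative tolerance 1e-8, at most 10000 evaluations.
    """
    x = np.asarray(activities, dtype=float)
    y = np.asarray(delta_i, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError("activities and delta_i must be equal-length 1-D")
    if log_activity:
        if np.any(x <= 0):
            raise InputError("log-activity fit requires strictly positive activities")
        x = np.log10(x)
    n_levels = len(np.unique(x))
    if n_levels < 5:
        raise InputError(
            f"need >= 5 distinct activity levels, got {n_levels}"
        )
    if np.ptp(y) == 0:
        raise FitError(
            "all scores identical: a2 - a1 is not identifiable",
            p0=None,
        )
    p0 = [float(y.min()), float(y.max()), float(np.median(x)), float(np.ptp(x)) / 4.0]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                boltzmann, x, y, p0=p0, maxfev=FIT_MAXFEV, xtol=FIT_XTOL
            )
    except RuntimeError as exc:
        resid = y - boltzmann(x, *p0)
        raise FitError(f"Boltzmann fit did not converge: {exc}", p0=p0,
                       residuals=resid) from exc
    a1, a2, x0, dx = (float(v) for v in popt)
    if dx < 0:  # (a1,a2,x0,-dx) with swapped asymptotes is the same curve
        a1, a2, dx = a2, a1, -dx
    resid = y - boltzmann(x, a1, a2, x0, dx)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot
    return BoltzmannCalibration(
        channel=channel,
        a1=a1,
        a2=a2,
        x0=x0,
        dx=dx,
        r_squared=r2,
        n_points=len(x),
        log_activity=log_activity,
    )


def invert(cal: BoltzmannCalibration, y: float) -> float:
    """Activity whose predicted score equals ``y`` (closed form).

    Defined for scores strictly between the asymptotes; at the midpoint
    (a1 + a2)/2 the inverse is exactly x0.
    """
    lo, hi = min(cal.a1, cal.a2), max(cal.a1, cal.a2)
    if y <= lo:
        raise CalibrationRangeError(
            f"score {y} at or below the blank asymptote a1 = {cal.a1:.6g}"
        )
    if y >= hi:
        raise CalibrationRangeError(
            f"score {y} at or above the saturation asymptote a2 = {cal.a2:.6g}"
        )
    x = cal.x0 + cal.dx * math.log((y - cal.a1) / (cal.a2 - y))
    if cal.log_activity:
        return 10.0 ** x
    return x


def lod_sn3(
    cal: BoltzmannCalibration,
    blanks,
    eps_fraction: float = 1e-6,
) -> LODEstimate:
    """S/N = 3 limit of detection from blank (zero-activity) replicates.

    The target signal is ``blank_mean + 3 * blank_sd``.  When that
    signal lies inside the curve's range it is inverted directly; when
    it falls at or below the low asymptote (within a tiny epsilon of the
    dynamic range) the low-end local slope s of the curve at activity 0
    is used instead: LOD = 3 * blank_sd / s.  Zero blank scatter returns
    LOD = 0 flagged degenerate.
    """
    blanks = np.asarray(blanks, dtype=float)
    if len(blanks) < 2:
        raise InsufficientReplicatesError("need >= 2 blank replicates")
    if cal.a2 <= cal.a1:
        raise InputError("LOD requires an increasing calibration (a2 > a1)")
    bm = float(blanks.mean())
    bs = float(blanks.std(ddof=1))
    if bs == 0.0:
        return LODEstimate(cal.channel, bm, bs, 0.0, method="degenerate")
    target = bm + 3.0 * bs
    if target >= cal.a2:
        raise LODUndefinedError(
            f"blank mean + 3 SD = {target:.4g} exceeds the saturation "
            f"asymptote a2 = {cal.a2:.4g}; the assay cannot detect"
        )
    eps = eps_fraction * cal.dynamic_range
    if target > cal.a1 + eps:
        lod = invert(cal, target)
        method = "invert"
    else:
        s = cal.slope_at_zero()
        if s <= 0:
            raise LODUndefinedError("calibration has non-positive low-end slope")
        lod = 3.0 * bs / s
        method = "slope"
    return LODEstimate(cal.channel, bm, bs, float(lod), method=method)


def rank_channels(cals, lods) -> list[str]:
    """Channels ordered best-first: ascending LOD, ties broken by
    descending dynamic range, then the fixed order R, G, B."""
    cal_by = {c.channel: c for c in cals}
    lod_by = {l.channel: l for l in lods}
    if set(cal_by) != set(lod_by):
        raise InputError("need one calibration and one LOD per channel")
    fixed = {ch: i for i, ch in enumerate(CHANNELS)}
    return sorted(
        cal_by,
        key=lambda ch: (
            lod_by[ch].lod,
            -cal_by[ch].dynamic_range,
            fixed.get(ch, len(fixed)),
        ),
    )


def save_calibration(cal: BoltzmannCalibration, path, lod: LODEstimate | None = None):
    """Store a calibration (and optionally its LOD) as JSON."""
    doc = {
        "channel": cal.channel,
        "a1": cal.a1,
        "a2": cal.a2,
        "x0": cal.x0,
        "dx": cal.dx,
        "r_squared": cal.r_squared,
        "n_points": cal.n_points,
        "log_activity": cal.log_activity,
        "fit": {"maxfev": FIT_MAXFEV, "xtol": FIT_XTOL},
    }
    if lod is not None:
        doc["lod"] = {
            "blank_mean": lod.blank_mean,
            "blank_sd": lod.blank_sd,
            "lod": lod.lod,
            "method": lod.method,
        }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2)


def load_calibration(path) -> tuple[BoltzmannCalibration, LODEstimate | None]:
    with open(path) as fh:
        doc = json.load(fh)
    cal = BoltzmannCalibration(
        channel=doc["channel"],
        a1=doc["a1"],
        a2=doc["a2"],
        x0=doc["x0"],
        dx=doc["dx"],
        r_squared=doc["r_squared"],
        n_points=doc.get("n_points", 0),
        log_activity=doc.get("log_activity", False),
    )
    lod = None
    if "lod" in doc:
        d = doc["lod"]
        lod = LODEstimate(
            channel=cal.channel,
            blank_mean=d["blank_mean"],
            blank_sd=d["blank_sd"],
            lod=d["lod"],
            method=d["method"],
        )
    return cal, lod
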
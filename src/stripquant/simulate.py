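"""Synthetic strip-image generator driven by chromogenic reaction kinetics.

The enzyme hydrolyses the colorless substrate soaked into the paper;
the product oxidizes to indigo, darkening the spot.  The simulator
abstracts that chemistry into a per-channel first-order approach to an
asymptote:

    I_c(t) = i0_c - (i0_c - iinf_c) * (1 - exp(-k(a) * t)),
    k(a)   = k_ref * a / a_ref,

with i0 the undeveloped paper-plus-sample tone, iinf the fully
developed indigo tone, and a rate proportional to enzyme activity a.
The defaults are calibrated so that at the reference plasma activity
a_ref = 2.73e-5 kat/mL the red channel runs 221 -> 41 -> 32 over
0/30/60 min, with green 195 -> 68 and blue 158 -> 84 at 60 min.

Noise model (both knobs default to the replicate scatter seen in
pentaplicate strip work, SDs of roughly 5-8 intensity units on the
difference score):

* replicate noise: one Gaussian draw per spot per capture, shared by
  the three channels — it emulates capture-to-capture luminance
  variation (flash, drop placement), which moves all channels together;
* pixel noise: independent Gaussian per pixel and channel (sensor
  noise and paper texture);

followed by clipping to [0, 255] and 8-bit quantization.  Every
stochastic operation takes an explicit seed; there is no global RNG
state.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import GeometryError, InputError
from .imaging import READINGS_COLUMNS, RGBImage, SpotROI, save_image

__all__ = [
    "REFERENCE_ACTIVITY",
    "KineticParams",
    "SimulationConfig",
    "SpotRecord",
    "SimulationManifest",
    "interior_color",
    "render_series",
    "make_readings",
    "write_series",
    "default_activities",
]

#: Reference plasma activity (kat/mL) at which k_ref was calibrated.
REFERENCE_ACTIVITY = 2.73e-5

DEFAULT_TIMES = tuple(range(0, 61, 5))


def default_activities(stock: float = REFERENCE_ACTIVITY, n_dilutions: int = 5,
                       include_blank: bool = True) -> tuple:
    """Two-fold dilution levels of a stock plus an optional blank."""
    acts = [stock / 2**k for k in range(n_dilutions + 1)]
    if include_blank:
        acts.append(0.0)
    return tuple(acts)


@dataclass(frozen=True)
class KineticParams:
    """Per-channel kinetic endpoints and the activity-scaled rate."""

    i0: tuple = (221.0, 195.0, 158.0)
    i_inf: tuple = (32.0, 68.0, 84.0)
    k_ref: float = 0.1015            # min^-1 at reference_activity
    reference_activity: float = REFERENCE_ACTIVITY

    def __post_init__(self):
        if len(self.i0) != 3 or len(self.i_inf) != 3:
            raise InputError("i0 and i_inf must be RGB triples")
        for c in range(3):
            if not (0 <= self.i_inf[c] <= self.i0[c] <= 255):
                raise InputError(
                    "need 0 <= i_inf <= i0 <= 255 per channel (darkening)"
                )
        if self.k_ref <= 0 or self.reference_activity <= 0:
            raise InputError("k_ref and reference_activity must be > 0")

    def rate(self, activity: float) -> float:
        return self.k_ref * activity / self.reference_activity


@dataclass(frozen=True)
class SimulationConfig:
    """Study design of one simulated experiment."""

    activities: tuple = field(default_factory=default_activities)
    times: tuple = DEFAULT_TIMES
    replicates: int = 5
    pixel_noise_sd: float = 2.0
    replicate_noise_sd: float = 4.0
    spot_radius: int = 12
    image_size: tuple | None = None        # (width, height); derived if None
    background: tuple = (235, 232, 225)
    seed: int = 0
    inhibition_fraction: float = 0.0

    def __post_init__(self):
        times = tuple(float(t) for t in self.times)
        if not times or times[0] != 0 or any(
            b <= a for a, b in zip(times, times[1:])
        ):
            raise InputError("times must strictly increase from 0")
        object.__setattr__(self, "times", times)
        object.__setattr__(
            self, "activities", tuple(float(a) for a in self.activities)
        )
        if any(a < 0 for a in self.activities):
            raise InputError("activities must be >= 0")
        if self.replicates < 1:
            raise InputError("replicates must be >= 1")
        if self.pixel_noise_sd < 0 or self.replicate_noise_sd < 0:
            raise InputError("noise SDs must be >= 0")
        if self.spot_radius < 2:
            raise InputError("spot_radius must be >= 2")
        if not (0.0 <= self.inhibition_fraction <= 1.0):
            raise InputError("inhibition_fraction must lie in [0, 1]")

    def effective_activity(self, activity: float) -> float:
        return activity * (1.0 - self.inhibition_fraction)

    def labels(self) -> list[str]:
        return [f"lvl{i:02d}" for i in range(len(self.activities))]

    def layout(self) -> tuple[tuple, list[float], float]:
        """(image (width, height), spot center x's, center y)."""
        r = self.spot_radius
        spacing = 4 * r
        margin = 2 * r
        n = len(self.activities)
        width = 2 * margin + (n - 1) * spacing
        height = 4 * r
        if self.image_size is not None:
            width, height = self.image_size
        xs = [margin + i * spacing for i in range(n)]
        return (width, height), xs, height / 2.0


@dataclass(frozen=True)
class SpotRecord:
    """Ground truth for one rendered spot (one activity x replicate)."""

    label: str
    activity: float            # nominal activity of the level
    effective_activity: float  # after any inhibition
    replicate: int
    center_x: float
    center_y: float
    radius: float
    colors: dict               # time (min) -> noise-free (r, g, b) floats


@dataclass(frozen=True)
class SimulationManifest:
    """Ground truth of a rendered series: the test oracle."""

    seed: int
    spots: tuple
    times: tuple
    files: dict = field(default_factory=dict)  # (time, replicate) -> path

    def spot(self, label: str, replicate: int) -> SpotRecord:
        for s in self.spots:
            if s.label == label and s.replicate == replicate:
                return s
        raise LookupError(f"no spot {label!r} replicate {replicate}")

    def rois(self) -> list[SpotROI]:
        seen = {}
        for s in self.spots:
            seen.setdefault(s.label, SpotROI(s.center_x, s.center_y, s.radius, s.label))
        return list(seen.values())

    def to_json(self) -> str:
        doc = {
            "seed": self.seed,
            "times": list(self.times),
            "files": {f"{t}:{r}": p for (t, r), p in self.files.items()},
            "spots": [
                {**asdict(s), "colors": {str(t): list(c) for t, c in s.colors.items()}}
                for s in self.spots
            ],
        }
        return json.dumps(doc, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SimulationManifest":
        doc = json.loads(text)
        spots = tuple(
            SpotRecord(
                label=s["label"],
                activity=s["activity"],
                effective_activity=s["effective_activity"],
                replicate=s["replicate"],
                center_x=s["center_x"],
                center_y=s["center_y"],
                radius=s["radius"],
                colors={float(t): tuple(c) for t, c in s["colors"].items()},
            )
            for s in doc["spots"]
        )
        files = {}
        for key, p in doc.get("files", {}).items():
            t, r = key.split(":")
            files[(float(t), int(r))] = p
        return cls(seed=doc["seed"], spots=spots, times=tuple(doc["times"]),
                   files=files)


def interior_color(params: KineticParams, activity: float, t: float) -> tuple:
    """Noise-free spot interior color (float triple) at time t minutes."""
    if activity < 0:
        raise InputError(f"activity must be >= 0, got {activity}")
    if t < 0:
        raise InputError(f"time must be >= 0, got {t}")
    k = params.rate(activity)
    out = []
    for c in range(3):
        i0, iinf = params.i0[c], params.i_inf[c]
        out.append(i0 - (i0 - iinf) * (1.0 - np.exp(-k * t)))
    return tuple(float(v) for v in out)


def _quantize(arr: np.ndarray) -> np.ndarray:
    return np.clip(np.floor(arr + 0.5), 0, 255).astype(np.uint8)


def _build_manifest(cfg: SimulationConfig, params: KineticParams,
                    xs, cy) -> list[SpotRecord]:
    spots = []
    for i, (label, act) in enumerate(zip(cfg.labels(), cfg.activities)):
        eff = cfg.effective_activity(act)
        colors = {t: interior_color(params, eff, t) for t in cfg.times}
        for rep in range(cfg.replicates):
            spots.append(
                SpotRecord(
                    label=label,
                    activity=act,
                    effective_activity=eff,
                    replicate=rep,
                    center_x=float(xs[i]),
                    center_y=float(cy),
                    radius=float(cfg.spot_radius),
                    colors=colors,
                )
            )
    return spots


def render_series(
    cfg: SimulationConfig, params: KineticParams | None = None
) -> tuple[dict, SimulationManifest]:
    """Render one image per (time, replicate), all activity levels as
    left-to-right spots, and return the ground-truth manifest.

    Returns ``(images, manifest)`` with ``images[(time, replicate)]`` an
    :class:`~stripquant.imaging.RGBImage`.  Deterministic given
    ``cfg.seed``.
    """
    params = params or KineticParams()
    (width, height), xs, cy = cfg.layout()
    r = cfg.spot_radius
    for x in xs:
        if not (r <= x < width - r and r <= cy < height - r):
            raise GeometryError(
                f"spot at ({x}, {cy}) radius {r} does not fit the "
                f"{width}x{height} image"
            )
    spots = _build_manifest(cfg, params, xs, cy)
    rng = np.random.default_rng(cfg.seed)
    yy, xx = np.mgrid[0:height, 0:width]
    disk_masks = [((xx - x) ** 2 + (yy - cy) ** 2) <= r**2 for x in xs]

    images = {}
    # Draw order fixed (replicate-major, then time) so seeds reproduce.
    for rep in range(cfg.replicates):
        for t in cfg.times:
            canvas = np.empty((height, width, 3), dtype=float)
            canvas[:] = np.asarray(cfg.background, dtype=float)
            for i, act in enumerate(cfg.activities):
                eff = cfg.effective_activity(act)
                base = np.asarray(interior_color(params, eff, t))
                offset = (
                    rng.normal(0.0, cfg.replicate_noise_sd)
                    if cfg.replicate_noise_sd > 0
                    else 0.0
                )
                canvas[disk_masks[i]] = base + offset
            if cfg.pixel_noise_sd > 0:
                canvas += rng.normal(0.0, cfg.pixel_noise_sd, canvas.shape)
            images[(t, rep)] = RGBImage(_quantize(canvas))
    manifest = SimulationManifest(seed=cfg.seed, spots=tuple(spots),
                                  times=cfg.times)
    return images, manifest


def write_series(images: dict, manifest: SimulationManifest, outdir) -> SimulationManifest:
    """Write rendered images as PNG plus a JSON manifest; returns a
    manifest carrying the file paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files = {}
    for (t, rep), img in sorted(images.items()):
        name = f"strip_t{int(t):03d}_rep{rep}.png"
        save_image(img, outdir / name)
        files[(t, rep)] = name
    manifest = SimulationManifest(
        seed=manifest.seed, spots=manifest.spots, times=manifest.times,
        files=files,
    )
    (outdir / "manifest.json").write_text(manifest.to_json())
    return manifest


def make_readings(
    cfg: SimulationConfig, params: KineticParams | None = None
) -> pd.DataFrame:
    """Draw per-spot readings straight from the kinetic model (replicate
    noise only, no image rendering) — the fast path for statistical
    tests.  Columns follow the shared readings table, plus the true
    ``activity`` of each level for downstream validation."""
    params = params or KineticParams()
    (width, height), xs, cy = cfg.layout()
    rng = np.random.default_rng(cfg.seed)
    rows = []
    for rep in range(cfg.replicates):
        for t in cfg.times:
            for i, (label, act) in enumerate(zip(cfg.labels(), cfg.activities)):
                eff = cfg.effective_activity(act)
                base = np.asarray(interior_color(params, eff, t))
                offset = (
                    rng.normal(0.0, cfg.replicate_noise_sd)
                    if cfg.replicate_noise_sd > 0
                    else 0.0
                )
                vals = _quantize(base + offset)
                rows.append(
                    {
                        "label": label,
                        "replicate": rep,
                        "time_min": t,
                        "center_x": float(xs[i]),
                        "center_y": float(cy),
                        "radius": float(cfg.spot_radius),
                        "r": int(vals[0]),
                        "g": int(vals[1]),
                        "b": int(vals[2]),
                        "activity": act,
                    }
                )
    return pd.DataFrame(rows, columns=READINGS_COLUMNS + ["activity"])
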
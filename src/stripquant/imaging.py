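"""Strip photograph I/O, spot regions, and RGB intensity extraction.

A developed strip carries circular sample spots on a light paper
background.  The raw record of the assay is an 8-bit RGB photograph;
each channel is an integer tone in [0, 255] (256 representable values
per channel).  Readings are taken at the "half semi-diameter" locus of a
spot, i.e. on the circle of radius ``radius / 2`` around the spot
center, which avoids both the rim (drying artifacts) and the exact
center (application artifacts).

Pixel coordinate convention, used throughout the package: origin at the
top-left corner, x increases rightward (columns), y increases downward
(rows), integer coordinates address pixel centers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image, UnidentifiedImageError
from skimage import measure

from .errors import DetectionError, FormatError, GeometryError, InputError

__all__ = [
    "RGBImage",
    "SpotROI",
    "ColorReading",
    "tone_values",
    "load_image",
    "save_image",
    "sample_spot_color",
    "detect_spots",
    "readings_to_frame",
    "write_readings_csv",
    "read_readings_csv",
]

#: Column order of the readings CSV shared by all pipeline stages.
READINGS_COLUMNS = [
    "label",
    "replicate",
    "time_min",
    "center_x",
    "center_y",
    "radius",
    "r",
    "g",
    "b",
]


def tone_values(bit_depth: int) -> int:
    """Number of representable tone values per channel at a bit depth.

    The consumer JPEG pipeline is 8-bit (256 tones per channel); raw or
    TIFF capture at 12-bit would give 4096 and 16-bit capture 65536.
    """
    if bit_depth < 1:
        raise InputError(f"bit depth must be >= 1, got {bit_depth}")
    return 2 ** int(bit_depth)


@dataclass(frozen=True)
class RGBImage:
    """An 8-bit three-channel image, shape ``(height, width, 3)`` uint8."""

    pixels: np.ndarray

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise InputError(f"expected (H, W, 3) pixel array, got shape {px.shape}")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise InputError("image must be at least 1x1")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise InputError("channel values must lie in [0, 255]")
            px = px.astype(np.uint8)
        object.__setattr__(self, "pixels", px)

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def height(self) -> int:
        return self.pixels.shape[0]


@dataclass(frozen=True)
class SpotROI:
    """Circular sample-spot region: center in pixels, radius in pixels."""

    center_x: float
    center_y: float
    radius: float
    label: str = ""

    def __post_init__(self):
        if self.radius < 2:
            raise InputError(
                f"spot radius must be >= 2 px so the half-radius locus is "
                f"distinct from the center (got {self.radius})"
            )


@dataclass(frozen=True)
class ColorReading:
    """Per-channel intensities of one spot at one capture time."""

    r: int
    g: int
    b: int
    time_min: float = 0.0
    label: str = ""

    def __post_init__(self):
        for name in ("r", "g", "b"):
            v = getattr(self, name)
            if not (0 <= v <= 255):
                raise InputError(f"channel {name}={v} outside [0, 255]")
        if self.time_min < 0:
            raise InputError(f"time_min must be >= 0, got {self.time_min}")

    def channel(self, name: str) -> int:
        return {"R": self.r, "G": self.g, "B": self.b}[name.upper()]


def load_image(path) -> RGBImage:
    """Read a PNG or JPEG photograph into an :class:`RGBImage`.

    Grayscale images are replicated across the three channels, alpha is
    discarded, and 16-bit sources are reduced to 8-bit by integer
    division (``value // 256``).
    """
    p = Path(path)
    if not p.exists():
        raise InputError(f"image file not found: {p}")
    try:
        with Image.open(p) as im:
            if im.mode in ("I", "I;16", "I;16B", "I;16L"):
                arr = np.asarray(im).astype(np.int64) // 256
                arr = np.clip(arr, 0, 255).astype(np.uint8)
                arr = np.stack([arr, arr, arr], axis=-1)
            else:
                arr = np.asarray(im.convert("RGB"))
    except UnidentifiedImageError as exc:
        raise FormatError(f"cannot decode image: {p}") from exc
    return RGBImage(arr)


def save_image(img: RGBImage, path) -> None:
    """Write an :class:`RGBImage` as PNG (lossless round trip)."""
    Image.fromarray(img.pixels, mode="RGB").save(path)


def _half_radius_points(roi: SpotROI, n_points: int, start_angle: float = 0.0):
    """Integer pixel positions nearest to n equally spaced points on the
    half-radius circle.  Angle 0 points along +x, so n_points=1 is the
    single pixel at (center_x + radius/2, center_y)."""
    rr = roi.radius / 2.0
    pts = []
    for j in range(n_points):
        ang = start_angle + 2.0 * math.pi * j / n_points
        x = roi.center_x + rr * math.cos(ang)
        y = roi.center_y + rr * math.sin(ang)
        pts.append((int(round(x)), int(round(y))))
    return pts

def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def sample_spot_color(
    img: RGBImage,
    roi: SpotROI,
    mode: str = "ring",
    n_points: int = 8,
    time_min: float = 0.0,
    label: str | None = None,
) -> ColorReading:
    """Read the spot color at the half-semi-diameter locus.

    ``mode="point"`` reads the single pixel at
    ``(center_x + radius/2, center_y)``, mimicking a manual click in an
    image editor.  ``mode="ring"`` (default) averages the pixels nearest
    to ``n_points`` equally spaced positions on the half-radius circle
    and rounds half-up back to the integer tone scale.
    """
    if mode not in ("point", "ring"):
        raise InputError(f"mode must be 'point' or 'ring', got {mode!r}")
    if n_points < 1:
        raise InputError(f"n_points must be >= 1, got {n_points}")
    pts = _half_radius_points(roi, 1 if mode == "point" else n_points)
    for x, y in pts:
        if not (0 <= x < img.width and 0 <= y < img.height):
            raise GeometryError(
                f"sampling locus ({x}, {y}) of spot {roi.label!r} lies outside "
                f"the {img.width}x{img.height} image"
            )
    vals = np.array([img.pixels[y, x, :] for x, y in pts], dtype=float)
    mean = vals.mean(axis=0)
    return ColorReading(
        r=_round_half_up(mean[0]),
        g=_round_half_up(mean[1]),
        b=_round_half_up(mean[2]),
        time_min=time_min,
        label=roi.label if label is None else label,
    )


def detect_spots(
    img: RGBImage,
    expected_n: int,
    min_radius: float = 3.0,
    threshold_offset: float = 25.0,
) -> list[SpotROI]:
    """Locate dark circular spots on a light background.

    Thresholds pixels darker than ``median - threshold_offset`` in the
    channel with the largest contrast, labels connected components, and
    returns the ``expected_n`` largest as circles (centroid + radius of
    the equivalent-area circle), ordered left to right.  This is a
    convenience for batch work; quantitative runs should pass explicit
    ROIs so results do not depend on detection heuristics.
    """
    if expected_n < 1:
        raise InputError(f"expected_n must be >= 1, got {expected_n}")
    px = img.pixels.astype(float)
    contrast = [px[:, :, c].max() - px[:, :, c].min() for c in range(3)]
    c = int(np.argmax(contrast))
    chan = px[:, :, c]
    mask = chan < (np.median(chan) - threshold_offset)
    labels = measure.label(mask, connectivity=2)
    props = [
        p
        for p in measure.regionprops(labels)
        if p.equivalent_diameter_area / 2.0 >= min_radius
    ]
    if not props:
        raise DetectionError(
            f"no connected dark region of radius >= {min_radius} px found"
        )
    props.sort(key=lambda p: p.area, reverse=True)
    chosen = props[:expected_n]
    rois = [
        SpotROI(
            center_x=float(p.centroid[1]),
            center_y=float(p.centroid[0]),
            radius=float(p.equivalent_diameter_area / 2.0),
            label=f"spot{i}",
        )
        for i, p in enumerate(chosen)
    ]
    rois.sort(key=lambda r: r.center_x)
    rois = [replace(r, label=f"spot{i}") for i, r in enumerate(rois)]
    if len(rois) < expected_n:
        import warnings

        warnings.warn(
            f"expected {expected_n} spots but found only {len(rois)}",
            stacklevel=2,
        )
    return rois


def readings_to_frame(
    readings,
    rois=None,
    replicate: int = 0,
) -> pd.DataFrame:
    """Collect :class:`ColorReading` objects into the shared readings table."""
    roi_by_label = {r.label: r for r in rois} if rois else {}
    rows = []
    for rd in readings:
        roi = roi_by_label.get(rd.label)
        rows.append(
            {
                "label": rd.label,
                "replicate": replicate,
                "time_min": rd.time_min,
                "center_x": roi.center_x if roi else np.nan,
                "center_y": roi.center_y if roi else np.nan,
                "radius": roi.radius if roi else np.nan,
                "r": rd.r,
                "g": rd.g,
                "b": rd.b,
            }
        )
    return pd.DataFrame(rows, columns=READINGS_COLUMNS)


def write_readings_csv(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, index=False)


def read_readings_csv(path) -> pd.DataFrame:
    p = Path(path)
    if not p.exists():
        raise InputError(f"readings file not found: {p}")
    frame = pd.read_csv(p)
    missing = {"label", "time_min", "r", "g", "b"} - set(frame.columns)
    if missing:
        raise FormatError(f"readings CSV missing columns: {sorted(missing)}")
    return frame
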
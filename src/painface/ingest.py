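"""Image preprocessing and landmark ingestion.

Faces arrive either as raw images (which an external face-mesh detector
turns into landmarks — see :data:`DetectorAdapter`) or directly as
per-frame landmark files. Before any displacement is measured, each
landmark set is brought into a *canonical frame*: eye centers horizontal,
interocular distance 1, midpoint of the eyes at the origin. All
displacement arithmetic downstream happens in these interocular units,
which makes activations comparable across faces, image resolutions and
head poses (up to in-plane rotation).

Input landmark coordinates follow the usual image-normalized convention:
x, y in roughly [0, 1] with the origin at the top-left and y pointing
down; z is an optional relative depth (0 when absent).
"""

from __future__ import annotations

import csv
import io
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable

import numpy as np
from PIL import Image

from .errors import (
    DegenerateGeometryError,
    InvalidArgumentError,
    ParseError,
    SchemaError,
)

__all__ = [
    "LandmarkSet",
    "CanonicalLandmarks",
    "resize_preserve_aspect",
    "unsharp_mask",
    "adjust_contrast_brightness",
    "normalize_pixels",
    "load_image",
    "load_landmarks",
    "write_landmarks",
    "align_landmarks",
    "detect_landmarks",
    "DetectorAdapter",
]


# ---------------------------------------------------------------------------
# landmark containers
# ---------------------------------------------------------------------------


@dataclass
class LandmarkSet:
    """One frame's facial points, ordered by mesh index.

    Parameters
    ----------
    frame_id
        Identifier of the source frame.
    points
        ``(n, 3)`` float array of ``(x, y, z)`` coordinates.
    """

    frame_id: str
    points: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] not in (2, 3):
            raise SchemaError(
                f"points must be (n, 2) or (n, 3); got shape {pts.shape}"
            )
        if pts.shape[1] == 2:  # pad missing depth with 0
            pts = np.column_stack([pts, np.zeros(len(pts))])
        if not np.all(np.isfinite(pts)):
            raise SchemaError("landmark coordinates must be finite")
        self.points = pts

    @property
    def n_points(self) -> int:
        return len(self.points)

    def copy(self) -> "LandmarkSet":
        return LandmarkSet(self.frame_id, self.points.copy())


@dataclass
class CanonicalLandmarks(LandmarkSet):
    """A :class:`LandmarkSet` in the canonical interocular frame.

    ``scale_ref`` records the interocular distance of the source frame
    (in its original units) so the similarity transform is invertible.
    """

    scale_ref: float = 1.0

    def __post_init__(self) -> None:
        super().__post_init__()
        if not (self.scale_ref > 0):
            raise SchemaError("scale_ref must be positive")

    def copy(self) -> "CanonicalLandmarks":
        return CanonicalLandmarks(self.frame_id, self.points.copy(), self.scale_ref)


#: Contract for a pluggable face-mesh detector: any callable mapping an
#: image array (H×W×C uint8) to a :class:`LandmarkSet`. The core library
#: never imports a concrete detector; users wire one in (e.g. a 468-point
#: face-mesh model) and pass it to :func:`detect_landmarks`.
DetectorAdapter = Callable[[np.ndarray], LandmarkSet]


def detect_landmarks(
    image: np.ndarray, detector: DetectorAdapter, expected_points: int | None = None
) -> LandmarkSet:
    """Run a detector adapter and validate its output shape."""
    lm = detector(image)
    if not isinstance(lm, LandmarkSet):
        raise SchemaError("detector adapter must return a LandmarkSet")
    if expected_points is not None and lm.n_points != expected_points:
        raise SchemaError(
            f"detector returned {lm.n_points} points, expected {expected_points}"
        )
    return lm


# ---------------------------------------------------------------------------
# image preprocessing
# ---------------------------------------------------------------------------


def _check_image(img: np.ndarray) -> np.ndarray:
    arr = np.asarray(img)
    if arr.ndim == 2:
        pass
    elif arr.ndim == 3 and arr.shape[2] in (1, 3):
        pass
    else:
        raise InvalidArgumentError(f"expected H×W or H×W×{{1,3}} image, got {arr.shape}")
    if arr.shape[0] < 1 or arr.shape[1] < 1:
        raise InvalidArgumentError("image must have at least one row and column")
    return arr


def load_image(path: str | Path) -> np.ndarray:
    """Read a PNG/JPEG file into an H×W×C uint8 array."""
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"))


def resize_preserve_aspect(img: np.ndarray, target_width: int) -> np.ndarray:
    """Resize to ``target_width`` keeping the aspect ratio.

    The output height is ``round(H * target_width / W)`` (at least 1).
    """
    arr = _check_image(img)
    if not isinstance(target_width, (int, np.integer)) or target_width < 1:
        raise InvalidArgumentError("target_width must be a positive integer")
    h, w = arr.shape[:2]
    new_h = max(1, round(h * target_width / w))
    if (w, h) == (target_width, new_h):
        return arr.copy()
    im = Image.fromarray(arr.astype(np.uint8))
    out = im.resize((int(target_width), int(new_h)), Image.BILINEAR)
    return np.asarray(out)


def unsharp_mask(
    img: np.ndarray,
    radius: float = 2.0,
    amount: float = 1.5,
    threshold: int = 3,
) -> np.ndarray:
    """Sharpen by adding back the thresholded difference from a Gaussian blur.

    ``out = img + amount * (img - blur(img, radius))`` wherever the
    absolute difference exceeds ``threshold``; elsewhere the pixel is
    left untouched. The result is clipped to [0, 255]. ``radius`` is the
    Gaussian sigma in pixels.
    """
    from scipy import ndimage

    arr = _check_image(img).astype(float)
    if radius < 0 or amount < 0 or threshold < 0:
        raise InvalidArgumentError("radius, amount and threshold must be >= 0")
    if amount == 0 or radius == 0:
        return np.clip(arr, 0, 255).astype(np.uint8)
    if arr.ndim == 3:
        blurred = np.stack(
            [ndimage.gaussian_filter(arr[..., c], sigma=radius) for c in range(arr.shape[2])],
            axis=-1,
        )
    else:
        blurred = ndimage.gaussian_filter(arr, sigma=radius)
    diff = arr - blurred
    sharp = arr + amount * diff
    out = np.where(np.abs(diff) > threshold, sharp, arr)
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def adjust_contrast_brightness(
    img: np.ndarray, contrast: float = 1.0, brightness: float = 1.0
) -> np.ndarray:
    """Scale deviation from the mean by ``contrast``, then scale by ``brightness``.

    ``out = brightness * (mean + contrast * (img - mean))``, clipped to [0, 255].
    """
    arr = _check_image(img).astype(float)
    if contrast < 0 or brightness < 0:
        raise InvalidArgumentError("contrast and brightness must be >= 0")
    mean = arr.mean()
    out = brightness * (mean + contrast * (arr - mean))
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def normalize_pixels(img: np.ndarray) -> np.ndarray:
    """Map 8-bit intensities to floats in [0, 1] (v ↦ v/255)."""
    arr = _check_image(img)
    return arr.astype(float) / 255.0


# ---------------------------------------------------------------------------
# landmark file IO
# ---------------------------------------------------------------------------


def load_landmarks(
    source: str | Path | io.TextIOBase,
    format: str | None = None,
    expected_points: int | None = None,
    frame_id: str | None = None,
) -> LandmarkSet:
    """Read a landmark file.

    JSON layout: ``{"frame_id": str, "points": [[x, y, z], ...]}``.
    CSV layout: header ``idx,x,y,z`` with one row per mesh index
    (the frame id defaults to the file stem).

    Raises
    ------
    ParseError
        If the file cannot be parsed.
    SchemaError
        If the point count disagrees with ``expected_points``.
    """
    if isinstance(source, (str, Path)):
        path = Path(source)
        if format is None:
            format = path.suffix.lstrip(".").lower()
        text = path.read_text()
        default_id = path.stem
    else:
        text = source.read()
        default_id = "stream"
        if format is None:
            raise InvalidArgumentError("format is required when reading a stream")

    if format == "json":
        try:
            doc = json.loads(text)
            fid = str(doc.get("frame_id", default_id))
            pts = np.asarray(doc["points"], dtype=float)
        except (json.JSONDecodeError, KeyError, TypeError, ValueError) as exc:
            raise ParseError(f"malformed landmark JSON: {exc}") from exc
    elif format == "csv":
        try:
            rows = list(csv.DictReader(io.StringIO(text)))
            rows.sort(key=lambda r: int(r["idx"]))
            pts = np.asarray(
                [[float(r["x"]), float(r["y"]), float(r.get("z", 0) or 0)] for r in rows]
            )
            fid = default_id
        except (KeyError, TypeError, ValueError) as exc:
            raise ParseError(f"malformed landmark CSV: {exc}") from exc
        if len(pts) == 0:
            raise ParseError("landmark CSV contains no rows")
    else:
        raise InvalidArgumentError(f"unknown landmark format {format!r}")

    if frame_id is not None:
        fid = frame_id
    lm = LandmarkSet(fid, pts)
    if expected_points is not None and lm.n_points != expected_points:
        raise SchemaError(
            f"{fid}: {lm.n_points} points, configured mesh size is {expected_points}"
        )
    return lm


def write_landmarks(
    lm: LandmarkSet, dest: str | Path, format: str | None = None
) -> Path:
    """Write a landmark set as JSON or CSV (inverse of :func:`load_landmarks`)."""
    path = Path(dest)
    if format is None:
        format = path.suffix.lstrip(".").lower()
    if format == "json":
        doc = {"frame_id": lm.frame_id, "points": [list(map(float, p)) for p in lm.points]}
        path.write_text(json.dumps(doc))
    elif format == "csv":
        buf = io.StringIO()
        writer = csv.writer(buf)
        writer.writerow(["idx", "x", "y", "z"])
        for i, (x, y, z) in enumerate(lm.points):
            writer.writerow([i, repr(float(x)), repr(float(y)), repr(float(z))])
        path.write_text(buf.getvalue())
    else:
        raise InvalidArgumentError(f"unknown landmark format {format!r}")
    return path


# ---------------------------------------------------------------------------
# canonical alignment
# ---------------------------------------------------------------------------


def align_landmarks(
    lm: LandmarkSet, left_eye_idx: int, right_eye_idx: int
) -> CanonicalLandmarks:
    """Similarity-normalize a landmark set to the canonical interocular frame.

    Rotation, uniform scaling and translation are applied so that the two
    eye-center landmarks end up at (-1/2, 0) and (+1/2, 0): eye line
    horizontal, interocular distance 1, midpoint at the origin. Depth (z)
    is scaled by the same factor but not rotated (the transform is
    in-plane). ``scale_ref`` keeps the source interocular distance.

    The operation is idempotent and invariant under any in-plane
    similarity transform of the input.
    """
    n = lm.n_points
    for idx in (left_eye_idx, right_eye_idx):
        if not (0 <= idx < n):
            raise SchemaError(f"eye index {idx} outside mesh of size {n}")
    left = lm.points[left_eye_idx, :2]
    right = lm.points[right_eye_idx, :2]
    delta = right - left
    dist = float(np.hypot(*delta))
    if dist < 1e-12:
        raise DegenerateGeometryError(
            "eye landmarks coincide; cannot define the interocular frame"
        )
    angle = math.atan2(delta[1], delta[0])
    c, s = math.cos(-angle), math.sin(-angle)
    rot = np.array([[c, -s], [s, c]])
    center = (left + right) / 2.0

    xy = (lm.points[:, :2] - center) @ rot.T / dist
    z = lm.points[:, 2] / dist
    pts = np.column_stack([xy, z])
    return CanonicalLandmarks(lm.frame_id, pts, scale_ref=dist)
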
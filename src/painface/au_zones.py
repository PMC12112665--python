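"""Action-unit zone displacements and intensity calibration.

Muscle activation is measured as the Euclidean displacement of each zone
landmark between a neutral reference frame and an activated frame, both
in canonical interocular coordinates. Displacements are mapped linearly
onto the 0–5 FACS intensity scale by a per-AU calibration constant
(``d_max`` scores as 5; larger displacements saturate). AU43 (eye
closure) is conventionally binary and is thresholded instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import CalibrationTable, ZoneConfig, AUZone
from .errors import ConfigError, InvalidArgumentError, SchemaError
from .ingest import CanonicalLandmarks

__all__ = [
    "ZoneIntensities",
    "AUIntensityVector",
    "displacement",
    "zone_displacements",
    "calibrate_intensity",
    "compute_zone_intensities",
    "reduce_to_vector",
]


@dataclass
class ZoneIntensities:
    """Per-AU lists of point-level intensities on the 0–5 scale."""

    values: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.values = {au: np.asarray(v, dtype=float) for au, v in self.values.items()}
        for au, v in self.values.items():
            if v.size == 0:
                raise SchemaError(f"{au}: empty intensity list")
            if np.any(v < 0) or np.any(v > 5):
                raise SchemaError(f"{au}: intensities outside [0, 5]")


@dataclass
class AUIntensityVector:
    """One scalar intensity per AU (AU43 binary)."""

    values: dict[str, float]

    def __post_init__(self) -> None:
        for au, v in self.values.items():
            if not (0 <= v <= 5):
                raise SchemaError(f"{au}: intensity {v} outside [0, 5]")
        if "AU43" in self.values and self.values["AU43"] not in (0.0, 1.0):
            raise SchemaError("AU43 must be binary (0 or 1)")

    def get(self, au_id: str, default: float = 0.0) -> float:
        return self.values.get(au_id, default)


def displacement(p_neutral, p_active, use_z: bool = False) -> float:
    """Euclidean displacement between a neutral and an activated landmark.

    By default only (x, y) enter the distance; set ``use_z`` to include
    relative depth.
    """
    a = np.asarray(p_neutral, dtype=float)
    b = np.asarray(p_active, dtype=float)
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise InvalidArgumentError("landmark coordinates must be finite")
    k = 3 if use_z else 2
    d = b[:k] - a[:k]
    return float(np.sqrt(np.sum(d * d)))


def zone_displacements(
    neutral: CanonicalLandmarks,
    active: CanonicalLandmarks,
    zone: AUZone,
    use_z: bool = False,
) -> np.ndarray:
    """Per-point displacements for one zone, in zone index order."""
    if neutral.n_points != active.n_points:
        raise SchemaError(
            f"mesh size mismatch: {neutral.n_points} vs {active.n_points}"
        )
    idx = np.asarray(zone.indices)
    if np.any(idx < 0) or np.any(idx >= neutral.n_points):
        raise SchemaError(f"{zone.au_id}: zone index outside mesh")
    k = 3 if use_z else 2
    diff = active.points[idx, :k] - neutral.points[idx, :k]
    return np.sqrt(np.sum(diff * diff, axis=1))


def calibrate_intensity(d: float, d_max: float) -> float:
    """Map a displacement to the 0–5 intensity scale: ``min(5 d / d_max, 5)``."""
    if not (d_max > 0):
        raise InvalidArgumentError("d_max must be positive")
    if d < 0:
        raise InvalidArgumentError("displacement must be non-negative")
    return min(5.0 * d / d_max, 5.0)


def compute_zone_intensities(
    neutral: CanonicalLandmarks,
    active: CanonicalLandmarks,
    cfg: ZoneConfig,
    cal: CalibrationTable,
    use_z: bool = False,
) -> ZoneIntensities:
    """Displacement → intensity for every configured zone.

    AU43 per-point values are binarized at the calibration table's
    ``binary_threshold``; every other AU stays continuous in [0, 5].
    """
    out: dict[str, np.ndarray] = {}
    for au_id, zone in cfg.zones.items():
        d = zone_displacements(neutral, active, zone, use_z=use_z)
        if au_id == "AU43":
            out[au_id] = (d >= cal.binary_threshold).astype(float)
        else:
            d_max = cal.require(au_id)
            out[au_id] = np.minimum(5.0 * d / d_max, 5.0)
    return ZoneIntensities(out)


def reduce_to_vector(zi: ZoneIntensities, mode: str = "max") -> AUIntensityVector:
    """Collapse each zone's point list to a scalar (max keeps the strongest
    activation, the conventional choice; mean is available)."""
    if mode not in ("max", "mean"):
        raise InvalidArgumentError(f"unknown reduction mode {mode!r}")
    reducer = np.max if mode == "max" else np.mean
    values = {}
    for au, v in zi.values.items():
        if v.size == 0:
            raise SchemaError(f"{au}: empty intensity list")
        # AU43 is a binary presence code: any closed-eye point means closure,
        # so it reduces by max under either mode.
        values[au] = float(np.max(v)) if au == "AU43" else float(reducer(v))
    return AUIntensityVector(values)
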
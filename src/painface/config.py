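"""Zone, calibration and run configuration.

The mapping from face-mesh landmark indices to FACS action-unit (AU)
zones is configuration, not code: the bundled ``zones_468_v1.json``
follows the standard 468-point face-mesh index convention and the usual
anatomical placement of each AU (between-brow cluster for AU1,
infraorbital triangle for AU6, nasal sidewalls for AU9, mouth corners
for AU15, chin for AU17, periocular ring for AU44, upper-lid gap for
AU43, plus the PSPI auxiliaries AU4/AU7/AU10). Any user-supplied JSON
document with the same shape replaces it.

Calibration maps canonical-unit displacements to the 0–5 FACS intensity
scale: ``d_max`` is the displacement scored as intensity 5. The default
(1 interocular unit for every AU) matches the synthetic face template's
full-intensity displacement, so calibration is exactly invertible in
round-trip tests and coordinate-noise sigmas read directly as fractions
of the full-scale displacement. The template geometry is stylized, not
anatomical; real deployments must calibrate d_max per AU against coded
ground truth (anatomical values are a few tenths of an interocular
unit).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .errors import ConfigError

__all__ = [
    "AUZone",
    "ZoneConfig",
    "CalibrationTable",
    "default_zone_config",
    "default_calibration",
    "load_zone_config",
    "load_calibration",
    "PSPI_AUS",
    "ZONE_MAX_AUS",
    "DEFAULT_DMAX",
    "KNOWN_AUS",
]

#: AUs entering the PSPI-style score: AU4 + max(AU6,AU7) + max(AU9,AU10) + AU43.
PSPI_AUS = ("AU4", "AU6", "AU7", "AU9", "AU10", "AU43")

#: The six zone-max AUs: max over each zone, summed.
ZONE_MAX_AUS = ("AU1", "AU6", "AU9", "AU15", "AU17", "AU44")

#: Default full-intensity (FACS 5) displacement, in interocular units.
DEFAULT_DMAX = 1.0

KNOWN_AUS = ("AU1", "AU4", "AU6", "AU7", "AU9", "AU10", "AU15", "AU17", "AU43", "AU44")


@dataclass(frozen=True)
class AUZone:
    """A named set of face-mesh indices covering one AU's anatomical region."""

    au_id: str
    name: str
    indices: tuple[int, ...]
    color_tag: str = ""

    def __post_init__(self) -> None:
        if len(self.indices) == 0:
            raise ConfigError(f"{self.au_id}: zone has no landmark indices")
        if len(set(self.indices)) != len(self.indices):
            raise ConfigError(f"{self.au_id}: duplicate landmark indices")


@dataclass(frozen=True)
class ZoneConfig:
    """Mesh size, AU zones, and the eye indices used for alignment."""

    mesh_size: int
    zones: dict[str, AUZone]
    left_eye_index: int
    right_eye_index: int
    version: str = "custom"

    def __post_init__(self) -> None:
        missing = [au for au in ZONE_MAX_AUS if au not in self.zones]
        if missing:
            raise ConfigError(f"zone config missing required zones: {missing}")
        for zone in self.zones.values():
            bad = [i for i in zone.indices if not (0 <= i < self.mesh_size)]
            if bad:
                raise ConfigError(
                    f"{zone.au_id}: indices {bad} outside mesh of size {self.mesh_size}"
                )
        for idx in (self.left_eye_index, self.right_eye_index):
            if not (0 <= idx < self.mesh_size):
                raise ConfigError(f"eye index {idx} outside mesh of size {self.mesh_size}")

    @property
    def has_pspi_zones(self) -> bool:
        return all(au in self.zones for au in PSPI_AUS)


@dataclass(frozen=True)
class CalibrationTable:
    """Per-AU displacement calibration.

    ``d_max[au]`` is the canonical-unit displacement mapped to intensity 5;
    ``binary_threshold`` is the displacement above which AU43 (eye
    closure) is scored 1.
    """

    d_max: dict[str, float]
    binary_threshold: float = 0.5 * DEFAULT_DMAX

    def __post_init__(self) -> None:
        for au, d in self.d_max.items():
            if not (d > 0):
                raise ConfigError(f"{au}: d_max must be positive, got {d}")
        if not (self.binary_threshold > 0):
            raise ConfigError("binary_threshold must be positive")

    def require(self, au_id: str) -> float:
        if au_id not in self.d_max:
            raise ConfigError(f"no calibration entry for {au_id}")
        return self.d_max[au_id]


def _zone_config_from_doc(doc: dict, version: str = "custom") -> ZoneConfig:
    try:
        zones = {
            au_id: AUZone(
                au_id=au_id,
                name=z.get("name", au_id),
                indices=tuple(int(i) for i in z["indices"]),
                color_tag=z.get("color_tag", ""),
            )
            for au_id, z in doc["zones"].items()
        }
        return ZoneConfig(
            mesh_size=int(doc["mesh_size"]),
            zones=zones,
            left_eye_index=int(doc["left_eye_index"]),
            right_eye_index=int(doc["right_eye_index"]),
            version=doc.get("version", version),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ConfigError(f"malformed zone config: {exc}") from exc


def default_zone_config() -> ZoneConfig:
    """The bundled 468-point zone configuration (``zones_468_v1``)."""
    text = resources.files("painface.data").joinpath("zones_468_v1.json").read_text()
    return _zone_config_from_doc(json.loads(text))


def load_zone_config(path: str | Path) -> ZoneConfig:
    """Load and validate a zone configuration JSON document."""
    return _zone_config_from_doc(json.loads(Path(path).read_text()))


def default_calibration(cfg: ZoneConfig | None = None) -> CalibrationTable:
    """Uniform default calibration: ``d_max`` = 0.2 for every configured AU."""
    if cfg is None:
        cfg = default_zone_config()
    return CalibrationTable(
        d_max={au: DEFAULT_DMAX for au in cfg.zones},
        binary_threshold=0.5 * DEFAULT_DMAX,
    )


def load_calibration(path: str | Path) -> CalibrationTable:
    """Load a calibration JSON: ``{"d_max": {au: value}, "binary_threshold": v}``."""
    try:
        doc = json.loads(Path(path).read_text())
        return CalibrationTable(
            d_max={str(k): float(v) for k, v in doc["d_max"].items()},
            binary_threshold=float(doc.get("binary_threshold", 0.5 * DEFAULT_DMAX)),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ConfigError(f"malformed calibration file: {exc}") from exc
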
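"""Synthetic neutral/activated landmark pairs with known ground truth.

The generator emulates the structure the pipeline consumes — a neutral
reference frame and an activated frame of the same face — with every
latent quantity known: per-AU intensities, the generating emotion, the
analytic zone-max pain score, and the binned pain level. It makes every
downstream stage testable without any image data.

Generative model
----------------
A deterministic canonical face template (unit interocular distance) is
drawn once per seed; each zone landmark also gets a fixed unit
displacement direction. An expression frame displaces each activated
zone point along its direction by ``(intensity / 5) · d_max``, exactly
inverting the displacement→intensity calibration, so at zero noise the
pipeline recovers intensities to machine precision. Emotions select
which AU pattern activates (the prototype map shared with the default
expression weight matrix), a per-frame amplitude drawn uniformly from
[0, 5] scales the pattern, and isotropic Gaussian coordinate noise is
added to the active frame only (the neutral frame is the reference).

Ground-truth pain follows the emotion-modulation premise of the scoring
model itself: the pain a subject experiences is the raw facial score
inflated (or damped) by the emotion's pain-correlation constant, so
``true_plew = w_emotion · true_ps`` and the true level bins that value.
The face displays the *unmodulated* amplitudes — which is exactly why
an unweighted reading of the face misestimates pain on emotive frames
and the emotion-weighted estimator does not.
"""

from __future__ import annotations

import csv
import io
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .config import (
    CalibrationTable,
    KNOWN_AUS,
    ZONE_MAX_AUS,
    ZoneConfig,
    default_calibration,
    default_zone_config,
)
from .emotion import (
    EMOTIONS,
    EMOTION_PROTOTYPES,
    EmotionWeightTable,
    default_weight_table,
)
from .errors import ConfigError, InvalidArgumentError
from .ingest import CanonicalLandmarks, LandmarkSet, load_landmarks, write_landmarks
from .pain_score import DEFAULT_THRESHOLDS, bin_pain_level

__all__ = [
    "FaceTemplate",
    "SyntheticFrame",
    "GenConfig",
    "make_template",
    "apply_activation",
    "generate_dataset",
    "make_temporal_series",
    "write_dataset",
    "load_dataset_dir",
]


@dataclass
class FaceTemplate:
    """Canonical landmark template plus per-zone-point displacement directions."""

    landmarks: CanonicalLandmarks
    directions: dict[str, np.ndarray]  # au_id -> (n_zone_points, 2) unit vectors
    config: ZoneConfig

    def __post_init__(self) -> None:
        for au, dirs in self.directions.items():
            norms = np.linalg.norm(dirs, axis=1)
            if not np.allclose(norms, 1.0, atol=1e-9):
                raise ConfigError(f"{au}: direction vectors must be unit norm")


@dataclass
class SyntheticFrame:
    """One generated neutral/activated pair with its latent ground truth."""

    neutral: CanonicalLandmarks
    active: CanonicalLandmarks
    true_emotion: str
    true_intensities: dict[str, float]
    true_ps: float
    true_plew: float
    true_level: int

    @property
    def frame_id(self) -> str:
        return self.active.frame_id


@dataclass(frozen=True)
class GenConfig:
    """Dataset generation parameters.

    ``emotion_mix`` gives class proportions (uniform over the 7 classes
    when None); ``noise_sigma`` is the isotropic coordinate noise, in
    canonical interocular units, added to the active frame.
    """

    n_frames: int
    emotion_mix: dict[str, float] | None = None
    amplitude_range: tuple[float, float] = (0.0, 5.0)
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ConfigError("n_frames must be >= 1")
        if self.noise_sigma < 0:
            raise ConfigError("noise_sigma must be >= 0")
        lo, hi = self.amplitude_range
        if not (0 <= lo <= hi <= 5):
            raise ConfigError("amplitude_range must satisfy 0 <= lo <= hi <= 5")
        if self.emotion_mix is not None:
            if set(self.emotion_mix) - set(EMOTIONS):
                raise ConfigError("emotion_mix contains unknown labels")
            total = sum(self.emotion_mix.values())
            if any(p < 0 for p in self.emotion_mix.values()) or abs(total - 1.0) > 1e-9:
                raise ConfigError("emotion_mix proportions must be >= 0 and sum to 1")


def make_template(
    seed: int, mesh_size: int = 468, cfg: ZoneConfig | None = None
) -> FaceTemplate:
    """Deterministic canonical face template for a given seed.

    Eye anchors sit at (±1/2, 0); all other points scatter over a
    face-sized box in canonical units. Each zone point gets a fixed
    random unit displacement direction.
    """
    if cfg is None:
        cfg = default_zone_config()
    needed = max(
        [max(z.indices) for z in cfg.zones.values()]
        + [cfg.left_eye_index, cfg.right_eye_index]
    )
    if mesh_size <= needed:
        raise ConfigError(
            f"mesh_size {mesh_size} too small for zone config (needs > {needed})"
        )
    rng = np.random.default_rng(seed)
    pts = np.column_stack(
        [
            rng.uniform(-1.0, 1.0, mesh_size),
            rng.uniform(-1.2, 1.2, mesh_size),
            np.zeros(mesh_size),
        ]
    )
    pts[cfg.left_eye_index] = (-0.5, 0.0, 0.0)
    pts[cfg.right_eye_index] = (0.5, 0.0, 0.0)
    landmarks = CanonicalLandmarks("template", pts, scale_ref=1.0)

    directions = {}
    for au_id, zone in cfg.zones.items():
        theta = rng.uniform(0, 2 * math.pi, len(zone.indices))
        directions[au_id] = np.column_stack([np.cos(theta), np.sin(theta)])
    return FaceTemplate(landmarks, directions, cfg)


def apply_activation(
    tpl: FaceTemplate,
    spec: dict[str, float],
    cal: CalibrationTable,
    frame_id: str = "activated",
) -> CanonicalLandmarks:
    """Displace zone points per an intensity spec (exact calibration inverse).

    Each zone point of an activated AU moves along its template direction
    by ``(intensity / 5) · d_max``; all other points are untouched.
    """
    pts = tpl.landmarks.points.copy()
    for au_id, intensity in spec.items():
        if au_id not in tpl.config.zones:
            raise ConfigError(f"activation for unconfigured AU {au_id}")
        if not (0 <= intensity <= 5):
            raise InvalidArgumentError(f"{au_id}: intensity {intensity} outside [0, 5]")
        zone = tpl.config.zones[au_id]
        step = (intensity / 5.0) * cal.require(au_id)
        pts[list(zone.indices), :2] += step * tpl.directions[au_id]
    return CanonicalLandmarks(frame_id, pts, scale_ref=1.0)


def _stratified_labels(cfg: GenConfig, rng: np.random.Generator) -> list[str]:
    """Largest-remainder allocation of class counts, then a seeded shuffle."""
    mix = cfg.emotion_mix or {e: 1.0 / len(EMOTIONS) for e in EMOTIONS}
    quotas = {e: cfg.n_frames * mix.get(e, 0.0) for e in EMOTIONS}
    counts = {e: int(math.floor(q)) for e, q in quotas.items()}
    short = cfg.n_frames - sum(counts.values())
    by_frac = sorted(EMOTIONS, key=lambda e: (-(quotas[e] - counts[e]), EMOTIONS.index(e)))
    for e in by_frac[:short]:
        counts[e] += 1
    labels = [e for e in EMOTIONS for _ in range(counts[e])]
    rng.shuffle(labels)
    return labels


def analytic_zone_max(spec: dict[str, float]) -> float:
    """Closed-form zone-max score of an intensity spec (the six pain zones)."""
    return float(sum(spec.get(au, 0.0) for au in ZONE_MAX_AUS))


def generate_dataset(
    cfg: GenConfig,
    tpl: FaceTemplate | None = None,
    cal: CalibrationTable | None = None,
    patterns: dict[str, tuple[str, ...]] = EMOTION_PROTOTYPES,
    table: EmotionWeightTable | None = None,
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
) -> list[SyntheticFrame]:
    """Generate a labelled dataset of neutral/activated frame pairs.

    Class assignment is stratified (exact counts when ``n_frames`` is
    divisible by the number of classes); a fixed seed reproduces the
    dataset byte for byte.
    """
    rng = np.random.default_rng(cfg.seed)
    if tpl is None:
        tpl = make_template(seed=cfg.seed, cfg=default_zone_config())
    if cal is None:
        cal = default_calibration(tpl.config)
    if table is None:
        table = default_weight_table()

    labels = _stratified_labels(cfg, rng)
    frames = []
    n_pts = tpl.landmarks.n_points
    for i, emo in enumerate(labels):
        fid = f"frame_{i:04d}"
        amplitude = rng.uniform(*cfg.amplitude_range)
        spec = {au: amplitude for au in patterns[emo]}
        active = apply_activation(tpl, spec, cal, frame_id=fid)
        if cfg.noise_sigma > 0:
            active.points[:, :2] += rng.normal(0.0, cfg.noise_sigma, (n_pts, 2))
        neutral = tpl.landmarks.copy()
        neutral.frame_id = fid
        true_ps = analytic_zone_max(spec)
        true_plew = table.w[emo] * true_ps
        frames.append(
            SyntheticFrame(
                neutral=neutral,
                active=active,
                true_emotion=emo,
                true_intensities={au: spec.get(au, 0.0) for au in tpl.config.zones},
                true_ps=true_ps,
                true_plew=true_plew,
                true_level=bin_pain_level(true_plew, thresholds),
            )
        )
    return frames


def make_temporal_series(
    emotion: str,
    duration: float = 60.0,
    fps: float = 1.0,
    tpl: FaceTemplate | None = None,
    cal: CalibrationTable | None = None,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> list[tuple[float, CanonicalLandmarks, CanonicalLandmarks]]:
    """A single-expression time series of (t, neutral, active) pairs.

    The expression amplitude follows a raised sinusoid
    ``a(t) = 3 + 1.5 sin(2πt / duration)``, a sustained visible episode
    that stays within the 0–5 intensity scale for the whole window.
    """
    if emotion not in EMOTIONS:
        raise InvalidArgumentError(f"unknown emotion {emotion!r}")
    if duration <= 0 or fps <= 0:
        raise InvalidArgumentError("duration and fps must be positive")
    rng = np.random.default_rng(seed)
    if tpl is None:
        tpl = make_template(seed=seed, cfg=default_zone_config())
    if cal is None:
        cal = default_calibration(tpl.config)
    series = []
    n_steps = int(round(duration * fps))
    n_pts = tpl.landmarks.n_points
    for k in range(n_steps):
        t = k / fps
        a = 3.0 + 1.5 * math.sin(2 * math.pi * t / duration)
        spec = {au: a for au in EMOTION_PROTOTYPES[emotion]}
        fid = f"t_{k:04d}"
        active = apply_activation(tpl, spec, cal, frame_id=fid)
        if noise_sigma > 0:
            active.points[:, :2] += rng.normal(0.0, noise_sigma, (n_pts, 2))
        neutral = tpl.landmarks.copy()
        neutral.frame_id = fid
        series.append((t, neutral, active))
    return series


# ---------------------------------------------------------------------------
# dataset file round-trip
# ---------------------------------------------------------------------------

_LABEL_FIELDS = ["frame_id", "emotion", "true_ps", "true_plew", "true_level"]


def write_dataset(frames: list[SyntheticFrame], outdir: str | Path) -> Path:
    """Write landmark JSON pairs plus a ``labels.csv`` ground-truth table."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    au_cols = sorted({au for f in frames for au in f.true_intensities})
    buf = io.StringIO()
    writer = csv.writer(buf)
    writer.writerow(_LABEL_FIELDS + au_cols)
    for f in frames:
        write_landmarks(f.neutral, out / f"{f.frame_id}_neutral.json")
        write_landmarks(f.active, out / f"{f.frame_id}_active.json")
        writer.writerow(
            [
                f.frame_id,
                f.true_emotion,
                repr(float(f.true_ps)),
                repr(float(f.true_plew)),
                f.true_level,
            ]
            + [repr(float(f.true_intensities.get(au, 0.0))) for au in au_cols]
        )
    (out / "labels.csv").write_text(buf.getvalue())
    return out


def load_dataset_dir(
    path: str | Path, expected_points: int | None = None
) -> list[tuple[str, LandmarkSet, LandmarkSet]]:
    """Read back ``*_neutral.json`` / ``*_active.json`` pairs, sorted by id."""
    root = Path(path)
    pairs = []
    for active_file in sorted(root.glob("*_active.json")):
        fid = active_file.name[: -len("_active.json")]
        neutral_file = root / f"{fid}_neutral.json"
        if not neutral_file.exists():
            raise InvalidArgumentError(f"no neutral frame for {fid}")
        neutral = load_landmarks(neutral_file, expected_points=expected_points, frame_id=fid)
        active = load_landmarks(active_file, expected_points=expected_points, frame_id=fid)
        pairs.append((fid, neutral, active))
    if not pairs:
        raise InvalidArgumentError(f"no landmark pairs found under {root}")
    return pairs
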
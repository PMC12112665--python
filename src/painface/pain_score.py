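"""Pain scores: PSPI baseline, zone-max score, emotion weighting, binning.

Two raw scores are computed per frame:

* the PSPI-style baseline
  ``AU4 + max(AU6, AU7) + max(AU9, AU10) + AU43``,
  capped at 15 by default (the conventional scale maximum; the raw sum
  of the stated AU ranges is 16 — the cap is a configurable flag, never
  a silent truncation of inputs); and
* the zone-max score
  ``Ps = max(AU1) + max(AU6) + max(AU9) + max(AU15) + max(AU17) + max(AU44)``,
  the sum of the strongest activation in each of the six pain zones,
  range [0, 30].

The emotion-weighted score multiplies a raw score by the detected
expression's pain-correlation constant. Two semantics are offered:
``hard`` (default) multiplies by the single detected label's weight;
``soft`` takes the probability-weighted mean of the constants — a
faithful reading of a sum over all seven expression categories. Scores
are binned into 6 ordinal pain levels (no pain … worst pain) on
configurable thresholds; weighted scores are binned on the same
thresholds, so weighting can move a frame across levels.
"""

from __future__ import annotations

from dataclasses import dataclass

from .au_zones import (
    AUIntensityVector,
    ZoneIntensities,
    compute_zone_intensities,
    reduce_to_vector,
)
from .config import CalibrationTable, ZoneConfig, ZONE_MAX_AUS
from .emotion import (
    AUWeightMatrix,
    EmotionDistribution,
    EmotionWeightTable,
    classify_au_vector,
    emotion_weight,
)
from .errors import InvalidArgumentError, SchemaError
from .ingest import CanonicalLandmarks

__all__ = [
    "PAIN_LEVEL_NAMES",
    "DEFAULT_THRESHOLDS",
    "PSPIConfig",
    "PainScore",
    "pspi_ple",
    "zone_max_ple",
    "weighted_ple",
    "bin_pain_level",
    "pain_level_name",
    "compute_pain",
]

#: Ordinal pain categories 0–5.
PAIN_LEVEL_NAMES = (
    "no pain",
    "mild",
    "moderate",
    "severe",
    "very severe",
    "worst pain",
)

#: Equal-width default bins over the zone-max range [0, 30];
#: left-bin-inclusive, anything above the last threshold is level 5.
DEFAULT_THRESHOLDS = (6.0, 12.0, 18.0, 24.0, 30.0)


@dataclass(frozen=True)
class PSPIConfig:
    """PSPI scoring options: cap at the conventional maximum of 15."""

    clamp_to_paper_range: bool = True
    range_max: float = 15.0

    def __post_init__(self) -> None:
        if not (self.range_max > 0):
            raise InvalidArgumentError("range_max must be positive")


@dataclass
class PainScore:
    """Per-frame pain estimate.

    ``ps`` is the raw zone-max score, ``pspi`` the PSPI baseline (None
    when the PSPI auxiliary zones are not configured), ``plew`` the
    emotion-weighted score, ``level`` its binned 0–5 category.
    """

    frame_id: str
    emotion: str
    p_emotion: EmotionDistribution
    pspi: float | None
    ps: float
    plew: float
    level: int
    mode: str

    @property
    def level_name(self) -> str:
        return PAIN_LEVEL_NAMES[self.level]


def pspi_ple(
    au4: float,
    au6: float,
    au7: float,
    au9: float,
    au10: float,
    au43: float,
    cfg: PSPIConfig = PSPIConfig(),
) -> float:
    """PSPI baseline: ``AU4 + max(AU6, AU7) + max(AU9, AU10) + AU43``."""
    for name, v in (("AU4", au4), ("AU6", au6), ("AU7", au7), ("AU9", au9), ("AU10", au10)):
        if not (0 <= v <= 5):
            raise InvalidArgumentError(f"{name} must lie in [0, 5], got {v}")
    if au43 not in (0, 1):
        raise InvalidArgumentError(f"AU43 must be 0 or 1, got {au43}")
    score = au4 + max(au6, au7) + max(au9, au10) + au43
    if cfg.clamp_to_paper_range:
        score = min(score, cfg.range_max)
    return float(score)


def zone_max_ple(zi: ZoneIntensities) -> float:
    """Zone-max score Ps: sum of the per-zone maxima over the six pain zones."""
    missing = [au for au in ZONE_MAX_AUS if au not in zi.values]
    if missing:
        raise SchemaError(f"zone intensities missing required zones: {missing}")
    return float(sum(zi.values[au].max() for au in ZONE_MAX_AUS))


def weighted_ple(
    ps: float,
    emotion: str | EmotionDistribution,
    table: EmotionWeightTable,
    mode: str = "hard",
) -> float:
    """Emotion-weighted pain score.

    hard: ``ps · w[label]`` for a single detected label;
    soft: ``ps · Σ_e p_e · w_e`` for a probability distribution.
    """
    if ps < 0:
        raise InvalidArgumentError("pain score must be non-negative")
    if mode == "hard":
        if isinstance(emotion, EmotionDistribution):
            from .emotion import classify

            label = classify(emotion)
        else:
            label = emotion
        return float(ps * emotion_weight(label, table))
    if mode == "soft":
        if not isinstance(emotion, EmotionDistribution):
            raise InvalidArgumentError("soft mode requires an EmotionDistribution")
        return float(ps * sum(p * emotion_weight(e, table) for e, p in emotion.p.items()))
    raise InvalidArgumentError(f"unknown mode {mode!r}")


def bin_pain_level(
    score: float, thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
) -> int:
    """Bin a score into the 6 ordinal pain levels.

    Zero is level 0 (no pain); otherwise the level is
    ``1 + #{thresholds strictly below the score}``, capped at 5, so each
    bin includes its right edge.
    """
    if score < 0:
        raise InvalidArgumentError("score must be non-negative")
    if any(b <= a for a, b in zip(thresholds, thresholds[1:])):
        raise InvalidArgumentError("thresholds must be strictly ascending")
    if score == 0:
        return 0
    return min(1 + sum(1 for t in thresholds if t < score), 5)


def pain_level_name(level: int) -> str:
    if not (0 <= level <= 5):
        raise InvalidArgumentError(f"pain level must be 0–5, got {level}")
    return PAIN_LEVEL_NAMES[level]


def compute_pain(
    neutral: CanonicalLandmarks,
    active: CanonicalLandmarks,
    cfg: ZoneConfig,
    cal: CalibrationTable,
    W: AUWeightMatrix,
    table: EmotionWeightTable,
    mode: str = "hard",
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
    pspi_cfg: PSPIConfig = PSPIConfig(),
    neutral_threshold: float = 1.0,
) -> PainScore:
    """Full per-frame pipeline.

    zone intensities → zone-max Ps → expression classification →
    emotion-weighted score → pain level. The PSPI baseline is also
    reported when the auxiliary zones (AU4, AU7, AU10, AU43) are
    configured. The reported ``level`` bins the weighted score.
    """
    zi = compute_zone_intensities(neutral, active, cfg, cal)
    vec = reduce_to_vector(zi, mode="max")
    ps = zone_max_ple(zi)
    label, dist = classify_au_vector(vec, W, neutral_threshold=neutral_threshold)
    plew = weighted_ple(ps, dist if mode == "soft" else label, table, mode=mode)
    level = bin_pain_level(plew, thresholds)
    pspi = None
    if cfg.has_pspi_zones:
        pspi = pspi_ple(
            vec.get("AU4"),
            vec.get("AU6"),
            vec.get("AU7"),
            vec.get("AU9"),
            vec.get("AU10"),
            vec.get("AU43"),
            pspi_cfg,
        )
    return PainScore(
        frame_id=active.frame_id,
        emotion=label,
        p_emotion=dist,
        pspi=pspi,
        ps=ps,
        plew=plew,
        level=level,
        mode=mode,
    )
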
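"""Facial expression recognition from AU intensities, and the
emotion–pain weight table.

The expression classifier is a linear score per emotion — a weighted sum
of AU intensities, FER_e = Σ_i W[e, i]·AU_i — turned into a probability
distribution by a softmax and decided by argmax. The default weight
matrix mirrors the prototype emotion→AU patterns of the synthetic face
generator (each emotion's row puts weight 1 on its prototype AUs); it is
a transparent, configurable stand-in for a learned expression model, not
a reproduction of one, and any user matrix with the same shape can be
loaded in its place.

The emotion–pain weight table carries the per-emotion constants used to
modulate raw pain scores: negative-affect expressions (sadness 1.7,
anger 1.6, fear 1.4, disgust 1.2) scale pain up, neutrality leaves it
unchanged (1.0), and positive/low-arousal expressions scale it down
(surprise 0.9, happiness 0.8).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .au_zones import AUIntensityVector
from .errors import ConfigError, InvalidArgumentError
from .config import KNOWN_AUS

__all__ = [
    "EMOTIONS",
    "EMOTION_PROTOTYPES",
    "DEFAULT_EMOTION_WEIGHTS",
    "AUWeightMatrix",
    "EmotionDistribution",
    "EmotionWeightTable",
    "default_weight_matrix",
    "load_weight_matrix",
    "default_weight_table",
    "load_weight_table",
    "fer_scores",
    "to_distribution",
    "classify",
    "classify_au_vector",
    "emotion_weight",
]

#: Canonical label order (ties in classification resolve to the earliest).
EMOTIONS = (
    "happiness",
    "surprise",
    "neutrality",
    "disgust",
    "fear",
    "anger",
    "sadness",
)

#: Prototype AU pattern per emotion: which zones a pure expression of that
#: emotion activates. Shared convention between the default weight matrix
#: and the synthetic face generator.
EMOTION_PROTOTYPES: dict[str, tuple[str, ...]] = {
    "happiness": ("AU6",),
    "surprise": ("AU1",),
    "neutrality": (),
    "disgust": ("AU9",),
    "fear": ("AU1", "AU44"),
    "anger": ("AU44", "AU17"),
    "sadness": ("AU15", "AU17", "AU1"),
}

#: Emotion–pain correlation constants.
DEFAULT_EMOTION_WEIGHTS: dict[str, float] = {
    "happiness": 0.8,
    "surprise": 0.9,
    "neutrality": 1.0,
    "disgust": 1.2,
    "fear": 1.4,
    "anger": 1.6,
    "sadness": 1.7,
}


@dataclass(frozen=True)
class AUWeightMatrix:
    """Per-(emotion, AU) weights for the linear expression scores."""

    weights: dict[str, dict[str, float]]

    def __post_init__(self) -> None:
        if set(self.weights) != set(EMOTIONS):
            raise ConfigError(
                f"weight matrix must cover exactly the emotions {EMOTIONS}"
            )
        au_sets = {frozenset(row) for row in self.weights.values()}
        if len(au_sets) != 1:
            raise ConfigError("every emotion row must cover the same AU set")
        for emo, row in self.weights.items():
            for au, w in row.items():
                if not math.isfinite(w):
                    raise ConfigError(f"non-finite weight for ({emo}, {au})")

    @property
    def au_ids(self) -> tuple[str, ...]:
        return tuple(next(iter(self.weights.values())))


@dataclass(frozen=True)
class EmotionDistribution:
    """Probabilities over the 7 expression classes."""

    p: dict[str, float]

    def __post_init__(self) -> None:
        if set(self.p) != set(EMOTIONS):
            raise ConfigError("distribution must cover exactly the 7 emotions")
        vals = np.array([self.p[e] for e in EMOTIONS])
        if np.any(vals < 0) or abs(vals.sum() - 1.0) > 1e-9:
            raise ConfigError("probabilities must be non-negative and sum to 1")


@dataclass(frozen=True)
class EmotionWeightTable:
    """Emotion → pain-modulation constant."""

    w: dict[str, float]

    def __post_init__(self) -> None:
        for emo, val in self.w.items():
            if not (val > 0):
                raise ConfigError(f"{emo}: emotion weight must be positive")


def default_weight_matrix(
    au_ids: tuple[str, ...] = KNOWN_AUS, penalty: float = 0.25
) -> AUWeightMatrix:
    """Prototype template-matching matrix.

    Each emotion's row puts weight ``1/|prototype|`` on its prototype AUs
    (so the score is the mean prototype activation, comparable across
    prototypes of different sizes) and ``-penalty`` on every other AU
    (activation outside the template argues against the emotion). Without
    the normalization, an emotion whose prototype is a superset of
    another's (fear ⊃ surprise) would outscore it on any noisy frame;
    without the penalty, a large prototype collects spurious credit from
    unrelated activation. The neutrality row is all zeros — neutrality is
    decided by the absence of activation (see :func:`classify_au_vector`).
    """
    weights: dict[str, dict[str, float]] = {}
    for emo in EMOTIONS:
        proto = EMOTION_PROTOTYPES[emo]
        if not proto:
            weights[emo] = {au: 0.0 for au in au_ids}
            continue
        w_on = 1.0 / len(proto)
        weights[emo] = {
            au: (w_on if au in proto else -penalty) for au in au_ids
        }
    return AUWeightMatrix(weights)


def load_weight_matrix(path: str | Path) -> AUWeightMatrix:
    try:
        doc = json.loads(Path(path).read_text())
        return AUWeightMatrix(
            {str(e): {str(a): float(v) for a, v in row.items()} for e, row in doc.items()}
        )
    except (json.JSONDecodeError, AttributeError, TypeError, ValueError) as exc:
        raise ConfigError(f"malformed weight matrix: {exc}") from exc


def default_weight_table() -> EmotionWeightTable:
    return EmotionWeightTable(dict(DEFAULT_EMOTION_WEIGHTS))


def load_weight_table(path: str | Path) -> EmotionWeightTable:
    try:
        doc = json.loads(Path(path).read_text())
        return EmotionWeightTable({str(e): float(v) for e, v in doc.items()})
    except (json.JSONDecodeError, AttributeError, TypeError, ValueError) as exc:
        raise ConfigError(f"malformed weight table: {exc}") from exc


def fer_scores(au: AUIntensityVector, W: AUWeightMatrix) -> dict[str, float]:
    """Linear expression scores: score_e = Σ_i W[e, i]·AU_i."""
    for au_id in au.values:
        for emo in EMOTIONS:
            if au_id not in W.weights[emo]:
                raise ConfigError(f"weight matrix has no entry for ({emo}, {au_id})")
    return {
        emo: float(sum(W.weights[emo][a] * v for a, v in au.values.items()))
        for emo in EMOTIONS
    }


def to_distribution(scores: dict[str, float], method: str = "softmax") -> EmotionDistribution:
    """Convert scores to probabilities (softmax, temperature 1)."""
    if method != "softmax":
        raise InvalidArgumentError(f"unknown method {method!r}")
    vals = np.array([scores[e] for e in EMOTIONS], dtype=float)
    if not np.all(np.isfinite(vals)):
        raise InvalidArgumentError("scores must be finite")
    vals = vals - vals.max()  # shift invariance / overflow guard
    exp = np.exp(vals)
    p = exp / exp.sum()
    return EmotionDistribution({e: float(pi) for e, pi in zip(EMOTIONS, p)})


def classify(dist: EmotionDistribution) -> str:
    """Argmax label; exact ties resolve to the earliest canonical label."""
    best = EMOTIONS[0]
    for emo in EMOTIONS[1:]:
        if dist.p[emo] > dist.p[best]:
            best = emo
    return best


def classify_au_vector(
    au: AUIntensityVector,
    W: AUWeightMatrix,
    neutral_threshold: float = 1.0,
) -> tuple[str, EmotionDistribution]:
    """Pipeline-level expression decision for one frame.

    A face with no appreciable activation is neutral by definition, but a
    linear score with no intercept assigns every emotion the same score
    at the origin. The gate handles this: when no AU intensity reaches
    ``neutral_threshold`` (0–5 scale) the frame is labelled neutrality;
    otherwise the softmax argmax decides. The distribution is returned
    either way for soft weighting.
    """
    dist = to_distribution(fer_scores(au, W))
    if all(v < neutral_threshold for v in au.values.values()):
        return "neutrality", dist
    return classify(dist), dist


def emotion_weight(label: str, table: EmotionWeightTable) -> float:
    """Look up the pain-modulation constant for an emotion label."""
    if label not in table.w:
        raise InvalidArgumentError(f"emotion {label!r} not in weight table")
    return table.w[label]
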
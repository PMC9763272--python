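"""Motricity Index scale definitions and discrete-score arithmetic.

The Motricity Index (MI) measures muscle strength of the paretic limb on an
ordinal scale.  For the upper limb, three actions are scored separately --
pinch grasp, elbow flexion and shoulder abduction -- each on a six-class
sub-item taking the Wade values {0, 9, 14, 19, 25, 33}.  The total upper-limb
score is the sum of the three sub-items plus one, so a fully intact limb
scores 33 + 33 + 33 + 1 = 100 and a plegic limb scores 1.

Because the scale is discrete, a continuous model prediction is only
clinically meaningful after it has been snapped to the nearest attainable
score; :func:`nearest_valid_score` implements that correction with ties
broken toward the lower (more conservative) score.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

__all__ = [
    "SUBITEM_CLASSES",
    "MIScale",
    "ELBOW_SCALE",
    "SHOULDER_SCALE",
    "UL_SCALE",
    "SCALES",
    "get_scale",
    "mi_total",
    "nearest_valid_score",
    "snap_scores",
]

#: The six attainable scores of one MI sub-item (Wade scoring).
SUBITEM_CLASSES: tuple[int, ...] = (0, 9, 14, 19, 25, 33)


def _ul_valid_scores() -> tuple[int, ...]:
    """All attainable MI upper-limb totals: sums of three sub-items plus one."""
    sums = {
        a + b + c + 1
        for a in SUBITEM_CLASSES
        for b in SUBITEM_CLASSES
        for c in SUBITEM_CLASSES
    }
    return tuple(sorted(sums))


@dataclass(frozen=True)
class MIScale:
    """A discrete clinical scale: its range and the set of attainable scores.

    Parameters
    ----------
    name:
        Outcome label, e.g. ``"ELBOW"``, ``"SHOULDER"`` or ``"UL"``.
    min_score, max_score:
        Bounds of the scale (0-33 for sub-items, 1-100 for the total).
    valid_scores:
        Ascending tuple of attainable scores; must contain both bounds.
    """

    name: str
    min_score: float
    max_score: float
    valid_scores: tuple[float, ...] = field(default=SUBITEM_CLASSES)

    def __post_init__(self) -> None:
        if self.max_score <= self.min_score:
            raise ValueError(f"scale {self.name!r}: max must exceed min")
        vs = tuple(sorted(self.valid_scores))
        object.__setattr__(self, "valid_scores", vs)
        if not vs:
            raise ValueError(f"scale {self.name!r}: empty valid-score set")
        if vs[0] != self.min_score or vs[-1] != self.max_score:
            raise ValueError(
                f"scale {self.name!r}: valid scores must span [min, max]"
            )

    @property
    def score_range(self) -> float:
        """Width of the scale, ``max - min``; the RMSE normalizer."""
        return self.max_score - self.min_score


ELBOW_SCALE = MIScale("ELBOW", 0, 33, SUBITEM_CLASSES)
SHOULDER_SCALE = MIScale("SHOULDER", 0, 33, SUBITEM_CLASSES)
UL_SCALE = MIScale("UL", 1, 100, _ul_valid_scores())

SCALES: dict[str, MIScale] = {
    "ELBOW": ELBOW_SCALE,
    "SHOULDER": SHOULDER_SCALE,
    "UL": UL_SCALE,
}


def get_scale(name: str) -> MIScale:
    """Look up a scale by outcome name (case-insensitive)."""
    try:
        return SCALES[name.upper()]
    except KeyError:
        raise KeyError(
            f"unknown outcome {name!r}; expected one of {sorted(SCALES)}"
        ) from None


def mi_total(elbow: float, shoulder: float, pinch: float) -> int:
    """Total upper-limb Motricity Index: sum of the three sub-items plus one.

    Each sub-item must be one of the attainable class values
    ``{0, 9, 14, 19, 25, 33}``; the maximum total is therefore 100 and the
    minimum 1.
    """
    for label, value in (("elbow", elbow), ("shoulder", shoulder), ("pinch", pinch)):
        if value not in SUBITEM_CLASSES:
            raise ValueError(
                f"{label} sub-item {value!r} is not an attainable MI class "
                f"{SUBITEM_CLASSES}"
            )
    return int(elbow + shoulder + pinch + 1)


def nearest_valid_score(predicted: float, scale: MIScale) -> float:
    """Snap a continuous prediction to the closest attainable score.

    Uses minimum absolute (Euclidean, in 1-D) distance over the scale's valid
    score set.  Exact ties are resolved toward the *lower* score so that the
    correction never inflates predicted recovery.
    """
    predicted = float(predicted)
    if not np.isfinite(predicted):
        raise ValueError("prediction must be finite")
    best = scale.valid_scores[0]
    best_dist = abs(predicted - best)
    for score in scale.valid_scores[1:]:
        dist = abs(predicted - score)
        if dist < best_dist:  # strict: earlier (lower) score wins ties
            best, best_dist = score, dist
    return best


def snap_scores(values: Iterable[float], scale: MIScale) -> np.ndarray:
    """Vectorized :func:`nearest_valid_score` over an iterable."""
    return np.array([nearest_valid_score(v, scale) for v in np.asarray(values, float)])
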
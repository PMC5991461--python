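"""Comparator cut-scores: classic Angoff and the direct suggestion mean.

The classic Angoff procedure asks each judge, per item, for the proportion
of minimally competent examinees who would answer correctly; the grand
mean of those proportions (times 100) is the cut-score.  The direct
baseline simply averages the cut-scores judges suggest for the whole
examination.  Both are reported alongside the anchor-interface method for
comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import PanelValidationError
from .panel_model import JudgePanel

__all__ = ["ItemRatingMatrix", "classic_angoff", "direct_suggested_mean"]


@dataclass(frozen=True)
class ItemRatingMatrix:
    """Complete judges x items matrix of Angoff proportions in [0, 1]."""

    judges: tuple[str, ...]
    items: tuple[str, ...]
    proportions: np.ndarray

    def __post_init__(self) -> None:
        props = np.asarray(self.proportions, dtype=float)
        if props.shape != (len(self.judges), len(self.items)):
            raise PanelValidationError(
                f"proportions shape {props.shape} does not match "
                f"{len(self.judges)} judges x {len(self.items)} items"
            )
        if props.size == 0:
            raise PanelValidationError("empty item rating matrix")
        if np.isnan(props).any():
            raise PanelValidationError("item rating matrix has missing cells")
        if (props < 0).any() or (props > 1).any():
            bad = np.argwhere((props < 0) | (props > 1))[0]
            raise PanelValidationError(
                f"proportion out of [0, 1] at judge {self.judges[bad[0]]!r}, "
                f"item {self.items[bad[1]]!r}"
            )
        object.__setattr__(self, "proportions", props)


def classic_angoff(matrix: ItemRatingMatrix) -> float:
    """Classic Angoff cut-score: 100 x grand mean over judges and items.

    Items are equally weighted; the result is invariant to row/column
    order and to transposition.
    """
    return 100.0 * float(np.mean(matrix.proportions))


def direct_suggested_mean(panel: JudgePanel) -> float:
    """Mean of the judges' directly suggested cut-scores.

    Every judge must have supplied a suggestion; otherwise the judges
    missing one are listed in the error.
    """
    missing = [r.judge_id for r in panel.ratings if r.suggested is None]
    if missing:
        raise PanelValidationError(
            f"judges without a suggested cut-score: {missing}"
        )
    if len(panel) == 0:
        raise PanelValidationError("empty panel")
    return float(np.mean([r.suggested for r in panel.ratings]))
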
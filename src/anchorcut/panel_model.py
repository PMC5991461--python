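"""Judge panels and their summary statistics.

A panel consists of independent experts who each answer two questions about
a whole examination on the percent scale:

* ``L`` — the highest score that still indicates the examinee is clearly
  incompetent (the "clear fail" anchor);
* ``H`` — the lowest score that indicates the examinee is clearly competent
  (the "clear pass" anchor);

and optionally a directly suggested cut-score.  The cut-score method
consumes only the panel means and standard errors of L and H, so this
module is responsible for producing those summaries, together with the two
robustness remedies appropriate when the normality assumption on judges'
anchors is doubtful: symmetric trimming of extreme judges and bootstrap
standard errors.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from .errors import InsufficientPanelError, PanelValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "JudgeRating",
    "JudgePanel",
    "PanelSummary",
    "NormalityReport",
    "summarize_panel",
    "trim_extremes",
    "bootstrap_se",
    "normality_diagnostics",
]


@dataclass(frozen=True)
class JudgeRating:
    """One judge's anchors, in percent of the maximum obtainable score.

    Parameters
    ----------
    judge_id
        Opaque identifier, unique within a panel.
    L
        Highest score indicating clear incompetence, in [0, scale_max].
    H
        Lowest score indicating clear competence, in [0, scale_max].
    suggested
        The judge's directly suggested cut-score, if asked; optional.
    """

    judge_id: str
    L: float
    H: float
    suggested: Optional[float] = None


@dataclass(frozen=True)
class JudgePanel:
    """An ordered collection of judge ratings sharing one percent scale.

    Judges whose L exceeds their H are internally inconsistent; they are
    retained by default (the two anchor questions are answered
    independently) with a warning logged, and can be excluded at
    construction with ``drop_inconsistent=True``.
    """

    ratings: tuple[JudgeRating, ...]
    scale_max: float = 100.0
    label: str = ""
    removed_judge_ids: tuple[str, ...] = field(default=())

    def __init__(
        self,
        ratings: Iterable[JudgeRating],
        scale_max: float = 100.0,
        label: str = "",
        removed_judge_ids: Sequence[str] = (),
        drop_inconsistent: bool = False,
    ) -> None:
        ratings = tuple(ratings)
        seen: set[str] = set()
        for r in ratings:
            if r.judge_id in seen:
                raise PanelValidationError(
                    f"duplicate judge_id {r.judge_id!r} in panel"
                )
            seen.add(r.judge_id)
            for name, value in (("L", r.L), ("H", r.H), ("suggested", r.suggested)):
                if value is None:
                    continue
                if not math.isfinite(value) or not 0.0 <= value <= scale_max:
                    raise PanelValidationError(
                        f"judge {r.judge_id!r}: {name}={value} outside "
                        f"[0, {scale_max}]"
                    )
        inconsistent = [r for r in ratings if r.L > r.H]
        if inconsistent:
            ids = [r.judge_id for r in inconsistent]
            if drop_inconsistent:
                logger.warning("excluding %d judge(s) with L > H: %s", len(ids), ids)
                removed_judge_ids = tuple(removed_judge_ids) + tuple(ids)
                ratings = tuple(r for r in ratings if r.L <= r.H)
            else:
                logger.warning("retaining %d judge(s) with L > H: %s", len(ids), ids)
        object.__setattr__(self, "ratings", ratings)
        object.__setattr__(self, "scale_max", float(scale_max))
        object.__setattr__(self, "label", label)
        object.__setattr__(self, "removed_judge_ids", tuple(removed_judge_ids))

    def __len__(self) -> int:
        return len(self.ratings)

    @property
    def L(self) -> np.ndarray:
        return np.array([r.L for r in self.ratings], dtype=float)

    @property
    def H(self) -> np.ndarray:
        return np.array([r.H for r in self.ratings], dtype=float)

    @property
    def suggested(self) -> Optional[np.ndarray]:
        """Suggested cut-scores, or None unless every judge gave one."""
        vals = [r.suggested for r in self.ratings]
        if not vals or any(v is None for v in vals):
            return None
        return np.array(vals, dtype=float)


@dataclass(frozen=True)
class PanelSummary:
    """Means, sample SDs and standard errors of the panel anchors.

    ``se_L``/``se_H`` equal ``sd/sqrt(n)`` when ``se_method`` is
    ``"analytic"``; with ``"bootstrap"`` they are SDs of resample means.
    Suggested-cut-score summaries are present only when every judge
    supplied one.
    """

    n: int
    mean_L: float
    mean_H: float
    sd_L: float
    sd_H: float
    se_L: float
    se_H: float
    mean_suggested: Optional[float] = None
    sd_suggested: Optional[float] = None
    se_suggested: Optional[float] = None
    trimmed: bool = False
    n_trimmed: int = 0
    se_method: str = "analytic"
    scale_max: float = 100.0
    label: str = ""


@dataclass(frozen=True)
class NormalityReport:
    """Advisory distributional diagnostics for one anchor's values.

    The advisory flag is informational only: the cut-score engine never
    refuses data on the basis of non-normality.
    """

    n: int
    skewness: float
    excess_kurtosis: float
    shapiro_p: float
    advisory: bool


def _mean_sd_se(values: np.ndarray) -> tuple[float, float, float]:
    n = values.size
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1))
    return mean, sd, sd / math.sqrt(n)


def summarize_panel(
    panel: JudgePanel,
    se_method: str = "analytic",
    bootstrap_replicates: int = 2000,
    seed: Optional[int] = None,
) -> PanelSummary:
    """Compute n, means, sample SDs (n-1 denominator) and SEs for L and H.

    Parameters
    ----------
    panel
        The judge panel; at least 2 ratings are required.
    se_method
        ``"analytic"`` uses SE = SD/sqrt(n); ``"bootstrap"`` replaces the
        SEs with bootstrap SEs (SD of resample means) and requires ``seed``.
    bootstrap_replicates, seed
        Bootstrap settings, used only when ``se_method="bootstrap"``.
    """
    if len(panel) < 2:
        raise InsufficientPanelError(
            f"insufficient panel: {len(panel)} rating(s), need at least 2"
        )
    if se_method not in ("analytic", "bootstrap"):
        raise ValueError(f"unknown se_method {se_method!r}")

    mean_L, sd_L, se_L = _mean_sd_se(panel.L)
    mean_H, sd_H, se_H = _mean_sd_se(panel.H)

    mean_s = sd_s = se_s = None
    sugg = panel.suggested
    if sugg is not None:
        mean_s, sd_s, se_s = _mean_sd_se(sugg)

    if se_method == "bootstrap":
        if seed is None:
            raise ValueError("bootstrap SEs require an explicit seed")
        se_L = bootstrap_se(panel.L, replicates=bootstrap_replicates, seed=seed)
        se_H = bootstrap_se(panel.H, replicates=bootstrap_replicates, seed=seed + 1)
        if sugg is not None:
            se_s = bootstrap_se(sugg, replicates=bootstrap_replicates, seed=seed + 2)

    return PanelSummary(
        n=len(panel),
        mean_L=mean_L,
        mean_H=mean_H,
        sd_L=sd_L,
        sd_H=sd_H,
        se_L=se_L,
        se_H=se_H,
        mean_suggested=mean_s,
        sd_suggested=sd_s,
        se_suggested=se_s,
        trimmed=bool(panel.removed_judge_ids),
        n_trimmed=len(panel.removed_judge_ids),
        se_method=se_method,
        scale_max=panel.scale_max,
        label=panel.label,
    )


def trim_extremes(panel: JudgePanel, k_per_side: int, field: str = "L") -> JudgePanel:
    """Remove the ``k_per_side`` lowest and highest judges on one anchor.

    Whole judges are removed (both their L and H), so the two anchor
    distributions remain drawn from the same panel.  Ties at the trim
    boundary are broken by judge input order (earlier judges trimmed
    first).  The input panel is unchanged; removed judge ids accumulate on
    the returned panel.
    """
    if k_per_side < 0:
        raise ValueError("k_per_side must be >= 0")
    if field not in ("L", "H"):
        raise ValueError(f"trim field must be 'L' or 'H', got {field!r}")
    if k_per_side == 0:
        return panel
    remaining = len(panel) - 2 * k_per_side
    if remaining < 2:
        raise InsufficientPanelError(
            f"trimming {k_per_side} per side leaves {max(remaining, 0)} "
            "judge(s); need at least 2"
        )
    values = getattr(panel, field)
    # ties at either boundary resolved by input position (earlier first)
    low_order = sorted(range(len(panel)), key=lambda i: (values[i], i))
    dropped = set(low_order[:k_per_side])
    high_order = sorted(range(len(panel)), key=lambda i: (-values[i], i))
    dropped |= set(
        [i for i in high_order if i not in dropped][:k_per_side]
    )
    kept = [r for i, r in enumerate(panel.ratings) if i not in dropped]
    removed = tuple(panel.ratings[i].judge_id for i in sorted(dropped))
    return JudgePanel(
        kept,
        scale_max=panel.scale_max,
        label=panel.label,
        removed_judge_ids=panel.removed_judge_ids + removed,
    )


def bootstrap_se(
    values: Sequence[float] | np.ndarray,
    replicates: int = 2000,
    seed: Optional[int] = None,
) -> float:
    """Bootstrap standard error of the mean: SD (n-1 denominator) of the
    means of ``replicates`` with-replacement resamples of the input size.

    Reproducible for a fixed seed; a seed is required so that audit runs
    can be replayed exactly.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise InsufficientPanelError(
            f"insufficient panel: {values.size} value(s), need at least 2"
        )
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if seed is None:
        raise ValueError("bootstrap_se requires an explicit seed")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, values.size, size=(replicates, values.size))
    means = values[idx].mean(axis=1)
    if replicates == 1:
        return 0.0
    return float(np.std(means, ddof=1))


def normality_diagnostics(values: Sequence[float] | np.ndarray) -> NormalityReport:
    """Sample skewness, excess kurtosis and a Shapiro-Wilk p-value.

    Sets an advisory flag when ``|skewness| > 1`` or Shapiro-Wilk p < 0.05.
    Advisory only — callers decide whether to trim or bootstrap.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        raise PanelValidationError(
            f"normality diagnostics need at least 3 values, got {values.size}"
        )
    if np.ptp(values) == 0:
        # constant sample: no shape to test
        return NormalityReport(values.size, 0.0, 0.0, float("nan"), False)
    skewness = float(stats.skew(values, bias=False))
    kurt = float(stats.kurtosis(values, bias=False))
    shapiro_p = float(stats.shapiro(values).pvalue)
    advisory = abs(skewness) > 1.0 or shapiro_p < 0.05
    return NormalityReport(values.size, skewness, kurt, shapiro_p, advisory)
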
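"""The anchor-interface cut-score method.

Given panel means and standard errors of the clear-fail anchor L and the
clear-pass anchor H, the method finds the single Z that solves

    Z * SE_L + Z * SE_H = mean_H - mean_L

i.e. Z = (mean_H - mean_L) / (SE_L + SE_H), and places the cut-score CS at
the interface of the two anchor sampling distributions:

    CS = mean_L + Z * SE_L = mean_H - Z * SE_H

The two anchored expressions are algebraically identical; both are computed
and their equality is preserved numerically as an internal consistency
check.  The confidence attached to the cut-score is the two-sided normal
mass between the anchors, 2*Phi(Z) - 1, which reproduces the familiar
68% / 95% / 99.7% at Z = 1 / 2 / 3.  The one-tailed p is 1 - Phi(Z).

A 95% confidence interval for the cut-score is available only while the
anchor distributions overlap at the 1.96 level (|Z| < 1.96): its lower
bound comes from the clear-pass anchor (mean_H - 1.96*SE_H) and its upper
bound from the clear-fail anchor (mean_L + 1.96*SE_L).  For |Z| >= 1.96
that construction inverts, so the interval is reported as absent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

from scipy.stats import norm

from .errors import DegeneratePanelError
from .panel_model import PanelSummary

logger = logging.getLogger(__name__)

__all__ = [
    "CutScoreResult",
    "Classification",
    "solve_z",
    "compute_cut_score",
    "confidence_level",
    "one_tailed_p",
    "ci_95",
    "classify_examinee",
]

#: CI applicability threshold; the interval itself is built from 1.96 SEs.
CI_Z_CRITICAL = 1.96


@dataclass(frozen=True)
class CutScoreResult:
    """Full output of the cut-score computation for one panel.

    ``cut_score_from_L`` and ``cut_score_from_H`` are the L- and H-anchored
    evaluations of the same point; ``cut_score`` is their average and
    agrees with both to numerical precision.  ``confidence`` is
    2*Phi(z) - 1 clipped to [0, 1]; ``p_one_tailed`` is 1 - Phi(z).
    ``ci_low``/``ci_high`` are absent when ``ci_applicable`` is False.
    """

    z: float
    cut_score: float
    cut_score_from_L: float
    cut_score_from_H: float
    confidence: float
    p_one_tailed: float
    ci_low: Optional[float]
    ci_high: Optional[float]
    ci_applicable: bool
    anchors_inverted: bool
    degenerate: bool
    summary: PanelSummary

    @property
    def ci_midpoint(self) -> Optional[float]:
        """Midpoint of the 95% CI; generally differs from the cut-score
        because the two bounds come from different anchor variances."""
        if self.ci_low is None or self.ci_high is None:
            return None
        return 0.5 * (self.ci_low + self.ci_high)

    @property
    def anchor_midpoint(self) -> float:
        """Plain midpoint (mean_L + mean_H)/2, ignoring anchor variances."""
        return 0.5 * (self.summary.mean_L + self.summary.mean_H)


@dataclass(frozen=True)
class Classification:
    """Pass/fail call for one examinee score against a cut-score result.

    ``within_ci`` is audit information (score inside the applicable 95%
    CI), never a third outcome.
    """

    score: float
    category: str  # "pass" | "fail"
    within_ci: bool


def solve_z(summary: PanelSummary) -> float:
    """Solve Z * SE_L + Z * SE_H = mean_H - mean_L for Z.

    Z is negative when the anchors are inverted (mean_H < mean_L).  With
    both SEs zero the equation is degenerate: equal means return 0 (the
    caller flags degeneracy), distinct means raise
    :class:`DegeneratePanelError`.
    """
    se_sum = summary.se_L + summary.se_H
    diff = summary.mean_H - summary.mean_L
    if se_sum == 0.0:
        if diff == 0.0:
            return 0.0
        raise DegeneratePanelError(
            "degenerate panel: SE_L + SE_H = 0 with mean_H != mean_L "
            "(infinite Z)"
        )
    return diff / se_sum


def confidence_level(z: float) -> float:
    """Confidence in the cut-score: max(0, 2*Phi(z) - 1).

    This is the normal mass separating the two anchor sampling
    distributions at the interface point; it equals 0.6827 / 0.9545 /
    0.9973 at z = 1 / 2 / 3.  Negative z (inverted anchors) yields 0.
    """
    return max(0.0, 2.0 * float(norm.cdf(z)) - 1.0)


def one_tailed_p(z: float) -> float:
    """Upper-tail normal probability 1 - Phi(z)."""
    return float(norm.sf(z))


def ci_95(summary: PanelSummary, z: float) -> Optional[tuple[float, float]]:
    """95% CI of the cut-score, or None when |z| >= 1.96.

    The lower bound is the lowest score the panel would accept as a clear
    pass at the 95% level (mean_H - 1.96*SE_H); the upper bound is the
    highest score still compatible with a clear fail (mean_L +
    1.96*SE_L).  The construction only makes sense while those two bounds
    bracket the cut-score, i.e. while |z| < 1.96.
    """
    if abs(z) >= CI_Z_CRITICAL:
        return None
    low = summary.mean_H - CI_Z_CRITICAL * summary.se_H
    high = summary.mean_L + CI_Z_CRITICAL * summary.se_L
    return (low, high)


def compute_cut_score(summary: PanelSummary) -> CutScoreResult:
    """Run the full method on a panel summary.

    Degenerate panels (both SEs zero, equal means) yield the common mean
    as the cut-score with confidence 0 and the ``degenerate`` flag set.
    A cut-score outside [0, scale_max] — possible only with inverted
    anchors — is clamped with a logged warning.
    """
    z = solve_z(summary)
    degenerate = summary.se_L + summary.se_H == 0.0
    cs_from_L = summary.mean_L + z * summary.se_L
    cs_from_H = summary.mean_H - z * summary.se_H
    cut_score = 0.5 * (cs_from_L + cs_from_H)
    if not 0.0 <= cut_score <= summary.scale_max:
        clamped = min(max(cut_score, 0.0), summary.scale_max)
        logger.warning(
            "cut-score %.4f outside [0, %s]; clamped to %.4f",
            cut_score, summary.scale_max, clamped,
        )
        cut_score = clamped
    confidence = 0.0 if degenerate else confidence_level(z)
    interval = None if degenerate else ci_95(summary, z)
    return CutScoreResult(
        z=z,
        cut_score=cut_score,
        cut_score_from_L=cs_from_L,
        cut_score_from_H=cs_from_H,
        confidence=confidence,
        p_one_tailed=one_tailed_p(z),
        ci_low=None if interval is None else interval[0],
        ci_high=None if interval is None else interval[1],
        ci_applicable=interval is not None,
        anchors_inverted=summary.mean_H < summary.mean_L,
        degenerate=degenerate,
        summary=summary,
    )


def classify_examinee(score: float, result: CutScoreResult) -> Classification:
    """Classify a score: pass at or above the cut-score, fail below.

    The cut-score means that, absent measurement error, every level below
    it indicates incompetence and every level at or above it competence —
    so a score exactly at the cut-score passes.
    """
    if not 0.0 <= score <= result.summary.scale_max:
        raise ValueError(
            f"score {score} outside [0, {result.summary.scale_max}]"
        )
    category = "pass" if score >= result.cut_score else "fail"
    within_ci = (
        result.ci_applicable
        and result.ci_low <= score <= result.ci_high  # type: ignore[operator]
    )
    return Classification(score=score, category=category, within_ci=within_ci)
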
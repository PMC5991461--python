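"""Shared fixtures: the pilot-panel summary and exact-moment panel builders."""

import numpy as np
import pytest

from anchorcut import JudgePanel, JudgeRating, PanelSummary

# Pilot-panel descriptive statistics (17 judges, percent scale): means,
# printed standard errors, and SDs for the clear-fail (L) and clear-pass
# (H) anchors plus the directly suggested cut-score.
PILOT = {
    "n": 17,
    "mean_L": 62.65, "se_L": 5.609, "sd_L": 23.12,
    "mean_H": 65.35, "se_H": 3.193, "sd_H": 13.16,
    "mean_suggested": 60.47, "se_suggested": 2.756, "sd_suggested": 11.36,
}


def values_with_moments(mean: float, se: float, n: int, seed: int = 0) -> np.ndarray:
    """n values whose sample mean and SE (SD/sqrt(n), ddof=1) are exact.

    Uses an equally spaced pattern standardised to sample mean 0 / sample
    SD 1 (max |z| < sqrt(3), so values stay on-scale for the panels used
    here) and permuted by the seed; rebuilds panels from printed summary
    statistics.
    """
    x = np.linspace(-1.0, 1.0, n)
    x = (x - x.mean()) / x.std(ddof=1)
    rng = np.random.default_rng(seed)
    rng.shuffle(x)
    return mean + se * np.sqrt(n) * x


def build_panel(mean_L, se_L, mean_H, se_H, n, seed=0, suggested=None,
                scale_max=100.0) -> JudgePanel:
    """Panel with exactly the requested anchor sample moments."""
    L = values_with_moments(mean_L, se_L, n, seed)
    H = values_with_moments(mean_H, se_H, n, seed + 1)
    if suggested is not None:
        mean_s, se_s = suggested
        s = values_with_moments(mean_s, se_s, n, seed + 2)
    ratings = [
        JudgeRating(
            judge_id=f"j{i}",
            L=float(L[i]),
            H=float(H[i]),
            suggested=float(s[i]) if suggested is not None else None,
        )
        for i in range(n)
    ]
    return JudgePanel(ratings, scale_max=scale_max)


@pytest.fixture
def pilot_summary() -> PanelSummary:
    """Summary-level view of the 17-judge pilot panel."""
    return PanelSummary(
        n=PILOT["n"],
        mean_L=PILOT["mean_L"], mean_H=PILOT["mean_H"],
        sd_L=PILOT["sd_L"], sd_H=PILOT["sd_H"],
        se_L=PILOT["se_L"], se_H=PILOT["se_H"],
        mean_suggested=PILOT["mean_suggested"],
        sd_suggested=PILOT["sd_suggested"],
        se_suggested=PILOT["se_suggested"],
    )


@pytest.fixture
def pilot_panel() -> JudgePanel:
    """A 17-judge panel whose sample moments match the pilot summary."""
    return build_panel(
        PILOT["mean_L"], PILOT["se_L"], PILOT["mean_H"], PILOT["se_H"],
        n=PILOT["n"], seed=11,
        suggested=(PILOT["mean_suggested"], PILOT["se_suggested"]),
    )
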
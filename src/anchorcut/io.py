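"""CSV input, report rendering and serialization.

Panel CSV schema: header ``judge_id,L,H[,suggested]``; percents on
[0, scale_max]; blank ``suggested`` cells allowed.  Item-matrix CSV:
header ``judge_id,item_1,...,item_k`` with proportions in [0, 1].

Reports are deterministic for fixed inputs and round the way results are
conventionally printed: Z to 3 dp, scores and CI bounds to 2 dp,
percentages to 1 dp.
"""

from __future__ import annotations

import hashlib
import json
import math
from pathlib import Path
from typing import Optional

import pandas as pd

from .baselines import ItemRatingMatrix
from .engine import Classification, CutScoreResult
from .errors import PanelValidationError
from .panel_model import JudgePanel, JudgeRating, PanelSummary

__all__ = [
    "read_panel_csv",
    "read_item_matrix_csv",
    "write_report",
    "result_to_dict",
    "result_from_dict",
    "file_digest",
]


def file_digest(path: str | Path) -> str:
    """SHA-256 of a file, for audit provenance in reports."""
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _parse_percent(
    raw: object, row: int, column: str, scale_max: float
) -> float:
    try:
        value = float(raw)  # type: ignore[arg-type]
    except (TypeError, ValueError):
        raise PanelValidationError(
            f"row {row}: non-numeric {column}={raw!r}"
        ) from None
    if not math.isfinite(value) or not 0.0 <= value <= scale_max:
        raise PanelValidationError(
            f"row {row}: {column}={value} outside [0, {scale_max}]"
        )
    return value


def read_panel_csv(
    path: str | Path,
    scale_max: float = 100.0,
    drop_inconsistent: bool = False,
) -> JudgePanel:
    """Parse a judge-panel CSV into a :class:`JudgePanel`.

    Row numbers in error messages are 1-based data rows (header = row 0).
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"judge_id": str})
    missing = {"judge_id", "L", "H"} - set(df.columns)
    if missing:
        raise PanelValidationError(
            f"{path.name}: missing required column(s) {sorted(missing)}"
        )
    has_suggested = "suggested" in df.columns
    ratings = []
    for i, rec in enumerate(df.to_dict("records"), start=1):
        row = int(i)
        suggested = None
        if has_suggested and not pd.isna(rec["suggested"]):
            suggested = _parse_percent(rec["suggested"], row, "suggested", scale_max)
        ratings.append(
            JudgeRating(
                judge_id=str(rec["judge_id"]),
                L=_parse_percent(rec["L"], row, "L", scale_max),
                H=_parse_percent(rec["H"], row, "H", scale_max),
                suggested=suggested,
            )
        )
    return JudgePanel(
        ratings,
        scale_max=scale_max,
        label=path.name,
        drop_inconsistent=drop_inconsistent,
    )


def read_item_matrix_csv(path: str | Path) -> ItemRatingMatrix:
    """Parse a judges x items Angoff proportion matrix from CSV."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"judge_id": str})
    if "judge_id" not in df.columns:
        raise PanelValidationError(f"{path.name}: missing 'judge_id' column")
    items = [c for c in df.columns if c != "judge_id"]
    if not items:
        raise PanelValidationError(f"{path.name}: no item columns")
    return ItemRatingMatrix(
        judges=tuple(df["judge_id"].astype(str)),
        items=tuple(items),
        proportions=df[items].to_numpy(dtype=float),
    )


def _round_opt(value: Optional[float], nd: int) -> Optional[float]:
    return None if value is None else round(value, nd)


def result_to_dict(
    result: CutScoreResult,
    baselines: Optional[dict[str, float]] = None,
    provenance: Optional[dict[str, object]] = None,
) -> dict:
    """Machine-readable form of a result (full precision, JSON-safe)."""
    s = result.summary
    out = {
        "summary": {
            "n": s.n,
            "mean_L": s.mean_L,
            "mean_H": s.mean_H,
            "sd_L": s.sd_L,
            "sd_H": s.sd_H,
            "se_L": s.se_L,
            "se_H": s.se_H,
            "mean_suggested": s.mean_suggested,
            "sd_suggested": s.sd_suggested,
            "se_suggested": s.se_suggested,
            "trimmed": s.trimmed,
            "n_trimmed": s.n_trimmed,
            "se_method": s.se_method,
            "scale_max": s.scale_max,
            "label": s.label,
        },
        "z": result.z,
        "cut_score": result.cut_score,
        "cut_score_from_L": result.cut_score_from_L,
        "cut_score_from_H": result.cut_score_from_H,
        "confidence": result.confidence,
        "p_one_tailed": result.p_one_tailed,
        "ci_low": result.ci_low,
        "ci_high": result.ci_high,
        "ci_applicable": result.ci_applicable,
        "ci_midpoint": result.ci_midpoint,
        "anchor_midpoint": result.anchor_midpoint,
        "anchors_inverted": result.anchors_inverted,
        "degenerate": result.degenerate,
    }
    if baselines:
        out["baselines"] = dict(baselines)
    if provenance:
        out["provenance"] = dict(provenance)
    return out


def result_from_dict(payload: dict) -> CutScoreResult:
    """Rebuild a :class:`CutScoreResult` from :func:`result_to_dict` output."""
    s = payload["summary"]
    summary = PanelSummary(
        n=s["n"], mean_L=s["mean_L"], mean_H=s["mean_H"],
        sd_L=s["sd_L"], sd_H=s["sd_H"], se_L=s["se_L"], se_H=s["se_H"],
        mean_suggested=s.get("mean_suggested"),
        sd_suggested=s.get("sd_suggested"),
        se_suggested=s.get("se_suggested"),
        trimmed=s.get("trimmed", False), n_trimmed=s.get("n_trimmed", 0),
        se_method=s.get("se_method", "analytic"),
        scale_max=s.get("scale_max", 100.0), label=s.get("label", ""),
    )
    return CutScoreResult(
        z=payload["z"],
        cut_score=payload["cut_score"],
        cut_score_from_L=payload["cut_score_from_L"],
        cut_score_from_H=payload["cut_score_from_H"],
        confidence=payload["confidence"],
        p_one_tailed=payload["p_one_tailed"],
        ci_low=payload["ci_low"],
        ci_high=payload["ci_high"],
        ci_applicable=payload["ci_applicable"],
        anchors_inverted=payload["anchors_inverted"],
        degenerate=payload["degenerate"],
        summary=summary,
    )


def write_report(
    result: CutScoreResult,
    baselines: Optional[dict[str, float]] = None,
    format: str = "text",
    provenance: Optional[dict[str, object]] = None,
) -> str:
    """Render a result as a plain-text or JSON report string.

    The text report shows both anchored cut-score computations, the
    confidence, one-tailed p, the 95% CI with its midpoint, and the plain
    anchor midpoint — the latter two are distinct quantities because the
    CI bounds come from two independent anchor variances.
    """
    if format == "json":
        return json.dumps(
            result_to_dict(result, baselines=baselines, provenance=provenance),
            indent=2,
            sort_keys=True,
        )
    if format != "text":
        raise ValueError(f"unknown report format {format!r}")

    s = result.summary
    lines = [
        "Cut-score report" + (f" — {s.label}" if s.label else ""),
        "=" * 40,
        f"Judges (n):            {s.n}"
        + (f"  ({s.n_trimmed} trimmed)" if s.trimmed else ""),
        f"Clear fail  L: mean {s.mean_L:.2f}  SD {s.sd_L:.2f}  SE {s.se_L:.3f}",
        f"Clear pass  H: mean {s.mean_H:.2f}  SD {s.sd_H:.2f}  SE {s.se_H:.3f}",
        f"SE method:             {s.se_method}",
        f"Z:                     {result.z:.3f}",
        f"Cut-score (from L):    {result.cut_score_from_L:.2f}",
        f"Cut-score (from H):    {result.cut_score_from_H:.2f}",
        f"Cut-score:             {result.cut_score:.2f}",
        f"Confidence:            {100 * result.confidence:.1f}%",
        f"One-tailed p:          {result.p_one_tailed:.2f}",
    ]
    if result.ci_applicable:
        lines += [
            f"95% CI:                {result.ci_low:.2f} – {result.ci_high:.2f}",
            f"95% CI midpoint:       {result.ci_midpoint:.2f}",
        ]
    else:
        lines.append("95% CI:                not applicable (|Z| >= 1.96)")
    lines.append(f"Anchor midpoint (L,H): {result.anchor_midpoint:.2f}")
    if s.mean_suggested is not None:
        lines.append(f"Suggested cut (mean):  {s.mean_suggested:.2f}")
    if result.degenerate:
        lines.append("FLAG: degenerate panel (SE_L + SE_H = 0)")
    if result.anchors_inverted:
        lines.append("FLAG: anchors inverted (mean_H < mean_L)")
    if baselines:
        lines.append("-" * 40)
        for name, value in baselines.items():
            lines.append(f"Baseline {name}: {value:.2f}")
    if provenance:
        lines.append("-" * 40)
        for key, value in provenance.items():
            lines.append(f"{key}: {value}")
    return "\n".join(lines) + "\n"


def format_classification(c: Classification) -> str:
    note = "  [within 95% CI]" if c.within_ci else ""
    return f"score {c.score:.2f}: {c.category}{note}"
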
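"""Pearson anchor-correlation screening of stage profiles.

Anchor proteins (in the motivating analysis, the five SCMC components Ooep,
Nlrp5, Tle6, Zbed3 and Padi6) are correlated against every other quantified
protein's stage trajectory.  A strong correlation is |r| >= 0.70 with
p <= 0.05, the p-value coming from the exact Student-t transform of r under
the bivariate-normal null:

    t = r * sqrt((n - 2) / (1 - r^2)),   t ~ t(n - 2)  (two-sided).

With the six preimplantation stages, n = 6 and df = 4, for which the
two-sided p has the closed form 1 - 1.5|r| + 0.5|r|^3.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import StageProfile, normalize_protein_id
from .errors import ValidationError

STRENGTH_CLASSES = ("strong_positive", "strong_negative", "none", "undefined")
COMBINATION_RULES = ("all", "any", "mean_profile")


class PearsonResult(NamedTuple):
    r: float
    n: int


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> PearsonResult:
    """Product-moment correlation over pairwise-complete entries.

    Returns ``(r, n)`` where n is the number of complete pairs used.  If
    fewer than 3 pairs are complete or either vector has zero spread over
    them, r is NaN (the "undefined" marker) rather than an exception — the
    caller propagates it to strength ``undefined``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("vectors must have the same length")
    ok = np.isfinite(x) & np.isfinite(y)
    n = int(ok.sum())
    if n < 3:
        return PearsonResult(math.nan, n)
    xs, ys = x[ok], y[ok]
    sx, sy = xs.std(), ys.std()
    if sx == 0 or sy == 0:
        return PearsonResult(math.nan, n)
    r = float(((xs - xs.mean()) * (ys - ys.mean())).mean() / (sx * sy))
    return PearsonResult(max(-1.0, min(1.0, r)), n)


def p_from_r(r: float, n: int) -> float:
    """Two-sided p-value for a Pearson r on n paired observations.

    Uses the exact t transform with n - 2 degrees of freedom; |r| = 1 gives
    p = 0 by continuity.
    """
    if n < 3:
        raise ValidationError("need n >= 3 paired observations for a p-value")
    if not math.isfinite(r) or abs(r) > 1:
        raise ValidationError(f"r must be a finite value in [-1, 1], got {r!r}")
    if abs(r) == 1.0:
        return 0.0
    t = abs(r) * math.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(t, df=n - 2))


@dataclass(frozen=True)
class ScreenConfig:
    """Thresholds and anchor handling for the correlation screen."""

    anchors: tuple[str, ...] = ("Ooep", "Nlrp5", "Tle6", "Zbed3", "Padi6")
    r_threshold: float = 0.70
    p_threshold: float = 0.05
    combination_rule: str = "all"
    digits: int = 4

    def __post_init__(self) -> None:
        if not 0 < self.r_threshold <= 1:
            raise ValidationError("r threshold must be in (0, 1]")
        if not 0 < self.p_threshold <= 1:
            raise ValidationError("p threshold must be in (0, 1]")
        if self.combination_rule not in COMBINATION_RULES:
            raise ValidationError(
                f"unknown combination rule {self.combination_rule!r}; "
                f"choose from {COMBINATION_RULES}"
            )
        if not self.anchors:
            raise ValidationError("at least one anchor id is required")


@dataclass(frozen=True)
class CorrelationRecord:
    """One (anchor, protein) correlation cell."""

    dataset_id: str
    anchor: str
    protein: str
    r: float
    p: float
    n: int
    strength: str

    def __post_init__(self) -> None:
        if self.strength not in STRENGTH_CLASSES:
            raise ValidationError(f"unknown strength class {self.strength!r}")


def classify_strength(r: float, p: float, config: ScreenConfig) -> str:
    """Strong positive/negative/none classification of an (r, p) pair."""
    if not math.isfinite(r) or not math.isfinite(p):
        return "undefined"
    if r >= config.r_threshold and p <= config.p_threshold:
        return "strong_positive"
    if r <= -config.r_threshold and p <= config.p_threshold:
        return "strong_negative"
    return "none"


@dataclass
class ScreenResult:
    """Records plus per-protein verdicts from an anchor screen."""

    records: list[CorrelationRecord]
    verdicts: pd.DataFrame  # protein_id, verdict, reason
    config: ScreenConfig = field(repr=False, default=ScreenConfig())

    def candidates(self, sign: str | None = None) -> set[str]:
        v = self.verdicts
        mask = v["verdict"].isin(["strong_positive", "strong_negative"])
        if sign == "+":
            mask = v["verdict"] == "strong_positive"
        elif sign == "-":
            mask = v["verdict"] == "strong_negative"
        return set(v.loc[mask, "protein_id"])


def _mean_anchor_profile(anchor_profiles: list[StageProfile]) -> np.ndarray:
    stacked = np.stack([a.values for a in anchor_profiles])
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(stacked, axis=0)
    obs = np.isfinite(mean)
    if obs.sum() >= 2 and mean[obs].std(ddof=1) > 0:
        out = np.full_like(mean, np.nan)
        out[obs] = (mean[obs] - mean[obs].mean()) / mean[obs].std(ddof=1)
        return out
    return mean


def screen_against_anchors(
    profiles: list[StageProfile],
    config: ScreenConfig,
    dataset_id: str = "",
) -> ScreenResult:
    """Correlate every non-anchor profile against every anchor profile.

    Anchors are excluded from the candidate pool.  The per-protein verdict
    follows ``config.combination_rule``:

    - ``all``: strong with the same sign against *every* anchor;
    - ``any``: strong against at least one anchor; conflicting signs across
      anchors exclude the protein with reason ``sign_conflict``;
    - ``mean_profile``: a single correlation against the standardized mean
      anchor profile.
    """
    by_id = {normalize_protein_id(p.protein_id): p for p in profiles}
    anchor_keys = [normalize_protein_id(a) for a in config.anchors]
    missing = [a for a, k in zip(config.anchors, anchor_keys) if k not in by_id]
    if missing:
        raise ValidationError(f"anchor(s) not present in the dataset: {missing}")
    anchor_profiles = [by_id[k] for k in anchor_keys]
    candidates = [
        p for p in profiles if normalize_protein_id(p.protein_id) not in set(anchor_keys)
    ]

    records: list[CorrelationRecord] = []
    verdict_rows: list[tuple[str, str, str]] = []

    if config.combination_rule == "mean_profile":
        mean_profile = _mean_anchor_profile(anchor_profiles)
        for prot in candidates:
            r, n = pearson_correlation(mean_profile, prot.values)
            p = p_from_r(r, n) if math.isfinite(r) and n >= 3 else math.nan
            strength = classify_strength(r, p, config)
            records.append(
                CorrelationRecord(dataset_id, "mean_anchor", prot.protein_id, r, p, n, strength)
            )
            verdict_rows.append((prot.protein_id, strength, ""))
    else:
        for prot in candidates:
            strengths: list[str] = []
            for anchor_name, anchor in zip(config.anchors, anchor_profiles):
                r, n = pearson_correlation(anchor.values, prot.values)
                p = p_from_r(r, n) if math.isfinite(r) and n >= 3 else math.nan
                strength = classify_strength(r, p, config)
                records.append(
                    CorrelationRecord(dataset_id, anchor_name, prot.protein_id, r, p, n, strength)
                )
                strengths.append(strength)
            strong = {s for s in strengths if s.startswith("strong")}
            if config.combination_rule == "all":
                if len(strong) == 1 and all(s in strong for s in strengths):
                    verdict_rows.append((prot.protein_id, strengths[0], ""))
                else:
                    reason = "sign_conflict" if len(strong) == 2 else "not_strong_vs_all_anchors"
                    verdict_rows.append((prot.protein_id, "none", reason))
            else:  # any
                if len(strong) == 2:
                    verdict_rows.append((prot.protein_id, "none", "sign_conflict"))
                elif len(strong) == 1:
                    verdict_rows.append((prot.protein_id, next(iter(strong)), ""))
                else:
                    verdict_rows.append((prot.protein_id, "none", "not_strong_vs_any_anchor"))

    verdicts = pd.DataFrame(verdict_rows, columns=["protein_id", "verdict", "reason"])
    return ScreenResult(records=records, verdicts=verdicts, config=config)


def records_to_frame(records: list[CorrelationRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (rec.dataset_id, rec.anchor, rec.protein, rec.n, rec.r, rec.p, rec.strength)
            for rec in records
        ],
        columns=["dataset_id", "anchor", "protein", "n", "r", "p", "strength"],
    )


DASH = "—"


def correlation_report(
    records: list[CorrelationRecord], config: ScreenConfig
) -> pd.DataFrame:
    """Wide report with one (protein, dataset) row and paired p/r columns per
    anchor, values rounded to ``config.digits`` and missing cells dashed."""
    anchors = list(dict.fromkeys(rec.anchor for rec in records))
    cell: dict[tuple[str, str], dict[str, str]] = {}
    for rec in records:
        row = cell.setdefault((rec.protein, rec.dataset_id), {})
        if math.isfinite(rec.r) and math.isfinite(rec.p):
            row[f"{rec.anchor}_p"] = f"{rec.p:.{config.digits}f}"
            row[f"{rec.anchor}_r"] = f"{rec.r:.{config.digits}f}"
    rows = []
    for (protein, dataset_id), values in cell.items():
        row = {"protein_id": protein, "dataset_id": dataset_id}
        for anchor in anchors:
            row[f"{anchor}_p"] = values.get(f"{anchor}_p", DASH)
            row[f"{anchor}_r"] = values.get(f"{anchor}_r", DASH)
        rows.append(row)
    columns = ["protein_id", "dataset_id"]
    for anchor in anchors:
        columns += [f"{anchor}_p", f"{anchor}_r"]
    return pd.DataFrame(rows, columns=columns)


def report_to_records(report: pd.DataFrame, n: int | None = None) -> list[CorrelationRecord]:
    """Parse a wide report back into records (strength re-derived from the
    default thresholds; n is taken from the argument, 0 when unknown)."""
    config = ScreenConfig()
    anchors = sorted(
        {c[:-2] for c in report.columns if c.endswith("_r")},
        key=lambda a: list(report.columns).index(f"{a}_r"),
    )
    records: list[CorrelationRecord] = []
    for _, row in report.iterrows():
        for anchor in anchors:
            p_txt, r_txt = str(row[f"{anchor}_p"]), str(row[f"{anchor}_r"])
            if DASH in (p_txt, r_txt) or p_txt == "nan":
                continue
            r, p = float(r_txt.replace("−", "-")), float(p_txt)
            records.append(
                CorrelationRecord(
                    dataset_id=row["dataset_id"],
                    anchor=anchor,
                    protein=row["protein_id"],
                    r=r,
                    p=p,
                    n=n or 0,
                    strength=classify_strength(r, p, config),
                )
            )
    return records


__all__ = [
    "PearsonResult",
    "pearson_correlation",
    "p_from_r",
    "ScreenConfig",
    "CorrelationRecord",
    "ScreenResult",
    "classify_strength",
    "screen_against_anchors",
    "records_to_frame",
    "correlation_report",
    "report_to_records",
]
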
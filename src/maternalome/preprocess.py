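"""Detection/quantification filtering, replicate aggregation, standardization.

The quantification rule is detection-based: a protein counts as quantified
when there is at least ``min_stages`` stages at which it was detected in at
least ``min_replicates`` biological replicates.  The default (1 stage, 3 of 3
replicates) is the strict reading of "detected in >=1 stage and >2
replicates" for a triplicate design; ``min_replicates=2`` gives the common
lenient variant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datasets import DetectionTable, ProteomeDataset, StageProfile, normalize_protein_id
from .errors import DegenerateProfileError, ValidationError

AGGREGATION_METHODS = ("mean_log2", "median_log2", "mean_raw")


@dataclass(frozen=True)
class QuantificationRule:
    """Detection thresholds defining a "quantified" protein."""

    min_stages: int = 1
    min_replicates: int = 3

    def __post_init__(self) -> None:
        if self.min_stages < 1 or self.min_replicates < 1:
            raise ValidationError("quantification rule thresholds must be >= 1")


def apply_quantification_filter(
    detection: DetectionTable, rule: QuantificationRule
) -> set[str]:
    """Canonical ids of proteins passing the detection-based rule.

    Retained iff detected in >= ``rule.min_replicates`` replicates at each of
    >= ``rule.min_stages`` stages.
    """
    if rule.min_replicates > detection.n_replicates:
        raise ValidationError(
            f"rule requires {rule.min_replicates} replicates but the dataset has "
            f"{detection.n_replicates}"
        )
    if rule.min_stages > len(detection.stages):
        raise ValidationError(
            f"rule requires {rule.min_stages} stages but the dataset has "
            f"{len(detection.stages)}"
        )
    reps_per_stage = detection.detected.sum(axis=2)  # (N, S)
    stages_passing = (reps_per_stage >= rule.min_replicates).sum(axis=1)
    keep = stages_passing >= rule.min_stages
    return {normalize_protein_id(p) for p, k in zip(detection.proteins, keep) if k}


def quantification_report(
    detection: DetectionTable, rule: QuantificationRule
) -> pd.DataFrame:
    """Per-protein filter report: retained flag and supporting counts."""
    retained = apply_quantification_filter(detection, rule)
    reps_per_stage = detection.detected.sum(axis=2)
    return pd.DataFrame(
        {
            "protein_id": detection.proteins,
            "retained": [
                int(normalize_protein_id(p) in retained) for p in detection.proteins
            ],
            "n_stages_passing": (reps_per_stage >= rule.min_replicates).sum(axis=1),
            "max_reps_in_a_stage": reps_per_stage.max(axis=1),
        }
    )


def aggregate_replicates(
    dataset: ProteomeDataset, method: str = "mean_log2"
) -> list[StageProfile]:
    """Collapse replicates into one per-stage trajectory per protein.

    ``mean_log2`` (default) averages log2 intensities over non-missing
    replicates and keeps the result on the log2 scale; ``median_log2``
    takes the log2 median; ``mean_raw`` averages raw intensities.  A stage
    with no observation is missing (NaN) in the profile.
    """
    if method not in AGGREGATION_METHODS:
        raise ValidationError(
            f"unknown aggregation method {method!r}; choose from {AGGREGATION_METHODS}"
        )
    abund = dataset.abundances
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        # an all-missing stage legitimately yields NaN; silence numpy's
        # "Mean of empty slice" for that case
        warnings.simplefilter("ignore", category=RuntimeWarning)
        if method == "mean_log2":
            values = np.nanmean(np.log2(abund), axis=2)
        elif method == "median_log2":
            values = np.nanmedian(np.log2(abund), axis=2)
        else:
            values = np.nanmean(abund, axis=2)
    return [
        StageProfile(protein_id=p, values=values[i], stages=dataset.stages)
        for i, p in enumerate(dataset.proteins)
    ]


def standardize_profile(profile: StageProfile) -> StageProfile:
    """Z-score a profile to mean 0 and sample standard deviation 1 (ddof=1)
    over its non-missing entries.

    Raises
    ------
    DegenerateProfileError
        For constant profiles or profiles with fewer than two observations —
        callers exclude these from clustering/screening rather than carrying
        infinities forward.
    """
    obs = np.isfinite(profile.values)
    if obs.sum() < 2:
        raise DegenerateProfileError(
            f"profile {profile.protein_id!r} has {int(obs.sum())} observed stage(s); need >= 2"
        )
    vals = profile.values[obs]
    sd = vals.std(ddof=1)
    if sd == 0:
        raise DegenerateProfileError(f"profile {profile.protein_id!r} is constant")
    out = np.full_like(profile.values, np.nan)
    out[obs] = (vals - vals.mean()) / sd
    return StageProfile(protein_id=profile.protein_id, values=out, stages=profile.stages)


def standardize_profiles(
    profiles: list[StageProfile],
) -> tuple[list[StageProfile], list[str]]:
    """Standardize a batch; returns (standardized, degenerate protein ids)."""
    ok: list[StageProfile] = []
    degenerate: list[str] = []
    for prof in profiles:
        try:
            ok.append(standardize_profile(prof))
        except DegenerateProfileError:
            degenerate.append(prof.protein_id)
    return ok, degenerate


def profiles_to_matrix(
    profiles: list[StageProfile], require_complete: bool = True
) -> tuple[np.ndarray, list[str]]:
    """Stack profiles into an (N, S) matrix plus the matching id list.

    With ``require_complete`` profiles containing missing stages are dropped
    (fuzzy c-means and PCA need complete vectors).
    """
    kept = [p for p in profiles if (p.is_complete or not require_complete)]
    if not kept:
        raise ValidationError("no complete profiles to stack")
    return np.stack([p.values for p in kept]), [p.protein_id for p in kept]


__all__ = [
    "QuantificationRule",
    "AGGREGATION_METHODS",
    "apply_quantification_filter",
    "quantification_report",
    "aggregate_replicates",
    "standardize_profile",
    "standardize_profiles",
    "profiles_to_matrix",
]
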
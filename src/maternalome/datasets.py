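"""In-memory containers for stage-resolved proteome data.

A :class:`ProteomeDataset` is a protein × stage × replicate array of
non-negative LFQ-style intensities with NaN as the missing marker.  Zero and
absent both mean "not detected" in label-free MS, so zeros are normalized to
NaN at construction.  Stage order is explicit metadata and fixed: every
downstream profile, cluster center and correlation is indexed by it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ValidationError

#: Canonical mouse preimplantation stage labels, in developmental order:
#: pronucleus, 2-cell, 4-cell, 8-cell, morula, blastocyst.
DEFAULT_STAGES: tuple[str, ...] = ("PN", "2C", "4C", "8C", "MO", "BL")


def normalize_protein_id(raw: str, isoform_sep: str | None = None) -> str:
    """Canonicalize a protein/gene identifier.

    Trims whitespace and case-folds, so that e.g. ``"Fbxw24 "`` and
    ``"FBXW24"`` map to the same id — datasets produced against different
    sequence databases are matched at the gene-symbol level.  If
    ``isoform_sep`` is given (e.g. ``"-"`` for UniProt isoform suffixes),
    everything from the first separator onward is dropped.

    Raises
    ------
    ValidationError
        If the identifier is empty after trimming.
    """
    if raw is None:
        raise ValidationError("protein identifier is missing")
    canonical = str(raw).strip()
    if not canonical:
        raise ValidationError("protein identifier is empty")
    if isoform_sep:
        canonical = canonical.split(isoform_sep, 1)[0]
        if not canonical:
            raise ValidationError(f"identifier {raw!r} is empty after isoform stripping")
    return canonical.casefold()


def find_id_collisions(raw_ids: Sequence[str], isoform_sep: str | None = None) -> dict[str, list[str]]:
    """Map each canonical id claimed by >1 distinct raw id to its claimants."""
    seen: dict[str, list[str]] = {}
    for raw in raw_ids:
        seen.setdefault(normalize_protein_id(raw, isoform_sep), []).append(raw)
    return {k: v for k, v in seen.items() if len(set(v)) > 1}


@dataclass
class ProteomeDataset:
    """Protein × stage × replicate abundance matrix with missing values.

    Parameters
    ----------
    dataset_id:
        Short label for the source dataset (e.g. ``"PA"``, ``"ZY_Gao"``).
    proteins:
        Ordered protein identifiers; must be unique after canonicalization.
    stages:
        Ordered stage labels; axis 1 of ``abundances`` follows this order.
    n_replicates:
        Number of biological replicates (axis 2).
    abundances:
        Array of shape ``(len(proteins), len(stages), n_replicates)`` holding
        non-negative intensities; NaN marks a missing (undetected) cell.
        Zeros are converted to NaN on construction.
    """

    dataset_id: str
    proteins: list[str]
    stages: tuple[str, ...]
    n_replicates: int
    abundances: np.ndarray
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.proteins = [str(p) for p in self.proteins]
        self.stages = tuple(str(s) for s in self.stages)
        if self.n_replicates < 1:
            raise ValidationError("n_replicates must be >= 1")
        self.abundances = np.asarray(self.abundances, dtype=float)
        expected = (len(self.proteins), len(self.stages), self.n_replicates)
        if self.abundances.shape != expected:
            raise ValidationError(
                f"abundance array shape {self.abundances.shape} != {expected} "
                "(protein x stage x replicate)"
            )
        canonical = [normalize_protein_id(p) for p in self.proteins]
        if len(set(canonical)) != len(canonical):
            dupes = sorted({c for c in canonical if canonical.count(c) > 1})
            raise ValidationError(f"duplicate protein ids after canonicalization: {dupes}")
        with np.errstate(invalid="ignore"):
            if np.any(self.abundances[np.isfinite(self.abundances)] < 0):
                raise ValidationError("abundances must be non-negative")
            if np.any(np.isinf(self.abundances)):
                raise ValidationError("abundances must be finite or NaN")
            # LFQ zero means non-detection: fold into the missing marker.
            self.abundances[self.abundances == 0] = np.nan
        self._index = {c: i for i, c in enumerate(canonical)}

    @property
    def n_proteins(self) -> int:
        return len(self.proteins)

    @property
    def n_stages(self) -> int:
        return len(self.stages)

    def protein_index(self, protein_id: str) -> int:
        key = normalize_protein_id(protein_id)
        if key not in self._index:
            raise KeyError(f"protein {protein_id!r} not in dataset {self.dataset_id!r}")
        return self._index[key]

    def __contains__(self, protein_id: str) -> bool:
        try:
            return normalize_protein_id(protein_id) in self._index
        except ValidationError:
            return False

    def detection(self) -> "DetectionTable":
        """Boolean detected/not-detected table (detected = finite positive)."""
        with np.errstate(invalid="ignore"):
            detected = np.isfinite(self.abundances) & (self.abundances > 0)
        return DetectionTable(
            dataset_id=self.dataset_id,
            proteins=list(self.proteins),
            stages=self.stages,
            n_replicates=self.n_replicates,
            detected=detected,
        )

    def copy(self) -> "ProteomeDataset":
        return ProteomeDataset(
            dataset_id=self.dataset_id,
            proteins=list(self.proteins),
            stages=self.stages,
            n_replicates=self.n_replicates,
            abundances=self.abundances.copy(),
        )


@dataclass
class DetectionTable:
    """Boolean detection table sharing the axes of its source dataset."""

    dataset_id: str
    proteins: list[str]
    stages: tuple[str, ...]
    n_replicates: int
    detected: np.ndarray

    def __post_init__(self) -> None:
        self.detected = np.asarray(self.detected, dtype=bool)
        expected = (len(self.proteins), len(self.stages), self.n_replicates)
        if self.detected.shape != expected:
            raise ValidationError(
                f"detection array shape {self.detected.shape} != {expected}"
            )

    @property
    def n_proteins(self) -> int:
        return len(self.proteins)

    def detected_proteins(self) -> set[str]:
        """Canonical ids of proteins detected in at least one cell."""
        mask = self.detected.any(axis=(1, 2))
        return {normalize_protein_id(p) for p, m in zip(self.proteins, mask) if m}


@dataclass
class StageProfile:
    """One protein's per-stage trajectory (replicate-aggregated or z-scored).

    ``values`` has one entry per stage in the dataset's stage order; NaN marks
    a stage with no observation.
    """

    protein_id: str
    values: np.ndarray
    stages: tuple[str, ...]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.stages = tuple(self.stages)
        if self.values.shape != (len(self.stages),):
            raise ValidationError(
                f"profile length {self.values.shape} != stage count {len(self.stages)}"
            )

    @property
    def n_observed(self) -> int:
        return int(np.isfinite(self.values).sum())

    @property
    def is_complete(self) -> bool:
        return self.n_observed == len(self.stages)
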
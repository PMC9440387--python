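"""Readers and writers for the tabular formats the pipeline touches.

Three dialects are supported:

- **long** TSV/CSV with one row per measurement
  (``protein_id, stage, replicate, intensity``),
- **wide** TSV with one row per protein and one ``<stage>_<rep>`` column per
  sample,
- a **MaxQuant proteinGroups-like** TSV with per-sample ``LFQ intensity``
  columns and the standard reverse/contaminant marker columns.

All readers order stages by the configured stage list, never by file order,
and record zero intensity as missing.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .datasets import DEFAULT_STAGES, ProteomeDataset, normalize_protein_id
from .errors import FormatError, ValidationError


@dataclass(frozen=True)
class LongColumns:
    """Column names of a long-format measurement table."""

    protein: str = "protein_id"
    stage: str = "stage"
    replicate: str = "replicate"
    intensity: str = "intensity"


def _sep_for(path: str | Path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_long_table(
    path: str | Path,
    columns: LongColumns | None = None,
    stages: Sequence[str] = DEFAULT_STAGES,
    dataset_id: str | None = None,
    n_replicates: int | None = None,
) -> ProteomeDataset:
    """Read a long-format (one row per measurement) TSV/CSV.

    The delimiter is inferred from the extension (``.csv`` → comma, anything
    else → tab).  Stage labels must come from ``stages``; replicate indices
    are 1-based.  Duplicate (protein, stage, replicate) rows are an error.
    """
    columns = columns or LongColumns()
    stages = tuple(stages)
    df = pd.read_csv(path, sep=_sep_for(path), float_precision="round_trip")
    required = [columns.protein, columns.stage, columns.replicate, columns.intensity]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")

    unknown = sorted(set(df[columns.stage].astype(str)) - set(stages))
    if unknown:
        raise ValidationError(
            f"{path}: unknown stage label(s) {unknown}; configured stages are {list(stages)}"
        )
    dup = df.duplicated(subset=[columns.protein, columns.stage, columns.replicate])
    if dup.any():
        first = df.loc[dup.idxmax(), required[:3]].tolist()
        raise ValidationError(f"{path}: duplicate measurement row for {first}")

    reps = df[columns.replicate].astype(int)
    if (reps < 1).any():
        raise ValidationError(f"{path}: replicate indices must be >= 1")
    n_rep = n_replicates or int(reps.max())
    if int(reps.max()) > n_rep:
        raise ValidationError(f"{path}: replicate index exceeds n_replicates={n_rep}")

    proteins = list(dict.fromkeys(df[columns.protein].astype(str)))
    pidx = {normalize_protein_id(p): i for i, p in enumerate(proteins)}
    sidx = {s: i for i, s in enumerate(stages)}
    abund = np.full((len(proteins), len(stages), n_rep), np.nan)
    for p, s, r, v in zip(
        df[columns.protein].astype(str),
        df[columns.stage].astype(str),
        reps,
        df[columns.intensity].astype(float),
    ):
        abund[pidx[normalize_protein_id(p)], sidx[s], r - 1] = v
    return ProteomeDataset(
        dataset_id=dataset_id or Path(path).stem,
        proteins=proteins,
        stages=stages,
        n_replicates=n_rep,
        abundances=abund,
    )


def write_long_table(
    dataset: ProteomeDataset, path: str | Path, columns: LongColumns | None = None
) -> None:
    """Write the non-missing cells of a dataset in long format."""
    columns = columns or LongColumns()
    rows = []
    for i, protein in enumerate(dataset.proteins):
        for j, stage in enumerate(dataset.stages):
            for k in range(dataset.n_replicates):
                v = dataset.abundances[i, j, k]
                if np.isfinite(v):
                    rows.append((protein, stage, k + 1, v))
    pd.DataFrame(
        rows, columns=[columns.protein, columns.stage, columns.replicate, columns.intensity]
    ).to_csv(path, sep=_sep_for(path), index=False)


def read_wide_table(
    path: str | Path,
    stages: Sequence[str] = DEFAULT_STAGES,
    dataset_id: str | None = None,
    protein_column: str = "protein_id",
) -> ProteomeDataset:
    """Read a wide TSV with one ``<stage>_<rep>`` intensity column per sample."""
    stages = tuple(stages)
    df = pd.read_csv(path, sep=_sep_for(path), float_precision="round_trip")
    if protein_column not in df.columns:
        raise FormatError(f"{path}: missing protein column {protein_column!r}")
    pattern = re.compile(r"^(?P<stage>.+)_(?P<rep>\d+)$")
    samples: list[tuple[str, int, str]] = []
    for col in df.columns:
        if col == protein_column:
            continue
        m = pattern.match(col)
        if not m:
            raise FormatError(f"{path}: column {col!r} is not of the form <stage>_<rep>")
        if m["stage"] not in stages:
            raise ValidationError(f"{path}: unknown stage label {m['stage']!r} in column {col!r}")
        samples.append((m["stage"], int(m["rep"]), col))
    if not samples:
        raise FormatError(f"{path}: no sample columns found")
    n_rep = max(r for _, r, _ in samples)
    proteins = df[protein_column].astype(str).tolist()
    sidx = {s: i for i, s in enumerate(stages)}
    abund = np.full((len(proteins), len(stages), n_rep), np.nan)
    for stage, rep, col in samples:
        abund[:, sidx[stage], rep - 1] = df[col].astype(float).to_numpy()
    return ProteomeDataset(
        dataset_id=dataset_id or Path(path).stem,
        proteins=proteins,
        stages=stages,
        n_replicates=n_rep,
        abundances=abund,
    )


def write_wide_table(
    dataset: ProteomeDataset, path: str | Path, protein_column: str = "protein_id"
) -> None:
    data = {protein_column: dataset.proteins}
    for j, stage in enumerate(dataset.stages):
        for k in range(dataset.n_replicates):
            data[f"{stage}_{k + 1}"] = dataset.abundances[:, j, k]
    pd.DataFrame(data).to_csv(path, sep=_sep_for(path), index=False)


def read_maxquant_like(
    path: str | Path,
    stages: Sequence[str] = DEFAULT_STAGES,
    dataset_id: str | None = None,
    intensity_prefix: str = "LFQ intensity ",
    sample_pattern: str = r"^(?P<stage>.+)_(?P<rep>\d+)$",
    gene_column: str = "Gene names",
    reverse_column: str = "Reverse",
    contaminant_column: str = "Potential contaminant",
) -> ProteomeDataset:
    """Read a proteinGroups-like TSV (one row per protein group).

    Rows flagged ``+`` in the reverse or contaminant columns are dropped,
    zero intensity becomes missing, and the first gene symbol in the
    (possibly ``;``-separated) gene-name field is the protein id.  Sample
    names after ``intensity_prefix`` are parsed with ``sample_pattern``,
    whose named groups ``stage`` and ``rep`` identify the sample.
    """
    stages = tuple(stages)
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if gene_column not in df.columns:
        raise FormatError(f"{path}: missing gene-symbol column {gene_column!r}")
    pattern = re.compile(sample_pattern)
    samples: list[tuple[str, int, str]] = []
    for col in df.columns:
        if not col.startswith(intensity_prefix):
            continue
        m = pattern.match(col[len(intensity_prefix):])
        if not m:
            raise FormatError(
                f"{path}: sample name {col[len(intensity_prefix):]!r} does not match "
                f"pattern {sample_pattern!r}"
            )
        if m["stage"] not in stages:
            raise ValidationError(f"{path}: unknown stage label {m['stage']!r} in {col!r}")
        samples.append((m["stage"], int(m["rep"]), col))
    if not samples:
        raise FormatError(f"{path}: no intensity column matches prefix {intensity_prefix!r}")

    for flag_col in (reverse_column, contaminant_column):
        if flag_col in df.columns:
            df = df[df[flag_col].fillna("") != "+"]
    df = df[df[gene_column].notna()]

    proteins = [str(g).split(";")[0].strip() for g in df[gene_column]]
    n_rep = max(r for _, r, _ in samples)
    sidx = {s: i for i, s in enumerate(stages)}
    abund = np.full((len(proteins), len(stages), n_rep), np.nan)
    for stage, rep, col in samples:
        abund[:, sidx[stage], rep - 1] = df[col].astype(float).to_numpy()
    return ProteomeDataset(
        dataset_id=dataset_id or Path(path).stem,
        proteins=proteins,
        stages=stages,
        n_replicates=n_rep,
        abundances=abund,
    )


def write_maxquant_like(
    dataset: ProteomeDataset,
    path: str | Path,
    intensity_prefix: str = "LFQ intensity ",
    gene_column: str = "Gene names",
) -> None:
    """Write a minimal proteinGroups-like TSV (zeros for missing cells)."""
    data: dict[str, list] = {gene_column: dataset.proteins}
    for j, stage in enumerate(dataset.stages):
        for k in range(dataset.n_replicates):
            col = f"{intensity_prefix}{stage}_{k + 1}"
            vals = dataset.abundances[:, j, k].copy()
            vals[~np.isfinite(vals)] = 0.0
            data[col] = vals.tolist()
    data["Reverse"] = [""] * dataset.n_proteins
    data["Potential contaminant"] = [""] * dataset.n_proteins
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)


__all__ = [
    "LongColumns",
    "read_long_table",
    "write_long_table",
    "read_wide_table",
    "write_wide_table",
    "read_maxquant_like",
    "write_maxquant_like",
    "normalize_protein_id",
]
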
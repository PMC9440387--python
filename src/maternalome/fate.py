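"""Exclusive-region set calculus and maternal-protein fate classification.

Given the detection (or candidate) sets of the MII oocyte, parthenogenetic
(PA) and fertilized (ZY) groups, every protein in the union belongs to
exactly one of seven exclusive Venn regions.  The region MII∩PA\\ZY — present
in the oocyte, persisting in uniparental embryos, gone from fertilized ones —
is the "degradation escape" class: maternal proteins that appear to avoid
the post-fertilization degradation wave when no sperm is involved.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping

import pandas as pd

from .datasets import normalize_protein_id
from .errors import ValidationError

FATE_REGIONS: tuple[str, ...] = (
    "MII_only",
    "PA_only",
    "ZY_only",
    "MII_PA_only",
    "MII_ZY_only",
    "PA_ZY_only",
    "MII_PA_ZY",
)

#: Human-readable aliases for the biologically named regions.
REGION_ALIASES: dict[str, str] = {
    "MII_PA_only": "degradation_escape",
    "MII_PA_ZY": "core_maternal",
    "MII_ZY_only": "persistent_after_fertilization",
}


def _canon(ids: Iterable[str]) -> set[str]:
    return {normalize_protein_id(i) for i in ids}


def exclusive_regions(
    named_sets: Mapping[str, Iterable[str]],
) -> dict[tuple[str, ...], set[str]]:
    """Partition the union of k named sets into its 2^k − 1 exclusive regions.

    Returns a mapping from the tuple of set names a region belongs to
    (in input order) to its members.  Regions are exclusive and exhaustive:
    their sizes sum to the size of the union.  Empty regions are included
    with empty member sets, which is what UpSet-style outputs enumerate.
    """
    names = list(named_sets)
    if len(names) != len(set(names)):
        raise ValidationError("duplicate set names")
    if not names:
        raise ValidationError("need at least one named set")
    sets = {name: _canon(named_sets[name]) for name in names}
    regions: dict[tuple[str, ...], set[str]] = {}
    for k in range(1, len(names) + 1):
        for combo in combinations(names, k):
            inside = set.intersection(*(sets[n] for n in combo))
            outside = set.union(set(), *(sets[n] for n in names if n not in combo))
            regions[combo] = inside - outside
    union = set.union(*sets.values()) if sets else set()
    assert sum(len(v) for v in regions.values()) == len(union)
    return regions


def upset_matrix(named_sets: Mapping[str, Iterable[str]]) -> pd.DataFrame:
    """Boolean membership matrix (one row per union member) for UpSet plotters."""
    names = list(named_sets)
    sets = {name: _canon(named_sets[name]) for name in names}
    union = sorted(set.union(set(), *sets.values()))
    return pd.DataFrame(
        {"protein_id": union, **{n: [p in sets[n] for p in union] for n in names}}
    )


@dataclass(frozen=True)
class FateAssignment:
    """One protein's exclusive MII/PA/ZY region with its biological alias."""

    protein_id: str
    region: str
    alias: str

    def __post_init__(self) -> None:
        if self.region not in FATE_REGIONS:
            raise ValidationError(f"unknown fate region {self.region!r}")


def fate_classify(
    mii: Iterable[str], pa: Iterable[str], zy: Iterable[str]
) -> list[FateAssignment]:
    """Assign every protein in MII ∪ PA ∪ ZY to one of the 7 fate regions."""
    regions = exclusive_regions({"MII": mii, "PA": pa, "ZY": zy})
    combo_to_region = {
        ("MII",): "MII_only",
        ("PA",): "PA_only",
        ("ZY",): "ZY_only",
        ("MII", "PA"): "MII_PA_only",
        ("MII", "ZY"): "MII_ZY_only",
        ("PA", "ZY"): "PA_ZY_only",
        ("MII", "PA", "ZY"): "MII_PA_ZY",
    }
    assignments = [
        FateAssignment(
            protein_id=protein,
            region=(region := combo_to_region[combo]),
            alias=REGION_ALIASES.get(region, region),
        )
        for combo, members in regions.items()
        for protein in sorted(members)
    ]
    seen = [a.protein_id for a in assignments]
    assert len(seen) == len(set(seen))
    return assignments


def fate_counts(assignments: list[FateAssignment]) -> pd.DataFrame:
    """Region → count summary (all 7 regions, zeros included)."""
    counts = {region: 0 for region in FATE_REGIONS}
    for a in assignments:
        counts[a.region] += 1
    return pd.DataFrame(
        {
            "region": list(counts),
            "alias": [REGION_ALIASES.get(r, r) for r in counts],
            "count": list(counts.values()),
        }
    )


def fate_table(assignments: list[FateAssignment]) -> pd.DataFrame:
    return pd.DataFrame(
        [(a.protein_id, a.region, a.alias) for a in assignments],
        columns=["protein_id", "region", "alias"],
    )


def dataset_intersection(named_sets: Mapping[str, Iterable[str]]) -> set[str]:
    """Plain intersection of >= 2 detection sets after id canonicalization."""
    if len(named_sets) < 2:
        raise ValidationError("need at least two sets to intersect")
    return set.intersection(*(_canon(s) for s in named_sets.values()))


def consensus_candidates(
    verdicts: Mapping[str, Mapping[str, str]], rule: str = "strict"
) -> tuple[dict[str, str], dict[str, str]]:
    """Cross-dataset consensus of signed screen verdicts.

    ``verdicts`` maps dataset id → {protein → "+" or "-"} (only strong
    proteins listed).  Under ``strict`` a protein is a consensus candidate
    iff it is strong in *every* dataset with the same sign; ``majority``
    requires a strict majority of datasets to agree on one sign.  Proteins
    strong with conflicting signs are excluded with reason ``sign_conflict``.

    Returns (consensus {protein → sign}, excluded {protein → reason}).
    """
    if rule not in ("strict", "majority"):
        raise ValidationError(f"unknown consensus rule {rule!r}")
    if len(verdicts) < 2:
        raise ValidationError("need verdicts from at least two datasets")
    for dataset_id, table in verdicts.items():
        bad = {s for s in table.values() if s not in ("+", "-")}
        if bad:
            raise ValidationError(f"dataset {dataset_id!r} has non-sign verdicts {bad}")
    canon: dict[str, dict[str, str]] = {
        ds: {normalize_protein_id(p): s for p, s in table.items()}
        for ds, table in verdicts.items()
    }
    union = set().union(*(set(t) for t in canon.values()))
    n_datasets = len(canon)
    consensus: dict[str, str] = {}
    excluded: dict[str, str] = {}
    for protein in sorted(union):
        signs = [t[protein] for t in canon.values() if protein in t]
        if len(set(signs)) > 1:
            excluded[protein] = "sign_conflict"
            continue
        sign = signs[0]
        if rule == "strict":
            if len(signs) == n_datasets:
                consensus[protein] = sign
            else:
                excluded[protein] = "absent_in_some_dataset"
        else:
            if len(signs) > n_datasets / 2:
                consensus[protein] = sign
            else:
                excluded[protein] = "no_majority"
    return consensus, excluded


__all__ = [
    "FATE_REGIONS",
    "REGION_ALIASES",
    "FateAssignment",
    "exclusive_regions",
    "upset_matrix",
    "fate_classify",
    "fate_counts",
    "fate_table",
    "dataset_intersection",
    "consensus_candidates",
]
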
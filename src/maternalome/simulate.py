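"""Synthetic proteome datasets with planted, recoverable structure.

The generator emulates the design of a label-free quantitative MS time course
over the six mouse preimplantation stages with three biological replicates:
log2-scale archetype mean trajectories (maternal decay, blastocyst rise,
mid-peak), additive Gaussian noise on log2 intensity (i.e. log-normal
multiplicative noise on the raw scale), and missing-completely-at-random
dropout.  Planted structure — anchor-correlated modules at exact target
correlations, and three-way detection-set fate regions — is emitted as a
separate :class:`SimulationTruth` so recovery experiments can score against
it.

All randomness flows from one explicit seed through `numpy`'s seed-sequence
spawning, so sub-simulations are independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datasets import DEFAULT_STAGES, ProteomeDataset, normalize_protein_id
from .errors import ValidationError

#: The seven exclusive regions of a three-set (MII/PA/ZY) Venn diagram.
TRI_STUDY_REGIONS: tuple[str, ...] = (
    "MII_only",
    "PA_only",
    "ZY_only",
    "MII_PA_only",
    "MII_ZY_only",
    "PA_ZY_only",
    "MII_PA_ZY",
)


@dataclass(frozen=True)
class ArchetypeSpec:
    """A named log2-scale mean trajectory over the stage axis."""

    name: str
    stage_means: tuple[float, ...]

    def means(self) -> np.ndarray:
        return np.asarray(self.stage_means, dtype=float)


def default_archetypes(stages: Sequence[str] = DEFAULT_STAGES) -> dict[str, ArchetypeSpec]:
    """Built-in expression archetypes on a log2 LFQ-intensity scale.

    ``maternal_decay`` falls monotonically (~4 log2 units PN→BL, the classic
    maternal-protein clearance profile), ``blastocyst_rise`` is flat through
    the 8-cell stage and jumps at morula/blastocyst (zygotic program), and
    ``mid_peak`` peaks at an interior cleavage stage.  Only six-stage defaults
    are provided; pass explicit specs for other stage vocabularies.
    """
    if len(stages) != 6:
        raise ValidationError("default archetypes are defined for a 6-stage axis")
    return {
        "maternal_decay": ArchetypeSpec("maternal_decay", (26.0, 25.3, 24.5, 23.6, 22.8, 22.0)),
        "blastocyst_rise": ArchetypeSpec("blastocyst_rise", (23.0, 23.0, 23.1, 23.3, 24.8, 26.5)),
        "mid_peak": ArchetypeSpec("mid_peak", (23.0, 24.4, 25.5, 24.6, 23.4, 22.6)),
    }


@dataclass
class SimulationTruth:
    """Ground truth emitted alongside simulated data, never embedded in it.

    ``table`` has one row per simulated protein: ``protein_id``,
    ``archetype`` (or the special labels ``anchor`` / ``planted`` / ``null``),
    ``planted_r`` (NaN when none), and ``fate_region`` (empty when the
    protein was not part of a tri-study draw).
    """

    table: pd.DataFrame
    seed: int

    def __post_init__(self) -> None:
        required = {"protein_id", "archetype", "planted_r", "fate_region"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValidationError(f"truth table missing columns {sorted(missing)}")
        ids = self.table["protein_id"].tolist()
        if len(set(ids)) != len(ids):
            raise ValidationError("truth table has duplicate protein ids")

    def archetype_of(self) -> dict[str, str]:
        return dict(zip(self.table["protein_id"], self.table["archetype"]))

    def fate_of(self) -> dict[str, str]:
        return {
            p: r
            for p, r in zip(self.table["protein_id"], self.table["fate_region"])
            if isinstance(r, str) and r
        }

    def write(self, path: str | Path) -> None:
        out = self.table.copy()
        out["seed"] = self.seed
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path: str | Path) -> "SimulationTruth":
        df = pd.read_csv(path, sep="\t")
        seed = int(df["seed"].iloc[0]) if "seed" in df.columns and len(df) else 0
        return cls(df.drop(columns=["seed"], errors="ignore"), seed=seed)


def _truth_frame(rows: list[tuple[str, str, float, str]]) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=["protein_id", "archetype", "planted_r", "fate_region"])


def simulate_dataset(
    n_proteins: int,
    weights: Mapping[str, float] | None = None,
    noise_sd: float = 0.5,
    dropout: float = 0.1,
    n_replicates: int = 3,
    seed: int = 0,
    stages: Sequence[str] = DEFAULT_STAGES,
    archetypes: Mapping[str, ArchetypeSpec] | None = None,
    dataset_id: str = "SIM",
    dropout_mode: str = "mcar",
) -> tuple[ProteomeDataset, SimulationTruth]:
    """Simulate an LFQ-style dataset from archetype mean trajectories.

    Each protein draws an archetype by ``weights`` (default: uniform over the
    built-in archetypes); its abundance at (stage s, replicate k) is
    ``2**(archetype_mean(s) + eps)`` with ``eps ~ Normal(0, noise_sd)``
    independently per cell.  Cells are then censored: with ``dropout_mode
    "mcar"`` each cell is missing independently with probability ``dropout``;
    with ``"intensity"`` the per-cell missingness probability follows a
    logistic curve in the log2 mean (low-abundance cells drop out more) with
    the same marginal rate at the mean abundance.

    Returns the dataset and a :class:`SimulationTruth` with the archetype
    labels. Deterministic given (parameters, seed).
    """
    if not 0 <= dropout < 1:
        raise ValidationError("dropout rate must be in [0, 1)")
    if noise_sd < 0:
        raise ValidationError("noise sd must be non-negative")
    if n_proteins < 1:
        raise ValidationError("n_proteins must be >= 1")
    if dropout_mode not in ("mcar", "intensity"):
        raise ValidationError(f"unknown dropout mode {dropout_mode!r}")
    stages = tuple(stages)
    archetypes = dict(archetypes or default_archetypes(stages))
    for spec in archetypes.values():
        if len(spec.stage_means) != len(stages):
            raise ValidationError(
                f"archetype {spec.name!r} has {len(spec.stage_means)} means for "
                f"{len(stages)} stages"
            )
    if weights is None:
        weights = {name: 1.0 / len(archetypes) for name in archetypes}
    unknown = set(weights) - set(archetypes)
    if unknown:
        raise ValidationError(f"weights name unknown archetypes {sorted(unknown)}")
    w = np.array([weights.get(name, 0.0) for name in archetypes], dtype=float)
    if w.min() < 0 or not np.isclose(w.sum(), 1.0):
        raise ValidationError("archetype weights must be non-negative and sum to 1")

    rng = np.random.default_rng(seed)
    names = list(archetypes)
    labels = rng.choice(len(names), size=n_proteins, p=w)
    means = np.stack([archetypes[names[i]].means() for i in labels])  # (N, S)

    log2 = means[:, :, None] + rng.normal(0.0, noise_sd, (n_proteins, len(stages), n_replicates))
    abund = np.exp2(log2)
    if dropout > 0:
        if dropout_mode == "mcar":
            miss = rng.random(abund.shape) < dropout
        else:
            # Logistic in the log2 cell mean, centered so the marginal rate
            # at the grand mean equals the requested dropout.
            center = float(np.mean(means))
            logit0 = np.log(dropout / (1 - dropout))
            prob = 1.0 / (1.0 + np.exp(-(logit0 - 1.0 * (log2 - center))))
            miss = rng.random(abund.shape) < prob
        abund[miss] = np.nan

    proteins = [f"prot{i:05d}" for i in range(n_proteins)]
    dataset = ProteomeDataset(
        dataset_id=dataset_id,
        proteins=proteins,
        stages=stages,
        n_replicates=n_replicates,
        abundances=abund,
    )
    truth = SimulationTruth(
        _truth_frame([(p, names[i], np.nan, "") for p, i in zip(proteins, labels)]),
        seed=seed,
    )
    return dataset, truth


def _zscore(v: np.ndarray) -> np.ndarray:
    sd = v.std(ddof=1)
    if sd == 0:
        raise ValidationError("cannot standardize a constant profile")
    return (v - v.mean()) / sd


def correlated_profile(
    anchor_means: np.ndarray, target_r: float, rng: np.random.Generator
) -> np.ndarray:
    """A unit-variance profile whose sample correlation with ``anchor_means``
    equals ``target_r`` exactly.

    Built by Gram–Schmidt: an independent random profile is orthogonalized
    against the standardized anchor, restandardized, and mixed as
    ``r·z(anchor) + sqrt(1−r²)·z(g)``.
    """
    if abs(target_r) > 1:
        raise ValidationError("|target_r| must be <= 1")
    za = _zscore(np.asarray(anchor_means, dtype=float))
    if abs(target_r) == 1.0:
        return np.sign(target_r) * za
    for _ in range(100):
        g = rng.normal(size=za.size)
        resid = g - g.mean() - (g @ za) / (za @ za) * za
        if resid.std(ddof=1) > 1e-12:
            break
    else:  # pragma: no cover - astronomically unlikely
        raise ValidationError("could not draw a profile independent of the anchor")
    zg = _zscore(resid)
    return target_r * za + np.sqrt(1 - target_r**2) * zg


def plant_anchor_module(
    dataset: ProteomeDataset,
    truth: SimulationTruth,
    anchor_archetype: ArchetypeSpec,
    target_r: Mapping[str, float],
    seed: int = 0,
    noise_sd: float = 0.5,
    base_level: float = 24.0,
    scale: float = 1.5,
) -> tuple[ProteomeDataset, SimulationTruth]:
    """Rewrite selected proteins so their noiseless stage means correlate
    with the anchor archetype at exact target values.

    For each (protein, r) in ``target_r`` the protein's mean trajectory is
    replaced by ``base_level + scale * q`` where ``q`` is the unit-variance
    profile from :func:`correlated_profile`; replicate noise is then redrawn
    at ``noise_sd``.  The realized correlation of the noiseless means with
    the anchor means equals r to within 1e-9 by construction.

    Returns a new (dataset, truth) pair; inputs are not mutated.
    """
    for r in target_r.values():
        if abs(r) > 1:
            raise ValidationError("|target_r| must be <= 1")
    dataset = dataset.copy()
    table = truth.table.copy()
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    anchor_means = anchor_archetype.means()
    if anchor_means.size != dataset.n_stages:
        raise ValidationError("anchor archetype length does not match dataset stages")
    for protein, r in target_r.items():
        i = dataset.protein_index(protein)
        q = correlated_profile(anchor_means, r, rng)
        means = base_level + scale * q
        dataset.abundances[i] = np.exp2(
            means[:, None] + rng.normal(0.0, noise_sd, (dataset.n_stages, dataset.n_replicates))
        )
        key = normalize_protein_id(protein)
        mask = table["protein_id"].map(normalize_protein_id) == key
        table.loc[mask, "planted_r"] = r
        table.loc[mask, "archetype"] = "planted"
    return dataset, SimulationTruth(table, seed=truth.seed)


def simulate_tri_study(
    universe_size: int,
    region_proportions: Mapping[str, float],
    seed: int = 0,
) -> tuple[dict[str, set[str]], SimulationTruth]:
    """Draw a universe of proteins into the seven MII/PA/ZY Venn regions.

    Each protein is assigned to exactly one region (or to no set, with the
    remaining probability mass) by a seeded multinomial draw; the three
    detection sets implied by the assignments are returned together with the
    per-protein truth.  ``fate_classify`` on the emitted sets recovers the
    truth labels exactly.
    """
    unknown = set(region_proportions) - set(TRI_STUDY_REGIONS)
    if unknown:
        raise ValidationError(f"unknown region name(s) {sorted(unknown)}")
    p = np.array([region_proportions.get(r, 0.0) for r in TRI_STUDY_REGIONS], dtype=float)
    if p.min() < 0:
        raise ValidationError("region proportions must be non-negative")
    if p.sum() > 1 + 1e-12:
        raise ValidationError("region proportions must sum to <= 1")
    probs = np.append(p, max(0.0, 1.0 - p.sum()))
    probs = probs / probs.sum()

    rng = np.random.default_rng(seed)
    draws = rng.choice(len(probs), size=universe_size, p=probs)
    proteins = [f"prot{i:05d}" for i in range(universe_size)]
    sets: dict[str, set[str]] = {"MII": set(), "PA": set(), "ZY": set()}
    rows = []
    for protein, d in zip(proteins, draws):
        region = TRI_STUDY_REGIONS[d] if d < len(TRI_STUDY_REGIONS) else ""
        rows.append((protein, "", np.nan, region))
        if region:
            for group in ("MII", "PA", "ZY"):
                if group in region.replace("_only", "").split("_"):
                    sets[group].add(protein)
    return sets, SimulationTruth(_truth_frame(rows), seed=seed)


@dataclass
class ScreenInstance:
    """A ready-made anchor-screen recovery experiment."""

    dataset: ProteomeDataset
    truth: SimulationTruth
    anchor_ids: list[str] = field(default_factory=list)
    planted_positive: set[str] = field(default_factory=set)
    planted_negative: set[str] = field(default_factory=set)


def simulate_screen_instance(
    n_planted: int = 50,
    n_null: int = 450,
    n_anchors: int = 5,
    target_abs_r: float = 0.9,
    noise_sd: float = 0.3,
    n_replicates: int = 3,
    seed: int = 0,
    stages: Sequence[str] = DEFAULT_STAGES,
    base_level: float = 24.0,
    scale: float = 1.5,
) -> ScreenInstance:
    """Build an anchor-screen test case with planted correlation structure.

    ``n_anchors`` anchor proteins share one SCMC-like maternal-decay module
    mean trajectory (the complex co-expresses tightly).  ``n_planted``
    proteins are planted at noiseless correlation ``±target_abs_r`` with the
    module mean (half each sign); ``n_null`` proteins get iid standard-normal
    stage profiles, independent of the anchors.  All proteins receive
    replicate noise at ``noise_sd`` log2 units.
    """
    stages = tuple(stages)
    rng = np.random.default_rng(seed)
    module = default_archetypes(stages)["maternal_decay"]
    n_stages = len(stages)

    anchor_ids = [f"anchor{i}" for i in range(n_anchors)]
    n_pos = n_planted - n_planted // 2
    planted_ids = [f"planted{i:03d}" for i in range(n_planted)]
    null_ids = [f"null{i:04d}" for i in range(n_null)]

    proteins = anchor_ids + planted_ids + null_ids
    abund = np.empty((len(proteins), n_stages, n_replicates))

    def noisy(means: np.ndarray) -> np.ndarray:
        return np.exp2(means[:, None] + rng.normal(0.0, noise_sd, (n_stages, n_replicates)))

    rows: list[tuple[str, str, float, str]] = []
    row = 0
    for a in anchor_ids:
        abund[row] = noisy(module.means())
        rows.append((a, "anchor", np.nan, ""))
        row += 1
    for i, p in enumerate(planted_ids):
        r = target_abs_r if i < n_pos else -target_abs_r
        q = correlated_profile(module.means(), r, rng)
        abund[row] = noisy(base_level + scale * q)
        rows.append((p, "planted", r, ""))
        row += 1
    for p in null_ids:
        means = base_level + scale * rng.normal(size=n_stages)
        abund[row] = noisy(means)
        rows.append((p, "null", np.nan, ""))
        row += 1

    dataset = ProteomeDataset(
        dataset_id="SIM_SCREEN",
        proteins=proteins,
        stages=stages,
        n_replicates=n_replicates,
        abundances=abund,
    )
    truth = SimulationTruth(_truth_frame(rows), seed=seed)
    return ScreenInstance(
        dataset=dataset,
        truth=truth,
        anchor_ids=anchor_ids,
        planted_positive={p for i, p in enumerate(planted_ids) if i < n_pos},
        planted_negative={p for i, p in enumerate(planted_ids) if i >= n_pos},
    )


__all__ = [
    "ArchetypeSpec",
    "SimulationTruth",
    "ScreenInstance",
    "TRI_STUDY_REGIONS",
    "default_archetypes",
    "simulate_dataset",
    "correlated_profile",
    "plant_anchor_module",
    "simulate_tri_study",
    "simulate_screen_instance",
]
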
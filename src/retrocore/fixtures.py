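"""Seeded synthetic analog libraries with planted cores.

Each series is assembled from a scaffold bearing one attachment point
(``[*:1]``) and a set of substituents joined through rule-cleavable
chemistry (amide, ester, ether or amine junctions), so that one
retrosynthetic step detaches the substituent and recovers the planted
core exactly.  Substituent sizes are bounded by the relevance threshold,
guaranteeing by construction that the planted core passes the size
criterion for every member.  Decoy molecules share no core with any
series and therefore land in singleton series.

Activity fixtures draw per-molecule pIC50 values around a per-series
center, emitted as IC50 in nM with an "=" qualifier, supporting
parameter-recovery tests of the CSAR profiling.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from rdkit import Chem

from .chemio import RawRecord, heavy_atom_count
from .csar import ActivityRecord
from .fragmentation import EnumerationConfig, enumerate_cores

__all__ = [
    "SeriesSpec",
    "SeriesGroundTruth",
    "LibraryGroundTruth",
    "FixtureError",
    "InfeasibleSpecError",
    "generate_series",
    "generate_library",
    "generate_activity",
    "random_series_specs",
    "standard_library",
    "hard_mode_component",
    "write_molecule_table",
    "write_activity_table",
    "ACYL_R_GROUPS",
    "ALKYL_R_GROUPS",
    "SCAFFOLD_POOL",
    "DECOY_POOL",
]


class FixtureError(RuntimeError):
    """Library construction failed (e.g. a decoy collides with a series)."""


class InfeasibleSpecError(ValueError):
    """The series specification cannot satisfy the fixture invariants."""


@dataclass(frozen=True)
class SeriesSpec:
    """Recipe for one planted analog series."""

    name: str
    scaffold_smiles: str  # must contain exactly one [*:1] attachment point
    r_groups: tuple[str, ...]  # each with one [*:1]
    n_members: int
    activity_center: float = 6.5
    activity_spread: float = 0.3


@dataclass(frozen=True)
class SeriesGroundTruth:
    name: str
    planted_core: str  # canonical SMILES of the H-capped scaffold
    member_ids: tuple[str, ...]
    member_smiles: tuple[str, ...]
    activity_center: float
    activity_spread: float


@dataclass
class LibraryGroundTruth:
    series: list[SeriesGroundTruth] = field(default_factory=list)
    decoy_ids: tuple[str, ...] = ()
    decoy_smiles: tuple[str, ...] = ()

    def partition_sizes(self) -> list[int]:
        """Expected analog-series sizes, descending (decoys are singletons)."""
        sizes = [len(s.member_ids) for s in self.series]
        sizes += [1] * len(self.decoy_ids)
        return sorted(sizes, reverse=True)

    def expected_partition(self) -> set[frozenset[str]]:
        """Ground-truth partition of canonical member structures."""
        parts = {frozenset(s.member_smiles) for s in self.series}
        parts |= {frozenset([d]) for d in self.decoy_smiles}
        return parts

    def to_json(self) -> str:
        payload = {
            "series": [
                {
                    "name": s.name,
                    "planted_core": s.planted_core,
                    "member_ids": list(s.member_ids),
                    "member_smiles": list(s.member_smiles),
                    "activity_center": s.activity_center,
                    "activity_spread": s.activity_spread,
                }
                for s in self.series
            ],
            "decoy_ids": list(self.decoy_ids),
            "decoy_smiles": list(self.decoy_smiles),
        }
        return json.dumps(payload, indent=2)


# Built-in chemistry pools.  Scaffolds carry one [*:1]; "acyl" scaffolds
# expose an N or O forming amide/ester junctions, "alkyl" scaffolds an O
# or amine N forming ether/amine junctions.
SCAFFOLD_POOL: tuple[tuple[str, str], ...] = (
    ("[*:1]Nc1ccc2ccccc2c1", "acyl"),
    ("[*:1]Nc1ccc(F)c(F)c1", "acyl"),
    ("[*:1]Nc1nc2ccccc2s1", "acyl"),
    ("[*:1]Nc1ccc(-c2ccccc2)cc1", "acyl"),
    ("[*:1]Nc1ccc(C#N)cc1", "acyl"),
    ("[*:1]Oc1ccc2cc(C)ccc2c1", "acyl"),
    ("[*:1]Oc1ccc(-n2ccnc2)cc1", "alkyl"),
    ("[*:1]Oc1ccc(Cl)cc1Cl", "alkyl"),
    ("[*:1]N(C)Cc1ccc(Cl)cc1", "alkyl"),
    ("[*:1]Nc1ccc(S(C)(=O)=O)cc1", "acyl"),
    ("[*:1]Nc1ccc2ncccc2c1", "acyl"),
    ("[*:1]N1CCN(c2ccccc2)CC1", "acyl"),
    ("[*:1]Nc1ccc2c(c1)OCO2", "acyl"),
    ("[*:1]Nc1ccc2cc(F)ccc2c1", "acyl"),
    ("[*:1]N1CCC(c2ccccc2)CC1", "acyl"),
    ("[*:1]Oc1ccc2ccccc2c1", "alkyl"),
)

ACYL_R_GROUPS: tuple[str, ...] = (
    "[*:1]C=O",
    "[*:1]C(C)=O",
    "[*:1]C(=O)CC",
    "[*:1]C(=O)CO",
    "[*:1]C(=O)CCl",
    "[*:1]C(=O)C(C)C",
    "[*:1]C(=O)CCC",
    "[*:1]C(=O)C1CC1",  # cyclic substituent: rings can be substituents
    "[*:1]C(=O)CCO",
    "[*:1]C(=O)C(C)CC",
    "[*:1]C(=O)CC1CC1",
    "[*:1]C(=O)CCCC",
    "[*:1]C(=O)OC",
    "[*:1]C(=O)OCC",
    "[*:1]C(=O)N(C)C",  # urea junction when joined to an amine scaffold
    "[*:1]C(=O)COC",
)

ALKYL_R_GROUPS: tuple[str, ...] = (
    "[*:1]C",
    "[*:1]CC",
    "[*:1]CCC",
    "[*:1]C(C)C",
    "[*:1]CCO",
    "[*:1]CCCC",
    "[*:1]CC(C)C",
    "[*:1]CCCO",
    "[*:1]CC1CC1",  # cyclic substituent
    "[*:1]CCCCC",
    "[*:1]CC(C)CC",
    "[*:1]CCOC",
    "[*:1]CCN(C)C",
    "[*:1]CF",
)

# Rule-inert ring systems: no acyclic bond matches any default rule, so
# each decoy's only core is itself.
DECOY_POOL: tuple[str, ...] = (
    "C1CCCCC1",
    "C1CCCCCC1",
    "C1CCNCC1",
    "c1ccncc1",
    "c1ccoc1",
    "c1ccsc1",
    "c1ccc2ccccc2c1",
    "C1CCOC1",
    "C1CCSC1",
    "Fc1ccccc1",
    "Clc1ccccc1",
    "Brc1ccccc1",
    "C1=CCCCC1",
    "c1ccc2[nH]ccc2c1",
    "c1ccc2occc2c1",
    "C1CC2CCC1CC2",
    "c1cncnc1",
    "C1CCC2CCCCC2C1",
    "c1cscn1",
    "C1CNCCN1",
    "OC1CCCCC1",
    "CC1CCCCC1",
    "c1ccc2ncccc2c1",
    "c1cnc2[nH]ccc2c1",
)


def _parse_with_attachment(smiles: str, what: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InfeasibleSpecError(f"unparseable {what} SMILES: {smiles!r}")
    dummies = [a for a in mol.GetAtoms() if a.GetAtomicNum() == 0]
    if len(dummies) != 1 or dummies[0].GetAtomMapNum() != 1:
        raise InfeasibleSpecError(
            f"{what} must carry exactly one [*:1] attachment point: {smiles!r}"
        )
    return mol


def _strip_attachment(mol: Chem.Mol) -> str:
    """Canonical SMILES of the structure with the attachment H-capped."""
    rw = Chem.RWMol(mol)
    idx = next(a.GetIdx() for a in rw.GetAtoms() if a.GetAtomicNum() == 0)
    rw.RemoveAtom(idx)
    out = rw.GetMol()
    Chem.SanitizeMol(out)
    return Chem.MolToSmiles(out)


def _join(scaffold: Chem.Mol, r_group: Chem.Mol) -> str:
    joined = Chem.molzip(Chem.CombineMols(scaffold, r_group))
    Chem.SanitizeMol(joined)
    return Chem.MolToSmiles(joined)


def generate_series(
    spec: SeriesSpec, config: EnumerationConfig | None = None
) -> tuple[list[RawRecord], SeriesGroundTruth]:
    """Build one series and its ground truth.

    Validates the fixture invariants: enough distinct substituents,
    substituent size within the relevance threshold, and — decisively —
    that the planted core is among each member's enumerated cores (which
    exercises junction cleavability end to end).
    """
    config = config or EnumerationConfig()
    scaffold = _parse_with_attachment(spec.scaffold_smiles, "scaffold")
    if spec.n_members < 1:
        raise InfeasibleSpecError("n_members must be >= 1")
    if spec.n_members > len(spec.r_groups):
        raise InfeasibleSpecError(
            f"series {spec.name!r}: {spec.n_members} members requested but "
            f"only {len(spec.r_groups)} substituents given"
        )
    planted = _strip_attachment(scaffold)
    scaffold_heavy = heavy_atom_count(scaffold)
    max_sub = (1.0 / config.ratio_threshold - 1.0) * scaffold_heavy + 1e-9
    records: list[RawRecord] = []
    member_smiles: list[str] = []
    for k, r_smiles in enumerate(spec.r_groups[: spec.n_members], start=1):
        r_group = _parse_with_attachment(r_smiles, "substituent")
        r_heavy = heavy_atom_count(r_group)
        if r_heavy > max_sub:
            raise InfeasibleSpecError(
                f"series {spec.name!r}: substituent {r_smiles!r} has "
                f"{r_heavy} heavy atoms, above the threshold-implied "
                f"maximum {max_sub:.2f}"
            )
        member = _join(scaffold, r_group)
        if member in member_smiles:
            raise InfeasibleSpecError(
                f"series {spec.name!r}: duplicate member from {r_smiles!r}"
            )
        if planted not in enumerate_cores(member, config):
            raise InfeasibleSpecError(
                f"series {spec.name!r}: junction of {r_smiles!r} is not "
                "rule-cleavable (planted core unreachable)"
            )
        member_smiles.append(member)
        records.append(
            RawRecord(source_id=f"{spec.name}-{k:02d}", smiles=member)
        )
    return records, SeriesGroundTruth(
        name=spec.name,
        planted_core=planted,
        member_ids=tuple(r.source_id for r in records),
        member_smiles=tuple(member_smiles),
        activity_center=spec.activity_center,
        activity_spread=spec.activity_spread,
    )


def _core_set(smiles: str, config: EnumerationConfig) -> set[str]:
    return set(enumerate_cores(smiles, config))


def generate_library(
    series_specs: Sequence[SeriesSpec],
    decoys: int = 0,
    seed: int = 0,
    config: EnumerationConfig | None = None,
    verify: bool = True,
) -> tuple[list[RawRecord], LibraryGroundTruth]:
    """Union of the generated series plus rule-inert decoys, shuffled
    deterministically by ``seed``.

    With ``verify`` (default), checks post hoc that no two series share a
    core and that every decoy's core set is disjoint from everything else
    (decoys that collide are replaced from the pool; running out raises
    :class:`FixtureError`).
    """
    config = config or EnumerationConfig()
    rng = np.random.default_rng(seed)
    records: list[RawRecord] = []
    truth = LibraryGroundTruth()
    series_cores: list[set[str]] = []
    for spec in series_specs:
        recs, gt = generate_series(spec, config)
        records.extend(recs)
        truth.series.append(gt)
        series_cores.append(
            set().union(*(_core_set(s, config) for s in gt.member_smiles))
        )
    if verify:
        for i in range(len(series_cores)):
            for j in range(i + 1, len(series_cores)):
                common = series_cores[i] & series_cores[j]
                if common:
                    raise FixtureError(
                        f"series {truth.series[i].name!r} and "
                        f"{truth.series[j].name!r} share cores: {sorted(common)}"
                    )
    used_cores: set[str] = set().union(*series_cores) if series_cores else set()
    if decoys > len(DECOY_POOL):
        raise FixtureError(
            f"{decoys} decoys requested but pool holds {len(DECOY_POOL)}"
        )
    pool = list(DECOY_POOL)
    rng.shuffle(pool)
    decoy_ids, decoy_smiles = [], []
    for cand in pool:
        if len(decoy_ids) == decoys:
            break
        canon = Chem.MolToSmiles(Chem.MolFromSmiles(cand))
        cores = _core_set(canon, config)
        if verify and cores & used_cores:
            continue  # collides; try the next pool entry
        used_cores |= cores
        decoy_ids.append(f"D-{len(decoy_ids) + 1:02d}")
        decoy_smiles.append(canon)
        records.append(RawRecord(source_id=decoy_ids[-1], smiles=canon))
    if len(decoy_ids) < decoys:
        raise FixtureError("decoy pool exhausted without a collision-free set")
    truth.decoy_ids = tuple(decoy_ids)
    truth.decoy_smiles = tuple(decoy_smiles)
    order = rng.permutation(len(records))
    records = [records[i] for i in order]
    return records, truth


def generate_activity(
    truth: LibraryGroundTruth,
    seed: int = 0,
    decoy_center: float = 5.0,
    decoy_spread: float = 0.5,
) -> list[ActivityRecord]:
    """Per-molecule activities: pIC50 ~ Normal(series center, spread),
    emitted as IC50 in nM with qualifier "="; deterministic under seed."""
    rng = np.random.default_rng(seed)
    out: list[ActivityRecord] = []
    for s in truth.series:
        for mid_ in s.member_ids:
            pic50 = s.activity_center + (
                s.activity_spread * rng.standard_normal()
                if s.activity_spread > 0
                else 0.0
            )
            out.append(
                ActivityRecord(
                    source_id=mid_,
                    value=10.0 ** (9.0 - pic50),
                    units="nM",
                    qualifier="=",
                )
            )
    for did in truth.decoy_ids:
        pic50 = decoy_center + (
            decoy_spread * rng.standard_normal() if decoy_spread > 0 else 0.0
        )
        out.append(
            ActivityRecord(
                source_id=did, value=10.0 ** (9.0 - pic50), units="nM",
                qualifier="=",
            )
        )
    return out


def random_series_specs(
    n_series: int,
    seed: int = 0,
    size_range: tuple[int, int] = (2, 8),
    center_range: tuple[float, float] = (5.5, 8.0),
    spread: float = 0.3,
    ratio_threshold: float = 2.0 / 3.0,
) -> list[SeriesSpec]:
    """Draw seeded series recipes from the built-in chemistry pools.

    Scaffolds are sampled without replacement (at most
    ``len(SCAFFOLD_POOL)`` series); substituents are filtered to the sizes
    the relevance threshold admits for each scaffold.
    """
    if n_series > len(SCAFFOLD_POOL):
        raise InfeasibleSpecError(
            f"at most {len(SCAFFOLD_POOL)} series available, "
            f"{n_series} requested"
        )
    rng = np.random.default_rng(seed)
    picks = rng.choice(len(SCAFFOLD_POOL), size=n_series, replace=False)
    specs = []
    for i, pi in enumerate(picks, start=1):
        scaffold_smiles, junction = SCAFFOLD_POOL[pi]
        scaffold_heavy = heavy_atom_count(
            _parse_with_attachment(scaffold_smiles, "scaffold")
        )
        max_sub = (1.0 / ratio_threshold - 1.0) * scaffold_heavy + 1e-9
        pool = ACYL_R_GROUPS if junction == "acyl" else ALKYL_R_GROUPS
        usable = [
            r
            for r in pool
            if heavy_atom_count(_parse_with_attachment(r, "substituent"))
            <= max_sub
        ]
        lo, hi = size_range
        size = int(rng.integers(lo, min(hi, len(usable)) + 1))
        order = rng.permutation(len(usable))
        specs.append(
            SeriesSpec(
                name=f"S{i:02d}",
                scaffold_smiles=scaffold_smiles,
                r_groups=tuple(usable[k] for k in order),
                n_members=size,
                activity_center=float(
                    rng.uniform(center_range[0], center_range[1])
                ),
                activity_spread=spread,
            )
        )
    return specs


def standard_library(
    seed: int = 0,
    n_series: int = 8,
    decoys: int = 6,
    config: EnumerationConfig | None = None,
    **spec_kw,
) -> tuple[list[RawRecord], LibraryGroundTruth]:
    """Convenience: seeded specs + library in one call."""
    config = config or EnumerationConfig()
    specs = random_series_specs(
        n_series, seed=seed, ratio_threshold=config.ratio_threshold, **spec_kw
    )
    return generate_library(specs, decoys=decoys, seed=seed, config=config)


def hard_mode_component() -> list[RawRecord]:
    """Three molecules forming one connected component that admits no
    single comprehensive core: greedy selection must split it into at
    least two single-scaffold groups."""
    return [
        RawRecord("H-01", "O=CNc1ccc2ccccc2c1"),
        RawRecord("H-02", "CC(=O)Nc1ccc2ccccc2c1"),
        RawRecord("H-03", "CC(=O)Nc1ccc2ccccc2c1-c1ccccc1"),
    ]


def write_molecule_table(records: Sequence[RawRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("smiles\tid\n")
        for r in records:
            fh.write(f"{r.smiles}\t{r.source_id}\n")


def write_activity_table(
    records: Sequence[ActivityRecord], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("id\tvalue\tunits\tqualifier\n")
        for r in records:
            fh.write(f"{r.source_id}\t{r.value!r}\t{r.units}\t{r.qualifier}\n")
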
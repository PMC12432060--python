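"""Combinatorial sulfated/non-sulfated phenolic suspect database.

A registry of phenolic aglycones (32 under the shipped default: phenols,
phenolic acids, coumarins and phlorotannins) is expanded combinatorially:
each aglycone, alone or condensed with one of four sugar/sugar-like moieties
(hexose, pentose, quinic acid, shikimic acid; one condensation = free moiety
minus H2O), carries 0-3 sulfate groups (+SO3 each).  The default build is
32 x 5 x 4 = 640 suspect entries, 160 of them non-sulfated, exported as a
mass list for feature filtering.
"""

from __future__ import annotations

import csv
import hashlib
import io
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import yaml

from .chem import (
    Formula,
    IonConvention,
    monoisotopic_mass,
    mz_deprotonated,
    parse_formula,
)

__all__ = [
    "Aglycone",
    "ConjugateMoiety",
    "CompoundEntry",
    "SuspectDatabase",
    "build_aglycone_registry",
    "build_moieties",
    "conjugate",
    "sulfate",
    "generate_database",
    "export_mass_list",
    "default_registry_path",
]

SULFATE_GROUP = Formula({"S": 1, "O": 3})
WATER = Formula({"H": 2, "O": 1})

VALID_SUBCLASSES = ("phenol", "phenolic_acid", "coumarin", "phlorotannin")

_SULFATE_SUFFIX = {0: "", 1: " sulfate", 2: " disulfate", 3: " trisulfate"}


@dataclass(frozen=True)
class Aglycone:
    """A core phenolic scaffold eligible for conjugation and sulfation."""

    name: str
    formula: Formula
    subclass: str
    aromatic_oh: int = 0
    aliphatic_oh: int = 0

    def __post_init__(self) -> None:
        if self.subclass not in VALID_SUBCLASSES:
            raise ValueError(f"unknown subclass {self.subclass!r} for {self.name}")
        if self.aromatic_oh < 0 or self.aliphatic_oh < 0:
            raise ValueError(f"negative OH count for {self.name}")


@dataclass(frozen=True)
class ConjugateMoiety:
    """A sugar/sugar-like conjugate; delta_formula = free moiety - H2O."""

    name: str
    delta_formula: Formula


@dataclass(frozen=True)
class CompoundEntry:
    """One suspect: aglycone x optional moiety x sulfation level."""

    id: str
    name: str
    aglycone_name: str
    moiety_name: str | None
    n_sulfates: int
    formula: Formula
    neutral_mass: float
    compound_class: str


@dataclass
class SuspectDatabase:
    """Ordered suspect entries plus build provenance."""

    entries: list[CompoundEntry]
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @property
    def formulas(self) -> set[Formula]:
        return {e.formula for e in self.entries}

    def mz_values(self, conv: IonConvention | None = None) -> list[float]:
        conv = conv or IonConvention()
        return [mz_deprotonated(e.neutral_mass, conv) for e in self.entries]


def default_registry_path() -> Path:
    """Path of the shipped aglycone/moiety registry YAML."""
    return Path(str(resources.files("sulfoscreen").joinpath("data/aglycones.yaml")))


def _load_registry_config(config: str | Path | dict | None) -> dict:
    if config is None:
        config = default_registry_path()
    if isinstance(config, (str, Path)):
        with open(config, "r", encoding="utf-8") as handle:
            config = yaml.safe_load(handle)
    if not isinstance(config, dict) or "aglycones" not in config:
        raise ValueError("registry config must be a mapping with an 'aglycones' list")
    return config


def build_aglycone_registry(
    config: str | Path | dict | None = None,
    expected_count: int | None = 32,
) -> list[Aglycone]:
    """Load and validate the aglycone registry.

    The shipped default encodes the 32 scaffolds screened for in seaweed
    extracts (6 phenols, 16 phenolic acids, 4 coumarins, 6 phlorotannins).
    Pass ``expected_count=None`` to allow custom registries of any size.
    """
    raw = _load_registry_config(config)
    registry: list[Aglycone] = []
    seen: set[str] = set()
    for item in raw["aglycones"]:
        name = str(item["name"])
        if name in seen:
            raise ValueError(f"duplicate aglycone name: {name!r}")
        seen.add(name)
        registry.append(
            Aglycone(
                name=name,
                formula=parse_formula(item["formula"]),
                subclass=item["subclass"],
                aromatic_oh=int(item.get("aromatic_oh", 0)),
                aliphatic_oh=int(item.get("aliphatic_oh", 0)),
            )
        )
    if expected_count is not None and len(registry) != expected_count:
        raise ValueError(
            f"registry has {len(registry)} aglycones, expected {expected_count}"
        )
    return registry


def build_moieties(config: str | Path | dict | None = None) -> list[ConjugateMoiety]:
    """Load the conjugate moieties (default: hexose, pentose, quinic, shikimic)."""
    raw = _load_registry_config(config)
    moieties = [
        ConjugateMoiety(name=str(m["name"]), delta_formula=parse_formula(m["delta_formula"]))
        for m in raw.get("moieties", [])
    ]
    if len({m.name for m in moieties}) != len(moieties):
        raise ValueError("duplicate moiety names in config")
    return moieties


def _entry_name(aglycone: str, moiety: str | None, n_sulfates: int) -> str:
    name = aglycone
    if moiety:
        name += f" {moiety} conjugate"
    return name + _SULFATE_SUFFIX[n_sulfates]


def _compound_class(subclass: str, n_sulfates: int) -> str:
    return subclass + ("_sulfate" if n_sulfates > 0 else "")


def conjugate(aglycone: Aglycone, moiety: ConjugateMoiety | None) -> CompoundEntry:
    """Condense an aglycone with a moiety (or none: identity on the formula)."""
    formula = aglycone.formula
    moiety_name = None
    if moiety is not None:
        formula = formula + moiety.delta_formula
        moiety_name = moiety.name
    return CompoundEntry(
        id=_entry_id(aglycone.name, moiety_name, 0),
        name=_entry_name(aglycone.name, moiety_name, 0),
        aglycone_name=aglycone.name,
        moiety_name=moiety_name,
        n_sulfates=0,
        formula=formula,
        neutral_mass=monoisotopic_mass(formula),
        compound_class=_compound_class(aglycone.subclass, 0),
    )


def sulfate(entry: CompoundEntry, n: int) -> CompoundEntry:
    """Add ``n`` sulfate groups (1-3) to a non-sulfated entry."""
    if not 1 <= n <= 3:
        raise ValueError(f"sulfation level must be 1-3, got {n}")
    if entry.n_sulfates != 0:
        raise ValueError("entry is already sulfated")
    formula = entry.formula + n * SULFATE_GROUP
    base_class = entry.compound_class
    return CompoundEntry(
        id=_entry_id(entry.aglycone_name, entry.moiety_name, n),
        name=_entry_name(entry.aglycone_name, entry.moiety_name, n),
        aglycone_name=entry.aglycone_name,
        moiety_name=entry.moiety_name,
        n_sulfates=n,
        formula=formula,
        neutral_mass=monoisotopic_mass(formula),
        compound_class=base_class + "_sulfate",
    )


def _entry_id(aglycone: str, moiety: str | None, n_sulfates: int) -> str:
    parts = [aglycone.replace(" ", "_")]
    if moiety:
        parts.append(moiety.replace(" ", "_"))
    parts.append(f"{n_sulfates}SO3")
    return "+".join(parts)


def generate_database(
    registry: Sequence[Aglycone] | None = None,
    moieties: Sequence[ConjugateMoiety] | None = None,
    max_sulfates: int = 3,
    conv: IonConvention | None = None,
) -> SuspectDatabase:
    """Expand registry x {none + moieties} x {0..max_sulfates} suspects.

    Entries are ordered by registry position, then moiety (free aglycone
    first), then sulfation level, so re-exports are deterministic.  Distinct
    (aglycone, moiety, n_sulfates) triples are kept even when their formulas
    collide: isobaric suspects are resolved downstream by RT and MS2, not in
    the mass list.
    """
    if max_sulfates < 0 or max_sulfates > 3:
        raise ValueError("max_sulfates must be between 0 and 3")
    if registry is None:
        registry = build_aglycone_registry()
    if moieties is None:
        moieties = build_moieties()
    conv = conv or IonConvention()

    entries: list[CompoundEntry] = []
    for aglycone in registry:
        for moiety in [None, *moieties]:
            base = conjugate(aglycone, moiety)
            entries.append(base)
            for n in range(1, max_sulfates + 1):
                entries.append(sulfate(base, n))

    digest = hashlib.sha256(
        "|".join(f"{a.name}:{a.formula.hill()}" for a in registry).encode()
        + "|".join(f"{m.name}:{m.delta_formula.hill()}" for m in moieties).encode()
        + f"|max_sulfates={max_sulfates}".encode()
    ).hexdigest()[:16]
    provenance = {
        "config_hash": digest,
        "n_aglycones": len(registry),
        "n_moieties": len(moieties),
        "max_sulfates": max_sulfates,
        "ion_convention": conv.describe(),
    }
    return SuspectDatabase(entries=entries, provenance=provenance)


def export_mass_list(
    db: SuspectDatabase,
    destination: str | Path | io.TextIOBase,
    conv: IonConvention | None = None,
) -> None:
    """Write the suspect database as a deterministic mass-list CSV.

    Columns: name, formula (Hill), neutral monoisotopic mass (5 decimals),
    [M-H]- m/z (5 decimals), compound class, n_sulfates.  Provenance and the
    ion-convention constants go into ``#`` header comment lines so the file
    is self-describing.
    """
    conv = conv or IonConvention()

    def _write(handle) -> None:
        for key, value in sorted(db.provenance.items()):
            handle.write(f"# {key}: {value}\n")
        writer = csv.writer(handle, lineterminator="\n")
        writer.writerow(["name", "formula", "neutral_mass", "mz_deprotonated", "compound_class", "n_sulfates"])
        for entry in db.entries:
            writer.writerow(
                [
                    entry.name,
                    entry.formula.hill(),
                    f"{entry.neutral_mass:.5f}",
                    f"{mz_deprotonated(entry.neutral_mass, conv):.5f}",
                    entry.compound_class,
                    entry.n_sulfates,
                ]
            )

    if isinstance(destination, (str, Path)):
        with open(destination, "w", encoding="utf-8", newline="") as handle:
            _write(handle)
    else:
        _write(destination)
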
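"""Bundled metabolite mass table and pathway collection.

A miniature, curated stand-in for the large public metabolite databases:
each record carries a name, HMDB accession, molecular formula, monoisotopic
mass and KEGG-style pathway memberships.  Monoisotopic masses are derived
from the formula by summing atomic monoisotopic masses, and the loader
re-checks the bundled values against the formula.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

__all__ = [
    "MetaboliteRecord",
    "PathwayDB",
    "formula_monoisotopic_mass",
    "load_bundled_metabolite_db",
    "hmdb_equal",
    "PROTON_MASS",
]

# Monoisotopic masses of the most abundant isotope (Da), CODATA/AME values.
ATOMIC_MONOISOTOPIC = {
    "H": 1.0078250319,
    "C": 12.0,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "P": 30.97376151,
    "S": 31.97207069,
    "Cl": 34.96885271,
    "Na": 22.98976928,
    "K": 38.96370668,
    "F": 18.99840322,
    "Se": 79.9165218,
    "I": 126.904473,
}

#: Mass of a proton (Da): the shift of [M+H]+ / [M-H]- ions.
PROTON_MASS = 1.007276466

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class DatabaseLoadError(ValueError):
    """Malformed bundled database file."""


def formula_monoisotopic_mass(formula: str) -> float:
    """Monoisotopic mass (Da) of a molecular formula like ``C11H12N2O2``."""
    pos = 0
    mass = 0.0
    for match in _FORMULA_TOKEN.finditer(formula):
        if match.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r} at offset {pos}")
        pos = match.end()
        element, count = match.group(1), match.group(2)
        if element not in ATOMIC_MONOISOTOPIC:
            raise ValueError(f"unknown element {element!r} in formula {formula!r}")
        mass += ATOMIC_MONOISOTOPIC[element] * (int(count) if count else 1)
    if pos != len(formula) or mass == 0.0:
        raise ValueError(f"cannot parse formula {formula!r}")
    return mass


def _hmdb_number(hmdb_id: str) -> int:
    m = re.fullmatch(r"HMDB0*(\d+)", hmdb_id.strip())
    if not m:
        raise ValueError(f"not an HMDB accession: {hmdb_id!r}")
    return int(m.group(1))


def hmdb_equal(a: str, b: str) -> bool:
    """True when two HMDB accessions refer to the same metabolite.

    Accessions occur both in the legacy 5-digit (HMDB00929) and current
    7-digit (HMDB0000929) zero-padded form.
    """
    return _hmdb_number(a) == _hmdb_number(b)


@dataclass(frozen=True)
class MetaboliteRecord:
    """One bundled metabolite: identity, mass and pathway memberships."""

    name: str
    hmdb_id: str
    formula: str
    monoisotopic_mass: float
    pathways: tuple[str, ...] = ()
    level: int = 2  # default annotation-confidence tier recorded as metadata
    synonyms: tuple[str, ...] = ()

    def matches_name(self, query: str) -> bool:
        q = query.strip().lower()
        return q == self.name.lower() or q in (s.lower() for s in self.synonyms)


@dataclass
class PathwayDB:
    """Pathway membership sets over a metabolite universe.

    ``pathways`` maps pathway name -> frozenset of HMDB accessions
    (canonical 7-digit form); ``universe`` is the set of all metabolites
    considered by over-representation tests.
    """

    pathways: dict[str, frozenset[str]]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        for name, members in self.pathways.items():
            if not members:
                raise ValueError(f"empty pathway {name!r}")
            if not members <= self.universe:
                raise ValueError(f"pathway {name!r} has members outside the universe")


def canonical_hmdb(hmdb_id: str) -> str:
    """Zero-padded 7-digit HMDB accession."""
    return f"HMDB{_hmdb_number(hmdb_id):07d}"


def _bundled_path() -> Path:
    return Path(str(resources.files("metabocc").joinpath("data/metabolite_db.tsv")))


def load_bundled_metabolite_db(
    path: str | Path | None = None,
) -> tuple[list[MetaboliteRecord], PathwayDB]:
    """Load the bundled metabolite table and its pathway collection.

    Returns the records and a :class:`PathwayDB` whose universe is the full
    set of bundled metabolites.  Raises :class:`DatabaseLoadError` with the
    offending line number on malformed input.
    """
    path = Path(path) if path is not None else _bundled_path()
    records: list[MetaboliteRecord] = []
    pathway_members: dict[str, set[str]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["name", "hmdb_id", "formula", "monoisotopic_mass", "level", "pathways", "synonyms"]
        if header != expected:
            raise DatabaseLoadError(f"{path}:1: unexpected header {header}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(expected):
                raise DatabaseLoadError(
                    f"{path}:{lineno}: expected {len(expected)} fields, got {len(fields)}"
                )
            name, hmdb_id, formula, mass_s, level_s, pathways_s, synonyms_s = fields
            try:
                mass = float(mass_s)
                level = int(level_s)
                hmdb = canonical_hmdb(hmdb_id)
                formula_mass = formula_monoisotopic_mass(formula)
            except ValueError as exc:
                raise DatabaseLoadError(f"{path}:{lineno}: {exc}") from exc
            if abs(formula_mass - mass) > 5e-4:
                raise DatabaseLoadError(
                    f"{path}:{lineno}: mass {mass} inconsistent with formula "
                    f"{formula} ({formula_mass:.4f})"
                )
            pathways = tuple(p for p in pathways_s.split(";") if p)
            synonyms = tuple(s for s in synonyms_s.split(";") if s)
            records.append(
                MetaboliteRecord(name, hmdb, formula, mass, pathways, level, synonyms)
            )
            for p in pathways:
                pathway_members.setdefault(p, set()).add(hmdb)
    universe = frozenset(r.hmdb_id for r in records)
    db = PathwayDB({k: frozenset(v) for k, v in pathway_members.items()}, universe)
    return records, db


def lookup(records: list[MetaboliteRecord], name: str) -> list[MetaboliteRecord]:
    """Case-insensitive name/synonym lookup; empty list when unknown."""
    return [r for r in records if r.matches_name(name)]


def lookup_hmdb(records: list[MetaboliteRecord], hmdb_id: str) -> MetaboliteRecord | None:
    for r in records:
        if hmdb_equal(r.hmdb_id, hmdb_id):
            return r
    return None
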
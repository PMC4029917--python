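"""Reading, standardizing and persisting compound libraries.

A library is an ordered collection of :class:`Compound` records, each
carrying an id, a human-readable name, a SMILES structure and a chemical
series tag (cathinone, piperazine, naphthoylindole cannabinoid, ...).
Structures are standardized on load: the largest covalent fragment is
kept (salt stripping), charges are neutralized where a simple proton
transfer suffices, and all stereochemistry is erased — the substructure-key
fingerprints computed downstream cannot distinguish enantiomers or
diastereomers, so erasing stereo up front makes that invariance a
guarantee rather than an accident of the fingerprint definition.

Aromaticity is perceived with RDKit's default model for every input;
no per-file or per-record overrides exist, so any two spellings of the
same molecule canonicalize identically.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from rdkit import Chem, RDLogger
from rdkit.Chem.MolStandardize import rdMolStandardize

logger = logging.getLogger(__name__)

RDLogger.DisableLog("rdApp.*")

#: Enumerated chemical-series tags. Anything else maps to "uncategorized".
CATEGORIES = frozenset({
    "cathinone",
    "piperazine",
    "tryptamine",
    "2C",
    "other-amphetamine-type",
    "JWH",
    "AM/UR/RCS/XLR",
    "other-synthetic-cannabinoid",
    "classic-cannabinoid",
    "endocannabinoid",
    "non-cannabinoid",
    "approved-drug",
    "uncategorized",
})

ROLES = frozenset({"library-member", "calibrator", "metabolite"})


class StructureParseError(ValueError):
    """A SMILES string could not be parsed into a valid molecule."""

    def __init__(self, smiles: str, position: int, detail: str = ""):
        self.smiles = smiles
        self.position = position
        self.detail = detail
        msg = f"cannot parse SMILES {smiles!r} (problem at or after position {position}"
        if detail:
            msg += f": {detail}"
        msg += ")"
        super().__init__(msg)


class LibraryError(ValueError):
    """A library file violates the format contract (duplicate ids, bad rows...)."""


def parse_structure(smiles: str) -> Chem.Mol:
    """Parse a SMILES string into an RDKit molecule.

    Aromaticity is perceived with RDKit's default aromaticity model, so
    parsing is insensitive to atom ordering: any SMILES spelling of a
    molecule yields the same canonical form.

    Raises
    ------
    StructureParseError
        If the string is empty, syntactically malformed, or chemically
        invalid. The error reports the position of the first token at
        which no valid molecule can be formed (found by longest-valid-
        prefix scan, 0-based).
    """
    if not smiles or not smiles.strip():
        raise StructureParseError(smiles, 0, "empty input")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise StructureParseError(smiles, _error_position(smiles))
    if mol.GetNumHeavyAtoms() < 1:
        raise StructureParseError(smiles, 0, "no heavy atoms")
    return mol


def _error_position(smiles: str) -> int:
    """Position of the first character after the longest parseable prefix.

    Sanitization is skipped during the scan: it localizes syntax errors;
    valence/kekulization problems surface at full length.
    """
    last_ok = 0
    for i in range(1, len(smiles) + 1):
        if Chem.MolFromSmiles(smiles[:i], sanitize=False) is not None:
            last_ok = i
    return last_ok


_LARGEST_FRAGMENT = rdMolStandardize.LargestFragmentChooser()
_UNCHARGER = rdMolStandardize.Uncharger()


def standardize(mol: Chem.Mol) -> Chem.Mol:
    """Standardize a parsed molecule.

    Keeps the largest covalent fragment (strips salts and solvates),
    neutralizes charges where a proton transfer suffices, and removes all
    stereochemical descriptors. Idempotent: standardizing an already
    standard molecule returns an equivalent structure.
    """
    mol = _LARGEST_FRAGMENT.choose(mol)
    mol = _UNCHARGER.uncharge(mol)
    mol = Chem.Mol(mol)
    Chem.RemoveStereochemistry(mol)
    Chem.SanitizeMol(mol)
    return mol


def canonical_smiles(mol: Chem.Mol) -> str:
    """Canonical (achiral) SMILES for a standardized molecule."""
    return Chem.MolToSmiles(mol)


@dataclass(frozen=True)
class Compound:
    """One library entry: an identified, standardized chemical structure."""

    id: str
    name: str
    smiles: str
    category: str = "uncategorized"
    shulgin_number: str | None = None
    role: str = "library-member"

    def mol(self) -> Chem.Mol:
        return parse_structure(self.smiles)

    @classmethod
    def from_smiles(
        cls,
        id: str,
        name: str,
        smiles: str,
        category: str = "uncategorized",
        shulgin_number: str | None = None,
        role: str = "library-member",
    ) -> "Compound":
        """Build a compound, standardizing the structure and validating tags."""
        mol = standardize(parse_structure(smiles))
        if category not in CATEGORIES:
            logger.warning(
                "unknown category %r for compound %s; using 'uncategorized'",
                category, id,
            )
            category = "uncategorized"
        if role not in ROLES:
            raise LibraryError(f"unknown role {role!r} for compound {id}")
        return cls(
            id=id,
            name=name,
            smiles=canonical_smiles(mol),
            category=category,
            shulgin_number=shulgin_number or None,
            role=role,
        )


@dataclass
class CompoundLibrary:
    """Ordered collection of compounds with unique ids."""

    compounds: list[Compound] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for c in self.compounds:
            if c.id in seen:
                raise LibraryError(f"duplicate compound id {c.id!r}")
            seen.add(c.id)

    def __len__(self) -> int:
        return len(self.compounds)

    def __iter__(self) -> Iterator[Compound]:
        return iter(self.compounds)

    def __getitem__(self, compound_id: str) -> Compound:
        for c in self.compounds:
            if c.id == compound_id:
                return c
        raise KeyError(compound_id)

    def __contains__(self, compound_id: str) -> bool:
        return any(c.id == compound_id for c in self.compounds)

    @property
    def ids(self) -> list[str]:
        return [c.id for c in self.compounds]

    def add(self, compound: Compound) -> None:
        if compound.id in self:
            raise LibraryError(f"duplicate compound id {compound.id!r}")
        self.compounds.append(compound)


def load_library(path: str | Path, format: str | None = None) -> CompoundLibrary:
    """Load a compound library from a ``.smi``, ``.csv`` or ``.sdf`` file.

    Every record is standardized and validated. Unparseable structures are
    collected and reported together; a duplicate id aborts the load.

    ``format`` defaults to the file extension. The ``.smi`` dialect is
    whitespace-separated "SMILES name..." with no header line; CSV requires
    at least ``id,name,smiles`` columns, with optional ``category``,
    ``shulgin_number`` and ``role``.
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "smi":
        rows = _read_smi(path)
    elif fmt == "csv":
        rows = _read_csv(path)
    elif fmt == "sdf":
        rows = _read_sdf(path)
    else:
        raise LibraryError(f"unsupported library format {fmt!r}")

    compounds: list[Compound] = []
    bad: list[str] = []
    for row in rows:
        try:
            compounds.append(Compound.from_smiles(**row))
        except StructureParseError as exc:
            bad.append(f"{row['id']}: {exc}")
    if bad:
        raise LibraryError(
            "unparseable structures in %s:\n  %s" % (path, "\n  ".join(bad))
        )
    return CompoundLibrary(compounds, provenance=str(path))


def _read_smi(path: Path) -> list[dict]:
    rows = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line:
                continue
            parts = line.split(None, 1)
            smiles = parts[0]
            name = parts[1].strip() if len(parts) > 1 else f"compound-{i + 1}"
            rows.append({"id": name, "name": name, "smiles": smiles})
    return rows


def _read_csv(path: Path) -> list[dict]:
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise LibraryError(f"{path}: empty file")
        missing = {"id", "name", "smiles"} - set(reader.fieldnames)
        if missing:
            raise LibraryError(f"{path}: missing columns {sorted(missing)}")
        rows = []
        for rec in reader:
            row = {
                "id": rec["id"].strip(),
                "name": rec["name"].strip(),
                "smiles": rec["smiles"].strip(),
            }
            if rec.get("category"):
                row["category"] = rec["category"].strip()
            if rec.get("shulgin_number"):
                row["shulgin_number"] = rec["shulgin_number"].strip()
            if rec.get("role"):
                row["role"] = rec["role"].strip()
            rows.append(row)
    return rows


def _read_sdf(path: Path) -> list[dict]:
    rows = []
    supplier = Chem.SDMolSupplier(str(path), sanitize=True)
    for i, mol in enumerate(supplier):
        if mol is None:
            raise LibraryError(f"{path}: unparseable SDF record {i + 1}")
        name = mol.GetProp("_Name") if mol.HasProp("_Name") else f"compound-{i + 1}"
        rows.append({"id": name, "name": name, "smiles": Chem.MolToSmiles(mol)})
    return rows


def write_library(library: CompoundLibrary, path: str | Path, format: str | None = None) -> None:
    """Write a library to CSV or JSON (canonical structures, all metadata)."""
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    records = [
        {
            "id": c.id,
            "name": c.name,
            "smiles": c.smiles,
            "category": c.category,
            "shulgin_number": c.shulgin_number or "",
            "role": c.role,
        }
        for c in library
    ]
    if fmt == "csv":
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(
                fh, fieldnames=["id", "name", "smiles", "category", "shulgin_number", "role"]
            )
            writer.writeheader()
            writer.writerows(records)
    elif fmt == "json":
        with open(path, "w") as fh:
            json.dump(
                {"provenance": library.provenance, "compounds": records}, fh, indent=1
            )
    else:
        raise LibraryError(f"unsupported output format {fmt!r}")
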
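"""Fixed-length public substructure-key fingerprints.

The default key table is the openly published reconstruction of the 166
MDL/MACCS public keys (the SMARTS table distributed with RDKit). Each key
is a substructure query plus a minimum distinct-match count: bit *i* is set
iff the molecule contains at least ``min_count`` distinct atom-set matches
of pattern *i*. Three keys of the public table are not expressible as a
single SMARTS and are evaluated procedurally: key 1 (any isotope-labelled
atom), key 125 (more than one aromatic ring) and key 166 (more than one
covalent fragment).

The table is data, not code: custom tables load from CSV
(``index,smarts,min_count``) and every fingerprint records the
``key_set_id`` it was computed with, so downstream outputs carry their
provenance and mixed-table comparisons are rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem

PUBLIC_166 = "public166"

#: Procedural keys of the public table: index -> (procedure name, min_count).
_SPECIAL_PROCEDURES = {
    1: ("isotope", 1),
    125: ("aromatic_ring", 2),
    166: ("fragment", 2),
}


class KeySetError(ValueError):
    """A key table is malformed (bad SMARTS, duplicate or gapped indices)."""


class KeySetMismatchError(ValueError):
    """Two fingerprints from different key tables were combined."""


@dataclass(frozen=True)
class KeyDefinition:
    """One substructure key: bit set iff distinct matches >= min_count."""

    index: int
    smarts: str | None  # None for procedural keys
    min_count: int = 1
    procedure: str | None = None
    _query: Chem.Mol | None = field(default=None, compare=False, repr=False)

    def query(self) -> Chem.Mol | None:
        return self._query


@dataclass(frozen=True)
class Fingerprint:
    """Binary key vector of length K plus the id of the table that defined it."""

    bits: np.ndarray  # bool array, position i-1 <-> key index i
    key_set_id: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "bits", np.asarray(self.bits, dtype=bool))

    def __len__(self) -> int:
        return len(self.bits)

    @property
    def on_keys(self) -> list[int]:
        """1-based indices of the set bits, matching published key numbering."""
        return [int(i) + 1 for i in np.flatnonzero(self.bits)]

    def to_hex(self) -> str:
        """Hex serialization (big-endian within bytes, key 1 first)."""
        return np.packbits(self.bits).tobytes().hex()

    @classmethod
    def from_hex(cls, hexstring: str, length: int, key_set_id: str) -> "Fingerprint":
        raw = np.unpackbits(np.frombuffer(bytes.fromhex(hexstring), dtype=np.uint8))
        return cls(bits=raw[:length].astype(bool), key_set_id=key_set_id)


class KeySet:
    """An ordered, compiled key table."""

    def __init__(self, keys: Sequence[KeyDefinition], key_set_id: str):
        indices = [k.index for k in keys]
        if len(set(indices)) != len(indices):
            dupes = sorted({i for i in indices if indices.count(i) > 1})
            raise KeySetError(f"duplicate key indices {dupes}")
        expected = list(range(1, len(keys) + 1))
        if sorted(indices) != expected:
            raise KeySetError(
                f"key indices must be contiguous 1..{len(keys)}; got {sorted(indices)[:5]}..."
            )
        self.keys: list[KeyDefinition] = sorted(keys, key=lambda k: k.index)
        self.key_set_id = key_set_id

    def __len__(self) -> int:
        return len(self.keys)

    def __iter__(self):
        return iter(self.keys)


def _compile(index: int, smarts: str, min_count: int) -> KeyDefinition:
    query = Chem.MolFromSmarts(smarts)
    if query is None:
        raise KeySetError(f"key {index}: invalid SMARTS {smarts!r}")
    return KeyDefinition(index=index, smarts=smarts, min_count=min_count, _query=query)


@lru_cache(maxsize=4)
def _builtin_public166() -> KeySet:
    from rdkit.Chem import MACCSkeys

    keys = []
    for index, (smarts, count) in MACCSkeys.smartsPatts.items():
        if index in _SPECIAL_PROCEDURES:
            proc, min_count = _SPECIAL_PROCEDURES[index]
            keys.append(
                KeyDefinition(index=index, smarts=None, min_count=min_count, procedure=proc)
            )
        else:
            # published tables state "matches > count"; as a minimum count
            # that is count + 1
            keys.append(_compile(index, smarts, count + 1))
    return KeySet(keys, PUBLIC_166)


def load_key_set(source: str | Path = PUBLIC_166) -> KeySet:
    """Load a key table: the builtin ``"public166"`` name or a CSV path.

    CSV columns: ``index,smarts,min_count`` (min_count optional, default 1).
    """
    if str(source) == PUBLIC_166:
        return _builtin_public166()
    path = Path(source)
    import csv

    keys = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"index", "smarts"} <= set(reader.fieldnames):
            raise KeySetError(f"{path}: need columns index,smarts[,min_count]")
        for rec in reader:
            keys.append(
                _compile(
                    int(rec["index"]),
                    rec["smarts"].strip(),
                    int(rec.get("min_count") or 1),
                )
            )
    return KeySet(keys, key_set_id=path.stem)


def _count_matches(mol: Chem.Mol, key: KeyDefinition) -> int:
    """Distinct substructure matches of a key in a molecule.

    Matches are counted as unique atom sets: automorphic re-orderings of
    the same atoms count once, which stabilizes count-threshold keys.
    """
    if key.procedure == "isotope":
        return sum(1 for a in mol.GetAtoms() if a.GetIsotope() != 0)
    if key.procedure == "aromatic_ring":
        from rdkit.Chem import rdMolDescriptors

        return rdMolDescriptors.CalcNumAromaticRings(mol)
    if key.procedure == "fragment":
        return len(Chem.GetMolFrags(mol))
    matches = mol.GetSubstructMatches(key.query(), uniquify=False, maxMatches=10000)
    return len({frozenset(m) for m in matches})


def compute_fingerprint(mol: Chem.Mol, key_set: KeySet | str = PUBLIC_166) -> Fingerprint:
    """Compute the key fingerprint of a (standardized) molecule.

    Deterministic and independent of atom numbering: substructure matching
    sees only the molecular graph.
    """
    if isinstance(key_set, str):
        key_set = load_key_set(key_set)
    bits = np.zeros(len(key_set), dtype=bool)
    for key in key_set:
        if _count_matches(mol, key) >= key.min_count:
            bits[key.index - 1] = True
    return Fingerprint(bits=bits, key_set_id=key_set.key_set_id)


def popcount(fp: Fingerprint) -> int:
    """Number of set bits."""
    return int(fp.bits.sum())


@lru_cache(maxsize=8192)
def _cached_fingerprint(canonical_smiles: str, key_set_id: str) -> Fingerprint:
    assert key_set_id == PUBLIC_166
    mol = Chem.MolFromSmiles(canonical_smiles)
    return compute_fingerprint(mol, _builtin_public166())


def fingerprint_for_smiles(canonical_smiles: str, key_set: KeySet | str = PUBLIC_166) -> Fingerprint:
    """Fingerprint keyed by canonical SMILES, memoized for the builtin table.

    Profiles evaluate the same standardized structures repeatedly (every
    assay re-profiles the whole library); caching on the canonical SMILES
    makes that cost once-per-structure. Custom tables bypass the cache.
    """
    if isinstance(key_set, str) and key_set == PUBLIC_166:
        return _cached_fingerprint(canonical_smiles, PUBLIC_166)
    if isinstance(key_set, KeySet) and key_set.key_set_id == PUBLIC_166:
        return _cached_fingerprint(canonical_smiles, PUBLIC_166)
    mol = Chem.MolFromSmiles(canonical_smiles)
    return compute_fingerprint(mol, key_set)
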
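"""Tanimoto similarity of library compounds to a target molecule.

The central quantity of the package: for fingerprints A and B,
``T(A,B) = |A ∧ B| / |A ∨ B|`` over set bits, ranging 0 (no shared keys)
to 1 (identical keys). A profile evaluates every library compound against
one target — typically the calibrator of an immunoassay — grouped by
chemical series, which is the data behind the similarity dot plots.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .chem import CompoundLibrary, parse_structure, standardize
from .fingerprints import (
    PUBLIC_166,
    Fingerprint,
    KeySet,
    KeySetMismatchError,
    compute_fingerprint,
    fingerprint_for_smiles,
    load_key_set,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SimilarityValue:
    compound_id: str
    target_id: str
    tanimoto: float


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto coefficient of two fingerprints from the same key table.

    Two all-zero fingerprints compare as 0.0 (with a warning), not 1.0:
    two molecules that set no keys at all should not be reported as
    maximally similar.
    """
    if a.key_set_id != b.key_set_id or len(a) != len(b):
        raise KeySetMismatchError(
            f"cannot compare fingerprints from key sets "
            f"{a.key_set_id!r} (K={len(a)}) and {b.key_set_id!r} (K={len(b)})"
        )
    union = int((a.bits | b.bits).sum())
    if union == 0:
        warnings.warn(
            "both fingerprints are all-zero; defining similarity as 0.0",
            stacklevel=2,
        )
        return 0.0
    return int((a.bits & b.bits).sum()) / union


@dataclass
class SimilarityProfile:
    """Tanimoto of every library compound (except the target) to one target."""

    target_id: str
    key_set_id: str
    entries: list[SimilarityValue] = field(default_factory=list)
    categories: dict[str, str] = field(default_factory=dict)  # compound_id -> category

    def __len__(self) -> int:
        return len(self.entries)

    def value(self, compound_id: str) -> float:
        for e in self.entries:
            if e.compound_id == compound_id:
                return e.tanimoto
        raise KeyError(compound_id)

    def by_category(self) -> dict[str, list[SimilarityValue]]:
        """Entries grouped by series tag, sorted descending within each group."""
        groups: dict[str, list[SimilarityValue]] = {}
        for e in self.entries:
            groups.setdefault(self.categories.get(e.compound_id, "uncategorized"), []).append(e)
        for vals in groups.values():
            vals.sort(key=lambda v: (-v.tanimoto, v.compound_id))
        return groups

    def to_frame(self) -> pd.DataFrame:
        """Long-form table (target_id, compound_id, category, tanimoto)."""
        return pd.DataFrame(
            {
                "target_id": self.target_id,
                "compound_id": [e.compound_id for e in self.entries],
                "category": [
                    self.categories.get(e.compound_id, "uncategorized")
                    for e in self.entries
                ],
                "tanimoto": [e.tanimoto for e in self.entries],
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def category_summary(self) -> dict[str, dict[str, float]]:
        """Per-category min/median/max, the content of the JSON summary."""
        out = {}
        for cat, grp in self.to_frame().groupby("category"):
            out[str(cat)] = {
                "n": int(len(grp)),
                "min": float(grp.tanimoto.min()),
                "median": float(grp.tanimoto.median()),
                "max": float(grp.tanimoto.max()),
            }
        return out


def profile(
    target_id: str,
    library: CompoundLibrary,
    key_set: KeySet | str = PUBLIC_166,
    target_smiles: str | None = None,
) -> SimilarityProfile:
    """Similarity of every library compound to the target.

    The target itself is excluded from its own profile (it would trivially
    contribute 1.0). It may be a library member or supplied separately via
    ``target_smiles``.
    """
    if isinstance(key_set, str):
        key_set = load_key_set(key_set)
    if target_smiles is not None:
        from .chem import canonical_smiles

        target_can = canonical_smiles(standardize(parse_structure(target_smiles)))
    elif target_id in library:
        target_can = library[target_id].smiles
    else:
        raise KeyError(f"target {target_id!r} not in library and no structure supplied")
    target_fp = fingerprint_for_smiles(target_can, key_set)

    prof = SimilarityProfile(target_id=target_id, key_set_id=key_set.key_set_id)
    for comp in library:
        if comp.id == target_id:
            continue
        fp = fingerprint_for_smiles(comp.smiles, key_set)
        prof.entries.append(
            SimilarityValue(comp.id, target_id, tanimoto(fp, target_fp))
        )
        prof.categories[comp.id] = comp.category
    return prof


def threshold_census(prof: SimilarityProfile, cutoff: float) -> dict[str, int]:
    """Per-category count of entries with tanimoto >= cutoff (inclusive)."""
    if not 0.0 <= cutoff <= 1.0:
        raise ValueError(f"cutoff must be in [0, 1], got {cutoff}")
    counts: dict[str, int] = {}
    for cat, entries in prof.by_category().items():
        n = sum(1 for e in entries if e.tanimoto >= cutoff)
        if n:
            counts[cat] = n
    return counts
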
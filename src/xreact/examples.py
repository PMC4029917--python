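"""Worked-example compound pairs from the designer-drug screening domain.

These are the canonical hand-checkable comparisons the package documents:
similarity of designer stimulants to the calibrators of the bath-salts
ELISAs, and of synthetic-cannabinoid metabolites to the JWH-018
N-pentanoic acid metabolite that calibrates several spice assays. Each
entry is (name_a, smiles_a, name_b, smiles_b).
"""

from __future__ import annotations

from .chem import parse_structure, standardize
from .fingerprints import PUBLIC_166, compute_fingerprint, load_key_set
from .similarity import tanimoto

JWH018_PENTANOIC = "OC(=O)CCCCn1cc(C(=O)c2cccc3ccccc23)c2ccccc21"

WORKED_EXAMPLE_PAIRS: dict[str, tuple[str, str, str, str]] = {
    "mephedrone-vs-methcathinone": (
        "mephedrone", "CC(NC)C(=O)c1ccc(C)cc1",
        "methcathinone", "CC(NC)C(=O)c1ccccc1",
    ),
    "mdma-vs-mephentermine": (
        "MDMA", "CNC(C)Cc1ccc2OCOc2c1",
        "mephentermine", "CNC(C)(C)Cc1ccccc1",
    ),
    "am2201-n4oh-metabolite-vs-jwh018-pentanoic-acid": (
        "AM-2201 N-4-hydroxy metabolite", "FCC(O)CCCn1cc(C(=O)c2cccc3ccccc23)c2ccccc21",
        "JWH-018 N-pentanoic acid metabolite", JWH018_PENTANOIC,
    ),
    "win55212-2-vs-jwh018-pentanoic-acid": (
        "WIN 55,212-2", "CC1=C(C(=O)c2cccc3ccccc23)c2cccc3c2N1CC(CN1CCOCC1)O3",
        "JWH-018 N-pentanoic acid metabolite", JWH018_PENTANOIC,
    ),
    "naphthoylindole-vs-jwh018-pentanoic-acid": (
        "3-(1-naphthoyl)-1H-indole", "O=C(c1cccc2ccccc12)c1c[nH]c2ccccc12",
        "JWH-018 N-pentanoic acid metabolite", JWH018_PENTANOIC,
    ),
    "anandamide-vs-jwh018-pentanoic-acid": (
        "anandamide", "CCCCCC=CCC=CCC=CCC=CCCCC(=O)NCCO",
        "JWH-018 N-pentanoic acid metabolite", JWH018_PENTANOIC,
    ),
    "mephentermine-vs-phentermine": (
        "mephentermine", "CNC(C)(C)Cc1ccccc1",
        "phentermine", "CC(C)(N)Cc1ccccc1",
    ),
    "benzylpiperazine-vs-phencyclidine": (
        "benzylpiperazine", "C(N1CCNCC1)c1ccccc1",
        "phencyclidine", "C1CCCCC1(c1ccccc1)N1CCCCC1",
    ),
}


def pair_similarity(key: str, key_set: str = PUBLIC_166) -> float:
    """Standardize both structures of a worked-example pair, fingerprint
    them and return their Tanimoto coefficient."""
    _, smiles_a, _, smiles_b = WORKED_EXAMPLE_PAIRS[key]
    ks = load_key_set(key_set)
    fa = compute_fingerprint(standardize(parse_structure(smiles_a)), ks)
    fb = compute_fingerprint(standardize(parse_structure(smiles_b)), ks)
    return tanimoto(fa, fb)
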
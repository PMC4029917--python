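import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from xreact import (
    Compound,
    CompoundLibrary,
    load_key_set,
)

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


# Named designer drugs, metabolites and everyday pharmaceuticals; a diverse
# fixture set for fingerprint and similarity checks. All achiral-spelling
# SMILES (stereo handled by standardization anyway).
FIXTURE_SMILES = {
    "methcathinone": "CC(NC)C(=O)c1ccccc1",
    "mephedrone": "CC(NC)C(=O)c1ccc(C)cc1",
    "methylethcathinone": "CCNC(C)C(=O)c1ccc(C)cc1",
    "3-fluoromethcathinone": "CC(NC)C(=O)c1cccc(F)c1",
    "MDPV": "CCCC(C(=O)c1ccc2OCOc2c1)N1CCCC1",
    "pyrovalerone": "CCCC(C(=O)c1ccc(C)cc1)N1CCCC1",
    "naphyrone": "CCCC(C(=O)c1ccc2ccccc2c1)N1CCCC1",
    "butylone": "CCC(NC)C(=O)c1ccc2OCOc2c1",
    "ethylone": "CCNC(C)C(=O)c1ccc2OCOc2c1",
    "amphetamine": "CC(N)Cc1ccccc1",
    "methamphetamine": "CNC(C)Cc1ccccc1",
    "MDMA": "CNC(C)Cc1ccc2OCOc2c1",
    "MDA": "CC(N)Cc1ccc2OCOc2c1",
    "mephentermine": "CNC(C)(C)Cc1ccccc1",
    "phentermine": "CC(C)(N)Cc1ccccc1",
    "ethylamphetamine": "CCNC(C)Cc1ccccc1",
    "4-methylthioamphetamine": "CC(N)Cc1ccc(SC)cc1",
    "PMA": "COc1ccc(CC(C)N)cc1",
    "benzylpiperazine": "C(N1CCNCC1)c1ccccc1",
    "TFMPP": "FC(F)(F)c1cccc(N2CCNCC2)c1",
    "mCPP": "Clc1cccc(N2CCNCC2)c1",
    "MeOPP": "COc1ccc(N2CCNCC2)cc1",
    "phencyclidine": "C1CCCCC1(c1ccccc1)N1CCCCC1",
    "ketamine": "CNC1(c2ccccc2Cl)CCCCC1=O",
    "2C-B": "COc1cc(CCN)c(OC)cc1Br",
    "2C-I": "COc1cc(CCN)c(OC)cc1I",
    "2C-E": "CCc1cc(OC)c(CCN)cc1OC",
    "mescaline": "COc1cc(CCN)cc(OC)c1OC",
    "DOB": "CC(N)Cc1cc(OC)c(Br)cc1OC",
    "DMT": "CN(C)CCc1c[nH]c2ccccc12",
    "psilocin": "CN(C)CCc1c[nH]c2cccc(O)c12",
    "5-MeO-DMT": "CN(C)CCc1c[nH]c2ccc(OC)cc12",
    "N,N-tetramethylenetryptamine": "C(Cc1c[nH]c2ccccc12)N1CCCC1",
    "tryptamine": "NCCc1c[nH]c2ccccc12",
    "JWH-018": "CCCCCn1cc(C(=O)c2cccc3ccccc23)c2ccccc21",
    "JWH-018-N-pentanoic-acid": "OC(=O)CCCCn1cc(C(=O)c2cccc3ccccc23)c2ccccc21",
    "JWH-018-N-5-hydroxy": "OCCCCCn1cc(C(=O)c2cccc3ccccc23)c2ccccc21",
    "JWH-073": "CCCCn1cc(C(=O)c2cccc3ccccc23)c2ccccc21",
    "JWH-073-N-butanoic-acid": "OC(=O)CCCn1cc(C(=O)c2cccc3ccccc23)c2ccccc21",
    "JWH-250": "CCCCCn1cc(C(=O)Cc2ccccc2OC)c2ccccc21",
    "JWH-250-N-4-hydroxy": "CC(O)CCCn1cc(C(=O)Cc2ccccc2OC)c2ccccc21",
    "JWH-200": "O=C(c1cccc2ccccc12)c1cn(CCN2CCOCC2)c2ccccc12",
    "JWH-175": "C(c1cccc2ccccc12)c1cn(CCCCC)c2ccccc12",
    "AM-2201": "FCCCCCn1cc(C(=O)c2cccc3ccccc23)c2ccccc21",
    "AM-2201-N-4-hydroxy": "FCC(O)CCCn1cc(C(=O)c2cccc3ccccc23)c2ccccc21",
    "RCS-4": "CCCCCn1cc(C(=O)c2ccc(OC)cc2)c2ccccc21",
    "3-naphthoylindole": "O=C(c1cccc2ccccc12)c1c[nH]c2ccccc12",
    "WIN-55212-2": "CC1=C(C(=O)c2cccc3ccccc23)c2cccc3c2N1CC(CN1CCOCC1)O3",
    "pravadoline": "COc1ccc(C(=O)c2c(C)n(CCN3CCOCC3)c3ccccc23)cc1",
    "THC": "CCCCCc1cc(O)c2C3C=C(C)CCC3C(C)(C)Oc2c1",
    "9-carboxy-THC": "CCCCCc1cc(O)c2C3C=C(C(=O)O)CCC3C(C)(C)Oc2c1",
    "anandamide": "CCCCCC=CCC=CCC=CCC=CCCCC(=O)NCCO",
    "2-AG": "CCCCCC=CCC=CCC=CCC=CCCCC(=O)OC(CO)CO",
    "caffeine": "Cn1cnc2c1c(=O)n(C)c(=O)n2C",
    "aspirin": "CC(=O)Oc1ccccc1C(=O)O",
    "ibuprofen": "CC(C)Cc1ccc(C(C)C(=O)O)cc1",
    "naproxen": "COc1ccc2cc(C(C)C(=O)O)ccc2c1",
    "diphenhydramine": "CN(C)CCOC(c1ccccc1)c1ccccc1",
    "fluoxetine": "CNCCC(Oc1ccc(C(F)(F)F)cc1)c1ccccc1",
    "morphine": "CN1CCC23c4c5ccc(O)c4OC2C(O)C=CC3C1C5",
    "cocaine": "COC(=O)C1C(OC(=O)c2ccccc2)CC2CCC1N2C",
    "nicotine": "CN1CCCC1c1cccnc1",
    "ethanol": "CCO",
    "benzene": "c1ccccc1",
    "dihydrogen": "[H][H]",
}


@pytest.fixture(scope="session")
def fixture_smiles() -> dict[str, str]:
    return dict(FIXTURE_SMILES)


@pytest.fixture(scope="session")
def key_set():
    return load_key_set("public166")


@pytest.fixture(scope="session")
def fixture_library() -> CompoundLibrary:
    cats = {
        "methcathinone": "cathinone", "mephedrone": "cathinone", "MDPV": "cathinone",
        "benzylpiperazine": "piperazine", "TFMPP": "piperazine",
        "DMT": "tryptamine", "psilocin": "tryptamine",
        "2C-B": "2C", "2C-I": "2C",
        "JWH-018": "JWH", "JWH-073": "JWH",
        "AM-2201": "AM/UR/RCS/XLR",
        "THC": "classic-cannabinoid", "anandamide": "endocannabinoid",
        "aspirin": "approved-drug", "caffeine": "approved-drug",
    }
    lib = CompoundLibrary(provenance="unit-test fixture")
    for name, smi in FIXTURE_SMILES.items():
        if name == "dihydrogen":
            continue  # no heavy-atom-rich structure; used separately
        lib.add(Compound.from_smiles(name, name, smi, cats.get(name, "uncategorized")))
    return lib


def random_score_table(rng: np.random.Generator, n_pos=8, n_neg=12, ties=False) -> pd.DataFrame:
    """Random score/label table for diagnostic-test oracles."""
    pos = rng.random(n_pos)
    neg = rng.random(n_neg) * 0.9
    if ties:
        pool = np.round(np.concatenate([pos, neg]), 1)
        pos, neg = pool[:n_pos], pool[n_pos:]
    return pd.DataFrame(
        {
            "score": np.concatenate([pos, neg]),
            "label": ["cross-reactive"] * n_pos + ["non-cross-reactive"] * n_neg,
        }
    )
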
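"""Synthetic compound libraries and cross-reactivity panels.

Real cross-reactivity panels are scarce: an assay insert lists a few dozen
tested compounds, while the structural universe of designer drugs is far
larger. This module generates both sides of the analysis with a known
ground truth so the whole pipeline is testable end to end:

* **Libraries** are built by decorating designer-drug scaffolds — the
  beta-keto amphetamines (cathinones), benzylpiperazines, 2C-type
  phenethylamines, tryptamines, and the naphthoylindole /
  phenylacetylindole synthetic cannabinoids — with small substituent pools
  at ring and amine positions, mimicking how real analog series arise.

* **Panels** assume the hypothesis under test actually holds: percent
  cross-reactivity is a monotone, noisy function of true fingerprint
  similarity *s* to the calibrator,

      percent = 100 * logistic(k * (s - m)) * exp(eps),  eps ~ N(0, sigma^2)

  a logistic link (midpoint ``m``, steepness ``k``) with multiplicative
  log-normal noise. The calibrator is forced to 100; a configurable
  fraction of compounds is marked untested, mirroring the large untested
  sets in real screening panels.

All randomness flows from the single seed in the config; identical
(config, seed) pairs reproduce identical libraries and panels.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .chem import Compound, CompoundLibrary
from .fingerprints import PUBLIC_166, KeySet, fingerprint_for_smiles, load_key_set
from .panels import AssayPanel, CrossReactivityRecord
from .similarity import tanimoto


@dataclass(frozen=True)
class ScaffoldSpec:
    """A decoratable scaffold: a SMILES template with named substituent slots.

    ``core`` is a Python format string whose ``{slot}`` placeholders are
    filled from ``substituent_pool``; the hydrogen substituent is spelled
    ``[H]`` so every filled template remains valid SMILES. Every enumerated
    product must parse and standardize cleanly (checked at generation).
    """

    name: str
    core: str
    substituent_pool: dict[str, tuple[str, ...]]
    category: str

    def enumerate_products(self) -> list[str]:
        """All distinct substituent combinations, in deterministic order."""
        slots = sorted(self.substituent_pool)
        out = []
        for combo in itertools.product(*(self.substituent_pool[s] for s in slots)):
            out.append(self.core.format(**dict(zip(slots, combo))))
        return out


_RING = ("[H]", "C", "CC", "CCC", "OC", "OCC", "F", "Cl", "Br", "I", "C(C)C", "C(F)(F)F")
_AMINE = ("[H]", "C", "CC", "CCC", "C(C)C")
_CHAIN = ("CCC", "CCCC", "CCCCC", "CCCCO", "CCCCC(=O)O", "CCCCF")

#: Default scaffold families, one per major designer-drug series.
DEFAULT_SCAFFOLDS: tuple[ScaffoldSpec, ...] = (
    ScaffoldSpec(
        name="cathinone-core",
        core="CC(N{amine})C(=O)c1ccc({ring})cc1",
        substituent_pool={"amine": _AMINE, "ring": _RING},
        category="cathinone",
    ),
    ScaffoldSpec(
        name="piperazine-core",
        core="C(N1CCN({amine})CC1)c1ccc({ring})cc1",
        substituent_pool={"amine": _AMINE, "ring": _RING},
        category="piperazine",
    ),
    ScaffoldSpec(
        name="2C-core",
        core="COc1cc(CCN{amine})c(OC)cc1{ring}",
        substituent_pool={"amine": _AMINE, "ring": _RING},
        category="2C",
    ),
    ScaffoldSpec(
        name="tryptamine-core",
        core="N({amine})CCc1c[nH]c2ccc({ring})cc12",
        substituent_pool={"amine": _AMINE, "ring": _RING},
        category="tryptamine",
    ),
    ScaffoldSpec(
        name="naphthoylindole-core",
        core="C({chain})n1cc(C(=O)c2ccc({ring})c3ccccc23)c2ccccc21",
        substituent_pool={"chain": _CHAIN, "ring": _RING},
        category="JWH",
    ),
    ScaffoldSpec(
        name="phenylacetylindole-core",
        core="C({chain})n1cc(C(=O)Cc2ccc({ring})cc2)c2ccccc21",
        substituent_pool={"chain": _CHAIN, "ring": _RING},
        category="JWH",
    ),
)


@dataclass(frozen=True)
class PanelSimConfig:
    """Parameters of the similarity -> cross-reactivity link.

    link_midpoint: similarity at which expected cross-reactivity is 50%.
    link_steepness: logistic slope; higher = sharper similar/dissimilar split.
    noise_sd: SD of the log-scale multiplicative noise.
    untested_fraction: fraction of non-calibrator compounds left unassayed.
    """

    calibrator_id: str
    link_midpoint: float = 0.6
    link_steepness: float = 15.0
    noise_sd: float = 0.1
    positive_threshold_percent: float = 0.8
    untested_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.link_midpoint < 1.0:
            raise ValueError("link_midpoint must lie in (0, 1)")
        if self.link_steepness <= 0:
            raise ValueError("link_steepness must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0.0 <= self.untested_fraction < 1.0:
            raise ValueError("untested_fraction must lie in [0, 1)")


def gen_library(
    specs: tuple[ScaffoldSpec, ...] = DEFAULT_SCAFFOLDS,
    n_per_scaffold: int = 25,
    seed: int = 0,
) -> CompoundLibrary:
    """Draw ``n_per_scaffold`` distinct decorated analogs per scaffold.

    The parent scaffold (all-hydrogen / first-pool decoration) is always
    included in addition to the sampled analogs, tagged with the
    scaffold's category. Deterministic for a fixed seed.
    """
    if n_per_scaffold < 1:
        raise ValueError("n_per_scaffold must be >= 1")
    rng = np.random.default_rng(seed)
    library = CompoundLibrary(provenance=f"synthetic scaffold decoration (seed={seed})")
    for spec in specs:
        products = spec.enumerate_products()
        parent = products[0]
        analogs = [p for p in products[1:]]
        if n_per_scaffold > len(analogs):
            raise ValueError(
                f"{spec.name}: requested {n_per_scaffold} analogs, pool has {len(analogs)}"
            )
        picks = rng.choice(len(analogs), size=n_per_scaffold, replace=False)
        library.add(
            Compound.from_smiles(
                id=f"{spec.name}", name=spec.name, smiles=parent, category=spec.category
            )
        )
        for j, k in enumerate(sorted(picks)):
            library.add(
                Compound.from_smiles(
                    id=f"{spec.name}-{j + 1:03d}",
                    name=f"{spec.name} analog {j + 1}",
                    smiles=analogs[k],
                    category=spec.category,
                )
            )
    return library


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def gen_panel(
    library: CompoundLibrary,
    config: PanelSimConfig,
    key_set: KeySet | str = PUBLIC_166,
    assay_name: str = "synthetic-assay",
) -> AssayPanel:
    """Simulate a cross-reactivity panel for a library and calibrator.

    True similarities are computed with the same fingerprint machinery the
    analysis uses; with ``noise_sd = 0`` the percent ordering therefore
    equals the similarity ordering exactly, and a compound at the link
    midpoint receives exactly 50%.
    """
    if config.calibrator_id not in library:
        raise ValueError(f"calibrator {config.calibrator_id!r} not in library")
    if isinstance(key_set, str):
        key_set = load_key_set(key_set)
    rng = np.random.default_rng(config.seed)

    cal_fp = fingerprint_for_smiles(library[config.calibrator_id].smiles, key_set)
    others = [c for c in library if c.id != config.calibrator_id]
    sims = np.array(
        [tanimoto(fingerprint_for_smiles(c.smiles, key_set), cal_fp) for c in others]
    )
    eps = rng.normal(0.0, config.noise_sd, size=len(others))
    percents = (
        100.0
        * _logistic(config.link_steepness * (sims - config.link_midpoint))
        * np.exp(eps)
    )
    untested = rng.random(len(others)) < config.untested_fraction

    records = [
        CrossReactivityRecord(library[config.calibrator_id].id, 100.0, tested=True)
    ]
    for comp, pct, skip in zip(others, percents, untested):
        if skip:
            records.append(CrossReactivityRecord(comp.id, None, tested=False))
        else:
            records.append(CrossReactivityRecord(comp.id, float(pct), tested=True))
    return AssayPanel(
        assay_name=assay_name,
        calibrator_id=config.calibrator_id,
        records=records,
        positive_threshold_percent=config.positive_threshold_percent,
    )
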
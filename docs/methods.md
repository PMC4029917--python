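# Methods

## Structure handling

All inputs are SMILES. Parsing and aromaticity perception use RDKit's
default aromaticity model, applied uniformly; there are no per-input
overrides, so any spelling of a molecule canonicalizes identically.
Standardization keeps the largest covalent fragment (package inserts and
drug libraries list parent drugs, not salts), neutralizes charges where a
simple proton transfer suffices, and erases all stereo descriptors.
Stereo erasure is deliberate: 2D substructure-key fingerprints cannot
distinguish enantiomers or diastereomers, and erasing stereo at
standardization turns that into a guarantee rather than a property that
happens to hold for the default key table.

## Fingerprints

The default key table is the openly published reconstruction of the 166
MDL/MACCS public keys, loaded at runtime from RDKit's key-definition
table. Key semantics follow the published definitions: a count key such as
"CH3 > 2" sets its bit iff the number of *distinct atom-set* matches is
strictly greater than the stated count (automorphic re-orderings of the
same atoms count once, which stabilizes count keys on symmetric
molecules). Three keys are procedural rather than SMARTS: isotope
presence, more-than-one aromatic ring, more-than-one fragment. Custom
tables load from CSV (`index,smarts,min_count`), and every fingerprint and
downstream output records its `key_set_id`, so results computed under
different tables cannot be silently mixed.

The exact key table used by commercial modelling suites is proprietary and
differs from the open reconstruction in a small number of ambiguous keys.
Worked-example similarities computed here can therefore differ by a few
hundredths from values printed by such software; the
mephedrone–methcathinone pair is the sharpest case, where a single
methyl-count key separates the two molecules (T = 14/15 ≈ 0.933) while
implementations with a different count dialect report 1.0. We keep the
published strict-count semantics because the alternatives (treating the
count as inclusive, or ignoring counts) distort other drug-pair
similarities far more than they gain on this pair.

## Similarity profiles

Tanimoto similarity is |intersection|/|union| over set bits. Two all-zero
fingerprints are defined to have similarity 0 (with a warning), not 1:
featureless molecules should not appear maximally similar. A profile
scores every library compound against one target (the assay calibrator, or
any drug of interest); the target is excluded from its own profile, and
calibrator metabolites are ordinary compounds when they are not the
target. Census counts at a similarity cutoff use "≥".

## Cross-reactivity panels

Percent cross-reactivity is relative to the calibrator at 100 %. A tested
compound is labelled cross-reactive when its percent **strictly exceeds**
the assay's positivity threshold (default 0.8 %, the bath-salts
convention; cannabinoid panels typically use 1 %). Ordinal bands (e.g.
"≥25 %", "1–24 %", "<1 %") use inclusive lower edges. Qualitative
below-detection entries are encoded as tested at 0 %. These conventions
are configuration, not code: each assay is a config entry.

## Diagnostic evaluation

Predicted-positive means score ≥ cutoff, which keeps the calibrator itself
positive at cutoff 1.0. Sensitivity, specificity and efficiency are the
standard ratios of the confusion counts; a zero-denominator metric is
reported as NaN and flagged, never as 0. The ROC curve is built at every
distinct observed score plus sentinels beyond both extremes, so its points
reproduce `confusion_at_cutoff` exactly; AUC is the trapezoidal area and
is asserted (to 1e-12) equal to the tie-corrected Mann–Whitney pair
statistic, which it equals analytically for this construction. Candidate
cutoffs for efficiency maximization are midpoints between adjacent
distinct scores plus the two sentinels — the selected cutoff therefore
need not equal any particular printed cutoff to reproduce the same
confusion counts. Efficiency ties break toward higher specificity, then
the higher cutoff: in a screening context false positives trigger
unnecessary confirmatory work. ROC analysis and cutoff selection refuse to
run unless both classes have ≥ `min_class_size` (default 5) compounds,
reporting both class sizes in the refusal; small-class ROC curves invite
over-interpretation.

## Synthetic data generator

The generator emulates the structure of real designer-drug screening
panels. Libraries decorate six scaffold cores — cathinone, benzylpiperazine,
2C-phenethylamine, tryptamine, naphthoylindole and phenylacetylindole —
with small pools of ring substituents (H, alkyl, alkoxy, halogen, CF3),
amine substituents and N-alkyl chains, mirroring how analog series arise
in practice. Default 25 analogs per scaffold plus each parent core;
~200-compound runs use 33 per scaffold. Every product must parse and
standardize cleanly; draws are without replacement from the enumerated
pool and fully determined by the seed.

Panels assume the hypothesis under study holds in the simulated world:
percent cross-reactivity is a noisy monotone function of true fingerprint
similarity *s* to the calibrator,

    percent = 100 · logistic(k·(s − m)) · exp(ε),  ε ~ N(0, σ²)

with defaults m = 0.6 (similarity at 50 % cross-reactivity, matching the
empirical ~0.6 similarity watershed for cross-reactive compounds),
k = 15 (sharp but not step-like transition), σ = 0.1 (≈10 % multiplicative
assay noise), positivity threshold 0.8 %, and half of the non-calibrator
compounds marked untested (real panels leave most of the structural
universe untested). The calibrator is forced to 100 % and tested. One seed
governs library and panel.

What the generator does **not** emulate: concentration-dependent
cross-reactivity (panels are single-number summaries), antibody epitope
chemistry (the link is a function of whole-molecule similarity, so the
simulation cannot produce the real-world hard cases where a small epitope
change breaks binding between globally similar molecules), and
heterogeneous data provenance. Passing parameter-recovery tests therefore
show the pipeline is correct and well-calibrated under its own model, not
that 2D similarity predicts any particular real assay.

## Numerical and degenerate-input choices

Fingerprint bits are 1-based to match published key numbering and
serialized as hex plus explicit length. Profiles sort descending within
category with compound id as deterministic tie-break. Empty tested sets
join to an empty scored table with a warning rather than an error. The
`.smi` dialect is whitespace-separated "SMILES name" with no header line.
Malformed SMILES raise a structured error reporting the longest parseable
prefix position.

## Problem sizes

Unit and property tests run on a 64-compound named-drug fixture library
and toy tables; oracle suites use 1,000 random fingerprint pairs and 200
random score tables; parameter recovery uses 204-compound libraries over
20 seeds, with permuted-percent nulls over the same seeds. The full suite
completes in well under a minute on one CPU thanks to a canonical-SMILES
fingerprint cache.

## Known limitations

The open key table is a reconstruction; absolute similarity values carry a
few-hundredths dialect uncertainty (bounds-type statements are robust to
this, exact-value comparisons at the third decimal are not). Binary
labels discard the ordinal information in percent bands when fitting
cutoffs. AUC confidence intervals and comparison of correlated ROC curves
are out of scope, as are hashed/circular fingerprints and any 3D methods.
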
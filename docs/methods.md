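# Methods

This note records the models, conventions and design choices behind
`augscreen`, in the spirit of a package methods appendix: what is computed,
under which assumptions, and where the genuinely open choices were made.

## Problem setting

SERCA2a (the cardiac sarco/endoplasmic reticulum Ca²⁺-ATPase) is a validated
heart-failure target whose *activation* by small molecules is pharmacologically
desirable but data-poor: only a handful of validated activators exist. A
conventional QSAR classifier trained on so few actives overfits badly. The
strategy implemented here enlarges the active class synthetically — growing
structural analogs of seed activators so that the classifier sees a continuous
structure–activity neighborhood rather than isolated points — and pairs it
with property-matched decoys so that the model must learn topology (scaffold
and substitution pattern), not trivial property differences.

## Molecular representation

* **Canonical SMILES** (RDKit, isomeric) is the molecule identity; two
  molecules are equal iff their canonical SMILES are equal.
* **Fingerprints**: MACCS keys (the 166 informative keys; RDKit's bit 0 is
  dropped, stored index = key − 1) and ECFP as Morgan radius 2 hashed to
  2,048 bits. Both are stored as explicit bit-index sets; Tanimoto similarity
  is |A∩B|/|A∪B|, with two empty sets defined as similarity 1.
* **Seven descriptors**: molecular weight (Da), Crippen atom-contribution
  cLogP, TPSA (Å²), H-bond donors, H-bond acceptors, rotatable bonds, aromatic
  rings. Donor convention: any N/O/S heavy atom bearing ≥ 1 hydrogen (water
  counts 1). Rotatable bonds use RDKit's strict SMARTS (single, non-ring,
  non-amide bonds between non-terminal heavy atoms; ethane counts 0).
  Acceptors use RDKit's Lipinski N+O-based count. These conventions are used
  consistently by the drug-likeness rules, so a molecule's rule verdicts are
  pure threshold functions of this one descriptor vector.
* **Feature matrix**: MACCS block ⧺ ECFP block ⧺ descriptor block, Z-score
  standardized with a scaler fitted on training rows only; constant columns
  map to zero rather than raising. Stored scalers are applied, never refitted.

## Analog growth (augmentation)

The generator is self-contained (no external fragment store): a built-in
library of ~280 fragments (alkyl/functionalized chains, substituted aromatics,
saturated rings, each with one `[*]` attachment point) is attached at
hydrogen-bearing heavy atoms; heteroatom–heteroatom single bonds are refused,
as are products that fail valence sanitization or exceed 600 Da (the mass cap
prevents unbounded aliphatic drift, which hashed-set fingerprints cannot
penalize).

"Optimization steps over runs" is realized as stochastic hill-walking: each
run starts from the seed and performs up to 200 accept/reject growth moves; a
move is accepted when the analog's Tanimoto similarity to the seed — computed
on Morgan fingerprints of radius `context_radius` = 3, so that acceptance is
sensitive to three-bond atom environments — stays inside the similarity window
[0.4, 0.95]. Every accepted state is a candidate analog; collection stops at a
per-seed target drawn uniformly from [200, 300]. All randomness flows from one
integer seed; identical seeds give identical analog sets.

**Curation** removes duplicates (canonical SMILES), structural-alert matches
(the packaged alert library), property-window violations (pipeline default:
MW 100–600, rotatable bonds ≤ 15, cLogP in [−3, 7.5]) and analogs outside the
seed-similarity window re-checked with standard ECFP radius 2. Rejections are
tallied per reason. The pipeline then fixes the curated-set size at its
configured target (default 575) by deterministic subsampling when more
survive, mirroring the scale of the study design.

## Decoys

Decoys are *selected*, DUD-E style, from a generated candidate pool that is
property-matched to the curated actives (MW distribution resampled with
Gaussian jitter σ = 15 Da; cLogP within the actives' range ± 1) but never
contains the activator scaffold. For each active, candidates must satisfy
(a) Euclidean distance ≤ `property_tolerance` over the seven descriptors
Z-scored on the pool, and (b) ECFP Tanimoto to the active < 0.30; the
`k = 50` closest by property distance are taken. The tolerance default is 3.0
— a generous cap below the ≈ √14 ≈ 3.7 expected distance of random pool pairs;
the matching pressure comes from the closeness ranking, the cap only excludes
pathological actives. An active whose neighborhood cannot supply 50 compliant
decoys is treated as a property outlier and excluded from the training set
(logged). The balanced set pairs every active with one uniformly sampled decoy
from its 50, rejecting duplicates, giving exactly 2 × n rows.

## Classifier

XGBoost (`hist` tree method, single thread) on the standardized feature
matrix. Hyperparameters are grid-searched with stratified 10-fold CV scored by
**recall** — in a screening context a missed activator is costlier than a
false positive — with ties broken by higher CV accuracy, then smaller
ensemble. The library default grid is
{100, 300, 600} trees × depth {3, 5, 7} × learning rate {0.05, 0.1, 0.3} ×
subsample {0.8, 1.0}; the pipeline's benchmark configuration uses a compact
grid ({100, 300} × {3, 5} × 0.1 × 1.0) with identical search semantics, which
keeps the end-to-end benchmark around two minutes on one CPU. The train/test
split is stratified 75/25 (a configurable default). Evaluation reports
confusion counts at threshold 0.5, accuracy, and ROC AUC by trapezoidal
integration; AUC equals the pairwise concordance probability, which the test
suite verifies against a brute-force count.

## Similarity network, cliffs, hits

The screened library forms an undirected graph: nodes carry the predicted
activation probability, and an edge joins two molecules when their ECFP
Tanimoto ≥ `edge_threshold` (default 0.6; the similarity cutoff is a genuinely
open choice and is recorded in the output metadata). Construction is exact
O(n²) (blockwise bit-count arithmetic), intended for libraries up to a few
tens of thousands of molecules. Hits must satisfy `prob_min` < p ≤ `prob_max`
(defaults 0.7 / 1.0; an optional 0.9 cap mirrors a band-selection variant) and
degree ≥ 3 — an isolated high-probability node is more likely classifier noise
than a SAR island. The neighbor rule is degree **≥** 3. Activity cliffs are
edges with Δp ≥ `cliff_delta` (default 0.5; "significant difference" is
otherwise unquantified). The 2-D t-SNE embedding uses RDKit's hashed
path-based fingerprint as a stand-in for proprietary path descriptors (not
claimed equivalent) and is reporting-only: hit selection never reads
embedding coordinates.

## Drug-likeness and alerts

The five rule sets use their literature bounds (Lipinski MW ≤ 500, cLogP ≤ 5,
HBD ≤ 5, HBA ≤ 10; Ghose 160 ≤ MW ≤ 480, −0.4 ≤ cLogP ≤ 5.6, 20 ≤ atoms ≤ 70
including H, 40 ≤ MR ≤ 130 with MR from the same Crippen scheme as cLogP;
Veber rotB ≤ 10, TPSA ≤ 140; Egan cLogP ≤ 5.88, TPSA ≤ 131.6; Muegge
200 ≤ MW ≤ 600, −2 ≤ cLogP ≤ 5, TPSA ≤ 150, rings ≤ 7, C > 4, heteroatoms > 1,
rotB ≤ 15, HBD ≤ 5, HBA ≤ 10). **Consensus** defaults to ≥ 3 of 5: strict
all-five consensus under these descriptor conventions rejects long-chain
phenolics (e.g. 12 rotatable bonds in an 8-gingerol-length chain fails Veber)
that are legitimate members of this chemotype; majority consensus keeps the
filter meaningful without excluding the chemotype itself. Note the rotatable-
bond cutoff interacts with counting conventions: under the strict SMARTS
convention some long-chain actives exceed 10, and no test asserts that every
reference compound passes. The alert library is a curated Brenk-style SMARTS
list (~40 mutagenicity/reactivity/toxicity patterns) packaged as a
user-replaceable text file; the final hit filter keeps a molecule iff
rotB ≤ 10, cLogP < 5, consensus passes and zero alerts match, and reports
*every* failed check for dropped molecules.

## Assay analysis

Activity is % of untreated control. The modulation call uses a symmetric
margin (default 5 points): activator above 100 + margin, inhibitor below
100 − margin, marginal otherwise; the boundary is exact (a mean at precisely
100 + margin is marginal). Dose–response fitting uses nonlinear least squares
(`scipy.optimize.least_squares`, xtol = ftol = gtol = 1e-12, ≤ 2000
evaluations) with EC50/IC50 on a log10 scale: 4PL initialized at bottom = the
lowest-concentration response, top = the response farthest from it,
log10 EC50 = mean log-concentration, slope 1, slope bounded to [0.05, 10];
the biphasic form `y = bottom + span·f_act(c; EC50, h₁)·(1 − f_inh(c; IC50, h₂))`
(the simplest bell shape with interpretable parameters) initialized at the
one-third/two-thirds points of the log-concentration range. Model choice is by
AICc (k = parameters + 1 for the error variance); the non-monotonic flag is
set iff the biphasic model wins by ΔAICc ≥ 4, the conventional "considerably
less support" cutoff. Slopes are bounded to [0.1, 5] (a physiological range),
and the optimizer uses warm restarts with cost-stability acceptance because
the biphasic surface has flat valleys where strict tolerances are never met
although the parameters are stationary. The log-scale parameterization makes
fits scale-consistent: multiplying all concentrations by 10 multiplies the
fitted EC50 by 10. A 4PL needs ≥ 5 distinct concentrations, the biphasic
model ≥ 7. The functional form behind a published EC50 is often unstated;
the 4PL is adopted as the monotone reference.

Two small-sample caveats matter on the nine-point triplicate design:

* **Model discrimination needs replicate-level data.** AICc's small-sample
  correction at n = 9 mean points penalizes the six-parameter biphasic model
  so severely (n − k − 1 = 1) that it can never be preferred against noisy
  data; fitted on the 27 replicate-level points the criterion discriminates
  reliably. `fit_dose_response` accepts repeated concentrations for exactly
  this reason, and the pipeline's flag checks pass replicate-level curves.
* **EC50 from this design is imprecise.** When the plateau is not reached
  within the 0.1–50 µM range (slope ≈ 1), the top/EC50 degeneracy limits any
  estimator: with 5 % per-replicate noise and N = 3, even an estimator with
  baseline and slope fixed at their true values shows a median relative EC50
  error of roughly a third. Fitted EC50s from such designs should be read as
  order-of-magnitude estimates unless the plateau is clearly established.

## Synthetic benchmark data

`synthetic_data` emulates the structure of the real screening problem without
external downloads:

* **Chemotype family** — guaiacol (2-methoxyphenol) head group joined through
  ketone / amide / alcohol / ester / furan-bridged linkers to lipophilic
  chains of 1–12 carbons (plain, trans-enone, β-hydroxy or phenyl-terminated),
  i.e. the vanilloid motif of gingerol/shogaol/capsaicinoid natural products.
  The combinatorial space (~165 structures) is enumerated, canonicalized and
  deterministically subsampled; median intra-family ECFP Tanimoto ≈ 0.47.
* **Screening library** — planted family members plus background molecules
  grown from assorted ring cores to match the family's MW distribution
  (Kolmogorov–Smirnov statistic < 0.2) and cLogP range, but never containing
  the guaiacol core, so planted-active recovery tests the fingerprint/SAR
  signal rather than descriptor shortcuts. Default: 50 planted in 5,000
  background.
* **Dose–response simulation** — replicate responses `model(c)·(1 + ε)`,
  ε ~ N(0, σ) with σ = 5 % by default, on the nine-point 0.1–50 µM design with
  N = 3, aggregated to mean/SEM.

What the benchmark does **not** capture: real natural-product libraries are
far more diverse than the generated background, contain the activator
chemotype at unknown prevalence, and their actives do not share one literal
scaffold. Because the planted family is perfectly scaffold-coherent and the
background scaffold-free, the synthetic classification task is easier than the
real one — benchmark accuracies near 1.0 demonstrate correct plumbing and
recovery mechanics, not real-world screening accuracy.

## Determinism and scale

Every stochastic stage takes an explicit seed; the pipeline derives per-stage
seeds from one master seed as `(master · 1,000,003 + crc32(stage)) mod 2³¹`,
and the run manifest records a SHA-256 hash of every artifact — identical
config + seed reproduce identical hashes. Default problem sizes (6 seeds
grown to 575 curated actives, 3,000-candidate decoy pool, 5,050-molecule
library) run end-to-end in about two minutes on one CPU.

## Known limitations

* The fragment-growth generator explores attachment-only space: it grows but
  never mutates or links, so ring replacements and scaffold hops are absent.
* Dense O(n²) network construction does not scale past ~10⁵ molecules; no
  approximate nearest-neighbor index is provided.
* Probabilities are uncalibrated; the 0.7 hit threshold is a rank cutoff, not
  a calibrated posterior.
* Stereochemistry is carried through canonical SMILES but not enumerated or
  expanded.
* The alert library is a compact curated list, not a comprehensive toxicology
  screen.
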
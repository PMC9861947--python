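# Methods

## Molecular representation

Structures (SMILES or MDL Molfile/SDF) are parsed with RDKit and reduced to a
`MoleculeGraph`: atoms as (element symbol, formal charge) pairs, edges as
unordered index pairs. Three deliberate erasures define the representation:

1. **Hydrogens are explicit.** Every hydrogen implied by standard valence and
   formal charge becomes an atom node before descriptor generation, so `C`
   and `[CH4]` are the same five-atom graph.
2. **Bond orders and aromaticity are not stored.** Descriptors see only
   connectivity; a Kekulé and an aromatic writing of the same ring are
   identical downstream.
3. **Stereochemistry is discarded.** Enantiomers and E/Z isomers are formally
   equivalent compounds.

The atom label is the element symbol with the formal-charge sign appended
when nonzero (`O-`, `N+`, `Ca++`). Formal charge is the implementable reading
of charge-aware atom typing here; a finer partial-charge typing would slot
into `atom_label` without touching anything downstream. Isotopes are ignored
(the descriptor is constitutional). Multi-fragment inputs keep the largest
covalent component (salt stripping, configurable off) with a canonical-SMILES
tie-break for determinism; training corpora routinely store salts and the
descriptor semantics apply to the parent molecule.

## MNA descriptors

`MNA_0(a)` is the atom label; `MNA_k(a)` wraps the **lexicographically
sorted** `MNA_{k-1}` strings of a's neighbors in parentheses. Sorting makes
the string canonical under any atom re-indexing; duplicate sublabels are kept
side by side (a CH4 carbon at level 1 is `C(HHHH)`). A compound is the set of
unique descriptors over all atoms and all levels `0..max_level`
(`max_level = 2` by default, configurable). Including all levels rather than
only the top one gives a richer vocabulary and degrades gracefully for tiny
molecules; set (not multiset) semantics follow the unique-descriptor
representation of this descriptor family. Both choices are switches
(`cumulative=False` keeps only the top level).

## Curation

Raw measurements become per-activity binary labels under two rulesets:

* **CHEMBL_PUBCHEM** — potency endpoints (IC50/GI50/Ki/Kact) are converted to
  nM (exact powers of ten for nM/µM/mM/M; no molar-mass conversion); active
  iff value **< 10,000 nM** (strict). Percent inhibition: active iff
  **> 50%** (strict). Everything measured but not active is inactive —
  inactivity is the absence of evidence of activity.
* **NCI60** — rows with a non-empty failure reason are deleted; replicate
  −log10 GI50 values per compound × cell line are aggregated (median by
  default — the robust choice for replicate screens; mean is a switch) and
  the compound is active iff the aggregate is **≥ 9 / 8 / 7** for the
  1 nM / 10 nM / 100 nM threshold variants (inclusive). Values outside
  [0, 15] are dropped with a warning as physically implausible.

Per-compound conflicts resolve **active-wins**, mirroring the asymmetric
definition above; labeling is therefore independent of row order. Activity
names are standardized by case-folding and punctuation-stripping before
lookup in a user-supplied synonym table (the name harmonization itself is
data, not algorithm). Activities with fewer than `min_actives` actives
(default 3 — a per-activity Bayesian model below that is noise) or with no
inactive are omitted, with record-level accounting so that actives +
inactives + dropped = input for every activity. Compounds with identical
descriptor sets are collapsed to one representative before training, with
labels merged active-wins.

## The Bayesian model

With N training compounds, n_d containing descriptor d, and per activity a:
n_a actives, n_da actives containing d, the scorer uses

    p_a  = n_a / N
    p_da = (n_da + c·p_a) / (n_d + c),   c = 1 (configurable)
    s(x, a) = mean over d ∈ D(x) ∩ vocabulary of arcsin(2·p_da − 1)

The regularization keeps p_da strictly inside (0, 1) so the arcsine — chosen
for variance stabilization of proportion estimates — never saturates at its
poles. Unseen descriptors are ignored; a query with zero vocabulary overlap
receives the prior score `arcsin(2·p_a − 1)` rather than an error, because
prediction for arbitrary novel structures is the point of the tool. A
compound not labeled active for an activity counts among its inactives.

**Analytic leave-one-out.** The LOO score of training compound x removes x's
own contributions from every count: N−1; n_d−1 for each d ∈ D(x); n_a and
n_da decremented iff x is active. A descriptor whose remaining count reaches
zero is excluded from the mean — it would not be in the vocabulary of a model
retrained without x — which makes the analytic shortcut *exactly* equal to
explicit retraining (tested to 1e−12). If removing x empties a class the
score is computed against the degenerate prior and logged.

**Pa/Pi calibration.** The model stores the sorted LOO scores of the training
actives and inactives per activity, and

    Pa = (#{LOO-active scores < s} + 0.5·ties) / n_a
    Pi = (#{LOO-inactive scores > s} + 0.5·ties) / (N − n_a)

Calibrating against LOO rather than plain training scores matters: plain
scores of training actives are optimistically shifted, and ranking against
them would break the defining property that the Pa of a typical true active
is uniform on [0, 1] (equivalently: a Pa > t filter loses a fraction ≈ t of
real actives). Half-credit ties match the midrank ROC convention. Prediction
lists are sorted by Pa − Pi descending, most probable activities first, with
an activity-id tie-break for byte-reproducible output.

## Validation

IAP — the probability that a randomly chosen active outscores a randomly
chosen inactive, numerically the ROC AUC — is computed by midrank statistics
in O(n log n) and checked in tests against brute-force pair counting and
scikit-learn's `roc_auc_score`. LOO IAP falls directly out of the calibration
arrays. k-fold IAP (default k = 20) deals seeded, label-stratified folds in
one continuing round-robin and pools the out-of-fold scores into a single
IAP; pooling is stable for activities with few actives, and the continuing
deal makes k = N coincide with analytic LOO exactly. Report rows mark an
activity "selected" iff its LOO IAP is strictly above the threshold (default
0.8); mean IAP is reported both over selected activities and over all, since
the two summaries answer different questions.

## Synthetic data

The descriptor-level generator is the primary test substrate: each compound
includes vocabulary item i independently with probability p_background
(default 0.05 over a 500-item vocabulary), except for a block of `n_enriched`
items (default 10) included with probability 0.9 in actives vs 0.1 in
inactives. Defaults — 300 actives, 1200 inactives — emulate a mid-sized
single-cell-line training set with a strong, exactly known
structure–activity signal. Labels are exact by construction and all
randomness flows through one seeded generator. Equal enrichment
probabilities give the null (label-independent) configuration used for
chance-level checks.

What it does *not* emulate: real descriptor sets are not independent
Bernoulli draws (substructures co-occur hierarchically), real signals are
weaker and confounded, and real corpora have activity cliffs, assay noise
and series redundancy. Passing tests therefore demonstrate correctness of
the machinery and its calibration/accuracy properties under controlled
signal, not expected accuracy on experimental corpora.

The SMILES-level generator is a smaller end-to-end smoke layer: druglike
molecules assembled from a fixed fragment library, with a primary
sulfonamide planted in actives and an IC50 table (mixed nM/µM units) that
round-trips cleanly through curation. It exercises the parse → descriptor →
curate → train path, not chemical-space realism.

## Problem sizes and numerics

The standard study condition throughout tests and the acceptance script is
the 300/1200 planted-signal set (~1–2 s to train and cross-validate);
chance-level behavior averages 20 seeded replicates of a 100/400 null set;
toy sets of ≤ 20 compounds back the exact LOO-equals-retrain checks. Model
files are versioned JSON (format magic, config, vocabulary counts,
calibration arrays); Python's float serialization round-trips bit-exactly,
and the round trip is tested prediction-for-prediction. Displayed Pa/Pi use
three decimals; files keep full precision.

## Limitations

* The concrete estimator (regularized p_da, arcsine mean, rank-based
  calibration) is this package's reconstruction of the naive-Bayes-with-
  enhancements family it follows; it reproduces the documented *behavior*
  (Pa semantics, LOO/IAP properties), not any proprietary implementation
  byte-for-byte.
* Formal charge stands in for finer charge typing; tautomers and protonation
  states are not canonicalized.
* No applicability-domain measure beyond the prior fallback; no multi-label
  dependence modeling; no continuous-potency regression.
* Unit handling is molar-only; % inhibition and −log10 GI50 are taken as
  given, with a plausibility window as the only sanity check.
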
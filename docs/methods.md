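# Methods

## Problem setting

Curated interaction networks of the human gut microbiome list bacterium–
metabolite pairs with directional labels (a metabolite is *consumed* — taken
up as a substrate — or *produced* — exported as a reaction product). All such
records are positives; the scientific content of this package is (a) a
defensible construction of theoretical negatives, (b) an encoding of
instances that carries enzymatic and structural information, and (c) an
evaluation protocol that separates genuine signal from dataset artefacts.

## Label normalization and metabolite filtering

Raw labels arrive in a four-way vocabulary. Molecular degradation is folded
into consumption (the compound is taken up and broken down by the cell's
enzymes); combined consumption-and-production entries are split into one
record per direction; duplicates collapse. Metabolites are kept when their
molecular weight lies in [50, 500] Da — inclusive on both ends, since the
window is a diffusion/bioavailability heuristic, not a sharp threshold — and
the molecule contains at least one carbon atom. Weights missing from the
input table are computed by the chemistry engine (RDKit: average atomic
weights, Wildman–Crippen logP, Lipinski donor/acceptor counts).

## Theoretical negatives

For each bacterium with positives under a direction label, candidate
negatives are all metabolites whose chemical category (10 curated categories
plus "others") differs from every category of that bacterium's positive
partners, excluding pairs that are themselves positives. Category identity is
the only structural exclusion — no fingerprint-distance rule — because the
category partition already encodes the "similar compounds are plausible
partners" assumption being controlled for.

The candidate superset is then down-sampled to match the positives'
association-score distribution. Each instance is summarized by the maximum
metabolite–protein score over its scored proteins (the strongest association
is what drives both curation bias and classifier shortcuts; a mean summary is
available by configuration). Scores are binned into 10 equal-width bins over
[0, 1000]; each bin receives a quota proportional to the positives' bin mass
with largest-remainder rounding (deterministic and exactly conserving), and
candidates are drawn per bin without replacement under an explicit seed.
Quota that cannot be filled in a bin moves to the nearest non-empty bins.
Agreement is reported as a Pearson chi-square on the 2×B contingency table
(bins empty in both samples dropped first). Sampling is one-shot: quota
matching already achieves p ≈ 1 whenever the candidate pool covers the
positives' score range; an optional re-seeding loop (`max_retries`) exists
for pools near the feasibility boundary. When the pool simply does not span
the positives' distribution (as in the default synthetic world, where
non-interacting pairs score near background), the residual chi-square is
reported honestly rather than hidden by resampling.

Balanced enzyme-level reaction sets (substrate/product classification) pair
each positive (EC, metabolite) with an equal number of negatives drawn
uniformly, seeded, from {enzymes absent from the positive set} × {metabolite
panel} minus the positive pairs.

## Encodings

EC numbers are four-field tokens with missing trailing fields. The bitwise
accuracy of predicted EC numbers is scored per hierarchy level 1–4: a
first-digit mismatch voids all levels; otherwise level L is correct when all
comparable digits among the first L match, where a field missing on either
side is skipped. The symmetric skip follows the "available digits" reading of
partial EC numbers; the alternative (penalizing missing *predicted* digits)
changes only level-4 scores for truncated predictions.

The enzyme encoder maps an EC to 1024 dimensions as the sum of four seeded
pseudo-random unit vectors keyed by its digit prefixes of length 1..4, so
enzymes sharing classification prefixes are close in cosine similarity —
mirroring the hierarchy-awareness expected of a trained EC embedding. The
non-enzyme placeholder 0.0.0.0, used to pad fixed-width vectors, encodes to
the zero vector so padding is inert in tree splits. Metabolites map to 300
dimensions via a seeded random projection of fingerprint on-bits. Both
fallbacks are pure functions of (token, seed constant); externally trained
embedding tables plug in through a token→vector TSV and are queried with the
literal token.

Feature vectors take the top-k enzymes by association score — ties broken by
EC string then protein ID, so the ranking is a total order and row-order
invariant — each encoded as a 1024-d block, padded to k blocks, followed by
the metabolite embedding: k·1024 + 300 features. Instances without a single
scored, EC-annotated enzyme are invalid and excluded, never silently zeroed.

## Models and evaluation

Random forests use 200 trees (the one stated hyperparameter; everything else
is scikit-learn defaults, recorded in run manifests) under stratified 5-fold
cross-validation with seeded shuffling; probabilities are tree-vote
fractions; the selection metric is the median per-fold balanced accuracy.
AUC uses the rank (Mann–Whitney) formulation with midranks, so it is exactly
the concordant-pair probability; scores equal to the 0.5 threshold classify
negative. PPV/F1 are NaN when nothing is predicted positive; MCC is 0 when
its denominator vanishes.

The enzyme-count sweep (default grid 5–120) reuses one fold assignment across
k so rows are comparable. Kernel PCA (cosine, polynomial, RBF, sigmoid,
linear; polynomial degree 3, coef0 1, gamma 1/n_features unless overridden)
is fitted inside each training fold and applied to the held-out fold — no
test leakage; a `global_fit` flag reproduces the fit-once variant. Component
counts are capped by min(training samples, features); component signs follow
a largest-|dual-coefficient|-positive convention so results are deterministic.

The kNN baseline places each training instance at (t, c) — Tanimoto
similarity of metabolite fingerprints, cosine similarity of enzyme encodings
— and ranks by Euclidean distance from the ideal point (1, 1), ties broken by
training index; odd k precludes vote ties. This is one consistent reading of
a combined "Euclidean distance-based similarity" over the two measures;
alternatives (summing similarities) order neighbours nearly identically.

## Consensus and validation scaffolding

The consensus averages complementary class probabilities of the two
directional models (consumption-positive with production-negative, and vice
versa), so both models contribute equally and the two consensus probabilities
sum to 1. Reported probabilities are rounded half-up to two decimals;
outputs always name p_consumption/p_production explicitly rather than relying
on tuple position. Unseen cross-combined negative sets take the metabolites
of one strictly-labelled set against the bacteria of the other, keeping
instances with at least one scored, EC-annotated enzyme. Random background
sets re-pair each experimental instance with a different bacterium drawn
uniformly (seeded) from the pool minus the original, preserving the
metabolite marginal exactly. Enrichment of interactor counts (proteins,
enzymes, role-accepted enzymes) between experimental and background sets uses
the Mann–Whitney U test (midranks, two-sided normal approximation with tie
and continuity corrections; sample sizes here are large enough that the
asymptotic p is accurate).

## Synthetic worlds

`WorldConfig` defaults define the study conditions used by the tests:
48 bacteria × 36 metabolites over 10 chemical categories — a desk-scale
analogue, roughly an order of magnitude below the curated datasets this
emulates; one consuming and one producing 3-field EC prefix per metabolite
with 6 member enzymes each; background repertoires of ~60 enzymes drawn from
a disjoint EC region; pathway adoption probabilities 0.22 (consumption) and
0.12 (production); a pair is labelled when the bacterium carries ≥3 enzymes
under the matching prefix, then flipped with probability `label_noise`
(default 0). Association scores are integer normal draws clipped to
[0, 1000]: N(700, 120) for pathway enzymes against their metabolite,
N(300, 120) for background proteins — wide enough to overlap, far enough
apart that enrichment tests have real signal. Synthetic SMILES are short
valid organic scaffolds per category, so both the fixture engine and RDKit
parse them.

What passing tests show: the pipeline recovers planted enzymatic signal
(median BAC ≥ 0.8 at zero label noise), collapses to chance under label
permutation, and orders RF above the similarity baseline. What they do not
show: performance on real curated data, where labels are noisy and
correlated, enzyme annotations are model predictions with their own error
structure, pathway membership is not cleanly prefix-shaped, and negative
candidates can share high-affinity binders with positives. Absolute
accuracies on synthetic worlds are therefore not forecasts.

## Numerical choices and degenerate inputs

Seeds are explicit everywhere randomness exists (generation, fold shuffling,
per-bin sampling, background re-pairing); fallback encoders hash keys with
BLAKE2 into per-key generator seeds, so outputs are platform-stable. Tanimoto
of two empty fingerprints is 0; cosine against a zero vector is 0; a
single-populated-bin chi-square is (0, 1); empty candidate pools, single-class
label vectors, sub-fold class counts, and oversize component requests raise
errors rather than degrade. Problem sizes in the test suite (worlds of 20–48
bacteria, reaction sets of a few hundred instances, 25–200 trees) were chosen
as the smallest scales at which the planted-signal contrasts are
statistically unambiguous.

## Known limitations

Chemical categories are taken as given (an input column), not inferred;
host-cell removal and taxon-ID mapping of real source databases are assumed
done upstream. The fallback encoders preserve hierarchy and determinism but
not the learned semantics of trained embeddings, so transfer conclusions
require plugging in real embedding tables. Enzyme prediction confidences are
carried through parsing but unused as feature weights, matching the feature
definition. The consensus rule presumes the two directional models are
calibrated comparably; no recalibration is attempted.
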
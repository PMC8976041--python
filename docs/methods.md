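# Methods

`druggability` implements a sequence-only pipeline for classifying
proteins as druggable (able to bind a drug-like small molecule) or
non-druggable: three composition-based feature encoders, boosted-tree
recursive feature elimination, tree-ensemble classification, and a
stratified cross-validation metric suite.

## Feature encoders

All encoders are defined on the canonical 20-letter amino acid alphabet
only; sanitization (case folding, `*` stripping, dropping records with
B/J/O/U/X/Z or gaps under the default `skip` policy) happens before
encoding.

**Amino acid composition (AAC).** The 20 residue frequencies
f_a = count(a)/L. Sums to 1; order-invariant.

**Grouped dipeptide composition (GDPC).** Residues are mapped to five
physicochemical classes — aromatic {W,Y,F}, positively charged {H,K,R},
aliphatic {A,I,M,G,L,V}, uncharged {C,T,P,S,Q,N}, negatively charged
{D,E} — and the 25 ordered adjacent-pair frequencies
f(m,n) = T_mn/(T−1) are reported, row-major in the group order above.
Some listings of this five-class scheme place G in both the aliphatic
and negative classes; a partition requires one membership, and we keep
G aliphatic (the standard convention), leaving {D,E} negative.

**Reduced amino acid alphabet (RAAA).** The Etchebest clusterings
C(5), C(8), C(9), C(11), C(13) recode the alphabet into k clusters:

```
C(5)  = G; IVFYW; ALMEQRK; P; NDHSTC
C(8)  = G; IV; FYW; ALM; EQRK; P; ND; HSTC
C(9)  = G; IV; FYW; ALM; EQRK; P; ND; HS; TC
C(11) = G; IV; FYW; A; LM; EQRK; P; ND; HS; T; C
C(13) = G; IV; FYW; A; L; M; E; QRK; P; ND; HS; T; C
```

For each scheme we compute the k cluster frequencies and the k² cluster
dipeptide frequencies and concatenate the five blocks in ascending k:
Σ(k + k²) = 506 features. Composition alone (46 features) would be too
small a space to select 73 features from, so dipeptide statistics are
part of the descriptor by construction.

**Pseudo amino acid composition (PseAAC) and its segmented variant.**
Type-1 PseAAC extends AAC with λ sequence-order correlation factors

θ_j = (1/(L−j)) Σ_i Θ(R_i, R_{i+j}),  Θ(a,b) = (1/3) Σ_p (p(a) − p(b))²,

where p ranges over standardized hydrophobicity (Tanford-type),
hydrophilicity (Hopp–Woods) and side-chain mass; each property row is
standardized to mean 0 and population (÷20) standard deviation 1 over
the residues. The descriptor is

A_u = f_u / (1 + w Σθ)   (u ≤ 20),   A_{20+j} = w θ_j / (1 + w Σθ),

so the full vector sums to 1. Defaults: λ = 5, w = 0.05 — the
conventional weight, and a λ small enough that every segment of a
50-residue protein remains valid. The segmented variant (S-PseAAC) cuts
the sequence into n_seg contiguous near-equal segments — segment k
covers 1-based positions ⌊(k−1)L/n_seg⌋+1 … ⌊kL/n_seg⌋ — and
concatenates the per-segment PseAAC vectors (default n_seg = 2, giving
2·(20+λ) = 50 features), capturing local composition that the global
descriptor averages away. Every segment must be longer than λ; the
pipeline's minimum-length gate (default 50) is auto-raised to
n_seg·(λ+1) when configured lower.

## Feature selection (XGB-RFE)

A gradient-boosted tree model is fitted on the labeled matrix and each
feature scored by its **total split gain** summed over all trees
(features never split on score exactly 0). The lowest-scoring `step`
features are dropped — ties broken by dropping the larger column index
first, for determinism — and the model refitted, until k features
remain. Selection runs **within each encoder block**, and the retained
blocks are concatenated in the order GDPC, RAAA, S-PseAAC to form the
optimized superset; default per-encoder counts are 17 (GDPC),
73 (RAAA), 36 (S-PseAAC), i.e. a 126-feature superset. The RFE-internal
model uses the same hyperparameters as the final classifier (single
source of truth).

Selection scope is configurable: `per_fold` (the default) refits the
selection inside each cross-validation fold on the training portion
only, which is leak-free; `global` selects once on the whole dataset
before CV, which is cheaper and matches the optimistic protocol some
published benchmarks appear to use, at the cost of an upward bias —
visible on null data, where globally selected features push apparent CV
accuracy somewhat above chance while remaining far from the separable
regime. Monotone containment across k is not guaranteed (RFE refits, so
the k=10 selection need not contain the k=5 one).

## Classifiers

Gradient-boosted trees (XGBoost), random forest, and extremely
randomized trees behind one config. Boosted-tree defaults:
500 estimators, learning rate (eta) 0.1, max depth 8, L2 (lambda) 1,
L1 (alpha) 1; a grid search helper evaluates a hyperparameter grid's
full Cartesian product by stratified-CV mean accuracy (ties broken by
grid order). RF/ERT mirror the 500-estimator count and otherwise use
library defaults, with the same depth cap and seed. Fitting is
single-threaded by default so repeated runs are bit-identical; a
threads knob exists, with the usual caveat that parallel histogram
building can perturb low-order bits. The probability threshold for hard
labels is fixed at 0.5.

## Evaluation

Stratified k-fold CV (default k = 10, shuffled with a fixed default
seed 42) with per-fold and mean±sd reporting of accuracy, sensitivity,
specificity, precision, recall, F-measure, AUC (rank-based, mid-rank
ties) and two Matthews-correlation forms:

* `mcc` — the standard coefficient
  (tp·tn − fp·fn)/√((tp+fp)(tp+fn)(tn+fp)(tn+fn));
* `mcc_alt` — an alternative formulation that circulates in this
  literature, acc/√((1 + err/P)(1 + err/N)) with err = fn+fp. The two
  agree at perfect classification but differ otherwise (0.7035 vs
  0.6538 on tp=40/fn=10/tn=45/fp=5); both are reported so results are
  comparable under either convention, and the test suite asserts the
  difference so the non-standard form is never silently "corrected".

Precision and recall use the standard definitions tp/(tp+fp) and
tp/(tp+fn); some printed variants swap the error terms, which we treat
as typographical. Metrics with a vanishing denominator (e.g. an empty
predicted class) are reported as flagged nulls, never coerced to 0.

## Synthetic data

The generator draws negatives i.i.d. from a background distribution
over the 20 residues (uniform by default; a frequency-table hook
exists) and positives from the same distribution with the enriched set
(default aromatic {W,Y,F}) multiplied by (1+δ) and renormalized;
lengths uniform on [len_min, len_max]. δ = 0 is an exact null — the two
classes share one generating law. Aromatic enrichment is the default
signal because all three encoders can see it (the GDPC aromatic class,
the FYW clusters of every reduced alphabet, the AAC part of PseAAC).
The generator validates machinery, not biology: uniform backgrounds,
i.i.d. residues and single-marginal enrichment say nothing about
performance on real druggable-protein sets, where signal is weaker,
compositional confounders exist and homology structures the classes.
Passing tests demonstrate that the pipeline recovers a known signal and
stays at chance on a true null — not that the headline accuracies on
any external benchmark will be reproduced.

## Problem sizes and numerical choices

* End-to-end checks run on 250+250 sequences of length 50–300 with
  δ = 5 (separable) and δ = 0 (null), tenfold CV, global selection
  scope with step 25 on the 506-wide RAAA block — our chosen
  study-scale configuration; defaults elsewhere remain step 1 and
  per-fold scope.
* Selection recovery uses 10 unit-variance Gaussian features shifted by
  1.0 in the positive class among 90 noise features, n = 400, step 1.
* Sum-to-one and oracle-equivalence invariants are checked to 1e-9 over
  1000 seeded random sequences.
* All randomness flows from explicit integer seeds (sequence
  generation, fold shuffling, tree fitting); identical config + seed
  reproduces reports byte-for-byte.

## Known limitations

* The full pre-selection S-PseAAC dimensionality depends on (λ, n_seg);
  the defaults give 50 features, from which 36 are selected.
* `mcc_alt` is reported as printed in parts of the literature, without
  claiming it estimates the Matthews correlation.
* Benchmark-grid replication on external FASTA data reports tables only;
  no accuracy assertions are made there (unknown seeds and selection
  scope in the published protocols).
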
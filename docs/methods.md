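# Methods

## Problem and model

Given a query protein known by UniProtKB accession, by amino-acid
sequence, or by both, the predictor assigns it a non-empty set of
subcellular locations out of an M-class catalog. The signal is purely
annotation-based: proteins sharing a location tend to be annotated with
similar sets of GO terms, across all three ontologies (cellular
component, biological process, molecular function — component terms
alone are unreliable because many proteins lack them or carry
inconsistent ones).

**GO-term retrieval.** Three input cases are handled. (1) Accession
only: the accession is the single search key into the GO-annotation
(GAF) table. (2) Sequence only: the accessions of the top *n* BLAST
homologs are the keys (n ∈ {1, 2, 4, 8} are the conventional settings;
*n* = 1 is the default and usually the best). (3) Both: the true
accession followed by the *n* homolog accessions, giving *n* + 1 GO
term multisets. A key with no annotation contributes a zero vector; a
sequence-only query with no homologs at all yields a single zero
vector. For novel proteins an optional *cascade* walks down the homolog
ranking until an annotated accession is found.

**Feature space.** The T distinct GO terms seen across the training
keys span the feature space (GO subspace selection: query terms outside
it are dropped, which keeps T in the hundreds instead of the full
ontology's tens of thousands). Coordinates are either binary GO hits or
term frequencies; TF is the default because occurrence counts carry
class information that 0/1 quantization discards. Terms are ordered
lexicographically so models are reproducible; no normalization is
applied by default (an optional L2 flag exists).

**Classifier.** M one-vs-rest soft-margin SVMs with transformed labels:
a protein is one training instance per resolved accession key, carrying
+1 for each of its locations and -1 elsewhere. It is never duplicated
per class — duplication would place identical patterns on both sides of
a margin. The per-key SVM scores of a query are fused with convex
weights (uniform over the keys present: w_0 = 1 for case 1, 1/n for
case 2, 1/(n + 1) for case 3), and the decision rule predicts every
class with a positive fused score, falling back to the single argmax
class otherwise — so predictions are never empty, and the *number* of
locations is decided by the whole ensemble rather than by a nearest
neighbor or a fixed threshold.

**Lookup baseline.** The direct table-lookup predictor matches a
query's GO-term set against per-class *essential* cellular-component
terms first, then against their direct is_a/part_of *child* terms
("occurs in" children are excluded as biological-process terms). All
classes matched in the winning tier are returned; matching neither tier
is an explicitly distinct "unpredictable" outcome. The packaged table
covers the six viral-protein locations (7/20/5/2/2/3 explicit terms per
class). The baseline's tendency to over-predict — a term set whose
explicit terms span more classes than the protein truly occupies — is
the motivation for the learned classifier.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| kernel | linear | K(x,y) = ⟨x,y⟩; high-dimensional sparse counts are near-linearly separable, and nonlinear kernels overfit when T exceeds the number of training vectors |
| C | 0.1 | soft-margin penalty, used for all kernels |
| σ (RBF) | — | width in K = exp(−‖x−y‖²/(2σ²)); conventional grid {2⁻², …, 2⁵} |
| d (polynomial) | — | degree in K = (⟨x,y⟩+1)^d, d ∈ {2, 3} |
| n_homologs | 1 | homolog keys in sequence modes; more homologs add noise faster than signal |
| vector_mode | tf | term-frequency vs binary coordinates |
| rebuild_subspace | true | rebuild T per LOOCV fold (no term-identity leakage); `false` freezes one global subspace, which is cheaper and is provided because either protocol is defensible |
| train_fused | false | train on per-key instances (default) or on each protein's weight-fused vector |

Eq.-level convention: the per-class bias sits inside the weighted key
sum; since the weights sum to one it contributes exactly b_m once.
Argmax ties in the fallback are broken toward the smallest class index.
A class with no positive (or no negative) training instances becomes a
constant minus-infinity stub: it can never be predicted positively and
only wins the fallback if every class is a stub, which is a training
error instead.

## Evaluation

N_act counts each protein once, N_loc once per (protein, location)
pair: N_act = Σ_m n_act(m), N_loc = Σ_m m·n_act(m). Locative accuracy
Λ_loc = Σ_i |ℳ(p_i) ∩ ℒ(p_i)| / N_loc credits partial matches and is
inflated by over-prediction (predicting all M classes for everything
gives Λ_loc = 1); actual accuracy Λ_act is the exact-set-match fraction
and scores that degenerate predictor at 0 whenever no true set is the
full catalog. Reports include per-class locative accuracies, the
over/equal/under-prediction distribution of |ℳ| − |ℒ| (buckets
partition N_act; *equal* is size-based, so a wrong same-size guess
still counts as equal-predicted there while failing Λ_act), and
per-multiplicity actual accuracies (strata with no proteins are
reported as absent, not 0/0). Accuracies are kept as exact rationals
alongside floats. Predicted sets from the SVM are never empty, but the
evaluator tolerates empty/None predictions (scored as under-prediction,
no exact match) so the lookup baseline's unpredictable proteins can be
scored.

Leave-one-out cross-validation iterates over *actual* proteins: each of
the N proteins is held out once and predicted by a model trained on the
other N − 1 (iterating over locative copies instead would put identical
vectors on both sides of a margin).

## Synthetic data: what it emulates and what it does not

The generator gives each class a block of `signature_terms_per_class`
signature GO terms (consecutive classes can share `signature_overlap`
of them); a protein is annotated with the union of its classes'
signatures, each kept term with occurrence count 1 + Poisson(depth − 1)
where the depth may differ by class so that counts themselves carry
signal. `noise_rate` degrades realism in both directions: each
signature annotation is dropped with that probability, and each term of
a disjoint noise pool is added with it. Homolog accessions carry copies
of the protein's annotation in which each signature term survives with
probability `homolog_fidelity`; homologs are emitted as BLAST outfmt-6
rows (self-hit included) so the real parsers run end to end. Label
multiplicities follow a configurable distribution, or exact counts for
the packaged virus-shaped fixture (M = 6, N = 207, 165/39/3 proteins
with 1/2/3 labels — the bookkeeping shape of the classic viral
benchmark). Everything derives from per-entity RNG substreams keyed by
a stable hash of the accession plus the user seed, so output is
byte-reproducible and order-independent.

What passing on synthetic data shows: the pipeline recovers multi-label
structure from term co-occurrence and multiplicity, degrades gracefully
with noise, and the TF representation dominates binary exactly when
depth varies by class. What it does not show: performance on real GOA
annotations, whose term usage follows the GO DAG, is evidence-code
biased and wildly non-uniform across proteins; synthetic sequences are
random strings and BLAST is never actually run, so homology realism is
limited to rank/score structure.

## Numerical choices and problem sizes

The per-class quadratic programs are solved by scikit-learn's SVC;
duals, support vectors and intercepts are extracted into a
self-contained JSON-serializable model whose kernels this package
evaluates itself (the linear weight-form and dual-form scores agree to
1e-9, which the tests assert against an independent primal hinge-loss
minimization). Statistical property tests (noise monotonicity,
TF-vs-binary) run LOOCV over 5 seeds on reduced datasets (N = 90,
M = 4), a size chosen to estimate means stably while keeping the suite
quick; the separability recovery check runs at the fixture's full
N = 207. Fusion weights must sum to 1 within 1e-12; GO subspace files,
label TSVs, homolog maps and predictions are all plain text.

## Known limitations

* No GO-DAG reasoning: ancestor/descendant relations are ignored except
  for the precompiled child terms of the lookup table.
* No qualifier/evidence-code filtering by default (an `exclude_not`
  flag exists); annotation quality is taken at face value.
* No probability calibration and no class weighting for imbalance;
  scores are raw SVM margins.
* A query whose keys are all unannotated is decided by biases alone
  (flagged `zero_vector`); a sequence-based backup predictor is out of
  scope, though a cascade over homolog ranks mitigates the common case.
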
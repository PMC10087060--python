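# Methods

## The prompting scheme

A single-step retrosynthesis translator maps a product SMILES to a
precursor SMILES (reactants and reagents merged, "."-joined). Cluster-token
prompting prepends one extra vocabulary item `[i]`, i ∈ [0, X), to the
tokenized product during training, where i names the reaction's class or
cluster. At inference the product is duplicated X times, once per token
(fan-out), and the per-token ranked predictions are merged into a single
list. The token acts as a soft conditioning term: it steers the decoder
toward disconnections typical of class i without forbidding anything, so
inapplicable prompts degrade gracefully into invalid predictions rather
than failures.

Three token sources are implemented:

* **superclass** — the leading integer of a hierarchical dotted reaction
  class code (12 superclasses, 0 = unrecognized … 11 = resolutions). X = 12.
* **random-group** — a seeded balanced random partition of the 12
  superclasses into X groups (group sizes differ by at most one). This is
  the ablation separating "any grouping" from "a chemically meaningful
  grouping".
* **kmeans** — unsupervised tokens for corpora without class labels:
  reaction fingerprints are mean-centered, projected onto the top-p
  principal components, and clustered with K-means; the cluster id is the
  token.

### Fingerprints

The default provider is a *structural difference fingerprint*: hashed
circular (Morgan) substructure counts of the product minus the summed
counts of the precursors, radius 2, width d = 256 counts. Chain
environments shared by product and precursors cancel, so the vector
concentrates on the reaction center, which is what the clustering should
see. The provider interface (`register_fingerprint_provider`) accepts any
record → vector function, so a learned reaction fingerprint can be plugged
in without touching the PCA/K-means/token code; the default was chosen
because it is deterministic, dependency-light and reproducible offline.

### PCA and K-means choices

PCA uses mean-centering without variance scaling (the inputs are counts on
a common scale). K-means defaults: 10 restarts (best inertia wins), 300
iteration cap, relative tolerance 1e-6, Lloyd's algorithm, explicit seed —
determinism is required because token identity must be stable between
training-data preparation and inference.

The cluster count is chosen from the inertia-vs-k curve. The classical
procedure is visual; `elbow_select` automates it with the discrete second
difference: k_opt = argmax_k [I(k−1) − 2 I(k) + I(k+1)], i.e. the point
where the decrease slackens most. An elbow-strength score (that second
difference divided by the total inertia drop) is reported so a flat curve —
no real cluster structure — is recognizable, and the full curve is always
exported for human confirmation. Within the scanned range the curve is
guaranteed non-increasing: if the best-of-restarts fit for k+1 lands above
the fit for k (a local-optimum artifact), the k+1 fit is warm-started from
the k-solution's centroids plus the worst-fit point, which can only lower
the inertia.

## Data cleaning

Rules run in a fixed order and each removal is attributed to the first rule
that fires, which makes the report counts well-defined and the pipeline
idempotent (cleaning its own output removes nothing):

1. unparsable reactions dropped; all molecules canonicalized; precursors
   become a set (patent stoichiometry is unreliable);
2. product-side molecules that also appear among the precursors are removed
   (residual reagents); anything still multi-product (or left empty) is
   dropped;
3. products containing an element absent from every precursor are dropped
   (mass balance cannot hold);
4. single-atom products dropped;
5. reactions where the net formal charge of either side exceeds 2 in
   absolute value are dropped. The charge bound is applied per side — the
   strictest symmetric reading — and both readings (per-side vs
   per-molecule) are defensible; the report makes the choice auditable;
6. reactions where either side exceeds 500 SMILES tokens are dropped. The
   bound is applied per side, not to the sum;
7. exact duplicates dropped (first occurrence kept);
8. groups sharing one canonical precursor set but conflicting products are
   dropped entirely (contradictory labels).

Two-group reaction strings `A>C` are accepted on ingestion as reagent-free
reactions and normalized immediately to the merged-precursor form.

The SMILES token grammar (bracket atoms, two-letter halogens, `%NN` ring
closures, all single structural characters) is pinned in one constant,
`SMILES_TOKEN_PATTERN`, with round-trip tests: `"".join(tokenize(s)) == s`.

Splits are seeded permutations with floor-sized validation/test sets and
the remainder in train, so the stated test/validation proportions are never
exceeded at the expense of training data; empty splits warn.

## Merging fan-out predictions

With topk predictions retained per token, the merged list holds up to
X·topk entries ordered rank-major, token-minor: every token's rank-1
prediction precedes any rank-2 prediction. Consequently the first X entries
of the merged list are exactly the X conditioned top-1s — the set whose
diversity the prompting scheme is designed to maximize. How to interleave
ranks globally is genuinely open (per-prompt model scores are not
comparable across prompts); rank-major is this package's documented choice.
Duplicate predictions across tokens are kept: collapsing them is the job of
the class-diversity metric, which counts distinct classes among *valid*
predictions only.

## Metrics

All molecule and set equality anywhere in the package is equality of
canonical SMILES (sets compared as sorted canonical forms). Top-n accuracy
demands the exact full precursor set, so a correct disconnection with a
different reagent counts as a miss — the strict reading, which is why
round-trip accuracy (forward-model recovery of the product) is the more
informative validity notion. RT_k keeps the fixed N·k denominator; samples
with fewer than k predictions contribute zero for missing ranks. CD_k uses
classes from a classifier applied to the predicted reaction (never
ground-truth labels): a prediction the classifier cannot name while being
valid is a data error, not a silent zero.

Expected shapes: CV and CD are non-decreasing in k and CV_k ≥ RT_k always;
RT typically *decays* with k for conditioned models because later ranks
include predictions under inapplicable prompts.

## Toy chemistry

The synthetic corpus exists to exercise every pipeline stage and the
diversity mechanism exactly, not to be chemically realistic. Molecules are
unbranched chains: alkyl segments (1–3 carbons by default) joined by 1–3
linkers drawn from six template families — ester `C(=O)O`, amide `C(=O)N`,
ether `O`, thioether `S`, secondary amine `N`, thioester `C(=O)S`. All
edits are string templates over these guaranteed-valid linear SMILES; RDKit
is used only to recover the linear form from an arbitrary (e.g.
canonicalized) spelling of the same molecule, so the oracles are
insensitive to how a SMILES is written.

* `generate_dataset(params)` samples, per reaction, the linker count, the
  families (by the class-imbalance weights), and segment lengths; the
  recorded reaction forms one linker of the weight-sampled family, and the
  recorded precursors are that family's first disconnection site — so the
  ground truth coincides with the conditioned top-1 for the matching token.
  Defaults: 500 reactions, T = 4 families, uniform weights, seed 0.
* `oracle_retro` splits the product at the prompted family's linkers, left
  to right; an inapplicable prompt returns the product itself as a
  deliberately invalid guess (the forward oracle rejects single-molecule
  "reactions", giving a clean validity notion).
* `baseline_retro` models the majority-class bias of an unconditioned
  model: it only ever disconnects the lowest-indexed applicable family,
  cycling its sites to fill the requested n — so its class diversity is 1
  by construction.
* `oracle_forward` / `oracle_classify` detect each precursor's functional
  role (acid, alcohol, amine, thiol, bromide) from its backbone terminals;
  the role pair identifies at most one family, whose template reassembles
  the product.

These definitions yield exact closed forms used in the tests: on any
generated set where product i admits A_i applicable families, the
conditioned pipeline over all T tokens with topk = 1 attains CV_T = 1,
RT_T = mean(A_i)/T and CD_T = mean(A_i), while the baseline attains CD = 1;
the diversity gap is mean(A_i) − 1 ≥ 0. This reproduces the direction and
mechanism of the diversity boost that prompting delivers on real corpora —
higher class diversity at lower round-trip accuracy — at desk scale.

What the toy world deliberately lacks: rings, branches, stereochemistry,
competing regiochemistry, reagents/solvents, noisy labels, and any model
uncertainty (the oracles are exact). Passing tests therefore validate the
*bookkeeping and the metrics*, not chemical prediction quality; conclusions
about a real corpus require plugging a trained translator into the
`fanout` → `evaluate` interface.

## Problem sizes and determinism

The default experiment and the test suite run on 150–1000 generated
reactions, fingerprint matrices of width 256, and K-means instances of at
most a few hundred points — sizes chosen so that a full end-to-end run
completes in seconds while every metric identity is still exercised
exactly. All randomness (generation, splits, groupings, K-means restarts)
flows through explicit integer seeds; rerunning any stage with the same
config is byte-identical.

## Known limitations

* The kmeans token mode guarantees tokens in [0, X) but not that every
  cluster is populated on new data.
* The cleaning report attributes each removal to the *first* matching rule;
  totals per rule are therefore order-dependent (the order is fixed and
  documented).
* `superclass` mode assumes single-product corpora with dotted class codes
  whose leading field is 0–11; other taxonomies need a custom scheme.
* The toy oracle treats the prompt token as the family id itself; a fitted
  kmeans scheme's cluster ids coincide with families only up to relabeling,
  which is irrelevant for the metrics (fan-out covers all tokens) but means
  per-token curves are not comparable across schemes.
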
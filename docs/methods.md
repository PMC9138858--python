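# Methods

This note records the model as implemented, the defaults and why they
were chosen, what the synthetic-data generator does and does not
emulate, and the numerical and design decisions that were genuinely
open.  All empirical statements below are quantities the test suite or
`scripts/acceptance.py` computes.

## Model and assumptions

The predictor treats miRNA–disease association as bipartite link
prediction.  Its core assumption is guilt by association: the
probability of a link (m, d) is predictable from how similar m is to
miRNAs already linked to diseases similar to d.  Similarity enters
through five sources — two computed from the association matrix itself
(GIP kernels `GM`, `GD`), and three from side information (functional
similarity `MF`, DAG-based semantic similarity `DS`, and the MeSH
network embedding `DM`).  Side sources are generally *partial*: a miRNA
may be absent from the functional-similarity matrix, a disease may lack
a MeSH heading or a DAG.  The fusion cascades (`MF`→`GM` for miRNAs;
`DM`→`DS`→`GD` for diseases) resolve every entry because the GIP
kernels are total by construction.  Each entry's provenance is kept in
a `source_map`, which both the tests and the evaluation report use.

A pair is represented by concatenating the miRNA's fused similarity row
and the disease's fused similarity row (width = #miRNAs + #diseases).
This is the de-facto convention in the miRNA–disease association
literature; the width therefore tracks cohort size, which is why the
autoencoder's role is dimensionality reduction.  No element-wise or
Kronecker pair encodings are provided.

One property of this family of methods deserves emphasis: the GIP
kernels are computed from the *full* association matrix, including
pairs that are later held out as test cases.  The held-out entries
therefore influence the features.  This mirrors the standard protocol
of the field and is deliberate; the label-permuted control quantifies
how much of the measured performance survives when the labels are
decoupled from the features.

## Parameters that matter

| parameter | default | meaning / rationale |
|---|---|---|
| GIP bandwidth form | `reciprocal` | δ = 1/((1/m)Σ‖profile‖²), the conventional GIP normalisation; `printed` selects the non-reciprocal variant δ = (1/m)Σ‖profile‖², under which the kernel narrows as the network densifies |
| Δ (semantic decay) | 0.5 | conventional value in the semantic-similarity literature; contribution of an ancestor k generations up is 0.5^k |
| LINE dim / order | 64 / first | first-order proximity is the pipeline default because MeSH-derived relational networks are forests: they contain no triangles, so second-order (shared-neighbour) proximity degenerates there; a regression test pins that first-order embedding similarity tracks the planted disease similarity more faithfully than second-order on a synthetic forest. `line_embed` itself defaults to second order, the embedding method's usual default, for callers embedding general graphs |
| LINE sampling | 5 negatives, lr 0.025 linearly decayed, |E| edge samples per epoch, 1000 epochs, capped at 2·10⁶ samples | the cited method's small-scale settings; negatives drawn ∝ degree^0.75 |
| AE widths | (512, 256, 128, 64, 128, 256, 512) | palindromic with a unique 64-wide rectified bottleneck; untied encoder/decoder weights |
| AE optimiser | Adam, lr 10⁻³, 50 epochs, batch 128 | longer training narrows but does not close the gap to the no-autoencoder pipeline while multiplying runtime, so 50 is kept |
| GBT | 500 trees, depth 6, lr 0.1, λ=1, γ=0 | exposed XGBoost surface; planted-world performance is insensitive to the tree count, depth and subsampling settings explored |
| CV | 5 stratified folds, threshold 0.5, negatives fixed once | stratification prevents degenerate folds at small n; a non-stratified mode and per-fold negative resampling are flags |

`smmda.autoencoder.fit_architecture` halves the layer stack until the
bottleneck is narrower than the input, so the CLI works on cohorts
smaller than the default architecture; the library itself refuses
inputs narrower than the configured bottleneck.

## Leakage policy

The autoencoder and the classifier are fit per training fold, never on
the full dataset (the conservative reading of an upstream protocol that
is silent on the point).  Each cross-validation fold's provenance
record stores the train/test index sets and the scope every stage was
fit on, and a test asserts the guard.  The similarity matrices are
computed once from the full association matrix, as discussed above.

## The synthetic world

`generate_world` plants a single latent structure that all features
share, so similarity is genuinely informative about held-out links:

* latent factors U (miRNAs×r), V (diseases×r), standard normal;
* associations sampled independently with P(link) = σ(α + uᵢ·vⱼ), the
  intercept α calibrated by bisection to the target density;
* functional similarity = shifted cosine of U rows, restricted to a
  coverage fraction of miRNAs;
* a MeSH-like forest grown by similarity-guided attachment: each new
  disease attaches under an existing one sampled ∝ exp(12·cos(vᵢ, vⱼ)),
  which makes tree distance reflect latent similarity (three roots,
  tree numbers valid under the `[A-Z][0-9]+(.[0-9]+)*` grammar);
* chain DAGs derived from the tree numbers for a `dag_coverage`
  fraction of diseases; the exported MeSH table is then shrunk to the
  `dm_coverage` fraction by repeatedly dropping random *leaves*, so the
  survivors stay closed under parenthood and the heading graph does not
  fragment, while diseases with a DAG but no table entry exercise the
  semantic branch and diseases with neither exercise the GIP branch.

Defaults are the evaluation's study conditions: 120 miRNAs, 90
diseases, rank 5, density 0.07, 60% functional coverage, 70% MeSH
coverage, 90% DAG coverage.

What the generator does **not** emulate: HMDD's heavy-tailed degree
distribution, real MeSH topology (multiple tree numbers per heading,
cross-category placement), miRNA family structure, or annotation bias.
Passing tests therefore show that the pipeline's machinery is correct
and that it extracts planted signal; they do not certify performance on
curated biological databases.

## What desk-scale worlds can show — a measured ceiling

`scripts/acceptance.py` reports, alongside the pipeline's
cross-validated metrics, two diagnostic ceilings computed on the same
pair set: `latent_oracle_auc_pct`, the AUC of scoring pairs by the true
latent logits uᵢ·vⱼ (~0.9; the remainder is irreducible Bernoulli
sampling noise), and `true_similarity_ceiling_auc_pct`, the AUC of the
row-concatenation representation fed the *true* latent cosine
similarity matrices instead of the estimated ones (~0.82-0.83 at this
sample size of ~1600 pairs — gradient-boosted trees must reconstruct a
bilinear interaction between the two feature blocks from few
examples).  The honest full pipeline lands between the label-permuted
control (~0.5) and that representation ceiling, typically ~0.70-0.73,
because the partially-covered side features *replace* kernel entries
that carry the held-out links themselves (the fusion cascades
substitute rather than concatenate).  At database scale (tens of
thousands of pairs, ~1900-wide features) this architecture family is
reported far higher; the gap is a property of sample size and feature
fidelity, not of the implementation, which is why the acceptance
script reports measured values rather than asserting scale-transferred
ones.

## Numerical choices and degenerate inputs

* Similarity matrices are validated symmetric to 1e-9; the semantic
  similarity ratio is clamped at 1.0 against float roundoff.
* An all-zero profile set makes the GIP bandwidth undefined: a
  degenerate-input error, not a silent default.
* A miRNA with an empty disease set gets an *undefined* (masked)
  functional-similarity row — including its diagonal — so fusion falls
  back to the GIP kernel rather than asserting self-similarity 1 for
  an entity with no evidence.
* Zero embedding vectors yield masked `DM` entries, not exceptions;
  isolated headings keep their random initial vectors but are masked.
* MCC with a zero denominator is reported as 0 with a warning.
* Ranking ties are broken by miRNA name, ascending.
* All stochastic stages (world sampling, negative sampling, fold
  shuffling, LINE SGD, autoencoder init and batching, XGBoost) are
  deterministic given their seeds at a fixed thread count (n_jobs=1).

## Known limitations

* Disease names are matched to MeSH headings by exact (case-folded)
  string equality; misses simply fall through the fusion cascade.
* The MeSH relational network treats tree-number parenthood as a
  single undirected edge type; sibling or co-category relations are
  not modelled.
* Functional-similarity recomputation implements plain best-match
  averaging without disease-group weighting variants.
* The LINE implementation is a compact edge-sampling SGD intended for
  graphs up to a few thousand nodes, not a large-scale implementation.
* Alternative embeddings (DeepWalk, SDNE, HOPE, Laplacian eigenmaps)
  and competitor models are out of scope.
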
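# Methods

## Problem and model

`mdfuse` treats miRNA–drug resistance (MDR) and miRNA–drug sensitivity
(MDS) association prediction as two independent binary link-prediction
tasks on a bipartite graph: known associations are positives, and
unobserved miRNA×drug pairs form the candidate negative pool. The model
assumes that association propensity is predictable from the two entities'
molecular content alone — the miRNA's nucleotide sequence and the drug's
2-D molecular structure — which is what allows it to score entities with
no known associations (the cold-start setting). It does not use
association-graph topology as an input feature.

Each entity receives two embeddings of the working dimension d:

* a **global** embedding from a frozen pretrained language model (PLM):
  the summary token (row 0 of the token matrix, the [CLS] convention) of
  a 640-dimensional RNA model for miRNAs or a 384-dimensional chemical
  model for drugs, adapted by a trainable affine+ReLU projection head.
  Backends are frozen feature extractors; no gradient flows into them.
* an **intrinsic** embedding from a trainable task-specific encoder:
  a multi-scale CNN over the sequence for miRNAs, a three-layer GCN over
  the heavy-atom molecular graph for drugs.

The two are fused per entity by bidirectional multi-head cross-attention
(residual + LayerNorm per direction, directions summed). Pair scores come
from a two-layer feed-forward head (ReLU, dropout, sigmoid) on the
concatenated fused embeddings, trained with mean binary cross-entropy.

## Parameters that matter

| parameter | default | notes |
|---|---|---|
| embedding dimension dm = dr | 128 | working width of all fused vectors |
| attention heads H | 4 | d_k = 128/4 = 32; H must divide d |
| CNN kernel sizes | 2, 3, 4 | di-/tri-/tetra-nucleotide motif scales |
| CNN channels per branch | 64 | concatenated to 192 before projection |
| nucleotide embedding width | 32 | shared across branches |
| sequence length | 24 nt | truncate (keep 5' prefix) / pad at 3' end |
| GCN widths | 128, 128, 128 | last width = dr, so no readout affine |
| head | 256 → 128 → 1 | ReLU + dropout 0.3, sigmoid output |
| learning rate / weight decay | 5e-4 / 5e-4 | Adam, decoupled weight decay |
| epochs | 100 | no early stopping |
| batch size | 0 (full batch) | see "Numerical choices" |
| negative:positive ratio | 1:1 | uniform over non-positive pairs |

## Evaluation protocols

* **5-fold CV**: negatives are sampled once globally, then positives and
  negatives are split together (stratified by default), so a test
  negative is never a training pair under any fold. Metrics are computed
  per fold and averaged; a pooled mode is available.
* **Cold start**: test entities are drawn from an intermediate band of
  positive degree (degree counted over positive associations only);
  every labeled pair touching a band entity is test, the complement is
  training, so no test-side entity occurs in training. Test negatives
  are the globally sampled negatives touching band entities, which under
  the 1:1 global ratio keeps the test set approximately balanced.
* **Case study**: one entity is masked as novel, its pairs removed from
  training; after retraining, every counterpart entity is scored against
  it and ranked (ties broken lexicographically by id).

AUC is computed by the tie-aware rank statistic (equivalent to the
pairwise Mann–Whitney count with half-credit ties). AUPR is average
precision with tied scores collapsed into a single threshold step; the
step estimator is used instead of trapezoidal interpolation because the
latter is optimistically biased on precision–recall curves.

## Synthetic benchmark

The generator emulates the structure of curated association data at desk
scale: 100 miRNAs of 18–24 nt, 30 template-grammar drugs (SMILES ≤ 100
characters, parseable by construction), sparse positives with long-tailed
drug degrees. Signal is planted in the *intrinsic* channels: exactly half
the miRNAs carry the motif `UGCAUGG`, exactly half the drugs contain a
pyridine ring, and a pair is positive with probability base + β (default
0.05 + 0.8) when both are carriers, base otherwise, with 2% label flips.
Exact-count carrier allocation keeps fixture tests deterministic.

The mock PLM backend hashes (token, position, seed) to normal deviates:
deterministic across platforms, consistent per input, but carrying no
chemistry. Learnability on this benchmark therefore demonstrates that the
intrinsic encoders and the fusion/optimization machinery work — it says
nothing about the quality of real PLM embeddings, real sequence–activity
relationships, or dataset biases in curated association databases. The
planted rule also caps attainable accuracy: with β = 0.8 and base 0.05
the Bayes-optimal 5-cv AUC on this benchmark is roughly 0.87–0.90, which
is the regime the reported ~0.87 sits in.

Default problem sizes were chosen so that the complete test suite and the
acceptance script each run in minutes on a single CPU: 100×30 entities
(~1600 labeled pairs at 1:1 balance) for protocol-level results, and a
20×8 fixture for mechanics tests.

## Numerical choices

* **Autodiff**: all neural components run on a compact in-package
  reverse-mode engine over float64 NumPy arrays. Gradient correctness is
  pinned by central finite-difference tests (1e-4 relative error).
* **Full-batch default**: every optimization step re-encodes all
  entities (CNN, GCN, fusion), so with minibatches an epoch costs one
  encoder pass per batch. Full-batch training makes an epoch a single
  encoder pass — about an order of magnitude faster on CPU at these
  problem sizes — and reaches the same held-out AUC within the epoch
  budget (0.870 full-batch vs 0.874 with batches of 128 on the reference
  benchmark fold). `batch_size` remains configurable for larger data.
* **Probability clipping**: pair probabilities are clamped to
  [1e-12, 1−1e-12] at the sigmoid output (the contract is an open
  interval; float64 sigmoid saturates beyond |logit| ≈ 37) and to
  [1e-7, 1−1e-7] inside the loss.
* **Masked CNN pooling**: convolution windows whose receptive field lies
  entirely in padding are excluded from the global max, and the padding
  token's embedding row is masked to zero, so sequence length never
  leaks through padding artifacts.
* **Attention value projection**: the shipped default uses a distinct
  W_V per standard attention. The formulation this model family derives
  from reuses the key projection for values; `strict_attention_v=True`
  ties V to W_K to reproduce that variant exactly.
* **Determinism**: one seed drives negative sampling, fold shuffling,
  weight initialisation, batch order and dropout; the mock backend's
  seed is part of the backend spec (frozen extractor semantics), so
  changing the training seed does not change the "pretrained" features.
* **Ties**: ranking ties in case-study lists break lexicographically by
  entity id; metric ties are handled as described above.
* **Degenerate inputs**: single-atom graphs are valid (Â = [[1]]);
  empty sequences, unparseable SMILES (error carries the drug id),
  single-class metric inputs, empty degree bands, and leakage-corrupted
  split plans all raise typed errors rather than producing numbers.

## Open design points resolved here

* The projection "FCNN" is a single affine+ReLU layer (minimal reading;
  depth is not specified by the model family).
* [CLS] is operationalised positionally as row 0 of the token matrix,
  independent of any tokenizer vocabulary.
* Truncation keeps the 5' prefix; global max is used for CNN pooling.
* The atom featurizer vocabulary is fixed and versioned
  (`FEATURIZER_SPEC`): atom type {C,N,O,S,F,Cl,Br,I,P,other},
  hybridization {sp, sp2, sp3, other}, degree 0–5, formal charge −2..+2,
  hydrogen count 0–4, radical electrons 0–2, aromaticity flag; every
  categorical block carries a reserved out-of-vocabulary slot. Hydrogens
  are implicit (heavy-atom graph).
* MDR and MDS are fully independent tasks; entities occurring in both
  are re-indexed per task.
* Cold-start evaluation reports per-seed results; repetition over seeds
  is the caller's loop.

## Known limitations

* Real RNA/chemical language-model checkpoints are consumed through the
  backend contract but not bundled; with the mock backend the global
  channel is an entity fingerprint, not transferable knowledge.
* No similarity-aware (cluster) splits: cold-start entities may still
  have near-duplicate neighbours in training.
* The GCN ignores bond features and 3-D geometry; the CNN sees at most
  24 nt.
* Transductive 5-cv on bipartite data lets entity-level regularities
  (e.g. degree) contribute to test performance; the cold-start protocol
  is the honest estimate for novel entities.
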
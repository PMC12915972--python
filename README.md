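# mdfuse

Cross-modal fusion models for predicting **miRNA–drug resistance and
sensitivity associations**.

MicroRNAs modulate how cancer cells respond to anticancer drugs, acting as
drivers of both chemoresistance and drug sensitivity. Screening candidate
miRNA–drug pairs experimentally is slow and expensive, so link-prediction
models that rank unobserved pairs are used to prioritise laboratory work.
`mdfuse` is a library and command-line tool for researchers building and
evaluating such models: it predicts, for a given miRNA and drug, the
probability of a resistance (or, as an independent task, sensitivity)
association.

## Model

Each entity is represented by two complementary embeddings of a common
working dimension *d* (default 128):

* **Global language-model channel.** A frozen pretrained language model
  embeds the raw string — an RNA foundation model maps a miRNA sequence to an
  *L*×640 token matrix, a chemical language model maps a SMILES string to an
  *L*×384 matrix. The summary ([CLS], first-row) token is extracted and
  adapted by a trainable affine+ReLU projection head:
  Z<sup>p</sup> = FCNN(PLM(S)[0]). Backends satisfy a small contract
  (`plm_backend`), so real checkpoints and the shipped deterministic mock
  backend are interchangeable; embeddings can be precomputed into an on-disk
  cache.
* **Intrinsic channel.** For miRNAs, a multi-scale CNN over the nucleotide
  sequence (standardised to 24 nt): a shared trainable nucleotide embedding
  feeds parallel convolution branches with kernel sizes {2, 3, 4}, each
  ReLU-activated and globally max-pooled over valid (non-padding) windows,
  then concatenated and projected to *d*. For drugs, a three-layer GCN over
  the RDKit heavy-atom graph, X<sup>(l+1)</sup> = ReLU(Â X<sup>(l)</sup>
  W<sup>(l)</sup>) with Â = D̂<sup>−1/2</sup>(A+I)D̂<sup>−1/2</sup>, read out
  by summed mean- and max-pooling over atoms.

The two channels of each entity are fused by **bidirectional multi-head
cross-attention**: with H heads of width d<sub>k</sub> = d/H, one block
computes softmax(QK<sup>T</sup>/√d<sub>k</sub>)V per head from
queries of one modality and keys/values of the other, concatenates heads,
projects, and applies a residual connection with layer normalisation; the
fused embedding is the sum of the two directed block outputs,
Z = Z<sup>ps</sup> + Z<sup>sp</sup>. A pair (i, j) is scored by a
feed-forward head on the concatenated fused embeddings,
ŷ<sub>ij</sub> = σ(FCNN(Z<sub>m,i</sub> ‖ Z<sub>r,j</sub>)), trained with
mean binary cross-entropy using Adam (learning rate and weight decay 5e-4).

Evaluation follows three protocols: balanced negative sampling with 5-fold
cross-validation; degree-banded **cold-start** splits in which every pair of
a held-out drug (or miRNA) is unseen during training; and a **case-study**
mode that masks one entity as novel, retrains, and ranks every counterpart
against it. Metrics are AUC (tie-aware Mann–Whitney) and AUPR (average
precision with tied scores grouped per threshold). Six ablation switches
drop either channel for either entity type to quantify each modality's
contribution. All neural components run on a small NumPy reverse-mode
autodiff engine included in the package; no GPU is required.

## Worked example

A synthetic benchmark with a planted signal — half the miRNAs carry a fixed
sequence motif, half the drugs contain a pyridine ring, and carrier–carrier
pairs associate at rate 0.85 versus 0.05 otherwise (2% label noise):

```python
from mdfuse import (SyntheticSpec, TrainConfig, generate_bundle,
                    sample_negatives, kfold_split, run_protocol)

bundle = generate_bundle(SyntheticSpec(seed=2))
print(f"{bundle.n_mirnas} miRNAs, {bundle.n_drugs} drugs, "
      f"{len(bundle.positives)} positive associations")

pairset = sample_negatives(bundle, ratio=1.0, seed=2)
plan = kfold_split(pairset, k=5, seed=2)
report = run_protocol(bundle, pairset, plan, TrainConfig(seed=2))
print(f"5-cv mean AUC  = {report.mean_auc:.4f}")
print(f"5-cv mean AUPR = {report.mean_aupr:.4f}")
```

Output:

```
100 miRNAs, 30 drugs, 783 positive associations
5-cv mean AUC  = 0.8732
5-cv mean AUPR = 0.8898
```

An AUC of 0.87 against a chance level of 0.5 shows the model recovering the
planted motif×substructure interaction from sequence and structure alone
(the mock language-model backend contributes no chemistry). Real data flows
through the same path: `load_bundle(associations.tsv, mirnas.fasta,
drugs.tsv, task)` accepts TSV association tables (`mirna_id<TAB>drug_id
[<TAB>label]`), FASTA or TSV sequences, and TSV SMILES.

The same pipeline from the shell:

```bash
mdfuse synth --out data/                                  # synthetic dataset
mdfuse train --data-dir data/ --task mdr --split cv5 --out runs/cv5
mdfuse rank  --data-dir data/ --task mdr --entity syn-drug-000 \
             --top-k 10 --out ranked.tsv                  # case-study ranking
```

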
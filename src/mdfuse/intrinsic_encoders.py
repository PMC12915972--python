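"""Task-specific intrinsic encoders for miRNA sequences and drug molecules.

Two trainable encoders complement the frozen language-model embeddings:

* a multi-scale 1-D CNN over the nucleotide sequence — a shared trainable
  nucleotide embedding table feeds three parallel convolution branches
  (kernel sizes 2, 3, 4 by default: di-, tri-, tetra-nucleotide motifs),
  each followed by ReLU and a masked global max over positions; branch
  outputs are concatenated and projected to the working dimension;
* a three-layer graph convolutional network over the heavy-atom
  molecular graph parsed from SMILES with RDKit, using the self-loop
  augmented symmetric normalization A_hat = D_hat^{-1/2}(A+I)D_hat^{-1/2}
  and a mean+max readout (summed) over atoms.

Sequences are standardized to 24 positions (truncation keeps the 5'
prefix; shorter sequences are padded at the 3' end). Pooling is masked:
convolution windows whose receptive field lies entirely in padding are
excluded, so padding never leaks length artifacts into the encoding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem.rdchem import HybridizationType

from ._autodiff import Tensor, concat, dropout, glorot_uniform

MAX_SEQ_LEN = 24
PAD_INDEX = 4
_NUC_INDEX = {"A": 0, "C": 1, "G": 2, "U": 3}


class SmilesParseError(ValueError):
    """SMILES string could not be parsed into a molecule."""


@dataclass
class PaddedSequence:
    """Fixed-length token index vector with a non-pad mask."""

    token_indices: np.ndarray  # (max_len,) int
    mask: np.ndarray  # (max_len,) bool

    def __post_init__(self):
        self.token_indices = np.asarray(self.token_indices, dtype=np.int64)
        self.mask = np.asarray(self.mask, dtype=bool)


def encode_sequence_tokens(seq: str, max_len: int = MAX_SEQ_LEN) -> PaddedSequence:
    """Map a canonicalized RNA string to fixed-length token indices.

    Longer sequences keep their 5' prefix; shorter ones are padded at
    the 3' end with a dedicated pad index whose embedding is masked to
    zero downstream.
    """
    if not seq:
        raise ValueError("empty sequence")
    idx = np.full(max_len, PAD_INDEX, dtype=np.int64)
    mask = np.zeros(max_len, dtype=bool)
    for p, ch in enumerate(seq[:max_len]):
        idx[p] = _NUC_INDEX[ch]
        mask[p] = True
    return PaddedSequence(token_indices=idx, mask=mask)


# -- molecular graphs -----------------------------------------------------

_ATOM_TYPES = ["C", "N", "O", "S", "F", "Cl", "Br", "I", "P"]  # + other
_HYBRIDIZATIONS = [HybridizationType.SP, HybridizationType.SP2,
                   HybridizationType.SP3]  # + other
_DEGREES = [0, 1, 2, 3, 4, 5]  # + other
_CHARGES = [-2, -1, 0, 1, 2]  # + other
_H_COUNTS = [0, 1, 2, 3, 4]  # + other
_RADICALS = [0, 1, 2]  # + other

FEATURIZER_SPEC = {
    "version": 1,
    "blocks": [
        ("atom_type", _ATOM_TYPES + ["other"]),
        ("hybridization", [str(h) for h in _HYBRIDIZATIONS] + ["other"]),
        ("degree", [str(d) for d in _DEGREES] + ["other"]),
        ("formal_charge", [str(c) for c in _CHARGES] + ["other"]),
        ("num_hydrogens", [str(h) for h in _H_COUNTS] + ["other"]),
        ("radical_electrons", [str(r) for r in _RADICALS] + ["other"]),
        ("aromatic", ["flag"]),
    ],
}

N_ATOM_FEATURES = sum(len(vocab) for _, vocab in FEATURIZER_SPEC["blocks"])


def _one_hot(value, vocab: list) -> np.ndarray:
    """One-hot with a trailing reserved slot for out-of-vocabulary values."""
    vec = np.zeros(len(vocab) + 1)
    vec[vocab.index(value) if value in vocab else len(vocab)] = 1.0
    return vec


def atom_features(atom: Chem.Atom) -> np.ndarray:
    """Concatenated one-hot blocks for one heavy atom, fixed documented order:
    atom type, hybridization, degree, formal charge, hydrogen count,
    radical electrons, aromaticity flag."""
    return np.concatenate([
        _one_hot(atom.GetSymbol(), _ATOM_TYPES),
        _one_hot(atom.GetHybridization(), _HYBRIDIZATIONS),
        _one_hot(atom.GetDegree(), _DEGREES),
        _one_hot(atom.GetFormalCharge(), _CHARGES),
        _one_hot(atom.GetTotalNumHs(), _H_COUNTS),
        _one_hot(atom.GetNumRadicalElectrons(), _RADICALS),
        np.array([1.0 if atom.GetIsAromatic() else 0.0]),
    ])


@dataclass
class MolecularGraph:
    """Heavy-atom graph: per-atom features, undirected bond list, adjacency."""

    atom_feats: np.ndarray  # (n, f)
    edges: list[tuple[int, int]]
    adjacency: np.ndarray  # (n, n) 0/1 symmetric, zero diagonal
    normalized_adjacency: np.ndarray = field(default=None)

    def __post_init__(self):
        A = np.asarray(self.adjacency, dtype=np.float64)
        if A.shape[0] != A.shape[1] or not np.array_equal(A, A.T):
            raise ValueError("adjacency must be square symmetric")
        if np.any(np.diag(A) != 0):
            raise ValueError("adjacency must have zero diagonal")
        if self.normalized_adjacency is None:
            self.normalized_adjacency = normalize_adjacency(A)

    @property
    def n_atoms(self) -> int:
        return self.atom_feats.shape[0]


def smiles_to_graph(smiles: str, drug_id: str | None = None) -> MolecularGraph:
    """Parse SMILES into an undirected heavy-atom molecular graph."""
    if not smiles:
        raise SmilesParseError(f"empty SMILES for drug {drug_id!r}")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None or mol.GetNumAtoms() == 0:
        raise SmilesParseError(
            f"unparseable SMILES {smiles!r}"
            + (f" for drug {drug_id!r}" if drug_id else ""))
    n = mol.GetNumAtoms()
    feats = np.stack([atom_features(a) for a in mol.GetAtoms()])
    adjacency = np.zeros((n, n))
    edges = []
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        adjacency[i, j] = adjacency[j, i] = 1.0
        edges.append((min(i, j), max(i, j)))
    return MolecularGraph(atom_feats=feats, edges=sorted(edges),
                          adjacency=adjacency)


def normalize_adjacency(A: np.ndarray) -> np.ndarray:
    """Self-loop augmented symmetric normalization D̂^{-1/2}(A+I)D̂^{-1/2}."""
    A = np.asarray(A, dtype=np.float64)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.array_equal(A, A.T):
        raise ValueError("adjacency must be symmetric")
    A_hat = A + np.eye(A.shape[0])
    d_inv_sqrt = 1.0 / np.sqrt(A_hat.sum(axis=1))
    return A_hat * d_inv_sqrt[:, None] * d_inv_sqrt[None, :]


# -- trainable encoders ---------------------------------------------------


class MultiScaleCNN:
    """Parallel 1-D convolution branches over the nucleotide embedding.

    Branch with kernel k sees 24-k+1 valid windows; windows starting in
    padding are excluded from the global max. The concatenated branch
    maxima pass through dropout and an affine+ReLU layer to width d_out.
    """

    def __init__(self, d_out: int, rng: np.random.Generator,
                 embed_dim: int = 32, channels: int = 64,
                 kernel_sizes: tuple[int, ...] = (2, 3, 4),
                 max_len: int = MAX_SEQ_LEN, dropout_rate: float = 0.3,
                 prefix: str = "cnn"):
        for k in kernel_sizes:
            if k > max_len:
                raise ValueError(f"kernel size {k} exceeds max_len {max_len}")
        self.d_out = d_out
        self.embed_dim = embed_dim
        self.channels = channels
        self.kernel_sizes = tuple(kernel_sizes)
        self.max_len = max_len
        self.dropout_rate = dropout_rate
        self.prefix = prefix
        # pad row stays zero through masking, not through its table entry
        self.embedding = Tensor(rng.normal(0.0, 0.1, size=(5, embed_dim)),
                                requires_grad=True)
        self.conv_w = {k: Tensor(glorot_uniform(rng, (k * embed_dim, channels)),
                                 requires_grad=True) for k in self.kernel_sizes}
        self.conv_b = {k: Tensor(np.zeros(channels), requires_grad=True)
                       for k in self.kernel_sizes}
        d_cat = channels * len(self.kernel_sizes)
        self.W_out = Tensor(glorot_uniform(rng, (d_cat, d_out)), requires_grad=True)
        self.b_out = Tensor(np.zeros(d_out), requires_grad=True)

    def params(self) -> dict[str, Tensor]:
        p = {f"{self.prefix}.embedding": self.embedding,
             f"{self.prefix}.W_out": self.W_out,
             f"{self.prefix}.b_out": self.b_out}
        for k in self.kernel_sizes:
            p[f"{self.prefix}.conv{k}.W"] = self.conv_w[k]
            p[f"{self.prefix}.conv{k}.b"] = self.conv_b[k]
        return p

    def __call__(self, tokens: np.ndarray, mask: np.ndarray,
                 train: bool = False,
                 rng: np.random.Generator | None = None) -> Tensor:
        """Encode a batch: tokens (n, max_len) int, mask (n, max_len) bool."""
        tokens = np.asarray(tokens, dtype=np.int64)
        mask = np.asarray(mask, dtype=bool)
        n, L = tokens.shape
        x = self.embedding.take(tokens.reshape(-1)).reshape(n, L, self.embed_dim)
        x = x * Tensor(mask[:, :, None].astype(np.float64))  # zero pad rows
        pooled = []
        for k in self.kernel_sizes:
            P = L - k + 1  # valid windows
            windows = concat([x[:, j:j + P, :] for j in range(k)], axis=2)
            h = (windows @ self.conv_w[k] + self.conv_b[k]).relu()
            # window j is entirely padding iff its first position is padding
            valid = mask[:, :P]
            h = h + Tensor(np.where(valid, 0.0, -1e9)[:, :, None])
            pooled.append(h.max(axis=1))
        z = concat(pooled, axis=1)
        if rng is not None:
            z = dropout(z, self.dropout_rate, rng, train)
        return (z @ self.W_out + self.b_out).relu()


class GCNEncoder:
    """Three spectral graph-convolution layers with mean+max readout.

    Per layer: X^{l+1} = ReLU(Â X^l W^l). The readout sums elementwise
    mean- and max-pooling over atoms; with the final layer width equal
    to the working dimension no extra affine map is needed.
    """

    def __init__(self, d_in: int, rng: np.random.Generator,
                 widths: tuple[int, ...] = (128, 128, 128),
                 prefix: str = "gcn"):
        self.d_in = d_in
        self.widths = tuple(widths)
        self.prefix = prefix
        dims = (d_in,) + self.widths
        self.weights = [Tensor(glorot_uniform(rng, (dims[i], dims[i + 1])),
                               requires_grad=True)
                        for i in range(len(self.widths))]

    @property
    def d_out(self) -> int:
        return self.widths[-1]

    def params(self) -> dict[str, Tensor]:
        return {f"{self.prefix}.W{i}": w for i, w in enumerate(self.weights)}

    def encode_one(self, graph: MolecularGraph) -> Tensor:
        if graph.atom_feats.shape[1] != self.d_in:
            raise ValueError(f"graph feature width {graph.atom_feats.shape[1]} "
                             f"!= encoder d_in {self.d_in}")
        h = Tensor(graph.atom_feats)
        A_hat = Tensor(graph.normalized_adjacency)
        for w in self.weights:
            h = (A_hat @ h @ w).relu()
        return h.mean(axis=0) + h.max(axis=0)

    def __call__(self, graphs: list[MolecularGraph]) -> Tensor:
        """Encode a list of graphs into an (n_graphs, d_out) matrix."""
        rows = [self.encode_one(g).reshape(1, self.d_out) for g in graphs]
        return concat(rows, axis=0)
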
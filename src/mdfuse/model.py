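"""End-to-end miRNA-drug association predictor and training loop.

For each miRNA the model fuses a projected frozen language-model
embedding with a multi-scale CNN sequence embedding; for each drug, a
projected language-model embedding with a GCN molecular-graph
embedding. Fusion is bidirectional multi-head cross-attention per
entity. A pair is scored by a feed-forward head on the concatenated
fused embeddings:

    p_ij = sigmoid(FCNN(Z_m,i || Z_r,j))

trained with mean binary cross-entropy and Adam (learning rate and
weight decay both 5e-4 by default, embedding dimension 128).

Ablation variants bypass fusion for the affected entity and pass the
remaining modality embedding through layer normalization alone:
``wo_plm_m`` / ``wo_plm_d`` drop the language-model channel for
miRNAs / drugs, ``wo_mcnn`` / ``wo_gcn`` drop the intrinsic channel,
``wo_plm`` and ``wo_mcnn_gnn`` drop both of one kind.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np

from ._autodiff import Adam, Tensor, concat, dropout, glorot_uniform
from .dataio import AssociationBundle
from .fusion import AttentionParams, cross_attention_block, passthrough_norm
from .intrinsic_encoders import (
    GCNEncoder,
    MolecularGraph,
    MultiScaleCNN,
    encode_sequence_tokens,
    smiles_to_graph,
)
from .plm_backend import (
    BackendSpec,
    ProjectionHead,
    embed_tokens,
    extract_summary_vector,
    mock_backend,
)
from .splits import LabeledPairSet

logger = logging.getLogger(__name__)

ABLATIONS = ("none", "wo_plm_m", "wo_plm_d", "wo_mcnn", "wo_gcn",
             "wo_plm", "wo_mcnn_gnn")


@dataclass
class TrainConfig:
    """Hyperparameters; defaults follow the reference configuration."""

    dm: int = 128
    dr: int = 128
    n_heads: int = 4
    kernel_sizes: tuple[int, ...] = (2, 3, 4)
    nuc_embed_dim: int = 32
    cnn_channels: int = 64
    max_seq_len: int = 24
    gcn_widths: tuple[int, ...] | None = None  # default: (dr, dr, dr)
    head_hidden: int = 128
    dropout: float = 0.3
    learning_rate: float = 5e-4
    weight_decay: float = 5e-4
    epochs: int = 100
    batch_size: int = 0  # 0 = full-batch; every step re-encodes all entities
    seed: int = 0
    ablation: str = "none"
    strict_attention_v: bool = False  # tie V's projection to W_K
    plm_m_dim: int = 640
    plm_r_dim: int = 384

    def __post_init__(self):
        if self.ablation not in ABLATIONS:
            raise ValueError(f"unknown ablation {self.ablation!r}; "
                             f"one of {ABLATIONS}")
        if self.gcn_widths is None:
            self.gcn_widths = (self.dr,) * 3
        self.kernel_sizes = tuple(self.kernel_sizes)
        self.gcn_widths = tuple(self.gcn_widths)
        for name in ("learning_rate", "epochs", "batch_size", "dm", "dr"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        return cls(**d)


@dataclass
class EntityFeatures:
    """Precomputed per-entity model inputs for one bundle.

    Language-model summary vectors are frozen constants; tokens, masks
    and molecular graphs feed the trainable intrinsic encoders.
    """

    plm_mirna: np.ndarray  # (M, plm_m_dim)
    plm_drug: np.ndarray  # (R, plm_r_dim)
    tokens: np.ndarray  # (M, max_len) int
    masks: np.ndarray  # (M, max_len) bool
    graphs: list[MolecularGraph]


def build_entity_features(bundle: AssociationBundle, cfg: TrainConfig,
                          rna_backend: BackendSpec | None = None,
                          smiles_backend: BackendSpec | None = None,
                          ) -> EntityFeatures:
    """Run backends and parsers once per entity."""
    rna_backend = rna_backend or mock_backend("rna", cfg.plm_m_dim)
    smiles_backend = smiles_backend or mock_backend("smiles", cfg.plm_r_dim)
    plm_m = np.stack([
        extract_summary_vector(embed_tokens(rna_backend, m.sequence))
        for m in bundle.mirnas])
    plm_r = np.stack([
        extract_summary_vector(embed_tokens(smiles_backend, d.smiles))
        for d in bundle.drugs])
    padded = [encode_sequence_tokens(m.sequence, cfg.max_seq_len)
              for m in bundle.mirnas]
    tokens = np.stack([p.token_indices for p in padded])
    masks = np.stack([p.mask for p in padded])
    graphs = [smiles_to_graph(d.smiles, d.id) for d in bundle.drugs]
    return EntityFeatures(plm_mirna=plm_m, plm_drug=plm_r,
                          tokens=tokens, masks=masks, graphs=graphs)


class AssociationPredictor:
    """Assembled encoders, fusion blocks and prediction head."""

    def __init__(self, cfg: TrainConfig, n_atom_features: int,
                 rng: np.random.Generator):
        self.cfg = cfg
        share = cfg.strict_attention_v
        self.proj_m = ProjectionHead(cfg.plm_m_dim, cfg.dm, rng, "proj_m")
        self.proj_r = ProjectionHead(cfg.plm_r_dim, cfg.dr, rng, "proj_r")
        self.cnn = MultiScaleCNN(cfg.dm, rng, embed_dim=cfg.nuc_embed_dim,
                                 channels=cfg.cnn_channels,
                                 kernel_sizes=cfg.kernel_sizes,
                                 max_len=cfg.max_seq_len,
                                 dropout_rate=cfg.dropout)
        self.gcn = GCNEncoder(n_atom_features, rng, widths=cfg.gcn_widths)
        if self.gcn.d_out != cfg.dr:
            raise ValueError("last GCN width must equal dr")
        self.fuse_m_ps = AttentionParams.init(cfg.dm, cfg.n_heads, rng, share)
        self.fuse_m_sp = AttentionParams.init(cfg.dm, cfg.n_heads, rng, share)
        self.fuse_r_ps = AttentionParams.init(cfg.dr, cfg.n_heads, rng, share)
        self.fuse_r_sp = AttentionParams.init(cfg.dr, cfg.n_heads, rng, share)
        d_pair = cfg.dm + cfg.dr
        self.head_W1 = Tensor(glorot_uniform(rng, (d_pair, cfg.head_hidden)),
                              requires_grad=True)
        self.head_b1 = Tensor(np.zeros(cfg.head_hidden), requires_grad=True)
        self.head_W2 = Tensor(glorot_uniform(rng, (cfg.head_hidden, 1)),
                              requires_grad=True)
        self.head_b2 = Tensor(np.zeros(1), requires_grad=True)

    def params(self) -> dict[str, Tensor]:
        p: dict[str, Tensor] = {}
        p.update(self.proj_m.params())
        p.update(self.proj_r.params())
        p.update(self.cnn.params())
        p.update(self.gcn.params())
        p.update(self.fuse_m_ps.named("fuse_m_ps"))
        p.update(self.fuse_m_sp.named("fuse_m_sp"))
        p.update(self.fuse_r_ps.named("fuse_r_ps"))
        p.update(self.fuse_r_sp.named("fuse_r_sp"))
        p.update({"head.W1": self.head_W1, "head.b1": self.head_b1,
                  "head.W2": self.head_W2, "head.b2": self.head_b2})
        return p

    # -- forward ----------------------------------------------------------

    def _fuse(self, z_plm: Tensor | None, z_int: Tensor | None,
              p_ps: AttentionParams, p_sp: AttentionParams) -> Tensor:
        """Bidirectional fusion with single-modality fallbacks."""
        if z_plm is not None and z_int is not None:
            n, d = z_plm.shape
            a = z_plm.reshape(n, 1, d)
            b = z_int.reshape(n, 1, d)
            fused = (cross_attention_block(a, b, p_ps)
                     + cross_attention_block(b, a, p_sp))
            return fused.reshape(n, d)
        remaining = z_plm if z_int is None else z_int
        return passthrough_norm(remaining, p_ps)

    def encode_entities(self, feats: EntityFeatures, train: bool = False,
                        rng: np.random.Generator | None = None,
                        ) -> tuple[Tensor, Tensor]:
        """Fused embeddings for all miRNAs (M, dm) and drugs (R, dr)."""
        ab = self.cfg.ablation
        z_mp = None if ab in ("wo_plm_m", "wo_plm") else \
            self.proj_m(Tensor(feats.plm_mirna))
        z_ms = None if ab in ("wo_mcnn", "wo_mcnn_gnn") else \
            self.cnn(feats.tokens, feats.masks, train=train, rng=rng)
        z_rp = None if ab in ("wo_plm_d", "wo_plm") else \
            self.proj_r(Tensor(feats.plm_drug))
        z_rt = None if ab in ("wo_gcn", "wo_mcnn_gnn") else \
            self.gcn(feats.graphs)
        if z_mp is None and z_ms is None:
            raise ValueError("ablation removed both miRNA modalities")
        if z_rp is None and z_rt is None:
            raise ValueError("ablation removed both drug modalities")
        z_m = self._fuse(z_mp, z_ms, self.fuse_m_ps, self.fuse_m_sp)
        z_r = self._fuse(z_rp, z_rt, self.fuse_r_ps, self.fuse_r_sp)
        return z_m, z_r

    def forward_pairs(self, z_m: Tensor, z_r: Tensor, pairs: np.ndarray,
                      train: bool = False,
                      rng: np.random.Generator | None = None) -> Tensor:
        """Pair probabilities (open interval (0,1)) for (mirna, drug) indices."""
        mi = pairs[:, 0]
        di = pairs[:, 1]
        x = concat([z_m.take(mi), z_r.take(di)], axis=1)
        h = (x @ self.head_W1 + self.head_b1).relu()
        if rng is not None:
            h = dropout(h, self.cfg.dropout, rng, train)
        logits = h @ self.head_W2 + self.head_b2
        # keep probabilities in the open interval even at saturated logits
        return logits.sigmoid().reshape(len(pairs)).clip(1e-12, 1.0 - 1e-12)


def predict_pair(mirna_fused: np.ndarray, drug_fused: np.ndarray,
                 model: AssociationPredictor) -> float:
    """Score one (miRNA, drug) pair from its fused embeddings."""
    z_m = np.asarray(mirna_fused, dtype=np.float64)
    z_r = np.asarray(drug_fused, dtype=np.float64)
    if z_m.shape != (model.cfg.dm,) or z_r.shape != (model.cfg.dr,):
        raise ValueError("fused embedding width mismatch with head")
    x = Tensor(np.concatenate([z_m, z_r]).reshape(1, -1))
    h = (x @ model.head_W1 + model.head_b1).relu()
    logits = h @ model.head_W2 + model.head_b2
    prob = float(logits.sigmoid().data[0, 0])
    return min(max(prob, 1e-12), 1.0 - 1e-12)


def bce_loss(probs: Tensor | np.ndarray, labels: np.ndarray,
             eps: float = 1e-7) -> Tensor:
    """Mean binary cross-entropy with probability clipping to [eps, 1-eps]."""
    p = probs if isinstance(probs, Tensor) else Tensor(np.asarray(probs))
    y = np.asarray(labels, dtype=np.float64).reshape(-1)
    if p.data.reshape(-1).shape != y.shape:
        raise ValueError("probs and labels length mismatch")
    p = p.reshape(y.shape[0]).clip(eps, 1.0 - eps)
    yt = Tensor(y)
    ll = yt * p.log() + (1.0 - yt) * (1.0 - p).log()
    return -ll.mean()


@dataclass
class TrainedModel:
    """A fitted predictor with its entity features and training history."""

    model: AssociationPredictor
    features: EntityFeatures
    cfg: TrainConfig
    history: list[float] = field(default_factory=list)
    _z_cache: tuple | None = None

    def score_pairs(self, pairs: np.ndarray) -> np.ndarray:
        """Deterministic eval-mode probabilities for (mirna, drug) indices."""
        if self._z_cache is None:
            z_m, z_r = self.model.encode_entities(self.features, train=False)
            self._z_cache = (z_m, z_r)
        z_m, z_r = self._z_cache
        pairs = np.asarray(pairs, dtype=np.int64).reshape(-1, 2)
        return self.model.forward_pairs(z_m, z_r, pairs, train=False).data


def train_model(bundle: AssociationBundle, pairset: LabeledPairSet,
                train_idx: np.ndarray, cfg: TrainConfig,
                features: EntityFeatures | None = None) -> TrainedModel:
    """Fit the predictor on one fold's training pairs.

    One global seed (``cfg.seed``) drives weight initialization, batch
    shuffling and dropout. Per-epoch mean training loss is recorded in
    the history. Raises on an empty training set or non-finite loss.
    """
    train_idx = np.asarray(train_idx, dtype=np.int64)
    if len(train_idx) == 0:
        raise ValueError("empty training set")
    if features is None:
        features = build_entity_features(bundle, cfg)
    rng = np.random.default_rng(cfg.seed)
    n_atom_features = features.graphs[0].atom_feats.shape[1]
    model = AssociationPredictor(cfg, n_atom_features, rng)
    opt = Adam(model.params(), lr=cfg.learning_rate,
               weight_decay=cfg.weight_decay)
    pairs = pairset.pairs[train_idx]
    labels = pairset.labels[train_idx]
    history: list[float] = []
    n = len(train_idx)
    batch = cfg.batch_size if cfg.batch_size > 0 else n
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, batch):
            sel = order[start:start + batch]
            z_m, z_r = model.encode_entities(features, train=True, rng=rng)
            probs = model.forward_pairs(z_m, z_r, pairs[sel], train=True,
                                        rng=rng)
            loss = bce_loss(probs, labels[sel])
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}: {loss.data}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(float(loss.data) * len(sel))
        history.append(sum(epoch_losses) / n)
    return TrainedModel(model=model, features=features, cfg=cfg,
                        history=history)
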
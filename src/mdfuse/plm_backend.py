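"""Pretrained-language-model backend contract and deterministic mock.

A backend maps a raw string (RNA sequence or SMILES) to an ``L' x D``
per-token embedding matrix whose first row is a summary token standing
for the whole input (the [CLS] convention: position 0 of the token
matrix). The summary vector is projected by a small trainable head to
the working embedding dimension. Downstream code consumes only the
projected vectors, so real transformer checkpoints (an RNA foundation
model at D=640, a chemical language model at D=384) and the mock
backend are interchangeable behind :func:`embed_tokens`.

The mock backend derives every token vector from a cryptographic hash
of ``(token, position, seed)``, giving bitwise-identical output across
platforms and runs with no model download. Its embeddings are
consistent per input but carry no chemistry or sequence semantics
beyond identity, which is exactly what backend-agnostic tests need.

Summary vectors can be precomputed into an on-disk cache: a JSON
sidecar (backend metadata + input hashes) next to a row-major
little-endian float32 matrix.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ._autodiff import Tensor

RNA_PLM_DIM = 640
SMILES_PLM_DIM = 384


class BackendMissingError(RuntimeError):
    """The requested backend is not installed/registered."""


class CacheMismatchError(ValueError):
    """Cache file metadata incompatible with the requesting pipeline."""


@dataclass(frozen=True)
class BackendSpec:
    """Identity and contract of an embedding backend."""

    name: str
    modality: str  # "rna" | "smiles"
    d_model: int
    deterministic: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.d_model <= 0:
            raise ValueError("d_model must be positive")
        if self.modality not in ("rna", "smiles"):
            raise ValueError(f"unknown modality {self.modality!r}")


@dataclass
class TokenEmbeddingMatrix:
    """Per-token embeddings, summary token first (L' = tokens + 1)."""

    values: np.ndarray  # (L', d_model)
    d_model: int

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[1] != self.d_model:
            raise ValueError("token matrix shape inconsistent with d_model")
        if self.values.shape[0] < 1:
            raise ValueError("token matrix must have at least one row")
        if not np.isfinite(self.values).all():
            raise ValueError("non-finite entries in token matrix")


def mock_backend(modality: str, d_model: int | None = None,
                 seed: int = 0) -> BackendSpec:
    """A download-free deterministic backend for the given modality."""
    if d_model is None:
        d_model = RNA_PLM_DIM if modality == "rna" else SMILES_PLM_DIM
    return BackendSpec(name=f"mock-{modality}", modality=modality,
                       d_model=d_model, deterministic=True, seed=seed)


def _hash_normal(key: str, d: int) -> np.ndarray:
    """Standard-normal vector seeded from a stable hash of ``key``."""
    digest = hashlib.blake2b(key.encode("utf-8"), digest_size=8).digest()
    sub_rng = np.random.Generator(np.random.PCG64(int.from_bytes(digest, "little")))
    return sub_rng.standard_normal(d)


def _tokenize(spec: BackendSpec, text: str) -> list[str]:
    # nucleotide tokens for RNA; character tokens for SMILES
    return list(text)


def embed_tokens(backend: BackendSpec, text: str) -> TokenEmbeddingMatrix:
    """Embed a string into an ``(L+1) x d_model`` matrix, summary row first."""
    if not text:
        raise ValueError("empty input string")
    if not backend.name.startswith("mock-"):
        raise BackendMissingError(
            f"backend {backend.name!r} is not available in this installation; "
            "register a real checkpoint or use mock_backend()")
    tokens = _tokenize(backend, text)
    rows = [_hash_normal(f"{backend.seed}|{backend.modality}|<summary>|{text}",
                         backend.d_model)]
    for pos, tok in enumerate(tokens):
        rows.append(_hash_normal(f"{backend.seed}|{backend.modality}|{tok}|{pos}",
                                 backend.d_model))
    return TokenEmbeddingMatrix(values=np.stack(rows), d_model=backend.d_model)


def extract_summary_vector(matrix: TokenEmbeddingMatrix) -> np.ndarray:
    """Row 0 of the token matrix: the whole-input summary embedding."""
    return matrix.values[0]


class ProjectionHead:
    """Single affine layer + ReLU adapting a frozen PLM vector to width d."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 prefix: str = "proj"):
        from ._autodiff import glorot_uniform
        self.d_in = d_in
        self.d_out = d_out
        self.W = Tensor(glorot_uniform(rng, (d_in, d_out)), requires_grad=True)
        self.b = Tensor(np.zeros(d_out), requires_grad=True)
        self.prefix = prefix

    def params(self) -> dict[str, Tensor]:
        return {f"{self.prefix}.W": self.W, f"{self.prefix}.b": self.b}

    def __call__(self, x: Tensor) -> Tensor:
        if x.shape[-1] != self.d_in:
            raise ValueError(f"projection head expects width {self.d_in}, "
                             f"got {x.shape[-1]}")
        return (x @ self.W + self.b).relu()


def project_embedding(vector: np.ndarray, head: ProjectionHead) -> np.ndarray:
    """Project a single d_model summary vector to the working dimension."""
    v = np.asarray(vector, dtype=np.float64)
    if v.ndim != 1:
        raise ValueError("expected a 1-D summary vector")
    return head(Tensor(v.reshape(1, -1))).data[0]


class EmbeddingCache:
    """Summary-vector cache keyed by input string.

    Layout: ``<path>.json`` sidecar with backend metadata and the list
    of input hashes, plus ``<path>.bin`` containing the float32 matrix
    row-major, little-endian.
    """

    def __init__(self, backend_name: str, d_model: int, seed: int,
                 vectors: dict[str, np.ndarray]):
        self.backend_name = backend_name
        self.d_model = d_model
        self.seed = seed
        self._vectors = vectors

    def __len__(self) -> int:
        return len(self._vectors)

    def lookup(self, text: str) -> np.ndarray:
        return self._vectors[text]

    @staticmethod
    def _key(text: str) -> str:
        return hashlib.blake2b(text.encode("utf-8"), digest_size=16).hexdigest()

    @classmethod
    def build(cls, backend: BackendSpec, inputs: list[str]) -> "EmbeddingCache":
        vectors: dict[str, np.ndarray] = {}
        for text in inputs:
            if text not in vectors:
                vectors[text] = extract_summary_vector(embed_tokens(backend, text))
        return cls(backend.name, backend.d_model, backend.seed, vectors)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        texts = list(self._vectors)
        matrix = np.stack([self._vectors[t] for t in texts]).astype("<f4")
        sidecar = {
            "backend": self.backend_name,
            "d_model": self.d_model,
            "seed": self.seed,
            "byte_order": "little",
            "dtype": "float32",
            "inputs": texts,
            "input_hashes": [self._key(t) for t in texts],
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))
        matrix.tofile(path.with_suffix(path.suffix + ".bin"))

    @classmethod
    def load(cls, path: str | Path, expected_d_model: int | None = None,
             ) -> "EmbeddingCache":
        path = Path(path)
        sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        if expected_d_model is not None and sidecar["d_model"] != expected_d_model:
            raise CacheMismatchError(
                f"cache built with d_model={sidecar['d_model']}, "
                f"pipeline expects {expected_d_model}")
        matrix = np.fromfile(path.with_suffix(path.suffix + ".bin"),
                             dtype="<f4").reshape(-1, sidecar["d_model"])
        vectors = {t: matrix[i].astype(np.float64)
                   for i, t in enumerate(sidecar["inputs"])}
        return cls(sidecar["backend"], sidecar["d_model"], sidecar["seed"], vectors)
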
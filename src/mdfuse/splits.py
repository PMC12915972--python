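"""Negative sampling and evaluation split construction.

Known associations are the positive class; unobserved miRNA-drug pairs
form the candidate negative pool from which balanced negatives are drawn
uniformly without replacement. Three split regimes are supported:

* ``cv5`` — k-fold cross-validation over labeled pairs (stratified by
  default so each fold keeps the 1:1 class balance within one pair);
* ``drug_cold`` / ``mirna_cold`` — degree-banded cold-start: every pair
  touching an entity whose positive degree falls in a chosen band is
  held out, so test-side entities never occur in training;
* ``mask_entity`` — case-study masking: one entity's pairs are removed
  from training and every counterpart entity becomes a ranking candidate.

Negatives are sampled once globally and then split together with
positives, so a test negative is never seen in training under any fold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.model_selection import KFold, StratifiedKFold

from .dataio import AssociationBundle


class SplitError(ValueError):
    """Invalid split request (empty band, bad k, unknown entity, ...)."""


@dataclass
class LabeledPairSet:
    """Parallel arrays of (mirna_index, drug_index) pairs and 0/1 labels."""

    pairs: np.ndarray  # (n, 2) int
    labels: np.ndarray  # (n,) int

    def __post_init__(self):
        self.pairs = np.asarray(self.pairs, dtype=np.int64).reshape(-1, 2)
        self.labels = np.asarray(self.labels, dtype=np.int64).reshape(-1)
        if len(self.pairs) != len(self.labels):
            raise SplitError("pairs and labels length mismatch")

    def __len__(self) -> int:
        return len(self.labels)


@dataclass
class SplitPlan:
    """Train/test index sets (into a LabeledPairSet) for one regime."""

    folds: list[tuple[np.ndarray, np.ndarray]]
    regime: str
    seed: int
    masked_entity: str | None = None
    masked_side: str | None = None
    candidates: list[int] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "regime": self.regime,
            "seed": self.seed,
            "masked_entity": self.masked_entity,
            "masked_side": self.masked_side,
            "candidates": list(map(int, self.candidates)),
            "folds": [
                {"train": list(map(int, tr)), "test": list(map(int, te))}
                for tr, te in self.folds
            ],
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "SplitPlan":
        payload = json.loads(Path(path).read_text())
        folds = [
            (np.asarray(f["train"], dtype=np.int64),
             np.asarray(f["test"], dtype=np.int64))
            for f in payload["folds"]
        ]
        return cls(folds=folds, regime=payload["regime"], seed=payload["seed"],
                   masked_entity=payload.get("masked_entity"),
                   masked_side=payload.get("masked_side"),
                   candidates=payload.get("candidates", []))


def sample_negatives(bundle: AssociationBundle, ratio: float = 1.0,
                     seed: int = 0) -> LabeledPairSet:
    """Positives plus ``floor(ratio * |positives|)`` uniform negatives.

    Negatives are drawn without replacement from all miRNA x drug pairs
    not in the positive set. Deterministic given ``seed``.
    """
    if ratio <= 0:
        raise SplitError("ratio must be positive")
    n_m, n_d = bundle.n_mirnas, bundle.n_drugs
    pos = sorted(bundle.positives)
    n_neg = int(np.floor(ratio * len(pos)))
    universe = n_m * n_d
    pool_size = universe - len(pos)
    if pool_size <= 0:
        raise SplitError("empty negative pool: positives cover the universe")
    if n_neg > pool_size:
        raise SplitError(f"negative pool too small ({pool_size} < {n_neg})")
    mask = np.ones(universe, dtype=bool)
    pos_flat = np.array([i * n_d + j for i, j in pos], dtype=np.int64)
    mask[pos_flat] = False
    pool = np.flatnonzero(mask)
    rng = np.random.default_rng(seed)
    chosen = rng.choice(pool, size=n_neg, replace=False)
    neg_pairs = np.stack([chosen // n_d, chosen % n_d], axis=1)
    pairs = np.concatenate([np.asarray(pos, dtype=np.int64).reshape(-1, 2),
                            neg_pairs], axis=0)
    labels = np.concatenate([np.ones(len(pos), dtype=np.int64),
                             np.zeros(n_neg, dtype=np.int64)])
    return LabeledPairSet(pairs=pairs, labels=labels)


def kfold_split(pairset: LabeledPairSet, k: int = 5, seed: int = 0,
                stratified: bool = True) -> SplitPlan:
    """Shuffled k-fold split of the labeled pair set."""
    n = len(pairset)
    if k < 2:
        raise SplitError("k must be >= 2")
    if k > n:
        raise SplitError(f"k={k} exceeds number of pairs ({n})")
    if stratified:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        gen = splitter.split(np.zeros(n), pairset.labels)
    else:
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
        gen = splitter.split(np.zeros(n))
    folds = [(tr.astype(np.int64), te.astype(np.int64)) for tr, te in gen]
    return SplitPlan(folds=folds, regime="cv5", seed=seed)


def cold_start_split(bundle: AssociationBundle, pairset: LabeledPairSet,
                     side: str, degree_band: tuple[int, int],
                     seed: int = 0) -> SplitPlan:
    """Hold out every pair touching entities in a positive-degree band.

    ``side`` is ``"drug"`` or ``"mirna"``. Degrees count positive
    associations only. The test set is all labeled pairs (positive and
    negative) touching a band-selected entity; the training set is the
    complement, which by construction contains no test-side entity.
    """
    if side not in ("drug", "mirna"):
        raise SplitError(f"unknown side {side!r}")
    lo, hi = degree_band
    deg = bundle.positive_degree(side)
    band = {e for e, d in deg.items() if lo <= d <= hi and d > 0}
    if not band:
        raise SplitError(f"empty band: no {side} has positive degree in "
                         f"[{lo}, {hi}]")
    col = 1 if side == "drug" else 0
    in_band = np.isin(pairset.pairs[:, col], sorted(band))
    test_idx = np.flatnonzero(in_band).astype(np.int64)
    train_idx = np.flatnonzero(~in_band).astype(np.int64)
    if len(train_idx) == 0:
        raise SplitError("band selects all entities: empty training set")
    regime = "drug_cold" if side == "drug" else "mirna_cold"
    return SplitPlan(folds=[(train_idx, test_idx)], regime=regime, seed=seed)


def mask_entity_split(bundle: AssociationBundle, pairset: LabeledPairSet,
                      entity_id: str) -> SplitPlan:
    """Treat one entity as novel: remove its pairs from training.

    The candidate set for ranking is every counterpart entity (all
    miRNAs when a drug is masked, and vice versa).
    """
    if entity_id in bundle.drug_index:
        side, col, idx = "drug", 1, bundle.drug_index[entity_id]
        candidates = list(range(bundle.n_mirnas))
    elif entity_id in bundle.mirna_index:
        side, col, idx = "mirna", 0, bundle.mirna_index[entity_id]
        candidates = list(range(bundle.n_drugs))
    else:
        raise SplitError(f"unknown entity id {entity_id!r}")
    touches = pairset.pairs[:, col] == idx
    train_idx = np.flatnonzero(~touches).astype(np.int64)
    test_idx = np.flatnonzero(touches).astype(np.int64)
    return SplitPlan(folds=[(train_idx, test_idx)], regime="mask_entity",
                     seed=0, masked_entity=entity_id, masked_side=side,
                     candidates=candidates)


def check_no_leakage(plan: SplitPlan, pairset: LabeledPairSet) -> None:
    """Assert split integrity; raises SplitError on violation.

    Checks train/test disjointness in every fold, and for cold/masking
    regimes exhaustively verifies that no test-side entity occurs in any
    training pair.
    """
    for f, (tr, te) in enumerate(plan.folds):
        if np.intersect1d(tr, te).size:
            raise SplitError(f"leakage: fold {f} train/test overlap")
        if plan.regime in ("drug_cold", "mirna_cold", "mask_entity"):
            col = 1 if plan.regime == "drug_cold" or plan.masked_side == "drug" \
                else 0
            test_entities = set(pairset.pairs[te, col].tolist())
            train_entities = set(pairset.pairs[tr, col].tolist())
            common = test_entities & train_entities
            if common:
                raise SplitError(f"leakage: fold {f} shares entities {common}")
    if plan.regime == "cv5":
        all_test = np.concatenate([te for _, te in plan.folds])
        if len(np.unique(all_test)) != len(all_test) or \
                len(all_test) != len(pairset):
            raise SplitError("cv5 test folds do not partition the pair set")
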
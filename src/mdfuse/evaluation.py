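"""Metrics and evaluation protocol runners.

Two threshold-free metrics summarize ranking quality of the pair
scores: AUC (the Mann-Whitney probability that a random positive
outscores a random negative, ties counted half) and AUPR computed as
average precision (precision summed over recall steps, equal scores
grouped into one threshold step — the unbiased step estimator rather
than trapezoidal PR interpolation).

:func:`run_protocol` executes a split plan end to end: per fold it
trains on the training indices only, scores the test indices, and
reports per-fold and mean metrics. Split integrity is verified before
any training; a corrupted plan aborts. :func:`rank_candidates`
implements the case-study protocol: one entity is masked as novel, the
model is retrained on the remaining pairs, and every counterpart entity
is scored against it and ranked.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.stats import rankdata

from .dataio import AssociationBundle
from .model import EntityFeatures, TrainConfig, build_entity_features, train_model
from .splits import (
    LabeledPairSet,
    SplitPlan,
    check_no_leakage,
    mask_entity_split,
    sample_negatives,
)

logger = logging.getLogger(__name__)


class MetricError(ValueError):
    """Metric undefined for the given inputs (single-class, no positives)."""


def compute_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve via the tie-aware rank statistic.

    Equals the mean over (positive, negative) pairs of
    ``[s_pos > s_neg] + 0.5 * [s_pos == s_neg]``.
    """
    scores = np.asarray(scores, dtype=np.float64).reshape(-1)
    labels = np.asarray(labels).reshape(-1)
    pos = labels == 1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise MetricError("AUC requires both classes present")
    ranks = rankdata(scores)  # average ranks handle ties
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def compute_aupr(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the precision-recall curve as average precision.

    Scores are swept from high to low; equal scores form a single
    threshold step. AP = sum over steps of (recall increment) x
    (precision at that step).
    """
    scores = np.asarray(scores, dtype=np.float64).reshape(-1)
    labels = np.asarray(labels).reshape(-1)
    n_pos = int((labels == 1).sum())
    if n_pos == 0:
        raise MetricError("AUPR requires at least one positive")
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    ap = 0.0
    tp = fp = 0
    prev_recall = 0.0
    i = 0
    n = len(s)
    while i < n:
        j = i
        while j < n and s[j] == s[i]:  # one tie group = one threshold
            j += 1
        tp += int((y[i:j] == 1).sum())
        fp += int((y[i:j] == 0).sum())
        recall = tp / n_pos
        precision = tp / (tp + fp)
        ap += (recall - prev_recall) * precision
        prev_recall = recall
        i = j
    return float(ap)


@dataclass
class MetricReport:
    """Per-fold and mean AUC/AUPR for one protocol run."""

    regime: str
    seed: int
    fold_auc: list[float]
    fold_aupr: list[float]
    n_train: list[int]
    n_test: list[int]
    pooled: bool = False

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.fold_auc))

    @property
    def mean_aupr(self) -> float:
        return float(np.mean(self.fold_aupr))

    def to_dict(self) -> dict:
        return {
            "regime": self.regime, "seed": self.seed, "pooled": self.pooled,
            "fold_auc": self.fold_auc, "fold_aupr": self.fold_aupr,
            "mean_auc": self.mean_auc, "mean_aupr": self.mean_aupr,
            "n_train": self.n_train, "n_test": self.n_test,
        }

    def save(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "report.json").write_text(json.dumps(self.to_dict(), indent=2))
        with open(out_dir / "report.csv", "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["fold", "auc", "aupr", "n_train", "n_test"])
            for f, (a, p, tr, te) in enumerate(
                    zip(self.fold_auc, self.fold_aupr, self.n_train, self.n_test)):
                w.writerow([f, f"{a:.6f}", f"{p:.6f}", tr, te])
            w.writerow(["mean", f"{self.mean_auc:.6f}",
                        f"{self.mean_aupr:.6f}", "", ""])


def run_protocol(bundle: AssociationBundle, pairset: LabeledPairSet,
                 plan: SplitPlan, cfg: TrainConfig,
                 features: EntityFeatures | None = None,
                 pooled: bool = False,
                 out_dir: str | Path | None = None) -> MetricReport:
    """Train and score every fold of a split plan.

    ``pooled=True`` concatenates scores across folds before computing a
    single metric pair (reported as one fold) instead of averaging
    per-fold metrics.
    """
    check_no_leakage(plan, pairset)
    if features is None:
        features = build_entity_features(bundle, cfg)
    fold_auc, fold_aupr, n_train, n_test = [], [], [], []
    pooled_scores, pooled_labels = [], []
    for tr, te in plan.folds:
        fitted = train_model(bundle, pairset, tr, cfg, features=features)
        scores = fitted.score_pairs(pairset.pairs[te])
        labels = pairset.labels[te]
        n_train.append(int(len(tr)))
        n_test.append(int(len(te)))
        if pooled:
            pooled_scores.append(scores)
            pooled_labels.append(labels)
        else:
            fold_auc.append(compute_auc(scores, labels))
            fold_aupr.append(compute_aupr(scores, labels))
    if pooled:
        s = np.concatenate(pooled_scores)
        y = np.concatenate(pooled_labels)
        fold_auc = [compute_auc(s, y)]
        fold_aupr = [compute_aupr(s, y)]
    report = MetricReport(regime=plan.regime, seed=cfg.seed,
                          fold_auc=fold_auc, fold_aupr=fold_aupr,
                          n_train=n_train, n_test=n_test, pooled=pooled)
    if out_dir is not None:
        report.save(out_dir)
    return report


@dataclass
class RankedCandidateList:
    """Candidates for a masked entity, sorted by score descending."""

    masked_entity: str
    candidate_ids: list[str]
    scores: list[float]
    seed: int = 0

    def __post_init__(self):
        pairs = sorted(zip(self.scores, self.candidate_ids),
                       key=lambda t: (-t[0], t[1]))
        self.scores = [s for s, _ in pairs]
        self.candidate_ids = [c for _, c in pairs]

    def top(self, k: int) -> list[tuple[str, float]]:
        return list(zip(self.candidate_ids[:k], self.scores[:k]))

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("rank\tentity_id\tscore\n")
            for r, (cid, s) in enumerate(zip(self.candidate_ids, self.scores),
                                         start=1):
                fh.write(f"{r}\t{cid}\t{s:.6f}\n")


def rank_candidates(bundle: AssociationBundle, masked_entity: str,
                    cfg: TrainConfig, top_k: int = 10,
                    pairset: LabeledPairSet | None = None,
                    features: EntityFeatures | None = None,
                    ) -> RankedCandidateList:
    """Case-study ranking: mask an entity, retrain, score all counterparts.

    The masked entity's pairs are removed from training; every
    counterpart entity in the bundle is then scored against it. Ties
    break lexicographically by candidate id. If ``top_k`` exceeds the
    candidate count the full list is returned with a warning.
    """
    if pairset is None:
        pairset = sample_negatives(bundle, ratio=1.0, seed=cfg.seed)
    plan = mask_entity_split(bundle, pairset, masked_entity)
    check_no_leakage(plan, pairset)
    train_idx = plan.folds[0][0]
    fitted = train_model(bundle, pairset, train_idx, cfg, features=features)
    if plan.masked_side == "drug":
        j = bundle.drug_index[masked_entity]
        cand_pairs = np.array([[i, j] for i in plan.candidates])
        cand_ids = [bundle.mirnas[i].id for i in plan.candidates]
    else:
        i = bundle.mirna_index[masked_entity]
        cand_pairs = np.array([[i, j] for j in plan.candidates])
        cand_ids = [bundle.drugs[j].id for j in plan.candidates]
    scores = fitted.score_pairs(cand_pairs)
    if top_k > len(cand_ids):
        logger.warning("top_k=%d exceeds candidate count %d; returning all",
                       top_k, len(cand_ids))
    return RankedCandidateList(masked_entity=masked_entity,
                               candidate_ids=cand_ids,
                               scores=[float(s) for s in scores],
                               seed=cfg.seed)
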
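import numpy as np
import pytest
from sklearn.metrics import average_precision_score, roc_auc_score

from mdfuse import (
    TrainConfig,
    compute_auc,
    compute_aupr,
    kfold_split,
    rank_candidates,
    run_protocol,
)
from mdfuse.evaluation import MetricError
from mdfuse.splits import SplitError


def _auc_pairwise_oracle(scores, labels):
    """Brute-force O(P*N) Mann-Whitney count with half-credit ties."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def _aupr_all_thresholds_oracle(scores, labels):
    """Evaluate precision at every distinct score threshold, summing
    precision times recall increments."""
    n_pos = labels.sum()
    thresholds = sorted(set(scores), reverse=True)
    ap, prev_recall = 0.0, 0.0
    for t in thresholds:
        kept = scores >= t
        tp = int((labels[kept] == 1).sum())
        precision = tp / kept.sum()
        recall = tp / n_pos
        ap += (recall - prev_recall) * precision
        prev_recall = recall
    return ap


class TestAUC:
    @pytest.mark.parametrize("scores, labels, expected", [
        ([0.9, 0.8, 0.3, 0.2], [1, 1, 0, 0], 1.0),
        ([0.2, 0.3, 0.8, 0.9], [1, 1, 0, 0], 0.0),
        ([0.5, 0.5], [1, 0], 0.5),
    ])
    def test_known_values(self, scores, labels, expected):
        assert compute_auc(np.array(scores), np.array(labels)) == \
            pytest.approx(expected)

    def test_matches_bruteforce_on_random_instances(self, rng):
        for _ in range(200):
            n = int(rng.integers(4, 30))
            scores = rng.choice(np.linspace(0, 1, 11), size=n)  # force ties
            labels = rng.integers(0, 2, size=n)
            if labels.sum() in (0, n):
                continue
            got = compute_auc(scores, labels)
            assert got == pytest.approx(_auc_pairwise_oracle(scores, labels),
                                        abs=1e-12)

    def test_matches_sklearn(self, rng):
        scores = rng.random(50)
        labels = rng.integers(0, 2, size=50)
        labels[0], labels[1] = 0, 1
        assert compute_auc(scores, labels) == \
            pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(MetricError):
            compute_auc(np.array([0.1, 0.2]), np.array([1, 1]))

    def test_adding_new_max_positive_never_decreases_auc(self, rng):
        for _ in range(30):
            n = int(rng.integers(4, 20))
            scores = rng.random(n)
            labels = rng.integers(0, 2, size=n)
            labels[0], labels[1] = 0, 1
            base = compute_auc(scores, labels)
            scores2 = np.append(scores, scores.max() + 1.0)
            labels2 = np.append(labels, 1)
            assert compute_auc(scores2, labels2) >= base - 1e-12


class TestAUPR:
    def test_perfect_ranking_is_one(self):
        assert compute_aupr(np.array([0.9, 0.8, 0.2, 0.1]),
                            np.array([1, 1, 0, 0])) == pytest.approx(1.0)

    def test_constant_scores_give_prevalence(self):
        # one threshold step at full recall: precision = p/n
        scores = np.full(10, 0.7)
        labels = np.array([1] * 3 + [0] * 7)
        assert compute_aupr(scores, labels) == pytest.approx(0.3)

    def test_hand_computed_average_precision(self):
        got = compute_aupr(np.array([0.9, 0.7, 0.6]), np.array([1, 0, 1]))
        assert got == pytest.approx(0.5 * 1.0 + 0.5 * (2 / 3), abs=1e-12)

    def test_matches_all_thresholds_oracle(self, rng):
        for _ in range(200):
            n = int(rng.integers(3, 30))
            scores = rng.choice(np.linspace(0, 1, 7), size=n)
            labels = rng.integers(0, 2, size=n)
            if labels.sum() == 0:
                continue
            got = compute_aupr(scores, labels)
            assert got == pytest.approx(
                _aupr_all_thresholds_oracle(scores, labels), abs=1e-10)

    def test_matches_sklearn_average_precision(self, rng):
        scores = rng.random(60)
        labels = rng.integers(0, 2, size=60)
        labels[0] = 1
        assert compute_aupr(scores, labels) == \
            pytest.approx(average_precision_score(labels, scores), abs=1e-10)

    def test_no_positives_rejected(self):
        with pytest.raises(MetricError):
            compute_aupr(np.array([0.5]), np.array([0]))


class TestRunProtocol:
    def test_cv5_report_shape_and_files(self, small_bundle, small_pairset,
                                        tiny_cfg, tmp_path):
        plan = kfold_split(small_pairset, k=5, seed=3)
        report = run_protocol(small_bundle, small_pairset, plan, tiny_cfg,
                              out_dir=tmp_path)
        assert len(report.fold_auc) == 5 and len(report.fold_aupr) == 5
        assert all(0.0 <= a <= 1.0 for a in report.fold_auc)
        assert (tmp_path / "report.json").exists()
        assert (tmp_path / "report.csv").exists()

    def test_same_seed_identical_report(self, small_bundle, small_pairset,
                                        tiny_cfg):
        plan = kfold_split(small_pairset, k=5, seed=3)
        r1 = run_protocol(small_bundle, small_pairset, plan, tiny_cfg)
        r2 = run_protocol(small_bundle, small_pairset, plan, tiny_cfg)
        assert r1.fold_auc == r2.fold_auc
        assert r1.fold_aupr == r2.fold_aupr

    def test_corrupted_plan_aborts(self, small_bundle, small_pairset,
                                   tiny_cfg):
        plan = kfold_split(small_pairset, k=5, seed=3)
        tr, te = plan.folds[0]
        plan.folds[0] = (np.concatenate([tr, te[:1]]), te)
        with pytest.raises(SplitError, match="leakage"):
            run_protocol(small_bundle, small_pairset, plan, tiny_cfg)

    def test_pooled_mode_reports_single_metric(self, small_bundle,
                                               small_pairset, tiny_cfg):
        plan = kfold_split(small_pairset, k=5, seed=3)
        report = run_protocol(small_bundle, small_pairset, plan, tiny_cfg,
                              pooled=True)
        assert len(report.fold_auc) == 1


class TestRankCandidates:
    def test_masked_drug_ranking(self, small_bundle, tiny_cfg):
        did = small_bundle.drugs[0].id
        ranked = rank_candidates(small_bundle, did, tiny_cfg, top_k=10)
        assert ranked.masked_entity == did
        assert len(ranked.candidate_ids) == small_bundle.n_mirnas
        scores = np.array(ranked.scores)
        assert np.all(np.diff(scores) <= 0)  # non-increasing
        assert np.all((scores > 0) & (scores < 1))
        top = ranked.top(10)
        assert len(top) == 10

    def test_tie_break_is_lexicographic(self):
        from mdfuse.evaluation import RankedCandidateList
        r = RankedCandidateList(masked_entity="d", scores=[0.5, 0.5, 0.9],
                                candidate_ids=["b", "a", "c"])
        assert r.candidate_ids == ["c", "a", "b"]

    def test_top_k_exceeding_candidates_returns_all(self, small_bundle,
                                                    tiny_cfg, caplog):
        did = small_bundle.drugs[1].id
        ranked = rank_candidates(small_bundle, did, tiny_cfg,
                                 top_k=10 * small_bundle.n_mirnas)
        assert len(ranked.candidate_ids) == small_bundle.n_mirnas

    def test_tsv_output(self, small_bundle, tiny_cfg, tmp_path):
        ranked = rank_candidates(small_bundle, small_bundle.drugs[0].id,
                                 tiny_cfg, top_k=5)
        out = tmp_path / "ranked.tsv"
        ranked.to_tsv(out)
        lines = out.read_text().strip().split("\n")
        assert lines[0] == "rank\tentity_id\tscore"
        assert len(lines) == small_bundle.n_mirnas + 1
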
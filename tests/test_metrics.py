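"""Network evaluation metrics: confusion counts, Hamming, ROC, PR."""

import numpy as np
import pytest
from sklearn.metrics import average_precision_score, roc_auc_score

from ckfsnet import aupr, auroc, confusion, evaluate, generate_network, hamming_distance
from ckfsnet.metrics import _labels_and_scores, pr_points, roc_points


def _random_instance(rng, n=6, n_edges=8):
    net = generate_network(n, n_edges, seed=int(rng.integers(2**31)))
    scores = rng.normal(size=(n, n))
    return net, scores


class TestConfusion:
    def test_direct_set_arithmetic(self):
        # gold {(1,2),(2,3)} vs predicted {(1,2),(1,3)} on a 4-gene universe
        scores = np.zeros((4, 4))
        scores[2, 1] = 0.9  # edge 1->2 (true positive)
        scores[3, 1] = 0.8  # edge 1->3 (false alarm)
        gold = {(1, 2), (2, 3)}
        T, F, M = confusion(gold, scores, threshold=0.5)
        assert (T, F, M) == (1, 1, 1)

    def test_infinite_threshold_predicts_nothing(self, rng):
        net, scores = _random_instance(rng)
        T, F, M = confusion(net, scores, threshold=np.inf)
        assert (T, F) == (0, 0)
        assert M == len(net.edge_set())

    def test_zero_threshold_saturates(self, rng):
        net, scores = _random_instance(rng)
        scores = np.where(scores == 0, 0.5, scores)
        T, F, M = confusion(net, scores, threshold=0.0)
        E = len(net.edge_set())
        assert M == 0
        assert F == 30 - E  # 6*5 off-diagonal candidates

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            confusion({(0, 5)}, np.zeros((3, 3)), threshold=0.1)


def test_identities_on_random_instances(rng):
    """T+M = E, Hamming = (F+M)/E, P = T/(T+F), R = T/(T+M)."""
    for _ in range(1000):
        net, scores = _random_instance(rng)
        E = len(net.edge_set())
        rep = evaluate(net, scores, threshold=float(rng.uniform(0, 2)))
        assert rep.T + rep.M == E
        assert rep.hamming == pytest.approx((rep.F + rep.M) / E)
        if rep.T + rep.F > 0:
            assert rep.precision == pytest.approx(rep.T / (rep.T + rep.F))
        assert rep.recall == pytest.approx(rep.T / (rep.T + rep.M))


class TestAuroc:
    def test_perfect_ranking(self):
        net = generate_network(5, 6, seed=0)
        scores = np.abs(net.weights) + (net.weights != 0)
        assert auroc(net, scores) == 1.0

    def test_matches_sklearn(self, rng):
        for _ in range(50):
            net, scores = _random_instance(rng)
            labels, vals = _labels_and_scores(net.edge_set(), scores, False)
            assert auroc(net, scores) == pytest.approx(
                roc_auc_score(labels, vals), abs=1e-12
            )

    def test_matches_threshold_sweep_oracle(self, rng):
        """Rank-based AUROC equals trapezoidal integration of the ROC curve
        enumerated threshold by threshold."""
        for _ in range(50):
            net, scores = _random_instance(rng)
            labels, vals = _labels_and_scores(net.edge_set(), scores, False)
            n_pos, n_neg = labels.sum(), (~labels).sum()
            fpr, tpr = [0.0], [0.0]
            for t in sorted(set(vals), reverse=True):
                pred = vals >= t
                tpr.append((pred & labels).sum() / n_pos)
                fpr.append((pred & ~labels).sum() / n_neg)
            oracle = np.trapezoid(tpr, fpr)
            assert auroc(net, scores) == pytest.approx(oracle, abs=1e-10)

    def test_invariant_under_monotone_transform(self, rng):
        net, scores = _random_instance(rng)
        a = auroc(net, scores)
        assert auroc(net, np.sign(scores) * np.exp(np.abs(scores))) == pytest.approx(a, abs=1e-12)

    def test_complement_for_reversed_ranking(self, rng):
        net, scores = _random_instance(rng)
        labels, vals = _labels_and_scores(net.edge_set(), scores, False)
        a = auroc(net, scores)
        # invert the ranking: large |score| becomes small, no ties introduced
        inv = 1.0 / (np.abs(scores) + 0.5)
        assert auroc(net, inv) == pytest.approx(1.0 - a, abs=1e-12)

    def test_degenerate_gold_rejected(self):
        with pytest.raises(ValueError):
            auroc(set(), np.ones((3, 3)))


class TestAupr:
    def test_perfect_ranking(self):
        net = generate_network(5, 6, seed=0)
        scores = np.abs(net.weights) + (net.weights != 0)
        assert aupr(net, scores) == 1.0

    def test_random_scores_approach_prevalence(self):
        # random ranking gives AP of roughly the positive prevalence, with
        # the well-known O(log P / n) upward bias at finite universe size
        rng = np.random.default_rng(3)
        net = generate_network(10, 18, seed=1)
        prevalence = 18 / 90
        vals = [aupr(net, rng.random((10, 10))) for _ in range(300)]
        assert prevalence < np.mean(vals) < 1.25 * prevalence

    def test_matches_exhaustive_enumeration(self, rng):
        """Step-rule AUPR equals the area accumulated by enumerating the
        (precision, recall) pairs at every distinct threshold."""
        for _ in range(50):
            net, scores = _random_instance(rng)
            labels, vals = _labels_and_scores(net.edge_set(), scores, False)
            n_pos = labels.sum()
            area, prev_recall = 0.0, 0.0
            for t in sorted(set(vals), reverse=True):
                pred = vals >= t
                tp = (pred & labels).sum()
                recall = tp / n_pos
                precision = tp / pred.sum()
                area += (recall - prev_recall) * precision
                prev_recall = recall
            assert aupr(net, scores) == pytest.approx(area, abs=1e-10)

    def test_matches_sklearn_average_precision(self, rng):
        for _ in range(20):
            net, scores = _random_instance(rng)
            labels, vals = _labels_and_scores(net.edge_set(), scores, False)
            # tie-free scores so the step rule and AP coincide exactly
            vals = vals + rng.uniform(0, 1e-9, size=vals.shape)
            assert aupr(net, np.zeros((6, 6)) + _embed(vals, 6)) == pytest.approx(
                average_precision_score(labels, vals), abs=1e-9
            )


def _embed(vals, n):
    """Place universe scores back into an n x n matrix (off-diagonal)."""
    out = np.zeros((n, n))
    i = 0
    for tgt in range(n):
        for src in range(n):
            if tgt != src:
                out[tgt, src] = vals[i]
                i += 1
    return out


def test_curve_points_are_valid_curves(rng):
    net, scores = _random_instance(rng)
    roc = roc_points(net, scores)
    assert tuple(roc[0]) == (0.0, 0.0)
    assert tuple(roc[-1]) == (1.0, 1.0)
    assert np.all(np.diff(roc[:, 0]) >= 0) and np.all(np.diff(roc[:, 1]) >= 0)
    pr = pr_points(net, scores)
    assert np.all((pr >= 0) & (pr <= 1))


def test_hamming_requires_edges():
    with pytest.raises(ValueError):
        hamming_distance(1, 1, 1, 0)
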
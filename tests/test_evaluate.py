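"""Metric suite: hand-computed cases, brute-force and sklearn cross-checks,
kappa identities, and the micro-ROC pair-counting oracle."""

import numpy as np
import pytest
import sklearn.metrics as skm

from neuronet19.evaluate import (ConfusionMatrix, classification_metrics,
                                 cohen_kappa, confusion_matrix, evaluate_model,
                                 micro_roc)


# ---------------------------------------------------------------- oracles
def metrics_bruteforce(counts):
    """One-vs-rest TP/TN/FP/FN loops, no vectorization."""
    k = len(counts)
    total = sum(sum(row) for row in counts)
    out = {"accuracy": sum(counts[i][i] for i in range(k)) / total,
           "precision": [], "recall": [], "f1": []}
    for c in range(k):
        tp = counts[c][c]
        fp = sum(counts[i][c] for i in range(k)) - tp
        fn = sum(counts[c][j] for j in range(k)) - tp
        p = tp / (tp + fp) if tp + fp else 0.0
        r = tp / (tp + fn) if tp + fn else 0.0
        f = 2 * p * r / (p + r) if p + r else 0.0
        out["precision"].append(p)
        out["recall"].append(r)
        out["f1"].append(f)
    return out


def kappa_bruteforce(counts):
    k = len(counts)
    total = sum(sum(row) for row in counts)
    p_o = sum(counts[i][i] for i in range(k)) / total
    p_e = sum(sum(counts[i]) * sum(counts[j][i] for j in range(k))
              for i in range(k)) / total ** 2
    return (p_o - p_e) / (1 - p_e)


def auc_paircount(labels, scores):
    """AUC = P(score+ > score-) + 0.5 P(tie) over all +/- pairs."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    wins = ties = 0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                wins += 1
            elif sp == sn:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def _cm(counts):
    counts = np.asarray(counts)
    return ConfusionMatrix(counts=counts,
                           class_names=[str(i) for i in range(len(counts))])


# ------------------------------------------------------ confusion matrix
def test_confusion_matrix_counts_and_trace_identity():
    cm = confusion_matrix([0, 0, 1, 1], [0, 1, 1, 1], 2)
    assert cm.counts.tolist() == [[1, 1], [0, 2]]
    rep = classification_metrics(cm)
    assert rep.accuracy == pytest.approx(np.trace(cm.counts) / cm.total)
    perfect = confusion_matrix([0, 1, 2, 3], [0, 1, 2, 3], 4)
    assert np.array_equal(perfect.counts, np.eye(4, dtype=int))


def test_confusion_matrix_rejects_out_of_range_labels():
    with pytest.raises(ValueError, match="range"):
        confusion_matrix([0, 5], [0, 1], 4)


# --------------------------------------------------------------- metrics
def test_binary_one_vs_rest_hand_case():
    # TP=9, FN=1 (class 0); FP=1, TN=89 (class 1 bucket)
    cm = _cm([[9, 1], [1, 89]])
    rep = classification_metrics(cm)
    assert rep.precision["0"] == pytest.approx(0.9)
    assert rep.recall["0"] == pytest.approx(0.9)
    assert rep.f1["0"] == pytest.approx(0.9)
    assert rep.accuracy == pytest.approx(0.98)


def test_perfect_diagonal_gives_all_ones():
    rep = classification_metrics(_cm(np.diag([5, 7, 9, 4])))
    assert rep.accuracy == 1.0 and rep.macro_f1 == 1.0 and rep.kappa == 1.0
    assert all(v == 1.0 for v in rep.precision.values())


def test_f1_fixed_point_when_precision_equals_recall():
    cm = _cm([[8, 2], [2, 88]])
    rep = classification_metrics(cm)
    assert rep.precision["0"] == rep.recall["0"]
    assert rep.f1["0"] == pytest.approx(rep.precision["0"])


def test_metrics_match_bruteforce_and_sklearn_on_random_matrices():
    rng = np.random.default_rng(99)
    for _ in range(300):
        k = int(rng.integers(2, 6))
        counts = rng.integers(0, 30, (k, k))
        if counts.sum() == 0 or np.trace(counts) == counts.sum() == 0:
            continue
        cm = _cm(counts)
        rep = classification_metrics(cm)
        ref = metrics_bruteforce(counts.tolist())
        assert rep.accuracy == pytest.approx(ref["accuracy"], abs=1e-12)
        for c in range(k):
            assert rep.precision[str(c)] == pytest.approx(ref["precision"][c], abs=1e-12)
            assert rep.recall[str(c)] == pytest.approx(ref["recall"][c], abs=1e-12)
            assert rep.f1[str(c)] == pytest.approx(ref["f1"][c], abs=1e-12)
        # independent library cross-check on a reconstructed label sample
        y_true = np.repeat(np.arange(k), counts.sum(axis=1))
        y_pred = np.concatenate([np.repeat(np.arange(k), row) for row in counts])
        if len(y_true):
            assert rep.accuracy == pytest.approx(
                skm.accuracy_score(y_true, y_pred), abs=1e-12)


# ----------------------------------------------------------------- kappa
def test_kappa_hand_cases():
    assert cohen_kappa(_cm(np.diag([10, 20, 5]))) == pytest.approx(1.0)
    assert cohen_kappa(_cm([[25, 25], [25, 25]])) == pytest.approx(0.0)
    assert cohen_kappa(_cm([[20, 5], [10, 65]])) == pytest.approx(0.625)


def test_kappa_matches_bruteforce_and_sklearn_and_permutation_invariance():
    rng = np.random.default_rng(7)
    for _ in range(300):
        k = int(rng.integers(2, 5))
        counts = rng.integers(1, 25, (k, k))
        kap = cohen_kappa(_cm(counts))
        assert kap == pytest.approx(kappa_bruteforce(counts.tolist()), abs=1e-12)
        perm = rng.permutation(k)
        assert cohen_kappa(_cm(counts[np.ix_(perm, perm)])) == pytest.approx(kap, abs=1e-12)
        y_true = np.repeat(np.arange(k), counts.sum(axis=1))
        y_pred = np.concatenate([np.repeat(np.arange(k), row) for row in counts])
        assert kap == pytest.approx(skm.cohen_kappa_score(y_true, y_pred), abs=1e-9)


def test_kappa_degenerate_marginals_raise():
    with pytest.raises(ValueError, match="p_e"):
        cohen_kappa(_cm([[10, 0], [0, 0]]))


def test_kappa_one_iff_diagonal():
    assert cohen_kappa(_cm([[3, 0], [0, 9]])) == 1.0
    assert cohen_kappa(_cm([[3, 1], [0, 9]])) < 1.0


# ------------------------------------------------------------- micro ROC
def test_micro_roc_perfect_and_chance():
    y = np.array([0, 1, 2, 3])
    perfect = np.eye(4)
    roc = micro_roc(y, perfect)
    assert roc.auc == pytest.approx(1.0)
    assert roc.fpr[0] == 0 and roc.tpr[0] == 0
    assert roc.fpr[-1] == 1 and roc.tpr[-1] == 1
    constant = np.full((8, 4), 0.25)
    assert micro_roc(np.arange(8) % 4, constant).auc == pytest.approx(0.5)


def test_micro_roc_two_class_worked_case():
    """Scores 0.9/0.4/0.6/0.1 for two classes; oracle enumerates pairs."""
    y = np.array([0, 1, 0, 1])
    probs = np.array([[0.9, 0.1], [0.4, 0.6], [0.6, 0.4], [0.1, 0.9]])
    roc = micro_roc(y, probs)
    onehot = np.eye(2, dtype=bool)[y].ravel()
    assert roc.auc == pytest.approx(auc_paircount(onehot, probs.ravel()), abs=1e-12)


def test_micro_roc_matches_paircount_oracle_on_random_scores():
    rng = np.random.default_rng(11)
    for _ in range(50):
        n, k = int(rng.integers(3, 10)), int(rng.integers(2, 5))
        y = rng.integers(0, k, n)
        raw = rng.random((n, k))
        # quantize to force ties through both code paths
        probs = np.round(raw / raw.sum(axis=1, keepdims=True), 1)
        roc = micro_roc(y, probs)
        onehot = np.zeros((n, k), dtype=bool)
        onehot[np.arange(n), y] = True
        expected = auc_paircount(onehot.ravel().tolist(), probs.ravel().tolist())
        assert roc.auc == pytest.approx(expected, abs=1e-12)
        assert (np.diff(roc.fpr) >= 0).all() and (np.diff(roc.tpr) >= 0).all()


def test_micro_roc_rejects_single_class_degenerate():
    with pytest.raises(ValueError, match="one class"):
        micro_roc(np.array([0]), np.array([[1.0]]))


# --------------------------------------------------------- evaluate_model
class _StubModel:
    """Fixed-probability model for wiring tests."""

    def __init__(self, probs):
        self._probs = np.asarray(probs)

    def predict_proba(self, x):
        return np.tile(self._probs, (len(x), 1))


def test_constant_prediction_on_balanced_set_scores_chance():
    x = np.zeros((8, 16, 16), dtype=np.uint8)
    y = np.arange(8) % 4
    model = _StubModel([0.7, 0.1, 0.1, 0.1])
    report, cm, roc = evaluate_model(model, x, y, list("abcd"))
    assert report.accuracy == pytest.approx(0.25)
    assert cm.counts[:, 0].sum() == 8
    # report is consistent with its own confusion matrix
    assert report.accuracy == pytest.approx(np.trace(cm.counts) / cm.total)
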
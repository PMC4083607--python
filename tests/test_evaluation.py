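import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cbep.evaluation import (
    epitope_metrics,
    leave_one_antigen_out,
    match_epitopes,
    residue_metrics,
)


def vectors_from_counts(tp, fp, tn, fn):
    """Build a label/score pair realizing the given confusion table at threshold 0."""
    labels = np.concatenate(
        [np.ones(tp + fn, dtype=int), np.zeros(fp + tn, dtype=int)]
    )
    scores = np.concatenate(
        [np.ones(tp), -np.ones(fn), np.ones(fp), -np.ones(tn)]
    )
    return labels, scores


def bruteforce_auc(labels, scores):
    """All-pairs comparison oracle with half credit for ties."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestResidueMetrics:
    def test_hand_arithmetic(self):
        labels, scores = vectors_from_counts(tp=3, fp=1, tn=5, fn=1)
        m = residue_metrics(labels, scores)
        assert m.sn == pytest.approx(0.75)
        assert m.sp == pytest.approx(5 / 6)
        assert m.acc == pytest.approx(0.8)
        assert m.f == pytest.approx(0.75)

    def test_perfect_separation(self):
        labels = np.array([0, 0, 1, 1])
        scores = np.array([-0.5, -0.2, 0.3, 0.9])
        m = residue_metrics(labels, scores)
        assert m.auc == 1.0 and m.acc == 1.0 and m.f == 1.0

    def test_single_class_auc_missing(self):
        m = residue_metrics(np.zeros(4, dtype=int), np.array([-1.0, -1, 1, 1]))
        assert m.auc is None and m.sn is None and m.sp == 0.5

    @given(
        tp=st.integers(0, 40), fp=st.integers(0, 40),
        tn=st.integers(0, 40), fn=st.integers(0, 40),
    )
    @settings(max_examples=200, deadline=None)
    def test_metric_identities(self, tp, fp, tn, fn):
        if tp + fp + tn + fn == 0:
            return
        labels, scores = vectors_from_counts(tp, fp, tn, fn)
        m = residue_metrics(labels, scores)
        assert (m.counts.tp, m.counts.fp, m.counts.tn, m.counts.fn) == (tp, fp, tn, fn)
        total = tp + fp + tn + fn
        assert m.acc == pytest.approx((tp + tn) / total)
        assert m.sn == (pytest.approx(tp / (tp + fn)) if tp + fn else None)
        assert m.sp == (pytest.approx(tn / (tn + fp)) if tn + fp else None)
        assert m.f == (
            pytest.approx(2 * tp / (2 * tp + fn + fp)) if 2 * tp + fn + fp else None
        )

    @given(seed=st.integers(0, 10_000), n=st.integers(5, 200))
    @settings(max_examples=60, deadline=None)
    def test_auc_matches_allpairs_oracle(self, seed, n):
        r = np.random.RandomState(seed)
        labels = r.randint(0, 2, size=n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        scores = np.round(r.normal(size=n), 1)  # quantized to force ties
        m = residue_metrics(labels, scores)
        assert m.auc == pytest.approx(bruteforce_auc(labels, scores))


class TestEpitopeMatching:
    def test_forty_percent_coverage_correct(self):
        res = match_epitopes([set(range(4))], {1: set(range(10))})
        assert res.n_matched == 1 and res.correct

    def test_exactly_thirty_percent_not_correct(self):
        res = match_epitopes([{0, 1, 2}], {1: set(range(10))})
        assert res.n_matched == 0 and not res.correct

    def test_distinct_matches_make_antigen_correct(self):
        pred = [{0, 1, 2}, {10, 11, 12}]
        obs = {1: {0, 1, 2, 3}, 2: {10, 11, 12, 13}}
        assert match_epitopes(pred, obs).correct

    def test_extra_cluster_breaks_antigen(self):
        pred = [{0, 1, 2}, {10, 11, 12}, {20, 21}]
        obs = {1: {0, 1, 2, 3}, 2: {10, 11, 12, 13}}
        res = match_epitopes(pred, obs)
        assert res.n_matched == 2 and not res.correct

    def test_one_to_one_matching(self):
        # one cluster covering both epitopes can match only one of them
        pred = [set(range(20))]
        obs = {1: set(range(5)), 2: set(range(10, 15))}
        res = match_epitopes(pred, obs)
        assert res.n_matched == 1 and not res.correct

    def test_ordering_invariance(self):
        pred = [{0, 1, 2}, {10, 11, 12}]
        obs = {1: {0, 1, 2, 3}, 2: {10, 11, 12, 13}}
        a = epitope_metrics({"c": (pred, obs)})
        b = epitope_metrics({"c": (pred[::-1], dict(reversed(list(obs.items()))))})
        assert a.v_site == b.v_site and a.v_p == b.v_p

    def test_aggregation(self):
        good = ([{0, 1, 2}], {1: {0, 1, 2, 3}})
        bad = ([{5, 6}, {8, 9}], {1: {0, 1, 2, 3}})
        m = epitope_metrics({"a": good, "b": bad})
        assert m.v_site == pytest.approx(1 / 3)
        assert m.v_p == pytest.approx(1 / 2)

    def test_empty_prediction_counts_as_wrong_antigen(self):
        m = epitope_metrics({"a": ([], {1: {0, 1, 2}})})
        assert m.v_p == 0.0 and m.v_site is None


class _MeanScorer:
    """Tiny deterministic stand-in classifier: score = mean feature value."""

    def fit(self, X, y):
        return self

    def decision_function(self, X):
        return np.asarray(X).mean(axis=1)

    def predict(self, X):
        return (self.decision_function(X) >= 0).astype(int)


class TestLeaveOneAntigenOut:
    def make_data(self, ids, rng, shift=2.0):
        feats, labels = {}, {}
        for i in ids:
            y = (rng.uniform(size=30) < 0.2).astype(int)
            X = rng.normal(size=(30, 4)) + shift * y[:, None]
            feats[i], labels[i] = X, y
        return feats, labels

    def test_fold_per_antigen(self, rng):
        feats, labels = self.make_data(["a", "b", "c"], rng)
        rep = leave_one_antigen_out(feats, labels, _MeanScorer)
        assert set(rep.per_antigen_auc) == {"a", "b", "c"}
        feats["d"], labels["d"] = feats["a"].copy(), labels["a"].copy()
        rep2 = leave_one_antigen_out(feats, labels, _MeanScorer)
        assert len(rep2.per_antigen_auc) == len(rep.per_antigen_auc) + 1

    def test_informative_features_give_high_auc(self, rng):
        feats, labels = self.make_data(["a", "b", "c", "d"], rng, shift=3.0)
        rep = leave_one_antigen_out(feats, labels, _MeanScorer)
        assert rep.mean_auc > 0.9

    def test_single_class_antigen_excluded_from_mean(self, rng):
        feats, labels = self.make_data(["a", "b"], rng)
        feats["z"] = rng.normal(size=(10, 4))
        labels["z"] = np.zeros(10, dtype=int)
        rep = leave_one_antigen_out(feats, labels, _MeanScorer)
        assert rep.per_antigen_auc["z"] is None
        defined = [v for k, v in rep.per_antigen_auc.items() if k != "z"]
        assert rep.mean_auc == pytest.approx(np.mean(defined))

    def test_needs_two_antigens(self, rng):
        feats, labels = self.make_data(["a"], rng)
        with pytest.raises(ValueError):
            leave_one_antigen_out(feats, labels, _MeanScorer)
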
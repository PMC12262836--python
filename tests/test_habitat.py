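"""Ensemble habitat model: splitting, AUC/TSS, filtering, ensembling and
binarization, with brute-force oracles for the rank statistics."""

import numpy as np
import pandas as pd
import pytest

from phckit.habitat import (
    ALGORITHMS,
    AllModelsExcludedError,
    HabitatSuitabilityModel,
    evaluate_model,
    filter_algorithms,
    max_sens_spec_threshold,
    split_data,
)


def auc_concordance_oracle(pred, truth):
    """All-pairs concordance count: ties count half."""
    pred, truth = np.asarray(pred), np.asarray(truth)
    pos = pred[truth == 1]
    neg = pred[truth == 0]
    total = 0.0
    for p in pos:
        total += np.sum(p > neg) + 0.5 * np.sum(p == neg)
    return total / (len(pos) * len(neg))


def threshold_scan_oracle(pred, truth):
    best_t, best = None, -np.inf
    for t in sorted(np.unique(pred)):
        binp = pred >= t
        sens = np.sum(binp & (truth == 1)) / truth.sum()
        spec = np.sum(~binp & (truth == 0)) / (len(truth) - truth.sum())
        if sens + spec > best + 1e-12:
            best, best_t = sens + spec, t
    return best_t


class TestSplit:
    def test_70_30_counts_per_class(self):
        y = np.array([1] * 100 + [0] * 100)
        tr, te = split_data(y, 0.7, np.random.default_rng(0))
        assert len(tr) == 140 and len(te) == 60
        assert y[tr].sum() == 70 and y[te].sum() == 30
        assert set(tr) | set(te) == set(range(200))
        assert set(tr) & set(te) == set()

    def test_full_train_fraction_rejected(self):
        y = np.array([0, 1] * 20)
        with pytest.raises(ValueError):
            split_data(y, 1.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            split_data(np.ones(20), 0.7)

    def test_same_seed_identical_split(self):
        y = np.array([0, 1] * 50)
        a = split_data(y, 0.7, np.random.default_rng(42))
        b = split_data(y, 0.7, np.random.default_rng(42))
        np.testing.assert_array_equal(a[0], b[0])


class TestMetrics:
    def test_perfect_ordering_gives_unit_scores(self):
        auc, tss = evaluate_model([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert auc == 1.0 and tss == 1.0

    def test_auc_matches_concordance_oracle(self):
        pred = np.array([0.9, 0.8, 0.4, 0.2])
        truth = np.array([1, 1, 0, 0])
        auc, _ = evaluate_model(pred, truth)
        assert auc == pytest.approx(auc_concordance_oracle(pred, truth))

    def test_all_tied_predictions_auc_half(self):
        auc, tss = evaluate_model([0.5] * 10, [1] * 5 + [0] * 5)
        assert auc == pytest.approx(0.5)
        assert tss == pytest.approx(0.0)

    def test_single_class_truth_rejected(self):
        with pytest.raises(ValueError):
            evaluate_model([0.1, 0.2], [1, 1])

    def test_monotone_transform_leaves_auc_tss_unchanged(self):
        rng = np.random.default_rng(3)
        pred = rng.random(60)
        truth = rng.integers(0, 2, 60)
        truth[:2] = [0, 1]
        base = evaluate_model(pred, truth)
        warped = evaluate_model(np.exp(3 * pred), truth)
        assert base == pytest.approx(warped)


class TestThreshold:
    def test_matches_exhaustive_scan(self):
        pred = np.array([0.1, 0.35, 0.4, 0.6, 0.62, 0.9])
        truth = np.array([0, 0, 1, 0, 1, 1])
        assert max_sens_spec_threshold(pred, truth) == threshold_scan_oracle(pred, truth)

    def test_separable_picks_minimum_presence_prediction(self):
        pred = np.array([0.9, 0.8, 0.7, 0.3, 0.2])
        truth = np.array([1, 1, 1, 0, 0])
        assert max_sens_spec_threshold(pred, truth) == 0.7

    def test_degenerate_constant_predictions(self):
        assert max_sens_spec_threshold([0.4] * 6, [1, 0, 1, 0, 1, 0]) == 0.4


class TestFilterRule:
    def test_straddling_means_produce_expected_set(self):
        rows = []
        for alg, auc, tss in [
            ("CTA", 0.84, 0.90),   # auc below -> out
            ("FDA", 0.86, 0.86),   # both above -> in
            ("GBM", 0.99, 0.849),  # tss below -> out
            ("GLM", 0.85, 0.85),   # exactly at cutoff -> in
        ]:
            for rep in range(10):
                rows.append({"algorithm": alg, "repeat_index": rep, "auc": auc, "tss": tss})
        included = filter_algorithms(pd.DataFrame(rows))
        assert included == ["FDA", "GLM"]

    def test_raising_cutoff_never_adds_models(self):
        rng = np.random.default_rng(0)
        rows = [
            {"algorithm": a, "auc": rng.uniform(0.7, 1), "tss": rng.uniform(0.7, 1)}
            for a in "ABCDEF" for _ in range(5)
        ]
        df = pd.DataFrame(rows)
        prev = set(filter_algorithms(df, 0.0, 0.0))
        for cut in (0.75, 0.8, 0.85, 0.9, 0.95):
            cur = set(filter_algorithms(df, cut, cut))
            assert cur <= prev
            prev = cur


class TestModelFit:
    def test_separable_toy_every_family_perfect(self):
        rng = np.random.default_rng(0)
        n = 60
        X = rng.standard_normal((n, 2))
        y = (X[:, 0] > 0).astype(int)
        X[:, 0] += np.where(y == 1, 3.0, -3.0)  # wide margin
        for name, factory in ALGORITHMS.items():
            est = factory(0)
            est.fit(X, y)
            pred = est.predict_proba(X)[:, 1]
            auc, _ = evaluate_model(pred, y)
            assert auc == 1.0, name

    def test_permuted_labels_mean_auc_near_half(self, small_landscape):
        occ = small_landscape["occurrences"].records.copy()
        rng = np.random.default_rng(7)
        occ["label"] = rng.permutation(occ["label"].to_numpy())
        model = HabitatSuitabilityModel(occ, small_landscape["stack"], algorithms=["GLM"])
        with pytest.raises(AllModelsExcludedError):
            model.fit(n_repeats=5, seed=1)
        # the permutation null itself: repeated split AUC averages ~0.5
        from phckit.habitat import split_data

        X = model.exog.to_numpy(float)
        y = model.endog
        aucs = []
        g = np.random.default_rng(2)
        for _ in range(5):
            tr, te = split_data(y, 0.7, g)
            est = ALGORITHMS["GLM"](0)
            est.fit(X[tr], y[tr])
            aucs.append(evaluate_model(est.predict_proba(X[te])[:, 1], y[te])[0])
        assert abs(np.mean(aucs) - 0.5) < 0.12

    def test_fit_and_binarize_on_small_landscape(self, small_landscape):
        model = HabitatSuitabilityModel(
            small_landscape["occurrences"], small_landscape["stack"],
            algorithms=["GLM", "RF"],
        )
        res = model.fit(n_repeats=3, seed=5, auc_cutoff=0.6, tss_cutoff=0.4)
        assert res.evals.shape[0] == 6
        product = res.binarize()
        cont, binary = product.continuous, product.binary
        assert 0.0 <= cont.values.min() and cont.values.max() <= 1.0
        # binary == continuous >= threshold, cellwise
        np.testing.assert_array_equal(
            binary.values, (cont.values >= product.threshold).astype(int)
        )
        assert "ensemble" in res.summary()

    def test_same_seed_reproduces_fit(self, small_landscape):
        kw = dict(n_repeats=2, seed=9, auc_cutoff=0.6, tss_cutoff=0.4)
        m = lambda: HabitatSuitabilityModel(
            small_landscape["occurrences"], small_landscape["stack"], algorithms=["CTA", "RF"]
        )
        r1, r2 = m().fit(**kw), m().fit(**kw)
        pd.testing.assert_frame_equal(r1.evals, r2.evals)

    def test_ensemble_weighted_mean(self):
        # hand-computed: weights (1,2,3), member predictions (0, 0.5, 1)
        class Fake:
            def __init__(self, p):
                self.p = p

            def predict_proba(self, X):
                return np.column_stack([1 - np.full(len(X), self.p), np.full(len(X), self.p)])

        from phckit.habitat import HabitatSuitabilityResults

        res = HabitatSuitabilityResults(
            model=None, evals=None, included_models=["a", "b", "c"],
            weights={"a": 1.0, "b": 2.0, "c": 3.0},
            fitted={"a": Fake(0.0), "b": Fake(0.5), "c": Fake(1.0)},
        )
        out = res.predict(np.zeros((4, 2)))
        np.testing.assert_allclose(out, 4.0 / 6.0)

    def test_single_member_ensemble_equals_member(self):
        class Fake:
            def predict_proba(self, X):
                p = np.linspace(0.1, 0.9, len(X))
                return np.column_stack([1 - p, p])

        from phckit.habitat import HabitatSuitabilityResults

        res = HabitatSuitabilityResults(None, None, ["only"], {"only": 0.7}, {"only": Fake()})
        out = res.predict(np.zeros((5, 2)))
        np.testing.assert_allclose(out, np.linspace(0.1, 0.9, 5))
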
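import numpy as np
import pytest

import eodsort as es
from eodsort.baselines import ScalogramSVC, TemplateCorrelationClassifier
from eodsort.errors import DomainError, ShapeError


@pytest.fixture(scope="module")
def fish_features(two_fish_waveforms):
    return {
        fish: es.feature_matrix(list(rows), "timefreq")
        for fish, rows in two_fish_waveforms.items()
    }


class TestBuildTemplates:
    def test_single_eod_template_is_its_scalogram(self, two_fish_waveforms):
        w = two_fish_waveforms["A"][0]
        ts = es.build_templates({"A": [w], "B": [two_fish_waveforms["B"][0]]})
        np.testing.assert_array_equal(
            ts.templates[0], es.feature_matrix([w], "timefreq")[0]
        )

    def test_two_identical_eods(self, two_fish_waveforms):
        w = two_fish_waveforms["A"][0]
        ts = es.build_templates({"A": [w, w.copy()], "B": [w]})
        np.testing.assert_allclose(
            ts.templates[0], es.feature_matrix([w], "timefreq")[0]
        )

    def test_noisy_template_correlates_with_clean(self, two_fish_waveforms):
        ts = es.build_templates(
            {"A": list(two_fish_waveforms["A"])})
        model = es.make_fish(11, 0.9)
        template = es.template_waveform(model, 50_000.0)
        clean = np.zeros(31)
        peak = int(np.argmax(np.abs(template)))
        clean[15 - peak: 15 - peak + template.size] = template
        clean_feat = es.feature_matrix([clean], "timefreq")[0]
        r = np.corrcoef(ts.templates[0], clean_feat)[0, 1]
        assert r > 0.99

    def test_empty_fish_set(self):
        with pytest.raises(DomainError):
            es.build_templates({})


class TestCorrelateClassify:
    def test_template_self_correlation(self, fish_features):
        ts = es.TemplateSet(
            templates=np.stack([fish_features["A"][0],
                                fish_features["B"][0]]),
            fish_ids=["A", "B"])
        labels = es.correlate_classify(fish_features["A"][:1], ts)
        assert labels[0] == "A"

    def test_easy_dyad_accuracy(self, fish_features):
        ts = es.TemplateSet(
            templates=np.stack([fish_features["A"][:50].mean(axis=0),
                                fish_features["B"][:50].mean(axis=0)]),
            fish_ids=["A", "B"])
        X = np.vstack([fish_features["A"][50:], fish_features["B"][50:]])
        truth = np.repeat(["A", "B"], 100)
        labels = es.correlate_classify(X, ts)
        assert np.mean(labels == truth) >= 0.95

    def test_identical_templates_all_ties_to_first(self, fish_features):
        t = fish_features["A"][:20].mean(axis=0)
        ts = es.TemplateSet(templates=np.stack([t, t]), fish_ids=["A", "B"])
        labels = es.correlate_classify(fish_features["B"][:30], ts)
        assert np.all(labels == "A")  # exact ties go to the first fish

    def test_grid_mismatch(self, fish_features):
        ts = es.TemplateSet(templates=fish_features["A"][:2, :100],
                            fish_ids=["A", "B"])
        with pytest.raises(ShapeError):
            es.correlate_classify(fish_features["B"], ts)


class TestTemplateCorrelationEstimator:
    def test_fit_predict(self, fish_features):
        X = np.vstack([fish_features["A"], fish_features["B"]])
        y = np.repeat(["A", "B"], 150)
        est = TemplateCorrelationClassifier().fit(X, y)
        assert np.mean(est.predict(X) == y) >= 0.95

    def test_single_class_rejected(self, fish_features):
        with pytest.raises(DomainError):
            TemplateCorrelationClassifier().fit(
                fish_features["A"], np.repeat("A", 150))


class TestScalogramSVC:
    def test_separable_features_high_cv_accuracy(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 0.3, (60, 5)),
                       rng.normal(3, 0.3, (60, 5))])
        y = np.repeat([0, 1], 60)
        est = ScalogramSVC(cv_folds=5, search_budget=12, seed=1).fit(X, y)
        assert est.cv_accuracy_ >= 0.99
        assert np.mean(est.predict(X) == y) >= est.cv_accuracy_ - 0.05

    def test_deterministic_hyperparameters(self):
        rng = np.random.default_rng(2)
        X = np.vstack([rng.normal(0, 1.0, (40, 4)),
                       rng.normal(1.5, 1.0, (40, 4))])
        y = np.repeat([0, 1], 40)
        a = ScalogramSVC(cv_folds=4, search_budget=10, seed=3).fit(X, y)
        b = ScalogramSVC(cv_folds=4, search_budget=10, seed=3).fit(X, y)
        assert (a.C_, a.gamma_) == (b.C_, b.gamma_)

    def test_single_class_rejected(self):
        with pytest.raises(DomainError):
            ScalogramSVC(cv_folds=3).fit(np.zeros((10, 3)), np.zeros(10))

    def test_all_zero_row_classified_without_crash(self, fish_features):
        X = np.vstack([fish_features["A"][:30], fish_features["B"][:30]])
        y = np.repeat(["A", "B"], 30)
        est = ScalogramSVC(cv_folds=3, search_budget=6, seed=0).fit(X, y)
        out = est.predict(np.zeros((2, X.shape[1])))
        assert out[0] == out[1]

    def test_permuting_rows_permutes_labels(self, fish_features):
        X = np.vstack([fish_features["A"][:30], fish_features["B"][:30]])
        y = np.repeat(["A", "B"], 30)
        est = ScalogramSVC(cv_folds=3, search_budget=6, seed=0).fit(X, y)
        test = np.vstack([fish_features["A"][30:40],
                          fish_features["B"][30:40]])
        perm = np.random.default_rng(5).permutation(20)
        np.testing.assert_array_equal(est.predict(test)[perm],
                                      est.predict(test[perm]))

    def test_dimension_mismatch(self, fish_features):
        X = np.vstack([fish_features["A"][:20], fish_features["B"][:20]])
        y = np.repeat(["A", "B"], 20)
        est = ScalogramSVC(cv_folds=3, search_budget=5, seed=0).fit(X, y)
        with pytest.raises(ShapeError):
            est.predict(X[:, :50])


class TestRankBySNR:
    def test_ranking_uses_raw_peak_amplitude(self):
        waveforms = []
        for i, amp in enumerate([0.01, 0.05, 0.03]):
            e = es.EODEvent(t_s=0.1 * i, channel=0, peak_amp_V=amp)
            waveforms.append(es.EODWaveform(y=np.zeros(31), event=e))
        top = es.rank_by_snr(waveforms, 2)
        assert [w.event.peak_amp_V for w in top] == [0.05, 0.03]

    def test_short_supply_uses_all(self):
        e = es.EODEvent(t_s=0.0, channel=0, peak_amp_V=0.01)
        w = es.EODWaveform(y=np.zeros(31), event=e)
        assert len(es.rank_by_snr([w], 5000)) == 1


class TestSupervisedOrdering:
    def test_svm_at_least_matches_correlation_in_median(self,
                                                        fish_features):
        """Same-session train/test: the SVM should not lose to the
        template-correlation baseline in the median over splits."""
        svm_accs, corr_accs = [], []
        for seed in range(3):
            rng = np.random.default_rng(seed)
            idx = rng.permutation(150)
            tr, te = idx[:100], idx[100:]
            X_tr = np.vstack([fish_features["A"][tr],
                              fish_features["B"][tr]])
            y_tr = np.repeat(["A", "B"], 100)
            X_te = np.vstack([fish_features["A"][te],
                              fish_features["B"][te]])
            y_te = np.repeat(["A", "B"], 50)
            svm = ScalogramSVC(cv_folds=3, search_budget=8, seed=seed)
            svm_accs.append(np.mean(svm.fit(X_tr, y_tr).predict(X_te) ==
                                    y_te))
            corr = TemplateCorrelationClassifier().fit(X_tr, y_tr)
            corr_accs.append(np.mean(corr.predict(X_te) == y_te))
        assert np.median(svm_accs) >= np.median(corr_accs) - 1e-9
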
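"""Supervised baselines: scalogram template correlation and an RBF-SVM.

Both baselines need solo recordings of each fish to build training data,
which is exactly the experimental burden the unsupervised separation
removes; they are provided for comparison benchmarks.

* Template correlation: the per-fish mean scalogram from solo recordings is
  the template; each dyad EOD goes to the fish whose template has the
  higher Pearson correlation with its scalogram.
* SVM: an RBF-kernel classifier on standardized flattened scalograms of the
  top-SNR solo EODs (SNR ranked by the raw pre-normalization peak
  amplitude), with (C, gamma) tuned by a seeded sequential search
  maximizing k-fold cross-validated accuracy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

from .errors import DomainError, ShapeError
from .representations import MorseParams, feature_matrix

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SVMConfig:
    """Training-set size, CV folds and search budget for the SVM baseline."""

    n_train_per_fish: int = 5000
    cv_folds: int = 10
    search_budget: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_train_per_fish < self.cv_folds:
            raise DomainError("n_train_per_fish must be >= cv_folds")


@dataclass
class TemplateSet:
    """Per-fish mean scalograms (flattened) sharing one scalogram grid."""

    templates: np.ndarray  # n_fish x d
    fish_ids: list[str]


def build_templates(solo_waveforms_per_fish: dict[str, list],
                    morse_params: MorseParams = MorseParams(),
                    fs: float = 50_000.0) -> TemplateSet:
    """Element-wise mean of per-EOD normalized scalograms, one per fish."""
    if not solo_waveforms_per_fish:
        raise DomainError("empty fish set")
    fish_ids = list(solo_waveforms_per_fish)
    templates = []
    for fish in fish_ids:
        waveforms = solo_waveforms_per_fish[fish]
        if not waveforms:
            raise DomainError(f"fish {fish!r} has no waveforms")
        feats = feature_matrix(waveforms, "timefreq", morse_params, fs=fs)
        templates.append(feats.mean(axis=0))
    return TemplateSet(templates=np.stack(templates), fish_ids=fish_ids)


def _pearson_rows(x: np.ndarray, templates: np.ndarray) -> np.ndarray:
    """Pearson r of each row of x against each template row (n x n_fish)."""
    xc = x - x.mean(axis=1, keepdims=True)
    tc = templates - templates.mean(axis=1, keepdims=True)
    xn = np.linalg.norm(xc, axis=1, keepdims=True)
    tn = np.linalg.norm(tc, axis=1, keepdims=True)
    r = (xc @ tc.T) / (xn * tn.T + 1e-300)
    r[xn.ravel() == 0] = 0.0  # zero-variance scalogram: r undefined -> 0
    return r


def correlate_classify(scalograms: np.ndarray, templates: TemplateSet,
                       ) -> np.ndarray:
    """Assign each EOD to the fish with the higher template correlation.

    Exact ties (including undefined correlations from zero-variance rows)
    go to the first fish of the template set, with a logged tie count.
    """
    scalograms = np.asarray(scalograms, dtype=float)
    if scalograms.shape[1] != templates.templates.shape[1]:
        raise ShapeError("scalogram grid does not match the templates")
    r = _pearson_rows(scalograms, templates.templates)
    ties = int(np.sum(np.max(r, axis=1) == np.min(r, axis=1)))
    if ties:
        log.warning("%d correlation ties assigned to fish %s", ties,
                    templates.fish_ids[0])
    # argmax takes the first maximal entry, which is the tie rule
    return np.array([templates.fish_ids[i] for i in np.argmax(r, axis=1)])


class TemplateCorrelationClassifier(ClassifierMixin, BaseEstimator):
    """Sklearn-style wrapper of the template-correlation baseline.

    fit(X, y) averages the scalogram feature rows per class into
    ``templates_``; predict returns the class of the higher Pearson r.
    """

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if self.classes_.size < 2:
            raise DomainError("need two classes to build dyad templates")
        self.templates_ = np.stack(
            [X[y == c].mean(axis=0) for c in self.classes_]
        )
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "templates_")
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ShapeError("feature dimension mismatch")
        r = _pearson_rows(X, self.templates_)
        return self.classes_[np.argmax(r, axis=1)]

    def decision_function(self, X):
        check_is_fitted(self, "templates_")
        r = _pearson_rows(np.asarray(X, dtype=float), self.templates_)
        return r[:, 1] - r[:, 0]


def _log_grid(lo: float, hi: float, n: int) -> np.ndarray:
    return np.logspace(np.log10(lo), np.log10(hi), n)


class ScalogramSVC(ClassifierMixin, BaseEstimator):
    """RBF-SVM on standardized scalogram features with sequential tuning.

    The hyperparameter search is a seeded two-stage sequential procedure: a
    coarse log grid over C in [1e-2, 1e3] and gamma in [1e-6, 1e1] scored by
    ``cv_folds``-fold CV accuracy, then a local log-space refinement around
    the best point, within ``search_budget`` total evaluations. Features are
    standardized by stored per-column mean and standard deviation (classes
    are balanced by construction, so plain column statistics apply).
    """

    def __init__(self, cv_folds: int = 10, search_budget: int = 25,
                 seed: int = 0):
        self.cv_folds = cv_folds
        self.search_budget = search_budget
        self.seed = seed

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if np.unique(y).size < 2:
            raise DomainError("single-class input: cannot train a classifier")
        budget = max(int(self.search_budget), 4)
        n_coarse = max(int(np.sqrt(budget * 0.6)), 2)
        coarse_c = _log_grid(1e-2, 1e3, n_coarse)
        coarse_g = _log_grid(1e-6, 1e1, n_coarse)
        cv = StratifiedKFold(n_splits=self.cv_folds, shuffle=True,
                             random_state=self.seed)
        evaluated: dict[tuple[float, float], float] = {}

        def score(c: float, g: float) -> float:
            key = (float(c), float(g))
            if key not in evaluated:
                pipe = self._pipeline(c, g)
                evaluated[key] = float(np.mean(
                    cross_val_score(pipe, X, y, cv=cv, scoring="accuracy")
                ))
            return evaluated[key]

        for c in coarse_c:
            for g in coarse_g:
                if len(evaluated) >= budget:
                    break
                score(c, g)
        best = max(evaluated, key=lambda k: (evaluated[k], -k[0], -k[1]))
        # refinement: shrink the log-space neighborhood around the incumbent
        step_c = 10 ** (5.0 / max(n_coarse - 1, 1) / 2)
        step_g = 10 ** (7.0 / max(n_coarse - 1, 1) / 2)
        while len(evaluated) < budget:
            improved = False
            for c in (best[0] / step_c, best[0], best[0] * step_c):
                for g in (best[1] / step_g, best[1], best[1] * step_g):
                    if len(evaluated) >= budget:
                        break
                    if score(c, g) > evaluated[best]:
                        best, improved = (float(c), float(g)), True
            if not improved:
                step_c, step_g = step_c ** 0.5, step_g ** 0.5
                if step_c < 1.05:
                    break
        self.C_, self.gamma_ = best
        self.cv_accuracy_ = evaluated[best]
        self.pipeline_ = self._pipeline(self.C_, self.gamma_).fit(X, y)
        self.classes_ = self.pipeline_.named_steps["svc"].classes_
        self.n_features_in_ = X.shape[1]
        return self

    @staticmethod
    def _pipeline(c: float, g: float) -> Pipeline:
        return Pipeline([("scale", StandardScaler()),
                         ("svc", SVC(kernel="rbf", C=c, gamma=g))])

    def predict(self, X):
        check_is_fitted(self, "pipeline_")
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ShapeError("feature dimension mismatch")
        return self.pipeline_.predict(X)


def rank_by_snr(waveforms, n_keep: int) -> list:
    """Top ``n_keep`` waveforms by raw |peak_amp_V| (pre-normalization SNR).

    Normalized snippets all peak at 1, so the signal-to-noise ranking uses
    the original signed peak voltage stored on each waveform's event. When
    fewer than ``n_keep`` are available, all are used with a warning.
    """
    ranked = sorted(waveforms, key=lambda w: -abs(w.event.peak_amp_V))
    if len(ranked) < n_keep:
        log.warning("only %d waveforms available (requested %d); using all",
                    len(ranked), n_keep)
        return ranked
    return ranked[:n_keep]


def svm_train(features_per_fish: dict[str, np.ndarray],
              config: SVMConfig = SVMConfig()) -> ScalogramSVC:
    """Train the SVM baseline from per-fish feature matrices."""
    if len(features_per_fish) < 2:
        raise DomainError("need two fish to train the dyad classifier")
    X = np.vstack(list(features_per_fish.values()))
    y = np.concatenate(
        [[fish] * len(m) for fish, m in features_per_fish.items()]
    )
    est = ScalogramSVC(cv_folds=config.cv_folds,
                       search_budget=config.search_budget, seed=config.seed)
    return est.fit(X, y)


def svm_classify(model: ScalogramSVC, features: np.ndarray) -> np.ndarray:
    """Classify feature rows with a trained SVM baseline."""
    return model.predict(features)
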
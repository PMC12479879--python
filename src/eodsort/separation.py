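"""Unsupervised dyad separation: t-SNE embedding + 2-cluster average linkage.

The pipeline embeds high-dimensional per-EOD features (by default flattened
Morse scalograms) into 2-D with t-SNE, cuts an average-linkage Euclidean
dendrogram of the embedding at two clusters, scores the partition with the
average silhouette and the CDbw composed-density index, and maps the two
clusters to fish identities from their amplitude/polarity signatures on the
two recording channels.
"""

from __future__ import annotations

import time
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.manifold import TSNE
from sklearn.metrics import silhouette_score

from .detection import DetectionConfig, detect_and_extract
from .errors import ConfigError, DomainError
from .io_core import EODEvent, Recording
from .representations import MorseParams, feature_matrix

log = logging.getLogger(__name__)

#: above this many events the linkage runs on a uniform subsample and the
#: remaining points inherit the label of their nearest clustered neighbor
LINKAGE_SUBSAMPLE = 30_000


@dataclass(frozen=True)
class SeparationConfig:
    """Hyperparameters of the unsupervised separation."""

    perplexity: float = 50.0
    seed: int = 0
    init: str = "pca"
    n_iter: int = 750
    linkage: str = "average"
    metric: str = "euclidean"
    k: int = 2

    def __post_init__(self) -> None:
        if self.perplexity < 5:
            raise ConfigError("perplexity must be >= 5")
        if self.k != 2:
            raise ConfigError("the separation targets dyads: k must be 2")


@dataclass
class SeparationResult:
    """Embedding, labels, quality metrics and identity map of one run."""

    embedding: np.ndarray
    labels: np.ndarray
    ss: float
    cdbw: float
    identity_map: dict[int, str]
    ambiguous: bool = False
    warnings: list[str] = field(default_factory=list)
    runtime_s: dict[str, float] = field(default_factory=dict)


def tsne_embed(features: np.ndarray,
               config: SeparationConfig = SeparationConfig()) -> np.ndarray:
    """2-D t-SNE embedding of the feature matrix; deterministic per seed."""
    features = np.asarray(features, dtype=float)
    n = features.shape[0]
    if n < 3 * config.perplexity:
        raise ConfigError(
            f"n = {n} is below 3 x perplexity ({config.perplexity:.0f}); "
            "lower the perplexity"
        )
    if not np.all(np.isfinite(features)):
        raise DomainError("features contain non-finite values")
    tsne = TSNE(n_components=2, perplexity=config.perplexity,
                init=config.init, max_iter=config.n_iter,
                random_state=config.seed, method="barnes_hut")
    return tsne.fit_transform(features)


def hcluster2(embedding: np.ndarray) -> np.ndarray:
    """Cut an average-linkage Euclidean dendrogram at exactly 2 clusters.

    Label ids are assigned by cluster size (0 = larger; ties broken by the
    cluster containing the lowest point index) so repeated runs are
    reproducible.
    """
    embedding = np.asarray(embedding, dtype=float)
    if embedding.shape[0] < 2:
        raise DomainError("need at least 2 points to cluster")
    tree = linkage(embedding, method="average", metric="euclidean")
    raw = fcluster(tree, t=2, criterion="maxclust")
    return _canonical_labels(raw)


def _canonical_labels(raw: np.ndarray) -> np.ndarray:
    ids, counts = np.unique(raw, return_counts=True)
    if ids.size == 1:
        return np.zeros_like(raw)
    order = sorted(
        ids, key=lambda c: (-counts[list(ids).index(c)],
                            int(np.argmax(raw == c)))
    )
    mapping = {c: i for i, c in enumerate(order)}
    return np.array([mapping[c] for c in raw])


def silhouette(embedding: np.ndarray, labels: np.ndarray) -> float:
    """Average silhouette score (b - a)/max(a, b); singletons contribute 0."""
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise DomainError("silhouette undefined for a single cluster")
    return float(silhouette_score(np.asarray(embedding, float), labels))


# ---------------------------------------------------------------------------
# CDbw composed-density validity index


def _representatives(points: np.ndarray, n_reps: int) -> np.ndarray:
    """Boundary representatives by farthest-point traversal from the centroid."""
    centroid = points.mean(axis=0)
    chosen = [int(np.argmax(np.linalg.norm(points - centroid, axis=1)))]
    d_min = np.linalg.norm(points - points[chosen[0]], axis=1)
    while len(chosen) < min(n_reps, points.shape[0]):
        nxt = int(np.argmax(d_min))
        chosen.append(nxt)
        d_min = np.minimum(d_min, np.linalg.norm(points - points[nxt], axis=1))
    return points[chosen]


def cdbw(embedding: np.ndarray, labels: np.ndarray, n_reps: int = 10,
         shrink: np.ndarray | None = None) -> float:
    """Composed density between and within clusters (higher is better).

    Each cluster is summarized by ``n_reps`` boundary representatives
    (farthest-point traversal from the centroid). Cohesion and compactness
    come from the fraction of cluster points within one standard radius of
    the representatives shrunk toward the centroid over factors
    s in {0.1, ..., 0.8}; separation contrasts the distance between closest
    representative pairs with the point density at their midpoints. Designed
    for non-spherical clusters where centroid-only indices mislead.
    """
    embedding = np.asarray(embedding, dtype=float)
    labels = np.asarray(labels)
    if shrink is None:
        shrink = np.arange(0.1, 0.81, 0.1)
    ids = np.unique(labels)
    clusters = [embedding[labels == c] for c in ids]
    if min(len(c) for c in clusters) < n_reps:
        raise ConfigError("n_reps exceeds the smallest cluster size")
    centroids = [c.mean(axis=0) for c in clusters]
    stdevs = [float(np.sqrt(np.mean(np.sum((c - m) ** 2, axis=1))))
              for c, m in zip(clusters, centroids)]
    reps = [_representatives(c, n_reps) for c in clusters]

    # separation: closest representative pairs vs midpoint density
    seps = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            d = cdist(reps[i], reps[j])
            close_i = np.argmin(d, axis=1)
            pairs = [(reps[i][a], reps[j][close_i[a]], d[a, close_i[a]])
                     for a in range(d.shape[0])]
            radius = 0.5 * (stdevs[i] + stdevs[j])
            both = np.vstack([clusters[i], clusters[j]])
            dens = []
            for va, vb, dist_ab in pairs:
                u = 0.5 * (va + vb)
                card = np.mean(np.linalg.norm(both - u, axis=1) <= radius)
                dens.append((dist_ab / (2.0 * radius + 1e-12)) * card)
            dens_bw = float(np.mean(dens))
            d_close = float(np.min(d))
            seps.append(d_close / (1.0 + dens_bw))
    sep = float(np.mean(seps))

    # within-cluster density of shrunk representatives
    dens_per_shrink = []
    for s in shrink:
        vals = []
        for c, m, sd, r in zip(clusters, centroids, stdevs, reps):
            shrunk = r + s * (m - r)
            inside = cdist(shrunk, c) <= max(sd, 1e-12)
            vals.append(float(np.mean(np.mean(inside, axis=1))))
        dens_per_shrink.append(float(np.mean(vals)))
    dens_per_shrink = np.asarray(dens_per_shrink)
    compactness = float(np.mean(dens_per_shrink))
    intra_change = float(np.mean(np.abs(np.diff(dens_per_shrink)))) \
        if dens_per_shrink.size > 1 else 0.0
    cohesion = compactness / (1.0 + intra_change)
    return cohesion * sep * compactness


# ---------------------------------------------------------------------------
# identity assignment


def assign_cluster_identity(events: list[EODEvent], labels: np.ndarray,
                            ) -> tuple[dict[int, str], bool]:
    """Map the two clusters to fish ids A/B from amplitude signatures.

    For each cluster the mean signed peak amplitude per channel is computed;
    clusters are ordered by (dominant channel, descending mean polarity on
    it) and assigned A then B. The fish's position in the tank determines
    which electrode pair dominates and with which sign, so in a stable scene
    this reproduces the manual identification step. Identical signatures are
    flagged ambiguous (returned flag True), not an error.
    """
    labels = np.asarray(labels)
    signatures: dict[int, tuple] = {}
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        sig = []
        for ch in (0, 1):
            amps = [events[i].peak_amp_V for i in idx if events[i].channel == ch]
            sig.append(float(np.mean(amps)) if amps else 0.0)
        dominant = int(np.argmax(np.abs(sig)))
        signatures[c] = (dominant, -sig[dominant], tuple(np.round(sig, 9)))
    ordered = sorted(signatures, key=lambda c: signatures[c])
    ambiguous = (len(ordered) == 2 and
                 signatures[ordered[0]][2] == signatures[ordered[1]][2])
    names = "AB"
    return {c: names[i] for i, c in enumerate(ordered)}, ambiguous


# ---------------------------------------------------------------------------
# estimator


class TSNEPairSeparator(ClusterMixin, BaseEstimator):
    """Sklearn-style clusterer: t-SNE embedding + average-linkage 2-cut.

    fit(X) computes ``embedding_`` (n x 2), ``labels_`` (0/1),
    ``silhouette_`` and ``cdbw_``. X is any n x d feature matrix; the
    toolkit feeds flattened Morse scalograms.
    """

    def __init__(self, perplexity: float = 50.0, seed: int = 0,
                 init: str = "pca", n_iter: int = 750, n_reps: int = 10,
                 compute_cdbw: bool = True):
        self.perplexity = perplexity
        self.seed = seed
        self.init = init
        self.n_iter = n_iter
        self.n_reps = n_reps
        self.compute_cdbw = compute_cdbw

    def _config(self) -> SeparationConfig:
        return SeparationConfig(perplexity=self.perplexity, seed=self.seed,
                                init=self.init, n_iter=self.n_iter)

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        t0 = time.perf_counter()
        self.embedding_ = tsne_embed(X, self._config())
        t1 = time.perf_counter()
        n = X.shape[0]
        if n > LINKAGE_SUBSAMPLE:
            rng = np.random.default_rng(self.seed)
            sub = np.sort(rng.choice(n, LINKAGE_SUBSAMPLE, replace=False))
            sub_labels = hcluster2(self.embedding_[sub])
            d = cdist(self.embedding_, self.embedding_[sub])
            self.labels_ = sub_labels[np.argmin(d, axis=1)]
            self.labels_[sub] = sub_labels
        else:
            self.labels_ = hcluster2(self.embedding_)
        t2 = time.perf_counter()
        if np.unique(self.labels_).size > 1:
            self.silhouette_ = silhouette(self.embedding_, self.labels_)
            counts = np.bincount(self.labels_)
            if self.compute_cdbw and counts.min() >= self.n_reps:
                self.cdbw_ = cdbw(self.embedding_, self.labels_, self.n_reps)
            else:
                self.cdbw_ = float("nan")
        else:  # degenerate: everything merged into one cluster
            self.silhouette_ = float("nan")
            self.cdbw_ = float("nan")
        self.runtime_s_ = {"tsne": t1 - t0, "cluster": t2 - t1}
        self.n_features_in_ = X.shape[1]
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


# ---------------------------------------------------------------------------
# end-to-end pipeline and perplexity selection


def separate(recording: Recording,
             detection_config: DetectionConfig = DetectionConfig(),
             morse_params: MorseParams = MorseParams(),
             config: SeparationConfig = SeparationConfig(),
             ) -> tuple[SeparationResult, list[EODEvent]]:
    """detect -> extract -> scalogram features -> embed -> cluster -> score.

    Returns the separation result and the detected events with their
    ``label`` field set to the assigned fish identity. Logs per-stage counts
    and runtimes. A recording holding a single fish still yields two
    clusters (k is fixed); low quality metrics flag the degeneracy in
    ``result.warnings``.
    """
    t0 = time.perf_counter()
    events, waveforms = detect_and_extract(recording, detection_config)
    t1 = time.perf_counter()
    log.info("detected %d EODs in %.1f s", len(events), t1 - t0)
    if len(events) < 3 * config.perplexity:
        raise ConfigError(
            f"only {len(events)} EODs detected, below 3 x perplexity "
            f"({config.perplexity:.0f}); lower the perplexity"
        )
    features = feature_matrix(waveforms, "timefreq", morse_params,
                              fs=recording.fs)
    t2 = time.perf_counter()
    est = TSNEPairSeparator(perplexity=config.perplexity, seed=config.seed,
                            init=config.init, n_iter=config.n_iter).fit(features)
    identity_map, ambiguous = assign_cluster_identity(events, est.labels_)
    warnings = []
    if ambiguous:
        warnings.append("cluster amplitude signatures are ambiguous")
    if np.isfinite(est.silhouette_) and est.silhouette_ < 0.25:
        warnings.append(
            "low silhouette: the recording may contain a single fish or "
            "indistinguishable individuals"
        )
    for e, lab in zip(events, est.labels_):
        e.label = identity_map[int(lab)]
    result = SeparationResult(
        embedding=est.embedding_, labels=est.labels_, ss=est.silhouette_,
        cdbw=est.cdbw_, identity_map=identity_map, ambiguous=ambiguous,
        warnings=warnings,
        runtime_s={"detect": t1 - t0, "features": t2 - t1,
                   **est.runtime_s_},
    )
    return result, events


def select_perplexity(feature_sets: list[tuple[np.ndarray, np.ndarray]],
                      grid: list[float], seed: int = 0,
                      ) -> tuple[float, "np.ndarray"]:
    """Pick the grid perplexity maximizing median MCC over labeled dyads.

    ``feature_sets`` is a list of (features, truth_labels) pairs. For each
    grid value the embed -> cluster -> align -> score loop runs on every
    set; the returned value attains the highest median MCC, with median
    accuracy then total runtime as tie-breakers. Also returns the score
    table (rows: perplexity, median_acc, median_mcc, runtime_s).
    """
    from .evaluation import align_labels, confusion_2x2, mcc

    if not grid:
        raise ConfigError("empty perplexity grid")
    for p in grid:
        if not 30 <= p <= 120:
            raise ConfigError(f"perplexity {p} outside the supported 30-120")
    rows = []
    for p in grid:
        accs, mccs = [], []
        t0 = time.perf_counter()
        for features, truth in feature_sets:
            est = TSNEPairSeparator(perplexity=p, seed=seed).fit(features)
            aligned, _ = align_labels(est.labels_, np.asarray(truth))
            accs.append(float(np.mean(aligned == np.asarray(truth))))
            mccs.append(mcc(confusion_2x2(aligned, np.asarray(truth))))
        rows.append((p, float(np.median(accs)), float(np.median(mccs)),
                     time.perf_counter() - t0))
    table = np.array(rows)
    best = sorted(rows, key=lambda r: (-r[2], -r[1], r[3]))[0][0]
    return float(best), table
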
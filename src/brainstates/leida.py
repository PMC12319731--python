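"""Leading Eigenvector Dynamics Analysis (LEiDA).

Pipeline: band-pass filter regional BOLD, take the analytic-signal phase,
form the per-timepoint phase-coherence matrix cos(theta_i - theta_j),
summarise each frame by its leading eigenvector (sign-fixed to a
majority-negative convention), pool frames across subjects, and cluster the
pooled eigenvectors with k-means over a range of k. The number of states is
chosen by jointly ranking Dunn's index, the mean silhouette coefficient and
the Calinski-Harabasz index. Each state is named after the reference
resting-state network that overlaps most with its positive-centroid regions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import eigh
from scipy.signal import butter, hilbert, sosfiltfilt
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans
from sklearn.metrics import calinski_harabasz_score, pairwise_distances, silhouette_samples

from .synth import BoldTimeSeries

__all__ = [
    "bandpass_filter",
    "instantaneous_phase",
    "phase_coherence_matrix",
    "phase_coherence_series",
    "leading_eigenvector",
    "leading_eigenvectors",
    "pool_eigenvectors",
    "unpool_labels",
    "dunn_index",
    "cluster_validity",
    "LeidaStates",
    "cluster_eigenvectors",
    "label_states",
    "assign_states",
]

_SIGN_TOL = 1e-12
GLOBAL_COHERENCE = "Global Coherence"


def bandpass_filter(
    ts: BoldTimeSeries | np.ndarray,
    low_hz: float = 0.01,
    high_hz: float = 0.1,
    sampling_interval: float | None = None,
    order: int = 2,
) -> BoldTimeSeries | np.ndarray:
    """Zero-phase Butterworth band-pass of each region's signal.

    The filter is applied forward and backward (``sosfiltfilt``), so the
    passband gain is the squared magnitude response and the phase response
    is identically zero -- instantaneous phases downstream are undistorted.
    """
    if isinstance(ts, BoldTimeSeries):
        data, dt = ts.data, ts.sampling_interval
    else:
        if sampling_interval is None:
            raise ValueError("sampling_interval required for a bare array")
        data, dt = np.asarray(ts, dtype=float), sampling_interval
    nyquist = 0.5 / dt
    if not 0 < low_hz < high_hz < nyquist:
        raise ValueError(
            f"band ({low_hz}, {high_hz}) Hz must satisfy 0 < low < high < Nyquist={nyquist:.4g}"
        )
    sos = butter(order, [low_hz, high_hz], btype="band", fs=1.0 / dt, output="sos")
    padlen = 3 * (2 * sos.shape[0] + 1)
    if data.shape[-1] <= padlen:
        raise ValueError(
            f"series length {data.shape[-1]} too short for filter warm-up (needs > {padlen})"
        )
    out = sosfiltfilt(sos, data, axis=-1)
    if isinstance(ts, BoldTimeSeries):
        return BoldTimeSeries(ts.subject_id, out, dt)
    return out


def instantaneous_phase(ts: BoldTimeSeries | np.ndarray) -> np.ndarray:
    """Analytic-signal phase of each (band-limited) region, radians in (-pi, pi].

    The first and last frame carry Hilbert endpoint transients; pooling
    discards them by default (see :func:`pool_eigenvectors`).
    """
    data = ts.data if isinstance(ts, BoldTimeSeries) else np.asarray(ts, dtype=float)
    if np.all(data == 0, axis=-1).any():
        raise ValueError("phase undefined for an all-zero channel")
    return np.angle(hilbert(data, axis=-1))


def phase_coherence_matrix(phases_at_t: np.ndarray) -> np.ndarray:
    """N x N matrix with entry (i, j) = cos(theta_i - theta_j)."""
    theta = np.asarray(phases_at_t, dtype=float)
    if not np.isfinite(theta).all():
        raise ValueError("phases must be finite")
    return np.cos(theta[:, None] - theta[None, :])


def phase_coherence_series(phases: np.ndarray) -> np.ndarray:
    """Stack of per-timepoint coherence matrices, shape (T, N, N)."""
    theta = np.asarray(phases, dtype=float)
    return np.cos(theta.T[:, :, None] - theta.T[:, None, :])


def _fix_sign(v: np.ndarray) -> np.ndarray:
    m = v.mean()
    if m > _SIGN_TOL or (abs(m) <= _SIGN_TOL and v[0] > _SIGN_TOL):
        return -v
    return v


def leading_eigenvector(frame: np.ndarray, degeneracy_tol: float = 1e-10) -> np.ndarray:
    """Unit eigenvector of the largest eigenvalue, majority-negative sign.

    Sign convention: flip so mean(v) <= 0; an exactly zero mean is broken by
    forcing the first element <= 0. A degenerate top eigenvalue triggers a
    warning and the deterministic eigensolver choice is kept.
    """
    frame = np.asarray(frame, dtype=float)
    n = frame.shape[0]
    vals, vecs = eigh(frame, subset_by_index=(n - 2, n - 1)) if n > 1 else eigh(frame)
    if n > 1 and abs(vals[-1] - vals[-2]) <= degeneracy_tol * max(1.0, abs(vals[-1])):
        warnings.warn("degenerate leading eigenvalue; deterministic eigensolver choice kept",
                      RuntimeWarning, stacklevel=2)
    v = vecs[:, -1]
    v = v / np.linalg.norm(v)
    return _fix_sign(v)


def leading_eigenvectors(phases: np.ndarray) -> np.ndarray:
    """Leading eigenvector of every frame's coherence matrix, shape (T, N)."""
    theta = np.asarray(phases, dtype=float)
    n, t = theta.shape
    out = np.empty((t, n))
    for j in range(t):
        frame = np.cos(theta[:, j][:, None] - theta[:, j][None, :])
        vals, vecs = eigh(frame, subset_by_index=(n - 1, n - 1))
        v = vecs[:, 0] / np.linalg.norm(vecs[:, 0])
        out[j] = _fix_sign(v)
    return out


def subject_eigenvectors(ts: BoldTimeSeries, low_hz: float = 0.01, high_hz: float = 0.1
                         ) -> np.ndarray:
    """Filter -> phase -> per-frame leading eigenvectors for one subject."""
    filtered = bandpass_filter(ts, low_hz, high_hz)
    return leading_eigenvectors(instantaneous_phase(filtered))


def pool_eigenvectors(
    cohort: dict[str, np.ndarray], keep_edges: bool = False
) -> tuple[np.ndarray, pd.DataFrame]:
    """Concatenate per-subject eigenvector series into one (frames x N) matrix.

    By default the first and last frame of every subject are discarded
    (analytic-signal endpoint artifacts); ``keep_edges=True`` retains all
    frames. The returned index maps each pooled row back to
    (subject_id, timepoint).
    """
    if not cohort:
        raise ValueError("empty cohort")
    widths = {v.shape[1] for v in cohort.values()}
    if len(widths) > 1:
        raise ValueError(f"inconsistent region counts across subjects: {sorted(widths)}")
    blocks, idx_subject, idx_time = [], [], []
    for sid, series in cohort.items():
        t = series.shape[0]
        sl = slice(None) if keep_edges else slice(1, t - 1)
        blocks.append(series[sl])
        times = np.arange(t)[sl]
        idx_subject.extend([sid] * times.size)
        idx_time.extend(times.tolist())
    pooled = np.vstack(blocks)
    index = pd.DataFrame({"subject_id": idx_subject, "timepoint": idx_time})
    return pooled, index


def unpool_labels(labels: np.ndarray, index: pd.DataFrame) -> dict[str, np.ndarray]:
    """Map pooled per-frame labels back to per-subject sequences."""
    labels = np.asarray(labels)
    out: dict[str, np.ndarray] = {}
    for sid, grp in index.groupby("subject_id", sort=False):
        out[sid] = labels[grp.index.to_numpy()]
    return out


# ---------------------------------------------------------------------------
# Cluster validity

def dunn_index(points: np.ndarray, labels: np.ndarray,
               distances: np.ndarray | None = None) -> float:
    """Min inter-cluster point-pair distance / max intra-cluster diameter.

    A zero intra-cluster diameter (all clusters of identical points) is
    replaced by machine epsilon to keep the ratio finite.
    """
    points = np.asarray(points, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("Dunn index requires at least 2 clusters")
    d = pairwise_distances(points) if distances is None else distances
    same = labels[:, None] == labels[None, :]
    inter = d[~same]
    iu = np.triu_indices(d.shape[0], k=1)
    intra_mask = same[iu]
    diam = d[iu][intra_mask].max() if intra_mask.any() else 0.0
    if diam <= 0.0:
        diam = np.finfo(float).eps
    return float(inter.min() / diam)


def cluster_validity(points: np.ndarray, labels: np.ndarray,
                     distances: np.ndarray | None = None
                     ) -> tuple[float, float, float]:
    """(Dunn, mean silhouette, Calinski-Harabasz) for one partition.

    Silhouette contributions of singleton clusters are 0.
    """
    points = np.asarray(points, dtype=float)
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("validity indices require at least 2 clusters")
    d = pairwise_distances(points) if distances is None else distances
    dunn = dunn_index(points, labels, distances=d)
    sil = float(silhouette_samples(d, labels, metric="precomputed").mean())
    ch = float(calinski_harabasz_score(points, labels))
    return dunn, sil, ch


# ---------------------------------------------------------------------------
# State model

class LeidaStates(ClusterMixin, BaseEstimator):
    """K-means state model over pooled leading eigenvectors with joint
    validity-index model selection.

    For each k in ``k_range`` a best-of-``n_restarts`` k-means partition
    (Euclidean distance, k-means++ seeding) is fitted and scored with Dunn's
    index, mean silhouette and Calinski-Harabasz. Each index ranks the
    candidate k (rank 1 = best); the k with the lowest mean rank wins, ties
    going to the smallest k. States are renumbered 1..K by descending pooled
    occupancy, mirroring the field convention that state 1 is the most
    frequent (typically globally coherent) state.

    Attributes
    ----------
    chosen_k_ : selected number of states
    centroids_ : (K, N) unit-norm centroids, sign-fixed like eigenvectors
    centroids_raw_ : (K, N) raw k-means centroids used for assignment
    labels_ : 1-based state of every pooled frame
    validity_ : DataFrame indexed by k with columns dunn/silhouette/
        calinski_harabasz/inertia/mean_rank
    state_names_ : set by :meth:`name_states`
    """

    def __init__(self, k_range=(2, 20), n_restarts: int = 50, max_iter: int = 300,
                 tol: float = 1e-6, random_state: int | None = None):
        self.k_range = k_range
        self.n_restarts = n_restarts
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be (frames x regions)")
        ks = list(range(int(self.k_range[0]), int(self.k_range[1]) + 1))
        if X.shape[0] < max(ks):
            raise ValueError("fewer pooled frames than the largest k searched")
        d = pairwise_distances(X)
        rows, fits = [], {}
        for i, k in enumerate(ks):
            km = KMeans(n_clusters=k, n_init=self.n_restarts, max_iter=self.max_iter,
                        tol=self.tol, init="k-means++", algorithm="lloyd",
                        random_state=None if self.random_state is None
                        else self.random_state + i)
            lab = km.fit_predict(X)
            dunn, sil, ch = cluster_validity(X, lab, distances=d)
            fits[k] = km
            rows.append(dict(k=k, dunn=dunn, silhouette=sil, calinski_harabasz=ch,
                             inertia=km.inertia_))
        table = pd.DataFrame(rows).set_index("k")
        ranks = table[["dunn", "silhouette", "calinski_harabasz"]].rank(
            ascending=False, method="min")
        table["mean_rank"] = ranks.mean(axis=1)
        best = int(table.index[np.argmin(table["mean_rank"].to_numpy())])
        km = fits[best]
        # renumber states by descending occupancy; ties by original label
        counts = np.bincount(km.labels_, minlength=best)
        order = np.argsort(-counts, kind="stable")
        remap = np.empty(best, dtype=int)
        remap[order] = np.arange(best)
        self.chosen_k_ = best
        self.centroids_raw_ = km.cluster_centers_[order]
        self.centroids_ = np.array([
            _fix_sign(c / np.linalg.norm(c)) for c in self.centroids_raw_
        ])
        self.labels_ = remap[km.labels_] + 1
        self.validity_ = table
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X) -> np.ndarray:
        """Assign each frame to its nearest centroid; 1-based state indices.

        Ties go to the lowest state index.
        """
        X = np.asarray(X, dtype=float)
        return assign_states(X, self.centroids_raw_)

    def name_states(self, region_networks) -> list[str]:
        """Label fitted states by reference-network overlap; stores state_names_."""
        self.state_names_ = label_states(self.centroids_, region_networks)
        return self.state_names_


def cluster_eigenvectors(pooled, k_range=(2, 20), n_restarts: int = 50,
                         seed: int | None = None) -> LeidaStates:
    """Functional wrapper over :class:`LeidaStates`."""
    return LeidaStates(k_range=k_range, n_restarts=n_restarts, random_state=seed).fit(pooled)


def assign_states(eigenvector_series: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    """Nearest-centroid (Euclidean) state per frame, 1-based; ties -> lowest index."""
    x = np.atleast_2d(np.asarray(eigenvector_series, dtype=float))
    c = np.asarray(centroids, dtype=float)
    if x.shape[1] != c.shape[1]:
        raise ValueError("region count mismatch between series and centroids")
    d2 = ((x[:, None, :] - c[None, :, :]) ** 2).sum(axis=2)
    return np.argmin(d2, axis=1) + 1  # argmin takes the first minimum -> lowest index


def label_states(centroids: np.ndarray, region_networks) -> list[str]:
    """Name each state after the network maximising overlap with its
    positive-centroid regions.

    Overlap score of a network = sum of positive centroid values over that
    network's regions. A centroid whose entries are all one sign carries no
    community structure and is named "Global Coherence". Ties break
    alphabetically.
    """
    networks = np.asarray(list(region_networks))
    if networks.size == 0:
        raise ValueError("empty reference partition")
    centroids = np.atleast_2d(np.asarray(centroids, dtype=float))
    if centroids.shape[1] != networks.size:
        raise ValueError("centroid length does not match region label count")
    names: list[str] = []
    uniq = sorted(set(networks.tolist()))
    for c in centroids:
        pos = c > 0
        if not pos.any() or pos.all():
            names.append(GLOBAL_COHERENCE)
            continue
        scores = {net: c[pos & (networks == net)].sum() for net in uniq}
        names.append(min(uniq, key=lambda net: (-scores[net], net)))
    return names
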
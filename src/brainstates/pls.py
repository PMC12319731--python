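"""Partial least squares brain-behavior statistics.

Two variants, both SVD-based:

* Behavioral PLS decomposes the brain-by-behavior Pearson cross-correlation
  matrix R = corr(Y, X) into latent variables (LVs) that pair a brain
  salience (weights over features) with a behavior salience.
* Mean-centered PLS decomposes the column-centered matrix of group means,
  extracting LVs that contrast groups.

Inference follows the permutation/bootstrap framework standard in
neuroimaging PLS: LV significance by permuting the behavior (or group)
assignment and comparing singular values directly; feature reliability by
bootstrap ratios (BSR = salience / bootstrap SE), with each resample's
saliences aligned to the original by an orthogonal Procrustes rotation to
avoid axis reflection and reordering artifacts. Permutation p-values use
the +1 smoothing, so they are never exactly 0.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.linalg import orthogonal_procrustes, svd
from sklearn.base import BaseEstimator

__all__ = [
    "BehavioralPLS",
    "MeanCenteredPLS",
    "behavioral_pls",
    "mean_centered_pls",
    "salience_cosine_similarity",
]

BSR_RELIABLE = 2.0  # ~95% normal-theory reliability threshold


def _as_2d(x, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if x.ndim != 2:
        raise ValueError(f"{name} must be 1- or 2-D")
    if not np.isfinite(x).all():
        raise ValueError(f"{name} contains non-finite values")
    return x


def _zscore(x: np.ndarray, name: str, columns=None) -> np.ndarray:
    sd = x.std(axis=0, ddof=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        labels = bad if columns is None else [columns[i] for i in bad]
        raise ValueError(f"zero-variance column(s) in {name}: {labels}")
    return (x - x.mean(axis=0)) / sd


def _cross_correlation(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Q x P Pearson correlation matrix between behavior and brain blocks."""
    n = X.shape[0]
    zx = _zscore(X, "X")
    zy = _zscore(Y, "Y")
    return (zy.T @ zx) / (n - 1)


def _svd_lv(R: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """SVD of the cross-block matrix: returns (behavior/group saliences U,
    singular values, brain saliences V) with L = min(Q, P) columns."""
    u, s, vt = svd(R, full_matrices=False)
    return u, s, vt.T


def _perm_pvalues(s_obs: np.ndarray, null_s: np.ndarray) -> np.ndarray:
    """p(LV l) = (1 + #{perm s_l >= obs s_l}) / (1 + n_perm), per LV."""
    n_perm = null_s.shape[0]
    exceed = (null_s >= s_obs[None, :]).sum(axis=0)
    return (1.0 + exceed) / (1.0 + n_perm)


def _align(V_b: np.ndarray, V: np.ndarray) -> np.ndarray:
    """Orthogonal Procrustes rotation of bootstrap saliences onto the original."""
    Q, _ = orthogonal_procrustes(V_b, V)
    return V_b @ Q


class BehavioralPLS(BaseEstimator):
    """Behavioral PLS with permutation and bootstrap inference.

    Parameters
    ----------
    n_perm, n_boot : resampling iterations (default 1000 each)
    random_state : seed for all resampling
    bsr_threshold : |BSR| above which a feature is flagged reliable

    Fitted attributes
    -----------------
    singular_values_ : (L,) descending
    brain_saliences_ : (P, L) unit-norm columns
    behavior_saliences_ : (Q, L) unit-norm columns
    perm_pvalues_ : (L,)
    bootstrap_ratios_ : (P, L) salience / bootstrap SE
    salience_se_ : (P, L)
    reliable_ : (P, L) boolean, |BSR| >= bsr_threshold
    brainscores_ : (n, L) z-scored X projected on brain saliences
    behavior_scores_ : (n, L) z-scored Y projected on behavior saliences
    """

    def __init__(self, n_perm: int = 1000, n_boot: int = 1000,
                 random_state: int | None = None, bsr_threshold: float = BSR_RELIABLE):
        self.n_perm = n_perm
        self.n_boot = n_boot
        self.random_state = random_state
        self.bsr_threshold = bsr_threshold

    def fit(self, X, Y):
        X = _as_2d(X, "X")
        Y = _as_2d(Y, "Y")
        if X.shape[0] != Y.shape[0]:
            raise ValueError("X and Y must have the same subject rows")
        if X.shape[0] < 3:
            raise ValueError("need at least 3 subjects")
        rng = np.random.default_rng(self.random_state)
        R = _cross_correlation(X, Y)
        U, s, V = _svd_lv(R)
        self.singular_values_ = s
        self.brain_saliences_ = V
        self.behavior_saliences_ = U
        self.brainscores_ = _zscore(X, "X") @ V
        self.behavior_scores_ = _zscore(Y, "Y") @ U

        null_s = np.empty((self.n_perm, s.size))
        n = X.shape[0]
        for b in range(self.n_perm):
            perm = rng.permutation(n)
            null_s[b] = _svd_lv(_cross_correlation(X, Y[perm]))[1]
        self.perm_pvalues_ = _perm_pvalues(s, null_s)

        boot_V = np.empty((self.n_boot, *V.shape))
        for b in range(self.n_boot):
            boot_V[b] = _align(self._resample_saliences(X, Y, rng), V)
        se = boot_V.std(axis=0, ddof=1)
        self.salience_se_ = se
        with np.errstate(divide="ignore"):
            bsr = np.where(se > 0, V / np.where(se > 0, se, 1.0), np.inf * np.sign(V))
        if (se == 0).any():
            warnings.warn("zero bootstrap SE: BSR unbounded for some weights",
                          RuntimeWarning, stacklevel=2)
        self.bootstrap_ratios_ = bsr
        self.reliable_ = np.abs(bsr) >= self.bsr_threshold
        return self

    @staticmethod
    def _resample_saliences(X, Y, rng, max_attempts: int = 10) -> np.ndarray:
        n = X.shape[0]
        for _ in range(max_attempts):
            idx = rng.integers(0, n, size=n)
            Xb, Yb = X[idx], Y[idx]
            if (Xb.std(axis=0) == 0).any() or (Yb.std(axis=0) == 0).any():
                continue
            return _svd_lv(_cross_correlation(Xb, Yb))[2]
        raise RuntimeError("bootstrap resamples kept producing zero-variance columns")


class MeanCenteredPLS(BaseEstimator):
    """Mean-centered (group-contrast) PLS with permutation and bootstrap
    inference, including per-group brainscore bootstrap CIs.

    Fitted attributes (beyond the behavioral variant's analogues):
    group_names_ : ordered group labels
    group_saliences_ : (G, L)
    group_brainscores_ : (G, L) mean subject brainscore per group
    group_brainscore_ci_ : (G, L, 2) percentile bootstrap 95% CI
    """

    def __init__(self, n_perm: int = 1000, n_boot: int = 1000,
                 random_state: int | None = None, bsr_threshold: float = BSR_RELIABLE,
                 ci_level: float = 0.95):
        self.n_perm = n_perm
        self.n_boot = n_boot
        self.random_state = random_state
        self.bsr_threshold = bsr_threshold
        self.ci_level = ci_level

    @staticmethod
    def _group_matrix(X, groups, order) -> np.ndarray:
        means = np.stack([X[groups == g].mean(axis=0) for g in order])
        return means - means.mean(axis=0)

    def fit(self, X, groups):
        X = _as_2d(X, "X")
        groups = np.asarray(groups)
        if groups.shape[0] != X.shape[0]:
            raise ValueError("groups must align with X rows")
        order = [g for g in dict.fromkeys(groups.tolist())]
        if len(order) < 2:
            raise ValueError("need at least 2 groups")
        sizes = {g: int((groups == g).sum()) for g in order}
        singles = [g for g, c in sizes.items() if c < 2]
        if singles:
            raise ValueError(f"singleton group(s): {singles}")
        rng = np.random.default_rng(self.random_state)

        Mc = self._group_matrix(X, groups, order)
        U, s, V = _svd_lv(Mc)
        self.group_names_ = order
        self.singular_values_ = s
        self.brain_saliences_ = V
        self.group_saliences_ = U
        centered = X - X.mean(axis=0)
        self.brainscores_ = centered @ V
        self.group_brainscores_ = np.stack(
            [self.brainscores_[groups == g].mean(axis=0) for g in order])

        null_s = np.empty((self.n_perm, s.size))
        for b in range(self.n_perm):
            null_s[b] = _svd_lv(self._group_matrix(X, groups[rng.permutation(groups.size)],
                                                   order))[1]
        self.perm_pvalues_ = _perm_pvalues(s, null_s)

        boot_V = np.empty((self.n_boot, *V.shape))
        boot_gs = np.empty((self.n_boot, len(order), s.size))
        idx_by_group = {g: np.flatnonzero(groups == g) for g in order}
        for b in range(self.n_boot):
            idx = np.concatenate([
                rng.choice(idx_by_group[g], size=idx_by_group[g].size, replace=True)
                for g in order
            ])
            Xb, gb = X[idx], groups[idx]
            Vb = _align(_svd_lv(self._group_matrix(Xb, gb, order))[2], V)
            boot_V[b] = Vb
            cb = Xb - Xb.mean(axis=0)
            scores_b = cb @ Vb
            boot_gs[b] = np.stack([scores_b[gb == g].mean(axis=0) for g in order])
        se = boot_V.std(axis=0, ddof=1)
        self.salience_se_ = se
        with np.errstate(divide="ignore"):
            bsr = np.where(se > 0, V / np.where(se > 0, se, 1.0), np.inf * np.sign(V))
        if (se == 0).any():
            warnings.warn("zero bootstrap SE: BSR unbounded for some weights",
                          RuntimeWarning, stacklevel=2)
        self.bootstrap_ratios_ = bsr
        self.reliable_ = np.abs(bsr) >= self.bsr_threshold
        alpha = (1.0 - self.ci_level) / 2.0
        lo = np.quantile(boot_gs, alpha, axis=0)
        hi = np.quantile(boot_gs, 1.0 - alpha, axis=0)
        self.group_brainscore_ci_ = np.stack([lo, hi], axis=-1)
        return self


def behavioral_pls(X, Y, n_perm: int = 1000, n_boot: int = 1000,
                   seed: int | None = None) -> BehavioralPLS:
    return BehavioralPLS(n_perm=n_perm, n_boot=n_boot, random_state=seed).fit(X, Y)


def mean_centered_pls(X, groups, n_perm: int = 1000, n_boot: int = 1000,
                      seed: int | None = None) -> MeanCenteredPLS:
    return MeanCenteredPLS(n_perm=n_perm, n_boot=n_boot, random_state=seed).fit(X, groups)


def salience_cosine_similarity(saliences_a, saliences_b, null_fn=None,
                               n_perm: int = 1000, seed: int | None = None
                               ) -> tuple[float, float | None]:
    """Cosine similarity between two salience vectors, with an optional
    permutation test.

    `null_fn(rng)` must return a null counterpart of `saliences_b`
    (e.g. the LV1 brain salience of model b refitted under permuted
    behavior); the p-value is (1 + #{|null cosine| >= |observed|}) /
    (1 + n_perm). Without `null_fn` only the cosine is returned (p None).
    """
    a = np.asarray(saliences_a, dtype=float).ravel()
    b = np.asarray(saliences_b, dtype=float).ravel()
    if a.size != b.size:
        raise ValueError("salience vectors must have equal length")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine undefined for a zero vector")
    cosine = float(a @ b / (na * nb))
    if null_fn is None:
        return cosine, None
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        null_b = np.asarray(null_fn(rng), dtype=float).ravel()
        nn = np.linalg.norm(null_b)
        if nn == 0:
            raise ValueError("null_fn returned a zero vector")
        if abs(float(a @ null_b / (na * nn))) >= abs(cosine):
            exceed += 1
    return cosine, (1.0 + exceed) / (1.0 + n_perm)
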
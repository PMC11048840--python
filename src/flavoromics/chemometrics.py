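"""Two-class OPLS-DA, cross-validated Q², permutation testing, VIP scores and
hierarchical clustering.

OPLS-DA splits predictor variation into one class-predictive component and a
small number of *orthogonal* components that capture structured variation
uncorrelated with class membership.  The implementation follows the
orthogonal-signal-correction NIPALS recipe: a PLS weight vector
``w ∝ X'y`` defines the predictive direction; each orthogonal component is
extracted from the part of the X-loading not collinear with ``w``, removed
from X by deflation, and the single predictive component is then fitted on
the filtered matrix.  Classes are encoded +1/-1 and centered, so the model
is an ordinary PLS1 regression on the class code after orthogonal filtering.

Model quality is summarized by R²X (fraction of X sum of squares captured by
the predictive plus orthogonal components), R²Y (fraction of the class-code
sum of squares explained in training) and Q² (1 - PRESS/SS under stratified
k-fold cross-validation, scaling re-estimated inside each training split).
Significance of the separation is assessed by refitting under random label
permutations and reporting add-one p-values, so an observed statistic that
no permutation reaches gets p = 1/(n_permutations + 1), never 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .io_core import IntensityMatrix, PipelineConfig, ValidationError

_DEGENERATE_TOL = 1e-12


# ---------------------------------------------------------------------------
# scaling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScalingRecord:
    """Per-variable centers/scales actually applied, plus dropped variables."""

    method: str
    centers: np.ndarray
    scales: np.ndarray
    variables: tuple[str, ...]
    dropped: tuple[str, ...]

    def apply(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.centers) / self.scales

    def undo(self, X_scaled: np.ndarray) -> np.ndarray:
        return np.asarray(X_scaled, dtype=float) * self.scales + self.centers


def _as_sample_matrix(X) -> tuple[np.ndarray, list[str], list[str] | None]:
    """Coerce input to (samples x variables array, variable names, sample labels).

    An :class:`IntensityMatrix` stores compounds x samples and is transposed;
    a DataFrame is taken as samples x variables; a bare array is used as-is.
    """
    if isinstance(X, IntensityMatrix):
        return X.values.to_numpy(dtype=float).T, list(X.values.index), X.samples
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), [str(c) for c in X.columns], [str(i) for i in X.index]
    arr = np.asarray(X, dtype=float)
    if arr.ndim != 2:
        raise ValidationError(f"expected a 2-D matrix, got shape {arr.shape}")
    return arr, [f"var{j}" for j in range(arr.shape[1])], None


def scale_matrix(X, method: str = "unit_variance") -> tuple[np.ndarray, ScalingRecord]:
    """Column-center and scale a samples x variables matrix.

    ``unit_variance`` divides each column by its sd, ``pareto`` by sqrt(sd),
    ``none`` only centers.  Zero-variance columns cannot be unit-variance
    scaled and are dropped with a warning.
    """
    if method not in ("unit_variance", "pareto", "none"):
        raise ValidationError(f"unknown scaling method {method!r}")
    arr, names, _ = _as_sample_matrix(X)
    if not np.isfinite(arr).all():
        raise ValidationError("non-finite values in matrix")
    sd = arr.std(axis=0, ddof=1) if arr.shape[0] > 1 else np.zeros(arr.shape[1])
    keep = np.ones(arr.shape[1], dtype=bool)
    if method == "unit_variance":
        keep = sd > 0
    dropped = tuple(n for n, k in zip(names, keep) if not k)
    if dropped:
        warnings.warn(f"dropping {len(dropped)} zero-variance variable(s)", stacklevel=2)
    arr = arr[:, keep]
    sd = sd[keep]
    centers = arr.mean(axis=0)
    if method == "unit_variance":
        scales = sd
    elif method == "pareto":
        scales = np.where(sd > 0, np.sqrt(sd), 1.0)
    else:
        scales = np.ones_like(sd)
    record = ScalingRecord(method, centers, scales,
                           tuple(n for n, k in zip(names, keep) if k), dropped)
    return record.apply(arr), record


def _kept_indices(record: ScalingRecord, n_vars: int) -> np.ndarray:
    """Column indices kept by a ScalingRecord built from a bare array
    (scale_matrix names bare-array columns ``var<j>``)."""
    if not record.dropped:
        return np.arange(n_vars)
    return np.array([int(name[3:]) for name in record.variables], dtype=int)


# ---------------------------------------------------------------------------
# OPLS-DA estimator
# ---------------------------------------------------------------------------

class OPLSDA(BaseEstimator):
    """Two-class orthogonal PLS discriminant analysis.

    Parameters
    ----------
    n_orthogonal : int or "auto"
        Number of orthogonal (class-uncorrelated) components to remove before
        the single predictive component.  ``"auto"`` keeps adding components
        while cross-validated Q² improves by more than ``auto_tol``.
    scaling : {"unit_variance", "pareto", "none"}
        Variable scaling, re-estimated inside every cross-validation split.
    cv_folds : int
        Stratified folds for Q²; collapses to leave-one-out (with a warning)
        when the smaller class has fewer samples than folds.
    positive_label : optional
        Class mapped to +1; defaults to the first label in sorted order.

    Fitted attributes use trailing underscores: ``predictive_scores_``,
    ``orthogonal_scores_``, ``weights_``, ``r2x_``, ``r2y_``, ``q2_``,
    ``vip_`` and friends.
    """

    def __init__(
        self,
        n_orthogonal: int | str = 1,
        scaling: str = "unit_variance",
        cv_folds: int = 7,
        auto_tol: float = 0.01,
        max_orthogonal: int = 5,
        positive_label=None,
        compute_q2: bool = True,
    ):
        self.n_orthogonal = n_orthogonal
        self.scaling = scaling
        self.cv_folds = cv_folds
        self.auto_tol = auto_tol
        self.max_orthogonal = max_orthogonal
        self.positive_label = positive_label
        self.compute_q2 = compute_q2

    # -- encoding ----------------------------------------------------------
    def _encode_y(self, y) -> tuple[np.ndarray, dict]:
        y = np.asarray(list(y))
        labels = sorted({str(v) for v in y.astype(str)})
        if len(labels) != 2:
            raise ValidationError(
                f"OPLS-DA requires exactly 2 classes, got {len(labels)} "
                f"({labels}); run pairwise contrasts for more groups"
            )
        pos = str(self.positive_label) if self.positive_label is not None else labels[0]
        if pos not in labels:
            raise ValidationError(f"positive_label {pos!r} not among classes {labels}")
        neg = labels[0] if labels[1] == pos else labels[1]
        class_map = {pos: 1.0, neg: -1.0}
        return np.array([class_map[str(v)] for v in y.astype(str)]), class_map

    # -- core NIPALS fit on an already scaled matrix ------------------------
    def _fit_core(self, Xs: np.ndarray, y_pm: np.ndarray, n_ortho: int) -> dict:
        n, p = Xs.shape
        y_mean = y_pm.mean()
        yc = y_pm - y_mean
        ssy = float(yc @ yc)
        ssx = float((Xs**2).sum())

        w = Xs.T @ yc
        wnorm = np.linalg.norm(w)
        if wnorm < _DEGENERATE_TOL or ssy < _DEGENERATE_TOL:
            z = np.zeros(p)
            return dict(w=z, q=0.0, p_pred=z, t_pred=np.zeros(n),
                        W_o=np.zeros((p, 0)), P_o=np.zeros((p, 0)), T_o=np.zeros((n, 0)),
                        y_mean=y_mean, r2x=0.0, r2y=0.0, ssy=ssy, degenerate=True)
        w = w / wnorm

        Xres = Xs.copy()
        W_o, P_o, T_o = [], [], []
        for _ in range(n_ortho):
            t = Xres @ w
            tt = float(t @ t)
            if tt < _DEGENERATE_TOL:
                break
            p_load = Xres.T @ t / tt
            w_o = p_load - float(w @ p_load) * w
            norm_o = np.linalg.norm(w_o)
            if norm_o < 1e-10:
                break  # no structured orthogonal variation left
            w_o /= norm_o
            t_o = Xres @ w_o
            tt_o = float(t_o @ t_o)
            if tt_o < _DEGENERATE_TOL:
                break
            p_o = Xres.T @ t_o / tt_o
            # sign convention: first nonzero loading entry positive
            nz = np.flatnonzero(np.abs(p_o) > _DEGENERATE_TOL)
            if nz.size and p_o[nz[0]] < 0:
                w_o, t_o, p_o = -w_o, -t_o, -p_o
            Xres = Xres - np.outer(t_o, p_o)
            W_o.append(w_o)
            P_o.append(p_o)
            T_o.append(t_o)

        # predictive component on the orthogonal-filtered matrix
        w_pred = Xres.T @ yc
        norm_pred = np.linalg.norm(w_pred)
        if norm_pred < _DEGENERATE_TOL:
            z = np.zeros(p)
            return dict(w=z, q=0.0, p_pred=z, t_pred=np.zeros(n),
                        W_o=np.zeros((p, 0)), P_o=np.zeros((p, 0)), T_o=np.zeros((n, 0)),
                        y_mean=y_mean, r2x=0.0, r2y=0.0, ssy=ssy, degenerate=True)
        w_pred /= norm_pred
        t_pred = Xres @ w_pred
        tt = float(t_pred @ t_pred)
        p_pred = Xres.T @ t_pred / tt
        q = float(yc @ t_pred / tt)
        nz = np.flatnonzero(np.abs(p_pred) > _DEGENERATE_TOL)
        if nz.size and p_pred[nz[0]] < 0:
            w_pred, t_pred, p_pred, q = -w_pred, -t_pred, -p_pred, -q

        resid_y = yc - t_pred * q
        r2y = 1.0 - float(resid_y @ resid_y) / ssy
        explained_x = tt * float(p_pred @ p_pred)
        for t_o, p_o in zip(T_o, P_o):
            explained_x += float(t_o @ t_o) * float(p_o @ p_o)
        r2x = explained_x / ssx if ssx > 0 else 0.0
        return dict(
            w=w_pred, q=q, p_pred=p_pred, t_pred=t_pred,
            W_o=np.column_stack(W_o) if W_o else np.zeros((p, 0)),
            P_o=np.column_stack(P_o) if P_o else np.zeros((p, 0)),
            T_o=np.column_stack(T_o) if T_o else np.zeros((n, 0)),
            y_mean=y_mean, r2x=r2x, r2y=r2y, ssy=ssy, degenerate=False,
        )

    @staticmethod
    def _predict_scores(core: dict, Xs: np.ndarray) -> np.ndarray:
        Xf = np.asarray(Xs, dtype=float).copy()
        for a in range(core["W_o"].shape[1]):
            t_o = Xf @ core["W_o"][:, a]
            Xf -= np.outer(t_o, core["P_o"][:, a])
        return Xf @ core["w"]

    # -- cross-validation ----------------------------------------------------
    def _cv_folds_indices(self, y_pm: np.ndarray) -> list[np.ndarray]:
        n = y_pm.size
        min_class = min(int((y_pm > 0).sum()), int((y_pm < 0).sum()))
        folds = min(self.cv_folds, n)
        if folds > min_class:
            if self.cv_folds != n:
                warnings.warn(
                    f"{self.cv_folds}-fold CV cannot stratify {min_class} samples "
                    "per class; falling back to leave-one-out",
                    stacklevel=3,
                )
            folds = n
        if folds == n:
            return [np.array([i]) for i in range(n)]
        # round-robin within each class keeps folds stratified and deterministic
        assignments = np.empty(n, dtype=int)
        for cls in (1.0, -1.0):
            idx = np.flatnonzero(y_pm == cls)
            assignments[idx] = np.arange(idx.size) % folds
        return [np.flatnonzero(assignments == f) for f in range(folds)]

    def _q2(self, X_raw: np.ndarray, y_pm: np.ndarray, n_ortho: int) -> float:
        folds = self._cv_folds_indices(y_pm)
        press = 0.0
        y_mean_all = y_pm.mean()
        ss = float(((y_pm - y_mean_all) ** 2).sum())
        if ss < _DEGENERATE_TOL:
            raise ValidationError("constant class labels: Q2 undefined")
        for test_idx in folds:
            train_mask = np.ones(y_pm.size, dtype=bool)
            train_mask[test_idx] = False
            y_train = y_pm[train_mask]
            if len({v for v in y_train}) < 2:
                raise ValidationError("a CV fold lost an entire class; reduce folds")
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # per-fold zero-variance drops
                Xs_train, record = scale_matrix(X_raw[train_mask], self.scaling)
            core = self._fit_core(Xs_train, y_train, n_ortho)
            kept = _kept_indices(record, X_raw.shape[1])
            Xs_test = record.apply(X_raw[np.ix_(test_idx, kept)])
            t_test = self._predict_scores(core, Xs_test)
            y_hat = t_test * core["q"] + core["y_mean"]
            press += float(((y_pm[test_idx] - y_hat) ** 2).sum())
        return 1.0 - press / ss

    # -- public API ----------------------------------------------------------
    def fit(self, X, y=None):
        X_raw, var_names, sample_names = _as_sample_matrix(X)
        if y is None:
            if not isinstance(X, IntensityMatrix):
                raise ValidationError("y may be omitted only for IntensityMatrix input")
            y = [X.groups[s] for s in X.samples]
        y_pm, class_map = self._encode_y(y)
        if X_raw.shape[0] != y_pm.size:
            raise ValidationError(f"X has {X_raw.shape[0]} samples but y has {y_pm.size}")
        if X_raw.shape[0] < 4:
            raise ValidationError("OPLS-DA needs >= 4 samples")

        Xs, record = scale_matrix(X_raw, self.scaling)
        self._kept_idx_ = _kept_indices(record, X_raw.shape[1])
        kept_names = [var_names[j] for j in self._kept_idx_]

        if self.n_orthogonal == "auto":
            best_n, best_q2 = 0, self._q2(X_raw, y_pm, 0)
            for n_try in range(1, self.max_orthogonal + 1):
                q2_try = self._q2(X_raw, y_pm, n_try)
                if q2_try > best_q2 + self.auto_tol:
                    best_n, best_q2 = n_try, q2_try
                else:
                    break
            n_ortho = best_n
        else:
            n_ortho = int(self.n_orthogonal)
            if n_ortho < 0:
                raise ValidationError("n_orthogonal must be >= 0")

        core = self._fit_core(Xs, y_pm, n_ortho)
        self._core_ = core
        self._scaling_record_ = record
        self.variable_names_ = kept_names
        self.sample_names_ = sample_names
        self.class_map_ = class_map
        self.classes_ = sorted(class_map, key=class_map.get, reverse=True)
        self.n_orthogonal_ = core["T_o"].shape[1]
        self.predictive_scores_ = core["t_pred"].reshape(-1, 1)
        self.orthogonal_scores_ = core["T_o"]
        self.predictive_loadings_ = core["p_pred"].reshape(-1, 1)
        self.orthogonal_loadings_ = core["P_o"]
        self.weights_ = core["w"].reshape(-1, 1)
        self.r2x_ = float(core["r2x"])
        self.r2y_ = float(core["r2y"])
        self.q2_ = self._q2(X_raw, y_pm, n_ortho) if self.compute_q2 else float("nan")
        self.vip_ = self._compute_vip()
        return self

    def _compute_vip(self) -> np.ndarray:
        # single predictive component: VIP_j = sqrt(p) * |w_j| / ||w||
        w = self._core_["w"]
        p = w.size
        wnorm = np.linalg.norm(w)
        if wnorm < _DEGENERATE_TOL:
            return np.zeros(p)
        return np.sqrt(p) * np.abs(w) / wnorm

    def transform(self, X):
        check_is_fitted(self, "_core_")
        X_raw, _, _ = _as_sample_matrix(X)
        Xs = self._scaling_record_.apply(X_raw[:, self._kept_idx_])
        return self._predict_scores(self._core_, Xs).reshape(-1, 1)

    def decision_function(self, X):
        check_is_fitted(self, "_core_")
        t = self.transform(X).ravel()
        return t * self._core_["q"] + self._core_["y_mean"]

    def predict(self, X):
        scores = self.decision_function(X)
        inv = {v: k for k, v in self.class_map_.items()}
        return np.array([inv[1.0] if s >= 0 else inv[-1.0] for s in scores])

    def vip_scores(self) -> dict[str, float]:
        check_is_fitted(self, "vip_")
        return dict(zip(self.variable_names_, map(float, self.vip_)))


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------

def fit_oplsda(
    X,
    y,
    n_orthogonal: int | str = 1,
    config: PipelineConfig | None = None,
    positive_label=None,
) -> OPLSDA:
    """Fit a two-class OPLS-DA model; thin wrapper over :class:`OPLSDA`."""
    cfg = config or PipelineConfig()
    return OPLSDA(
        n_orthogonal=n_orthogonal,
        scaling=cfg.scaling_method,
        cv_folds=cfg.cv_folds,
        positive_label=positive_label,
    ).fit(X, y)


def cross_validate_q2(X, y, folds: int | None = None, config: PipelineConfig | None = None,
                      n_orthogonal: int = 1) -> float:
    """Stratified k-fold Q² = 1 - PRESS/SS, scaling re-estimated per split."""
    cfg = config or PipelineConfig()
    est = OPLSDA(n_orthogonal=n_orthogonal, scaling=cfg.scaling_method,
                 cv_folds=folds if folds is not None else cfg.cv_folds)
    X_raw, _, _ = _as_sample_matrix(X)
    y_pm, _ = est._encode_y(y)
    return est._q2(X_raw, y_pm, n_orthogonal)


@dataclass(frozen=True)
class PermutationResult:
    observed_r2y: float
    observed_q2: float
    permuted_r2y: tuple[float, ...]
    permuted_q2: tuple[float, ...]
    p_r2y: float
    p_q2: float
    seed: int


def permutation_test(
    X,
    y,
    n_permutations: int | None = None,
    seed: int | None = None,
    config: PipelineConfig | None = None,
    n_orthogonal: int = 1,
) -> PermutationResult:
    """Label-permutation significance of the class separation.

    The class labels are shuffled ``n_permutations`` times with a seeded
    generator, the model (including its cross-validated Q²) is refit per
    shuffle, and add-one p-values are reported:
    p = (1 + #{permuted >= observed}) / (1 + n_permutations).
    """
    cfg = config or PipelineConfig()
    n_perm = n_permutations if n_permutations is not None else cfg.n_permutations
    if n_perm < 1:
        raise ValidationError("n_permutations must be >= 1")
    seed = seed if seed is not None else cfg.rng_seed
    rng = np.random.default_rng(seed)

    def fit_stats(labels) -> tuple[float, float]:
        est = OPLSDA(n_orthogonal=n_orthogonal, scaling=cfg.scaling_method,
                     cv_folds=cfg.cv_folds).fit(X, labels)
        return est.r2y_, est.q2_

    y_arr = np.asarray(list(y))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # LOO fallback warning once is enough
        obs_r2y, obs_q2 = fit_stats(y_arr)
        perm_r2y, perm_q2 = [], []
        for _ in range(n_perm):
            perm = rng.permutation(y_arr.size)
            r2y, q2 = fit_stats(y_arr[perm])
            perm_r2y.append(r2y)
            perm_q2.append(q2)
    tol = 1e-12  # permutations matching the observed statistic count as >=
    p_r2y = (1 + sum(v >= obs_r2y - tol for v in perm_r2y)) / (1 + n_perm)
    p_q2 = (1 + sum(v >= obs_q2 - tol for v in perm_q2)) / (1 + n_perm)
    return PermutationResult(obs_r2y, obs_q2, tuple(perm_r2y), tuple(perm_q2),
                             p_r2y, p_q2, seed)


def vip(model: OPLSDA) -> dict[str, float]:
    """Variable importance in projection; squared scores average to 1."""
    return model.vip_scores()


# ---------------------------------------------------------------------------
# hierarchical clustering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClusterTree:
    """Agglomerative merge history over samples (scipy linkage encoding)."""

    linkage_matrix: np.ndarray
    labels: tuple[str, ...]

    @property
    def leaf_order(self) -> tuple[str, ...]:
        order = hierarchy.leaves_list(self.linkage_matrix)
        return tuple(self.labels[i] for i in order)

    def cut(self, k: int) -> dict[str, int]:
        assign = hierarchy.fcluster(self.linkage_matrix, t=k, criterion="maxclust")
        return dict(zip(self.labels, map(int, assign)))


def hcluster(X, distance: str = "euclidean", linkage: str = "average") -> ClusterTree:
    """Cluster samples on z-scored variables.

    ``distance``: euclidean or correlation; ``linkage``: average, complete or
    ward (ward requires euclidean distance).
    """
    if distance not in ("euclidean", "correlation"):
        raise ValidationError(f"unknown distance {distance!r}")
    if linkage not in ("average", "complete", "ward"):
        raise ValidationError(f"unknown linkage {linkage!r}")
    if linkage == "ward" and distance != "euclidean":
        raise ValidationError("ward linkage requires euclidean distance")
    arr, _, sample_names = _as_sample_matrix(X)
    if arr.shape[0] < 2:
        raise ValidationError("need >= 2 samples to cluster")
    if not np.isfinite(arr).all():
        raise ValidationError("non-finite values in matrix")
    sd = arr.std(axis=0, ddof=1) if arr.shape[0] > 1 else np.ones(arr.shape[1])
    sd = np.where(sd > 0, sd, 1.0)
    z = (arr - arr.mean(axis=0)) / sd
    dvec = pdist(z, metric=distance)
    Z = hierarchy.linkage(dvec, method=linkage)
    labels = tuple(sample_names or [f"sample{i}" for i in range(arr.shape[0])])
    return ClusterTree(Z, labels)
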
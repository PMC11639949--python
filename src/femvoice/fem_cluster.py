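"""Fuzzy expectation-maximization (FEM) clustering of joint speech features.

The clustering stage assigns every feature frame a *membership vector*
over K speech-type clusters (K-1 dysarthric types plus one normal-speech
cluster).  It alternates

* an E-step computing fuzzy memberships from distances to the centers,

      mu_ij = 1 / sum_k (d_ij / d_ik) ** (2 / (m - 1))

  where ``d_ij`` is the Euclidean distance of point i to center j and
  ``m > 1`` is the fuzziness coefficient, and

* an M-step moving each center to the membership-weighted mean

      C_j = sum_i mu_ij**m x_i / sum_i mu_ij**m,

which is the unique minimizer of the objective
``J = sum_ij mu_ij**m d_ij**2`` for fixed memberships, so J is
non-increasing across iterations.  Initialization anchors the last
center at the mean of the normal-speech frames; the remaining K-1
centers are data points drawn uniformly at random.  Iteration stops when
either the maximum center displacement or the Frobenius norm of the
membership change falls below its tolerance.

The public surface is both functional (:func:`e_step`, :func:`m_step`,
:func:`fit_fem`, ...) and an sklearn-style estimator
(:class:`FuzzyEMClustering`) that composes with scikit-learn pipelines.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, ClusterMixin

logger = logging.getLogger(__name__)

__all__ = [
    "FemConfig",
    "ClusterModel",
    "FemResult",
    "FuzzyEMClustering",
    "init_centers",
    "e_step",
    "m_step",
    "objective",
    "fit_fem",
    "predict_membership",
]


@dataclass
class FemConfig:
    """Configuration of the FEM clustering stage."""

    n_clusters: int = 15
    m: float = 2.0
    tol_centers: float = 1e-6
    tol_memberships: float = 1e-6
    max_iter: int = 300
    seed: int = 0
    distance: str = "euclidean"
    standardize: bool = True

    def __post_init__(self) -> None:
        if self.n_clusters < 2:
            raise ValueError("n_clusters must be >= 2")
        if not self.m > 1.0:
            raise ValueError("fuzziness m must be strictly > 1 (memberships degenerate at m = 1)")
        if self.tol_centers <= 0 or self.tol_memberships <= 0:
            raise ValueError("tolerances must be positive")
        if self.distance != "euclidean":
            raise ValueError(f"unsupported distance {self.distance!r}; only 'euclidean'")


@dataclass
class ClusterModel:
    """A fitted cluster model: centers in input-space units, fuzziness m,
    and the index of the normal-speech cluster.

    ``mean``/``scale`` record an optional per-dimension standardization
    applied before distance computation (identity when ``None``)."""

    centers: np.ndarray
    m: float
    normal_index: int
    mean: np.ndarray | None = None
    scale: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=np.float64)
        if not np.all(np.isfinite(self.centers)):
            raise ValueError("cluster centers must be finite")
        if not 0 <= self.normal_index < self.centers.shape[0]:
            raise ValueError("normal_index out of range")

    @property
    def n_clusters(self) -> int:
        return self.centers.shape[0]

    @property
    def normal_center(self) -> np.ndarray:
        """Normal-speech centroid in input-space units."""
        return self.centers[self.normal_index]

    def _transform(self, x: np.ndarray) -> np.ndarray:
        if self.mean is None:
            return x
        return (x - self.mean) / self.scale

    def predict_membership(self, x: np.ndarray) -> np.ndarray:
        """Fuzzy membership rows for one vector or a batch of rows."""
        x = np.asarray(x, dtype=np.float64)
        single = x.ndim == 1
        x2 = np.atleast_2d(x)
        if x2.shape[1] != self.centers.shape[1]:
            raise ValueError(
                f"dimension mismatch: data has {x2.shape[1]} features, "
                f"model expects {self.centers.shape[1]}"
            )
        u = e_step(self._transform(x2), self._transform(self.centers), self.m)
        return u[0] if single else u

    def to_json(self, path) -> None:
        payload = {
            "centers": self.centers.tolist(),
            "m": self.m,
            "normal_index": self.normal_index,
            "mean": None if self.mean is None else np.asarray(self.mean).tolist(),
            "scale": None if self.scale is None else np.asarray(self.scale).tolist(),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path) -> "ClusterModel":
        p = json.loads(Path(path).read_text())
        return cls(
            centers=np.asarray(p["centers"]),
            m=p["m"],
            normal_index=p["normal_index"],
            mean=None if p["mean"] is None else np.asarray(p["mean"]),
            scale=None if p["scale"] is None else np.asarray(p["scale"]),
        )


@dataclass
class FemResult:
    model: ClusterModel
    U: np.ndarray
    objective_trace: list[float]
    n_iter: int
    converged: bool
    converged_by: str  # 'centers' | 'membership' | 'max_iter'


def init_centers(
    data: np.ndarray, normal_mask, n_clusters: int, seed: int
) -> tuple[np.ndarray, int]:
    """Anchored initialization: K-1 centers are distinct data points chosen
    uniformly at random; the last center is the mean of the normal-speech
    points.  Returns ``(centers, normal_index)`` with ``normal_index = K-1``.
    """
    data = np.asarray(data, dtype=np.float64)
    normal_mask = np.asarray(normal_mask, dtype=bool)
    if normal_mask.shape[0] != data.shape[0]:
        raise ValueError("normal_mask length must equal the number of data points")
    if not normal_mask.any():
        raise ValueError("normal_mask selects no points; the normal anchor needs >= 1")
    unique = np.unique(data, axis=0)
    if unique.shape[0] < n_clusters - 1:
        raise ValueError(
            f"need >= {n_clusters - 1} distinct data points, have {unique.shape[0]}"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(unique.shape[0], size=n_clusters - 1, replace=False)
    centers = np.vstack([unique[idx], data[normal_mask].mean(axis=0)])
    return centers, n_clusters - 1


def e_step(data: np.ndarray, centers: np.ndarray, m: float) -> np.ndarray:
    """Fuzzy membership update.  Rows sum to 1; a point at zero distance
    from a center gets full membership at the first such center."""
    if not m > 1.0:
        raise ValueError("fuzziness m must be > 1")
    data = np.atleast_2d(np.asarray(data, dtype=np.float64))
    centers = np.atleast_2d(np.asarray(centers, dtype=np.float64))
    d = cdist(data, centers)
    if not np.all(np.isfinite(d)):
        raise ValueError("non-finite distances in E-step")
    u = np.zeros_like(d)
    zero_rows = (d == 0.0).any(axis=1)
    if zero_rows.any():
        first_zero = np.argmax(d[zero_rows] == 0.0, axis=1)
        u[np.flatnonzero(zero_rows), first_zero] = 1.0
    reg = ~zero_rows
    if reg.any():
        w = d[reg] ** (-2.0 / (m - 1.0))
        u[reg] = w / w.sum(axis=1, keepdims=True)
    return u


def m_step(
    data: np.ndarray, U: np.ndarray, m: float, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Membership-weighted mean update of the centers.

    A cluster whose total weight ``sum_i mu_ij**m`` vanishes is
    reinitialized from a random data point (seeded via ``rng``) and the
    event is logged."""
    data = np.asarray(data, dtype=np.float64)
    U = np.asarray(U, dtype=np.float64)
    w = U**m
    wsum = w.sum(axis=0)
    centers = np.zeros((U.shape[1], data.shape[1]))
    dead = wsum <= 0.0
    if dead.any():
        if rng is None:
            rng = np.random.default_rng(0)
        for j in np.flatnonzero(dead):
            centers[j] = data[rng.integers(0, data.shape[0])]
            logger.warning("cluster %d lost all membership weight; reinitialized", j)
    alive = ~dead
    centers[alive] = (w[:, alive].T @ data) / wsum[alive, None]
    return centers


def objective(data: np.ndarray, U: np.ndarray, centers: np.ndarray, m: float) -> float:
    """Fuzzy clustering objective ``J = sum_ij mu_ij**m d_ij**2``."""
    d2 = cdist(np.atleast_2d(data), np.atleast_2d(centers), "sqeuclidean")
    return float((np.asarray(U) ** m * d2).sum())


def _fem_loop(
    data: np.ndarray,
    centers: np.ndarray,
    cfg: FemConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, list[float], int, bool, str]:
    U = e_step(data, centers, cfg.m)
    trace = [objective(data, U, centers, cfg.m)]
    converged = False
    converged_by = "max_iter"
    it = 0
    for it in range(1, cfg.max_iter + 1):
        new_centers = m_step(data, U, cfg.m, rng)
        new_U = e_step(data, new_centers, cfg.m)
        trace.append(objective(data, new_U, new_centers, cfg.m))
        # per-center max Euclidean displacement vs Frobenius norm of dU
        center_move = np.linalg.norm(new_centers - centers, axis=1).max()
        du = np.linalg.norm(new_U - U)
        centers, U = new_centers, new_U
        if center_move < cfg.tol_centers:
            converged, converged_by = True, "centers"
            break
        if du < cfg.tol_memberships:
            converged, converged_by = True, "membership"
            break
    return centers, U, trace, it, converged, converged_by


def fit_fem(data: np.ndarray, normal_mask, cfg: FemConfig | None = None, **kwargs) -> FemResult:
    """Run the full FEM clustering stage; see the module docstring.

    ``kwargs`` override individual :class:`FemConfig` fields when ``cfg``
    is not given."""
    if cfg is None:
        cfg = FemConfig(**kwargs)
    data = np.asarray(data, dtype=np.float64)
    if data.shape[0] < cfg.n_clusters:
        raise ValueError("need at least n_clusters data points")
    mean = scale = None
    work = data
    if cfg.standardize:
        mean = data.mean(axis=0)
        scale = data.std(axis=0)
        scale = np.where(scale > 0, scale, 1.0)
        work = (data - mean) / scale
    centers0, normal_index = init_centers(work, normal_mask, cfg.n_clusters, cfg.seed)
    rng = np.random.default_rng(cfg.seed)
    centers, U, trace, n_iter, converged, converged_by = _fem_loop(work, centers0, cfg, rng)
    if mean is not None:
        centers_in = centers * scale + mean
    else:
        centers_in = centers
    model = ClusterModel(centers_in, cfg.m, normal_index, mean=mean, scale=scale)
    return FemResult(model, U, trace, n_iter, converged, converged_by)


def predict_membership(x: np.ndarray, model: ClusterModel) -> np.ndarray:
    """Membership rows for new data under a fitted model (same arithmetic
    as :func:`e_step` on the fixed centers)."""
    return model.predict_membership(x)


class FuzzyEMClustering(ClusterMixin, BaseEstimator):
    """Fuzzy EM clustering with a normal-speech anchored cluster.

    Parameters
    ----------
    n_clusters : int, default 15
        Number of speech-type clusters K (the reference setting uses
        one cluster per speech type: 14 dysarthric + 1 normal).
    m : float, default 2.0
        Fuzziness coefficient; must be > 1.  Larger m gives softer
        memberships.
    tol_centers, tol_memberships : float, default 1e-6
        Convergence tolerances on the maximum center displacement and on
        the Frobenius norm of the membership change; either suffices.
    max_iter : int, default 300
    standardize : bool, default True
        Z-score each feature dimension before clustering (MFCC and
        one-hot phoneme scales differ by orders of magnitude).  Centers
        are always reported in original input units.
    random_state : int, default 0
        Seeds the random choice of the K-1 non-anchored initial centers.

    Attributes
    ----------
    cluster_centers_ : ndarray of shape (n_clusters, n_features)
        Centers in input units.
    normal_index_ : int
        Index of the normal-speech cluster (always ``n_clusters - 1``).
    membership_ : ndarray of shape (n_samples, n_clusters)
        Final fuzzy memberships of the training data.
    objective_trace_ : list of float
        Objective J after initialization and after every iteration;
        non-increasing.
    n_iter_, converged_, converged_by_ :
        Iteration count and which criterion stopped the loop.

    Examples
    --------
    >>> import numpy as np
    >>> X = np.vstack([np.zeros((20, 2)), 10 + np.zeros((20, 2))])
    >>> normal = np.arange(40) >= 20
    >>> est = FuzzyEMClustering(n_clusters=2, standardize=False).fit(X, normal_mask=normal)
    >>> est.predict(np.array([[9.5, 9.5]]))[0] == est.normal_index_
    True
    """

    def __init__(
        self,
        n_clusters: int = 15,
        m: float = 2.0,
        tol_centers: float = 1e-6,
        tol_memberships: float = 1e-6,
        max_iter: int = 300,
        standardize: bool = True,
        random_state: int = 0,
    ):
        self.n_clusters = n_clusters
        self.m = m
        self.tol_centers = tol_centers
        self.tol_memberships = tol_memberships
        self.max_iter = max_iter
        self.standardize = standardize
        self.random_state = random_state

    def _config(self) -> FemConfig:
        return FemConfig(
            n_clusters=self.n_clusters,
            m=self.m,
            tol_centers=self.tol_centers,
            tol_memberships=self.tol_memberships,
            max_iter=self.max_iter,
            seed=self.random_state,
            standardize=self.standardize,
        )

    def fit(self, X, y=None, normal_mask=None):
        """Fit on frame features X; ``normal_mask`` flags normal-speech rows."""
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2:
            raise ValueError("X must be a 2-D feature matrix")
        if normal_mask is None:
            raise ValueError(
                "normal_mask is required: the last cluster is anchored at the "
                "mean of the normal-speech frames"
            )
        res = fit_fem(X, normal_mask, self._config())
        self.model_ = res.model
        self.cluster_centers_ = res.model.centers
        self.normal_index_ = res.model.normal_index
        self.membership_ = res.U
        self.objective_trace_ = res.objective_trace
        self.n_iter_ = res.n_iter
        self.converged_ = res.converged
        self.converged_by_ = res.converged_by
        self.labels_ = res.U.argmax(axis=1)
        self.n_features_in_ = X.shape[1]
        return self

    def predict_membership(self, X) -> np.ndarray:
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "model_")
        return self.model_.predict_membership(X)

    # soft memberships double as cluster "probabilities"
    predict_proba = predict_membership

    def predict(self, X) -> np.ndarray:
        return np.atleast_2d(self.predict_membership(X)).argmax(axis=1)

    def fit_predict(self, X, y=None, **fit_params):
        return self.fit(X, **fit_params).labels_

    def transform(self, X) -> np.ndarray:
        """Membership matrix as a (n_samples, n_clusters) embedding."""
        return np.atleast_2d(self.predict_membership(X))

    def to_model(self) -> ClusterModel:
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "model_")
        return self.model_
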
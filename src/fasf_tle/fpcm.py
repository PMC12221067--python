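"""Fuzzy possibilistic c-means (FPCM) tissue clustering.

FPCM augments fuzzy c-means with a possibilistic (typicality) membership
so that outliers, which fuzzy memberships must still share across
clusters, receive uniformly low typicality instead of distorting the
centres.  Per voxel *i* and cluster *C* with Euclidean distance
``D_iC = |x_i - v_C|``:

fuzzy membership (rows sum to 1)::

    U_iC = 1 / sum_K (D_iC / D_iK)^(2/(M-1))

possibilistic membership (unnormalized, per-cluster bandwidth eta_C)::

    a_iC = 1 / (1 + (D_iC / eta_C)^Q)

objective::

    J = sum_i sum_C [ U_iC^M D_iC^2 + a_iC^Q D_iC^2 ]

centre update::

    v_C = sum_i (a_iC^Q U_iC^M x_i) / sum_i (a_iC^Q U_iC^M)

The loop alternates membership and centre updates until the objective
changes by less than ``epsilon``; each voxel is finally labelled
``argmax_C (U_iC * a_iC)``.  Clusters are reported sorted by ascending
centre intensity so label ids are deterministic (CSF < GM < WM on
T1-like contrast).

``eta_C`` is estimated once, after an initial fuzzy-only pass, as the
membership-weighted mean squared distance within each cluster
(``eta_C = K_scale * sum U^M D^2 / sum U^M``), then held fixed — with a
fixed eta every alternating update decreases J, which is what makes the
recorded objective trace non-increasing.
"""

from __future__ import annotations

import logging

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_is_fitted

from .config import FPCMConfig
from .types import LabelVolume, VolumeImage

logger = logging.getLogger("fasf_tle")

__all__ = [
    "FPCM",
    "init_centers",
    "update_fuzzy_memberships",
    "update_possibilistic_memberships",
    "estimate_eta",
    "fpcm_objective",
    "update_centers",
    "fpcm_segment",
]

ETA_FLOOR = 1e-6


def _as_2d(values: np.ndarray) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        values = values[:, None]
    return values


def _distances(values: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """Euclidean distance matrix, n x c."""
    values = _as_2d(values)
    centers = _as_2d(centers)
    diff = values[:, None, :] - centers[None, :, :]
    return np.sqrt(np.sum(diff**2, axis=2))


def init_centers(
    values: np.ndarray, c: int, seed: int = 0, method: str = "quantile"
) -> np.ndarray:
    """Deterministic initial centres from the masked voxel values.

    The quantile method places centre k at the ``(k + 0.5)/c`` quantile
    (per feature dimension); ``kmeanspp`` is a seeded k-means++-style
    farthest-point draw.
    """
    values = _as_2d(values)
    n_distinct = np.unique(values, axis=0).shape[0]
    if n_distinct < c:
        raise ValueError(f"need at least {c} distinct values, got {n_distinct}")
    if method == "quantile":
        qs = (np.arange(c) + 0.5) / c
        centers = np.quantile(values, qs, axis=0)
    elif method == "kmeanspp":
        rng = np.random.default_rng(seed)
        centers_list = [values[rng.integers(len(values))]]
        for _ in range(1, c):
            d2 = np.min(
                np.sum((values[:, None, :] - np.array(centers_list)[None]) ** 2, axis=2),
                axis=1,
            )
            p = d2 / d2.sum() if d2.sum() > 0 else None
            centers_list.append(values[rng.choice(len(values), p=p)])
        centers = np.array(centers_list)
    else:
        raise ValueError(f"unknown init method {method!r}")
    # nudge exact duplicates apart so distances are well defined
    if np.unique(centers, axis=0).shape[0] < c:
        span = values.max() - values.min()
        centers = centers + 1e-9 * span * np.arange(c)[:, None]
    return centers if centers.shape[1] > 1 else centers


def update_fuzzy_memberships(values: np.ndarray, centers: np.ndarray, M: float) -> np.ndarray:
    """Fuzzy membership update; rows sum to 1, zero distance wins outright."""
    if M <= 1:
        raise ValueError(f"fuzziness M must exceed 1, got {M}")
    D = _distances(values, centers)
    U = np.zeros_like(D)
    zero = D <= 0
    has_zero = zero.any(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        power = 2.0 / (M - 1.0)
        ratio = (D[:, :, None] / D[:, None, :]) ** power  # D_iC / D_iK
        U_reg = 1.0 / np.sum(ratio, axis=2)
    U[~has_zero] = U_reg[~has_zero]
    if has_zero.any():
        rows = np.where(has_zero)[0]
        U[rows] = 0.0
        for r in rows:  # split ties among coincident centres
            z = np.where(zero[r])[0]
            U[r, z] = 1.0 / len(z)
    return U


def update_possibilistic_memberships(
    values: np.ndarray, centers: np.ndarray, Q: float, eta: np.ndarray | float
) -> np.ndarray:
    """Typicality update a_iC = 1 / (1 + (D_iC/eta_C)^Q)."""
    eta = np.atleast_1d(np.asarray(eta, dtype=float))
    if np.any(eta <= 0):
        raise ValueError("eta must be strictly positive")
    D = _distances(values, centers)
    return 1.0 / (1.0 + (D / eta[None, :]) ** Q)


def estimate_eta(
    U: np.ndarray,
    values: np.ndarray,
    centers: np.ndarray,
    M: float,
    K_scale: float = 1.0,
) -> np.ndarray:
    """Per-cluster bandwidth: membership-weighted mean squared distance."""
    D = _distances(values, centers)
    W = U**M
    den = W.sum(axis=0)
    bad = np.where(den <= 0)[0]
    if bad.size:
        raise ValueError(f"degenerate cluster(s) {bad.tolist()}: zero total membership")
    eta = K_scale * np.sum(W * D**2, axis=0) / den
    floored = eta < ETA_FLOOR
    if floored.any():
        logger.warning("eta floored at %.0e for clusters %s", ETA_FLOOR,
                       np.where(floored)[0].tolist())
        eta = np.maximum(eta, ETA_FLOOR)
    return eta


def fpcm_objective(
    U: np.ndarray,
    A: np.ndarray,
    values: np.ndarray,
    centers: np.ndarray,
    M: float,
    Q: float,
) -> float:
    """J = sum over voxels and clusters of U^M D^2 + a^Q D^2."""
    D2 = _distances(values, centers) ** 2
    return float(np.sum((U**M) * D2 + (A**Q) * D2))


def update_centers(
    U: np.ndarray, A: np.ndarray, values: np.ndarray, M: float, Q: float
) -> np.ndarray:
    """Centre update: weighted mean with weights a^Q * U^M."""
    X = _as_2d(values)
    W = (A**Q) * (U**M)
    den = W.sum(axis=0)
    if np.any(den <= 0):
        bad = np.where(den <= 0)[0].tolist()
        raise ValueError(f"degenerate cluster(s) {bad}: zero centre denominator")
    return (W.T @ X) / den[:, None]


class FPCM(BaseEstimator, ClusterMixin):
    """Fuzzy possibilistic c-means clusterer.

    Parameters
    ----------
    n_clusters : number of tissue classes (GM/WM/CSF -> 3).
    M, Q : fuzzy and possibilistic exponents, both > 1.
    eta : "auto" (estimated after a fuzzy-only pass) or an explicit
        positive value shared by all clusters.
    eta_scale : multiplier on the automatic eta estimate.
    epsilon : stop when the objective changes by less than this.
    init : "quantile" (deterministic) or "kmeanspp" (seeded).

    Attributes
    ----------
    cluster_centers_ : (c, d) centres sorted by ascending first feature.
    memberships_ : (n, c) fuzzy memberships U.
    typicalities_ : (n, c) possibilistic memberships alpha.
    labels_ : (n,) argmax_C (U * alpha), 0-based.
    objective_trace_ : objective value per iteration (non-increasing).
    eta_ : (c,) bandwidths used.
    converged_ : whether |dJ| < epsilon was reached within max_iter.
    """

    def __init__(
        self,
        n_clusters: int = 3,
        M: float = 2.0,
        Q: float = 2.0,
        eta: str | float = "auto",
        eta_scale: float = 1.0,
        epsilon: float = 1e-5,
        max_iter: int = 100,
        init: str = "quantile",
        fuzzy_init_iter: int = 10,
        random_state: int = 0,
    ):
        self.n_clusters = n_clusters
        self.M = M
        self.Q = Q
        self.eta = eta
        self.eta_scale = eta_scale
        self.epsilon = epsilon
        self.max_iter = max_iter
        self.init = init
        self.fuzzy_init_iter = fuzzy_init_iter
        self.random_state = random_state

    def fit(self, X, y=None):
        if self.M <= 1 or self.Q <= 1:
            raise ValueError("M and Q must both exceed 1")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        X = _as_2d(np.asarray(X, dtype=float))
        c = self.n_clusters
        V = _as_2d(init_centers(X, c, self.random_state, self.init))

        # fuzzy-only warm-up: standard FCM updates, used to calibrate eta
        U = update_fuzzy_memberships(X, V, self.M)
        for _ in range(self.fuzzy_init_iter):
            W = U**self.M
            den = W.sum(axis=0)
            if np.any(den <= 0):
                break
            V = (W.T @ X) / den[:, None]
            U = update_fuzzy_memberships(X, V, self.M)

        if self.eta == "auto":
            eta = estimate_eta(U, X, V, self.M, self.eta_scale)
        else:
            eta = np.full(c, float(self.eta))
            if np.any(eta <= 0):
                raise ValueError("eta must be positive")

        trace: list[float] = []
        converged = False
        A = update_possibilistic_memberships(X, V, self.Q, eta)
        for _ in range(self.max_iter):
            U_new = update_fuzzy_memberships(X, V, self.M)
            A_new = update_possibilistic_memberships(X, V, self.Q, eta)
            V_new = update_centers(U_new, A_new, X, self.M, self.Q)
            J = fpcm_objective(U_new, A_new, X, V_new, self.M, self.Q)
            if trace and J > trace[-1]:
                # objective stalled: keep the previous (better) state
                converged = True
                break
            U, A, V = U_new, A_new, V_new
            if trace and abs(trace[-1] - J) < self.epsilon:
                trace.append(J)
                converged = True
                break
            trace.append(J)
        if not converged:
            logger.warning("FPCM did not converge in %d iterations", self.max_iter)

        order = np.argsort(V[:, 0], kind="stable")
        self.cluster_centers_ = V[order]
        self.memberships_ = U[:, order]
        self.typicalities_ = A[:, order]
        self.eta_ = eta[order]
        self.labels_ = np.argmax(self.memberships_ * self.typicalities_, axis=1)
        self.objective_trace_ = trace
        self.n_iter_ = len(trace)
        self.converged_ = converged
        return self

    def predict(self, X):
        check_is_fitted(self, "cluster_centers_")
        X = _as_2d(np.asarray(X, dtype=float))
        U = update_fuzzy_memberships(X, self.cluster_centers_, self.M)
        A = update_possibilistic_memberships(X, self.cluster_centers_, self.Q, self.eta_)
        return np.argmax(U * A, axis=1)


def fpcm_segment(
    vol: VolumeImage | np.ndarray,
    mask: np.ndarray | None = None,
    params: FPCMConfig | None = None,
) -> tuple[LabelVolume, FPCM]:
    """Cluster in-mask voxel intensities; labels 1..c by ascending centre.

    Out-of-mask voxels are labelled 0.  Returns the label volume and the
    fitted :class:`FPCM` estimator (memberships, centres, objective trace).
    """
    params = params or FPCMConfig()
    data = vol.data if isinstance(vol, VolumeImage) else np.asarray(vol, dtype=float)
    if mask is None:
        mask = np.ones(data.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")

    est = FPCM(
        n_clusters=params.c,
        M=params.M,
        Q=params.Q,
        eta=params.eta,
        eta_scale=params.eta_scale,
        epsilon=params.epsilon,
        max_iter=params.max_iter,
        init=params.init,
    ).fit(data[mask].ravel())

    labels = np.zeros(data.shape, dtype=np.int32)
    labels[mask] = est.labels_ + 1
    legend = {k + 1: f"tissue_{k + 1}" for k in range(params.c)}
    if params.c == 3:
        legend = {1: "CSF", 2: "GM", 3: "WM"}
    affine = vol.affine if isinstance(vol, VolumeImage) else None
    spacing = vol.spacing if isinstance(vol, VolumeImage) else None
    return LabelVolume(labels, legend, spacing, affine), est
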
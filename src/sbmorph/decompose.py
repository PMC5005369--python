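"""MDL order selection, PCA whitening, Infomax ICA and Z-maps.

The data matrix X (subjects x voxels) is centered per voxel, whitened in
subject space to ``k`` principal coordinates, and unmixed by
natural-gradient Infomax with the logistic nonlinearity.  The result is
the factorization X_centered ~= A . S with A the subjects x k mixing
matrix (loading coefficients) and S the k x voxels source matrix; A . S
reproduces the rank-k PCA reconstruction exactly (up to numerical
round-off), independent of how well the rotation converged.

Source sign is fixed so every source row has positive skewness (blob-like
gray-matter patterns point "up"), rows are scaled to unit variance with
the scale absorbed into A, and components are ordered by descending
explained variance (squared loading-column norm).
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy.special import expit
from scipy.stats import skew

from .preprocess import DataMatrix, Mask

__all__ = [
    "WhiteningResult",
    "SBMResult",
    "ZMap",
    "InfomaxInfo",
    "covariance_spectrum",
    "estimate_order_mdl",
    "whiten",
    "infomax_ica",
    "decompose",
    "zscale_and_threshold",
]

_RANK_RTOL = 1e-10


def _as_matrix(X) -> np.ndarray:
    if isinstance(X, DataMatrix):
        return X.X
    return np.asarray(X, float)


def _center(X: np.ndarray) -> np.ndarray:
    """Remove the per-voxel mean across subjects (column centering)."""
    return X - X.mean(axis=0, keepdims=True)


def covariance_spectrum(X) -> np.ndarray:
    """Descending eigenvalues of the subject-space covariance (1/V) Xc Xc'."""
    Xc = _center(_as_matrix(X))
    V = Xc.shape[1]
    s = np.linalg.svd(Xc, compute_uv=False)
    return s**2 / V


def estimate_order_mdl(X, return_curve: bool = False):
    """Model order by the minimum-description-length criterion.

    Treats the V in-mask voxels as observations of the subject-space
    random vector and scores, for each candidate order k,

        MDL(k) = -V (p - k) log(GM_k / AM_k) + 1/2 k (2p - k + 1) log V,

    where GM_k and AM_k are the geometric and arithmetic means of the
    p - k smallest covariance eigenvalues.  Returns the arg-min over
    k in [1, p-1] (p = number of non-negligible eigenvalues).  A
    degenerate, all-equal spectrum returns 1 with a warning.
    """
    Xm = _as_matrix(X)
    if Xm.shape[0] < 2 or Xm.shape[1] < 2:
        raise ValueError("need at least 2 subjects and 2 voxels")
    V = Xm.shape[1]
    ev = covariance_spectrum(Xm)
    ev = ev[ev > ev[0] * _RANK_RTOL]
    p = ev.size
    if p < 2 or (ev[0] - ev[-1]) <= ev[0] * 1e-12:
        warnings.warn("degenerate eigenvalue spectrum; returning order 1")
        if return_curve:
            return 1, np.array([0.0])
        return 1
    ks = np.arange(1, p)
    curve = np.empty(p - 1)
    logev = np.log(ev)
    for i, k in enumerate(ks):
        tail = ev[k:]
        gm = np.exp(logev[k:].mean())
        am = tail.mean()
        curve[i] = -V * (p - k) * np.log(gm / am) + 0.5 * k * (
            2 * p - k + 1
        ) * np.log(V)
    k_hat = int(ks[np.argmin(curve)])
    if return_curve:
        return k_hat, curve
    return k_hat


@dataclasses.dataclass
class WhiteningResult:
    """Rank-k subject-space whitening of the centered data matrix.

    ``Y`` (k x voxels) has identity covariance across voxels;
    ``dewhitener @ Y`` is the rank-k PCA reconstruction of the centered
    data.
    """

    k: int
    mean: np.ndarray               # per-voxel mean removed before whitening
    whitener: np.ndarray           # k x n_subjects
    dewhitener: np.ndarray         # n_subjects x k
    eigenvalues: np.ndarray        # full descending spectrum
    Y: np.ndarray                  # k x n_voxels whitened coordinates


def whiten(X, k: int) -> WhiteningResult:
    """Project centered data rows onto ``k`` whitened coordinates."""
    Xm = _as_matrix(X)
    if k < 1:
        raise ValueError("k must be >= 1")
    mean = Xm.mean(axis=0)
    Xc = Xm - mean
    V = Xc.shape[1]
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    rank = int(np.sum(s > s[0] * _RANK_RTOL)) if s.size else 0
    if k > rank:
        raise ValueError(f"k={k} exceeds rank {rank} of the centered data")
    # canonical sign: largest-|entry| subject weight positive per component
    for j in range(k):
        i_star = int(np.argmax(np.abs(U[:, j])))
        if U[i_star, j] < 0:
            U[:, j] = -U[:, j]
            Vt[j] = -Vt[j]
    eigenvalues = s**2 / V
    Y = np.sqrt(V) * Vt[:k]
    whitener = (np.sqrt(V) / s[:k])[:, None] * U[:, :k].T
    dewhitener = U[:, :k] * (s[:k] / np.sqrt(V))[None, :]
    return WhiteningResult(
        k=k, mean=mean, whitener=whitener, dewhitener=dewhitener,
        eigenvalues=eigenvalues, Y=Y,
    )


@dataclasses.dataclass
class InfomaxInfo:
    converged: bool
    n_iter: int
    final_lr: float
    n_restarts: int


def infomax_ica(
    Y: np.ndarray,
    seed: int = 0,
    learning_rate: float | None = None,
    max_iter: int = 2000,
    tol: float = 1e-7,
    max_restarts: int = 5,
) -> tuple[np.ndarray, InfomaxInfo]:
    """Natural-gradient Infomax unmixing of whitened data.

    Full-batch updates with the logistic score ``g(u) = 1/(1+e^-u)``:

        W <- W + lr * (I + (1 - 2 g(u)) u' / V) W,   u = W Y + b,

    with a bias ``b`` learned alongside (useful for skewed sources), the
    learning rate annealed by x0.9 whenever successive updates point in
    opposing directions, convergence when the relative weight-change
    norm drops below ``tol``, and a bounded-retry restart at halved
    learning rate on weight blow-up.  Deterministic given ``seed``.
    """
    Y = np.asarray(Y, float)
    k, V = Y.shape
    lr0 = learning_rate if learning_rate is not None else 0.1 / np.log(k * np.e)
    rng = np.random.default_rng(seed)
    eye = np.eye(k)

    for attempt in range(max_restarts + 1):
        # random orthogonal start, fresh draw per attempt
        Q, R = np.linalg.qr(rng.standard_normal((k, k)))
        W = Q * np.sign(np.diag(R))[None, :]
        b = np.zeros((k, 1))
        lr = lr0 / (2.0**attempt)
        prev_dW = None
        blew_up = False
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            U = W @ Y + b
            q = 1.0 - 2.0 * expit(U)          # -tanh(u/2)
            grad = (eye + (q @ U.T) / V) @ W
            dW = lr * grad
            W = W + dW
            b = b + lr * q.mean(axis=1, keepdims=True)
            if not np.all(np.isfinite(W)) or np.abs(W).max() > 1e8:
                blew_up = True
                break
            nd = np.linalg.norm(dW) / np.linalg.norm(W)
            if prev_dW is not None and float(np.sum(dW * prev_dW)) < 0:
                lr *= 0.9
            prev_dW = dW
            if nd < tol:
                converged = True
                break
        if not blew_up:
            return W, InfomaxInfo(converged, it, lr, attempt)
    raise RuntimeError(
        f"Infomax diverged after {max_restarts} restarts (seed={seed}); "
        "try a smaller learning rate"
    )


@dataclasses.dataclass
class SBMResult:
    """ICA factorization X_centered ~= A . S of a cohort data matrix."""

    A: np.ndarray                  # subjects x k loading coefficients
    S: np.ndarray                  # k x voxels source maps (unit variance rows)
    k: int
    seed: int
    converged: bool
    n_iter: int
    subject_order: list[str] | None = None
    mask: Mask | None = None
    whitening: WhiteningResult | None = dataclasses.field(default=None, repr=False)

    def reconstruction(self) -> np.ndarray:
        return self.A @ self.S

    def relative_reconstruction_error(self, X) -> float:
        """Frobenius distance of A.S from the rank-k PCA reconstruction."""
        wh = self.whitening if self.whitening is not None else whiten(X, self.k)
        target = wh.dewhitener @ wh.Y
        return float(
            np.linalg.norm(self.reconstruction() - target)
            / np.linalg.norm(target)
        )


def _fix_signs_and_scale(A: np.ndarray, S: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Positive-skew sign convention, unit-variance source rows, EV ordering."""
    A = A.copy()
    S = S.copy()
    for j in range(S.shape[0]):
        if skew(S[j]) < 0:
            S[j] = -S[j]
            A[:, j] = -A[:, j]
        sd = S[j].std()
        if sd > 0:
            S[j] /= sd
            A[:, j] *= sd
    order = np.argsort(-np.sum(A**2, axis=0), kind="stable")
    return A[:, order], S[order]


def decompose(X, k: int, seed: int = 0, **ica_kwargs) -> SBMResult:
    """Whiten to order ``k`` and unmix with Infomax.

    Returns an :class:`SBMResult` whose ``A @ S`` equals the rank-k PCA
    reconstruction of the per-voxel-centered data.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    wh = whiten(X, k)
    W, info = infomax_ica(wh.Y, seed=seed, **ica_kwargs)
    S = W @ wh.Y
    A = wh.dewhitener @ np.linalg.inv(W)
    A, S = _fix_signs_and_scale(A, S)
    subject_order = X.subject_order if isinstance(X, DataMatrix) else None
    mask = X.mask if isinstance(X, DataMatrix) else None
    return SBMResult(
        A=A, S=S, k=k, seed=seed, converged=info.converged, n_iter=info.n_iter,
        subject_order=subject_order, mask=mask, whitening=wh,
    )


@dataclasses.dataclass
class ZMap:
    """A source map scaled to unit SD over the mask and thresholded."""

    values: np.ndarray             # 3-D Z values (0 outside mask)
    surviving: np.ndarray          # 3-D boolean map of supra-threshold voxels
    threshold: float
    component_index: int | None = None
    two_sided: bool = True


def zscale_and_threshold(
    s_row: np.ndarray,
    mask: Mask,
    z_cut: float = 2.5,
    two_sided: bool = True,
    component_index: int | None = None,
) -> ZMap:
    """Z-scale a source row over the mask and threshold at ``z_cut``.

    Two-sided by default: a voxel survives when ``|Z| > z_cut``; with
    ``two_sided=False`` only positive exceedances survive.
    """
    s = np.asarray(s_row, float)
    if s.shape != (mask.n_voxels,):
        raise ValueError(
            f"source row length {s.shape} does not match mask ({mask.n_voxels})"
        )
    sd = s.std()
    if sd == 0:
        raise ValueError("zero-variance source row cannot be Z-scaled")
    z = (s - s.mean()) / sd
    values = mask.scatter(z)
    exceed = np.abs(z) > z_cut if two_sided else z > z_cut
    surviving = mask.scatter(exceed.astype(float)) > 0.5
    return ZMap(
        values=values, surviving=surviving, threshold=float(z_cut),
        component_index=component_index, two_sided=two_sided,
    )
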
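"""Recovery scoring against planted ground truth.

Used to grade how well a decomposition recovered the generator's planted
sources: Hungarian best-match assignment on absolute spatial correlation,
and the Amari index for unmixing-matrix accuracy on toy problems.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linear_sum_assignment

from .preprocess import Mask

__all__ = ["match_components", "amari_index"]


def match_components(
    true_maps: np.ndarray,
    est_sources: np.ndarray,
    mask: Mask | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Best one-to-one matching of estimated sources to true maps.

    ``true_maps`` is (k, *grid) or (k, n_voxels); ``est_sources`` is
    (k_est, n_voxels) in mask linearization when a mask is given.
    Returns ``(assignment, abs_corr)``: for each true map, the index of
    its matched estimated source and the absolute spatial Pearson
    correlation, under the Hungarian assignment maximizing total |r|.
    """
    T = np.asarray(true_maps, float)
    if T.ndim > 2:
        T = T.reshape(T.shape[0], -1)
        if mask is not None:
            T = T[:, mask.linear_index]
    E = np.asarray(est_sources, float)
    kt, ke = T.shape[0], E.shape[0]
    corr = np.abs(np.corrcoef(T, E)[:kt, kt:])
    rows, cols = linear_sum_assignment(-corr)
    assignment = np.full(kt, -1, int)
    scores = np.zeros(kt)
    for r, c in zip(rows, cols):
        assignment[r] = c
        scores[r] = corr[r, c]
    return assignment, scores


def amari_index(P: np.ndarray) -> float:
    """Permutation/scale-invariant separation error of ``P = W @ A_true``.

    0 for a perfect (signed, scaled) permutation, normalized to [0, 1].
    """
    P = np.abs(np.asarray(P, float))
    k = P.shape[0]
    if P.shape != (k, k):
        raise ValueError("P must be square")
    row = (P / P.max(axis=1, keepdims=True)).sum(axis=1) - 1.0
    col = (P / P.max(axis=0, keepdims=True)).sum(axis=0) - 1.0
    return float((row.sum() + col.sum()) / (2.0 * k * (k - 1)))
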
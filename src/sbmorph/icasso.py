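"""ICASSO-style stability analysis of the ICA decomposition.

ICA is repeated from ``n_runs`` random initializations (consecutive
seeds), the pooled source estimates are clustered by average-linkage
agglomeration on 1 - |r| dissimilarity, and each cluster is summarized
by its quality index

    Iq = mean intra-cluster |r|  -  mean member-to-non-member |r|,

which is 1 for a component re-estimated identically in every run.  The
final decomposition is rebuilt from cluster centrotypes (the member most
similar to the rest of its cluster) with loadings refit to the data by
least squares.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .decompose import SBMResult, _center, _fix_signs_and_scale, decompose
from .preprocess import DataMatrix

__all__ = [
    "IcassoResult",
    "component_similarity",
    "cluster_components",
    "quality_index",
    "centrotype",
    "run_icasso",
]


def component_similarity(pooled_sources: np.ndarray) -> np.ndarray:
    """Absolute Pearson correlation between all pooled source vectors."""
    P = np.asarray(pooled_sources, float)
    if P.ndim != 2 or P.shape[0] < 2:
        raise ValueError("need at least 2 pooled components")
    sds = P.std(axis=1)
    if np.any(sds == 0):
        bad = np.flatnonzero(sds == 0).tolist()
        raise ValueError(f"zero-variance source vector(s) at pooled index {bad}")
    sim = np.abs(np.corrcoef(P))
    np.fill_diagonal(sim, 1.0)
    return np.clip(sim, 0.0, 1.0)


def cluster_components(similarity: np.ndarray, k: int) -> list[np.ndarray]:
    """Average-linkage clustering on 1 - similarity, cut at ``k`` clusters.

    Returned clusters are ordered by their lowest member index, so the
    partition is deterministic for a given similarity matrix.
    """
    sim = np.asarray(similarity, float)
    m = sim.shape[0]
    if k > m:
        raise ValueError(f"k={k} exceeds number of pooled components {m}")
    dis = 1.0 - sim
    np.fill_diagonal(dis, 0.0)
    dis = (dis + dis.T) / 2.0
    Z = linkage(squareform(dis, checks=False), method="average")
    labels = fcluster(Z, t=k, criterion="maxclust")
    clusters = [np.flatnonzero(labels == c) for c in np.unique(labels)]
    clusters.sort(key=lambda idx: int(idx[0]))
    return clusters


def quality_index(
    cluster: np.ndarray, similarity: np.ndarray, floor: bool = True
) -> float:
    """Intra-cluster minus extra-cluster mean similarity.

    Singleton clusters have intra-similarity 1 by convention.  With
    ``floor=True`` (default) the value is clipped below at 0 to honor
    the nominal [0, 1] range; ``floor=False`` returns the raw value,
    which can be negative when a cluster is less coherent than its
    surroundings.
    """
    idx = np.asarray(cluster, int)
    if idx.size == 0:
        raise ValueError("empty cluster")
    sim = np.asarray(similarity, float)
    if idx.size == 1:
        intra = 1.0
    else:
        block = sim[np.ix_(idx, idx)]
        intra = float((block.sum() - np.trace(block)) / (idx.size * (idx.size - 1)))
    others = np.setdiff1d(np.arange(sim.shape[0]), idx)
    extra = float(sim[np.ix_(idx, others)].mean()) if others.size else 0.0
    raw = intra - extra
    if floor and raw < 0:
        warnings.warn(f"quality index {raw:.4f} below 0; floored")
        return 0.0
    return raw


def centrotype(cluster: np.ndarray, similarity: np.ndarray) -> int:
    """Cluster member maximizing total similarity to the other members.

    Ties resolve to the lowest pooled index, i.e. lowest run index then
    lowest component index under run-major pooling.
    """
    idx = np.asarray(cluster, int)
    if idx.size == 0:
        raise ValueError("empty cluster")
    block = similarity[np.ix_(idx, idx)]
    totals = block.sum(axis=1) - np.diag(block)
    return int(idx[int(np.argmax(totals))])


@dataclasses.dataclass
class IcassoResult:
    """Stability summary over repeated ICA runs."""

    n_runs: int                    # surviving runs pooled
    k: int
    similarity: np.ndarray         # (n_runs*k) x (n_runs*k) absolute correlations
    clusters: list[np.ndarray]     # partition of pooled component indices
    iq: np.ndarray                 # per final component, floored at 0
    iq_raw: np.ndarray             # per final component, unfloored
    centrotype_indices: np.ndarray # pooled index of each final component
    result: SBMResult              # centrotype sources + least-squares loadings
    base_seed: int = 0
    seeds: list[int] = dataclasses.field(default_factory=list)


def run_icasso(
    X,
    k: int,
    n_runs: int = 20,
    base_seed: int = 0,
    **ica_kwargs,
) -> IcassoResult:
    """Repeat the decomposition ``n_runs`` times and cluster the sources.

    Runs use seeds ``base_seed .. base_seed + n_runs - 1``.  A run that
    fails after Infomax's internal retries is dropped with a warning;
    fewer than 2 surviving runs is an error.  Final loadings are the
    least-squares fit of the centered data onto the centrotype sources.
    """
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    seeds = list(range(base_seed, base_seed + n_runs))
    runs: list[SBMResult] = []
    used_seeds: list[int] = []
    for s in seeds:
        try:
            runs.append(decompose(X, k, seed=s, **ica_kwargs))
            used_seeds.append(s)
        except RuntimeError as e:  # ICA divergence after bounded retries
            warnings.warn(f"dropping ICASSO run with seed {s}: {e}")
    if len(runs) < 2:
        raise RuntimeError("fewer than 2 ICASSO runs survived; cannot cluster")

    pooled = np.vstack([r.S for r in runs])
    sim = component_similarity(pooled)
    clusters = cluster_components(sim, k)
    iq_raw = np.array([quality_index(c, sim, floor=False) for c in clusters])
    iq = np.clip(iq_raw, 0.0, None)
    centro = np.array([centrotype(c, sim) for c in clusters])

    S = pooled[centro].copy()
    Xc = _center(X.X if isinstance(X, DataMatrix) else np.asarray(X, float))
    # least-squares mixing matrix against the centrotype sources
    A = np.linalg.lstsq(S.T, Xc.T, rcond=None)[0].T
    A, S = _fix_signs_and_scale(A, S)
    # _fix_signs_and_scale reorders components; track the permutation so
    # iq/clusters stay aligned with the final component order
    order = _component_order(pooled[centro], S)
    clusters = [clusters[i] for i in order]
    iq_raw = iq_raw[order]
    iq = iq[order]
    centro = centro[order]

    final = SBMResult(
        A=A, S=S, k=k, seed=base_seed,
        converged=all(r.converged for r in runs),
        n_iter=max(r.n_iter for r in runs),
        subject_order=X.subject_order if isinstance(X, DataMatrix) else None,
        mask=X.mask if isinstance(X, DataMatrix) else None,
    )
    return IcassoResult(
        n_runs=len(runs), k=k, similarity=sim, clusters=clusters,
        iq=iq, iq_raw=iq_raw, centrotype_indices=centro, result=final,
        base_seed=base_seed, seeds=used_seeds,
    )


def _component_order(before: np.ndarray, after: np.ndarray) -> list[int]:
    """Match reordered unit-variance rows back to their originals by |r|."""
    corr = np.abs(np.corrcoef(after, before)[: after.shape[0], after.shape[0]:])
    order = []
    taken: set[int] = set()
    for i in range(after.shape[0]):
        j = int(np.argmax(np.where(np.isin(np.arange(corr.shape[1]), list(taken)),
                                   -1.0, corr[i])))
        order.append(j)
        taken.add(j)
    return order
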
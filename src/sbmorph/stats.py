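"""Statistics on loading coefficients.

Group comparisons use a variance-equality F-test followed by Welch's
unequal-variance t-test per component, with Bonferroni familywise
correction across the k components.  Clinical-score correlations are
Pearson correlations computed within the patient group (scores are
administered to patients only), Bonferroni-corrected over the number of
scores tested per component.  A confound check (e.g. loading vs IQ) is
a single uncorrected correlation.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .decompose import SBMResult

__all__ = [
    "variance_test",
    "welch_ttest",
    "compare_groups",
    "correlate_scores",
    "confound_check",
]


def _loadings(result) -> np.ndarray:
    if isinstance(result, SBMResult):
        return result.A
    return np.asarray(result, float)


def variance_test(x, y) -> tuple[float, float]:
    """Two-sided F-test of equal variances.

    F is the larger sample variance over the smaller, with the matching
    degrees of freedom; p is the two-sided tail probability.  Identical
    samples of equal size give (1.0, 1.0).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs n >= 2")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        raise ValueError("both samples have zero variance")
    if vx >= vy:
        num_var, den_var, dfn, dfd = vx, vy, x.size - 1, y.size - 1
    else:
        num_var, den_var, dfn, dfd = vy, vx, y.size - 1, x.size - 1
    if den_var == 0:
        warnings.warn("one sample is constant; F-test p reported as 0")
        return float("inf"), 0.0
    f = num_var / den_var
    p = min(1.0, 2.0 * sps.f.sf(f, dfn, dfd))
    return float(f), float(p)


def welch_ttest(x, y) -> tuple[float, float, float]:
    """Welch's two-sample t-test: (t, Welch-Satterthwaite df, two-sided p)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs n >= 2")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        raise ValueError("both samples are constant")
    res = sps.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def compare_groups(
    result,
    groups: Sequence[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-component group test on the loading columns.

    ``groups`` is one label per loading row (exactly two distinct
    labels).  The t statistic is first-listed group minus the other.
    ``p_fwe`` is the Bonferroni correction over the k components;
    ``significant`` flags ``p_fwe < alpha``.
    """
    A = _loadings(result)
    groups = np.asarray(list(groups))
    if groups.size != A.shape[0]:
        raise ValueError("one group label per loading row required")
    labels = list(pd.unique(groups))
    if len(labels) != 2:
        raise ValueError(f"exactly two group labels required, got {labels}")
    ix = groups == labels[0]
    iy = groups == labels[1]
    k = A.shape[1]
    rows = []
    for j in range(k):
        f, p_var = variance_test(A[ix, j], A[iy, j])
        t, df, p_raw = welch_ttest(A[ix, j], A[iy, j])
        p_fwe = min(1.0, k * p_raw)
        rows.append(
            {
                "component": j,
                "f_stat": f,
                "p_var": p_var,
                "t_stat": t,
                "df": df,
                "p_raw": p_raw,
                "p_fwe": p_fwe,
                "significant": p_fwe < alpha,
            }
        )
    return pd.DataFrame(rows)


def correlate_scores(
    result,
    participants: pd.DataFrame,
    components: Sequence[int],
    score_names: Sequence[str] = ("score_total", "score_social", "score_stereo"),
    group: str | None = "patient",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pearson correlations between loadings and clinical scores.

    Computed within ``group`` (default the patient group; ``None`` uses
    all rows), pairwise-complete over missing scores.  ``p_corrected``
    is Bonferroni over the number of scores tested per component.  A
    constant score yields a NaN row (with a warning) while the other
    scores proceed.
    """
    A = _loadings(result)
    if len(participants) != A.shape[0]:
        raise ValueError("participants table length must match loading rows")
    sel = np.ones(len(participants), bool)
    if group is not None and "group" in participants.columns:
        sel = (participants["group"] == group).to_numpy()
    m = len(score_names)
    rows = []
    for j in components:
        lam = A[:, j]
        for name in score_names:
            score = pd.to_numeric(participants[name], errors="coerce").to_numpy(float)
            ok = sel & np.isfinite(score) & np.isfinite(lam)
            n = int(ok.sum())
            if n < 3:
                raise ValueError(
                    f"score {name!r}: fewer than 3 complete observations"
                )
            if np.std(score[ok]) == 0:
                warnings.warn(f"score {name!r} is constant; correlation undefined")
                r, p_raw, p_corr = np.nan, np.nan, np.nan
            else:
                r, p_raw = sps.pearsonr(lam[ok], score[ok])
                p_corr = min(1.0, m * p_raw)
            rows.append(
                {
                    "component": j,
                    "score": name,
                    "r": float(r),
                    "n": n,
                    "p_raw": float(p_raw),
                    "p_corrected": float(p_corr),
                    "significant": bool(p_corr < alpha) if np.isfinite(p_corr) else False,
                    "kind": "score",
                }
            )
    return pd.DataFrame(rows)


def confound_check(
    result,
    covariate,
    component: int,
    name: str = "confound",
) -> pd.DataFrame:
    """Uncorrected correlation of one component's loadings vs a covariate.

    Missing covariate values exclude those subjects (reported ``n``
    reflects the exclusion); a constant covariate is an error.
    """
    A = _loadings(result)
    cov = np.asarray(pd.to_numeric(pd.Series(covariate), errors="coerce"), float)
    if cov.size != A.shape[0]:
        raise ValueError("covariate length must match loading rows")
    lam = A[:, component]
    ok = np.isfinite(cov) & np.isfinite(lam)
    if ok.sum() < 3:
        raise ValueError("fewer than 3 complete covariate observations")
    if np.std(cov[ok]) == 0:
        raise ValueError("constant covariate")
    r, p = sps.pearsonr(lam[ok], cov[ok])
    return pd.DataFrame(
        [
            {
                "component": component,
                "score": name,
                "r": float(r),
                "n": int(ok.sum()),
                "p_raw": float(p),
                "p_corrected": float(p),
                "significant": bool(p < 0.05),
                "kind": "confound",
            }
        ]
    )
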
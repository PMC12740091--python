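"""ROI-level and vertexwise age-association statistics.

The core model is ordinary least squares of a metric on age with biological
sex as a covariate,

    metric = β₀ + β₁·age + β₂·sex + ε,

with a two-sided t-test on β₁ and Benjamini–Hochberg FDR correction across
the test family (the six subfields within each metric for ROI analysis;
all vertices within a map for vertexwise analysis).  The age-only model is
additionally summarized by the Pearson correlation r, which relates to the
t-statistic through t = r·√(n−2)/√(1−r²).

Model variants: M1 age; M2 age + age²; M3 age + sex; M4 age + age² + sex.
Nested variants are compared with the Gaussian-likelihood ratio statistic
n·ln(RSS₀/RSS₁) against a χ² with the coefficient-count difference as
degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "RegressionResult",
    "ols_age_model",
    "bh_fdr",
    "welch_t_from_summary",
    "pooled_t_from_summary",
    "lrt_nested",
    "vertexwise_regression",
    "spatial_correlation_matrix",
    "roi_summary",
]

MODEL_TERMS = {
    "M1": ("age",),
    "M2": ("age", "age2"),
    "M3": ("age", "sex"),
    "M4": ("age", "age2", "sex"),
}


@dataclass
class RegressionResult:
    beta0: float
    beta_age: float
    beta_sex: float | None
    beta_age2: float | None
    t_age: float
    p_age: float
    r: float
    n: int
    dof: int
    fdr_p: float | None = None


def _design(ages: np.ndarray, sexes: np.ndarray | None, model: str) -> np.ndarray:
    terms = MODEL_TERMS[model]
    cols = [np.ones(len(ages))]
    cols.append(ages)
    if "age2" in terms:
        cols.append(ages**2)
    if "sex" in terms:
        if sexes is None:
            raise ValueError(f"model {model} needs a sex covariate")
        cols.append(sexes)
    return np.column_stack(cols)


def ols_age_model(
    y, ages, sexes=None, model: str = "M3"
) -> RegressionResult:
    """OLS fit of a metric on age (and optionally age², sex).

    The reported r always comes from the age-only fit, matching the
    convention of summarizing the age association by the Pearson
    correlation; t and p are for the age coefficient of the requested
    model.
    """
    y = np.asarray(y, dtype=float)
    ages = np.asarray(ages, dtype=float)
    if sexes is not None:
        sexes = np.asarray(sexes, dtype=float)
    if model not in MODEL_TERMS:
        raise ValueError(f"unknown model {model!r}; choose from {sorted(MODEL_TERMS)}")
    x = _design(ages, sexes, model)
    n, p = x.shape
    if n <= p + 1:
        raise ValueError(f"need more than {p + 1} observations for model {model}")
    rank = np.linalg.matrix_rank(x)
    if rank < p:
        raise ValueError("collinear design matrix")
    beta, _, _, _ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    dof = n - p
    if np.ptp(y) == 0:
        # constant response: no association, by convention
        beta = np.zeros(p)
        beta[0] = y[0]
        t_age, p_age = 0.0, 1.0
    else:
        sigma2 = resid @ resid / dof
        cov = sigma2 * np.linalg.inv(x.T @ x)
        t_age = (
            beta[1] / np.sqrt(cov[1, 1]) if cov[1, 1] > 0 else np.inf * np.sign(beta[1])
        )
        p_age = 2.0 * sps.t.sf(abs(t_age), dof)
    sy = y.std()
    r = 0.0 if sy == 0 or ages.std() == 0 else float(np.corrcoef(ages, y)[0, 1])
    terms = MODEL_TERMS[model]
    idx = 2
    beta_age2 = None
    if "age2" in terms:
        beta_age2 = float(beta[idx])
        idx += 1
    beta_sex = float(beta[idx]) if "sex" in terms else None
    return RegressionResult(
        beta0=float(beta[0]),
        beta_age=float(beta[1]),
        beta_sex=beta_sex,
        beta_age2=beta_age2,
        t_age=float(t_age),
        p_age=float(p_age),
        r=r,
        n=n,
        dof=dof,
    )


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def welch_t_from_summary(n1, mean1, sd1, n2, mean2, sd2):
    """Welch's unequal-variance two-sample t from group summaries.

    Returns ``(t, dof, p)`` with the Welch–Satterthwaite degrees of freedom.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least two observations")
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    v1, v2 = sd1**2 / n1, sd2**2 / n2
    t = (mean1 - mean2) / np.sqrt(v1 + v2)
    dof = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    p = 2.0 * sps.t.sf(abs(t), dof)
    return float(t), float(dof), float(p)


def pooled_t_from_summary(n1, mean1, sd1, n2, mean2, sd2):
    """Classical (equal-variance) two-sample t from group summaries.

    Returns ``(t, dof, p)`` with dof = n1 + n2 − 2.  This is the form that
    reproduces the reported male/female age-balance statistic of the cohort
    this package emulates (t = 0.3517, p = 0.7261 for the 32/40 split);
    :func:`welch_t_from_summary` is the unequal-variance alternative.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least two observations")
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2)
    t = (mean1 - mean2) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    dof = n1 + n2 - 2
    p = 2.0 * sps.t.sf(abs(t), dof)
    return float(t), float(dof), float(p)


def _rss(y: np.ndarray, x: np.ndarray) -> float:
    beta, _, _, _ = np.linalg.lstsq(x, y, rcond=None)
    r = y - x @ beta
    return float(r @ r)


def lrt_nested(y, design_simple, design_complex):
    """Likelihood-ratio test of nested OLS models.

    The simple design's column space must be contained in the complex
    design's.  Statistic: n·ln(RSS₀/RSS₁) ~ χ²(Δp).
    """
    y = np.asarray(y, dtype=float)
    x0 = np.atleast_2d(np.asarray(design_simple, dtype=float))
    x1 = np.atleast_2d(np.asarray(design_complex, dtype=float))
    if x0.shape[0] != len(y) or x1.shape[0] != len(y):
        raise ValueError("design row counts must match y")
    # nesting check: projecting x0 onto span(x1) must reproduce it
    proj, _, _, _ = np.linalg.lstsq(x1, x0, rcond=None)
    if not np.allclose(x1 @ proj, x0, atol=1e-8):
        raise ValueError("designs are not nested")
    df = np.linalg.matrix_rank(x1) - np.linalg.matrix_rank(x0)
    rss0, rss1 = _rss(y, x0), _rss(y, x1)
    if df == 0 or rss1 <= 0:
        return 0.0, 1.0
    stat = len(y) * np.log(rss0 / rss1)
    stat = max(stat, 0.0)
    p = float(sps.chi2.sf(stat, df)) if df > 0 else 1.0
    return float(stat), p


def vertexwise_regression(
    maps: np.ndarray,
    ages,
    sexes=None,
    alpha: float = 0.05,
    model: str = "M3",
) -> dict:
    """Age regression at every vertex of a (n_subjects, n_vertices) array.

    Returns per-vertex ``r``, ``t``, ``p``, ``fdr_p`` arrays and the binary
    ``significant`` mask (BH-FDR across vertices at ``alpha``).  Vertices
    that are constant across subjects get r = 0, t = 0, p = 1.
    """
    maps = np.asarray(maps, dtype=float)
    ages = np.asarray(ages, dtype=float)
    if maps.ndim != 2:
        raise ValueError("maps must be (n_subjects, n_vertices)")
    if maps.shape[0] != len(ages):
        raise ValueError(
            f"subject count mismatch: {maps.shape[0]} maps vs {len(ages)} ages"
        )
    if sexes is not None:
        sexes = np.asarray(sexes, dtype=float)
    x = _design(ages, sexes, model)
    n, p_cols = x.shape
    dof = n - p_cols
    xtx_inv = np.linalg.inv(x.T @ x)
    pinv = xtx_inv @ x.T
    beta = pinv @ maps  # (p, n_vertices)
    resid = maps - x @ beta
    sigma2 = (resid**2).sum(axis=0) / dof
    se = np.sqrt(np.maximum(sigma2 * xtx_inv[1, 1], 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta[1] / se, 0.0)
    p = 2.0 * sps.t.sf(np.abs(t), dof)
    ac = ages - ages.mean()
    yc = maps - maps.mean(axis=0)
    denom = np.sqrt((ac**2).sum() * (yc**2).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(denom > 0, ac @ yc / denom, 0.0)
    const = maps.std(axis=0) == 0
    t[const], p[const], r[const] = 0.0, 1.0, 0.0
    fdr_p = bh_fdr(p)
    return {
        "r": r,
        "t": t,
        "p": p,
        "fdr_p": fdr_p,
        "significant": fdr_p < alpha,
        "beta_age": beta[1],
        "dof": dof,
    }


def spatial_correlation_matrix(
    metric_maps: dict, alpha: float = 0.05
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Pearson correlation matrix between subject-mean per-vertex maps.

    Missing vertices are excluded pairwise; significance of off-diagonal
    entries is BH-FDR corrected over the upper triangle.  Returns
    ``(r, p, significant)`` DataFrames keyed by metric name.
    """
    names = list(metric_maps)
    k = len(names)
    arrays = [np.asarray(metric_maps[n], dtype=float) for n in names]
    n_vert = {len(a) for a in arrays}
    if len(n_vert) != 1:
        raise ValueError("metric maps must share vertex indexing")
    r_mat = np.eye(k)
    p_mat = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            ok = ~(np.isnan(arrays[i]) | np.isnan(arrays[j]))
            m = int(ok.sum())
            if m < 3:
                raise ValueError(
                    f"fewer than 3 common vertices between {names[i]} and {names[j]}"
                )
            r = float(np.corrcoef(arrays[i][ok], arrays[j][ok])[0, 1])
            if abs(r) >= 1.0:
                p = 0.0
            else:
                t = r * np.sqrt((m - 2) / (1.0 - r**2))
                p = 2.0 * sps.t.sf(abs(t), m - 2)
            r_mat[i, j] = r_mat[j, i] = r
            p_mat[i, j] = p_mat[j, i] = p
    iu = np.triu_indices(k, 1)
    sig = np.zeros((k, k), dtype=bool)
    if len(iu[0]):
        adj = bh_fdr(p_mat[iu])
        sig[iu] = adj < alpha
        sig |= sig.T
    return (
        pd.DataFrame(r_mat, index=names, columns=names),
        pd.DataFrame(p_mat, index=names, columns=names),
        pd.DataFrame(sig, index=names, columns=names),
    )


def roi_summary(
    maps: np.ndarray, labels: np.ndarray, label_names: dict | None = None
) -> pd.DataFrame:
    """Unweighted per-ROI means of per-vertex maps, one row per subject.

    ``maps`` is (n_subjects, n_vertices); vertices with NaN (e.g. thickness
    in the dentate gyrus) are ignored within each ROI; an ROI that is
    entirely NaN yields NaN.
    """
    maps = np.atleast_2d(np.asarray(maps, dtype=float))
    labels = np.asarray(labels)
    if maps.shape[1] != len(labels):
        raise ValueError("label length must match vertex count")
    uniq = [u for u in np.unique(labels) if u != 0]
    out = {}
    for u in uniq:
        sel = labels == u
        if not np.any(sel):
            raise ValueError(f"empty ROI {u}")
        vals = maps[:, sel]
        counts = (~np.isnan(vals)).sum(axis=1)
        sums = np.nansum(vals, axis=1)
        col = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        name = (label_names or {}).get(u, str(u))
        out[name] = col
    return pd.DataFrame(out)
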
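"""Group-level inference for connectivity features.

Covers the four statistical tools of the analysis:

* distance-based PERMANOVA (Anderson pseudo-F on Mahalanobis distances, with
  free label permutations and optional pairwise post-hocs under BH-FDR);
* OLS residualization of nuisance covariates (age, optionally sex);
* partial Spearman correlation (rank correlation of covariate residuals) with
  one- or two-sided p-values and Benjamini-Hochberg adjustment;
* the locus-coeruleus x cognitive-reserve regression
  ``fluidity ~ poly(LC, 2) * reserve_group`` with an R-convention orthogonal
  polynomial basis and a median split of the (age-residualized) reserve score.

Cohort tables are plain pandas DataFrames with columns ``subject_id``,
``group``, ``age``, ``sex`` plus numeric feature/score columns; every analysis
is complete-case with the effective n reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sstats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "GROUP_LABELS",
    "PermanovaResult",
    "RegressionFit",
    "residualize",
    "mahalanobis_distances",
    "permanova",
    "partial_spearman",
    "fdr_adjust",
    "orthogonal_poly",
    "fit_lc_reserve_model",
    "split_possible_probable",
    "validate_cohort",
]

#: fixed vocabulary of diagnostic group labels (3-group collapse supported)
GROUP_LABELS = ("HC", "CN-CCF", "MCI-LB", "possible MCI-LB", "probable MCI-LB")


@dataclass(frozen=True)
class PermanovaResult:
    pseudo_F: float
    p: float
    n_perm: int
    df_between: int
    df_within: int
    n_obs: int
    pairwise: list | None = None  # (pair, F, p, p_fdr) tuples


@dataclass(frozen=True)
class RegressionFit:
    coefficients: dict
    se: dict
    t: dict
    p: dict
    overall_F: float
    overall_df: tuple[int, int]
    overall_p: float
    n_obs: int


def validate_cohort(df: pd.DataFrame) -> pd.DataFrame:
    """Check the cohort-table contract (unique ids, known group labels)."""
    if df["subject_id"].duplicated().any():
        raise ValueError("duplicated subject_id")
    unknown = set(df["group"]) - set(GROUP_LABELS)
    if unknown:
        raise ValueError(f"unknown group labels: {sorted(unknown)}")
    return df


def residualize(values: np.ndarray, covariates: np.ndarray | None) -> np.ndarray:
    """OLS residuals of ``values`` on an intercept plus ``covariates``.

    Rows with missing data (in values or covariates) are dropped from the fit
    and returned as NaN, preserving alignment.
    """
    values = np.asarray(values, dtype=float)
    if covariates is None:
        return values - np.nanmean(values)
    cov = np.asarray(covariates, dtype=float)
    if cov.ndim == 1:
        cov = cov[:, None]
    ok = np.isfinite(values) & np.all(np.isfinite(cov), axis=1)
    if ok.sum() < cov.shape[1] + 2:
        raise ValueError("too few complete rows to residualize")
    if not ok.all():
        logger.info("residualize: dropping %d incomplete rows", int((~ok).sum()))
    design = np.column_stack([np.ones(ok.sum()), cov[ok]])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("covariate matrix is rank deficient")
    beta, *_ = np.linalg.lstsq(design, values[ok], rcond=None)
    out = np.full(values.shape, np.nan)
    out[ok] = values[ok] - design @ beta
    return out


def mahalanobis_distances(features: np.ndarray) -> np.ndarray:
    """Pairwise Mahalanobis distances under the pooled sample covariance.

    Raises on a singular covariance (p >= n or collinear features) rather than
    silently falling back to a pseudo-inverse.
    """
    x = np.asarray(features, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if not np.all(np.isfinite(x)):
        raise ValueError("features must be complete-case (no NaN)")
    n, p = x.shape
    if n <= p:
        raise ValueError("need more subjects than features for the covariance")
    cov = np.cov(x, rowvar=False, ddof=1).reshape(p, p)
    evals = np.linalg.eigvalsh(cov)
    if evals.min() <= evals.max() * 1e-10:
        raise ValueError(
            "singular feature covariance; reduce or decorrelate the features"
        )
    chol = np.linalg.cholesky(cov)
    # whiten by the Cholesky factor, then take Euclidean distances
    z = np.linalg.solve(chol, x.T).T
    diff = z[:, None, :] - z[None, :, :]
    return np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))


def _group_indicator(groups: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    labels, inv = np.unique(groups, return_inverse=True)
    return labels, inv


def _permanova_f(d2: np.ndarray, inv: np.ndarray, k: int, counts: np.ndarray) -> float:
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, k=1)].sum() / n
    ss_within = 0.0
    for g in range(k):
        idx = np.flatnonzero(inv == g)
        ss_within += d2[np.ix_(idx, idx)].sum() / (2 * counts[g])
    ss_between = ss_total - ss_within
    df_b, df_w = k - 1, n - k
    if ss_within <= 0:
        return float("inf") if ss_between > 0 else float("nan")
    return (ss_between / df_b) / (ss_within / df_w)


def permanova(
    dist: np.ndarray,
    groups,
    n_perm: int = 20000,
    seed: int = 0,
    pairwise: bool = False,
    _block: int = 512,
) -> PermanovaResult:
    """Anderson-style PERMANOVA on a distance matrix.

    ``pseudo_F = (SS_between/df_between) / (SS_within/df_within)`` computed
    from squared distances; the p-value is ``(1 + #{F_perm >= F_obs}) /
    (1 + n_perm)`` under free whole-label permutation. With ``pairwise=True``
    each group pair is re-tested on its submatrix of the full distance matrix
    and the pairwise p-values are BH-adjusted across pairs.
    """
    dist = np.asarray(dist, dtype=float)
    groups = np.asarray(groups)
    n = dist.shape[0]
    if dist.shape != (n, n) or not np.allclose(dist, dist.T):
        raise ValueError("dist must be a symmetric square matrix")
    if np.any(np.diag(dist) != 0):
        raise ValueError("dist must have a zero diagonal")
    labels, inv = _group_indicator(groups)
    k = len(labels)
    counts = np.bincount(inv)
    if k < 2 or counts.min() < 2:
        raise ValueError("need >= 2 groups with >= 2 members each")
    d2 = dist**2
    if np.allclose(d2[np.triu_indices(n, k=1)], d2[0, 1]):
        logger.warning("constant distances: degenerate PERMANOVA")
        return PermanovaResult(float("nan"), float("nan"), n_perm, k - 1, n - k, n)

    f_obs = _permanova_f(d2, inv, k, counts)
    rng = np.random.default_rng(seed)
    count_ge = 0
    # vectorized permutation blocks: SS_within via fancy indexing per group
    for start in range(0, n_perm, _block):
        b = min(_block, n_perm - start)
        perms = np.argsort(rng.random((b, n)), axis=1)
        ss_within = np.zeros(b)
        for g in range(k):
            pos = np.flatnonzero(inv == g)  # fixed label positions
            idx = perms[:, pos]  # (b, n_g) permuted members of group g
            sub = d2[idx[:, :, None], idx[:, None, :]]
            ss_within += sub.sum(axis=(1, 2)) / (2 * counts[g])
        ss_total = d2[np.triu_indices(n, k=1)].sum() / n
        ss_between = ss_total - ss_within
        with np.errstate(divide="ignore", invalid="ignore"):
            f_perm = (ss_between / (k - 1)) / (ss_within / (n - k))
        count_ge += int(np.sum(f_perm >= f_obs))
    p = (1 + count_ge) / (1 + n_perm)

    pairwise_results = None
    if pairwise:
        pairwise_results = []
        raw = []
        for a in range(k):
            for b_ in range(a + 1, k):
                sel = np.flatnonzero((inv == a) | (inv == b_))
                sub = permanova(
                    dist[np.ix_(sel, sel)], groups[sel], n_perm=n_perm, seed=seed
                )
                raw.append(((str(labels[a]), str(labels[b_])), sub.pseudo_F, sub.p))
        adj = fdr_adjust(np.array([r[2] for r in raw]))
        pairwise_results = [
            (pair, f, pv, float(pa)) for (pair, f, pv), pa in zip(raw, adj)
        ]
    return PermanovaResult(
        pseudo_F=float(f_obs),
        p=float(p),
        n_perm=n_perm,
        df_between=k - 1,
        df_within=n - k,
        n_obs=n,
        pairwise=pairwise_results,
    )


def partial_spearman(
    x,
    y,
    covariates=None,
    alternative: str = "two-sided",
) -> tuple[float, float]:
    """Spearman correlation of covariate residuals, with stated sidedness.

    Both variables are residualized on the covariates (OLS, complete cases),
    then ranked; the p-value uses the t approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        ok = np.isfinite(x) & np.isfinite(y) & np.all(np.isfinite(cov), axis=1)
        rx = residualize(x[ok], cov[ok])
        ry = residualize(y[ok], cov[ok])
    else:
        ok = np.isfinite(x) & np.isfinite(y)
        rx, ry = x[ok], y[ok]
    if ok.sum() < 5:
        raise ValueError("need at least 5 complete pairs")
    if np.std(rx) == 0 or np.std(ry) == 0:
        return float("nan"), float("nan")
    res = sstats.spearmanr(rx, ry, alternative=alternative)
    return float(res.statistic), float(res.pvalue)


def fdr_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def orthogonal_poly(x: np.ndarray, degree: int = 2) -> np.ndarray:
    """Orthogonal polynomial basis in the convention of R's ``poly()``:
    columns are centered, mutually orthogonal, orthogonal to the intercept,
    and scaled to unit Euclidean norm; column j has a positive leading
    coefficient on x**j."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if degree >= n:
        raise ValueError("degree must be < number of observations")
    if np.unique(x).size <= degree:
        raise ValueError("too few distinct x values for the requested degree")
    vander = np.vander(x, degree + 1, increasing=True)
    q, r = np.linalg.qr(vander)
    basis = q[:, 1:] * np.sign(np.diag(r)[1:])
    return basis / np.linalg.norm(basis, axis=0)


def fit_lc_reserve_model(
    table: pd.DataFrame,
    fluidity_feature: str,
    lc_feature: str,
    reserve_score: str,
    age_col: str = "age",
) -> RegressionFit:
    """OLS fit of ``fluidity ~ poly(LC, 2) * reserve_group``.

    Fluidity, LC signal and the reserve score are first residualized on age;
    the reserve residual is median-split into lower/higher subgroups (<=
    median -> lower); the LC variable enters through a degree-2 orthogonal
    polynomial basis fully interacted with the subgroup indicator.
    """
    cols = [fluidity_feature, lc_feature, reserve_score, age_col]
    data = table[cols].astype(float)
    ok = np.all(np.isfinite(data.values), axis=1)
    data = data.loc[ok]
    n = len(data)
    if n < 20:
        raise ValueError("need at least 20 complete cases")
    age = data[age_col].values
    y = residualize(data[fluidity_feature].values, age)
    lc = residualize(data[lc_feature].values, age)
    reserve = residualize(data[reserve_score].values, age)
    if np.unique(reserve).size == 1:
        raise ValueError("reserve score constant: median split impossible")
    high = (reserve > np.median(reserve)).astype(float)  # 1 = higher reserve
    basis = orthogonal_poly(lc, 2)
    design = np.column_stack(
        [
            np.ones(n),
            basis[:, 0],
            basis[:, 1],
            high,
            basis[:, 0] * high,
            basis[:, 1] * high,
        ]
    )
    names = [
        "intercept",
        "poly1",
        "poly2",
        "group_high",
        "poly1:group_high",
        "poly2:group_high",
    ]
    fit = sm.OLS(y, design).fit()
    return RegressionFit(
        coefficients=dict(zip(names, fit.params)),
        se=dict(zip(names, fit.bse)),
        t=dict(zip(names, fit.tvalues)),
        p=dict(zip(names, fit.pvalues)),
        overall_F=float(fit.fvalue),
        overall_df=(int(fit.df_model), int(fit.df_resid)),
        overall_p=float(fit.f_pvalue),
        n_obs=n,
    )


def split_possible_probable(
    table: pd.DataFrame, counts_col: str = "n_core_features"
) -> pd.DataFrame:
    """Relabel MCI-LB subjects by core-clinical-feature count.

    One core feature -> possible MCI-LB; two or more -> probable MCI-LB; zero
    or missing -> unclassified (row dropped with a log record).
    """
    out = table.copy()
    is_mci = out["group"] == "MCI-LB"
    counts = pd.to_numeric(out.loc[is_mci, counts_col], errors="coerce")
    if (counts.dropna() < 0).any():
        raise ValueError("negative core-feature counts")
    possible = counts == 1
    probable = counts >= 2
    unclassified = ~(possible | probable)
    out.loc[is_mci & possible.reindex(out.index, fill_value=False), "group"] = (
        "possible MCI-LB"
    )
    out.loc[is_mci & probable.reindex(out.index, fill_value=False), "group"] = (
        "probable MCI-LB"
    )
    drop_idx = counts.index[unclassified]
    if len(drop_idx):
        logger.warning(
            "excluding %d MCI-LB subjects unclassified by core-feature count",
            len(drop_idx),
        )
        out = out.drop(index=drop_idx)
    return out.reset_index(drop=True)
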
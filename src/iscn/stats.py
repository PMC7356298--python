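"""Group comparison and brain-behaviour correlation statistics.

The statistical stage mirrors a standard covariate-adjusted neuroimaging
workflow:

* per-index one-way ANCOVA (``value ~ group + covariate``) with the group
  F test, partial eta squared, Benjamini-Hochberg FDR across the index
  family, and LSD (unadjusted pairwise t) post-hoc tests on
  covariate-adjusted means where the omnibus test survives FDR;
* partial Pearson correlations (residual correlation after regressing out
  covariates) with a seeded bootstrap percentile confidence interval.

All tests are two-tailed; sample statistics use the ``n - 1`` denominator.
Models are fitted by ordinary least squares on an explicit design matrix,
so every quantity is reproducible bit-for-bit given the inputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateInputError, ValidationError

__all__ = [
    "PairwiseResult",
    "GroupComparisonResult",
    "CorrelationResult",
    "ancova_per_index",
    "fdr_adjust",
    "lsd_posthoc",
    "compare_global",
    "compare_nodal",
    "partial_correlation",
    "bootstrap_partial_correlation",
    "correlation_screen",
    "manova_pretest",
]

logger = logging.getLogger(__name__)


@dataclass
class PairwiseResult:
    pair: tuple[str, str]
    mean_difference: float
    t: float
    p: float


@dataclass
class GroupComparisonResult:
    index_name: str
    F: float
    df: tuple[int, int]
    p_raw: float
    p_fdr: float | None
    partial_eta_squared: float
    posthoc: list[PairwiseResult] = field(default_factory=list)


@dataclass
class CorrelationResult:
    var_x: str
    var_y: str
    covariates: list[str]
    group: str | None
    n: int
    r: float
    p_parametric: float
    ci_low: float | None = None
    ci_high: float | None = None
    p_bootstrap: float | None = None
    n_boot: int | None = None
    n_redrawn: int = 0
    seed: int | None = None


def _group_design(
    groups: np.ndarray, order: list[str], covariate: np.ndarray | None
) -> tuple[np.ndarray, np.ndarray]:
    """Full and reduced (no-group) design matrices, dummy-coded on order[0].

    Constant covariate columns carry no adjustment (they are absorbed by
    the intercept) and are dropped, so a zero or constant covariate reduces
    the model to the classical one-way ANOVA.
    """
    n = len(groups)
    cols = [np.ones(n)]
    for g in order[1:]:
        cols.append((groups == g).astype(float))
    cov_cols = []
    if covariate is not None:
        cov = np.asarray(covariate, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        cov_cols = [
            cov[:, j] for j in range(cov.shape[1]) if cov[:, j].std() > 0
        ]
    X_full = np.column_stack(cols + cov_cols)
    X_red = np.column_stack([np.ones(n)] + cov_cols)
    return X_full, X_red


def _sse(X: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid)


def _check_inputs(values, groups, covariate):
    y = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if y.ndim != 1 or len(y) != len(groups):
        raise ValidationError("values and group labels must align")
    if not np.isfinite(y).all():
        raise ValidationError("non-finite outcome values")
    order = list(dict.fromkeys(groups.tolist()))
    if len(order) < 2:
        raise DegenerateInputError("need at least 2 groups")
    for g in order:
        if (groups == g).sum() < 2:
            raise DegenerateInputError(f"group {g!r} has fewer than 2 subjects")
    if y.std(ddof=1) == 0:
        raise DegenerateInputError("outcome is constant across subjects")
    if covariate is not None:
        cov = np.asarray(covariate, dtype=float)
        if not np.isfinite(cov).all():
            raise ValidationError("non-finite covariate values")
    return y, groups, order


def ancova_per_index(
    values,
    groups,
    covariate=None,
    index_name: str = "",
) -> GroupComparisonResult:
    """One-way fixed-effects ANCOVA for the group factor.

    Fits ``value ~ group + covariate`` by OLS and tests the group effect by
    the extra-sum-of-squares F test against the covariate-only model.  With
    a constant (or absent) covariate this reduces exactly to the classical
    one-way ANOVA.  Partial eta squared is ``SS_group / (SS_group + SS_error)``.
    """
    y, groups, order = _check_inputs(values, groups, covariate)
    X_full, X_red = _group_design(groups, order, covariate)
    if np.linalg.matrix_rank(X_full) < X_full.shape[1]:
        raise DegenerateInputError("rank-deficient design (collinear covariate?)")
    sse_full = _sse(X_full, y)
    sse_red = _sse(X_red, y)
    df1 = len(order) - 1
    df2 = len(y) - X_full.shape[1]
    if df2 <= 0:
        raise DegenerateInputError("no residual degrees of freedom")
    ss_group = max(sse_red - sse_full, 0.0)
    if sse_full == 0.0:
        raise DegenerateInputError("saturated model (zero residual variance)")
    F = (ss_group / df1) / (sse_full / df2)
    p = float(sps.f.sf(F, df1, df2))
    eta2 = ss_group / (ss_group + sse_full)
    return GroupComparisonResult(
        index_name=index_name,
        F=float(F),
        df=(df1, df2),
        p_raw=p,
        p_fdr=None,
        partial_eta_squared=float(eta2),
    )


def fdr_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values (input order preserved)."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValidationError("p must be a non-empty 1-d vector")
    if ((p < 0) | (p > 1) | ~np.isfinite(p)).any():
        raise ValidationError("p values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def lsd_posthoc(values, groups, covariate=None) -> list[PairwiseResult]:
    """LSD pairwise comparisons on covariate-adjusted means.

    Differences of adjusted group means are contrasts of the omnibus OLS
    coefficients; their standard errors use the pooled residual mean square
    and its degrees of freedom.  P values are intentionally unadjusted
    (the LSD convention).
    """
    y, groups, order = _check_inputs(values, groups, covariate)
    X, _ = _group_design(groups, order, covariate)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DegenerateInputError("rank-deficient design (collinear covariate?)")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    df2 = len(y) - X.shape[1]
    ms_error = float(resid @ resid) / df2
    xtx_inv = np.linalg.inv(X.T @ X)
    results = []
    # dummy coding: column j+1 is the offset of order[j+1] from order[0]
    coef_index = {g: j + 1 for j, g in enumerate(order[1:])}
    p_dim = X.shape[1]
    for ga, gb in combinations(order, 2):
        c = np.zeros(p_dim)
        if ga in coef_index:
            c[coef_index[ga]] = 1.0
        if gb in coef_index:
            c[coef_index[gb]] -= 1.0
        diff = float(c @ beta)
        se = float(np.sqrt(ms_error * (c @ xtx_inv @ c)))
        t = diff / se
        p = 2.0 * float(sps.t.sf(abs(t), df2))
        results.append(PairwiseResult(pair=(ga, gb), mean_difference=diff, t=t, p=p))
    return results


def _compare_family(
    table: pd.DataFrame,
    groups,
    covariate,
    alpha: float,
) -> tuple[list[GroupComparisonResult], list[str]]:
    """ANCOVA per column, FDR across the family, LSD where FDR-significant.

    Constant (zero-variance) columns are excluded from the family with a
    logged warning; the FDR family size shrinks accordingly.
    """
    results: list[GroupComparisonResult] = []
    excluded: list[str] = []
    for col in table.columns:
        y = table[col].to_numpy(dtype=float)
        try:
            res = ancova_per_index(y, groups, covariate, index_name=str(col))
        except DegenerateInputError as exc:
            if "constant" in str(exc) or "saturated" in str(exc):
                logger.warning("excluding degenerate index %r: %s", col, exc)
                excluded.append(str(col))
                continue
            raise
        results.append(res)
    if results:
        p_adj = fdr_adjust([r.p_raw for r in results])
        for r, pa in zip(results, p_adj):
            r.p_fdr = float(pa)
            if pa < alpha:
                r.posthoc = lsd_posthoc(
                    table[r.index_name].to_numpy(dtype=float), groups, covariate
                )
    return results, excluded


def compare_global(
    global_metrics: pd.DataFrame,
    groups,
    covariate=None,
    alpha: float = 0.05,
) -> list[GroupComparisonResult]:
    """ANCOVA for each global index with FDR across the family of indices."""
    results, excluded = _compare_family(global_metrics, groups, covariate, alpha)
    if excluded:
        raise DegenerateInputError(
            f"degenerate global index column(s): {excluded}"
        )
    return results


def compare_nodal(
    nodal_metrics: pd.DataFrame,
    groups,
    covariate=None,
    alpha: float = 0.05,
) -> tuple[list[GroupComparisonResult], list[str]]:
    """ANCOVA per region with FDR across regions.

    Returns the per-region results and the names of any zero-variance
    regions excluded from the FDR family.
    """
    return _compare_family(nodal_metrics, groups, covariate, alpha)


def manova_pretest(
    table: pd.DataFrame, groups, covariate=None
) -> tuple[float, float, float]:
    """Optional multivariate omnibus test across all columns jointly.

    Wilks' lambda for the group effect after covariate adjustment, with
    Rao's F approximation.  Returns ``(wilks_lambda, F, p)``.  The
    per-index ANCOVA family remains the primary analysis; this pre-test is
    provided for users who want a single gatekeeper test.
    """
    Y = table.to_numpy(dtype=float)
    _, groups_arr, order = _check_inputs(Y[:, 0], groups, covariate)
    X_full, X_red = _group_design(groups_arr, order, covariate)

    def resid(X):
        B, *_ = np.linalg.lstsq(X, Y, rcond=None)
        return Y - X @ B

    E = resid(X_full)
    R = resid(X_red)
    E_sscp = E.T @ E
    H_sscp = R.T @ R - E_sscp
    lam = float(
        np.linalg.det(E_sscp) / np.linalg.det(E_sscp + H_sscp)
    )
    p_dim = Y.shape[1]
    q = len(order) - 1
    n = Y.shape[0]
    df_err = n - X_full.shape[1]
    t = np.sqrt((p_dim**2 * q**2 - 4) / (p_dim**2 + q**2 - 5)) if (
        p_dim**2 + q**2 - 5
    ) > 0 else 1.0
    w = df_err + q - (p_dim + q + 1) / 2.0
    df1 = p_dim * q
    df2 = w * t - (p_dim * q - 2) / 2.0
    lam_t = lam ** (1.0 / t)
    F = (1 - lam_t) / lam_t * df2 / df1
    p = float(sps.f.sf(F, df1, df2))
    return lam, float(F), p


def _residualize(v: np.ndarray, Z: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(Z, v, rcond=None)
    return v - Z @ beta


def partial_correlation(
    x,
    y,
    covariates=None,
    var_x: str = "x",
    var_y: str = "y",
    covariate_names: list[str] | None = None,
    group: str | None = None,
) -> CorrelationResult:
    """Partial Pearson correlation of ``x`` and ``y`` given covariates.

    Computed as the Pearson correlation of OLS residuals after regressing
    both variables on the covariates (plus an intercept); the parametric
    p value uses a t distribution with ``n - 2 - k`` degrees of freedom for
    ``k`` covariates.  With no covariates this is the plain Pearson r.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be 1-d vectors of equal length")
    if covariates is None:
        Z = np.empty((len(x), 0))
    else:
        Z = np.asarray(covariates, dtype=float)
        if Z.ndim == 1:
            Z = Z[:, None]
    if not (np.isfinite(x).all() and np.isfinite(y).all() and np.isfinite(Z).all()):
        raise ValidationError("non-finite values in correlation inputs")
    n, k = len(x), Z.shape[1]
    if n <= k + 2:
        raise DegenerateInputError(
            f"need n > #covariates + 2 (n={n}, covariates={k})"
        )
    design = np.column_stack([np.ones(n), Z])
    rx = _residualize(x, design)
    ry = _residualize(y, design)
    sx, sy = rx.std(ddof=1), ry.std(ddof=1)
    if sx == 0 or sy == 0:
        raise DegenerateInputError("zero residual variance in x or y")
    r = float(np.clip((rx @ ry) / ((n - 1) * sx * sy), -1.0, 1.0))
    dof = n - 2 - k
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(dof / (1.0 - r * r))
        p = 2.0 * float(sps.t.sf(abs(t), dof))
    return CorrelationResult(
        var_x=var_x,
        var_y=var_y,
        covariates=list(covariate_names or []),
        group=group,
        n=n,
        r=r,
        p_parametric=p,
    )


def bootstrap_partial_correlation(
    x,
    y,
    covariates=None,
    n_boot: int = 5000,
    seed: int | None = None,
    var_x: str = "x",
    var_y: str = "y",
    covariate_names: list[str] | None = None,
    group: str | None = None,
    max_redraws: int = 100_000,
) -> CorrelationResult:
    """Partial correlation with a bootstrap percentile 95% interval.

    Subjects are resampled with replacement ``n_boot`` times; resamples with
    degenerate variance are redrawn (counted in ``n_redrawn``).  The
    bootstrap p value is the two-sided proportion of resampled r values on
    the far side of zero.  Deterministic given ``seed``.
    """
    base = partial_correlation(
        x, y, covariates, var_x=var_x, var_y=var_y,
        covariate_names=covariate_names, group=group,
    )
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if covariates is None:
        Z = np.empty((len(x), 0))
    else:
        Z = np.asarray(covariates, dtype=float)
        if Z.ndim == 1:
            Z = Z[:, None]
    n = len(x)
    rng = np.random.default_rng(seed)
    rs = np.empty(n_boot)
    redrawn = 0
    i = 0
    while i < n_boot:
        idx = rng.integers(0, n, size=n)
        xb, yb, Zb = x[idx], y[idx], Z[idx]
        design = np.column_stack([np.ones(n), Zb])
        if np.linalg.matrix_rank(design) < design.shape[1]:
            redrawn += 1
            if redrawn > max_redraws:
                raise DegenerateInputError("too many degenerate bootstrap resamples")
            continue
        rx = _residualize(xb, design)
        ry = _residualize(yb, design)
        sx, sy = rx.std(ddof=1), ry.std(ddof=1)
        if sx == 0 or sy == 0:
            redrawn += 1
            if redrawn > max_redraws:
                raise DegenerateInputError("too many degenerate bootstrap resamples")
            continue
        rs[i] = np.clip((rx @ ry) / ((n - 1) * sx * sy), -1.0, 1.0)
        i += 1
    if redrawn:
        logger.warning("redrew %d degenerate bootstrap resamples", redrawn)
    lo, hi = np.percentile(rs, [2.5, 97.5])
    p_boot = 2.0 * min((rs <= 0).mean(), (rs >= 0).mean())
    base.ci_low = float(lo)
    base.ci_high = float(hi)
    base.p_bootstrap = float(min(p_boot, 1.0))
    base.n_boot = n_boot
    base.n_redrawn = redrawn
    base.seed = seed
    return base


def correlation_screen(
    indices: pd.DataFrame,
    scores: pd.DataFrame,
    groups,
    covariates_per_group: dict[str, list[str]],
    covariate_table: pd.DataFrame | None = None,
    n_boot: int = 5000,
    seed: int | None = None,
) -> list[CorrelationResult]:
    """Within-group partial correlations of each index against each score.

    ``covariates_per_group`` names, per group label, the columns of
    ``covariate_table`` to partial out (an empty list means plain Pearson).
    Scores entirely missing within a group are skipped; partially missing
    scores are used pairwise-complete.  Bootstrap seeds for each
    (group, index, score) combination are spawned deterministically from
    ``seed``.
    """
    groups = np.asarray(groups)
    results: list[CorrelationResult] = []
    ss = np.random.SeedSequence(seed)
    for group_label in dict.fromkeys(groups.tolist()):
        mask = groups == group_label
        cov_names = list(covariates_per_group.get(group_label, []))
        if cov_names and covariate_table is None:
            raise ValidationError("covariates requested but no covariate table given")
        for index_col in indices.columns:
            for score_col in scores.columns:
                xv = indices.loc[mask, index_col].to_numpy(dtype=float)
                yv = scores.loc[mask, score_col].to_numpy(dtype=float)
                if cov_names:
                    Z = covariate_table.loc[mask, cov_names].to_numpy(dtype=float)
                else:
                    Z = np.empty((mask.sum(), 0))
                keep = np.isfinite(xv) & np.isfinite(yv) & np.isfinite(Z).all(axis=1)
                if not keep.any():
                    continue
                sub_seed = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31))
                results.append(
                    bootstrap_partial_correlation(
                        xv[keep],
                        yv[keep],
                        Z[keep] if cov_names else None,
                        n_boot=n_boot,
                        seed=sub_seed,
                        var_x=str(index_col),
                        var_y=str(score_col),
                        covariate_names=cov_names,
                        group=str(group_label),
                    )
                )
    return results
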
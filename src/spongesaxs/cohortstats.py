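"""Cohort statistics linking nanostructure to reflectance.

Operates on a per-sample table with sex (M/F), year, the six Porod-peak
parameters (positions q1/q2, widths h1/h2, log-amplitudes loga1/loga2),
the three reflectance variables (brightness, uv_chroma, hue) and optionally
a predicted hue.  The pipeline mirrors a classical quantitative-plumage
workflow:

* within-sex standardization of sexually dimorphic measures;
* Student t-tests (pooled variance) for sex means, two-tailed F-tests for
  sex variances;
* Pearson correlation matrices of standardized measures;
* general linear models with backward stepwise simplification and
  single-term reintroduction, respecting marginality (interactions leave
  before their main effects);
* varimax-rotated principal components to decorrelate collinear predictors;
* dichromatism residual analysis: regression coefficients fitted on males
  only, residuals for both sexes compared by t-test;
* a paired estimated-vs-measured hue comparison with a sex-by-data-type
  interaction (difference scores, exactly equivalent to a two-level
  repeated-measures factor);
* between-round repeatability with a sex-difference test on the slopes.

Ordinary least-squares fits go through statsmodels; test statistics through
scipy.  All p-values are two-sided and no multiplicity correction is
applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats


@dataclass(frozen=True)
class TestResult:
    """One hypothesis test: statistic, degrees of freedom, p, direction."""

    name: str
    statistic: float
    df: float | tuple
    p_value: float
    direction: str = ""

    def __post_init__(self) -> None:
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value must be in [0, 1]")


# ---------------------------------------------------------------------------
# standardization and simple comparisons
# ---------------------------------------------------------------------------

def sex_standardize(
    table: pd.DataFrame, columns: Sequence[str], sex_col: str = "sex"
) -> pd.DataFrame:
    """Append within-sex z-score columns (suffix ``_z``, n-1 denominator)."""
    out = table.copy()
    for col in columns:
        z = np.full(len(out), np.nan)
        for sex, group in out.groupby(sex_col):
            vals = group[col].to_numpy(dtype=float)
            if len(vals) < 2:
                raise ValueError(f"sex {sex} has fewer than 2 rows")
            sd = vals.std(ddof=1)
            if sd == 0:
                raise ValueError(f"zero within-sex variance in column '{col}'")
            z[out[sex_col] == sex] = (vals - vals.mean()) / sd
        out[f"{col}_z"] = z
    return out


def sex_mean_variance_tests(
    table: pd.DataFrame, column: str, sex_col: str = "sex"
) -> tuple[TestResult, TestResult]:
    """Pooled-variance t-test of sex means and two-tailed variance-ratio F-test."""
    groups = {sex: g[column].to_numpy(dtype=float) for sex, g in table.groupby(sex_col)}
    if len(groups) != 2:
        raise ValueError("table must contain exactly two sexes")
    (s1, x1), (s2, x2) = sorted(groups.items())
    if len(x1) < 2 or len(x2) < 2:
        raise ValueError("each sex needs at least 2 rows")

    t_stat, t_p = stats.ttest_ind(x1, x2, equal_var=True)
    df_t = len(x1) + len(x2) - 2
    t_res = TestResult(
        name=f"t({column})", statistic=float(t_stat), df=df_t, p_value=float(t_p),
        direction=f"{s1}>{s2}" if t_stat > 0 else f"{s2}>{s1}",
    )

    v1, v2 = x1.var(ddof=1), x2.var(ddof=1)
    if v1 >= v2:
        f_stat, dfn, dfd, larger = v1 / v2, len(x1) - 1, len(x2) - 1, s1
    else:
        f_stat, dfn, dfd, larger = v2 / v1, len(x2) - 1, len(x1) - 1, s2
    f_p = min(1.0, 2.0 * stats.f.sf(f_stat, dfn, dfd))
    f_res = TestResult(
        name=f"F({column})", statistic=float(f_stat), df=(dfn, dfd),
        p_value=float(f_p), direction=f"var {larger} larger",
    )
    return t_res, f_res


def pearson_matrix(
    table: pd.DataFrame, columns: Sequence[str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson r with two-sided p from the t transform (n-2 df)."""
    n = len(table)
    if n < 3:
        raise ValueError("need at least 3 rows")
    cols = list(columns)
    for col in cols:
        if table[col].std(ddof=1) == 0:
            raise ValueError(f"constant column '{col}': correlation undefined")
    r = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    p = pd.DataFrame(np.zeros((len(cols), len(cols))), index=cols, columns=cols)
    for i, a in enumerate(cols):
        for j in range(i + 1, len(cols)):
            b = cols[j]
            rr, pp = stats.pearsonr(table[a], table[b])
            r.loc[a, b] = r.loc[b, a] = rr
            p.loc[a, b] = p.loc[b, a] = pp
    return r, p


# ---------------------------------------------------------------------------
# design-matrix machinery for the GLMs
# ---------------------------------------------------------------------------

def _categorical_codes(values: pd.Series) -> np.ndarray:
    """Sum-to-zero (deviation) contrast columns for a categorical variable.

    Deviation coding keeps main-effect tests meaningful in the presence of
    their interactions (type-III convention).
    """
    codes, uniques = pd.factorize(values, sort=True)
    k = len(uniques)
    if k < 2:
        return np.zeros((len(values), 0))
    out = np.zeros((len(values), k - 1))
    for level in range(1, k):
        out[:, level - 1] = (codes == level).astype(float)
        out[codes == 0, level - 1] = -1.0
    return out


def _term_block(table: pd.DataFrame, term: str, categorical: set[str]) -> np.ndarray:
    """Columns of the design matrix contributed by one model term."""
    parts = term.split(":")
    blocks = []
    for part in parts:
        if part in categorical:
            block = _categorical_codes(table[part])
            if block.shape[1] == 0:
                raise ValueError(f"categorical term '{part}' has a single level")
        else:
            block = table[part].to_numpy(dtype=float).reshape(-1, 1)
        blocks.append(block)
    out = blocks[0]
    for block in blocks[1:]:
        out = np.einsum("ij,ik->ijk", out, block).reshape(len(table), -1)
    return out


def _fit_ols(y: np.ndarray, blocks: list[np.ndarray]) -> sm.regression.linear_model.RegressionResults:
    X = np.hstack([np.ones((len(y), 1))] + blocks) if blocks else np.ones((len(y), 1))
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design: aliased terms present")
    return sm.OLS(y, X).fit()


def _partial_f(
    table: pd.DataFrame,
    y: np.ndarray,
    terms: list[str],
    target: str,
    categorical: set[str],
) -> tuple[float, tuple[int, int], float]:
    """Type-III-style partial F for ``target`` given the other ``terms``."""
    blocks_full = [_term_block(table, t, categorical) for t in terms]
    full = _fit_ols(y, blocks_full)
    reduced_terms = [t for t in terms if t != target]
    blocks_red = [_term_block(table, t, categorical) for t in reduced_terms]
    reduced = _fit_ols(y, blocks_red)
    df1 = int(full.df_model - reduced.df_model)
    df2 = int(full.df_resid)
    if df1 <= 0 or df2 <= 0:
        return np.nan, (df1, df2), np.nan
    num = (reduced.ssr - full.ssr) / df1
    den = full.ssr / df2
    if den == 0:
        return np.inf, (df1, df2), 0.0
    f = num / den
    return float(f), (df1, df2), float(stats.f.sf(f, df1, df2))


def _mains_of(term: str) -> set[str]:
    return set(term.split(":"))


def _removable(terms: list[str]) -> list[str]:
    """Terms droppable under marginality: no retained interaction contains them."""
    out = []
    for t in terms:
        if ":" in t:
            out.append(t)
            continue
        in_interaction = any(t in _mains_of(u) and u != t for u in terms if ":" in u)
        if not in_interaction:
            out.append(t)
    return out


def glm_backward_reintroduce(
    table: pd.DataFrame,
    response: str,
    terms: Sequence[str],
    alpha: float = 0.05,
    categorical: Sequence[str] = ("sex", "year"),
) -> pd.DataFrame:
    """Backward stepwise model simplification with single-term reintroduction.

    Starting from the full model, the least-significant removable term with
    p > ``alpha`` is dropped (interactions before their main effects, main
    effects kept while an interaction involving them remains) until no term
    can be removed.  Each dropped term is then reintroduced alone into the
    final model to report its F, df and p; retained terms report their
    partial F in the final model.

    Returns a tidy DataFrame with columns term, F, df1, df2, p, retained.
    """
    terms = list(terms)
    cat = {c for c in categorical if c in set().union(*map(_mains_of, terms)) or c in terms}
    y = table[response].to_numpy(dtype=float)

    current = list(terms)
    dropped: list[str] = []
    while current:
        candidates = _removable(current)
        worst, worst_p = None, -np.inf
        for t in candidates:
            _, _, p = _partial_f(table, y, current, t, cat)
            if np.isnan(p):
                continue
            if p > worst_p:
                worst, worst_p = t, p
        if worst is None or worst_p <= alpha:
            break
        current.remove(worst)
        dropped.append(worst)

    records = []
    for t in current:
        f, df, p = _partial_f(table, y, current, t, cat)
        records.append({"term": t, "F": f, "df1": df[0], "df2": df[1], "p": p,
                        "retained": True})
    for t in dropped:
        f, df, p = _partial_f(table, y, current + [t], t, cat)
        records.append({"term": t, "F": f, "df1": df[0], "df2": df[1], "p": p,
                        "retained": False})
    out = pd.DataFrame.from_records(records)
    order = {t: i for i, t in enumerate(terms)}
    return out.sort_values("term", key=lambda s: s.map(order)).reset_index(drop=True)


# ---------------------------------------------------------------------------
# varimax orthogonalization
# ---------------------------------------------------------------------------

def _varimax_rotation(L: np.ndarray, max_iter: int = 500, tol: float = 1e-12) -> np.ndarray:
    """Orthogonal rotation maximizing the varimax simplicity criterion."""
    p, k = L.shape
    R = np.eye(k)
    d = 0.0
    for _ in range(max_iter):
        Lr = L @ R
        u, s, vt = np.linalg.svd(
            L.T @ (Lr**3 - Lr @ np.diag(np.sum(Lr**2, axis=0)) / p)
        )
        R = u @ vt
        d_new = float(np.sum(s))
        if d_new < d * (1.0 + tol):
            break
        d = d_new
    return R


def varimax_orthogonalize(
    table: pd.DataFrame, columns: Sequence[str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Decorrelate predictors with varimax-rotated principal components.

    All principal components of the correlation matrix are retained; the
    orthonormal eigenvector matrix is varimax-rotated, and scores are
    computed from the whitened component scores so they are exactly
    mutually uncorrelated (any orthogonal rotation of whitened scores
    preserves the identity covariance).

    Returns (scores, loadings): scores has one column RC1..RCk per rotated
    component; loadings is the orthonormal rotated eigenvector matrix with
    the original columns as rows.
    """
    cols = list(columns)
    if len(cols) < 2:
        raise ValueError("need at least 2 columns")
    if len(table) <= len(cols):
        raise ValueError("need more rows than columns")
    X = table[cols].to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = [c for c, s in zip(cols, sd) if s == 0]
        raise ValueError(f"constant columns: {bad}")
    Z = (X - X.mean(axis=0)) / sd
    C = Z.T @ Z / (len(Z) - 1)
    evals, V = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1]
    evals, V = np.clip(evals[order], 1e-12, None), V[:, order]

    T = _varimax_rotation(V)
    loadings = V @ T
    scores = Z @ V @ np.diag(1.0 / np.sqrt(evals)) @ T

    names = [f"RC{i + 1}" for i in range(len(cols))]
    scores_df = pd.DataFrame(scores, index=table.index, columns=names)
    loadings_df = pd.DataFrame(loadings, index=cols, columns=names)
    return scores_df, loadings_df


# ---------------------------------------------------------------------------
# dichromatism and hue-prediction analyses
# ---------------------------------------------------------------------------

def male_residual_dichromatism(
    table: pd.DataFrame,
    response: str,
    predictors: Sequence[str],
    sex_col: str = "sex",
    male_label: str = "M",
) -> tuple[TestResult, pd.Series]:
    """Does nanostructure explain dichromatism?  Male-line residual test.

    The regression of ``response`` on ``predictors`` is fitted on male rows
    only; residuals for every row are computed from the male coefficients
    and compared between the sexes with a pooled t-test.  A non-significant
    result means the predictors account for the sex difference.
    """
    predictors = list(predictors)
    males = table[table[sex_col] == male_label]
    if len(males) < len(predictors) + 2:
        raise ValueError("too few male rows to fit the regression")
    Xm = sm.add_constant(males[predictors].to_numpy(dtype=float))
    fit = sm.OLS(males[response].to_numpy(dtype=float), Xm).fit()
    X_all = sm.add_constant(table[predictors].to_numpy(dtype=float), has_constant="add")
    resid = table[response].to_numpy(dtype=float) - X_all @ fit.params
    resid = pd.Series(resid, index=table.index, name=f"{response}_resid_male_line")

    is_male = (table[sex_col] == male_label).to_numpy()
    rm, rf = resid[is_male], resid[~is_male]
    scale = max(float(np.std(table[response])), 1.0)
    if np.max(np.abs(resid)) < 1e-10 * scale:
        # both sexes exactly on the male line: no dichromatism left
        t_stat, p = 0.0, 1.0
    else:
        t_stat, p = stats.ttest_ind(rm, rf, equal_var=True)
    res = TestResult(
        name=f"residual dichromatism ({response})",
        statistic=float(t_stat), df=len(resid) - 2, p_value=float(p),
        direction="M>F" if t_stat > 0 else "F>M",
    )
    return res, resid


def paired_hue_comparison(
    table: pd.DataFrame,
    measured_col: str = "hue",
    predicted_col: str = "predicted_hue",
    sex_col: str = "sex",
) -> dict:
    """Estimated-versus-measured hue with sex as a between factor.

    Differences d = estimated - measured are the two-level repeated-measures
    contrast; the sex-by-data-type interaction is the two-sample comparison
    of d between sexes (reported as t and F = t^2), and per-sex paired
    t-tests with mean differences serve as post hoc analyses.
    """
    for col in (measured_col, predicted_col):
        if col not in table or table[col].isna().any():
            raise ValueError(f"missing values in '{col}'")
    d = table[predicted_col].to_numpy(dtype=float) - table[measured_col].to_numpy(dtype=float)
    sexes = sorted(table[sex_col].unique())
    if len(sexes) != 2:
        raise ValueError("both sexes must be represented")

    groups = {s: d[(table[sex_col] == s).to_numpy()] for s in sexes}
    t_stat, p = stats.ttest_ind(groups[sexes[0]], groups[sexes[1]], equal_var=True)
    n = len(d)
    interaction = TestResult(
        name="sex x data-type interaction",
        statistic=float(t_stat**2), df=(1, n - 2), p_value=float(p),
        direction=f"{sexes[0]} diff larger" if t_stat > 0 else f"{sexes[1]} diff larger",
    )

    per_sex: dict[str, TestResult] = {}
    mean_diff: dict[str, float] = {}
    for s in sexes:
        ds = groups[s]
        mean_diff[s] = float(np.mean(ds))
        if np.allclose(ds, ds[0]) and ds.std(ddof=1) == 0:
            stat, pp = (0.0, 1.0) if ds[0] == 0 else (np.inf, 0.0)
        else:
            stat, pp = stats.ttest_1samp(ds, 0.0)
        per_sex[s] = TestResult(
            name=f"paired t ({s})", statistic=float(stat), df=len(ds) - 1,
            p_value=float(pp),
            direction="overestimate" if mean_diff[s] > 0 else "underestimate",
        )
    return {"interaction": interaction, "per_sex": per_sex, "mean_difference": mean_diff}


def repeatability(
    round1: pd.DataFrame,
    round2: pd.DataFrame,
    parameters: Sequence[str],
    id_col: str = "sample",
    sex_col: str = "sex",
) -> pd.DataFrame:
    """Between-round repeatability of sex-standardized parameters.

    Rounds are matched on ``id_col``; each parameter is sex-standardized
    within each round and correlated across rounds (Pearson r).  The sex
    difference in repeatability is the sex-by-round-1 interaction in a
    linear model predicting the round-2 value; because that pooled-variance
    slope test loses power when the residual spread differs strongly
    between sexes, per-sex correlations and their Fisher-z comparison are
    reported alongside it.

    Returns a DataFrame with columns parameter, r, p_r, r_by_sex (dict),
    F_interaction, df1, df2, p_interaction, z_fisher, p_fisher.
    """
    merged = round1.merge(round2, on=id_col, suffixes=("_r1", "_r2"))
    if merged.empty:
        raise ValueError("no overlapping sample ids between rounds")
    sex = merged[f"{sex_col}_r1"] if f"{sex_col}_r1" in merged else merged[sex_col]
    records = []
    for param in parameters:
        sub = pd.DataFrame({
            "sex": sex.to_numpy(),
            "v1": merged[f"{param}_r1"].to_numpy(dtype=float),
            "v2": merged[f"{param}_r2"].to_numpy(dtype=float),
        })
        sub = sex_standardize(sub, ["v1", "v2"])
        r, p_r = stats.pearsonr(sub["v1_z"], sub["v2_z"])
        tab = glm_backward_reintroduce(
            sub, "v2_z", ["v1_z", "sex", "v1_z:sex"], alpha=1.0
        )
        row = tab[tab["term"] == "v1_z:sex"].iloc[0]

        r_by_sex: dict[str, float] = {}
        zs, ns = [], []
        for s, grp in sub.groupby("sex"):
            rs = float(stats.pearsonr(grp["v1_z"], grp["v2_z"])[0])
            r_by_sex[s] = rs
            zs.append(np.arctanh(np.clip(rs, -1 + 1e-12, 1 - 1e-12)))
            ns.append(len(grp))
        if len(zs) == 2 and min(ns) > 3:
            z_fisher = float((zs[0] - zs[1]) / np.sqrt(1 / (ns[0] - 3) + 1 / (ns[1] - 3)))
            p_fisher = float(2 * stats.norm.sf(abs(z_fisher)))
        else:
            z_fisher, p_fisher = np.nan, np.nan
        records.append({
            "parameter": param, "r": float(r), "p_r": float(p_r),
            "r_by_sex": r_by_sex,
            "F_interaction": float(row["F"]), "df1": int(row["df1"]),
            "df2": int(row["df2"]), "p_interaction": float(row["p"]),
            "z_fisher": z_fisher, "p_fisher": p_fisher,
        })
    return pd.DataFrame.from_records(records)
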
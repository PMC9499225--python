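"""Covariate-adjusted comparative statistics for eye morphometry.

This module implements, from their defining formulas, the battery used to
compare eye traits across species while controlling for body size:

* MANCOVA / ANCOVA with type-III tests, Wilks' lambda (Rao's F
  approximation) and Pillai's trace, and estimated marginal means (EMMs)
  evaluated at a fixed covariate value (by default the grand mean of the
  included observations);
* LSD (unadjusted pairwise t) post-hoc comparisons with compact letter
  displays, and Tukey(-Kramer) HSD via the studentized range;
* assumption checks: Box's M (chi-square approximation, conventionally
  judged at alpha = 0.001), Levene's test (absolute deviations from group
  means), and the homogeneity-of-regression-slopes test (multivariate test
  of the group x covariate interaction);
* one-way repeated-measures ANOVA with Mauchly's sphericity test and a
  multivariate (Wilks) test on difference scores;
* Fisher's exact test for general r x c tables by full enumeration.

Wilks' lambda is judged against Pillai's trace automatically when Box's M
rejects at 0.001 (the criterion-selection policy used with heteroscedastic
covariance matrices); both criteria are always reported.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .model import (
    ContingencyTable,
    EstimabilityError,
    ResourceError,
    ValidationError,
)

__all__ = [
    "TermTest",
    "MultivariateTest",
    "MultivariateFitResult",
    "PosthocResult",
    "SphericityResult",
    "AssumptionResult",
    "fit_mancova",
    "estimated_marginal_means",
    "lsd_letters",
    "letters_from_pmatrix",
    "fisher_exact_rxc",
    "ancova",
    "two_way_ancova",
    "box_m",
    "levene",
    "rm_anova",
    "one_way_anova",
    "tukey_hsd",
    "pooled_t_test",
]

logger = logging.getLogger(__name__)

#: conventional significance level for judging Box's M
BOX_M_ALPHA = 0.001


# ---------------------------------------------------------------------------
# result containers


@dataclass
class TermTest:
    """Univariate F test of one model term."""

    F: float
    df_num: float
    df_den: float
    p: float
    ss: float = math.nan
    degenerate: bool = False  # zero-residual fit; p forced to 0


@dataclass
class MultivariateTest:
    """One multivariate criterion with its F approximation."""

    statistic: float
    criterion: str  # "wilks" | "pillai"
    F: float
    df_num: float
    df_den: float
    p: float


@dataclass
class MultivariateFitResult:
    """MANCOVA output: criteria, per-response tests, EMMs, post hoc."""

    responses: Sequence[str]
    group_levels: Sequence[str]
    wilks: MultivariateTest
    pillai: MultivariateTest
    covariate_wilks: MultivariateTest | None
    covariate_pillai: MultivariateTest | None
    per_response: Mapping[str, TermTest]
    covariate_per_response: Mapping[str, TermTest]
    emm_table: pd.DataFrame
    evaluation_point: float | None
    df_resid: int
    posthoc: Mapping[str, "PosthocResult"] = field(default_factory=dict)
    preferred_criterion: str = "wilks"
    # internal handles for EMM re-evaluation
    _fit: object = field(default=None, repr=False, compare=False)
    _cov_col: int | None = field(default=None, repr=False, compare=False)

    @property
    def wilks_lambda(self) -> float:
        return self.wilks.statistic

    @property
    def pillai_trace(self) -> float:
        return self.pillai.statistic


@dataclass
class PosthocResult:
    """Pairwise p-values plus a compact letter display.

    Letters follow descending means ('a' marks the largest); groups sharing
    a letter are not significantly different at ``alpha``.
    """

    groups: Sequence[str]
    means: np.ndarray
    p_matrix: np.ndarray
    letters: Mapping[str, str]
    alpha: float

    def __post_init__(self) -> None:
        # self-consistency: sharing a letter implies non-significance and
        # every non-significant pair shares a letter
        k = len(self.groups)
        for i, j in itertools.combinations(range(k), 2):
            share = set(self.letters[self.groups[i]]) & set(self.letters[self.groups[j]])
            sig = self.p_matrix[i, j] < self.alpha
            if share and sig:
                raise AssertionError("letter display contradicts p matrix")
            if not share and not sig:
                raise AssertionError("non-significant pair shares no letter")


@dataclass
class SphericityResult:
    """Repeated-measures ANOVA output with Mauchly's sphericity test."""

    n_subjects: int
    n_levels: int
    mauchly_W: float
    chi_square: float
    df: int
    p: float
    within_F: float
    within_df: tuple
    within_p: float
    multivariate_wilks: float
    multivariate_F: float
    multivariate_df: tuple
    multivariate_p: float
    level_means: pd.Series
    posthoc: PosthocResult | None = None
    degenerate: bool = False


@dataclass
class AssumptionResult:
    """Box's M, Levene per response, and homogeneity of slopes."""

    box_M: float
    box_chi2: float
    box_df: int
    box_p: float
    levene: Mapping[str, TermTest]
    slopes_wilks: MultivariateTest | None
    recommended_criterion: str  # "pillai" if Box's M rejects at 0.001


# ---------------------------------------------------------------------------
# linear-model core


class _LinearFit:
    """Multiresponse least squares with block hypothesis tests."""

    def __init__(self, X: np.ndarray, Y: np.ndarray, colnames: Sequence[str]):
        self.X = X
        self.Y = Y
        self.colnames = list(colnames)
        n, q = X.shape
        rank = np.linalg.matrix_rank(X)
        if rank < q:
            raise EstimabilityError(
                "design matrix is rank deficient (empty cell or a group with "
                "too few observations for the requested terms)"
            )
        self.B, *_ = np.linalg.lstsq(X, Y, rcond=None)
        resid = Y - X @ self.B
        self.E = resid.T @ resid
        self.df_resid = n - rank
        self.XtX_inv = np.linalg.inv(X.T @ X)

    def sigma2(self) -> np.ndarray:
        return np.diag(self.E) / self.df_resid

    def block_H(self, cols: Sequence[int]) -> np.ndarray:
        """Hypothesis SSCP for H0: B[cols] = 0 (type III for this block)."""
        Bh = self.B[np.asarray(cols)]
        M = self.XtX_inv[np.ix_(cols, cols)]
        return Bh.T @ np.linalg.solve(M, Bh)

    def predict_row(self, x: np.ndarray) -> np.ndarray:
        return x @ self.B

    def row_variance_factor(self, x: np.ndarray) -> float:
        return float(x @ self.XtX_inv @ x)


def _wilks_F(lmbda: float, p: int, q: int, df_e: int) -> MultivariateTest:
    """Rao's F approximation for Wilks' lambda.

    p responses, q hypothesis df, df_e error df.
    """
    pq = p * q
    if p**2 + q**2 - 5 > 0:
        t = math.sqrt((p**2 * q**2 - 4) / (p**2 + q**2 - 5))
    else:
        t = 1.0
    w = df_e + q - (p + q + 1) / 2.0
    df2 = w * t - (pq - 2) / 2.0
    lam_t = lmbda ** (1.0 / t) if lmbda > 0 else 0.0
    if lam_t == 0.0:
        F = math.inf
        pval = 0.0
    else:
        F = (1.0 - lam_t) / lam_t * df2 / pq
        pval = float(sps.f.sf(F, pq, df2))
    return MultivariateTest(lmbda, "wilks", F, pq, df2, pval)


def _pillai_F(V: float, p: int, q: int, df_e: int) -> MultivariateTest:
    s = min(p, q)
    m = (abs(p - q) - 1) / 2.0
    nn = (df_e - p - 1) / 2.0
    df1 = s * (2 * m + s + 1)
    df2 = s * (2 * nn + s + 1)
    denom = s - V
    if denom <= 0:
        F = math.inf
        pval = 0.0
    else:
        F = (2 * nn + s + 1) / (2 * m + s + 1) * V / denom
        pval = float(sps.f.sf(F, df1, df2))
    return MultivariateTest(V, "pillai", F, df1, df2, pval)


def _mv_tests(H: np.ndarray, E: np.ndarray, q: int, df_e: int):
    """Wilks and Pillai tests from hypothesis/error SSCP matrices."""
    p = H.shape[0]
    HE = H + E
    sign_e, logdet_e = np.linalg.slogdet(E)
    sign_he, logdet_he = np.linalg.slogdet(HE)
    if sign_e <= 0 or sign_he <= 0:
        lmbda = 0.0
    else:
        lmbda = float(np.exp(logdet_e - logdet_he))
    lmbda = min(lmbda, 1.0)
    V = float(np.trace(H @ np.linalg.pinv(HE)))
    V = min(max(V, 0.0), float(min(p, q)))
    return _wilks_F(lmbda, p, q, df_e), _pillai_F(V, p, q, df_e)


def _dummies(values: pd.Series):
    levels = sorted(pd.unique(values.astype(str)))
    codes = pd.Categorical(values.astype(str), categories=levels).codes
    return np.asarray(codes), levels


def _treatment_block(codes: np.ndarray, n_levels: int) -> np.ndarray:
    """Reference (first-level) coded dummies, n x (k-1)."""
    out = np.zeros((len(codes), n_levels - 1))
    for j in range(1, n_levels):
        out[codes == j, j - 1] = 1.0
    return out


def _sum_block(codes: np.ndarray, n_levels: int) -> np.ndarray:
    """Sum-to-zero coded dummies, n x (k-1) (last level = -1)."""
    out = np.zeros((len(codes), n_levels - 1))
    for j in range(n_levels - 1):
        out[codes == j, j] = 1.0
    out[codes == n_levels - 1, :] = -1.0
    return out


# ---------------------------------------------------------------------------
# MANCOVA / ANCOVA


def _prepare(data: pd.DataFrame, responses, group_factor, covariate):
    cols = list(responses) + [group_factor] + ([covariate] if covariate else [])
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise ValidationError(f"columns not in data: {missing}")
    df = data.dropna(subset=cols).reset_index(drop=True)
    codes, levels = _dummies(df[group_factor])
    if len(levels) < 2:
        raise ValidationError("need at least 2 groups")
    return df, codes, levels


def fit_mancova(
    data: pd.DataFrame,
    responses: Sequence[str],
    group_factor: str,
    covariate: str | None = None,
    emm_at: float | None = None,
    alpha: float = 0.05,
    transform: Mapping[str, str] | None = None,
) -> MultivariateFitResult:
    """Multivariate analysis of covariance with EMMs and LSD letters.

    Fits ``responses ~ group + covariate`` (common slope), reports Wilks'
    lambda and Pillai's trace with their F approximations for the group and
    covariate effects, type-III per-response F tests, EMMs at ``emm_at``
    (default: grand mean of the covariate), and per-response LSD letter
    displays at ``alpha``.

    ``transform`` optionally maps a response name to ``"log"`` or ``"sqrt"``;
    transformations are applied explicitly, never silently.
    """
    responses = list(responses)
    df, codes, levels = _prepare(data, responses, group_factor, covariate)
    if transform:
        df = df.copy()
        for col, how in transform.items():
            if how == "log":
                df[col] = np.log(df[col])
            elif how == "sqrt":
                df[col] = np.sqrt(df[col])
            else:
                raise ValidationError(f"unknown transform {how!r} for {col}")
    n, k, p = len(df), len(levels), len(responses)
    if n <= k + p + 1:
        raise ValidationError(
            f"need n > groups + responses + 1 (= {k + p + 1}), got n = {n}"
        )
    Y = df[responses].to_numpy(dtype=float)
    blocks = {"intercept": [0]}
    X_parts = [np.ones((n, 1))]
    group_cols = list(range(1, k))
    X_parts.append(_treatment_block(codes, k))
    blocks["group"] = group_cols
    names = ["intercept"] + [f"{group_factor}[{lv}]" for lv in levels[1:]]
    cov_col = None
    if covariate:
        x = df[covariate].to_numpy(dtype=float)
        cov_col = k
        X_parts.append(x[:, None])
        blocks["covariate"] = [cov_col]
        names.append(covariate)
    X = np.hstack(X_parts)
    fit = _LinearFit(X, Y, names)

    q_group = k - 1
    Hg = fit.block_H(group_cols)
    wilks, pillai = _mv_tests(Hg, fit.E, q_group, fit.df_resid)
    cov_wilks = cov_pillai = None
    cov_uni: dict = {}
    if covariate:
        Hc = fit.block_H([cov_col])
        cov_wilks, cov_pillai = _mv_tests(Hc, fit.E, 1, fit.df_resid)

    sigma2 = fit.sigma2()
    per_resp = {}
    for j, resp in enumerate(responses):
        per_resp[resp] = _uni_term(Hg[j, j], q_group, fit.E[j, j], fit.df_resid)
        if covariate:
            Hc = fit.block_H([cov_col])
            cov_uni[resp] = _uni_term(Hc[j, j], 1, fit.E[j, j], fit.df_resid)

    at = emm_at
    if covariate and at is None:
        at = float(df[covariate].mean())
    emm_tab, rows_x = _emm_table(fit, levels, responses, k, cov_col, at)

    posthoc = {}
    for j, resp in enumerate(responses):
        pm, means = _pairwise_lsd(fit, rows_x, j, sigma2[j])
        posthoc[resp] = PosthocResult(
            groups=levels,
            means=means,
            p_matrix=pm,
            letters=letters_from_pmatrix(levels, means, pm, alpha),
            alpha=alpha,
        )

    preferred = "wilks"
    return MultivariateFitResult(
        responses=responses,
        group_levels=levels,
        wilks=wilks,
        pillai=pillai,
        covariate_wilks=cov_wilks,
        covariate_pillai=cov_pillai,
        per_response=per_resp,
        covariate_per_response=cov_uni,
        emm_table=emm_tab,
        evaluation_point=at,
        df_resid=fit.df_resid,
        posthoc=posthoc,
        preferred_criterion=preferred,
        _fit=fit,
        _cov_col=cov_col,
    )


def _uni_term(ss_h: float, df_h: int, ss_e: float, df_e: int) -> TermTest:
    # a residual SS at rounding-noise level relative to the hypothesis SS is
    # a perfect fit: infinite F, flagged, p forced to 0
    if df_e <= 0 or ss_e <= 1e-10 * max(abs(ss_h), 1.0):
        return TermTest(math.inf, df_h, df_e, 0.0, ss=ss_h, degenerate=True)
    F = (ss_h / df_h) / (ss_e / df_e)
    return TermTest(float(F), df_h, df_e, float(sps.f.sf(F, df_h, df_e)), ss=float(ss_h))


def _emm_table(fit, levels, responses, k, cov_col, at):
    rows_x = []
    records = []
    ncol = fit.X.shape[1]
    sigma2 = fit.sigma2()
    for g, lv in enumerate(levels):
        x = np.zeros(ncol)
        x[0] = 1.0
        if g >= 1:
            x[g] = 1.0  # treatment dummy columns are 1..k-1
        if cov_col is not None:
            x[cov_col] = at
        rows_x.append(x)
        pred = fit.predict_row(x)
        vf = fit.row_variance_factor(x)
        for j, resp in enumerate(responses):
            records.append(
                {
                    "group": lv,
                    "response": resp,
                    "emm": float(pred[j]),
                    "se": float(math.sqrt(max(sigma2[j] * vf, 0.0))),
                }
            )
    return pd.DataFrame(records), rows_x


def _pairwise_lsd(fit, rows_x, resp_idx, sigma2_j):
    k = len(rows_x)
    means = np.array([fit.predict_row(x)[resp_idx] for x in rows_x])
    pm = np.ones((k, k))
    for i, j in itertools.combinations(range(k), 2):
        c = rows_x[i] - rows_x[j]
        var = sigma2_j * float(c @ fit.XtX_inv @ c)
        if var <= 0:
            p = 0.0 if means[i] != means[j] else 1.0
        else:
            t = (means[i] - means[j]) / math.sqrt(var)
            p = float(2.0 * sps.t.sf(abs(t), fit.df_resid))
        pm[i, j] = pm[j, i] = p
    return pm, means


def estimated_marginal_means(
    fit: MultivariateFitResult, at_covariate: float | None = None
) -> pd.DataFrame:
    """EMM table of a fitted MANCOVA, optionally re-evaluated elsewhere.

    Re-evaluation shifts each EMM by ``b_j (at - at_fit)`` using the fitted
    common slope; a point far outside the fitted one triggers a warning.
    """
    if at_covariate is None or fit.evaluation_point is None:
        return fit.emm_table.copy()
    lin: _LinearFit = fit._fit
    cov_col = fit._cov_col
    cov_vals = lin.X[:, cov_col]
    lo, hi = cov_vals.min(), cov_vals.max()
    if not (lo <= at_covariate <= hi):
        logger.warning(
            "EMM evaluation point %s outside observed covariate range [%g, %g]",
            at_covariate,
            lo,
            hi,
        )
    k = len(fit.group_levels)
    sigma2 = lin.sigma2()
    records = []
    for g, lv in enumerate(fit.group_levels):
        x = np.zeros(lin.X.shape[1])
        x[0] = 1.0
        if g >= 1:
            x[g] = 1.0
        x[cov_col] = at_covariate
        pred = lin.predict_row(x)
        vf = lin.row_variance_factor(x)
        for j, resp in enumerate(fit.responses):
            records.append(
                {
                    "group": lv,
                    "response": resp,
                    "emm": float(pred[j]),
                    "se": float(math.sqrt(max(sigma2[j] * vf, 0.0))),
                }
            )
    return pd.DataFrame(records)


def emm_contrast(
    fit: MultivariateFitResult, group_1: str, group_2: str, response: str
) -> tuple:
    """EMM difference ``group_1 - group_2`` and its standard error.

    The SE accounts for the covariance between EMMs induced by the shared
    intercept and slope (it is the proper contrast SE, not
    ``sqrt(se1^2 + se2^2)``).
    """
    lin: _LinearFit = fit._fit
    levels = list(fit.group_levels)
    j = list(fit.responses).index(response)
    ncol = lin.X.shape[1]

    def row(lv):
        g = levels.index(lv)
        x = np.zeros(ncol)
        x[0] = 1.0
        if g >= 1:
            x[g] = 1.0
        if fit._cov_col is not None:
            x[fit._cov_col] = fit.evaluation_point
        return x

    c = row(group_1) - row(group_2)
    diff = float((c @ lin.B)[j])
    se = math.sqrt(max(lin.sigma2()[j] * float(c @ lin.XtX_inv @ c), 0.0))
    return diff, se


# ---------------------------------------------------------------------------
# compact letter displays


def letters_from_pmatrix(
    groups: Sequence[str], means: np.ndarray, p_matrix: np.ndarray, alpha: float
) -> dict:
    """Insert-and-absorb compact letter display.

    Letters are assigned in descending order of the group means, so 'a'
    always marks (a set containing) the largest mean.  Non-transitive
    significance patterns are handled by the standard column-splitting
    sweep; the result is validated against the p matrix by the caller.
    """
    k = len(groups)
    order = np.argsort(-np.asarray(means, dtype=float), kind="stable")
    columns = [set(range(k))]
    for i, j in itertools.combinations(range(k), 2):
        if p_matrix[i, j] >= alpha:
            continue
        new_cols = []
        for col in columns:
            if i in col and j in col:
                new_cols.append(col - {i})
                new_cols.append(col - {j})
            else:
                new_cols.append(col)
        # absorb subsets
        columns = []
        for col in new_cols:
            if any(col < other for other in new_cols) or col in columns:
                continue
            columns.append(col)
    # order columns by the best (largest-mean) group they contain
    rank = {g: r for r, g in enumerate(order)}
    columns.sort(key=lambda col: min(rank[g] for g in col))
    letters = {g: "" for g in groups}
    for letter_idx, col in enumerate(columns):
        ch = chr(ord("a") + letter_idx)
        for g in sorted(col, key=lambda g: rank[g]):
            letters[groups[g]] += ch
    return {g: "".join(sorted(s)) for g, s in letters.items()}


def lsd_letters(
    emms: Sequence[float],
    ses: Sequence[float],
    df: int,
    alpha: float = 0.05,
    groups: Sequence[str] | None = None,
) -> PosthocResult:
    """LSD letters from EMMs and their standard errors.

    Pairwise t = (e_i - e_j) / sqrt(se_i^2 + se_j^2) on ``df`` error df
    (EMM covariances are ignored here; use :func:`fit_mancova` for exact
    pairwise contrasts within a fitted model).
    """
    emms = np.asarray(emms, dtype=float)
    ses = np.asarray(ses, dtype=float)
    if len(emms) < 2:
        raise ValidationError("need at least 2 groups")
    if groups is None:
        groups = [f"g{i}" for i in range(len(emms))]
    k = len(emms)
    pm = np.ones((k, k))
    for i, j in itertools.combinations(range(k), 2):
        se = math.sqrt(ses[i] ** 2 + ses[j] ** 2)
        if se == 0:
            p = 1.0 if emms[i] == emms[j] else 0.0
        else:
            p = float(2.0 * sps.t.sf(abs(emms[i] - emms[j]) / se, df))
        pm[i, j] = pm[j, i] = p
    return PosthocResult(
        groups=list(groups),
        means=emms,
        p_matrix=pm,
        letters=letters_from_pmatrix(list(groups), emms, pm, alpha),
        alpha=alpha,
    )


# ---------------------------------------------------------------------------
# Fisher's exact test, r x c, full enumeration


def fisher_exact_rxc(table, guard: int = 10_000_000) -> float:
    """Exact two-sided p for an r x c table by full enumeration.

    Enumerates every nonnegative integer table with the observed margins and
    sums the probabilities (multivariate hypergeometric under fixed margins)
    of all tables no more probable than the observed one -- the conventional
    exact two-sided definition.  Raises :class:`ResourceError` if more than
    ``guard`` tables would be visited.
    """
    if isinstance(table, ContingencyTable):
        counts = table.counts
    else:
        counts = np.asarray(table, dtype=int)
        if counts.ndim != 2 or np.any(counts < 0):
            raise ValidationError("table must be a 2D nonnegative integer array")
    rows = counts.sum(axis=1)
    cols = counts.sum(axis=0)
    N = int(counts.sum())
    if N == 0:
        raise ValidationError("empty table")
    lg = math.lgamma
    const = sum(lg(r + 1) for r in rows) + sum(lg(c + 1) for c in cols) - lg(N + 1)

    def logprob(cells) -> float:
        return const - sum(lg(x + 1) for x in cells)

    lp_obs = logprob(counts.ravel())
    tol = 1e-7  # relative tolerance on probability ties
    r, c = counts.shape
    visited = 0
    total_p = 0.0

    def recurse(row_idx: int, col_rem, acc_cells, acc_lp_rows):
        nonlocal visited, total_p
        if row_idx == r - 1:
            # last row forced by column remainders
            cells = list(col_rem)
            visited += 1
            if visited > guard:
                raise ResourceError(
                    f"more than {guard} tables; consider a Monte-Carlo test"
                )
            lp = logprob(acc_cells + cells)
            if lp <= lp_obs + tol:
                total_p += math.exp(lp)
            return
        target = int(rows[row_idx])

        def fill(col_idx: int, remaining: int, row_cells):
            if col_idx == c - 1:
                if remaining <= col_rem[col_idx]:
                    new_rem = list(col_rem)
                    cells_full = row_cells + [remaining]
                    for jj, v in enumerate(cells_full):
                        new_rem[jj] = col_rem[jj] - v
                    recurse(row_idx + 1, new_rem, acc_cells + cells_full, None)
                return
            for v in range(min(remaining, col_rem[col_idx]) + 1):
                fill(col_idx + 1, remaining - v, row_cells + [v])

        fill(0, target, [])

    recurse(0, list(cols), [], None)
    return float(min(total_p, 1.0))


# ---------------------------------------------------------------------------
# univariate ANCOVA variants


def ancova(
    data: pd.DataFrame,
    dep: str,
    group_factor: str,
    covariate: str,
    test_slopes: bool = False,
    emm_at: float | None = None,
    alpha: float = 0.05,
) -> dict:
    """Univariate ANCOVA: type-III F for group, covariate and (optionally)
    the group x covariate interaction (homogeneity-of-slopes test).

    Returns ``{"group", "covariate", "interaction", "emm", "posthoc",
    "df_resid"}``; the interaction entry is None unless ``test_slopes``.
    """
    df, codes, levels = _prepare(data, [dep], group_factor, covariate)
    n, k = len(df), len(levels)
    y = df[dep].to_numpy(dtype=float)[:, None]
    x = df[covariate].to_numpy(dtype=float)
    G = _treatment_block(codes, k)
    X = np.hstack([np.ones((n, 1)), G, x[:, None]])
    names = ["intercept"] + [f"g{i}" for i in range(1, k)] + [covariate]
    inter = None
    if test_slopes:
        Xi = np.hstack([X, G * x[:, None]])
        fit_i = _LinearFit(Xi, y, names + [f"g{i}:x" for i in range(1, k)])
        cols = list(range(k + 1, Xi.shape[1]))
        H = fit_i.block_H(cols)
        inter = _uni_term(H[0, 0], len(cols), fit_i.E[0, 0], fit_i.df_resid)
    fit = _LinearFit(X, y, names)
    Hg = fit.block_H(list(range(1, k)))
    Hc = fit.block_H([k])
    group_t = _uni_term(Hg[0, 0], k - 1, fit.E[0, 0], fit.df_resid)
    cov_t = _uni_term(Hc[0, 0], 1, fit.E[0, 0], fit.df_resid)
    at = emm_at if emm_at is not None else float(x.mean())
    emm_tab, rows_x = _emm_table(fit, levels, [dep], k, k, at)
    pm, means = _pairwise_lsd(fit, rows_x, 0, fit.sigma2()[0])
    post = PosthocResult(
        groups=levels,
        means=means,
        p_matrix=pm,
        letters=letters_from_pmatrix(levels, means, pm, alpha),
        alpha=alpha,
    )
    return {
        "group": group_t,
        "covariate": cov_t,
        "interaction": inter,
        "emm": emm_tab,
        "posthoc": post,
        "df_resid": fit.df_resid,
        "evaluation_point": at,
    }


def two_way_ancova(
    data: pd.DataFrame,
    dep: str,
    factor_a: str,
    factor_b: str,
    covariate: str | None = None,
    alpha: float = 0.05,
) -> dict:
    """Two-way ANCOVA with interaction, type-III tests, and Tukey HSD.

    Factors are sum-to-zero coded so the type-III main-effect tests are
    well defined in the presence of the interaction.  Every A x B cell must
    be represented; a factor with a single level degrades to a one-way
    ANCOVA on the other factor.
    """
    cols = [dep, factor_a, factor_b] + ([covariate] if covariate else [])
    df = data.dropna(subset=[c for c in cols if c]).reset_index(drop=True)
    ca, la = _dummies(df[factor_a])
    cb, lb = _dummies(df[factor_b])
    if len(la) == 1 or len(lb) == 1:
        keep = factor_a if len(lb) == 1 else factor_b
        if covariate is None:
            raise ValidationError("one-way collapse without covariate: use one_way_anova")
        res = ancova(df, dep, keep, covariate, alpha=alpha)
        res["collapsed_to"] = keep
        return res
    cell_counts = pd.crosstab(df[factor_a], df[factor_b])
    if (cell_counts == 0).any().any() or cell_counts.shape != (len(la), len(lb)):
        raise EstimabilityError(
            "empty A x B cell: interaction not estimable from this design"
        )
    n = len(df)
    y = df[dep].to_numpy(dtype=float)[:, None]
    A = _sum_block(ca, len(la))
    B = _sum_block(cb, len(lb))
    AB = np.column_stack(
        [A[:, i] * B[:, j] for i in range(A.shape[1]) for j in range(B.shape[1])]
    )
    parts = [np.ones((n, 1)), A, B, AB]
    idx_a = list(range(1, 1 + A.shape[1]))
    idx_b = list(range(idx_a[-1] + 1, idx_a[-1] + 1 + B.shape[1]))
    idx_ab = list(range(idx_b[-1] + 1, idx_b[-1] + 1 + AB.shape[1]))
    idx_cov = None
    if covariate:
        parts.append(df[covariate].to_numpy(dtype=float)[:, None])
        idx_cov = idx_ab[-1] + 1
    X = np.hstack(parts)
    fit = _LinearFit(X, y, [f"c{i}" for i in range(X.shape[1])])
    out = {}
    for name, idx in (
        (factor_a, idx_a),
        (factor_b, idx_b),
        (f"{factor_a}:{factor_b}", idx_ab),
    ):
        H = fit.block_H(idx)
        out[name] = _uni_term(H[0, 0], len(idx), fit.E[0, 0], fit.df_resid)
    if idx_cov is not None:
        H = fit.block_H([idx_cov])
        out[covariate] = _uni_term(H[0, 0], 1, fit.E[0, 0], fit.df_resid)
    mse = float(fit.sigma2()[0])
    tukey = {}
    for name, series, levels in ((factor_a, df[factor_a], la), (factor_b, df[factor_b], lb)):
        means = df.groupby(series.astype(str))[dep].mean().reindex(levels)
        ns = df.groupby(series.astype(str))[dep].size().reindex(levels)
        tukey[name] = tukey_hsd(
            means.to_numpy(), mse, fit.df_resid, ns.to_numpy(), alpha, groups=levels
        )
    out.update({"tukey": tukey, "df_resid": fit.df_resid, "mse": mse})
    return out


# ---------------------------------------------------------------------------
# assumption checks


def box_m(data: pd.DataFrame, responses: Sequence[str], group_factor: str) -> dict:
    """Box's M test for equality of group covariance matrices.

    M = (N - k) ln|S_pooled| - sum_g (n_g - 1) ln|S_g| with the standard
    chi-square approximation; judged conventionally at alpha = 0.001.
    """
    responses = list(responses)
    df, codes, levels = _prepare(data, responses, group_factor, None)
    p = len(responses)
    k = len(levels)
    Ss, ns = [], []
    for g, lv in enumerate(levels):
        sub = df.loc[codes == g, responses].to_numpy(dtype=float)
        n_g = len(sub)
        if n_g <= p:
            raise ValidationError(
                f"group {lv!r} has n = {n_g} <= {p} responses; covariance singular"
            )
        S = np.cov(sub, rowvar=False, ddof=1).reshape(p, p)
        sign, _ = np.linalg.slogdet(S)
        if sign <= 0:
            raise ValidationError(f"singular within-group covariance for group {lv!r}")
        Ss.append(S)
        ns.append(n_g)
    N = sum(ns)
    S_pooled = sum((n_g - 1) * S for n_g, S in zip(ns, Ss)) / (N - k)
    _, logdet_pooled = np.linalg.slogdet(S_pooled)
    M = (N - k) * logdet_pooled - sum(
        (n_g - 1) * np.linalg.slogdet(S)[1] for n_g, S in zip(ns, Ss)
    )
    c = (sum(1.0 / (n_g - 1) for n_g in ns) - 1.0 / (N - k)) * (
        2 * p**2 + 3 * p - 1
    ) / (6.0 * (p + 1) * (k - 1))
    chi2 = M * (1 - c)
    dof = p * (p + 1) * (k - 1) // 2
    pval = float(sps.chi2.sf(chi2, dof))
    return {"M": float(M), "chi2": float(chi2), "df": int(dof), "p": pval}


def levene(data: pd.DataFrame, response: str, group_factor: str) -> TermTest:
    """Levene's test with mean centering (ANOVA on |y - group mean|)."""
    df, codes, levels = _prepare(data, [response], group_factor, None)
    groups = [
        df.loc[codes == g, response].to_numpy(dtype=float) for g in range(len(levels))
    ]
    if any(len(g) < 2 for g in groups):
        raise ValidationError("each group needs n >= 2")
    devs = [np.abs(g - g.mean()) for g in groups]
    if all(np.ptp(d) == 0 for d in devs):
        k = len(groups)
        N = sum(len(g) for g in groups)
        return TermTest(0.0, k - 1, N - k, 1.0)
    F, p = sps.levene(*groups, center="mean")
    k = len(groups)
    N = sum(len(g) for g in groups)
    return TermTest(float(F), k - 1, N - k, float(p))


def homogeneity_of_slopes(
    data: pd.DataFrame,
    responses: Sequence[str],
    group_factor: str,
    covariate: str,
) -> MultivariateTest:
    """Multivariate (Wilks) test of the group x covariate interaction."""
    responses = list(responses)
    df, codes, levels = _prepare(data, responses, group_factor, covariate)
    n, k = len(df), len(levels)
    Y = df[responses].to_numpy(dtype=float)
    x = df[covariate].to_numpy(dtype=float)
    G = _treatment_block(codes, k)
    X = np.hstack([np.ones((n, 1)), G, x[:, None], G * x[:, None]])
    fit = _LinearFit(X, Y, [f"c{i}" for i in range(X.shape[1])])
    cols = list(range(k + 1, X.shape[1]))
    H = fit.block_H(cols)
    wilks, _ = _mv_tests(H, fit.E, len(cols), fit.df_resid)
    return wilks


def assumption_checks(
    data: pd.DataFrame,
    responses: Sequence[str],
    group_factor: str,
    covariate: str,
) -> AssumptionResult:
    """Run the full pre-model battery and pick the multivariate criterion.

    Pillai's trace is recommended over Wilks' lambda when Box's M rejects
    at the 0.001 level (logged).
    """
    bm = box_m(data, responses, group_factor)
    lev = {r: levene(data, r, group_factor) for r in responses}
    slopes = homogeneity_of_slopes(data, responses, group_factor, covariate)
    criterion = "wilks"
    if bm["p"] < BOX_M_ALPHA:
        criterion = "pillai"
        logger.info(
            "Box's M p = %.4g < %.3g: recommending Pillai's trace", bm["p"], BOX_M_ALPHA
        )
    return AssumptionResult(
        box_M=bm["M"],
        box_chi2=bm["chi2"],
        box_df=bm["df"],
        box_p=bm["p"],
        levene=lev,
        slopes_wilks=slopes,
        recommended_criterion=criterion,
    )


# ---------------------------------------------------------------------------
# repeated measures


def rm_anova(data, level_names: Sequence[str] | None = None, alpha: float = 0.05) -> SphericityResult:
    """One-way repeated-measures ANOVA across within-subject levels.

    ``data`` is subjects x levels (DataFrame or 2D array; e.g. workers x
    the five eye regions).  Reports Mauchly's W with its chi-square
    approximation (df = k(k-1)/2 - 1), the sphericity-assumed
    within-subjects F (df = k-1, (k-1)(n-1)), the multivariate (Wilks /
    Hotelling) test on difference scores, and LSD pairwise comparisons of
    the level means (paired t tests).  Incomplete rows are dropped listwise
    with a warning.
    """
    if isinstance(data, pd.DataFrame):
        names = list(data.columns) if level_names is None else list(level_names)
        arr = data.to_numpy(dtype=float)
    else:
        arr = np.asarray(data, dtype=float)
        names = (
            list(level_names)
            if level_names is not None
            else [f"level{i}" for i in range(arr.shape[1])]
        )
    if arr.ndim != 2:
        raise ValidationError("data must be subjects x levels")
    complete = ~np.isnan(arr).any(axis=1)
    if not complete.all():
        logger.warning("dropping %d incomplete subjects", int((~complete).sum()))
        arr = arr[complete]
    n, k = arr.shape
    if k < 3:
        raise ValidationError("need at least 3 within-subject levels")
    if n < 3:
        raise ValidationError("need at least 3 complete subjects")

    grand = arr.mean()
    subj_means = arr.mean(axis=1)
    lvl_means = arr.mean(axis=0)
    ss_total = ((arr - grand) ** 2).sum()
    ss_subj = k * ((subj_means - grand) ** 2).sum()
    ss_treat = n * ((lvl_means - grand) ** 2).sum()
    ss_err = ss_total - ss_subj - ss_treat
    df_treat, df_err = k - 1, (k - 1) * (n - 1)
    degenerate = False
    if ss_err <= 1e-300:
        degenerate = True
        F_w = 0.0 if ss_treat <= 1e-300 else math.inf
        p_w = 1.0 if ss_treat <= 1e-300 else 0.0
    else:
        F_w = (ss_treat / df_treat) / (ss_err / df_err)
        p_w = float(sps.f.sf(F_w, df_treat, df_err))

    # Mauchly on orthonormal contrasts
    S = np.cov(arr, rowvar=False, ddof=1)
    C = _orthonormal_contrasts(k)
    T = C @ S @ C.T
    sign, logdet = np.linalg.slogdet(T)
    tr = float(np.trace(T))
    dof_m = k * (k - 1) // 2 - 1
    if sign <= 0 or tr <= 0:
        degenerate = True
        W, chi2, p_m = math.nan, math.nan, math.nan
    else:
        W = float(np.exp(logdet - (k - 1) * math.log(tr / (k - 1))))
        W = min(W, 1.0)
        d = 1.0 - (2 * (k - 1) ** 2 + (k - 1) + 2) / (6.0 * (k - 1) * (n - 1))
        chi2 = -(n - 1) * d * math.log(W) if W > 0 else math.inf
        p_m = float(sps.chi2.sf(chi2, dof_m))

    # multivariate test on difference scores (Hotelling T^2 -> Wilks)
    D = arr[:, 1:] - arr[:, [0]]
    dbar = D.mean(axis=0)
    Sd = np.cov(D, rowvar=False, ddof=1)
    try:
        T2 = n * dbar @ np.linalg.solve(Sd, dbar)
        wilks = 1.0 / (1.0 + T2 / (n - 1))
        F_mv = (n - k + 1) / ((n - 1) * (k - 1)) * T2
        df_mv = (k - 1, n - k + 1)
        p_mv = float(sps.f.sf(F_mv, *df_mv)) if n - k + 1 > 0 else math.nan
    except np.linalg.LinAlgError:
        degenerate = True
        T2 = math.nan
        wilks, F_mv, df_mv, p_mv = math.nan, math.nan, (k - 1, n - k + 1), math.nan

    # LSD pairwise: paired t tests on level pairs
    pm = np.ones((k, k))
    for i, j in itertools.combinations(range(k), 2):
        d = arr[:, i] - arr[:, j]
        sd = d.std(ddof=1)
        if sd == 0:
            p = 1.0 if d.mean() == 0 else 0.0
        else:
            t = d.mean() / (sd / math.sqrt(n))
            p = float(2.0 * sps.t.sf(abs(t), n - 1))
        pm[i, j] = pm[j, i] = p
    post = PosthocResult(
        groups=names,
        means=lvl_means,
        p_matrix=pm,
        letters=letters_from_pmatrix(names, lvl_means, pm, alpha),
        alpha=alpha,
    )
    return SphericityResult(
        n_subjects=n,
        n_levels=k,
        mauchly_W=W,
        chi_square=chi2,
        df=dof_m,
        p=p_m,
        within_F=float(F_w),
        within_df=(df_treat, df_err),
        within_p=p_w,
        multivariate_wilks=float(wilks),
        multivariate_F=float(F_mv),
        multivariate_df=df_mv,
        multivariate_p=p_mv,
        level_means=pd.Series(lvl_means, index=names),
        posthoc=post,
        degenerate=degenerate,
    )


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k-1) x k orthonormal contrasts (normalized Helmert)."""
    H = np.zeros((k - 1, k))
    for i in range(k - 1):
        H[i, : i + 1] = 1.0
        H[i, i + 1] = -(i + 1)
        H[i] /= np.linalg.norm(H[i])
    return H


# ---------------------------------------------------------------------------
# simple ANOVA / post hoc


def one_way_anova(
    data: pd.DataFrame, dep: str, group_factor: str, alpha: float = 0.05
) -> dict:
    """One-way ANOVA with LSD letters on the group means."""
    df, codes, levels = _prepare(data, [dep], group_factor, None)
    groups = [
        df.loc[codes == g, dep].to_numpy(dtype=float) for g in range(len(levels))
    ]
    k = len(groups)
    N = sum(len(g) for g in groups)
    grand = df[dep].mean()
    ss_b = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_w = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b, df_w = k - 1, N - k
    if ss_w <= 0:
        F = 0.0 if ss_b <= 0 else math.inf
        p = 1.0 if ss_b <= 0 else 0.0
    else:
        F = (ss_b / df_b) / (ss_w / df_w)
        p = float(sps.f.sf(F, df_b, df_w))
    mse = ss_w / df_w if df_w > 0 else math.nan
    means = np.array([g.mean() for g in groups])
    ns = np.array([len(g) for g in groups])
    pm = np.ones((k, k))
    for i, j in itertools.combinations(range(k), 2):
        se = math.sqrt(mse * (1.0 / ns[i] + 1.0 / ns[j])) if mse > 0 else 0.0
        if se == 0:
            pv = 1.0 if means[i] == means[j] else 0.0
        else:
            t = (means[i] - means[j]) / se
            pv = float(2.0 * sps.t.sf(abs(t), df_w))
        pm[i, j] = pm[j, i] = pv
    post = PosthocResult(
        groups=levels,
        means=means,
        p_matrix=pm,
        letters=letters_from_pmatrix(levels, means, pm, alpha),
        alpha=alpha,
    )
    return {"F": float(F), "df": (df_b, df_w), "p": p, "posthoc": post, "mse": mse}


def tukey_hsd(
    means: Sequence[float],
    mse: float,
    df: int,
    ns: Sequence[int],
    alpha: float = 0.05,
    groups: Sequence[str] | None = None,
) -> PosthocResult:
    """Tukey(-Kramer) HSD pairwise decisions from summary statistics.

    Unbalanced designs use the Tukey-Kramer standard error
    sqrt(mse/2 (1/n_i + 1/n_j)); p-values come from the studentized range
    distribution with k groups and ``df`` error df.
    """
    means = np.asarray(means, dtype=float)
    ns = np.asarray(ns, dtype=int)
    k = len(means)
    if k < 2:
        raise ValidationError("need at least 2 groups")
    if mse < 0 or df <= 0:
        raise ValidationError("mse must be >= 0 and df > 0")
    if groups is None:
        groups = [f"g{i}" for i in range(k)]
    pm = np.ones((k, k))
    for i, j in itertools.combinations(range(k), 2):
        se = math.sqrt(mse / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
        if se == 0:
            p = 1.0 if means[i] == means[j] else 0.0
        else:
            q = abs(means[i] - means[j]) / se
            p = float(sps.studentized_range.sf(q, k, df))
        pm[i, j] = pm[j, i] = p
    return PosthocResult(
        groups=list(groups),
        means=means,
        p_matrix=pm,
        letters=letters_from_pmatrix(list(groups), means, pm, alpha),
        alpha=alpha,
    )


def pooled_t_test(x: Sequence[float], y: Sequence[float]) -> dict:
    """Pooled-variance two-sample t (x minus y), df = n1 + n2 - 2."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValidationError("each group needs at least 2 values")
    n1, n2 = len(x), len(y)
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / df
    diff = x.mean() - y.mean()
    if sp2 == 0:
        t = 0.0 if diff == 0 else math.copysign(math.inf, diff)
        p = 1.0 if diff == 0 else 0.0
    else:
        t = diff / math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
        p = float(2.0 * sps.t.sf(abs(t), df))
    return {"t": float(t), "df": int(df), "p": p}
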
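"""Cohort statistics: the analysis plan behind the vein-WMH association.

Implements, from first principles, each inferential step used to relate
deep-medullary-vein voxel counts to white-matter-hyperintensity burden:
natural-log transform of skewed volumes, median dichotomization (ties to
the low group), Welch/pooled t-tests, Fisher's exact test by full
enumeration of margin-preserving r x c tables, partial Pearson correlation
by OLS residualization, maximum-likelihood logistic regression via IRLS,
backward stepwise elimination with likelihood-ratio removal tests and
forced covariates, two-way ANOVA intraclass correlation, and Bonferroni
adjustment.

The stepwise procedure uses exact refit likelihood-ratio tests (the
full model is refitted without each candidate) rather than the
conditional-estimate approximation some legacy software applies; the
removal threshold defaults to p = 0.10.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import gammaln

__all__ = [
    "AssociationResult",
    "LogisticModel",
    "ICCResult",
    "SeparationError",
    "natural_log_transform",
    "dichotomize_at_median",
    "partial_pearson",
    "two_sample_t_test",
    "fisher_exact",
    "fit_logistic",
    "backward_stepwise_logistic",
    "icc",
    "bonferroni_adjust",
]


class SeparationError(RuntimeError):
    """Perfect (or quasi-complete) separation: the MLE does not exist."""


# ------------------------------------------------------------ transforms

def natural_log_transform(values) -> np.ndarray:
    """Elementwise natural log; nonpositive entries are an error naming
    the offending row."""
    arr = np.asarray(values, dtype=float)
    bad = np.where(~(arr > 0))[0]
    if len(bad):
        raise ValueError(
            f"natural log requires positive values; rows {bad.tolist()[:10]} "
            f"have values {arr[bad[:10]].tolist()}"
        )
    return np.log(arr)


def dichotomize_at_median(values) -> tuple[np.ndarray, float]:
    """Split at the sample median: label ``low`` when value <= median,
    ``high`` when above (ties go low). Returns (labels, cutoff)."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least two values to dichotomize")
    if np.ptp(arr) == 0:
        raise ValueError("all values identical; median split is degenerate")
    cutoff = float(np.median(arr))
    labels = np.where(arr <= cutoff, "low", "high")
    if (labels == "high").sum() == 0:
        raise ValueError("median split is degenerate: no values above the median")
    return labels, cutoff


# ----------------------------------------------------------- correlation

@dataclass
class AssociationResult:
    """Plain and partial Pearson correlation between two variables."""

    r_plain: float
    r_partial: float
    df: int
    p_value: float
    covariates: tuple[str, ...]
    n: int


def _check_full_rank(design: np.ndarray, names) -> None:
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # name columns whose removal restores full column rank
        collinear = []
        for j in range(design.shape[1]):
            reduced = np.delete(design, j, axis=1)
            if np.linalg.matrix_rank(reduced) == rank:
                collinear.append(names[j] if j < len(names) else f"col{j}")
        raise ValueError(f"design matrix is rank deficient; collinear columns: {collinear}")


def _residualize(v: np.ndarray, design: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(design, v, rcond=None)
    return v - design @ beta


def partial_pearson(
    x, y, covariates: pd.DataFrame | np.ndarray | None = None
) -> AssociationResult:
    """Partial Pearson correlation of x and y given covariates.

    Both variables are residualized on [intercept + covariates] by OLS and
    the partial r is the Pearson correlation of the residuals. The p-value
    is two-sided from t = r * sqrt(df / (1 - r^2)), df = n - #cov - 2.
    With no covariates this reduces to the plain Pearson correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if len(y) != n:
        raise ValueError("x and y lengths differ")
    if covariates is None:
        cov_arr = np.empty((n, 0))
        names: tuple[str, ...] = ()
    elif isinstance(covariates, pd.DataFrame):
        cov_arr = covariates.to_numpy(dtype=float)
        names = tuple(covariates.columns)
    else:
        cov_arr = np.asarray(covariates, dtype=float)
        if cov_arr.ndim == 1:
            cov_arr = cov_arr[:, None]
        names = tuple(f"cov{j}" for j in range(cov_arr.shape[1]))
    q = cov_arr.shape[1]
    if n <= q + 2:
        raise ValueError(f"need n > {q + 2} observations for {q} covariates, got {n}")
    design = np.column_stack([np.ones(n), cov_arr])
    _check_full_rank(design, ("intercept", *names))

    r_plain = float(np.corrcoef(x, y)[0, 1])
    rx = _residualize(x, design)
    ry = _residualize(y, design)
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = n - q - 2
    r_c = min(max(r, -1.0 + 1e-15), 1.0 - 1e-15)
    t = r_c * math.sqrt(df / (1.0 - r_c * r_c))
    p = float(2.0 * sps.t.sf(abs(t), df))
    return AssociationResult(
        r_plain=r_plain, r_partial=r, df=df, p_value=p, covariates=names, n=n
    )


# ---------------------------------------------------------------- t-test

def two_sample_t_test(a, b, equal_var: bool = False) -> tuple[float, float, float]:
    """Independent-samples two-tailed t-test (Welch by default).

    Returns (t, df, p). The degenerate case of zero variance in both
    groups with equal means is defined as t = 0, p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return 0.0, float(len(a) + len(b) - 2), 1.0
        return math.inf, float(len(a) + len(b) - 2), 0.0
    res = sps.ttest_ind(a, b, equal_var=equal_var)
    return float(res.statistic), float(res.df), float(res.pvalue)


# ---------------------------------------------------------- Fisher exact

def _table_log_prob(table: np.ndarray, lg_margins: float, lg_n: float) -> float:
    return lg_margins - lg_n - gammaln(table + 1.0).sum()


def _enumerate_tables(row_sums, col_sums):
    """Yield all nonnegative integer tables with the given margins."""
    r, c = len(row_sums), len(col_sums)
    table = np.zeros((r, c), dtype=np.int64)

    def rec(i, remaining_cols):
        if i == r - 1:
            # last row is forced
            table[i, :] = remaining_cols
            if (table[i, :] >= 0).all():
                yield table
            return
        # fill row i cell by cell
        def fill(j, left):
            if j == c - 1:
                if 0 <= left <= remaining_cols[j]:
                    table[i, j] = left
                    yield True
                return
            hi = min(left, remaining_cols[j])
            for v in range(hi + 1):
                table[i, j] = v
                yield from fill(j + 1, left - v)

        for _ in fill(0, int(row_sums[i])):
            new_rem = remaining_cols - table[i, :]
            yield from rec(i + 1, new_rem)

    yield from rec(0, np.asarray(col_sums, dtype=np.int64))


def fisher_exact(table, max_tables: int = 2_000_000) -> float:
    """Two-sided Fisher exact p for an r x c contingency table (r*c <= 12)
    by full enumeration of margin-preserving tables.

    The p-value is the total conditional (multivariate hypergeometric)
    probability of all tables no more probable than the observed one
    (the probability method).
    """
    obs = np.asarray(table, dtype=np.int64)
    if obs.ndim != 2:
        raise ValueError("contingency table must be 2-dimensional")
    if (obs < 0).any():
        raise ValueError("counts must be nonnegative integers")
    r, c = obs.shape
    if r * c > 12:
        raise ValueError(
            f"table with {r * c} cells exceeds the enumeration budget; "
            "use a chi-square test instead (not applied automatically)"
        )
    row_sums = obs.sum(axis=1)
    col_sums = obs.sum(axis=0)
    n = int(obs.sum())
    if n == 0:
        raise ValueError("table is empty")
    lg_margins = gammaln(row_sums + 1.0).sum() + gammaln(col_sums + 1.0).sum()
    lg_n = gammaln(n + 1.0)
    lp_obs = _table_log_prob(obs, lg_margins, lg_n)
    tol = 1e-9 * abs(lp_obs) + 1e-12
    total = 0.0
    count = 0
    for t in _enumerate_tables(row_sums, col_sums):
        count += 1
        if count > max_tables:
            raise ValueError(
                "enumeration budget exceeded; use a chi-square test instead"
            )
        lp = _table_log_prob(t, lg_margins, lg_n)
        if lp <= lp_obs + tol:
            total += math.exp(lp)
    return min(total, 1.0)


# ------------------------------------------------------------- logistic

@dataclass
class LogisticModel:
    """Fitted logistic regression with Wald inference and, for stepwise
    fits, the removal trace."""

    outcome: str
    table: pd.DataFrame  # index: term; columns: estimate, se, or, ci_low, ci_high, p
    log_likelihood: float
    n: int
    forced: tuple[str, ...] = ()
    removal_trace: list = field(default_factory=list)  # (term, step, removal_p)

    @property
    def terms(self) -> list[str]:
        return [t for t in self.table.index if t != "intercept"]


def _irls(y: np.ndarray, design: np.ndarray, max_iter: int = 100,
          tol: float = 1e-8) -> tuple[np.ndarray, float, np.ndarray]:
    """IRLS maximum likelihood for logistic regression.

    Returns (beta, log-likelihood, covariance). Raises SeparationError when
    the fitted probabilities classify the outcome perfectly (the MLE is
    then unbounded) or the coefficients diverge numerically.
    """
    n, p = design.shape
    beta = np.zeros(p)
    ll_old = -math.inf
    for _ in range(max_iter):
        eta = design @ beta
        eta = np.clip(eta, -35, 35)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        w = np.maximum(w, 1e-12)
        z = eta + (y - mu) / w
        wd = design * w[:, None]
        hess = design.T @ wd
        try:
            beta_new = np.linalg.solve(hess, wd.T @ z)
        except np.linalg.LinAlgError as e:
            raise SeparationError(f"singular information matrix: {e}") from e
        if not np.all(np.isfinite(beta_new)) or np.abs(beta_new).max() > 1e6:
            raise SeparationError(
                "coefficients diverging with a monotone likelihood: separation"
            )
        ll = float(np.sum(y * eta - np.log1p(np.exp(eta))))
        if ll_old > -math.inf and abs(ll - ll_old) <= tol * (abs(ll_old) + tol):
            beta = beta_new
            break
        beta, ll_old = beta_new, ll
    eta = np.clip(design @ beta, -35, 35)
    mu = 1.0 / (1.0 + np.exp(-eta))
    ll = float(np.sum(y * eta - np.log1p(np.exp(eta))))
    # perfect classification: every case above 1-1e-8, every control below
    # 1e-8 -- the canonical (quasi-)complete separation diagnostic
    if np.all(mu[y == 1.0] > 1.0 - 1e-8) and np.all(mu[y == 0.0] < 1e-8):
        raise SeparationError(
            "fitted probabilities classify the outcome perfectly: the data "
            "are (quasi-)separated and the MLE is unbounded"
        )
    w = np.maximum(mu * (1.0 - mu), 1e-12)
    cov = np.linalg.inv(design.T @ (design * w[:, None]))
    return beta, ll, cov


def fit_logistic(
    y, X: pd.DataFrame | np.ndarray, outcome: str = "outcome",
    forced: tuple[str, ...] = (),
) -> LogisticModel:
    """Maximum-likelihood logistic regression (intercept added internally).

    Wald standard errors; odds ratios with 95% CI = exp(beta +/- 1.96 SE).
    Errors on single-class outcomes, collinear designs, and separation.
    """
    y = np.asarray(y, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("both outcome classes must be present")
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        arr = X.to_numpy(dtype=float)
    else:
        arr = np.asarray(X, dtype=float)
        if arr.ndim == 1:
            arr = arr[:, None]
        names = [f"x{j}" for j in range(arr.shape[1])]
    design = np.column_stack([np.ones(len(y)), arr])
    _check_full_rank(design, ["intercept", *names])
    beta, ll, cov = _irls(y, design)
    se = np.sqrt(np.diag(cov))
    zcrit = 1.959963984540054  # two-sided 95% normal quantile
    zstat = beta / se
    pvals = 2.0 * sps.norm.sf(np.abs(zstat))
    table = pd.DataFrame(
        {
            "estimate": beta,
            "se": se,
            "or": np.exp(beta),
            "ci_low": np.exp(beta - zcrit * se),
            "ci_high": np.exp(beta + zcrit * se),
            "p": pvals,
        },
        index=["intercept", *names],
    )
    return LogisticModel(
        outcome=outcome, table=table, log_likelihood=ll, n=len(y), forced=tuple(forced)
    )


def univariate_screen(
    y, candidates: pd.DataFrame, p_threshold: float = 0.1
) -> list[str]:
    """Single-variable logistic screens; returns candidates with p < threshold."""
    keep = []
    for name in candidates.columns:
        m = fit_logistic(y, candidates[[name]])
        if float(m.table.loc[name, "p"]) < p_threshold:
            keep.append(name)
    return keep


def backward_stepwise_logistic(
    y,
    candidates: pd.DataFrame,
    forced: tuple[str, ...] = (),
    always_include: tuple[str, ...] = (),
    p_remove: float = 0.10,
    screen_p: float | None = 0.1,
    outcome: str = "outcome",
) -> LogisticModel:
    """Backward stepwise logistic regression with forced covariates.

    The starting model holds the forced terms, the ``always_include`` terms
    (entered regardless of their univariate p, e.g. prespecified
    demographics and the vein voxel count), and every other candidate
    passing the univariate screen at p < ``screen_p`` (set ``screen_p=None``
    to disable the screen). At each step the non-forced term whose
    likelihood-ratio removal test (full refit vs refit without the term)
    has the largest p above ``p_remove`` is dropped; the procedure stops
    when every non-forced term has removal p <= ``p_remove``. Forced terms
    are never candidates for removal.
    """
    y = np.asarray(y, dtype=float)
    cols = list(candidates.columns)
    missing = [t for t in (*forced, *always_include) if t not in cols]
    if missing:
        raise ValueError(f"terms {missing} not in the candidate table")
    screened: list[str] = []
    if screen_p is not None:
        rest = [c for c in cols if c not in forced and c not in always_include]
        screened = univariate_screen(y, candidates[rest], screen_p) if rest else []
    else:
        screened = [c for c in cols if c not in forced and c not in always_include]
    current = list(dict.fromkeys([*forced, *always_include, *screened]))
    if not current:
        raise ValueError("candidate set is empty after the univariate screen")

    trace: list[tuple[str, int, float]] = []
    step = 0
    model = fit_logistic(y, candidates[current], outcome=outcome, forced=forced)
    while True:
        removable = [t for t in current if t not in forced]
        if not removable:
            break
        pvals = {}
        for term in removable:
            reduced_terms = [t for t in current if t != term]
            if reduced_terms:
                reduced = fit_logistic(y, candidates[reduced_terms])
                ll0 = reduced.log_likelihood
            else:
                p0 = y.mean()
                ll0 = float(len(y) * (p0 * math.log(p0) + (1 - p0) * math.log(1 - p0)))
            lr = 2.0 * (model.log_likelihood - ll0)
            pvals[term] = float(sps.chi2.sf(max(lr, 0.0), df=1))
        worst = max(pvals, key=lambda t: pvals[t])
        if pvals[worst] <= p_remove:
            break
        step += 1
        trace.append((worst, step, pvals[worst]))
        current = [t for t in current if t != worst]
        model = fit_logistic(y, candidates[current], outcome=outcome, forced=forced)
    model.removal_trace = trace
    model.forced = tuple(forced)
    return model


# -------------------------------------------------------------------- ICC

@dataclass
class ICCResult:
    """Single-measures intraclass correlation from a two-way ANOVA."""

    icc: float
    form: str  # "agreement" | "consistency"
    ms_subjects: float
    ms_raters: float
    ms_error: float
    var_subjects: float
    var_raters: float
    var_error: float
    n_subjects: int
    k_raters: int


def icc(ratings, form: str = "agreement") -> ICCResult:
    """Two-way, single-measures intraclass correlation coefficient.

    ``ratings`` is a complete subjects x raters matrix. The two-way ANOVA
    decomposition gives mean squares for subjects (MSB), raters (MSC) and
    error (MSE):

    - agreement (absolute):   (MSB - MSE) / (MSB + (k-1) MSE + k (MSC - MSE)/n)
    - consistency:            (MSB - MSE) / (MSB + (k-1) MSE)

    The agreement form charges systematic rater differences to the
    denominator; consistency ignores them.
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2:
        raise ValueError("ratings must be a subjects x raters matrix")
    n, k = x.shape
    if n < 5 or k < 2:
        raise ValueError(f"need >= 5 subjects and >= 2 raters, got {n} x {k}")
    if np.isnan(x).any():
        raise ValueError("ratings matrix must be complete")
    if form not in ("agreement", "consistency"):
        raise ValueError(f"unknown ICC form {form!r}")
    grand = x.mean()
    subj_means = x.mean(axis=1)
    rater_means = x.mean(axis=0)
    msb = k * float(((subj_means - grand) ** 2).sum()) / (n - 1)
    msc = n * float(((rater_means - grand) ** 2).sum()) / (k - 1)
    resid = x - subj_means[:, None] - rater_means[None, :] + grand
    mse = float((resid**2).sum()) / ((n - 1) * (k - 1))
    if msb == 0:
        raise ValueError("zero between-subject variance; ICC undefined")
    if form == "agreement":
        denom = msb + (k - 1) * mse + k * (msc - mse) / n
    else:
        denom = msb + (k - 1) * mse
    return ICCResult(
        icc=float((msb - mse) / denom),
        form=form,
        ms_subjects=msb,
        ms_raters=msc,
        ms_error=mse,
        var_subjects=(msb - mse) / k,
        var_raters=max((msc - mse) / n, 0.0),
        var_error=mse,
        n_subjects=n,
        k_raters=k,
    )


# -------------------------------------------------------------- adjustment

def bonferroni_adjust(pvalues) -> np.ndarray:
    """Bonferroni: adjusted p = min(1, p * m). Order-preserving."""
    arr = np.asarray(pvalues, dtype=float)
    if ((arr < 0) | (arr > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return np.minimum(1.0, arr * arr.size)
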
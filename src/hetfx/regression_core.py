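"""OLS with two-way (case x reader) cluster-robust covariance and tests.

The covariance estimator is the inclusion-exclusion combination of
one-way cluster sandwiches: ``V = V_case + V_reader - V_pair`` where
``V_pair`` clusters on unique (case, reader) pairs. No small-sample
correction is applied by default; a finite-sample ``G/(G-1)`` inflation
is available via ``df_correction=True``. If the combined matrix has a
negative eigenvalue (a known possibility of inclusion-exclusion),
negative eigenvalues are truncated to zero with a warning.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


class RankDeficientError(np.linalg.LinAlgError):
    pass


@dataclasses.dataclass
class FitResult:
    names: list[str]
    params: np.ndarray
    cov: np.ndarray
    n_obs: int
    n_clusters: dict[str, int]
    resid: np.ndarray | None = None
    eig_repaired: bool = False
    cov_raw: np.ndarray | None = None  # before negative-eigenvalue repair
    extra: dict = dataclasses.field(default_factory=dict)

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.cov), 0.0, None))

    def conf_int(self, alpha: float = 0.05) -> np.ndarray:
        z = stats.norm.ppf(1 - alpha / 2)
        se = self.se
        return np.column_stack([self.params - z * se, self.params + z * se])

    def index_of(self, name: str) -> int:
        return self.names.index(name)

    def coef(self, name: str) -> float:
        return float(self.params[self.index_of(name)])

    def coef_se(self, name: str) -> float:
        return float(self.se[self.index_of(name)])

    def to_dict(self) -> dict:
        ci = self.conf_int()
        return {
            "names": list(self.names),
            "params": [float(v) for v in self.params],
            "se": [float(v) for v in self.se],
            "ci_low": [float(v) for v in ci[:, 0]],
            "ci_high": [float(v) for v in ci[:, 1]],
            "n_obs": self.n_obs,
            "n_clusters": dict(self.n_clusters),
            "eig_repaired": self.eig_repaired,
        }


@dataclasses.dataclass(frozen=True)
class TestResult:
    statistic: float
    distribution: str  # e.g. "chi2(3)", "t(10)", "F(4, 95)"
    p_value: float
    hypothesis: str
    degenerate: bool = False

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _cluster_meat(scores: np.ndarray, codes: np.ndarray) -> np.ndarray:
    """sum over clusters g of (sum_i in g s_i)(sum_i in g s_i)'."""
    k = scores.shape[1]
    n_groups = codes.max() + 1
    sums = np.zeros((n_groups, k))
    np.add.at(sums, codes, scores)
    return sums.T @ sums


def fit_ols(
    y,
    X,
    clusters: tuple | None = None,
    names: list[str] | None = None,
    df_correction: bool = False,
) -> FitResult:
    """OLS point estimates with two-way cluster-robust covariance.

    ``clusters`` is a pair of row-aligned identifier arrays (case ids,
    reader ids). Either element may be None; with both None the
    heteroskedasticity-robust (HC0) sandwich is returned. A cluster
    dimension with a single cluster is dropped with a warning (falls
    back to the other dimension).
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, k = X.shape
    if names is None:
        names = [f"x{i}" for i in range(k)]
    if len(names) != k:
        raise ValueError("names length must match design columns")
    rank = np.linalg.matrix_rank(X)
    if rank < k:
        # name the columns whose removal restores full rank
        suspects = []
        for j in range(k):
            keep = [c for c in range(k) if c != j]
            if np.linalg.matrix_rank(X[:, keep]) == rank:
                suspects.append(names[j])
        raise RankDeficientError(
            f"design matrix is rank deficient (rank {rank} < {k}); "
            f"collinear candidates: {suspects}"
        )
    xtx = X.T @ X
    beta = np.linalg.solve(xtx, X.T @ y)
    resid = y - X @ beta
    bread = np.linalg.inv(xtx)
    scores = X * resid[:, None]

    dims: list[tuple[str, np.ndarray]] = []
    if clusters is not None:
        for label, ids in zip(("case", "reader"), clusters):
            if ids is None:
                continue
            codes = pd.factorize(np.asarray(ids))[0]
            n_g = codes.max() + 1
            if n_g == 1:
                warnings.warn(
                    f"cluster dimension {label!r} has a single cluster; "
                    "falling back to the remaining dimension(s)",
                    stacklevel=2,
                )
                continue
            dims.append((label, codes))

    n_clusters = {label: int(codes.max() + 1) for label, codes in dims}
    if not dims:
        meat = _cluster_meat(scores, np.arange(n))  # HC0
    elif len(dims) == 1:
        label, codes = dims[0]
        g = codes.max() + 1
        c = g / (g - 1) if df_correction else 1.0
        meat = c * _cluster_meat(scores, codes)
    else:
        (l1, c1), (l2, c2) = dims
        pair = pd.factorize(c1.astype(np.int64) * (c2.max() + 1) + c2)[0]
        def corr(codes):
            g = codes.max() + 1
            return g / (g - 1) if (df_correction and g > 1) else 1.0
        meat = (
            corr(c1) * _cluster_meat(scores, c1)
            + corr(c2) * _cluster_meat(scores, c2)
            - corr(pair) * _cluster_meat(scores, pair)
        )
        n_clusters["pair"] = int(pair.max() + 1)
    cov = bread @ meat @ bread
    cov = (cov + cov.T) / 2
    cov_raw = cov.copy()
    eig_repaired = False
    eigval, eigvec = np.linalg.eigh(cov)
    if eigval.min() < 0:
        if eigval.min() < -1e-12 * max(eigval.max(), 1.0):
            warnings.warn(
                "two-way cluster covariance had negative eigenvalue(s); "
                "truncated to zero",
                stacklevel=2,
            )
            eig_repaired = True
        cov = (eigvec * np.clip(eigval, 0.0, None)) @ eigvec.T
        cov = (cov + cov.T) / 2
    return FitResult(
        names=list(names),
        params=beta,
        cov=cov,
        n_obs=n,
        n_clusters=n_clusters,
        resid=resid,
        eig_repaired=eig_repaired,
        cov_raw=cov_raw,
    )


def treatment_effect_model(table: pd.DataFrame, df_correction: bool = False) -> FitResult:
    """``error ~ 1 + C(treatment)`` with two-way clustering.

    ``table`` needs columns error, assisted, case_id, radiologist_id.
    The reported treatment effect follows the improvement convention:
    ``te = -(assisted coefficient)``, stored under ``extra``.
    """
    assisted = table["assisted"].to_numpy(dtype=float)
    if np.unique(assisted).size < 2:
        raise ValueError("both treatment conditions are required")
    X = np.column_stack([np.ones(len(table)), assisted])
    fit = fit_ols(
        table["error"].to_numpy(dtype=float),
        X,
        clusters=(table["case_id"].to_numpy(), table["radiologist_id"].to_numpy()),
        names=["intercept", "treatment"],
        df_correction=df_correction,
    )
    fit.extra["te"] = -fit.coef("treatment")
    fit.extra["te_se"] = fit.coef_se("treatment")
    return fit


def subgroup_te_model(
    table: pd.DataFrame, group_col: str = "subgroup", df_correction: bool = False
) -> FitResult:
    """``error ~ 1 + C(subgroup) + C(treatment):C(subgroup)``.

    Per-subgroup treatment interaction coefficients; subgroup treatment
    effects (improvement convention, i.e. negated interaction terms) and
    robust CIs are stored in ``extra["subgroup_tes"]``.
    """
    groups = pd.Categorical(table[group_col])
    levels = list(groups.categories)
    assisted = table["assisted"].to_numpy(dtype=float)
    cells = pd.crosstab(groups, assisted)
    if (cells.to_numpy() == 0).any() or cells.shape[1] < 2:
        empty = [
            (str(g), int(t))
            for g in cells.index
            for t in (0, 1)
            if t not in cells.columns or cells.loc[g, t] == 0
        ]
        raise ValueError(f"empty subgroup-condition cell(s): {empty}")
    n = len(table)
    codes = groups.codes
    cols = [np.ones(n)]
    names = ["intercept"]
    for j, level in enumerate(levels[1:], start=1):
        cols.append((codes == j).astype(float))
        names.append(f"subgroup[{level}]")
    for j, level in enumerate(levels):
        cols.append(((codes == j) & (assisted == 1)).astype(float))
        names.append(f"treatment:subgroup[{level}]")
    fit = fit_ols(
        table["error"].to_numpy(dtype=float),
        np.column_stack(cols),
        clusters=(table["case_id"].to_numpy(), table["radiologist_id"].to_numpy()),
        names=names,
        df_correction=df_correction,
    )
    z = stats.norm.ppf(0.975)
    tes = {}
    for level in levels:
        name = f"treatment:subgroup[{level}]"
        te = -fit.coef(name)
        se = fit.coef_se(name)
        n_g = int((codes == levels.index(level)).sum())
        tes[str(level)] = {
            "te": te,
            "se": se,
            "ci_low": te - z * se,
            "ci_high": te + z * se,
            "n": n_g,
        }
    fit.extra["subgroup_tes"] = tes
    fit.extra["levels"] = [str(l) for l in levels]
    return fit


def wald_joint_equality(fit: FitResult, coefficient_names: list[str]) -> TestResult:
    """Wald chi-square test of joint equality among coefficients.

    Uses the pairwise-difference restriction matrix (successive
    differences, k-1 restrictions) and the fit's robust covariance.
    """
    idx = [fit.index_of(name) for name in coefficient_names]
    k = len(idx)
    if k < 2:
        raise ValueError("need at least two coefficients")
    theta = fit.params[idx]
    V = fit.cov[np.ix_(idx, idx)]
    R = np.zeros((k - 1, k))
    for i in range(k - 1):
        R[i, i] = 1.0
        R[i, i + 1] = -1.0
    d = R @ theta
    mid = R @ V @ R.T
    scale = max(1.0, float(np.max(np.abs(theta))))
    if np.max(np.abs(d)) <= 1e-10 * scale:
        # numerically identical estimates: statistic 0 without inverting a
        # (then typically near-singular) restricted covariance
        return TestResult(
            statistic=0.0,
            distribution=f"chi2({k - 1})",
            p_value=1.0,
            hypothesis=f"joint equality of {coefficient_names}",
        )
    try:
        sol = np.linalg.solve(mid, d)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            f"restricted covariance is singular: {err}"
        ) from err
    statistic = float(d @ sol)
    p = float(stats.chi2.sf(statistic, k - 1))
    return TestResult(
        statistic=statistic,
        distribution=f"chi2({k - 1})",
        p_value=p,
        hypothesis=f"joint equality of {coefficient_names}",
    )


def wald_zero(fit: FitResult, name: str) -> TestResult:
    """Wald test of a single coefficient against zero (chi-square, 1 dof)."""
    est, se = fit.coef(name), fit.coef_se(name)
    if se == 0:
        return TestResult(float("inf") if est else 0.0, "chi2(1)", 0.0 if est else 1.0, f"{name} = 0", degenerate=True)
    statistic = (est / se) ** 2
    return TestResult(statistic, "chi2(1)", float(stats.chi2.sf(statistic, 1)), f"{name} = 0")


def unpaired_t_test(group_a, group_b, equal_var: bool = True) -> TestResult:
    """Two-sided unpaired t-test (pooled-variance by default)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two observations")
    degenerate = a.std(ddof=1) == 0 and b.std(ddof=1) == 0
    if degenerate and np.mean(a) == np.mean(b):
        dof = a.size + b.size - 2
        return TestResult(0.0, f"t({dof})", 1.0, "mean(a) = mean(b)", degenerate=True)
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    dof = a.size + b.size - 2 if equal_var else float(res.df)
    return TestResult(
        statistic=float(res.statistic),
        distribution=f"t({dof})",
        p_value=float(res.pvalue),
        hypothesis="mean(a) = mean(b)",
        degenerate=bool(degenerate),
    )


def benjamini_hochberg(p_values, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Step-up FDR control; returns (reject flags, adjusted p-values).

    adjusted p(j) = min over ranks >= j of m * p(rank) / rank, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    adj = np.minimum.accumulate((m * ranked / np.arange(1, m + 1))[::-1])[::-1]
    adj = np.clip(adj, 0.0, 1.0)
    passed = ranked <= q * np.arange(1, m + 1) / m
    cutoff = np.max(np.nonzero(passed)[0]) + 1 if passed.any() else 0
    reject_sorted = np.arange(m) < cutoff
    reject = np.empty(m, dtype=bool)
    adjusted = np.empty(m, dtype=float)
    reject[order] = reject_sorted
    adjusted[order] = adj
    return reject, adjusted


def auroc_bin_f_test(group_aurocs, group_ses, group_ns) -> TestResult:
    """One-way F-test on binned AUROCs from group summaries.

    SSB uses group sizes and the size-weighted grand mean; SSW
    back-converts each group AUROC's standard error (of a mean) into a
    within-group sum of squares: ``(n_g - 1) * n_g * se_g^2``.
    """
    a = np.asarray(group_aurocs, dtype=float)
    se = np.asarray(group_ses, dtype=float)
    n = np.asarray(group_ns, dtype=float)
    if a.size < 2:
        raise ValueError("need at least two groups")
    if np.any(~np.isfinite(a)):
        raise ValueError("undefined group AUROC")
    if np.any(n < 2):
        raise ValueError("every group needs n >= 2")
    k = a.size
    total = n.sum()
    grand = float((n * a).sum() / total)
    ssb = float((n * (a - grand) ** 2).sum())
    ssw = float(((n - 1) * n * se**2).sum())
    df1, df2 = k - 1, total - k
    if ssw == 0:
        statistic = float("inf") if ssb > 0 else 0.0
        return TestResult(statistic, f"F({df1}, {int(df2)})", 0.0 if ssb > 0 else 1.0, "equal group AUROCs", degenerate=True)
    statistic = (ssb / df1) / (ssw / df2)
    p = float(stats.f.sf(statistic, df1, df2))
    return TestResult(statistic, f"F({df1}, {int(df2)})", p, "equal group AUROCs")
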
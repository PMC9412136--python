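"""Stage-wise inference on diversity records.

Covers the analysis battery applied to the per-plot diversity table:
a Shapiro-Wilk normality gate, one-way ANOVA across restoration stages
with multiple comparisons summarized as a compact letter display,
a Pearson correlation matrix with significance stars, and binary
stepwise regression of stability on functional diversity (x1) and
functional redundancy (x2) with standardized partial coefficients.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .community_model import ValidationError


# ---------------------------------------------------------------- normality


@dataclass
class NormalityReport:
    metric: str
    table: pd.DataFrame  # group, n, W, p, normal, degenerate
    passed: bool
    alpha: float = 0.05


def normality_gate(
    values, groups, metric: str = "", alpha: float = 0.05, hard: bool = False
) -> NormalityReport:
    """Shapiro-Wilk test per group; the gate passes if every group does.

    With a failing group the report flags it and (by default) the
    pipeline proceeds with a warning; ``hard=True`` raises instead.
    Groups of identical values are degenerate and reported as failing.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    rows = []
    ok = True
    for g in pd.unique(groups):
        x = values[groups == g]
        if x.size < 3:
            raise ValidationError(f"group {g!r} has n = {x.size} < 3: Shapiro-Wilk undefined")
        if np.ptp(x) == 0:
            rows.append({"group": g, "n": x.size, "W": math.nan, "p": 0.0,
                         "normal": False, "degenerate": True})
            ok = False
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            w, p = stats.shapiro(x)
        normal = p >= alpha
        ok = ok and normal
        rows.append({"group": g, "n": x.size, "W": float(w), "p": float(p),
                     "normal": bool(normal), "degenerate": False})
    report = NormalityReport(metric=metric, table=pd.DataFrame(rows), passed=ok, alpha=alpha)
    if not ok:
        failing = report.table.loc[~report.table["normal"], "group"].tolist()
        msg = f"normality gate failed for {metric or 'metric'} in group(s) {failing}"
        if hard:
            raise ValidationError(msg)
        warnings.warn(msg, stacklevel=2)
    return report


# ------------------------------------------------------------------- ANOVA


@dataclass
class StageComparison:
    metric: str
    F: float
    p: float
    group_means: dict[str, float]
    letters: dict[str, str]
    method: str = "tukey"
    pairwise_p: dict[tuple[str, str], float] = field(default_factory=dict)


def _compact_letter_display(
    groups: list[str], means: dict[str, float], significant: set[frozenset]
) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    Start from one set holding all groups; for every significantly
    different pair split any set containing both; absorb subsets; then
    name the letters a, b, c ... from the set whose members have the
    highest mean downwards.
    """
    sets: list[set[str]] = [set(groups)]
    for pair in significant:
        g1, g2 = tuple(pair)
        for s in list(sets):
            if g1 in s and g2 in s:
                sets.remove(s)
                sets.extend([s - {g1}, s - {g2}])
        # absorb: drop any set contained in another
        sets = [s for s in sets if s and not any(s < t for t in sets if t is not s)]
        # dedupe
        uniq: list[set[str]] = []
        for s in sets:
            if s not in uniq:
                uniq.append(s)
        sets = uniq
    sets.sort(key=lambda s: -max(means[g] for g in s))
    letter_of_set = {i: chr(ord("a") + i) for i in range(len(sets))}
    letters = {g: "" for g in groups}
    for i, s in enumerate(sets):
        for g in s:
            letters[g] += letter_of_set[i]
    return {g: "".join(sorted(letters[g])) for g in groups}


def stage_anova(
    records: pd.DataFrame,
    metric: str,
    method: str = "tukey",
    alpha: float = 0.05,
) -> StageComparison:
    """One-way ANOVA of a metric across stages with a letter display.

    ``method`` selects the multiple-comparison procedure: ``tukey``
    (Tukey HSD, default) or ``lsd`` (Fisher LSD: pairwise t tests on
    the pooled ANOVA mean square, unadjusted).
    """
    if method not in ("tukey", "lsd"):
        raise ValidationError(f"unknown multiple-comparison method {method!r}")
    from .community_model import STAGES

    df = records[["stage", metric]].dropna()
    df = df[np.isfinite(df[metric].to_numpy(dtype=float))]
    stage_order = [s for s in STAGES if s in set(df["stage"])]
    groups = {s: df.loc[df["stage"] == s, metric].to_numpy(dtype=float) for s in stage_order}
    for s, x in groups.items():
        if x.size < 2:
            raise ValidationError(f"stage {s!r} has n = {x.size} < 2 replicates")
    means = {s: float(np.mean(x)) for s, x in groups.items()}
    allvals = np.concatenate(list(groups.values()))

    if np.ptp(allvals) == 0:  # all values identical: no variance anywhere
        return StageComparison(
            metric=metric, F=0.0, p=1.0, group_means=means,
            letters={s: "a" for s in stage_order}, method=method,
        )

    F, p = stats.f_oneway(*groups.values())

    pairwise: dict[tuple[str, str], float] = {}
    if method == "tukey":
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        res = pairwise_tukeyhsd(df[metric].to_numpy(dtype=float),
                                df["stage"].to_numpy(), alpha=alpha)
        tbl = pd.DataFrame(res.summary().data[1:], columns=res.summary().data[0])
        for _, row in tbl.iterrows():
            pairwise[(str(row["group1"]), str(row["group2"]))] = float(row["p-adj"])
    else:  # Fisher LSD on pooled MSE
        k = len(groups)
        n_tot = allvals.size
        mse = sum(((x - np.mean(x)) ** 2).sum() for x in groups.values()) / (n_tot - k)
        dfree = n_tot - k
        names = list(groups)
        for i in range(k):
            for j in range(i + 1, k):
                xi, xj = groups[names[i]], groups[names[j]]
                se = math.sqrt(mse * (1 / xi.size + 1 / xj.size))
                t = (np.mean(xi) - np.mean(xj)) / se if se > 0 else math.inf
                pw = 2 * stats.t.sf(abs(t), dfree) if se > 0 else 0.0
                pairwise[(names[i], names[j])] = float(pw)

    significant = {frozenset(pair) for pair, pv in pairwise.items() if pv < alpha}
    letters = _compact_letter_display(stage_order, means, significant)
    return StageComparison(
        metric=metric, F=float(F), p=float(p), group_means=means,
        letters=letters, method=method, pairwise_p=pairwise,
    )


# -------------------------------------------------------------- correlation


@dataclass
class CorrelationMatrix:
    variables: list[str]
    r: pd.DataFrame
    p: pd.DataFrame
    stars: pd.DataFrame


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def pearson_matrix(table: pd.DataFrame) -> CorrelationMatrix:
    """Pairwise Pearson r with two-sided t-distribution p values.

    Requires >= 3 rows and no constant column (r undefined there).
    """
    num = table.select_dtypes(include=[np.number])
    if len(num) < 3:
        raise ValidationError("Pearson correlation needs at least 3 observations")
    for col in num.columns:
        if np.ptp(num[col].to_numpy(dtype=float)) == 0:
            raise ValidationError(f"constant column {col!r}: correlation undefined")
    cols = list(num.columns)
    k = len(cols)
    r = np.eye(k)
    p = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            ri, pi = stats.pearsonr(num[cols[i]], num[cols[j]])
            r[i, j] = r[j, i] = ri
            p[i, j] = p[j, i] = pi
    rdf = pd.DataFrame(r, index=cols, columns=cols)
    pdf = pd.DataFrame(p, index=cols, columns=cols)
    sdf = pdf.map(_stars)
    np.fill_diagonal(sdf.values, "")
    return CorrelationMatrix(variables=cols, r=rdf, p=pdf, stars=sdf)


# ---------------------------------------------------------------- stepwise


@dataclass
class RegressionResult:
    response: str
    intercept: float
    coefficients: dict[str, float]
    std_coefficients: dict[str, float]
    r_squared: float
    overall_p: float | None
    included: list[str]
    n: int

    def equation(self, digits: int = 3) -> str:
        terms = [f"{self.intercept:.{digits}f}"]
        for name, b in self.coefficients.items():
            sign = "+" if b >= 0 else "-"
            terms.append(f"{sign} {abs(b):.{digits}f}*{name}")
        return f"{self.response} = " + " ".join(terms)

    def to_dict(self) -> dict:
        return {
            "response": self.response,
            "intercept": self.intercept,
            "coefficients": self.coefficients,
            "std_coefficients": self.std_coefficients,
            "r_squared": self.r_squared,
            "overall_p": self.overall_p,
            "included": self.included,
            "n": self.n,
            "equation": self.equation(),
        }


def _ols(y: np.ndarray, X: pd.DataFrame):
    import statsmodels.api as sm

    return sm.OLS(y, sm.add_constant(X, has_constant="add")).fit()


def stepwise_regression(
    y,
    X: pd.DataFrame,
    response: str = "y",
    entry_p: float = 0.05,
    stay_p: float = 0.10,
) -> RegressionResult:
    """Forward-entry / backward-elimination least squares.

    Candidates enter one at a time by smallest partial-F p value below
    ``entry_p`` and are removed when their p value exceeds ``stay_p``
    (SPSS-style defaults 0.05 / 0.10). A candidate may only enter while
    at least one residual degree of freedom remains. The final model is
    refit by OLS; standardized coefficients are b * SD(x) / SD(y).
    """
    y = np.asarray(y, dtype=float)
    if X.shape[0] != y.size:
        raise ValidationError("y and X must have the same number of rows")
    n = y.size
    cand = list(X.columns)
    if n <= 1:
        raise ValidationError("need more than one observation")
    xmat = X.to_numpy(dtype=float)
    if len(cand) >= 2 and np.linalg.matrix_rank(np.column_stack([np.ones(n), xmat])) < min(
        n, len(cand) + 1
    ):
        raise ValidationError("predictors are perfectly collinear")

    included: list[str] = []
    ss_tot = float(((y - y.mean()) ** 2).sum())
    while True:
        changed = False
        # stop once the current model fits perfectly: partial tests on
        # numerically-zero residuals are meaningless
        if included:
            fit = _ols(y, X[included])
            if float(fit.ssr) <= 1e-12 * max(ss_tot, 1.0):
                break
        # forward step
        trial_p = {}
        for c in cand:
            if c in included:
                continue
            if n - (len(included) + 2) < 1:  # intercept + predictors + candidate
                continue
            fit = _ols(y, X[included + [c]])
            pv = float(fit.pvalues[c])
            if not math.isnan(pv):
                trial_p[c] = pv
        if trial_p:
            best = min(trial_p, key=trial_p.get)
            if trial_p[best] < entry_p:
                included.append(best)
                changed = True
        # backward step
        while included:
            fit = _ols(y, X[included])
            pvals = fit.pvalues.drop("const")
            worst = pvals.idxmax()
            if float(pvals[worst]) > stay_p:
                included.remove(worst)
                changed = True
            else:
                break
        if not changed:
            break

    if included:
        fit = _ols(y, X[included])
        intercept = float(fit.params["const"])
        coefs = {c: float(fit.params[c]) for c in included}
        r2 = float(fit.rsquared)
        overall_p = float(fit.f_pvalue) if math.isfinite(fit.f_pvalue) else None
        sy = float(np.std(y, ddof=1))
        std_coefs = {
            c: coefs[c] * float(np.std(X[c].to_numpy(dtype=float), ddof=1)) / sy
            for c in included
        }
    else:
        intercept = float(np.mean(y))
        coefs, std_coefs = {}, {}
        r2, overall_p = 0.0, None

    return RegressionResult(
        response=response,
        intercept=intercept,
        coefficients=coefs,
        std_coefficients=std_coefs,
        r_squared=r2,
        overall_p=overall_p,
        included=included,
        n=n,
    )
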
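"""Cohort statistics: grade-group comparisons and baseline-nadir association.

Mirrors the statistical layer of a clinical haematotoxicity analysis:
skewed variables are log transformed (automatic rule: absolute sample
skewness <= 1 keeps the identity scale), categorical variables are compared
with chi-square tests, continuous ones with one-way ANOVA (normal scale) or
Kruskal-Wallis (skewed), with Bonferroni-adjusted post hoc tests (pairwise
Welch t for ANOVA, Dunn for Kruskal-Wallis) when the omnibus test is
significant at 0.05.  The baseline-nadir relation is assessed by Pearson
correlation and ordinary least-squares regression of nadir on baseline.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "ScaleDecision",
    "choose_scale",
    "GroupComparison",
    "compare_groups",
    "dunn_test",
    "AssociationResult",
    "baseline_nadir_association",
    "summarize_cohort",
]

ALPHA = 0.05
SKEWNESS_LIMIT = 1.0


@dataclass
class ScaleDecision:
    scale: str  # "identity" | "log"
    transformed: np.ndarray
    skew_raw: float
    skew_transformed: float


def choose_scale(values, max_abs_skew: float = SKEWNESS_LIMIT) -> ScaleDecision:
    """Decide between the identity and log scale by sample skewness.

    The identity scale is kept when |skewness| <= ``max_abs_skew``
    (constant samples have zero skewness by convention); otherwise the
    values are log transformed, which requires them to be positive.
    """
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if x.size == 0:
        raise ValueError("no values to scale")
    if np.ptp(x) == 0:
        return ScaleDecision("identity", x, 0.0, 0.0)
    skew_raw = float(sps.skew(x))
    if abs(skew_raw) <= max_abs_skew:
        return ScaleDecision("identity", x, skew_raw, skew_raw)
    if np.any(x <= 0):
        raise ValueError("log scale selected but values are not all positive")
    lx = np.log(x)
    return ScaleDecision("log", lx, skew_raw, float(sps.skew(lx)))


@dataclass
class GroupComparison:
    variable: str
    test: str  # "chi-square" | "anova" | "kruskal-wallis"
    statistic: float
    p_value: float
    scale: str
    group_summaries: dict
    post_hoc: list[dict] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def to_json(self) -> dict:
        return {
            "variable": self.variable,
            "test": self.test,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "scale": self.scale,
            "group_summaries": self.group_summaries,
            "post_hoc": self.post_hoc,
            "warnings": self.warnings,
        }


def dunn_test(groups: dict[str, np.ndarray]) -> list[dict]:
    """Dunn's rank-based pairwise test with Bonferroni adjustment.

    z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T) (1/n_i + 1/n_j)) with
    the tie correction T = sum(t^3 - t) / (12 (N - 1)) over tie groups.
    """
    names = list(groups)
    pooled = np.concatenate([np.asarray(groups[g], dtype=float) for g in names])
    n_total = pooled.size
    ranks = sps.rankdata(pooled)
    mean_ranks = {}
    pos = 0
    for g in names:
        n = len(groups[g])
        mean_ranks[g] = float(ranks[pos : pos + n].mean())
        pos += n
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    pairs = list(itertools.combinations(names, 2))
    out = []
    for a, b in pairs:
        se = np.sqrt(var_base * (1.0 / len(groups[a]) + 1.0 / len(groups[b])))
        z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
        p = 2.0 * sps.norm.sf(abs(z))
        out.append(
            {
                "pair": (a, b),
                "statistic": float(z),
                "p_raw": float(p),
                "p_adjusted": float(min(p * len(pairs), 1.0)),
            }
        )
    return out


def _pairwise_welch(groups: dict[str, np.ndarray]) -> list[dict]:
    pairs = list(itertools.combinations(groups, 2))
    out = []
    for a, b in pairs:
        t, p = sps.ttest_ind(groups[a], groups[b], equal_var=False)
        out.append(
            {
                "pair": (a, b),
                "statistic": float(t),
                "p_raw": float(p),
                "p_adjusted": float(min(p * len(pairs), 1.0)),
            }
        )
    return out


def _pairwise_chi2(table: pd.DataFrame) -> list[dict]:
    pairs = list(itertools.combinations(table.index, 2))
    out = []
    for a, b in pairs:
        sub = table.loc[[a, b]]
        sub = sub.loc[:, sub.sum(axis=0) > 0]
        stat, p, _, _ = sps.chi2_contingency(sub.to_numpy(), correction=False)
        out.append(
            {
                "pair": (a, b),
                "statistic": float(stat),
                "p_raw": float(p),
                "p_adjusted": float(min(p * len(pairs), 1.0)),
            }
        )
    return out


def compare_groups(
    table: pd.DataFrame,
    variable: str,
    grouping: str = "grade_group",
    kind: str = "auto",
    alpha: float = ALPHA,
) -> GroupComparison:
    """Omnibus comparison of one variable across grade groups, with post hoc.

    ``kind="auto"`` treats non-numeric columns as categorical; numeric
    columns use ANOVA on the identity scale or Kruskal-Wallis when the
    automatic scale rule selects log.  Post hoc pairwise tests (Bonferroni
    adjusted) are run only when the omnibus p is below ``alpha``.
    """
    df = table[[grouping, variable]].dropna()
    groups = {str(g): sub[variable] for g, sub in df.groupby(grouping, sort=True)}
    if len(groups) < 2:
        raise ValueError(f"need at least 2 non-empty groups, got {len(groups)}")
    if any(len(v) == 0 for v in groups.values()):
        raise ValueError("empty group encountered")
    warnings_list: list[str] = []

    is_categorical = kind == "categorical" or (
        kind == "auto" and not pd.api.types.is_numeric_dtype(df[variable])
    )
    if is_categorical:
        ct = pd.crosstab(df[grouping], df[variable])
        stat, p, _, expected = sps.chi2_contingency(ct.to_numpy(), correction=False)
        if np.any(expected < 1):
            warnings_list.append("chi-square expected cell count below 1")
        summaries = {
            g: {"n": int(row.sum()), "counts": {str(k): int(v) for k, v in row.items()}}
            for g, row in ct.iterrows()
        }
        post = _pairwise_chi2(ct) if p < alpha else []
        return GroupComparison(variable, "chi-square", float(stat), float(p), "identity",
                               {str(k): v for k, v in summaries.items()}, post, warnings_list)

    pooled_scale = choose_scale(df[variable].to_numpy())
    arrays = {g: np.asarray(v, dtype=float) for g, v in groups.items()}
    if pooled_scale.scale == "identity":
        stat, p = sps.f_oneway(*arrays.values())
        test = "anova"
        summaries = {
            g: {"n": int(v.size), "mean": float(v.mean()), "sd": float(v.std(ddof=1)) if v.size > 1 else None}
            for g, v in arrays.items()
        }
        post = _pairwise_welch(arrays) if p < alpha else []
    else:
        stat, p = sps.kruskal(*arrays.values())
        test = "kruskal-wallis"
        summaries = {
            g: {
                "n": int(v.size),
                "median": float(np.median(v)),
                "iqr": [float(np.percentile(v, 25)), float(np.percentile(v, 75))],
            }
            for g, v in arrays.items()
        }
        post = dunn_test(arrays) if p < alpha else []
    return GroupComparison(variable, test, float(stat), float(p), pooled_scale.scale, summaries, post, warnings_list)


@dataclass
class AssociationResult:
    parameter: str
    n: int
    scale: str
    correlation: float
    correlation_p: float
    beta: float
    beta_ci: tuple[float, float]
    r_squared: float
    regression_p: float
    intercept: float

    def to_json(self) -> dict:
        return {
            "parameter": self.parameter,
            "n": self.n,
            "scale": self.scale,
            "correlation": self.correlation,
            "correlation_p": self.correlation_p,
            "beta": self.beta,
            "beta_ci": list(self.beta_ci),
            "r_squared": self.r_squared,
            "regression_p": self.regression_p,
            "intercept": self.intercept,
        }


def baseline_nadir_association(
    table: pd.DataFrame,
    baseline_col: str,
    nadir_col: str,
    parameter: str | None = None,
    scale: str = "auto",
    method: str = "pearson",
) -> AssociationResult:
    """Correlation and OLS regression of nadir on baseline for one parameter.

    ``scale="auto"`` applies the skewness rule to the pooled baseline+nadir
    values so both axes share one scale; ``method`` may be ``"pearson"``
    (default) or ``"spearman"``.
    """
    df = table[[baseline_col, nadir_col]].dropna()
    if len(df) < 3:
        raise ValueError("need at least 3 complete baseline/nadir pairs")
    x = df[baseline_col].to_numpy(dtype=float)
    y = df[nadir_col].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("baseline values have zero variance")
    if scale == "auto":
        scale = choose_scale(np.concatenate([x, y])).scale
    if scale == "log":
        if np.any(x <= 0) or np.any(y <= 0):
            raise ValueError("log scale selected but values are not all positive")
        x, y = np.log(x), np.log(y)
    elif scale != "identity":
        raise ValueError(f"unknown scale {scale!r}")
    if method == "pearson":
        r, r_p = sps.pearsonr(x, y)
    elif method == "spearman":
        r, r_p = sps.spearmanr(x, y)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    ci = model.conf_int(alpha=0.05)
    return AssociationResult(
        parameter=parameter or baseline_col,
        n=len(df),
        scale=scale,
        correlation=float(r),
        correlation_p=float(r_p),
        beta=float(model.params[1]),
        beta_ci=(float(ci[1][0]), float(ci[1][1])),
        r_squared=float(model.rsquared),
        regression_p=float(model.pvalues[1]),
        intercept=float(model.params[0]),
    )


def summarize_cohort(table: pd.DataFrame, group_col: str | None = None) -> pd.DataFrame:
    """Descriptive table: mean +- SD, median [IQR] and n per variable.

    Numeric variables report mean/SD when the skewness rule keeps the
    identity scale and median [25th-75th percentile, linear interpolation]
    otherwise; categorical variables report level counts.  With
    ``group_col`` the summaries are produced per group.
    """
    if table.empty:
        raise ValueError("cohort table is empty")

    def one(df: pd.DataFrame, label: str) -> list[dict]:
        rows = []
        for col in df.columns:
            if col == group_col:
                continue
            ser = df[col].dropna()
            row: dict = {"group": label, "variable": col, "n": int(ser.size)}
            if pd.api.types.is_numeric_dtype(ser) and ser.size > 0:
                vals = ser.to_numpy(dtype=float)
                dec = choose_scale(vals) if np.all(vals > 0) else None
                skewed = dec is not None and dec.scale == "log"
                row["mean"] = float(vals.mean())
                row["sd"] = float(vals.std(ddof=1)) if vals.size > 1 else None
                row["median"] = float(np.median(vals))
                row["q25"] = float(np.percentile(vals, 25))
                row["q75"] = float(np.percentile(vals, 75))
                row["summary"] = (
                    f"{row['median']:.1f} [{row['q25']:.1f}-{row['q75']:.1f}]"
                    if skewed
                    else (f"{row['mean']:.1f} ± {row['sd']:.1f}" if row["sd"] is not None else f"{row['mean']:.1f}")
                )
            elif ser.size > 0:
                counts = ser.value_counts()
                row["summary"] = "; ".join(f"{k}: {v} ({100 * v / ser.size:.0f}%)" for k, v in counts.items())
            rows.append(row)
        return rows

    if group_col is None:
        rows = one(table, "all")
    else:
        rows = []
        for g, sub in table.groupby(group_col, sort=True):
            rows.extend(one(sub, str(g)))
    return pd.DataFrame(rows)
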
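"""Rater-vs-classifier validation statistics.

Operates on a long-format rater table — one row per (section, genotype,
rater) percent-vacuolation measurement, where "raters" are human scorers
and/or the automated classifier — and reproduces the standard validation
analysis for such designs: a square-root transform to normalise the skewed
percentage distribution, a balanced fixed-effects two-way ANOVA
(genotype × rater) with eta-squared effect sizes, pairwise Pearson
correlation matrices with critical-r thresholds, and a Tukey HSD post hoc for
one-way genotype comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multicomp import pairwise_tukeyhsd

REQUIRED_COLUMNS = ("section_id", "genotype", "rater_id", "percent")


class DesignError(ValueError):
    """Raised when the table is not a balanced crossed genotype x rater design."""


def _check_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"rater table is missing columns: {missing}")
    if ((table["percent"] < 0) | (table["percent"] > 100)).any():
        raise ValueError("percent values must lie in [0, 100]")
    return table


def read_rater_table(path: str) -> pd.DataFrame:
    """Read a long-format rater table CSV (section_id, genotype, rater_id, percent)."""
    return _check_table(pd.read_csv(path))


def sqrt_transform(table: pd.DataFrame) -> pd.DataFrame:
    """Square-root transform of the percent column (normalises the distribution)."""
    _check_table(table)
    if (table["percent"] < 0).any():
        raise ValueError("cannot square-root transform negative percentages")
    out = table.copy()
    out["percent"] = np.sqrt(out["percent"].to_numpy(dtype=float))
    return out


@dataclass(frozen=True)
class AnovaResult:
    """Two-way fixed-effects decomposition with eta-squared effect sizes.

    ``table`` has one row per effect (genotype, rater, interaction, residual)
    with columns sum_sq, df, F, p, eta_sq. Eta-squared is SS_effect/SS_total.
    """

    table: pd.DataFrame

    @property
    def ss_total(self) -> float:
        return float(self.table["sum_sq"].sum())

    def effect(self, name: str) -> pd.Series:
        return self.table.loc[name]

    def report(self) -> str:
        lines = []
        for name in ("genotype", "rater", "interaction"):
            row = self.table.loc[name]
            resid_df = int(self.table.loc["residual", "df"])
            lines.append(
                f"{name.capitalize()}: F({int(row['df'])},{resid_df}) = "
                f"{row['F']:.4g}, eta2 = {row['eta_sq']:.4g}, p = {row['p']:.4g}"
            )
        return "\n".join(lines)


def two_way_anova(table: pd.DataFrame) -> AnovaResult:
    """Balanced two-way ANOVA (genotype x rater, with interaction) on percent.

    Requires every genotype x rater cell to hold the same number (>= 2) of
    observations, so the type-I and type-III decompositions coincide.
    F statistics use the residual mean square; eta-squared is the effect's
    share of the total sum of squares.
    """
    _check_table(table)
    cells = table.groupby(["genotype", "rater_id"], observed=True).size()
    n_genotypes = table["genotype"].nunique()
    n_raters = table["rater_id"].nunique()
    if n_genotypes < 2 or n_raters < 2:
        raise DesignError("two-way analysis needs >= 2 genotypes and >= 2 raters")
    if len(cells) != n_genotypes * n_raters or cells.nunique() != 1:
        raise DesignError(
            "design is not balanced and fully crossed; cell counts:\n"
            f"{cells.to_string()}"
        )
    if int(cells.iloc[0]) < 2:
        raise DesignError("each genotype x rater cell needs n >= 2")

    values = table["percent"].to_numpy(dtype=float)
    ss_total_direct = float(((values - values.mean()) ** 2).sum())
    if ss_total_direct < 1e-12:
        # perfectly constant response: every effect is exactly zero
        df_g, df_r = n_genotypes - 1, n_raters - 1
        df_i = df_g * df_r
        df_res = len(table) - n_genotypes * n_raters
        out = pd.DataFrame(
            {
                "sum_sq": [0.0, 0.0, 0.0, 0.0],
                "df": [df_g, df_r, df_i, df_res],
                "F": [0.0, 0.0, 0.0, np.nan],
                "p": [1.0, 1.0, 1.0, np.nan],
                "eta_sq": [0.0, 0.0, 0.0, 0.0],
            },
            index=["genotype", "rater", "interaction", "residual"],
        )
        return AnovaResult(out)

    model = smf.ols(
        "percent ~ C(genotype) * C(rater_id)", data=table
    ).fit()
    aov = sm.stats.anova_lm(model, typ=2)
    rename = {
        "C(genotype)": "genotype",
        "C(rater_id)": "rater",
        "C(genotype):C(rater_id)": "interaction",
        "Residual": "residual",
    }
    aov = aov.rename(index=rename)
    ss_total = float(aov["sum_sq"].sum())
    out = pd.DataFrame(
        {
            "sum_sq": aov["sum_sq"],
            "df": aov["df"].astype(int),
            "F": aov["F"],
            "p": aov["PR(>F)"],
            "eta_sq": aov["sum_sq"] / ss_total,
        }
    )
    # internal consistency: effects + residual reconstruct the total SS
    if not np.isclose(ss_total, ss_total_direct, rtol=1e-8, atol=1e-10):
        raise AssertionError("sum-of-squares decomposition failed to close")
    return AnovaResult(out)


@dataclass(frozen=True)
class CorrMatrix:
    """Pairwise Pearson correlations between raters over shared sections.

    ``r`` is the symmetric rater x rater correlation matrix (diagonal 1; NaN
    where a rater has zero variance), ``n`` the per-pair section count,
    ``critical`` maps alpha to the two-tailed critical r at n - 2 degrees of
    freedom, and ``human_avg_vs_classifier`` is the correlation of the
    classifier column with the per-section arithmetic mean of all human
    raters (NaN when no classifier column is present).
    """

    r: pd.DataFrame
    n: pd.DataFrame
    critical: dict[float, float]
    human_avg_vs_classifier: float


def critical_r(alpha: float, df: int, tails: str = "two") -> float:
    """Critical Pearson r: ``t / sqrt(t^2 + df)`` at the Student-t quantile.

    ``df`` is n - 2. Strictly decreasing in df; increasing as alpha shrinks.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if df < 1:
        raise ValueError(f"df must be >= 1, got {df}")
    if tails == "two":
        t = sps.t.ppf(1.0 - alpha / 2.0, df)
    elif tails == "one":
        t = sps.t.ppf(1.0 - alpha, df)
    else:
        raise ValueError("tails must be 'one' or 'two'")
    return float(t / np.sqrt(t**2 + df))


def correlation_matrix(
    table: pd.DataFrame,
    by_genotype: bool = False,
    classifier_rater: str = "classifier",
    alphas: tuple[float, ...] = (0.05, 0.01),
) -> CorrMatrix | dict[str, CorrMatrix]:
    """Pairwise Pearson correlations over sections, pairing by section_id.

    With ``by_genotype=True`` returns one matrix per genotype. A rater column
    with zero variance yields NaN correlations for its pairs rather than an
    error. Critical values are two-tailed at the (common) pair df; when pair
    sizes differ the smallest pair df is used.
    """
    _check_table(table)
    if by_genotype:
        return {
            g: correlation_matrix(
                sub, by_genotype=False, classifier_rater=classifier_rater,
                alphas=alphas,
            )
            for g, sub in table.groupby("genotype", observed=True)
        }
    wide = table.pivot_table(
        index="section_id", columns="rater_id", values="percent", aggfunc="mean"
    )
    raters = list(wide.columns)
    k = len(raters)
    r = np.full((k, k), np.nan)
    n = np.zeros((k, k), dtype=int)
    for i in range(k):
        for j in range(i, k):
            pair = wide.iloc[:, [i, j]].dropna()
            n[i, j] = n[j, i] = len(pair)
            if i == j:
                r[i, j] = 1.0
                continue
            if len(pair) < 3:
                raise ValueError(
                    f"raters {raters[i]!r} and {raters[j]!r} share fewer than "
                    "3 sections"
                )
            x = pair.iloc[:, 0].to_numpy(dtype=float)
            y = pair.iloc[:, 1].to_numpy(dtype=float)
            if x.std() == 0 or y.std() == 0:
                continue  # undefined correlation stays NaN
            r[i, j] = r[j, i] = float(np.corrcoef(x, y)[0, 1])
    min_df = int(n[np.triu_indices(k, 1)].min()) - 2 if k > 1 else 1
    critical = {a: critical_r(a, max(min_df, 1)) for a in alphas}

    hvc = float("nan")
    humans = [c for c in raters if c != classifier_rater]
    if classifier_rater in raters and humans:
        sub = wide[humans + [classifier_rater]].dropna()
        avg = sub[humans].mean(axis=1).to_numpy(dtype=float)
        clf = sub[classifier_rater].to_numpy(dtype=float)
        if len(sub) >= 3 and avg.std() > 0 and clf.std() > 0:
            hvc = float(np.corrcoef(avg, clf)[0, 1])
    return CorrMatrix(
        r=pd.DataFrame(r, index=raters, columns=raters),
        n=pd.DataFrame(n, index=raters, columns=raters),
        critical=critical,
        human_avg_vs_classifier=hvc,
    )


def tukey_oneway(
    values: np.ndarray | pd.Series, groups: np.ndarray | pd.Series, alpha: float = 0.05
):
    """One-way ANOVA F test plus Tukey HSD pairwise comparisons.

    Returns ``(F, p, tukey)`` where ``tukey`` is the statsmodels
    ``TukeyHSDResults`` (its ``reject`` / ``pvalues`` attributes give the
    pairwise significance pattern).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    samples = [values[groups == g] for g in pd.unique(groups)]
    f_stat, p = sps.f_oneway(*samples)
    tukey = pairwise_tukeyhsd(values, groups, alpha=alpha)
    return float(f_stat), float(p), tukey


def validation_report(
    table: pd.DataFrame, classifier_rater: str = "classifier"
) -> str:
    """Plain-text validation report: sqrt-transform, two-way ANOVA, correlations."""
    transformed = sqrt_transform(table)
    anova = two_way_anova(transformed)
    overall = correlation_matrix(table, classifier_rater=classifier_rater)
    lines = [
        "Two-way ANOVA on square-root transformed percent vacuolation",
        anova.report(),
        "",
        "Pearson correlations (raw percent, pairing by section):",
        overall.r.round(3).to_string(),
        "",
    ]
    for a, rc in overall.critical.items():
        lines.append(f"critical r at p = {a:g}: {rc:.3f}")
    if not np.isnan(overall.human_avg_vs_classifier):
        lines.append(
            f"human average vs classifier: r = "
            f"{overall.human_avg_vs_classifier:.3f}"
        )
    return "\n".join(lines)
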
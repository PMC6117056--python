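"""Cohort-level statistics: normality-gated comparisons, correlations,
and p-value-gated bidirectional stepwise regression with standardized
coefficients.

Conventions follow common clinical-imaging practice: group summaries are
reported as median (25th, 75th percentile); the Shapiro-Wilk test gates the
choice between parametric and rank-based procedures; no multiple-testing
correction is applied by default (a Benjamini-Hochberg helper is provided).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "GroupComparison",
    "CorrelationResult",
    "RegressionReport",
    "compare_groups",
    "correlate",
    "stepwise_regression",
    "benjamini_hochberg",
]


@dataclass
class GroupComparison:
    variable: str
    summaries: dict  # group -> {n, median, q25, q75, mean, sd}
    test_used: str  # "t", "Mann-Whitney" or "degenerate"
    normality_p: dict  # group -> Shapiro-Wilk p
    statistic: float
    pvalue: float
    alpha_normality: float
    note: str = ""

    def to_dict(self) -> dict:
        return {
            "variable": self.variable,
            "summaries": self.summaries,
            "test_used": self.test_used,
            "normality_p": self.normality_p,
            "statistic": self.statistic,
            "pvalue": self.pvalue,
            "alpha_normality": self.alpha_normality,
            "note": self.note,
        }


@dataclass
class CorrelationResult:
    x: str
    y: str
    r: float
    pvalue: float
    method: str  # "pearson" or "spearman"
    n: int
    normality_p: dict

    def to_dict(self) -> dict:
        return {
            "x": self.x, "y": self.y, "r": self.r, "pvalue": self.pvalue,
            "method": self.method, "n": self.n, "normality_p": self.normality_p,
        }


def _summary(values: np.ndarray) -> dict:
    return {
        "n": int(values.size),
        "median": float(np.median(values)),
        "q25": float(np.percentile(values, 25)),
        "q75": float(np.percentile(values, 75)),
        "mean": float(values.mean()),
        "sd": float(values.std(ddof=1)) if values.size > 1 else 0.0,
    }


def compare_groups(
    table: pd.DataFrame,
    variable: str,
    alpha_normality: float = 0.05,
    group_col: str = "group",
    groups: tuple[str, str] = ("COPD", "control"),
    student: bool = False,
) -> GroupComparison:
    """Two-group comparison with a Shapiro-Wilk normality gate.

    If either group fails Shapiro-Wilk at ``alpha_normality`` the
    Mann-Whitney U test is used; otherwise a t-test (Welch-corrected by
    default; ``student`` forces the classic equal-variance form). A constant
    variable is reported as degenerate rather than tested.
    """
    samples = []
    for g in groups:
        v = pd.to_numeric(table.loc[table[group_col] == g, variable], errors="coerce")
        v = v.dropna().to_numpy(dtype=float)
        if v.size < 3:
            raise ValueError(f"group {g!r} has {v.size} values for {variable!r}; need >= 3")
        samples.append(v)
    a, b = samples
    summaries = {g: _summary(v) for g, v in zip(groups, samples)}
    if a.std() == 0.0 or b.std() == 0.0:
        return GroupComparison(
            variable=variable,
            summaries=summaries,
            test_used="degenerate",
            normality_p={g: float("nan") for g in groups},
            statistic=float("nan"),
            pvalue=float("nan"),
            alpha_normality=alpha_normality,
            note="constant variable in at least one group; no test performed",
        )
    norm_p = {g: float(sps.shapiro(v).pvalue) for g, v in zip(groups, samples)}
    if min(norm_p.values()) < alpha_normality:
        res = sps.mannwhitneyu(a, b, alternative="two-sided")
        test = "Mann-Whitney"
    else:
        res = sps.ttest_ind(a, b, equal_var=student)
        test = "t"
    return GroupComparison(
        variable=variable,
        summaries=summaries,
        test_used=test,
        normality_p=norm_p,
        statistic=float(res.statistic),
        pvalue=float(res.pvalue),
        alpha_normality=alpha_normality,
    )


def correlate(
    table: pd.DataFrame, x: str, y: str, alpha_normality: float = 0.05
) -> CorrelationResult:
    """Bivariate correlation: Pearson by default, Spearman when either
    variable fails the Shapiro-Wilk normality gate."""
    df = table[[x, y]].apply(pd.to_numeric, errors="coerce").dropna()
    if len(df) < 4:
        raise ValueError(f"need >= 4 complete pairs for {x!r} vs {y!r}, got {len(df)}")
    xv, yv = df[x].to_numpy(dtype=float), df[y].to_numpy(dtype=float)
    norm_p = {
        x: float(sps.shapiro(xv).pvalue),
        y: float(sps.shapiro(yv).pvalue),
    }
    if min(norm_p.values()) < alpha_normality:
        r, p = sps.spearmanr(xv, yv)
        method = "spearman"
    else:
        r, p = sps.pearsonr(xv, yv)
        method = "pearson"
    return CorrelationResult(
        x=x, y=y, r=float(r), pvalue=float(p), method=method, n=len(df), normality_p=norm_p
    )


# ---------------------------------------------------------------------------
# Stepwise regression


@dataclass
class RegressionReport:
    """Outcome of the stepwise selection: standardized coefficients of the
    selected variables, cumulative R-squared, and the selection trace."""

    outcome: str
    candidates: list[str]
    selected: dict  # variable -> {"beta": std beta, "pvalue": p in final model}
    unselected: dict  # variable -> {"pvalue": last-considered p}
    r_squared: float
    trace: list = field(default_factory=list)
    p_enter: float = 0.05
    p_remove: float = 0.10
    n: int = 0

    def to_frame(self) -> pd.DataFrame:
        """Table in the dash/p-value layout: one row per candidate."""
        rows = []
        for c in self.candidates:
            if c in self.selected:
                rows.append({"variable": c, "beta": self.selected[c]["beta"],
                             "pvalue": self.selected[c]["pvalue"], "selected": True})
            else:
                rows.append({"variable": c, "beta": float("nan"),
                             "pvalue": self.unselected.get(c, {}).get("pvalue", float("nan")),
                             "selected": False})
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "candidates": self.candidates,
            "selected": self.selected,
            "unselected": self.unselected,
            "r_squared": self.r_squared,
            "trace": self.trace,
            "p_enter": self.p_enter,
            "p_remove": self.p_remove,
            "n": self.n,
        }

    def summary(self) -> str:
        lines = [
            f"Stepwise regression: {self.outcome} ~ {{{', '.join(self.candidates)}}}"
            f"  (n={self.n}, p_enter={self.p_enter}, p_remove={self.p_remove})",
            f"{'variable':<14}{'std beta':>10}{'p-value':>12}",
        ]
        for row in self.to_frame().itertuples():
            beta = f"{row.beta:.3f}" if np.isfinite(row.beta) else "-"
            lines.append(f"{row.variable:<14}{beta:>10}{row.pvalue:>12.4g}")
        lines.append(f"cumulative R^2 = {self.r_squared:.3f}")
        return "\n".join(lines)


def _zscore(values: np.ndarray) -> np.ndarray:
    return (values - values.mean()) / values.std(ddof=1)


def stepwise_regression(
    table: pd.DataFrame,
    outcome: str,
    candidates: list[str],
    p_enter: float = 0.05,
    p_remove: float = 0.10,
    max_cond: float = 1e8,
) -> RegressionReport:
    """Bidirectional p-value-gated stepwise OLS with standardized betas.

    Forward step: add the candidate with the smallest partial p-value below
    ``p_enter``. Backward step: drop any included term whose p-value exceeds
    ``p_remove``. Iterate to a fixed point. All variables (outcome included)
    are z-scored, so reported coefficients are standardized betas; with a
    single selected predictor the beta equals the Pearson correlation.
    Candidates whose addition would make the design ill-conditioned
    (condition number above ``max_cond``) are skipped with a warning.
    """
    cols = [outcome] + list(candidates)
    df = table[cols].apply(pd.to_numeric, errors="coerce").dropna()
    n = len(df)
    if n <= len(candidates) + 2:
        raise ValueError(f"need n > {len(candidates) + 2} complete rows, got {n}")
    if df[outcome].std(ddof=1) == 0:
        raise ValueError("outcome has zero variance")
    skipped = set()
    for c in candidates:
        if df[c].std(ddof=1) == 0:
            warnings.warn(f"candidate {c!r} is constant; skipped", stacklevel=2)
            skipped.add(c)
    z = pd.DataFrame({c: _zscore(df[c].to_numpy(dtype=float)) for c in cols if c not in skipped})
    y = z[outcome].to_numpy()

    included: list[str] = []
    last_p: dict[str, float] = {}
    trace: list[dict] = []

    def fit(names: list[str]):
        X = sm.add_constant(z[names].to_numpy()) if names else np.ones((n, 1))
        return sm.OLS(y, X).fit()

    for _ in range(2 * len(candidates) + 10):
        changed = False
        # forward
        pool = [c for c in candidates if c not in included and c not in skipped]
        best_c, best_p = None, np.inf
        for c in pool:
            design = z[included + [c]].to_numpy()
            if np.linalg.cond(design) > max_cond:
                warnings.warn(f"candidate {c!r} is collinear with the current model; skipped",
                              stacklevel=2)
                skipped.add(c)
                continue
            res = fit(included + [c])
            p = float(res.pvalues[-1])
            last_p[c] = p
            if p < best_p:
                best_c, best_p = c, p
        if best_c is not None and best_p < p_enter:
            included.append(best_c)
            trace.append({"action": "add", "variable": best_c, "pvalue": best_p,
                          "r_squared": float(fit(included).rsquared)})
            changed = True
        # backward
        if included:
            res = fit(included)
            pv = dict(zip(included, res.pvalues[1:]))
            worst = max(pv, key=pv.get)
            if pv[worst] > p_remove:
                included.remove(worst)
                last_p[worst] = float(pv[worst])
                trace.append({"action": "remove", "variable": worst, "pvalue": float(pv[worst]),
                              "r_squared": float(fit(included).rsquared)})
                changed = True
        if not changed:
            break

    if included:
        final = fit(included)
        selected = {
            c: {"beta": float(final.params[i + 1]), "pvalue": float(final.pvalues[i + 1])}
            for i, c in enumerate(included)
        }
        r2 = float(final.rsquared)
    else:
        selected, r2 = {}, 0.0
    unselected = {
        c: {"pvalue": last_p.get(c, float("nan"))} for c in candidates if c not in selected
    }
    return RegressionReport(
        outcome=outcome,
        candidates=list(candidates),
        selected=selected,
        unselected=unselected,
        r_squared=r2,
        trace=trace,
        p_enter=p_enter,
        p_remove=p_remove,
        n=n,
    )


def benjamini_hochberg(pvalues: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """FDR-adjusted p-values (off by default everywhere; provided as an
    option for users who want multiplicity control)."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(np.asarray(pvalues, dtype=float), alpha=alpha, method="fdr_bh")[1]
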
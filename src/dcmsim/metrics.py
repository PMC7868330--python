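"""Recovery and classification metrics, tetrachoric validation, factorial ANOVA.

RMSE and bias for a single item parameter over R replications are

    RMSE = sqrt( sum_r (lambda - lambda_hat_r)^2 / R ),
    bias = sum_r (lambda - lambda_hat_r) / R,

i.e. bias is *true minus estimate*.  Condition-level summaries average these
per-parameter values over the items within each parameter family (intercept,
main, e, interaction).  Classification accuracy is the percentage of
respondents whose whole estimated attribute profile matches the truth.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import multivariate_normal, norm

from .models import ItemParams


def rmse(true_value: float, estimates) -> float:
    est = np.asarray(estimates, dtype=float)
    if est.size == 0:
        raise ValueError("need at least one estimate")
    return float(np.sqrt(np.mean((true_value - est) ** 2)))


def bias(true_value: float, estimates) -> float:
    est = np.asarray(estimates, dtype=float)
    if est.size == 0:
        raise ValueError("need at least one estimate")
    return float(np.mean(true_value - est))


def classification_accuracy(true_profiles, estimated_profiles) -> float:
    """Percent of respondents with an exact whole-profile match."""
    t = np.asarray(true_profiles)
    e = np.asarray(estimated_profiles)
    if t.shape != e.shape:
        raise ValueError("profile matrices must have equal shapes")
    return 100.0 * float(np.mean((t == e).all(axis=1)))


def parameter_errors(
    true_params: list[ItemParams], est_params: list[ItemParams]
) -> pd.DataFrame:
    """Per-parameter (item, term, family, true, estimate) rows for one fit."""
    rows = []
    for i, (tp, ep) in enumerate(zip(true_params, est_params, strict=True)):
        if tp.names != ep.names:
            raise ValueError(f"item {i + 1}: parameter structure mismatch")
        for name, fam, tv, ev in zip(tp.names, tp.families, tp.values, ep.values):
            rows.append(
                {"item": i + 1, "term": name, "family": fam,
                 "true": float(tv), "estimate": float(ev)}
            )
    return pd.DataFrame(rows)


def recovery_metrics(error_tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Family-level mean RMSE / mean bias across items, over replications.

    Each element of ``error_tables`` is one replication's parameter_errors
    output; RMSE and bias are computed per parameter over replications, then
    averaged over the parameters within each family.
    """
    if not error_tables:
        raise ValueError("need at least one replication")
    stacked = pd.concat(error_tables, ignore_index=True)
    per_param = (
        stacked.groupby(["item", "term", "family"])
        .apply(
            lambda g: pd.Series(
                {
                    "rmse": rmse(g["true"].iloc[0], g["estimate"]),
                    "bias": bias(g["true"].iloc[0], g["estimate"]),
                }
            ),
            include_groups=False,
        )
        .reset_index()
    )
    per_param["abs_bias"] = per_param["bias"].abs()
    fam = (
        per_param.groupby("family")[["rmse", "bias", "abs_bias"]]
        .mean()
        .rename(columns={"rmse": "mean_rmse", "bias": "mean_bias",
                         "abs_bias": "mean_abs_bias"})
        .reset_index()
    )
    return fam


def tetrachoric(table) -> float:
    """ML tetrachoric correlation from a 2x2 contingency table of counts.

    Thresholds are fixed at the sample margins; the correlation then solves
    the orthant-probability equation P(Z1 > t1, Z2 > t2; rho) = p11 by root
    finding.  Estimates are capped at +/-0.999 at the boundary.
    """
    from scipy.optimize import brentq

    tab = np.asarray(table, dtype=float)
    if tab.shape != (2, 2) or (tab < 0).any():
        raise ValueError("need a 2x2 table of nonnegative counts")
    n = tab.sum()
    if n <= 0 or (tab.sum(axis=0) <= 0).any() or (tab.sum(axis=1) <= 0).any():
        raise ValueError("all margins must be positive")
    p1 = tab[1].sum() / n  # P(var1 = 1)
    p2 = tab[:, 1].sum() / n
    p11 = tab[1, 1] / n
    t1, t2 = norm.ppf(1 - p1), norm.ppf(1 - p2)

    def orthant(rho):
        cov = np.array([[1.0, rho], [rho, 1.0]])
        cdf = multivariate_normal(mean=[0.0, 0.0], cov=cov).cdf([t1, t2])
        return 1 - norm.cdf(t1) - norm.cdf(t2) + cdf

    cap = 0.999
    lo, hi = orthant(-cap) - p11, orthant(cap) - p11
    if hi <= 0:
        return cap
    if lo >= 0:
        return -cap
    return float(brentq(lambda r: orthant(r) - p11, -cap, cap, xtol=1e-8))


def tetrachoric_from_binary(x, y) -> float:
    """Tetrachoric correlation of two binary vectors."""
    x = np.asarray(x).astype(int)
    y = np.asarray(y).astype(int)
    tab = np.zeros((2, 2))
    for i in (0, 1):
        for j in (0, 1):
            tab[i, j] = np.sum((x == i) & (y == j))
    return tetrachoric(tab)


def partial_eta_squared(
    summaries: pd.DataFrame,
    outcomes: list[str],
    factors: list[str],
) -> pd.DataFrame:
    """Factorial-ANOVA partial eta-squared per effect for each outcome column.

    Fits an OLS with all factor main effects and two-way interactions on the
    condition-level summaries (Type II sums of squares) and reports
    SS_effect / (SS_effect + SS_residual).  Factors with fewer than two
    distinct levels among the non-missing rows of an outcome (e.g. the model
    factor for interaction-parameter outcomes, which only mixed-model tests
    produce) are dropped for that outcome and reported as NaN.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    results = {}
    for outcome in outcomes:
        sub = summaries.dropna(subset=[outcome]).copy()
        active = [f for f in factors if sub[f].nunique() >= 2]
        if len(active) < 1 or len(sub) < 3:
            results[outcome] = {}
            continue
        if np.isclose(sub[outcome].std(), 0.0):
            # constant outcome: no effect explains anything
            results[outcome] = {f: 0.0 for f in active}
            continue
        terms = [f"C({f})" for f in active]
        levels = {f: sub[f].nunique() for f in active}
        df_main = 1 + sum(l - 1 for l in levels.values())
        df_inter = sum(
            (levels[a] - 1) * (levels[b] - 1)
            for i, a in enumerate(active)
            for b in active[i + 1:]
        )
        # keep two-way interactions only if residual degrees of freedom remain
        if len(sub) > df_main + df_inter:
            terms += [
                f"C({a}):C({b})"
                for i, a in enumerate(active)
                for b in active[i + 1:]
            ]
        formula = f"Q('{outcome}') ~ " + " + ".join(terms)
        fit = smf.ols(formula, data=sub).fit()
        anova = sm.stats.anova_lm(fit, typ=2)
        ss_resid = anova.loc["Residual", "sum_sq"]
        eta = {}
        for effect in anova.index:
            if effect == "Residual":
                continue
            ss = anova.loc[effect, "sum_sq"]
            key = effect.replace("C(", "").replace(")", "")
            eta[key] = ss / (ss + ss_resid) if ss + ss_resid > 0 else 0.0
        results[outcome] = eta
    all_effects = sorted({e for v in results.values() for e in v})
    out = pd.DataFrame(index=all_effects, columns=outcomes, dtype=float)
    for outcome, eta in results.items():
        for effect, val in eta.items():
            out.loc[effect, outcome] = val
    out.index.name = "effect"
    return out
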
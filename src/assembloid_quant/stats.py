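"""Group-comparison and dose-response statistics.

Implements the statistical layer used throughout the assembloid figures:
relative viability normalization, four-parameter-logistic (4PL) IC50
fitting, one-way ANOVA, and Dunnett / Tukey multiple-comparison families
with the usual significance-star tiers.

Dunnett's test follows the standard construction: per-comparison t
statistics against the control on the pooled error variance, with the
familywise adjustment from the joint multivariate-t distribution of the
comparisons (correlations determined by group sizes;
rho_ij = lambda_i * lambda_j with lambda_i = sqrt(n_i / (n_i + n_0))).
The box probability is evaluated with seeded quasi-Monte Carlo
(scipy.stats.multivariate_t), accurate to well under 1e-3.

Tukey's HSD uses the studentized range distribution on the pooled MSE.
Two-way ANOVA tables come from an OLS fit with type-II sums of squares
(the designs here are balanced, where types coincide).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .synthetic import four_param_logistic

_TIERS = [(0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*")]


def significance_tiers(p_values) -> list[str]:
    """Map (adjusted) p-values to star labels.

    Strict inequalities, matching the figure-legend convention
    "*p < 0.05": a boundary value falls in the weaker tier, so p = 0.05 is
    "ns".
    """
    arr = np.atleast_1d(np.asarray(p_values, dtype=float))
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    out = []
    for p in arr:
        label = "ns"
        for cut, stars in _TIERS:
            if p < cut:
                label = stars
                break
        out.append(label)
    return out


# --------------------------------------------------------------------------
# relative viability
# --------------------------------------------------------------------------

def relative_viability(
    raw: pd.DataFrame,
    untreated_label,
    treatment_col: str = "treatment",
    value_col: str = "viability",
    by: list[str] | None = None,
) -> pd.DataFrame:
    """Normalize measurements to the untreated-control mean.

    Each measurement is divided by the mean of the untreated arm within its
    plate/condition grouping (``by`` columns); the normalized untreated
    mean is 1 by construction.
    """
    df = raw.copy()
    group_iter = df.groupby(by, sort=False) if by else [(None, df)]
    rel = np.full(len(df), np.nan)
    for _, sub in group_iter:
        untreated = sub.loc[sub[treatment_col] == untreated_label, value_col]
        if len(untreated) == 0:
            raise ValueError(f"no untreated arm ({untreated_label!r}) present")
        m = untreated.mean()
        if not m > 0:
            raise ValueError("untreated mean must be > 0")
        rel[sub.index.to_numpy()] = sub[value_col].to_numpy() / m
    df["relative_viability"] = rel
    return df


# --------------------------------------------------------------------------
# 4PL dose-response
# --------------------------------------------------------------------------

class FitError(RuntimeError):
    """Dose-response fit could not produce a usable estimate."""


@dataclass
class DoseResponseFit:
    """Fitted 4PL parameters. At dose = ic50 the curve is (top+bottom)/2."""

    top: float
    bottom: float
    ic50: float
    hill: float
    std_errors: dict
    converged: bool
    flat: bool
    rss: float
    n_obs: int
    spans_transition: bool = True

    def predict(self, dose) -> np.ndarray:
        return four_param_logistic(np.asarray(dose, dtype=float),
                                   self.top, self.bottom, self.ic50, self.hill)


class FourParamLogisticModel:
    """Estimator-style wrapper around the 4PL fit.

    ``fit(doses, responses)`` stores ``top_``, ``bottom_``, ``ic50_``,
    ``hill_`` and ``result_``; ``predict(doses)`` evaluates the curve.
    """

    def __init__(self, n_starts: int = 5, seed: int = 0):
        self.n_starts = n_starts
        self.seed = seed

    def get_params(self, deep: bool = True) -> dict:
        return {"n_starts": self.n_starts, "seed": self.seed}

    def set_params(self, **params) -> "FourParamLogisticModel":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, doses, responses) -> "FourParamLogisticModel":
        self.result_ = fit_4pl(doses, responses, n_starts=self.n_starts)
        self.top_ = self.result_.top
        self.bottom_ = self.result_.bottom
        self.ic50_ = self.result_.ic50
        self.hill_ = self.result_.hill
        return self

    def predict(self, doses) -> np.ndarray:
        if not hasattr(self, "result_"):
            raise FitError("model is not fitted")
        return self.result_.predict(doses)


def fit_4pl(
    doses, responses, n_starts: int = 5, weighting: str = "relative"
) -> DoseResponseFit:
    """Least-squares 4PL fit on log10 dose with multi-start initialization.

    r(d) = bottom + (top - bottom) / (1 + (d / ic50)^hill), optimized over
    (top, bottom, log10 ic50, hill). Starts place the inflection at evenly
    spaced quantiles of the observed log-dose range to avoid local minima.
    Degenerate inputs yield diagnostics: constant responses -> flat fit
    with no IC50; an IC50 outside the dosed range is flagged as not
    spanning the transition.

    ``weighting="relative"`` (default) divides residuals by the model
    value, the maximum-likelihood weighting for luminescence viability
    readouts whose noise is proportional to the signal (constant CV);
    the divisor is floored at 5% of the response range so a zero bottom
    plateau cannot dominate the loss. ``weighting="none"`` fits absolute
    residuals.
    """
    if weighting not in ("relative", "none"):
        raise ValueError(f"unknown weighting {weighting!r}")
    d = np.asarray(doses, dtype=float)
    r = np.asarray(responses, dtype=float)
    if d.shape != r.shape:
        raise ValueError("doses and responses must have equal length")
    if np.any(d <= 0):
        raise ValueError("doses must be > 0")
    if np.any(r < 0):
        raise ValueError("responses must be >= 0")
    if len(np.unique(d)) < 4:
        raise FitError("need at least 4 distinct doses")
    if np.ptp(r) == 0 or np.ptp(r) < 1e-12 * max(1.0, abs(r.mean())):
        return DoseResponseFit(
            top=float(r.mean()), bottom=float(r.mean()), ic50=np.nan,
            hill=np.nan, std_errors={}, converged=False, flat=True,
            rss=0.0, n_obs=len(r),
        )

    logd = np.log10(d)

    def model(theta):
        top, bottom, log_ic50, hill = theta
        return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (logd - log_ic50)))

    scale_floor = 0.05 * float(np.ptp(r))

    def resid(theta):
        mu = model(theta)
        if weighting == "relative":
            return (mu - r) / np.maximum(np.abs(mu), scale_floor)
        return mu - r

    top0, bot0 = float(r.max()), float(r.min())
    quantiles = np.linspace(0.15, 0.85, n_starts)
    starts = []
    for q in quantiles:
        lq = np.quantile(logd, q)
        for hill0 in (1.0, 2.0):
            starts.append([top0, bot0, lq, hill0])

    best = None
    for x0 in starts:
        try:
            sol = optimize.least_squares(
                resid, x0=x0,
                bounds=([-np.inf, -np.inf, logd.min() - 3, 1e-3],
                        [np.inf, np.inf, logd.max() + 3, 50.0]),
            )
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not best.success:
        raise FitError("4PL fit failed to converge from any start")

    top, bottom, log_ic50, hill = best.x
    if top < bottom:  # canonical orientation: flip sign of hill
        top, bottom, hill = bottom, top, -hill
    ic50 = 10.0 ** log_ic50

    # covariance from the Jacobian at the optimum
    std = {}
    try:
        J = best.jac
        dof = max(len(r) - 4, 1)
        s2 = 2.0 * best.cost / dof
        cov = s2 * np.linalg.pinv(J.T @ J)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
        std = {"top": se[0], "bottom": se[1],
               "log10_ic50": se[2], "hill": se[3]}
    except Exception:  # pragma: no cover
        pass

    spans = bool(d.min() <= ic50 <= d.max())
    if not spans:
        warnings.warn(
            "fitted IC50 lies outside the dosed range; the doses do not "
            "span the transition", stacklevel=2,
        )
    return DoseResponseFit(
        top=float(top), bottom=float(bottom), ic50=float(ic50),
        hill=float(hill), std_errors=std, converged=True, flat=False,
        rss=float(2.0 * best.cost), n_obs=len(r), spans_transition=spans,
    )


# --------------------------------------------------------------------------
# ANOVA and multiple comparisons
# --------------------------------------------------------------------------

@dataclass
class ComparisonFamily:
    """Omnibus ANOVA plus a family of adjusted pairwise comparisons."""

    test: str
    omnibus: dict                       # factor -> {"F": ..., "p": ...}
    comparisons: pd.DataFrame           # contrast, estimate, t, p_unadj, p_adj, stars
    df_error: float
    mse: float
    notes: list[str] = field(default_factory=list)


def _group_arrays(groups) -> tuple[list, list[np.ndarray]]:
    if isinstance(groups, dict):
        labels = list(groups)
        arrays = [np.asarray(groups[k], dtype=float) for k in labels]
    else:
        labels = [f"g{i}" for i in range(len(groups))]
        arrays = [np.asarray(g, dtype=float) for g in groups]
    return labels, arrays


def one_way_anova(groups) -> tuple[float, float]:
    """Between/within sums-of-squares F test. Returns (F, p).

    Zero within-group variance with unequal means yields F = inf, p = 0.
    """
    _, arrays = _group_arrays(groups)
    if len(arrays) < 2:
        raise ValueError("need >= 2 groups")
    if any(len(a) < 2 for a in arrays):
        raise ValueError("each group needs n >= 2")
    all_vals = np.concatenate(arrays)
    grand = all_vals.mean()
    ss_between = sum(len(a) * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df_b = len(arrays) - 1
    df_w = len(all_vals) - len(arrays)
    if ss_within == 0:
        if ss_between == 0:
            return 0.0, 1.0
        return float("inf"), 0.0
    F = (ss_between / df_b) / (ss_within / df_w)
    p = float(stats.f.sf(F, df_b, df_w))
    return float(F), p


def _pooled_mse(arrays) -> tuple[float, float]:
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df = sum(len(a) for a in arrays) - len(arrays)
    return ss_within / df, float(df)


def _dunnett_box_prob(R: np.ndarray, df: float, limit: float,
                      seed: int = 12345) -> float:
    """P(max_j |T_j| <= limit) under the equicorrelated multivariate t."""
    k = R.shape[0]
    mvt = stats.multivariate_t(shape=R, df=df)
    return float(
        mvt.cdf(
            np.full(k, limit),
            lower_limit=np.full(k, -limit),
            random_state=np.random.default_rng(seed),
        )
    )


def dunnett(groups: dict, control_label, seed: int = 12345) -> ComparisonFamily:
    """Dunnett's many-to-one comparisons against a designated control.

    Two-sided; adjusted p_i = P(max_j |T_j| >= |t_i|) under the joint null
    multivariate-t with correlations from the group sizes. A two-group
    design reduces exactly to the pooled t-test.
    """
    if control_label not in groups:
        raise ValueError(f"control group {control_label!r} missing")
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    labels = [control_label] + [g for g in groups if g != control_label]
    arrays = [np.asarray(groups[g], dtype=float) for g in labels]
    mse, df = _pooled_mse(arrays)
    n0 = len(arrays[0])
    m0 = arrays[0].mean()
    ns = np.array([len(a) for a in arrays[1:]], dtype=float)
    lam = np.sqrt(ns / (ns + n0))
    R = np.outer(lam, lam)
    np.fill_diagonal(R, 1.0)

    rows = []
    for i, (lab, a) in enumerate(zip(labels[1:], arrays[1:])):
        est = a.mean() - m0
        se = np.sqrt(mse * (1.0 / len(a) + 1.0 / n0))
        t = est / se if se > 0 else (0.0 if est == 0 else np.inf)
        p_un = float(2.0 * stats.t.sf(abs(t), df)) if np.isfinite(t) else 0.0
        if len(labels) == 2:
            p_adj = p_un
        elif not np.isfinite(t):
            p_adj = 0.0
        elif t == 0:
            p_adj = 1.0
        else:
            p_adj = max(0.0, 1.0 - _dunnett_box_prob(R, df, abs(t), seed))
            p_adj = max(p_adj, p_un)  # familywise never below per-comparison
        rows.append({
            "contrast": f"{lab} - {control_label}",
            "estimate": est, "t": t, "p_unadj": p_un, "p_adj": min(p_adj, 1.0),
        })
    comp = pd.DataFrame(rows)
    comp["stars"] = significance_tiers(comp["p_adj"])
    F, p = one_way_anova({lab: arr for lab, arr in zip(labels, arrays)})
    return ComparisonFamily(
        test="one_way_dunnett",
        omnibus={"group": {"F": F, "p": p}},
        comparisons=comp, df_error=df, mse=mse,
    )


def tukey(groups: dict) -> ComparisonFamily:
    """Tukey HSD all-pairs comparisons via the studentized range.

    q = |t| * sqrt(2) on the pooled MSE; with two groups this reduces to
    the two-sided pooled t-test. Unbalanced designs use the
    Tukey-Kramer standard error.
    """
    labels, arrays = _group_arrays(groups)
    if len(arrays) < 2:
        raise ValueError("need >= 2 groups")
    mse, df = _pooled_mse(arrays)
    k = len(arrays)
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = arrays[i], arrays[j]
            est = b.mean() - a.mean()
            se = np.sqrt(mse * 0.5 * (1.0 / len(a) + 1.0 / len(b)))
            q = abs(est) / se if se > 0 else (0.0 if est == 0 else np.inf)
            if not np.isfinite(q):
                p_adj, p_un = 0.0, 0.0
            else:
                p_adj = float(stats.studentized_range.sf(q, k, df))
                t = q / np.sqrt(2.0)
                p_un = float(2.0 * stats.t.sf(t, df))
                p_adj = min(max(p_adj, p_un), 1.0)
            rows.append({
                "contrast": f"{labels[j]} - {labels[i]}",
                "estimate": est, "t": (q / np.sqrt(2.0)) if np.isfinite(q) else np.inf,
                "p_unadj": p_un, "p_adj": p_adj,
            })
    comp = pd.DataFrame(rows)
    comp["stars"] = significance_tiers(comp["p_adj"])
    F, p = one_way_anova(dict(zip(labels, arrays)))
    return ComparisonFamily(
        test="one_way_tukey",
        omnibus={"group": {"F": F, "p": p}},
        comparisons=comp, df_error=df, mse=mse,
    )


def two_way_anova_tukey(
    data: pd.DataFrame,
    factor_a: str,
    factor_b: str,
    value_col: str,
    tukey_on: str | None = None,
) -> ComparisonFamily:
    """Two-way ANOVA (type II) with Tukey comparisons on one factor.

    Requires every factor-level cell to be non-empty; replicates are needed
    for the interaction term. Tukey comparisons are computed between the
    marginal means of ``tukey_on`` (default ``factor_a``), using the
    residual MSE of the full two-way model.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    tukey_on = tukey_on or factor_a
    df = data.rename(columns={factor_a: "_A", factor_b: "_B",
                              value_col: "_y"}).copy()
    cells = df.groupby(["_A", "_B"]).size().unstack()
    if cells.isna().any().any():
        missing = [
            (a, b) for a in cells.index for b in cells.columns
            if pd.isna(cells.loc[a, b])
        ]
        raise ValueError(f"empty design cell(s): {missing}")
    counts = cells.to_numpy()
    if counts.min() != counts.max():
        warnings.warn(
            "unbalanced two-way design: using type II sums of squares",
            stacklevel=2,
        )
    model = smf.ols("_y ~ C(_A) * C(_B)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    omnibus = {
        factor_a: {"F": float(table.loc["C(_A)", "F"]),
                   "p": float(table.loc["C(_A)", "PR(>F)"])},
        factor_b: {"F": float(table.loc["C(_B)", "F"]),
                   "p": float(table.loc["C(_B)", "PR(>F)"])},
        "interaction": {"F": float(table.loc["C(_A):C(_B)", "F"]),
                        "p": float(table.loc["C(_A):C(_B)", "PR(>F)"])},
    }
    mse = float(table.loc["Residual", "sum_sq"] / table.loc["Residual", "df"])
    df_err = float(table.loc["Residual", "df"])

    col = "_A" if tukey_on == factor_a else "_B"
    levels = list(pd.unique(df[col]))
    k = len(levels)
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            a = df.loc[df[col] == levels[i], "_y"].to_numpy()
            b = df.loc[df[col] == levels[j], "_y"].to_numpy()
            est = b.mean() - a.mean()
            se = np.sqrt(mse * 0.5 * (1.0 / len(a) + 1.0 / len(b)))
            q = abs(est) / se if se > 0 else 0.0
            p_adj = float(stats.studentized_range.sf(q, k, df_err)) if q > 0 else 1.0
            p_un = float(2.0 * stats.t.sf(q / np.sqrt(2.0), df_err)) if q > 0 else 1.0
            rows.append({
                "contrast": f"{levels[j]} - {levels[i]}",
                "estimate": est, "t": q / np.sqrt(2.0),
                "p_unadj": p_un, "p_adj": min(max(p_adj, p_un), 1.0),
            })
    comp = pd.DataFrame(rows)
    comp["stars"] = significance_tiers(comp["p_adj"])
    return ComparisonFamily(
        test="two_way_tukey", omnibus=omnibus, comparisons=comp,
        df_error=df_err, mse=mse,
    )
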
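"""Group-level inference for delta-SUV tables and behavior.

Each animal contributes many delta-SUV records per region (one per coronal
slice and hemisphere), so group comparisons use a linear mixed model with
a fixed group effect and a random intercept per subject, fit by restricted
maximum likelihood.  The group effect is tested with an F statistic whose
denominator degrees of freedom are between-subject (``n_subjects - 2``),
the conservative choice for a two-group nested design.  Per-subject
summaries (mean delta-SUV, session freezing) are compared with the pooled
two-sample t test, and region-behavior coupling with ordinary Pearson
correlation.

No multiple-testing correction is applied across regions by default (raw
per-region p values are reported); pass the eight p values to
``holm_correction`` to adjust them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class LmmResult:
    group_effect_estimate: float
    se: float
    F_stat: float
    p_value: float
    group_means: dict[str, float]
    n_obs: int
    n_subjects: int
    df_denom: float
    method: str
    warnings: list[str]


@dataclass
class TTestResult:
    mean_a: float
    mean_b: float
    T_stat: float
    p_value: float
    df: int


@dataclass
class CorrelationResult:
    slope: float
    intercept: float
    pearson_r: float
    p_value: float
    n: int
    defined: bool = True


def t_test(a, b) -> TTestResult:
    """Two-sample pooled-variance (Student's) t test, two-sided.

    Degenerate zero-pooled-variance inputs return T = 0, p = 1 when the
    means are equal and T = +/-inf, p = 0 when they differ.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    df = a.size + b.size - 2
    sp2 = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / df
    diff = a.mean() - b.mean()
    if sp2 == 0.0:
        if diff == 0.0:
            return TTestResult(a.mean(), b.mean(), 0.0, 1.0, df)
        return TTestResult(a.mean(), b.mean(), float(np.sign(diff) * np.inf), 0.0, df)
    t = diff / np.sqrt(sp2 * (1.0 / a.size + 1.0 / b.size))
    p = 2.0 * sps.t.sf(abs(t), df)
    return TTestResult(float(a.mean()), float(b.mean()), float(t), float(p), df)


def lmm_group_test(
    delta: pd.DataFrame,
    labels: dict[str, str],
    group_order: tuple[str, str] = ("CON", "LS"),
    df_method: str = "between_subject",
) -> LmmResult:
    """Mixed-model group test for one region's delta-SUV records.

    Model: ``delta_suv ~ group`` with a random intercept per subject and
    record-level residual, fit by REML.  The group effect (second group
    minus first in ``group_order``) is tested with
    ``F = (estimate / se)^2`` against F(1, df) where df is
    ``n_subjects - 2`` (``df_method="between_subject"``, default) or
    ``n_obs - 2`` (``df_method="residual"``).

    When every subject contributes exactly one record the random intercept
    is unidentifiable; the model then reduces to its boundary limit, the
    pooled two-sample t test, and ``F = t^2`` exactly.
    """
    if df_method not in ("between_subject", "residual"):
        raise ValueError(f"unknown df_method {df_method!r}")
    df = delta.copy()
    df["group"] = df["subject"].map(labels)
    if df["group"].isna().any():
        missing = sorted(df.loc[df["group"].isna(), "subject"].unique())
        raise ValueError(f"subjects missing group labels: {missing}")
    df["g"] = (df["group"] == group_order[1]).astype(float)
    n_subjects = df["subject"].nunique()
    per_group = df.groupby("group")["subject"].nunique()
    for g in group_order:
        if per_group.get(g, 0) < 2:
            raise ValueError(f"need >= 2 subjects in group {g!r}")
    n_obs = len(df)
    df_denom = n_subjects - 2 if df_method == "between_subject" else n_obs - 2
    warns: list[str] = []

    max_per_subject = df.groupby("subject").size().max()
    if max_per_subject == 1:
        # random intercept unidentifiable: boundary limit == pooled t test
        a = df.loc[df["g"] == 0.0, "delta_suv"].to_numpy()
        b = df.loc[df["g"] == 1.0, "delta_suv"].to_numpy()
        tt = t_test(b, a)  # effect = group_order[1] - group_order[0]
        est = tt.mean_a - tt.mean_b
        se = est / tt.T_stat if tt.T_stat != 0 else np.nan
        F = tt.T_stat**2
        p = float(sps.f.sf(F, 1, df_denom)) if np.isfinite(F) else 0.0
        return LmmResult(
            group_effect_estimate=float(est),
            se=float(abs(se)) if np.isfinite(se) else float("nan"),
            F_stat=float(F),
            p_value=p,
            group_means={group_order[0]: tt.mean_b, group_order[1]: tt.mean_a},
            n_obs=n_obs,
            n_subjects=n_subjects,
            df_denom=df_denom,
            method="ols_degenerate",
            warnings=["single record per subject; random intercept dropped"],
        )

    import statsmodels.formula.api as smf
    from statsmodels.tools.sm_exceptions import ConvergenceWarning

    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            model = smf.mixedlm("delta_suv ~ g", df, groups=df["subject"])
            fit = model.fit(reml=True, method=["lbfgs", "powell"])
        for w in caught:
            if issubclass(w.category, (ConvergenceWarning, UserWarning, RuntimeWarning)):
                warns.append(str(w.message))
        sigma_e2 = float(fit.scale)
        sigma_b2 = float(np.asarray(fit.cov_re)[0, 0])
    except Exception as exc:  # REML optimizer failure on degenerate data
        warns.append(f"REML fit failed ({type(exc).__name__}); "
                     "components fixed at the boundary sigma_b^2 = 0")
        resid_within = df.groupby("subject")["delta_suv"].transform("mean")
        sigma_e2 = float(((df["delta_suv"] - resid_within) ** 2).sum()
                         / max(n_obs - n_subjects, 1))
        sigma_b2 = 0.0

    # REML variance components; the random-intercept variance may sit at
    # the boundary 0 (singular fit), which is kept with a warning.
    if sigma_b2 < 0 or not np.isfinite(sigma_b2):
        sigma_b2 = 0.0
    if sigma_b2 == 0.0:
        warns.append("between-subject variance at boundary 0")

    # Closed-form GLS for the fixed effects given the fitted components:
    # each subject's block V_i = sigma_e^2 I + sigma_b^2 J contributes
    # weight w_i = n_i / (sigma_e^2 + n_i sigma_b^2) on its mean.  This
    # avoids the numerically fragile Hessian-based covariance near the
    # boundary.  The standard error is scaled by the empirical weighted
    # between-subject residual variance rather than the plug-in
    # components — plug-in Wald errors are anticonservative when the
    # random-intercept variance is truncated at 0 — which makes the F
    # test reduce exactly to the subject-means t test under balance.
    per = df.groupby("subject").agg(n=("delta_suv", "size"),
                                    m=("delta_suv", "mean"),
                                    g=("g", "first"))
    w = per["n"] / (sigma_e2 + per["n"] * sigma_b2)
    g = per["g"]
    sw, swg, swgg = w.sum(), (w * g).sum(), (w * g * g).sum()
    swy, swgy = (w * per["m"]).sum(), (w * g * per["m"]).sum()
    det = sw * swgg - swg**2
    intercept = (swgg * swy - swg * swgy) / det
    est = (sw * swgy - swg * swy) / det
    resid = per["m"] - (intercept + est * g)
    phi = float((w * resid**2).sum()) / (n_subjects - 2)
    se = float(np.sqrt(phi * sw / det))
    F = (est / se) ** 2 if se > 0 else float("inf")
    p = float(sps.f.sf(F, 1, df_denom))
    return LmmResult(
        group_effect_estimate=float(est),
        se=se,
        F_stat=float(F),
        p_value=p,
        group_means={group_order[0]: float(intercept),
                     group_order[1]: float(intercept + est)},
        n_obs=n_obs,
        n_subjects=n_subjects,
        df_denom=df_denom,
        method="mixedlm_reml",
        warnings=warns,
    )


def region_behavior_correlation(x, y) -> CorrelationResult:
    """Pearson correlation and least-squares line of per-subject delta-SUV
    against per-subject percent freezing.

    Constant x or y makes r undefined; the result is returned with
    ``defined=False`` and NaN statistics rather than r = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        return CorrelationResult(
            slope=float("nan"), intercept=float("nan"), pearson_r=float("nan"),
            p_value=float("nan"), n=x.size, defined=False,
        )
    lr = sps.linregress(x, y)
    return CorrelationResult(
        slope=float(lr.slope),
        intercept=float(lr.intercept),
        pearson_r=float(lr.rvalue),
        p_value=float(lr.pvalue),
        n=int(x.size),
    )


def mann_whitney_u(a, b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U (utility; not used by any default report)."""
    res = sps.mannwhitneyu(a, b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def holm_correction(p_values: dict[str, float]) -> dict[str, float]:
    """Holm step-down adjustment of a region -> p mapping (optional)."""
    from statsmodels.stats.multitest import multipletests

    keys = list(p_values)
    _, adj, _, _ = multipletests([p_values[k] for k in keys], method="holm")
    return dict(zip(keys, (float(v) for v in adj)))
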
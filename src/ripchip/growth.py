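"""GFP-competition assay statistics.

The assay co-cultures transduced (GFP+) and untransduced cells; the GFP+
percentage is tracked for ~3 weeks, the first measurement (day 3 or 4) is
set to 1, and the analysis models the *relative percentage minus 1* with an
intercept-free mixed model: the only fixed effects are the
construct x day interaction terms (no intercept, no main effects, because
the response is identically 0 at baseline by construction), with a random
intercept per biological replicate.  The construct contrast is a Wald test
on the test-minus-control interaction terms, referred to an F distribution
with a residual-based denominator df for small-sample calibration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM

from .errors import ConfigError, DesignError, UsageError

SERIES_COLUMNS = ["construct", "replicate", "day", "gfp_pct"]


def normalize_series(raw: pd.DataFrame) -> pd.DataFrame:
    """Baseline-normalize GFP time courses.

    ``raw`` is long-format with columns construct, replicate, day, gfp_pct;
    per replicate the first measured day's value is set to 1
    (``relative_value``) and ``response = relative_value - 1``.  Days must be
    strictly increasing within each replicate as given.
    """
    missing = [c for c in SERIES_COLUMNS if c not in raw.columns]
    if missing:
        raise ConfigError(f"series table missing columns: {missing}")
    out = []
    for (construct, rep), sub in raw.groupby(["construct", "replicate"], sort=True):
        days = sub["day"].to_numpy()
        if len(days) < 2:
            raise ConfigError(f"replicate ({construct}, {rep}) has fewer than 2 time points")
        if not (np.diff(days) > 0).all():
            raise ConfigError(f"days not strictly increasing for replicate ({construct}, {rep})")
        baseline = float(sub["gfp_pct"].iloc[0])
        if baseline <= 0:
            raise ConfigError(f"zero/negative baseline GFP%% for replicate ({construct}, {rep})")
        sub = sub.copy()
        sub["relative_value"] = sub["gfp_pct"] / baseline
        sub["response"] = sub["relative_value"] - 1.0
        out.append(sub)
    return pd.concat(out, ignore_index=True)


@dataclass
class GrowthDesign:
    """Fixed-effect design for the intercept-free growth model."""

    X: pd.DataFrame  # rows align with `data`
    y: pd.Series  # response (relative value - 1)
    groups: pd.Series  # replicate grouping for the random intercept
    constructs: list[str]
    day_coding: str
    post_days: list[int]


def build_design(normalized: pd.DataFrame, day_coding: str = "categorical") -> GrowthDesign:
    """Build the fixed-effect matrix: construct x day interactions only.

    Categorical coding yields one indicator column per (construct,
    post-baseline day); linear coding yields one ``day - baseline_day``
    slope column per construct.  Baseline-day rows are retained with all-zero
    fixed-effect rows (their response is identically 0).
    """
    if day_coding not in ("categorical", "linear"):
        raise ConfigError(f"day_coding must be 'categorical' or 'linear', got {day_coding!r}")
    constructs = sorted(normalized["construct"].unique())
    if len(constructs) < 2:
        raise DesignError("at least two constructs are required for a contrast")
    for construct in constructs:
        if normalized.loc[normalized["construct"] == construct, "replicate"].nunique() < 2:
            raise DesignError(f"construct {construct!r} has fewer than 2 replicates")
    days = sorted(normalized["day"].unique())
    day0, post_days = days[0], days[1:]

    cols = {}
    if day_coding == "categorical":
        for construct in constructs:
            for d in post_days:
                cols[f"{construct}:day{d}"] = (
                    (normalized["construct"] == construct) & (normalized["day"] == d)
                ).astype(float)
    else:
        for construct in constructs:
            cols[f"{construct}:slope"] = np.where(
                normalized["construct"] == construct, normalized["day"] - day0, 0.0
            )
    X = pd.DataFrame(cols, index=normalized.index)
    groups = normalized["construct"].astype(str) + "/" + normalized["replicate"].astype(str)
    return GrowthDesign(
        X=X,
        y=normalized["response"],
        groups=groups,
        constructs=constructs,
        day_coding=day_coding,
        post_days=post_days,
    )


@dataclass
class GrowthFit:
    """Fitted growth model with the construct contrast.

    ``method`` records which inferential route produced the p-value:
    ``splitplot-exact`` (balanced categorical designs), ``reml-wald``
    (REML mixed model, F with containment df), or ``ols-wald`` (fallback
    when the random-intercept variance collapses).
    """

    params: pd.Series
    bse: pd.Series
    contrast_estimate: float  # mean test-minus-control difference (per-day slope if linear)
    wald_statistic: float
    df_num: int
    df_den: float
    p_value: float
    converged: bool
    method: str
    random_intercept_var: float

    @property
    def used_fallback_ols(self) -> bool:
        return self.method == "ols-wald"


def _contrast_matrix(design: GrowthDesign, test_construct: str, ref_construct: str) -> np.ndarray:
    names = list(design.X.columns)
    rows = []
    if design.day_coding == "categorical":
        for d in design.post_days:
            r = np.zeros(len(names))
            r[names.index(f"{test_construct}:day{d}")] = 1.0
            r[names.index(f"{ref_construct}:day{d}")] = -1.0
            rows.append(r)
    else:
        r = np.zeros(len(names))
        r[names.index(f"{test_construct}:slope")] = 1.0
        r[names.index(f"{ref_construct}:slope")] = -1.0
        rows.append(r)
    return np.vstack(rows)


def _splitplot_exact(
    normalized_rows: pd.DataFrame, design: GrowthDesign, test_construct: str, ref_construct: str
) -> GrowthFit | None:
    """Exact inference for balanced categorical designs.

    In the random-intercept model with a complete replicate x post-day grid,
    the joint construct x day Wald contrast splits into two independent
    exact F statistics: a between-replicate comparison of replicate means
    (df 1, g-2) and the classical split-plot interaction test on
    within-replicate deviations (df d-1, (g-2)(d-1)).  Their p-values are
    combined by Fisher's method, which is exact at every level under the
    model.  Returns None when the grid is incomplete or too small.
    """
    sub = normalized_rows[normalized_rows["construct"].isin([test_construct, ref_construct])]
    sub = sub[sub["day"].isin(design.post_days)]
    d = len(design.post_days)
    pivot = sub.pivot_table(index=["construct", "replicate"], columns="day", values="response")
    if pivot.isna().any().any() or pivot.shape[1] != d:
        return None
    g = len(pivot)
    arms = pivot.index.get_level_values("construct")
    r_test = int((arms == test_construct).sum())
    r_ref = int((arms == ref_construct).sum())
    if g - 2 < 1 or min(r_test, r_ref) < 2 or d < 2:
        return None

    values = pivot.to_numpy()  # g x d
    rep_means = values.mean(axis=1)
    arm_day_means = pivot.groupby(level="construct").mean()  # 2 x d
    cell_test = arm_day_means.loc[test_construct].to_numpy()
    cell_ref = arm_day_means.loc[ref_construct].to_numpy()
    delta = cell_test - cell_ref
    c = 1.0 / r_test + 1.0 / r_ref

    # between stratum: two-sample comparison of replicate means
    arm_mean_of_reps = {a: rep_means[arms == a].mean() for a in (test_construct, ref_construct)}
    ss_between = sum(
        ((rep_means[arms == a] - arm_mean_of_reps[a]) ** 2).sum()
        for a in (test_construct, ref_construct)
    )
    ms_between = d * ss_between / (g - 2)  # estimates sigma^2 + d*sigma_b^2
    delta_bar = float(delta.mean())
    if ms_between > 0:
        f_between = delta_bar**2 / (c * ms_between / d)
    else:  # noiseless data: any nonzero difference is infinitely significant
        f_between = 0.0 if abs(delta_bar) < 1e-12 else np.inf
    p_between = float(stats.f.sf(f_between, 1, g - 2))

    # within stratum: split-plot interaction on deviations from replicate means
    dev = values - rep_means[:, None]
    arm_dev_means = np.vstack(
        [dev[arms == a].mean(axis=0) for a in (test_construct, ref_construct)]
    )
    rss_within = sum(
        ((dev[arms == a] - arm_dev_means[i]) ** 2).sum()
        for i, a in enumerate((test_construct, ref_construct))
    )
    df_within = (g - 2) * (d - 1)
    ms_within = rss_within / df_within  # estimates sigma^2
    dev_delta = delta - delta_bar
    if ms_within > 0:
        f_within = float((dev_delta**2).sum() / c) / ((d - 1) * ms_within)
    else:
        f_within = 0.0 if float((dev_delta**2).sum()) < 1e-24 else np.inf
    p_within = float(stats.f.sf(f_within, d - 1, df_within))

    fisher = -2.0 * (np.log(max(p_between, 1e-300)) + np.log(max(p_within, 1e-300)))
    p_value = float(stats.chi2.sf(fisher, 4))

    sigma2 = ms_within
    sigma_b2 = max((ms_between - ms_within) / d, 0.0)
    # cell means are the (restricted) MLE fixed effects in the balanced case
    params, bse = {}, {}
    for construct, cells, r_arm in (
        (test_construct, cell_test, r_test),
        (ref_construct, cell_ref, r_ref),
    ):
        for j, day in enumerate(design.post_days):
            params[f"{construct}:day{day}"] = float(cells[j])
            bse[f"{construct}:day{day}"] = float(np.sqrt((sigma2 + sigma_b2) / r_arm))
    wald = float(f_between + (d - 1) * f_within)
    return GrowthFit(
        params=pd.Series(params).reindex(design.X.columns),
        bse=pd.Series(bse).reindex(design.X.columns),
        contrast_estimate=delta_bar,
        wald_statistic=wald,
        df_num=d,
        df_den=float(df_within),
        p_value=p_value,
        converged=True,
        method="splitplot-exact",
        random_intercept_var=sigma_b2,
    )


def fit_growth_model(
    design: GrowthDesign,
    test_construct: str | None = None,
    ref_construct: str | None = None,
    normalized: pd.DataFrame | None = None,
) -> GrowthFit:
    """Fit the intercept-free growth model and test the construct contrast.

    Balanced categorical designs (complete replicate x day grid) use the
    exact split-plot decomposition of the joint Wald contrast (see
    :func:`_splitplot_exact`); pass ``normalized`` (the output of
    :func:`normalize_series`) to enable it.  Other designs get a REML
    random-intercept fit whose Wald statistic is referred to F(q, ddf) with
    ``ddf = n_obs - rank(X) - n_groups`` (containment-style), falling back
    to ordinary least squares with a warning when the random-intercept
    variance estimate collapses to zero or the fit fails.
    """
    constructs = design.constructs
    if test_construct is None or ref_construct is None:
        if len(constructs) != 2:
            raise UsageError("test/ref constructs must be named when more than two are present")
        ref_construct, test_construct = constructs
        if "control" in constructs:
            ref_construct = "control"
            test_construct = next(c for c in constructs if c != "control")
    if test_construct == ref_construct:
        raise UsageError("test and reference constructs must differ")

    if design.day_coding == "categorical" and normalized is not None:
        exact = _splitplot_exact(normalized, design, test_construct, ref_construct)
        if exact is not None:
            return exact

    X_full = design.X.to_numpy()
    y_full = design.y.to_numpy(dtype=float)
    # Baseline-day rows are all-zero in X and identically 0 in y by
    # construction of the normalization; they carry no information and their
    # zero "residuals" would deflate the variance estimate, so the
    # likelihood is evaluated on the informative rows only.
    informative = X_full.any(axis=1)
    X = X_full[informative]
    y = y_full[informative]
    groups = design.groups[informative]
    n_obs, p = X.shape
    n_groups = groups.nunique()

    params = bse = None
    cov_params = None
    re_var = 0.0
    converged = True
    used_fallback = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model = MixedLM(y, X, groups=groups.to_numpy())
            result = model.fit(reml=True, method="lbfgs")
            re_var = float(np.asarray(result.cov_re).ravel()[0])
            converged = bool(result.converged)
            if converged and re_var > 1e-10:
                params = result.fe_params
                cov_params = np.asarray(result.cov_params())[:p, :p]
                bse = result.bse_fe
        except (np.linalg.LinAlgError, ValueError):
            converged = False

    if params is None:
        # random-effect variance at (or numerically indistinguishable from)
        # zero, or the REML fit failed: ordinary least squares on the same
        # fixed-effect design
        used_fallback = True
        warnings.warn("random-intercept variance ~0 or fit failed; using OLS fallback", stacklevel=2)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        dof = n_obs - p
        sigma2 = float(resid @ resid) / dof if dof > 0 else np.nan
        cov_params = sigma2 * np.linalg.pinv(X.T @ X)
        params = beta
        bse = np.sqrt(np.diag(cov_params))

    R = _contrast_matrix(design, test_construct, ref_construct)
    q = R.shape[0]
    rb = R @ np.asarray(params)
    middle = R @ cov_params @ R.T
    wald = float(rb @ np.linalg.solve(middle, rb))
    df_den = max(n_obs - p - (n_groups if not used_fallback else 0), 1)
    f_stat = wald / q
    p_value = float(stats.f.sf(f_stat, q, df_den))
    contrast_estimate = float(np.mean(rb)) if design.day_coding == "categorical" else float(rb[0])

    return GrowthFit(
        params=pd.Series(np.asarray(params), index=design.X.columns),
        bse=pd.Series(np.asarray(bse), index=design.X.columns),
        contrast_estimate=contrast_estimate,
        wald_statistic=wald,
        df_num=q,
        df_den=float(df_den),
        p_value=p_value,
        converged=converged,
        method="ols-wald" if used_fallback else "reml-wald",
        random_intercept_var=re_var,
    )


def analyze_growth(
    raw: pd.DataFrame,
    day_coding: str = "categorical",
    test_construct: str | None = None,
    ref_construct: str | None = None,
) -> GrowthFit:
    """Convenience wrapper: normalize -> design -> fit."""
    normalized = normalize_series(raw)
    design = build_design(normalized, day_coding=day_coding)
    return fit_growth_model(
        design, test_construct=test_construct, ref_construct=ref_construct, normalized=normalized
    )


def mann_whitney(
    group_a, group_b, alternative: str = "two_sided"
) -> tuple[float, float]:
    """Mann-Whitney U test between two independent groups.

    Uses the exact null distribution when the combined sample is small
    (n_a + n_b <= 16) and tie-free, otherwise the normal approximation with
    tie and continuity corrections.  ``alternative`` follows the convention
    that "greater" means group_a tends to exceed group_b.  Two identical
    groups yield U = n_a*n_b/2 and p = 1.
    """
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise UsageError("both groups must be non-empty")
    alt = {"two_sided": "two-sided", "greater": "greater", "less": "less"}.get(alternative)
    if alt is None:
        raise ConfigError(f"alternative must be two_sided/greater/less, got {alternative!r}")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:  # every value identical: maximally tied, no evidence
        return len(a) * len(b) / 2.0, 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(pooled) <= 16 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative=alt, method=method, use_continuity=True)
    return float(res.statistic), float(min(res.pvalue, 1.0))
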
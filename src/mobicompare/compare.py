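"""Statistical comparison of harmonised mobility series.

Four tools, mirroring how cross-source mobility studies are analysed:

* Pearson correlation with a two-sided t-test (small n: ~22 waves);
* OLS trend lines between two channels' relative changes — slope 1,
  intercept 0 is the "measures agree 1:1" reference case;
* a time-fixed-effects OLS on the long wave panel, where wave dummies
  absorb the common trend and channel x subgroup interactions quantify
  between-channel subgroup differences;
* a two-group, two-period difference-in-differences estimator for a
  lockdown effect, computed from cell means and cross-checkable against
  the OLS interaction coefficient.

Wave-level aggregates are treated as fixed observations; standard errors
do not propagate within-wave sampling noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .synthetic import ValidationError

__all__ = [
    "CorrelationResult",
    "TrendLine",
    "DiDResult",
    "pearson_correlation",
    "trend_line",
    "time_fe_regression",
    "did_estimate",
]


class DegenerateSeriesError(ValueError):
    """A series has zero variance (or too few pairs) for the statistic."""


@dataclass
class CorrelationResult:
    r: float
    n: int
    p_value: float
    label: str = ""

    def __str__(self) -> str:
        return f"{self.label or 'correlation'}: r = {self.r:.3f} (n = {self.n}, p = {self.p_value:.3g}, 2-sided)"


@dataclass
class TrendLine:
    slope: float
    intercept: float
    resid_se: float
    n: int


@dataclass
class DiDResult:
    effect: float
    se: float
    cell_means: pd.DataFrame
    n: int


def _pairwise_complete(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = pd.Series(x).astype(float).to_numpy()
    y = pd.Series(y).astype(float).to_numpy()
    if len(x) != len(y):
        raise ValidationError("x and y must have equal length")
    ok = ~(np.isnan(x) | np.isnan(y))
    return x[ok], y[ok]


def pearson_correlation(x, y, label: str = "") -> CorrelationResult:
    """Product-moment correlation on pairwise-complete observations.

    Two-sided p-value from t = r sqrt(n-2) / sqrt(1-r^2) on n-2 degrees
    of freedom; |r| = 1 reports p = 0.  Requires n >= 3 and positive
    variance in both series.
    """
    xv, yv = _pairwise_complete(x, y)
    n = len(xv)
    if n < 3:
        raise ValidationError(f"need at least 3 complete pairs, got {n}")
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        raise DegenerateSeriesError("correlation undefined: a series has zero variance")
    r, p = stats.pearsonr(xv, yv)
    if abs(r) >= 1.0 - 1e-12:  # numerically perfect linear relation
        p = 0.0
    return CorrelationResult(r=float(r), n=n, p_value=float(p), label=label)


def trend_line(x, y) -> TrendLine:
    """OLS fit of y on x with intercept; returns slope, intercept and the
    residual standard error."""
    xv, yv = _pairwise_complete(x, y)
    if len(xv) < 2:
        raise ValidationError("need at least 2 complete pairs")
    if np.ptp(xv) == 0:
        raise DegenerateSeriesError("trend line undefined: x is constant")
    X = sm.add_constant(xv)
    fit = sm.OLS(yv, X).fit()
    resid_se = float(np.sqrt(fit.scale)) if fit.df_resid > 0 else float("nan")
    return TrendLine(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        resid_se=resid_se,
        n=len(xv),
    )


def time_fe_regression(
    panel: pd.DataFrame,
    response_channel: str | None = None,
    reference_channel: str | None = None,
    response: str = "rel_change_pct",
):
    """Time-fixed-effects OLS on the long wave panel.

    Design: response ~ channel + subgroup + channel x subgroup + wave
    dummies, with reference levels (first channel, first subgroup, first
    wave) dropped.  Wave dummies absorb the common time trend; channel
    main effects and interactions measure level differences between
    channels overall and per subgroup.

    ``response_channel`` / ``reference_channel`` restrict the panel to
    those two channels (and to the subgroups both observe), with the
    reference channel as the dropped level; by default all channels and
    subgroups enter.

    Returns the fitted statsmodels results object (summary(), params,
    bse, ...).  Raises on < 2 waves, < 2 channels, or a rank-deficient
    design (listing aliased terms).
    """
    for col in ("channel", "subgroup", "wave", response):
        if col not in panel.columns:
            raise ValidationError(f"panel missing column '{col}'")
    data = panel.dropna(subset=[response]).copy()
    if (response_channel is None) != (reference_channel is None):
        raise ValidationError("give both response_channel and reference_channel, or neither")
    if response_channel is not None:
        data = data[data["channel"].isin([reference_channel, response_channel])]
        shared = set.intersection(
            *(set(g["subgroup"]) for _, g in data.groupby("channel"))
        ) if not data.empty else set()
        data = data[data["subgroup"].isin(shared)]
        order = [reference_channel, response_channel]
        data["channel"] = pd.Categorical(data["channel"], categories=order, ordered=True)
    if data["wave"].nunique() < 2:
        raise ValidationError("time-fixed effects need at least 2 waves")
    if data["channel"].nunique() < 2:
        raise ValidationError("need at least 2 channels to compare")
    terms = ["C(channel)"]
    if data["subgroup"].nunique() > 1:
        terms += ["C(subgroup)", "C(channel):C(subgroup)"]
    terms.append("C(wave)")
    formula = f"{response} ~ " + " + ".join(terms)
    model = smf.ols(formula, data=data)
    rank = np.linalg.matrix_rank(model.exog)
    if rank < model.exog.shape[1]:
        # identify aliased columns via pivoted QR on the design
        q, r_mat, piv = _qr_pivot(model.exog)
        aliased = [model.exog_names[i] for i in piv[rank:]]
        raise ValidationError(f"rank-deficient design; aliased terms: {aliased}")
    return model.fit()


def _qr_pivot(X):
    from scipy.linalg import qr

    q, r_mat, piv = qr(X, pivoting=True)
    return q, r_mat, piv


def did_estimate(
    panel: pd.DataFrame,
    group_col: str = "group",
    period_col: str = "period",
    value_col: str = "value",
    treated: str = "treated",
    control: str = "control",
    pre: str = "pre",
    post: str = "post",
) -> DiDResult:
    """Two-group, two-period difference-in-differences.

    effect = (mean treated post - mean treated pre)
           - (mean control post - mean control pre),
    identical to the interaction coefficient of the two-way OLS
    value ~ treated * post, from which the standard error is taken.
    Raises if any of the four group x period cells is empty (naming it).
    """
    for col in (group_col, period_col, value_col):
        if col not in panel.columns:
            raise ValidationError(f"panel missing column '{col}'")
    data = panel.dropna(subset=[value_col])
    cells = {}
    for g in (treated, control):
        for p in (pre, post):
            sel = data[(data[group_col] == g) & (data[period_col] == p)][value_col]
            if len(sel) == 0:
                raise ValidationError(f"empty DiD cell: group={g}, period={p}")
            cells[(g, p)] = sel
    effect = (cells[(treated, post)].mean() - cells[(treated, pre)].mean()) - (
        cells[(control, post)].mean() - cells[(control, pre)].mean()
    )
    d = data[data[group_col].isin([treated, control]) & data[period_col].isin([pre, post])]
    X = pd.DataFrame(
        {
            "const": 1.0,
            "treated": (d[group_col] == treated).astype(float),
            "post": (d[period_col] == post).astype(float),
        }
    )
    X["treated_post"] = X["treated"] * X["post"]
    fit = sm.OLS(d[value_col].to_numpy(), X.to_numpy()).fit()
    se = float(fit.bse[3]) if fit.df_resid > 0 else float("nan")
    means = (
        d.groupby([group_col, period_col])[value_col].mean().rename("mean").reset_index()
    )
    return DiDResult(effect=float(effect), se=se, cell_means=means, n=len(d))
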
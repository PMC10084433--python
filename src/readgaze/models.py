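"""Appraisal scale scoring and the statistical models.

Scale scoring: each appraisal construct (comprehensibility, interest) is
measured by three 7-point items; reverse-coded differentials are flipped
(x -> 8 - x), the scale score is the mean of the aligned items, and
internal consistency is summarized by Cronbach's alpha.

Modeling follows a two-step design. First a linear regression model with
bidirectional stepwise variable reduction (AIC criterion, starting from
the full main-effects model — the conventional behavior of R's stepAIC)
explains each appraisal from the screened eye-movement features; reported
are R^2 (percent), F with its degrees of freedom, and per-predictor
t-values. Second, the selected predictor set is held fixed and evaluated
by leave-one-out cross-validation: the coefficients are retrained on N-1
sessions for every held-out session, and predictive performance is
summarized by min-max normalized RMSE (denominator: range of the ACTUAL
response values) and Pearson's r between predictions and actuals.
Predictions are not clipped to the 1-7 response range.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.linalg import LinAlgError, cho_factor, cho_solve
from statsmodels.nonparametric.smoothers_lowess import lowess

from .simulate import ITEM_DEFINITIONS

ID_COLUMNS = ("participant", "article", "block", "presentation_order")
APPRAISALS = ("comprehensibility", "interest")


@dataclass(frozen=True)
class ScaleDefinition:
    construct: str
    items: tuple  # item column names
    reverse_coded: tuple  # parallel bool flags
    low: int = 1
    high: int = 7


DEFAULT_SCALES = tuple(
    ScaleDefinition(construct=construct,
                    items=tuple(name for name, _ in items),
                    reverse_coded=tuple(rev for _, rev in items))
    for construct, items in ITEM_DEFINITIONS.items())


def cronbach_alpha(items: np.ndarray) -> float:
    """alpha = k/(k-1) * (1 - sum of item variances / variance of item sum),
    with sample (n-1) variances; ``items`` is an n x k array of aligned
    (same-polarity) item scores."""
    x = np.asarray(items, dtype=float)
    k = x.shape[1]
    item_var = np.var(x, axis=0, ddof=1).sum()
    total_var = np.var(x.sum(axis=1), ddof=1)
    if total_var == 0:
        return float("nan")
    return float(k / (k - 1) * (1.0 - item_var / total_var))


def equicorrelated_alpha(k: int, rho: float) -> float:
    """Closed-form alpha of k items with equal pairwise correlation rho
    (the Spearman-Brown / standardized-alpha identity)."""
    return k * rho / (1.0 + (k - 1) * rho)


def score_scales(ratings: pd.DataFrame,
                 definitions: tuple = DEFAULT_SCALES):
    """Score the questionnaire scales.

    Reverse-coded items are flipped (x -> 8 - x) so higher always means
    more comprehensible / more interesting; the scale score is the mean of
    the three aligned items. Returns (scores table, Cronbach's alpha per
    construct). Out-of-range item values are an input error naming the row.
    """
    out = ratings[[c for c in ID_COLUMNS if c in ratings.columns]].copy()
    alphas: dict[str, float] = {}
    for sd in definitions:
        aligned = np.empty((len(ratings), len(sd.items)))
        for j, (item, rev) in enumerate(zip(sd.items, sd.reverse_coded)):
            v = ratings[item].to_numpy(float)
            bad = (v < sd.low) | (v > sd.high) | ~np.isfinite(v)
            if bad.any():
                raise ValueError(
                    f"item {item!r} out of range [{sd.low}, {sd.high}] "
                    f"at row {int(np.flatnonzero(bad)[0])}")
            aligned[:, j] = (sd.low + sd.high) - v if rev else v
        out[sd.construct] = aligned.mean(axis=1)
        alphas[sd.construct] = cronbach_alpha(aligned)
    return out, alphas


# ---------------------------------------------------------------------------
# Stepwise linear model


@dataclass
class StepwiseModel:
    response: str
    predictors: list
    coefficients: dict          # name -> beta (includes "const")
    t_values: dict              # name -> t
    r_squared_pct: float
    f_statistic: float
    df_model: int
    df_resid: int
    p_value: float
    aic: float
    n_obs: int
    criterion: str = "aic"
    direction: str = "bidirectional from full model"

    def to_dict(self) -> dict:
        return {
            "response": self.response,
            "predictors": list(self.predictors),
            "coefficients": {k: float(v)
                             for k, v in self.coefficients.items()},
            "t_values": {k: float(v) for k, v in self.t_values.items()},
            "r_squared_pct": float(self.r_squared_pct),
            "f_statistic": float(self.f_statistic),
            "df_model": int(self.df_model),
            "df_resid": int(self.df_resid),
            "p_value": float(self.p_value),
            "aic": float(self.aic),
            "n_obs": int(self.n_obs),
            "criterion": self.criterion,
            "direction": self.direction,
            "nrmse_convention": "RMSE / (max - min) of actual response",
        }


def candidate_predictors(table: pd.DataFrame, response: str) -> list[str]:
    """All numeric feature columns, excluding identifiers, the response,
    the other appraisal scale, and any questionnaire item columns (leakage
    guard)."""
    item_names = {name for items in ITEM_DEFINITIONS.values()
                  for name, _ in items}
    banned = set(ID_COLUMNS) | set(APPRAISALS) | item_names | {response}
    return [c for c in table.columns
            if c not in banned and pd.api.types.is_numeric_dtype(table[c])]


def _subset_rss(G: np.ndarray, g: np.ndarray, yy: float,
                subset: list[int]) -> float:
    if not subset:
        return yy
    idx = np.asarray(subset)
    try:
        cf = cho_factor(G[np.ix_(idx, idx)])
        b = cho_solve(cf, g[idx])
    except LinAlgError:
        return math.inf
    return max(float(yy - g[idx] @ b), 1e-12)


def fit_stepwise(table: pd.DataFrame, response: str,
                 predictors: list[str] | None = None,
                 max_steps: int = 1000) -> StepwiseModel:
    """Bidirectional stepwise linear regression minimizing AIC, started
    from the full main-effects model.

    At each step every single-predictor removal and re-addition is scored
    by AIC = n log(RSS/n) + 2(p + 2); the best strictly improving move is
    applied until none remains. The search runs on standardized copies of
    the predictors via their Gram matrix (numerically equivalent, much
    cheaper); the final model is refit on the original scale.
    """
    if predictors is None:
        predictors = candidate_predictors(table, response)
    if response in predictors:
        raise ValueError("response variable may not appear among predictors")
    other = set(APPRAISALS) - {response}
    if other & set(predictors):
        raise ValueError(f"appraisal column {other} may not be a predictor")
    y = table[response].to_numpy(float)
    n = len(y)
    # constant columns carry no information and break standardization
    sds = table[predictors].std(ddof=0)
    predictors = [p for p in predictors if sds[p] > 0]
    p_full = len(predictors)
    if n <= p_full + 1:
        raise ValueError(
            f"n = {n} observations cannot support {p_full} predictors; "
            "screen the table more aggressively")

    X = table[predictors].to_numpy(float)
    Xs = (X - X.mean(axis=0)) / X.std(axis=0)
    yc = y - y.mean()
    G = Xs.T @ Xs
    g = Xs.T @ yc
    yy = float(yc @ yc)

    def aic_of(subset: list[int]) -> float:
        rss = _subset_rss(G, g, yy, subset)
        if not math.isfinite(rss):
            return math.inf
        return n * math.log(rss / n) + 2.0 * (len(subset) + 2)

    current = list(range(p_full))
    current_aic = aic_of(current)
    for _ in range(max_steps):
        best_move, best_aic = None, current_aic
        in_set = set(current)
        for j in current:
            a = aic_of([k for k in current if k != j])
            if a < best_aic - 1e-9:
                best_move, best_aic = ("drop", j), a
        for j in range(p_full):
            if j not in in_set:
                a = aic_of(current + [j])
                if a < best_aic - 1e-9:
                    best_move, best_aic = ("add", j), a
        if best_move is None:
            break
        kind, j = best_move
        if kind == "drop":
            current.remove(j)
        else:
            current.append(j)
        current_aic = best_aic

    selected = [predictors[j] for j in sorted(current)]
    Xf = sm.add_constant(table[selected].to_numpy(float))
    fit = sm.OLS(y, Xf).fit()
    names = ["const"] + selected
    return StepwiseModel(
        response=response,
        predictors=selected,
        coefficients=dict(zip(names, fit.params)),
        t_values=dict(zip(names, fit.tvalues)),
        r_squared_pct=float(fit.rsquared * 100.0),
        f_statistic=float(fit.fvalue),
        df_model=int(fit.df_model),
        df_resid=int(fit.df_resid),
        p_value=float(fit.f_pvalue),
        aic=float(fit.aic),
        n_obs=n,
    )


# ---------------------------------------------------------------------------
# Leave-one-out cross-validation


@dataclass
class CVResult:
    response: str
    predictors: list
    predicted: np.ndarray
    actual: np.ndarray
    nrmse: float
    pearson_r: float
    flagged_folds: list = field(default_factory=list)


def loocv(table: pd.DataFrame, predictors: list[str],
          response: str) -> CVResult:
    """Leave-one-out cross-validation with a FIXED predictor set.

    Each of the N sessions is predicted by a model whose coefficients are
    retrained on the other N - 1 sessions (no variable reduction inside
    the loop). For ordinary least squares the N refits equal the exact
    hat-matrix identity pred_i = y_i - e_i / (1 - h_ii), which is what is
    computed; folds whose leverage makes the refit singular (h_ii ~ 1) are
    flagged and excluded from the summary statistics.

    nRMSE divides the RMSE by the range (max - min) of the actual
    response; Pearson's r is computed between predictions and actuals.
    """
    y = table[response].to_numpy(float)
    X = sm.add_constant(table[list(predictors)].to_numpy(float),
                        has_constant="add")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    XtX_inv = np.linalg.pinv(X.T @ X)
    h = np.einsum("ij,jk,ik->i", X, XtX_inv, X)
    flagged = np.flatnonzero(h >= 1.0 - 1e-8)
    with np.errstate(divide="ignore", invalid="ignore"):
        pred = y - resid / (1.0 - h)
    ok = h < 1.0 - 1e-8
    rng_y = float(y[ok].max() - y[ok].min())
    rmse = float(np.sqrt(np.mean((pred[ok] - y[ok]) ** 2)))
    nrmse = rmse / rng_y if rng_y > 0 else math.inf
    if np.std(pred[ok]) > 0 and np.std(y[ok]) > 0:
        r = float(stats.pearsonr(pred[ok], y[ok])[0])
    else:
        r = float("nan")
    return CVResult(response=response, predictors=list(predictors),
                    predicted=pred, actual=y, nrmse=nrmse, pearson_r=r,
                    flagged_folds=flagged.tolist())


# ---------------------------------------------------------------------------
# Correlation table and report


def _star(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def correlation_table(table: pd.DataFrame,
                      feature_cols: list[str] | None = None,
                      appraisals: tuple = APPRAISALS) -> pd.DataFrame:
    """Pearson r of every feature with every appraisal, with two-sided
    t-test p-values and significance stars at .001 / .01 / .05.

    No multiple-testing correction is applied (per-cell stars); the number
    of tests is len(features) x len(appraisals). Constant features yield
    NaN. Features are annotated with their normalization variant.
    """
    if feature_cols is None:
        feature_cols = [c for c in table.columns
                        if c not in ID_COLUMNS and c not in appraisals
                        and pd.api.types.is_numeric_dtype(table[c])]
    rows = []
    for feat in feature_cols:
        norm = ("participant" if feat.endswith("_a") else
                "participant_block" if feat.endswith("_b") else "raw")
        row: dict = {"feature": feat, "normalization": norm}
        x = table[feat].to_numpy(float)
        for app in appraisals:
            yv = table[app].to_numpy(float)
            m = np.isfinite(x) & np.isfinite(yv)
            if m.sum() < 3 or np.std(x[m]) == 0 or np.std(yv[m]) == 0:
                r, p = float("nan"), float("nan")
            else:
                r, p = stats.pearsonr(x[m], yv[m])
            row[f"r_{app}"] = float(r)
            row[f"p_{app}"] = float(p)
            row[f"stars_{app}"] = _star(p) if np.isfinite(p) else ""
        rows.append(row)
    return pd.DataFrame(rows)


def chance_level(n_levels: int) -> float:
    """Baseline accuracy (percent) of guessing on an n-level response:
    100/7 = 14.29% for a 7-point scale, 100/2 = 50.00% for a binary one."""
    if n_levels < 1:
        raise ValueError("n_levels must be >= 1")
    return 100.0 / n_levels


def _kde_grid(values: np.ndarray, grid: np.ndarray):
    if np.std(values) == 0:
        return np.full_like(grid, np.nan)
    return stats.gaussian_kde(values)(grid)


def prediction_report(cv: CVResult, span: float = 0.75,
                      out_png: str | None = None) -> dict:
    """Plot-ready predicted-vs-actual summary for one cross-validated model.

    Emits the point pairs, a locally weighted (lowess) trend of actual on
    predicted, 95% prediction intervals from the linear fit of actual on
    predicted, kernel-density margins for both axes, and the chance-level
    baselines for 7-point and binary response scales. When ``out_png`` is
    given a figure is also rendered.
    """
    ok = np.isfinite(cv.predicted)
    pred, act = cv.predicted[ok], cv.actual[ok]
    order = np.argsort(pred)
    trend = lowess(act, pred, frac=span, return_sorted=True)

    X = sm.add_constant(pred)
    fit = sm.OLS(act, X).fit()
    grid = np.linspace(pred.min(), pred.max(), 100)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        frame = fit.get_prediction(
            sm.add_constant(grid)).summary_frame(alpha=0.05)
    dens_grid = np.linspace(min(pred.min(), act.min()),
                            max(pred.max(), act.max()), 200)
    report = {
        "points": {"predicted": pred.tolist(), "actual": act.tolist()},
        "trend": {"x": trend[:, 0].tolist(), "y": trend[:, 1].tolist()},
        "interval": {"x": grid.tolist(),
                     "lower": frame["obs_ci_lower"].tolist(),
                     "upper": frame["obs_ci_upper"].tolist()},
        "density": {"grid": dens_grid.tolist(),
                    "predicted": _kde_grid(pred, dens_grid).tolist(),
                    "actual": _kde_grid(act, dens_grid).tolist()},
        "baselines_pct": {"seven_point": chance_level(7),
                          "binary": chance_level(2)},
        "nrmse": cv.nrmse,
        "pearson_r": cv.pearson_r,
        "span": span,
        "n": int(len(pred)),
        "sorted_order": order.tolist(),
    }
    if out_png is not None:
        _render_report(report, cv.response, out_png)
    return report


def _render_report(report: dict, response: str, out_png: str) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig = plt.figure(figsize=(6, 6))
    gs = fig.add_gridspec(2, 2, width_ratios=(5, 1), height_ratios=(1, 5),
                          wspace=0.04, hspace=0.04)
    ax = fig.add_subplot(gs[1, 0])
    ax_top = fig.add_subplot(gs[0, 0], sharex=ax)
    ax_right = fig.add_subplot(gs[1, 1], sharey=ax)
    pts = report["points"]
    ax.scatter(pts["predicted"], pts["actual"], s=8, alpha=0.4,
               color="#31688e", linewidths=0)
    ax.plot(report["trend"]["x"], report["trend"]["y"], color="#b40426")
    ax.fill_between(report["interval"]["x"], report["interval"]["lower"],
                    report["interval"]["upper"], alpha=0.15,
                    color="#b40426")
    ax.set_xlabel(f"predicted {response}")
    ax.set_ylabel(f"appraised {response}")
    d = report["density"]
    ax_top.fill_between(d["grid"], d["predicted"], alpha=0.4,
                        color="#31688e")
    ax_right.fill_betweenx(d["grid"], d["actual"], alpha=0.4,
                           color="#31688e")
    for a in (ax_top, ax_right):
        a.axis("off")
    ax.set_title(f"r = {report['pearson_r']:.3f}, "
                 f"nRMSE = {report['nrmse']:.3f}", fontsize=10, loc="left")
    fig.savefig(out_png, dpi=120, bbox_inches="tight")
    plt.close(fig)
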
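"""Mixed-model analysis of hyperparameter effects on nMMA / btMMA.

Cross-validation emits one metric value per (grid point, fold, inner
test pen).  Because pens — not sequences — are the independent unit,
the effect of each preprocessing / architecture factor is estimated
with a linear mixed-effects model: the metric as response, the factors
as categorical fixed effects, and a random intercept per test pen
(REML).  Factor significance is assessed with Wald F-tests on the fixed
effects, which coincide with Type-III tests on the balanced grids the
CV produces; post-hoc pairwise level contrasts use estimated marginal
means with Tukey (studentized-range) adjustment.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats

_LSTM_FACTORS = ("n_obs", "n_pc", "n_layers", "node_rule", "dropout")
_CNN_FACTORS = ("n_obs", "n_pc", "n_layers", "first_filters", "dropout")


@dataclass
class FittedLMEM:
    """A fitted mixed model plus the metadata the test tables need."""

    result: object                     # statsmodels MixedLMResults
    metric: str
    factors: tuple[str, ...]
    data: pd.DataFrame
    converged: bool
    used_reml: bool

    @property
    def ddf(self) -> int:
        """Residual-style denominator degrees of freedom."""
        return int(len(self.data) - self.result.k_fe)

    def group_variance(self) -> float:
        """Estimated variance of the pen random intercept."""
        return float(np.asarray(self.result.cov_re).ravel()[0])


def _prepare(results: pd.DataFrame, metric: str, family: str) -> tuple[pd.DataFrame, tuple[str, ...]]:
    df = results.copy()
    if "status" in df.columns:
        df = df[df["status"] == "ok"]
    if "family" in df.columns:
        df = df[df["family"] == family]
    if "test_pen_id" in df.columns:
        df = df[df["test_pen_id"] != "combined"]
    df = df.dropna(subset=[metric])
    factors = _LSTM_FACTORS if family == "lstm" else _CNN_FACTORS
    present = tuple(
        f for f in factors
        if f in df.columns and df[f].notna().any() and df[f].nunique() >= 2
    )
    for f in present:
        df[f] = df[f].astype(str)
    if df["test_pen_id"].nunique() < 2:
        raise ValueError("need at least two pens for a pen random effect")
    return df.reset_index(drop=True), present


def fit_lmem(results: pd.DataFrame, metric: str, family: str) -> FittedLMEM:
    """Fit metric ~ factors + (1 | test pen) by REML.

    Singular or non-converged REML fits are retried with ML and flagged
    via ``converged`` / ``used_reml``.
    """
    if metric not in ("nmma", "btmma"):
        raise ValueError("metric must be 'nmma' or 'btmma'")
    df, factors = _prepare(results, metric, family)
    if not factors:
        raise ValueError("no factor has at least two levels in these results")
    formula = f"{metric} ~ " + " + ".join(f"C({f})" for f in factors)
    used_reml = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, df, groups=df["test_pen_id"])
        result = model.fit(reml=True)
        converged = bool(result.converged)
        if not converged:
            used_reml = False
            result = model.fit(reml=False)
            converged = bool(result.converged)
            warnings.warn("REML fit did not converge; fell back to ML", stacklevel=2)
    return FittedLMEM(result, metric, factors, df, converged, used_reml)


def _factor_params(fitted: FittedLMEM, factor: str) -> list[str]:
    prefix = f"C({factor})["
    return [name for name in fitted.result.fe_params.index if name.startswith(prefix)]


def anova(fitted: FittedLMEM) -> pd.DataFrame:
    """Per-factor Wald F-table (SS, MS, DF, F, p).

    The F statistic for a factor with q level-contrast coefficients b
    and covariance V is ``F = b' V^{-1} b / q``; sums of squares are
    reported on the residual-variance scale (``SS = F * q * sigma^2``)
    so that MS / F / p carry the inferential content.
    """
    res = fitted.result
    beta = res.fe_params
    cov = res.cov_params().loc[beta.index, beta.index]
    sigma2 = float(res.scale)
    rows = []
    for factor in fitted.factors:
        names = _factor_params(fitted, factor)
        q = len(names)
        if q == 0:
            continue
        b = beta[names].to_numpy()
        V = cov.loc[names, names].to_numpy()
        f_stat = float(b @ np.linalg.solve(V, b) / q)
        p = float(stats.f.sf(f_stat, q, fitted.ddf))
        ss = f_stat * q * sigma2
        rows.append(
            {
                "factor": factor,
                "sum_sq": ss,
                "mean_sq": ss / q,
                "df": q,
                "F": f_stat,
                "p": p,
            }
        )
    return pd.DataFrame(rows)


def _emm_contrasts(fitted: FittedLMEM, factor: str) -> pd.DataFrame:
    """Pairwise level differences of estimated marginal means.

    With treatment coding and only main effects, the EMM difference
    between two levels equals the difference of their coefficients
    (the reference level's coefficient being 0).
    """
    res = fitted.result
    beta = res.fe_params
    cov = res.cov_params().loc[beta.index, beta.index]
    levels = sorted(fitted.data[factor].unique(), key=_level_sort_key)
    coef = {}
    var = {}
    names = {lvl: f"C({factor})[T.{lvl}]" for lvl in levels}
    for lvl in levels:
        if names[lvl] in beta.index:
            coef[lvl] = float(beta[names[lvl]])
        else:
            coef[lvl] = 0.0  # reference level
    rows = []
    for a, b in itertools.combinations(levels, 2):
        diff = coef[a] - coef[b]
        va = cov.loc[names[a], names[a]] if names[a] in beta.index else 0.0
        vb = cov.loc[names[b], names[b]] if names[b] in beta.index else 0.0
        vab = (
            cov.loc[names[a], names[b]]
            if names[a] in beta.index and names[b] in beta.index
            else 0.0
        )
        se = float(np.sqrt(max(va + vb - 2 * vab, 0.0)))
        rows.append({"level_a": a, "level_b": b, "estimate": diff, "se": se})
    out = pd.DataFrame(rows)
    out.attrs["k_levels"] = len(levels)
    return out


def _level_sort_key(level: str):
    try:
        return (0, float(level))
    except ValueError:
        return (1, level)


def posthoc(fitted: FittedLMEM, factor: str) -> pd.DataFrame:
    """Tukey-adjusted pairwise contrasts of a factor's marginal means.

    For ``n_pc`` the contrasts against the ``none`` level double as the
    comparisons versus the no-PCA baseline.
    """
    if factor not in fitted.factors:
        raise ValueError(f"factor {factor!r} not in the fitted model")
    table = _emm_contrasts(fitted, factor)
    k = table.attrs["k_levels"]
    if k < 2:
        raise ValueError(f"factor {factor!r} has fewer than two levels")
    ddf = fitted.ddf
    q_stat = np.sqrt(2.0) * np.abs(table["estimate"]) / table["se"].replace(0, np.nan)
    with np.errstate(invalid="ignore"):
        table["p_adj"] = stats.studentized_range.sf(q_stat.fillna(0.0), k, ddf)
    table.loc[table["se"] == 0, "p_adj"] = 1.0
    return table


def simulate_cv_table(
    seed: int,
    family: str = "lstm",
    pens: int = 8,
    effect_npc: float = 0.0,
    effect_threshold: int = 32,
    pen_sd: float = 0.01,
    resid_sd: float = 0.02,
    baseline: float = 0.6,
    n_obs_levels=(10, 20, 30),
    n_pc_levels=(4, 8, 16, 32, 64, 128, 256, 512, "none"),
    n_layers_levels=(1, 2, 3),
    width_levels=None,
    dropout_levels=(0.0, 0.2),
) -> pd.DataFrame:
    """Simulated CV-result table with a plantable n_pc effect.

    Each grid point contributes one row per pen (pens cycle through the
    folds as inner test pens).  ``effect_npc`` is added to the metric
    whenever the point's n_pc is >= ``effect_threshold`` (the no-PCA
    baseline counts as above threshold, since it keeps all components);
    all other factors are null.  Used to check that the LMEM machinery
    recovers planted effects and stays quiet on null factors.
    """
    rng = np.random.default_rng(seed)
    if width_levels is None:
        width_levels = ("mean", "half_mean", "sum") if family == "lstm" else (8, 16, 32, 64)
    width_col = "node_rule" if family == "lstm" else "first_filters"
    pen_ids = [str(i + 1) for i in range(pens)]
    pen_effect = dict(zip(pen_ids, rng.normal(0.0, pen_sd, pens)))
    rows = []
    for o, p, l, w, d in itertools.product(
        n_obs_levels, n_pc_levels, n_layers_levels, width_levels, dropout_levels
    ):
        lifted = effect_npc if (p == "none" or int(p) >= effect_threshold) else 0.0
        for pen in pen_ids:
            value = baseline + lifted + pen_effect[pen] + rng.normal(0.0, resid_sd)
            rows.append(
                {
                    "family": family,
                    "fold_id": (pen_ids.index(pen) // 2) + 1,
                    "test_pen_id": pen,
                    "n_obs": o,
                    "n_pc": p,
                    "n_layers": l,
                    width_col: w,
                    "dropout": d,
                    "nmma": value,
                    "btmma": value,
                    "status": "ok",
                }
            )
    return pd.DataFrame(rows)
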
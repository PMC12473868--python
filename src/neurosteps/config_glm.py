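"""Gamma GLM over configuration scores: effect sizes, fit check, selection.

The grid of per-configuration scores (median LOSO RMSE scaled to 1 s) is
positive and right-skewed, so the four design factors — sensor location,
filter band, window length, regressor type — are modelled with a
main-effects-only generalized linear model with a gamma distribution and log
link.  Coefficients exponentiate to multiplicative effects on the expected
RMSE relative to each factor's reference level (waist, wide band, medium
window, GB).  Short (0.5 s) windows are excluded before fitting: their score
distribution is bimodal and much worse, violating the gamma assumption.

Reporting mirrors the standard effect-size table: exp(β), 95 % CI on the exp
scale, p-value, and the predicted RMSE for each level with all other factors
held at reference.  Parameter importance is the percentage increase of the
worst level's predicted RMSE over the best level's within each factor.
Model fit is checked with a Kolmogorov–Smirnov test of quantile residuals
against the standard normal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .models import ConfigScore, SensorAnalysisConfig, scores_to_frame

#: Reference level per design factor.
DEFAULT_REFERENCES = {
    "location": "waist",
    "filter_band": "wide",
    "window_length": "medium",
    "regressor": "GB",
}

#: Window lengths are reported by name.
WINDOW_NAMES = {0.5: "short", 2.0: "medium", 5.0: "long"}
WINDOW_VALUES = {v: k for k, v in WINDOW_NAMES.items()}

_FACTORS = ("location", "filter_band", "window_length", "regressor")


@dataclass
class GlmSummary:
    """Effect-size table plus the fitted-model handle.

    ``table`` columns: parameter, level, effect_size, ci_low, ci_high,
    p_value, predicted_rmse, is_reference.  ``reference_rmse`` is the
    model-predicted RMSE with every factor at its reference.
    """

    table: pd.DataFrame
    reference_rmse: float
    references: dict[str, str]
    result: object | None = field(default=None, repr=False)

    @classmethod
    def from_effects(cls, reference_rmse: float, rows,
                     references: dict[str, str] | None = None) -> "GlmSummary":
        """Build a summary from externally given effect sizes.

        ``rows``: iterables of (parameter, level, effect_size, ci_low,
        ci_high, p_value).  Predicted RMSEs are reference_rmse × effect size.
        Useful for re-deriving reported quantities from a published table.
        """
        references = dict(references or DEFAULT_REFERENCES)
        recs = []
        for param, ref_level in references.items():
            recs.append(dict(parameter=param, level=ref_level, effect_size=1.0,
                             ci_low=np.nan, ci_high=np.nan, p_value=np.nan,
                             predicted_rmse=reference_rmse, is_reference=True))
        for param, level, eff, lo, hi, p in rows:
            recs.append(dict(parameter=param, level=level, effect_size=float(eff),
                             ci_low=float(lo), ci_high=float(hi), p_value=float(p),
                             predicted_rmse=reference_rmse * float(eff),
                             is_reference=False))
        return cls(table=pd.DataFrame(recs), reference_rmse=float(reference_rmse),
                   references=references)

    def to_csv(self, path) -> None:
        """Export the effect-size table (level, effect size, CI, p, RMSE)."""
        self.table.to_csv(path, index=False)


def _prepare_frame(scores, exclude_short: bool) -> pd.DataFrame:
    if isinstance(scores, pd.DataFrame):
        df = scores.copy()
    else:
        df = scores_to_frame(list(scores))
    df["window_length"] = [WINDOW_NAMES.get(float(w), str(w)) for w in df["window_length"]]
    if exclude_short:
        df = df[df["window_length"] != "short"].reset_index(drop=True)
    if (df["rmse_per_s"] <= 0).any():
        raise ValueError("gamma GLM requires strictly positive RMSE outcomes")
    return df


def fit_config_glm(scores, references: dict[str, str] | None = None,
                   exclude_short: bool = True) -> GlmSummary:
    """Fit the main-effects gamma GLM (log link) to configuration scores.

    ``scores`` may be a list of :class:`ConfigScore` or a data frame with
    columns location, filter_band, window_length, regressor, rmse_per_s.
    Factors with a single observed level are dropped from the design (their
    reference is retained downstream).
    """
    references = dict(references or DEFAULT_REFERENCES)
    df = _prepare_frame(scores, exclude_short)
    if len(df) < 3:
        raise ValueError("too few configuration scores to fit the GLM")

    terms = []
    active = []
    for factor in _FACTORS:
        levels = df[factor].astype(str).unique()
        if len(levels) < 2:
            continue
        ref = references[factor]
        if ref not in levels:
            raise ValueError(f"reference level {ref!r} absent for factor {factor!r}")
        terms.append(f"C({factor}, Treatment(reference='{ref}'))")
        active.append(factor)
    if not terms:
        raise ValueError("no factor varies across the provided scores")

    formula = "rmse_per_s ~ " + " + ".join(terms)
    df = df.copy()
    df[[c for c in _FACTORS]] = df[[c for c in _FACTORS]].astype(str)
    model = smf.glm(formula, data=df,
                    family=sm.families.Gamma(link=sm.families.links.Log()))
    rank = np.linalg.matrix_rank(model.exog)
    if rank < model.exog.shape[1]:
        _, _, piv = scipy.linalg.qr(model.exog, pivoting=True)
        aliased = [model.exog_names[i] for i in piv[rank:]]
        raise ValueError(f"rank-deficient design; aliased term(s): {aliased}")
    result = model.fit()

    conf = result.conf_int()
    reference_rmse = float(np.exp(result.params["Intercept"]))
    recs = []
    for factor in _FACTORS:
        ref = references[factor]
        recs.append(dict(parameter=factor, level=ref, effect_size=1.0,
                         ci_low=np.nan, ci_high=np.nan, p_value=np.nan,
                         predicted_rmse=reference_rmse, is_reference=True))
        if factor not in active:
            continue
        prefix = f"C({factor}, Treatment(reference='{ref}'))[T."
        for name in result.params.index:
            if name.startswith(prefix):
                level = name[len(prefix):-1]
                beta = float(result.params[name])
                recs.append(dict(
                    parameter=factor, level=level,
                    effect_size=float(np.exp(beta)),
                    ci_low=float(np.exp(conf.loc[name, 0])),
                    ci_high=float(np.exp(conf.loc[name, 1])),
                    p_value=float(result.pvalues[name]),
                    predicted_rmse=float(np.exp(result.params["Intercept"] + beta)),
                    is_reference=False,
                ))
    return GlmSummary(table=pd.DataFrame(recs), reference_rmse=reference_rmse,
                      references=references, result=result)


def residual_fit_test(fit) -> tuple[float, float]:
    """Kolmogorov–Smirnov check of gamma quantile residuals vs N(0, 1).

    Quantile residuals map each observation through its fitted gamma CDF
    (shape 1/φ with φ the deviance-based dispersion, scale μφ) and then
    through the standard-normal quantile function; under a correct model they
    are standard normal.  Returns (KS statistic, p-value).
    """
    result = fit.result if isinstance(fit, GlmSummary) else fit
    if result is None:
        raise ValueError("summary holds no fitted model")
    y = np.asarray(result.model.endog, dtype=float)
    mu = np.asarray(result.fittedvalues, dtype=float)
    if result.df_resid < 1 or y.size < 2:
        raise ValueError("residual test undefined for fewer than 2 residuals")
    dispersion = result.deviance / result.df_resid
    shape = 1.0 / dispersion
    u = scipy.stats.gamma.cdf(y, a=shape, scale=mu / shape)
    eps = 1e-12
    residuals = scipy.stats.norm.ppf(np.clip(u, eps, 1 - eps))
    stat, p = scipy.stats.kstest(residuals, "norm")
    return float(stat), float(p)


@dataclass(frozen=True)
class ImportanceReport:
    """Worst-vs-best predicted RMSE per factor, as percentage increase."""

    rows: pd.DataFrame  # parameter, worst_level, best_level, pct_increase


def importance_report(summary: GlmSummary) -> ImportanceReport:
    """Worst/best levels per factor and the % by which worst exceeds best.

    The reference level participates with effect size 1.0.  The ratio of
    effect sizes equals the ratio of predicted RMSEs, so the report is
    invariant to rescaling all scores.
    """
    recs = []
    for factor, grp in summary.table.groupby("parameter", sort=False):
        worst = grp.loc[grp["effect_size"].idxmax()]
        best = grp.loc[grp["effect_size"].idxmin()]
        pct = (worst["effect_size"] / best["effect_size"] - 1.0) * 100.0
        recs.append(dict(parameter=factor, worst_level=worst["level"],
                         best_level=best["level"], pct_increase=float(pct)))
    return ImportanceReport(rows=pd.DataFrame(recs))


def select_optimal_config(summary: GlmSummary, alpha: float = 0.05) -> SensorAnalysisConfig:
    """Pick the per-factor level for the final algorithm.

    Within each factor, only levels *significantly better* than the reference
    (p < α and effect size < 1) are eligible; among those the lowest
    predicted RMSE wins, otherwise the reference is retained.
    """
    chosen: dict[str, str] = {}
    for factor in _FACTORS:
        ref = summary.references[factor]
        grp = summary.table[summary.table["parameter"] == factor]
        better = grp[(~grp["is_reference"])
                     & (grp["p_value"] < alpha)
                     & (grp["effect_size"] < 1.0)]
        if len(better):
            chosen[factor] = str(better.loc[better["predicted_rmse"].idxmin(), "level"])
        else:
            chosen[factor] = ref
    return SensorAnalysisConfig(
        location=chosen["location"],
        filter_band=chosen["filter_band"],
        window_length=WINDOW_VALUES[chosen["window_length"]],
        regressor=chosen["regressor"],
    )
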
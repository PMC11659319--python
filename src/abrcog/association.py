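"""Linear association suite: univariate and age-adjusted OLS with diagnostics.

Convention used throughout (matching the reporting scale of the underlying
study design): cognition outcomes are composite / domain z-scores, age and
PTA enter in raw units (years, dB HL) so their slopes read "z per year" and
"z per dB", and ABR predictors are z-scored against the analyzed sample so
their slopes read "z per z". Age adjustment means adding age (years) as a
covariate. Group comparisons use a one-way general linear model with
post-hoc pairwise contrasts under Bonferroni correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.diagnostic import het_white, linear_reset
from statsmodels.stats.outliers_influence import variance_inflation_factor
from statsmodels.stats.stattools import jarque_bera

from .schema import COGNITIVE_MEASURES, COMPOSITE_COLUMN, InputError, ModelError, z_column

#: the study's own sample-size rule: >= 10 observations per independent variable
MIN_OBS_PER_IV = 10

#: default ABR predictors of the suite (z-scored before fitting)
ABR_PREDICTORS = (
    "wave_i_latency",
    "wave_i_amplitude",
    "wave_v_latency",
    "wave_v_amplitude",
    "iv_latency_difference",
    "log_vi_amplitude_ratio",
)

DIAG_ALPHA = 0.05  # warn threshold for diagnostic p-values
VIF_WARN = 10.0


@dataclass(frozen=True)
class RegressionSpec:
    """One model: ``outcome ~ predictor (+ covariates)``.

    ``standardize`` lists variables to z-score against the *full* table
    before any subsetting, so subgroup fits reuse full-sample z units.
    ``subset`` is an optional pandas query string.
    """

    outcome: str
    predictor: str
    covariates: tuple[str, ...] = ()
    standardize: tuple[str, ...] = ()
    subset: str | None = None

    def __post_init__(self) -> None:
        if self.outcome == self.predictor:
            raise InputError("outcome and predictor must differ")
        if self.outcome in self.covariates:
            raise InputError("covariates must exclude the outcome")


@dataclass
class RegressionResult:
    """Slope of the named predictor with t-based CI and two-sided p."""

    B: float
    ci95: tuple[float, float]
    p: float
    n: int
    spec: RegressionSpec
    diagnostics: dict = field(default_factory=dict)
    fit: object | None = None  # statsmodels results, kept for diagnostics


def _zscore(x: pd.Series) -> pd.Series:
    sd = x.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        raise ModelError(f"cannot z-score constant column '{x.name}'")
    return (x - x.mean()) / sd


def fit_linear_model(table: pd.DataFrame, spec: RegressionSpec) -> RegressionResult:
    """OLS fit of ``spec`` returning B, 95% CI and p for the predictor."""
    cols = [spec.outcome, spec.predictor, *spec.covariates]
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ModelError(f"table lacks columns {missing}")
    work = table[cols].apply(pd.to_numeric, errors="coerce").copy()
    for col in spec.standardize:
        if col in work.columns:
            work[col] = _zscore(work[col])
    if spec.subset is not None:
        work = work.loc[table.query(spec.subset).index.intersection(work.index)]
    work = work.dropna()
    n = len(work)
    n_iv = 1 + len(spec.covariates)
    if n < MIN_OBS_PER_IV * n_iv:
        raise ModelError(
            f"n={n} below the {MIN_OBS_PER_IV}-observations-per-IV rule for {n_iv} IVs"
        )
    X = sm.add_constant(work[[spec.predictor, *spec.covariates]], has_constant="add")
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ModelError(f"rank-deficient design for {spec.outcome} ~ {list(X.columns)[1:]}")
    fit = sm.OLS(work[spec.outcome], X).fit()
    ci = fit.conf_int(alpha=0.05).loc[spec.predictor]
    return RegressionResult(
        B=float(fit.params[spec.predictor]),
        ci95=(float(ci[0]), float(ci[1])),
        p=float(fit.pvalues[spec.predictor]),
        n=n,
        spec=spec,
        diagnostics=model_diagnostics(fit),
        fit=fit,
    )


def model_diagnostics(fit) -> dict:
    """Normality, heteroscedasticity, linearity and collinearity summaries.

    Jarque–Bera on residuals, White's test, Ramsey RESET (powers 2–3) and
    per-predictor variance inflation factors, each with a pass/warn status.
    Diagnostics are surfaced, never used to auto-reject a model.
    """
    out: dict = {}
    resid = fit.resid
    exog = np.asarray(fit.model.exog, dtype=float)

    jb_stat, jb_p, _, _ = jarque_bera(resid)
    out["normality"] = {
        "stat": float(jb_stat),
        "p": float(jb_p),
        "status": "pass" if jb_p > DIAG_ALPHA else "warn",
    }
    try:
        w_stat, w_p, _, _ = het_white(resid, exog)
        out["heteroscedasticity"] = {
            "stat": float(w_stat),
            "p": float(w_p),
            "status": "pass" if w_p > DIAG_ALPHA else "warn",
        }
    except (ValueError, np.linalg.LinAlgError):
        out["heteroscedasticity"] = {"stat": np.nan, "p": np.nan, "status": "unavailable"}
    try:
        reset = linear_reset(fit, power=3, use_f=True)
        out["linearity"] = {
            "stat": float(reset.statistic),
            "p": float(reset.pvalue),
            "status": "pass" if reset.pvalue > DIAG_ALPHA else "warn",
        }
    except (ValueError, np.linalg.LinAlgError):
        out["linearity"] = {"stat": np.nan, "p": np.nan, "status": "unavailable"}

    names = list(fit.model.exog_names)
    vifs: dict[str, float] = {}
    if exog.shape[1] > 2:  # const + >=2 predictors; single-predictor VIF is 1
        with np.errstate(divide="ignore", invalid="ignore"):
            for j, name in enumerate(names):
                if name == "const":
                    continue
                vifs[name] = float(variance_inflation_factor(exog, j))
    else:
        vifs = {name: 1.0 for name in names if name != "const"}
    worst = max(vifs.values()) if vifs else 1.0
    out["vif"] = {
        "values": vifs,
        "status": "pass" if worst < VIF_WARN else "warn",
    }
    return out


def run_association_suite(
    scored: pd.DataFrame,
    outcomes: Sequence[str] | None = None,
    predictors: Sequence[str] | None = None,
    subgroups: bool = True,
) -> pd.DataFrame:
    """Tidy table of every association model (one row per fit).

    For each outcome (composite + 10 domain z-scores by default) and each
    predictor (age, PTA, hearing category, the ABR features): a univariate
    fit and an age-adjusted fit, on the full sample and — when ``subgroups``
    — within each age group. Errors are recorded per row and the suite
    continues.
    """
    if outcomes is None:
        outcomes = [COMPOSITE_COLUMN] + [
            z_column(m) for m in COGNITIVE_MEASURES if z_column(m) in scored.columns
        ]
    if predictors is None:
        predictors = ["age", "pta"] + [p for p in ABR_PREDICTORS if p in scored.columns]
        if "hearing_category" in scored.columns:
            scored = scored.copy()
            scored["hearing_loss_binary"] = (
                scored["hearing_category"].eq("hearing loss").astype(float)
            )
            predictors.append("hearing_loss_binary")

    subsets: list[tuple[str, str | None]] = [("full", None)]
    if subgroups and "age_group" in scored.columns:
        for g in scored["age_group"].dropna().unique():
            subsets.append((str(g), f"age_group == '{g}'"))

    rows = []
    for outcome in outcomes:
        for predictor in predictors:
            std = (predictor,) if predictor in ABR_PREDICTORS else ()
            for adjusted in (False, True):
                if adjusted and predictor == "age":
                    continue
                covs = ("age",) if adjusted else ()
                for subset_name, query in subsets:
                    spec = RegressionSpec(
                        outcome=outcome,
                        predictor=predictor,
                        covariates=covs,
                        standardize=std,
                        subset=query,
                    )
                    row = {
                        "model_id": f"{outcome}~{predictor}"
                        + ("+age" if adjusted else "")
                        + f"|{subset_name}",
                        "outcome": outcome,
                        "predictor": predictor,
                        "covariates": "+".join(covs),
                        "subgroup": subset_name,
                    }
                    try:
                        res = fit_linear_model(scored, spec)
                        diag = res.diagnostics
                        row.update(
                            n=res.n,
                            B=res.B,
                            ci_low=res.ci95[0],
                            ci_high=res.ci95[1],
                            p=res.p,
                            normality=diag["normality"]["status"],
                            heteroscedasticity=diag["heteroscedasticity"]["status"],
                            linearity=diag["linearity"]["status"],
                            vif=diag["vif"]["status"],
                            error="",
                        )
                    except (ModelError, InputError) as exc:
                        row.update(
                            n=np.nan, B=np.nan, ci_low=np.nan, ci_high=np.nan, p=np.nan,
                            normality="", heteroscedasticity="", linearity="", vif="",
                            error=str(exc),
                        )
                    rows.append(row)
    return pd.DataFrame(rows)


def compare_age_groups(
    scored: pd.DataFrame, outcome: str, group_col: str = "age_group"
) -> dict:
    """One-way group GLM: overall F/p plus Bonferroni-adjusted pairwise contrasts.

    Pairwise contrasts use the pooled residual variance of the one-way
    model; p-values are multiplied by the number of comparisons (capped
    at 1).
    """
    work = scored[[outcome, group_col]].dropna()
    groups = [g for g, _ in work.groupby(group_col, observed=True)]
    counts = work.groupby(group_col, observed=True).size()
    if len(groups) < 2 or (counts < 2).any():
        raise InputError("need >= 2 groups with >= 2 members each")

    dummies = pd.get_dummies(work[group_col], drop_first=True, dtype=float)
    X = sm.add_constant(dummies)
    fit = sm.OLS(work[outcome].astype(float), X).fit()
    f_stat, f_p = float(fit.fvalue), float(fit.f_pvalue)

    from scipy import stats

    mse = float(fit.mse_resid)
    df_resid = int(fit.df_resid)
    means = work.groupby(group_col, observed=True)[outcome].mean()
    m = len(groups) * (len(groups) - 1) // 2
    pairwise = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            a, b = groups[i], groups[j]
            diff = float(means[a] - means[b])
            se = float(np.sqrt(mse * (1.0 / counts[a] + 1.0 / counts[b])))
            if se == 0:
                t = 0.0 if diff == 0 else np.inf
            else:
                t = diff / se
            p_raw = 2.0 * stats.t.sf(abs(t), df_resid) if np.isfinite(t) else 0.0
            pairwise.append(
                {
                    "group_a": a,
                    "group_b": b,
                    "mean_difference": diff,
                    "t": float(t),
                    "p_bonferroni": min(p_raw * m, 1.0),
                }
            )
    return {"F": f_stat, "p": f_p, "df": (len(groups) - 1, df_resid), "pairwise": pairwise}
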
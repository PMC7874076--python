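"""Behavioral statistics on turn-level measures.

Each acoustic measure is z-scored within speaker over all of that speaker's
turns in all debates, then modeled with a linear mixed-effects model with
fixed effects of AGREE (yes/no) and BINS (first three vs. last three turns;
middle turns excluded) and by-speaker random intercepts and slopes — no
interaction term.  A one-sided paired t-test (H1: disagree > agree) compares
matched turns, and a mixed-effects logistic regression predicts debate
agreement from the four z-scored measures simultaneously with random
intercepts by speaker.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.genmod.bayes_mixed_glm import BinomialBayesMixedGLM

__all__ = [
    "MEASURES",
    "zscore_by_speaker",
    "LmmResult",
    "fit_lmm",
    "paired_onesided_ttest",
    "LogisticResult",
    "fit_mixed_logistic",
    "simulate_lmm_cohort",
    "simulate_logistic_cohort",
]

MEASURES = ("SYLR", "MF0", "RF0", "ASE")


def zscore_by_speaker(
    data: pd.DataFrame,
    measures: tuple[str, ...] = MEASURES,
    speaker_col: str = "speaker",
) -> pd.DataFrame:
    """Add ``z<measure>`` columns: per speaker, (x - mean) / SD pooled over
    all that speaker's turns in all debates (sample SD, n-1).

    Speakers with zero variance on a measure get missing z-values.
    """
    out = data.copy()
    for m in measures:
        def _z(x: pd.Series) -> pd.Series:
            sd = x.std(ddof=1)
            if not np.isfinite(sd) or sd == 0:
                return pd.Series(np.nan, index=x.index)
            return (x - x.mean()) / sd

        out[f"z{m}"] = data.groupby(speaker_col, group_keys=False)[m].apply(_z)
    return out


@dataclass
class LmmResult:
    """Mixed-model summary: one row per fixed-effect term."""

    response: str
    terms: pd.DataFrame  # index term; columns coef, se, t, df, p
    converged: bool
    df_method: str  # "residual" (Satterthwaite unavailable -> flagged approximate)
    random_structure: str
    n_obs: int
    warnings: list[str] = field(default_factory=list)

    def coef(self, term: str) -> float:
        return float(self.terms.loc[term, "coef"])

    def tvalue(self, term: str) -> float:
        return float(self.terms.loc[term, "t"])


def _prepare_lmm_frame(data: pd.DataFrame, response: str) -> pd.DataFrame:
    df = data.copy()
    if "bin" in df.columns:
        df = df[df["bin"].isin(["FIRST3", "LAST3"])].copy()
        df["TURNS_LAST3"] = (df["bin"] == "LAST3").astype(float)
    if "condition" in df.columns and "AGREE_NO" not in df.columns:
        df["AGREE_NO"] = (df["condition"] == "disagree").astype(float)
    df = df.dropna(subset=[response])
    return df


def fit_lmm(
    data: pd.DataFrame,
    response: str,
    fixed: tuple[str, ...] = ("AGREE_NO", "TURNS_LAST3"),
    group_col: str = "speaker",
    random_slopes: bool = True,
) -> LmmResult:
    """REML fit of ``response ~ AGREE_NO + TURNS_LAST3`` with by-speaker
    random intercepts and slopes.

    t statistics use residual degrees of freedom (n - rank), flagged as an
    approximation since a Satterthwaite correction is not available here; on
    non-convergence the random structure is simplified to intercept-only and
    the result flagged.
    """
    df = _prepare_lmm_frame(data, response)
    speakers = df[group_col].nunique()
    if speakers < 5:
        raise ValueError(f"need at least 5 speakers, got {speakers}")
    formula = f"{response} ~ " + " + ".join(fixed)
    notes: list[str] = []

    def _try(re_formula: str | None):
        try:
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                model = smf.mixedlm(formula, df, groups=df[group_col],
                                    re_formula=re_formula)
                fit = model.fit(reml=True, method=["lbfgs", "powell"])
            msgs = [str(w.message) for w in caught]
            return fit, msgs
        except (np.linalg.LinAlgError, ValueError) as exc:
            return None, [f"mixed fit failed: {exc}"]

    attempts = []
    if random_slopes:
        attempts.append(("~" + " + ".join(fixed), "intercept+slopes"))
    attempts.append((None, "intercept" if not random_slopes else "intercept (fallback)"))

    fit = None
    structure = "none"
    converged = False
    for re_formula, label in attempts:
        fit, msgs = _try(re_formula)
        notes.extend(
            m for m in msgs
            if "Convergence" in m or "singular" in m.lower() or "failed" in m
        )
        if fit is not None and fit.converged:
            structure = label
            converged = True
            break
        if fit is not None:
            structure = label
            notes.append(f"{label}: did not converge")
        fit = fit if fit is not None else None

    n = len(df)
    dof = n - (len(fixed) + 1)
    term_names = ["Intercept", *fixed]
    if fit is not None:
        params = {t: fit.params[t] for t in term_names}
        bses = {t: fit.bse[t] for t in term_names}
    else:
        # final fallback: pooled OLS, flagged -- mixed machinery unusable
        ols = smf.ols(formula, df).fit()
        params = {t: ols.params[t] for t in term_names}
        bses = {t: ols.bse[t] for t in term_names}
        structure = "none (OLS fallback)"
        notes.append("mixed model unusable; pooled OLS estimates reported")
    rows = []
    for term in term_names:
        coef = params[term]
        se = bses[term]
        tval = coef / se if se > 0 else 0.0
        rows.append(
            {"term": term, "coef": coef, "se": se, "t": tval, "df": dof,
             "p": 2 * stats.t.sf(abs(tval), dof)}
        )
    terms = pd.DataFrame(rows).set_index("term")
    return LmmResult(
        response=response,
        terms=terms,
        converged=converged,
        df_method="residual",
        random_structure=structure,
        n_obs=n,
        warnings=notes,
    )


def paired_onesided_ttest(
    disagree: np.ndarray, agree: np.ndarray
) -> tuple[float, int, float]:
    """One-sided paired t-test of H1: disagree > agree on matched turns.

    Returns (t, df, p).  Degenerate zero-variance differences are reported as
    p -> 0 (or 1) according to the sign of the constant difference.
    """
    d = np.asarray(disagree, dtype=float) - np.asarray(agree, dtype=float)
    d = d[np.isfinite(d)]
    if d.size == 0:
        raise ValueError("no complete pairs")
    n = d.size
    sd = d.std(ddof=1) if n > 1 else 0.0
    if sd == 0:
        if d.mean() == 0:
            return 0.0, n - 1, 0.5
        return (np.inf if d.mean() > 0 else -np.inf), n - 1, (0.0 if d.mean() > 0 else 1.0)
    t = d.mean() / (sd / np.sqrt(n))
    return float(t), n - 1, float(stats.t.sf(t, n - 1))


@dataclass
class LogisticResult:
    """Mixed logistic regression of debate condition on the z-measures."""

    terms: pd.DataFrame  # index covariate; columns coef, se, z, p, odds_ratio
    random_intercept_sd: float
    method: str  # "vb" | "penalized-logit"
    converged: bool

    def odds_ratio(self, term: str) -> float:
        return float(self.terms.loc[term, "odds_ratio"])


def fit_mixed_logistic(
    data: pd.DataFrame,
    covariates: tuple[str, ...] = ("zSYLR", "zMF0", "zRF0", "zASE"),
    response: str = "AGREE_NO",
    group_col: str = "speaker",
) -> LogisticResult:
    """Predict disagreement from the four z-measures simultaneously, with
    random intercepts by speaker (variational Bayes fit).

    Falls back to an L2-penalized plain logistic regression (flagged) when
    the mixed fit fails, e.g. under complete separation.
    """
    df = data.dropna(subset=[response, *covariates]).copy()
    y = df[response].astype(float)
    if y.nunique() < 2:
        raise ValueError("both outcome classes must be present")
    formula = f"{response} ~ " + " + ".join(covariates)
    try:
        model = BinomialBayesMixedGLM.from_formula(
            formula, {"speaker_re": f"0 + C({group_col})"}, df
        )
        fit = model.fit_vb()
        names = list(fit.model.exog_names)
        coefs = fit.fe_mean
        ses = fit.fe_sd
        re_sd = float(np.exp(fit.vcp_mean[0])) if len(fit.vcp_mean) else 0.0
        method = "vb"
        converged = True
    except Exception:  # pragma: no cover - separation / numerical failure
        mat = sm.add_constant(df[list(covariates)])
        fit = sm.Logit(y, mat).fit_regularized(alpha=1.0, disp=False)
        names = list(mat.columns)
        coefs = np.asarray(fit.params)
        # crude SEs from the unpenalized information matrix
        p = 1 / (1 + np.exp(-(mat @ fit.params)))
        W = np.diag(p * (1 - p))
        cov = np.linalg.pinv(mat.T @ W @ mat)
        ses = np.sqrt(np.diag(cov))
        re_sd = 0.0
        method = "penalized-logit"
        converged = False
    rows = []
    for name, c, s in zip(names, coefs, ses):
        z = c / s if s > 0 else 0.0
        rows.append(
            {"term": name, "coef": c, "se": s, "z": z,
             "p": 2 * stats.norm.sf(abs(z)), "odds_ratio": float(np.exp(c))}
        )
    terms = pd.DataFrame(rows).set_index("term")
    return LogisticResult(terms=terms, random_intercept_sd=re_sd,
                          method=method, converged=converged)


# ---------------------------------------------------------------------------
# Simulators for parameter-recovery studies
# ---------------------------------------------------------------------------

def simulate_lmm_cohort(
    n_speakers: int = 36,
    n_turns: int = 24,
    agree_effect: float = 0.4,
    last3_effect: float = -0.2,
    intercept_sd: float = 0.3,
    slope_sd: float = 0.1,
    resid_sd: float = 1.0,
    seed: int = 0,
    response: str = "zASE",
) -> pd.DataFrame:
    """Turn-level data drawn from the LMM's own generative model (balanced
    conditions and bins; by-speaker random intercepts and AGREE slopes)."""
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_speakers):
        b0 = rng.normal(0, intercept_sd)
        b1 = rng.normal(0, slope_sd)
        for k in range(n_turns):
            agree_no = float(k % 2)
            last3 = float((k // 2) % 2)
            y = (b0 + (agree_effect + b1) * agree_no + last3_effect * last3
                 + rng.normal(0, resid_sd))
            rows.append(
                {"speaker": f"s{s:02d}", "AGREE_NO": agree_no,
                 "TURNS_LAST3": last3, response: y}
            )
    return pd.DataFrame(rows)


def simulate_logistic_cohort(
    n_speakers: int = 36,
    n_turns: int = 24,
    beta_zase: float = float(np.log(1.6)),
    intercept_sd: float = 0.3,
    seed: int = 0,
) -> pd.DataFrame:
    """Turn-level data from the mixed-logistic generative model: condition
    labels drawn from logit(p) = b_zASE * zASE + speaker intercept."""
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_speakers):
        b0 = rng.normal(0, intercept_sd)
        z = rng.standard_normal((n_turns, 4))
        eta = b0 + beta_zase * z[:, 3]
        y = rng.random(n_turns) < 1 / (1 + np.exp(-eta))
        for k in range(n_turns):
            rows.append(
                {"speaker": f"s{s:02d}", "zSYLR": z[k, 0], "zMF0": z[k, 1],
                 "zRF0": z[k, 2], "zASE": z[k, 3], "AGREE_NO": float(y[k])}
            )
    return pd.DataFrame(rows)
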
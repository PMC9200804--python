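"""Clinical staging, evolving biomarkers, and survival statistics.

Implements the 20-2-20 clinical risk stage (M-protein >2 g/dL, involved/
uninvolved FLC ratio >20, bone-marrow plasma cells >20%; 0/1/>=2 factors ->
low/intermediate/high), evolving-biomarker rules (eMP: >=25% rise in
M-protein within 12 months of diagnosis with a >=0.5 g/dL absolute minimum;
eHb: >=0.5 g/dL hemoglobin drop within 12 months), and the survival stack:
Kaplan-Meier with Greenwood intervals, log-rank tests, Cox proportional
hazards (Efron ties, via lifelines), Harrell's concordance index, and nested
Cox model comparison by likelihood ratio.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy.stats import chi2, fisher_exact, norm

logger = logging.getLogger(__name__)

#: Genetic subtype -> progression-risk group, fixed by the subtyping study:
#: TL2 is low risk; HL1 and HL4 intermediate; HL2, TL1 and HL3 high.
DEFAULT_RISK_MAP: dict[str, str] = {
    "TL2": "low",
    "HL1": "intermediate",
    "HL4": "intermediate",
    "HL2": "high",
    "TL1": "high",
    "HL3": "high",
}

RISK_LEVELS = ("low", "intermediate", "high")


def stage_20_2_20(
    m_protein: float | None,
    flc_ratio: float | None,
    bmpc_percent: float | None,
) -> tuple[str, int | None]:
    """20-2-20 clinical stage and risk-factor count.

    Strict inequalities exactly as defined: a factor counts only when
    M-protein >2 g/dL, FLC ratio >20, or BMPC >20%. Any missing input gives
    stage "missing".
    """
    inputs = (m_protein, flc_ratio, bmpc_percent)
    if any(v is None or (isinstance(v, float) and np.isnan(v)) for v in inputs):
        return "missing", None
    if any(v < 0 for v in inputs):
        raise ValueError(f"staging inputs must be non-negative, got {inputs}")
    count = int(m_protein > 2) + int(flc_ratio > 20) + int(bmpc_percent > 20)
    stage = "low" if count == 0 else ("intermediate" if count == 1 else "high")
    return stage, count


def detect_evolving_biomarkers(
    mp_series: Sequence[tuple[float, float]],
    hb_series: Sequence[tuple[float, float]],
) -> tuple[bool, bool]:
    """Evolving M-protein / hemoglobin flags from longitudinal series.

    eMP: some reading at month in (0, 12] satisfies BOTH a >=25% relative
    and a >=0.5 g/dL absolute rise over the month-0 baseline. eHb: some
    reading at month in (0, 12] is >=0.5 g/dL below baseline. A series
    without a month-0 baseline cannot be evaluated and yields False; a zero
    M-protein baseline falls back to the absolute rule with a warning.
    """
    emp = False
    if mp_series:
        months = [m for m, _ in mp_series]
        if months[0] == 0:
            baseline = mp_series[0][1]
            for month, value in mp_series[1:]:
                if month > 12:
                    break
                abs_ok = value - baseline >= 0.5
                if baseline == 0:
                    logger.warning("zero M-protein baseline: eMP uses absolute rule only")
                    rel_ok = True
                else:
                    rel_ok = (value - baseline) / baseline >= 0.25
                if abs_ok and rel_ok:
                    emp = True
                    break
    ehb = False
    if hb_series:
        months = [m for m, _ in hb_series]
        if months[0] == 0:
            baseline = hb_series[0][1]
            ehb = any(
                baseline - value >= 0.5
                for month, value in hb_series[1:]
                if month <= 12
            )
    return emp, ehb


@dataclass
class SurvivalFit:
    """Kaplan-Meier summaries per group plus optional pooled statistics."""

    curves: dict[str, pd.DataFrame]
    medians: dict[str, float]
    median_cis: dict[str, tuple[float, float]]
    logrank_chi2: float | None = None
    logrank_p: float | None = None
    reverse_km_median_followup: float | None = None
    fitters: dict[str, KaplanMeierFitter] = field(repr=False, default_factory=dict)


def km_fit(
    times: Sequence[float],
    events: Sequence[bool],
    groups: Sequence | None = None,
) -> SurvivalFit:
    """Product-limit survival curves with Greenwood 95% intervals.

    The median is the smallest time with S(t) <= 0.5 (NaN when the curve
    never reaches 0.5, e.g. all patients censored). Median follow-up is the
    reverse Kaplan-Meier estimate (event indicators flipped, pooled).
    With >=2 groups the pooled log-rank chi-square and p are attached.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if np.any(times <= 0):
        raise ValueError("times must be > 0")
    groups = np.asarray(["all"] * len(times)) if groups is None else np.asarray(groups)
    curves: dict[str, pd.DataFrame] = {}
    medians: dict[str, float] = {}
    median_cis: dict[str, tuple[float, float]] = {}
    fitters: dict[str, KaplanMeierFitter] = {}
    for g in pd.unique(groups):
        mask = groups == g
        kmf = KaplanMeierFitter()
        kmf.fit(times[mask], events[mask], label=str(g))
        curve = kmf.survival_function_.copy()
        curve.columns = ["survival"]
        ci = kmf.confidence_interval_
        curve["ci_lower"] = ci.iloc[:, 0].to_numpy()
        curve["ci_upper"] = ci.iloc[:, 1].to_numpy()
        curves[str(g)] = curve
        medians[str(g)] = float(kmf.median_survival_time_)
        from lifelines.utils import median_survival_times

        med_ci = median_survival_times(kmf.confidence_interval_)
        median_cis[str(g)] = (
            float(med_ci.iloc[0, 0]),
            float(med_ci.iloc[0, 1]),
        )
        fitters[str(g)] = kmf
    rev = KaplanMeierFitter()
    rev.fit(times, ~events)
    chi2_stat = p = None
    if len(curves) >= 2:
        chi2_stat, p = logrank_test(times, events, groups)
    return SurvivalFit(
        curves=curves,
        medians=medians,
        median_cis=median_cis,
        logrank_chi2=chi2_stat,
        logrank_p=p,
        reverse_km_median_followup=float(rev.median_survival_time_),
        fitters=fitters,
    )


def logrank_test(
    times: Sequence[float],
    events: Sequence[bool],
    groups: Sequence,
) -> tuple[float, float]:
    """Log-rank statistic over pooled event times; chi-square with
    (n_groups - 1) degrees of freedom."""
    groups = np.asarray(groups)
    uniq = pd.unique(groups)
    if len(uniq) < 2:
        raise ValueError("log-rank needs at least 2 non-empty groups")
    res = multivariate_logrank_test(
        np.asarray(times, dtype=float), groups, np.asarray(events, dtype=bool)
    )
    return float(res.test_statistic), float(res.p_value)


@dataclass
class CoxFit:
    """A fitted Cox proportional-hazards model."""

    summary: pd.DataFrame  # term, coef, HR, CI, p
    log_likelihood: float
    n_params: int
    n_events: int
    fitter: CoxPHFitter = field(repr=False, default=None)
    covariates: list[str] = field(default_factory=list)

    def risk_scores(self, covariates: pd.DataFrame) -> np.ndarray:
        return self.fitter.predict_partial_hazard(covariates).to_numpy().ravel()


def cox_fit(
    covariates: pd.DataFrame,
    times: Sequence[float],
    events: Sequence[bool],
) -> CoxFit:
    """Cox partial-likelihood fit (Efron tie handling, via lifelines).

    Hazard ratios are exp(coef) with Wald 95% intervals and p-values.
    Constant covariates are rejected; complete-separation warnings from the
    fitter are surfaced.
    """
    covariates = pd.DataFrame(covariates).reset_index(drop=True)
    const = [c for c in covariates.columns if covariates[c].nunique() <= 1]
    if const:
        raise ValueError(f"constant covariate(s): {const}")
    events = np.asarray(events, dtype=bool)
    if events.sum() < covariates.shape[1]:
        raise ValueError("fewer events than parameters")
    df = covariates.copy()
    df["_time"] = np.asarray(times, dtype=float)
    df["_event"] = events.astype(int)
    cph = CoxPHFitter()
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        cph.fit(df, duration_col="_time", event_col="_event")
        for w in caught:
            if "convergence" in str(w.message).lower() or "separation" in str(w.message).lower():
                logger.warning("cox_fit: %s", w.message)
    summary = cph.summary.reset_index().rename(
        columns={
            "covariate": "term",
            "exp(coef)": "HR",
            "exp(coef) lower 95%": "ci_lower",
            "exp(coef) upper 95%": "ci_upper",
        }
    )[["term", "coef", "HR", "ci_lower", "ci_upper", "p"]]
    return CoxFit(
        summary=summary,
        log_likelihood=float(cph.log_likelihood_),
        n_params=covariates.shape[1],
        n_events=int(events.sum()),
        fitter=cph,
        covariates=list(covariates.columns),
    )


def compare_models(
    base: CoxFit,
    extended: CoxFit,
    covariates: pd.DataFrame | None = None,
    times: Sequence[float] | None = None,
    events: Sequence[bool] | None = None,
) -> dict:
    """Likelihood-ratio comparison of nested Cox models.

    LR = 2*(loglik_ext - loglik_base) on df = parameter difference; when the
    survival data are supplied, both models' Harrell C and the difference
    are reported as well.
    """
    if not set(base.covariates) <= set(extended.covariates):
        raise ValueError("models are not nested (base covariates must be a subset)")
    if base.n_events != extended.n_events:
        raise ValueError("models were fit on different patients")
    df_diff = extended.n_params - base.n_params
    lr = 2.0 * (extended.log_likelihood - base.log_likelihood)
    if df_diff == 0:
        lr, p = 0.0, 1.0
    else:
        lr = max(lr, 0.0)
        p = float(chi2.sf(lr, df_diff))
    out = {"lr_chi2": lr, "df": df_diff, "p": p}
    if covariates is not None and times is not None and events is not None:
        covariates = pd.DataFrame(covariates).reset_index(drop=True)
        c_base, *_ = c_index(
            base.risk_scores(covariates[base.covariates]), times, events
        )
        c_ext, *_ = c_index(
            extended.risk_scores(covariates[extended.covariates]), times, events
        )
        out.update(c_base=c_base, c_extended=c_ext, delta_c=c_ext - c_base)
    return out


def c_index(
    risk_scores: Sequence[float],
    times: Sequence[float],
    events: Sequence[bool],
) -> tuple[float, float, float]:
    """Harrell's concordance for censored survival data, with a 95% CI.

    Usable pairs are those orderable under censoring: distinct times where
    the earlier time is an event. A pair is concordant when the earlier
    patient has the higher risk score; tied scores contribute 0.5. The CI is
    a Noether-type normal approximation sqrt(C*(1-C)/n_pairs), clipped to
    [0, 1].
    """
    s = np.asarray(risk_scores, dtype=float)
    if not np.isfinite(s).all():
        raise ValueError("risk scores must be finite")
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    # pair (i, j) usable iff t_i < t_j and event_i
    earlier = (t[:, None] < t[None, :]) & e[:, None]
    n_pairs = int(earlier.sum())
    if n_pairs == 0:
        raise ValueError("no usable pairs")
    conc = (s[:, None] > s[None, :]) & earlier
    ties = (s[:, None] == s[None, :]) & earlier
    c = (conc.sum() + 0.5 * ties.sum()) / n_pairs
    se = np.sqrt(max(c * (1 - c), 0.0) / n_pairs)
    lo, hi = np.clip([c - norm.ppf(0.975) * se, c + norm.ppf(0.975) * se], 0.0, 1.0)
    return float(c), float(lo), float(hi)


def biomarker_association(
    flags: Sequence[bool],
    risk_groups: Sequence[str],
    method: str = "table",
) -> dict:
    """Odds of an evolving biomarker in high-risk vs other patients.

    Default is the 2x2 cross-product odds ratio (Haldane-Anscombe 0.5
    correction on zero cells, Woolf logit CI) with a two-sided Fisher exact
    p; ``method='logistic'`` fits a logistic regression of the flag on the
    high-risk indicator instead.
    """
    flags = np.asarray(flags, dtype=bool)
    high = np.asarray([g == "high" for g in risk_groups])
    if high.all() or (~high).all():
        raise ValueError("need both high-risk and other patients")
    if flags.all() or (~flags).all():
        raise ValueError("degenerate flags: all identical")
    a = int((high & flags).sum())
    b = int((high & ~flags).sum())
    c = int((~high & flags).sum())
    d = int((~high & ~flags).sum())
    if method == "logistic":
        import statsmodels.api as sm

        Xd = sm.add_constant(high.astype(float))
        fit = sm.Logit(flags.astype(float), Xd).fit(disp=0)
        coef = fit.params[1]
        lo, hi = fit.conf_int()[1]
        return {
            "odds_ratio": float(np.exp(coef)),
            "ci_lower": float(np.exp(lo)),
            "ci_upper": float(np.exp(hi)),
            "p": float(fit.pvalues[1]),
            "table": (a, b, c, d),
        }
    if method != "table":
        raise ValueError("method must be 'table' or 'logistic'")
    cells = np.array([a, b, c, d], dtype=float)
    if (cells == 0).any():
        cells = cells + 0.5
    a_, b_, c_, d_ = cells
    or_ = (a_ * d_) / (b_ * c_)
    se = np.sqrt(1 / a_ + 1 / b_ + 1 / c_ + 1 / d_)
    z = norm.ppf(0.975)
    _, p = fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return {
        "odds_ratio": float(or_),
        "ci_lower": float(np.exp(np.log(or_) - z * se)),
        "ci_upper": float(np.exp(np.log(or_) + z * se)),
        "p": float(p),
        "table": (a, b, c, d),
    }
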
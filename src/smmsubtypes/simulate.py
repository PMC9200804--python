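"""Synthetic SMM cohorts with planted genetic subtypes.

The generator emulates the statistical structure the subtyping analysis
assumes: six subtypes (HL1-HL4 hyperdiploid-like, TL1-TL2 translocation-
like) planted in a sparse binary driver matrix via subtype-specific
signature features, a summative hyperdiploidy feature spanning the four HL
subtypes, risk-group-specific exponential time to progression (medians
2.6 / 5.2 / 11 years for high / intermediate / low), independent uniform
administrative censoring, and evolving-biomarker longitudinal series
enriched in high-risk patients. Features are conditionally independent
given the subtype; every draw comes from per-patient counter-derived
sub-seeds so a cohort is bit-reproducible from its master seed regardless
of patient order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from .alterations import AlterationMatrix, ClinicalRecord
from .outcomes import DEFAULT_RISK_MAP

logger = logging.getLogger(__name__)

SUBTYPES = ("HL1", "HL2", "HL3", "HL4", "TL1", "TL2")

#: ~42 driver features: 5 IgH/MYC translocations, a summative hyperdiploidy
#: flag, 20 driver SNVs and 16 arm-level CNAs.
DEFAULT_CATALOG: list[str] = [
    "t(11;14)", "t(4;14)", "t(14;16)", "t(14;20)", "t(8;14)",
    "HRD",
    "NRAS", "KRAS", "BRAF", "TP53", "ATM", "MAFB", "CDKN2C", "DIS3", "MAF",
    "FGFR3", "PRKD2", "PRDM1", "HIST1H1E", "CCND1", "NFKBIA", "NFKB2",
    "KLHL6", "TRAF3", "MAX", "CYLD",
    "del16q", "del6q", "del1p", "del17p", "del4q", "del18q", "del14q",
    "del8p", "del10p", "del12p",
    "gain11q", "gain2p", "gain1q", "gain3", "gain5", "gain9",
]

#: Subtype signature features, mirroring the landmark alterations of each
#: genetic subtype: HL1 (hyperdiploid + NRAS/TRAF3/MAX), HL2 (16q/6q/1p
#: deletions, t(14;20), TP53/ATM/CYLD), HL3 (KRAS, NFKBIA, MYC
#: translocation), HL4 (NFKB2, KLHL6, 2p/1q gains), TL1 (t(4;14)/t(14;16),
#: DIS3/MAF/FGFR3, 14q/8p deletions), TL2 (t(11;14), CCND1, 11q gain).
DEFAULT_SIGNATURES: dict[str, tuple[str, ...]] = {
    "HL1": ("NRAS", "TRAF3", "MAX", "gain5", "gain9"),
    "HL2": ("del16q", "del6q", "del1p", "t(14;20)", "TP53", "ATM", "CYLD"),
    "HL3": ("KRAS", "NFKBIA", "t(8;14)", "gain3"),
    "HL4": ("NFKB2", "KLHL6", "gain2p", "gain1q"),
    "TL1": ("t(4;14)", "t(14;16)", "DIS3", "MAF", "FGFR3", "del14q", "del8p"),
    "TL2": ("t(11;14)", "CCND1", "gain11q"),
}

#: Per-subtype rate of the summative hyperdiploidy feature: high in the HL
#: subtypes, low in the TL subtypes, with the HL2 rate at the observed 69%.
DEFAULT_HYPERDIPLOID_RATES: dict[str, float] = {
    "HL1": 0.9,
    "HL2": 0.69,
    "HL3": 0.9,
    "HL4": 0.9,
    "TL1": 0.1,
    "TL2": 0.1,
}

HYPERDIPLOIDY_FEATURE = "HRD"

# fixed stream offsets for counter-derived per-patient sub-seeds
_STREAM_FEATURES = 0
_STREAM_CLINICAL = 1
_STREAM_SURVIVAL = 2
_STREAM_EVOLVING = 3
_STREAM_SUBTYPE = 4


@dataclass
class CohortConfig:
    """Study conditions for a synthetic cohort.

    Defaults match the cohort the subtyping analysis was built around:
    214 patients, 6 subtypes, signature features at 0.7 within their
    subtype against a 0.05 background, risk-group median TTP of
    2.6 / 5.2 / 11 years, ~34% censoring, and eMP/eHb odds multipliers of
    9.4 / 5.3 in high-risk patients over a 5% base rate.
    """

    n_patients: int = 214
    k_true: int = 6
    mixing_proportions: dict[str, float] = field(
        default_factory=lambda: {s: 1.0 / len(SUBTYPES) for s in SUBTYPES}
    )
    catalog: list[str] = field(default_factory=lambda: list(DEFAULT_CATALOG))
    signature_map: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_SIGNATURES)
    )
    p_signature: float = 0.7
    p_background: float = 0.05
    hyperdiploid_rates: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_HYPERDIPLOID_RATES)
    )
    risk_map: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_RISK_MAP))
    survival_medians_years: dict[str, float] = field(
        default_factory=lambda: {"low": 11.0, "intermediate": 5.2, "high": 2.6}
    )
    censoring_rate: float = 0.34
    emp_odds: float = 9.4
    ehb_odds: float = 5.3
    base_evolving_prob: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.mixing_proportions.values())
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"mixing proportions sum to {total}, not 1")
        rates = [
            self.p_signature,
            self.p_background,
            self.censoring_rate,
            self.base_evolving_prob,
            *self.hyperdiploid_rates.values(),
        ]
        if any(not 0 <= r <= 1 for r in rates):
            raise ValueError("all rates must lie in [0, 1]")
        if any(m <= 0 for m in self.survival_medians_years.values()):
            raise ValueError("survival medians must be > 0")
        missing = [
            f
            for feats in self.signature_map.values()
            for f in feats
            if f not in self.catalog
        ]
        if missing:
            raise ValueError(f"signature features not in catalog: {sorted(set(missing))}")
        unmapped = [s for s in self.mixing_proportions if s not in self.risk_map]
        if unmapped:
            raise ValueError(f"subtypes without a risk group: {unmapped}")

    @property
    def subtypes(self) -> list[str]:
        return list(self.mixing_proportions)


@dataclass
class SyntheticCohort:
    """A generated cohort: matrix, planted labels, clinical tables."""

    matrix: AlterationMatrix
    true_labels: np.ndarray
    clinical: pd.DataFrame
    series: pd.DataFrame
    config: CohortConfig

    def records(self) -> list[ClinicalRecord]:
        out = []
        series = self.series
        for _, r in self.clinical.iterrows():
            pid = r["patient_id"]
            sub = series[series["patient_id"] == pid]
            mp = sub[sub["marker"] == "mp"].sort_values("month")
            hb = sub[sub["marker"] == "hb"].sort_values("month")
            out.append(
                ClinicalRecord(
                    patient_id=pid,
                    m_protein_baseline=r["m_protein_baseline"],
                    flc_ratio=r["flc_ratio"],
                    bmpc_percent=r["bmpc_percent"],
                    hemoglobin_baseline=r["hemoglobin_baseline"],
                    mp_series=list(zip(mp["month"], mp["value"])),
                    hb_series=list(zip(hb["month"], hb["value"])),
                    ttp_months=r["ttp_months"],
                    progressed=bool(r["progressed"]),
                )
            )
        return out


def _patient_rng(seed: int, stream: int, index: int) -> np.random.Generator:
    """Counter-derived per-patient stream: independent of patient order."""
    return np.random.default_rng(np.random.SeedSequence([seed, stream, index]))


def _censoring_horizon(config: CohortConfig) -> float:
    """Administrative-censoring horizon T_max (months) solved so that the
    expected censored fraction matches ``censoring_rate`` under the
    exponential mixture implied by the config."""
    if config.censoring_rate <= 0:
        return float("inf")
    weights: dict[str, float] = {}
    for subtype, pi in config.mixing_proportions.items():
        group = config.risk_map[subtype]
        weights[group] = weights.get(group, 0.0) + pi
    rates = {
        g: np.log(2) / (config.survival_medians_years[g] * 12.0) for g in weights
    }

    def censored_fraction(tmax: float) -> float:
        return sum(
            w * (1.0 - np.exp(-rates[g] * tmax)) / (rates[g] * tmax)
            for g, w in weights.items()
        )

    lo, hi = 1e-6, 1e7
    target = config.censoring_rate
    return float(brentq(lambda t: censored_fraction(t) - target, lo, hi))


def draw_subtypes(config: CohortConfig) -> np.ndarray:
    """Per-patient subtype labels drawn from the mixing proportions."""
    subtypes = config.subtypes
    probs = np.array([config.mixing_proportions[s] for s in subtypes])
    labels = np.empty(config.n_patients, dtype=object)
    for i in range(config.n_patients):
        rng = _patient_rng(config.seed, _STREAM_SUBTYPE, i)
        labels[i] = subtypes[int(rng.choice(len(subtypes), p=probs))]
    return labels


def generate_matrix(
    config: CohortConfig, true_labels: np.ndarray
) -> AlterationMatrix:
    """Binary driver matrix: signature features at ``p_signature`` inside
    their subtype, ``p_background`` elsewhere; the summative hyperdiploidy
    feature at its per-subtype rate."""
    n, m = config.n_patients, len(config.catalog)
    values = np.zeros((n, m), dtype=np.int8)
    col = {f: j for j, f in enumerate(config.catalog)}
    for i in range(n):
        rng = _patient_rng(config.seed, _STREAM_FEATURES, i)
        s = true_labels[i]
        sig = set(config.signature_map.get(s, ()))
        for f in config.catalog:
            if f == HYPERDIPLOIDY_FEATURE and s in config.hyperdiploid_rates:
                p = config.hyperdiploid_rates[s]
            elif f in sig:
                p = config.p_signature
            else:
                p = config.p_background
            values[i, col[f]] = int(rng.random() < p)
    return AlterationMatrix(
        patient_ids=[f"P{i:04d}" for i in range(n)],
        feature_ids=list(config.catalog),
        values=values,
    )


def generate_survival(
    true_labels: Sequence[str],
    risk_map: Mapping[str, str],
    config: CohortConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Exponential time to progression in months, with independent uniform
    administrative censoring calibrated to the configured censored fraction.

    Event times use rate ln(2)/median for the patient's risk group; the
    observed time is min(event, censor) and ``progressed`` marks events.
    """
    labels = list(true_labels)
    unmapped = sorted({s for s in labels if s not in risk_map})
    if unmapped:
        raise ValueError(f"labels without a risk group: {unmapped}")
    tmax = _censoring_horizon(config)
    ttp = np.empty(len(labels))
    progressed = np.empty(len(labels), dtype=bool)
    for i, s in enumerate(labels):
        rng = _patient_rng(config.seed, _STREAM_SURVIVAL, i)
        median_months = config.survival_medians_years[risk_map[s]] * 12.0
        t_event = rng.exponential(median_months / np.log(2))
        t_cens = rng.uniform(0, tmax) if np.isfinite(tmax) else np.inf
        if t_event <= t_cens:
            ttp[i] = t_event
            progressed[i] = True
        else:
            ttp[i] = t_cens
            progressed[i] = False
    ttp = np.maximum(ttp, 1e-6)  # strictly positive observed times
    return ttp, progressed


_MP_MONTHS = (0.0, 3.0, 6.0, 9.0, 12.0, 18.0, 24.0)


def generate_evolving_flags(
    true_labels: Sequence[str],
    risk_map: Mapping[str, str],
    config: CohortConfig,
    mp_baselines: Sequence[float],
    hb_baselines: Sequence[float],
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Designate evolving patients and build matching longitudinal series.

    A patient is designated eMP (resp. eHb) with probability
    logit^-1(logit(base) + 1{high risk} * ln(odds multiplier)); designated
    patients receive series satisfying the eMP/eHb rules, all others receive
    series that violate them. Returns (emp, ehb, long-format series).
    """
    labels = list(true_labels)
    emp = np.zeros(len(labels), dtype=bool)
    ehb = np.zeros(len(labels), dtype=bool)
    rows = []
    base_logit = logit(config.base_evolving_prob)
    for i, s in enumerate(labels):
        rng = _patient_rng(config.seed, _STREAM_EVOLVING, i)
        is_high = risk_map[s] == "high"
        p_emp = expit(base_logit + (np.log(config.emp_odds) if is_high else 0.0))
        p_ehb = expit(base_logit + (np.log(config.ehb_odds) if is_high else 0.0))
        emp[i] = rng.random() < p_emp
        ehb[i] = rng.random() < p_ehb
        b_mp = mp_baselines[i]
        b_hb = hb_baselines[i]
        if emp[i]:
            # reach both thresholds by month 9 with 30% headroom
            rise = max(0.25 * b_mp, 0.5) * 1.3
        else:
            # stay strictly below the 0.5 g/dL absolute minimum
            rise = min(0.2 * b_mp, 0.35)
        drop = 0.7 if ehb[i] else 0.2
        for month in _MP_MONTHS:
            frac = min(month / 9.0, 1.0)
            jitter_mp = rng.uniform(-0.03, 0.03) if month > 0 else 0.0
            jitter_hb = rng.uniform(-0.05, 0.05) if month > 0 else 0.0
            rows.append(
                {
                    "patient_id": f"P{i:04d}",
                    "marker": "mp",
                    "month": month,
                    "value": max(b_mp + rise * frac + jitter_mp, 0.0),
                }
            )
            rows.append(
                {
                    "patient_id": f"P{i:04d}",
                    "marker": "hb",
                    "month": month,
                    "value": max(b_hb - drop * frac + jitter_hb, 4.0),
                }
            )
    return emp, ehb, pd.DataFrame(rows)


def _draw_clinical(
    config: CohortConfig, true_labels: np.ndarray
) -> pd.DataFrame:
    """Baseline staging inputs.

    M-protein is log-normal (median ~1.4 g/dL) with a lower location for
    the low-risk TL2-analog subtype (its tumors present with lower
    M-protein) and a mildly higher location, FLC ratio and plasma-cell
    burden in high-risk subtypes so the clinical stage carries real — but
    incomplete — prognostic signal.
    """
    rows = []
    for i, s in enumerate(true_labels):
        rng = _patient_rng(config.seed, _STREAM_CLINICAL, i)
        group = config.risk_map[s]
        mu_mp = np.log(1.4)
        if group == "low":
            mu_mp = np.log(0.9)
        elif group == "high":
            mu_mp += 0.25
        mu_flc = np.log(8.0) + (0.5 if group == "high" else 0.0)
        bmpc_loc = 15.0 + (6.0 if group == "high" else 0.0)
        rows.append(
            {
                "patient_id": f"P{i:04d}",
                "m_protein_baseline": float(rng.lognormal(mu_mp, 0.5)),
                "flc_ratio": float(rng.lognormal(mu_flc, 1.0)),
                "bmpc_percent": float(np.clip(rng.normal(bmpc_loc, 8.0), 1.0, 60.0)),
                "hemoglobin_baseline": float(np.clip(rng.normal(13.2, 1.4), 8.0, 17.5)),
            }
        )
    return pd.DataFrame(rows)


def generate_cohort(config: CohortConfig | None = None) -> SyntheticCohort:
    """Generate a full synthetic cohort under the configured conditions.

    Bit-reproducible from ``config.seed``: same seed, same matrix and
    clinical tables.
    """
    config = config or CohortConfig()
    labels = draw_subtypes(config)
    matrix = generate_matrix(config, labels)
    clinical = _draw_clinical(config, labels)
    ttp, progressed = generate_survival(labels, config.risk_map, config)
    emp, ehb, series = generate_evolving_flags(
        labels,
        config.risk_map,
        config,
        clinical["m_protein_baseline"].to_numpy(),
        clinical["hemoglobin_baseline"].to_numpy(),
    )
    clinical = clinical.assign(
        ttp_months=ttp,
        progressed=progressed,
        true_subtype=labels,
        risk_group=[config.risk_map[s] for s in labels],
        emp_designated=emp,
        ehb_designated=ehb,
    )
    return SyntheticCohort(
        matrix=matrix,
        true_labels=labels,
        clinical=clinical,
        series=series,
        config=config,
    )
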
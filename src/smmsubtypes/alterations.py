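"""Binary patient x alteration matrices and clinical tables.

The central container is :class:`AlterationMatrix`: a validated 0/1 matrix
with patients as rows and genetic features (driver SNVs, arm/focal CNAs,
IgH/MYC translocations, summative ploidy flags) as columns. Missing calls are
resolved to 0 before construction; there is no missing state inside the
matrix.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

FEATURE_CLASSES = ("SNV", "CNA", "TRANSLOCATION", "PLOIDY")

_CNA_PATTERN = re.compile(r"^(del|gain|amp|loss|\+|-)", re.IGNORECASE)
_PLOIDY_IDS = {"hrd", "hyperdiploidy", "hyperdiploid", "hypodiploid", "hypodiploidy"}


class MatrixValidationError(ValueError):
    """Raised when a matrix or its source file violates the 0/1 contract."""


def infer_feature_class(feature_id: str) -> str:
    """Heuristic feature class: ``t(`` -> TRANSLOCATION, del/gain/amp/+/-
    prefixes -> CNA, known ploidy flags -> PLOIDY, anything else -> SNV."""
    fid = feature_id.strip()
    if fid.lower() in _PLOIDY_IDS:
        return "PLOIDY"
    if fid.lower().startswith("t("):
        return "TRANSLOCATION"
    if _CNA_PATTERN.match(fid):
        return "CNA"
    return "SNV"


@dataclass
class AlterationMatrix:
    """Patients x binary genetic features.

    Parameters
    ----------
    patient_ids : unique row identifiers.
    feature_ids : unique column identifiers.
    values : array of shape (n_patients, n_features) with entries in {0, 1}.
    feature_class : optional map feature_id -> one of ``FEATURE_CLASSES``;
        missing entries are inferred from the feature id.
    """

    patient_ids: list[str]
    feature_ids: list[str]
    values: np.ndarray
    feature_class: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.patient_ids = [str(p) for p in self.patient_ids]
        self.feature_ids = [str(f) for f in self.feature_ids]
        values = np.asarray(self.values)
        if values.ndim != 2:
            raise MatrixValidationError("matrix must be two-dimensional")
        n, m = values.shape
        if n < 2 or m < 2:
            raise MatrixValidationError(
                f"need at least 2 patients and 2 features, got {n} x {m}"
            )
        if len(self.patient_ids) != n or len(self.feature_ids) != m:
            raise MatrixValidationError("id lists do not match matrix shape")
        dup_p = _duplicates(self.patient_ids)
        if dup_p:
            raise MatrixValidationError(f"duplicate patient ids: {sorted(dup_p)}")
        dup_f = _duplicates(self.feature_ids)
        if dup_f:
            raise MatrixValidationError(f"duplicate feature ids: {sorted(dup_f)}")
        bad = ~np.isin(values, (0, 1))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise MatrixValidationError(
                f"non-binary value {values[i, j]!r} at patient "
                f"{self.patient_ids[i]!r}, feature {self.feature_ids[j]!r}"
            )
        self.values = values.astype(np.int8)
        classes = dict(self.feature_class)
        for fid in self.feature_ids:
            cls = classes.get(fid, infer_feature_class(fid))
            if cls not in FEATURE_CLASSES:
                raise MatrixValidationError(
                    f"unknown feature class {cls!r} for feature {fid!r}"
                )
            classes[fid] = cls
        self.feature_class = classes
        zero_rows = np.flatnonzero(self.values.sum(axis=1) == 0)
        if zero_rows.size:
            logger.warning(
                "%d patient(s) carry no alteration: %s",
                zero_rows.size,
                [self.patient_ids[i] for i in zero_rows[:10]],
            )

    @property
    def n_patients(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.patient_ids, columns=self.feature_ids
        )

    def subset_patients(self, indices: Sequence[int]) -> "AlterationMatrix":
        idx = list(indices)
        return AlterationMatrix(
            patient_ids=[self.patient_ids[i] for i in idx],
            feature_ids=list(self.feature_ids),
            values=self.values[idx, :],
            feature_class=dict(self.feature_class),
        )

    def subset_features(self, feature_ids: Sequence[str]) -> "AlterationMatrix":
        pos = {f: i for i, f in enumerate(self.feature_ids)}
        missing = [f for f in feature_ids if f not in pos]
        if missing:
            raise KeyError(f"features not in matrix: {missing}")
        cols = [pos[f] for f in feature_ids]
        return AlterationMatrix(
            patient_ids=list(self.patient_ids),
            feature_ids=list(feature_ids),
            values=self.values[:, cols],
            feature_class={f: self.feature_class[f] for f in feature_ids},
        )


def _duplicates(items: Iterable[str]) -> set[str]:
    seen: set[str] = set()
    dups: set[str] = set()
    for x in items:
        if x in seen:
            dups.add(x)
        seen.add(x)
    return dups


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def load_matrix(path: str | Path, class_path: str | Path | None = None) -> AlterationMatrix:
    """Read a patients-as-rows TSV/CSV binary matrix.

    First column holds patient ids, the header row holds feature ids. An
    optional side-car table (``feature_id``, ``feature_class`` columns)
    overrides the inferred feature classes.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0, dtype=str)
    if df.empty:
        raise MatrixValidationError(f"empty matrix file: {path}")
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise MatrixValidationError(f"non-numeric cell in {path}: {exc}") from exc
    if not np.isin(values, (0.0, 1.0)).all():
        bad = np.argwhere(~np.isin(values, (0.0, 1.0)))[0]
        raise MatrixValidationError(
            f"non-binary value {values[bad[0], bad[1]]!r} at row "
            f"{df.index[bad[0]]!r}, column {df.columns[bad[1]]!r} in {path}"
        )
    classes: dict[str, str] = {}
    if class_path is not None:
        side = pd.read_csv(Path(class_path), sep=_sep_for(Path(class_path)))
        classes = dict(zip(side["feature_id"].astype(str), side["feature_class"]))
    return AlterationMatrix(
        patient_ids=list(df.index.astype(str)),
        feature_ids=list(df.columns.astype(str)),
        values=values,
        feature_class=classes,
    )


def write_matrix(matrix: AlterationMatrix, path: str | Path) -> None:
    """Write the matrix as patients-as-rows TSV/CSV (bit-exact roundtrip)."""
    path = Path(path)
    df = matrix.to_frame()
    df.index.name = "patient_id"
    df.to_csv(path, sep=_sep_for(path))


def binarize_calls(
    snv_calls: Mapping[str, Iterable[str]],
    cna_calls: Mapping[str, Iterable[str]],
    tra_calls: Mapping[str, Iterable[str]],
    feature_catalog: Sequence[str],
    strict: bool = True,
    feature_class: Mapping[str, str] | None = None,
) -> AlterationMatrix:
    """Collapse per-patient call lists into a presence/absence matrix.

    Entry (p, f) is 1 iff patient p has at least one call for feature f;
    duplicate calls are idempotent. Calls to features outside the catalog
    raise in strict mode and are skipped with a warning otherwise. Patients
    with no calls keep an all-zero row.
    """
    catalog = [str(f) for f in feature_catalog]
    if not catalog:
        raise ValueError("feature catalog is empty")
    col = {f: j for j, f in enumerate(catalog)}
    patients = sorted(set(snv_calls) | set(cna_calls) | set(tra_calls))
    values = np.zeros((len(patients), len(catalog)), dtype=np.int8)
    row = {p: i for i, p in enumerate(patients)}
    for calls in (snv_calls, cna_calls, tra_calls):
        for pid, feats in calls.items():
            for f in feats:
                f = str(f)
                if f not in col:
                    if strict:
                        raise KeyError(
                            f"call to uncataloged feature {f!r} for patient {pid!r}"
                        )
                    logger.warning(
                        "skipping uncataloged feature %r for patient %r", f, pid
                    )
                    continue
                values[row[pid], col[f]] = 1
    return AlterationMatrix(
        patient_ids=patients,
        feature_ids=catalog,
        values=values,
        feature_class=dict(feature_class) if feature_class else {},
    )


def derive_ploidy_flags(chromosome_count: int) -> tuple[bool, bool]:
    """Karyotype flags: hyperdiploid iff >48 chromosomes, hypodiploid iff <45.

    Counts of 45-48 are neither; the two flags are mutually exclusive.
    """
    count = int(chromosome_count)
    if count != chromosome_count or count <= 0:
        raise ValueError(f"chromosome count must be a positive integer, got {chromosome_count!r}")
    return count > 48, count < 45


def read_maf(path: str | Path) -> dict[str, list[str]]:
    """Read a MAF-dialect table into per-patient gene lists.

    Only ``Hugo_Symbol`` and ``Tumor_Sample_Barcode`` are consulted.
    """
    df = pd.read_csv(Path(path), sep="\t", comment="#", dtype=str)
    for colname in ("Hugo_Symbol", "Tumor_Sample_Barcode"):
        if colname not in df.columns:
            raise ValueError(f"MAF file {path} lacks required column {colname}")
    out: dict[str, list[str]] = {}
    for pid, genes in df.groupby("Tumor_Sample_Barcode")["Hugo_Symbol"]:
        out[str(pid)] = [str(g) for g in genes]
    return out


def read_gistic(
    path: str | Path, direction: str = "both"
) -> dict[str, list[str]]:
    """Read GISTIC-thresholded calls (sample x arm, values in {-2..2}).

    A call is emitted when |value| >= 1 in the configured direction
    (``gain``, ``loss`` or ``both``); feature ids are prefixed ``gain``/``del``.
    """
    if direction not in ("gain", "loss", "both"):
        raise ValueError("direction must be 'gain', 'loss' or 'both'")
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    out: dict[str, list[str]] = {}
    for pid, rowvals in df.iterrows():
        calls: list[str] = []
        for arm, v in rowvals.items():
            v = float(v)
            if v >= 1 and direction in ("gain", "both"):
                calls.append(f"gain{arm}")
            elif v <= -1 and direction in ("loss", "both"):
                calls.append(f"del{arm}")
        out[str(pid)] = calls
    return out


# ---------------------------------------------------------------------------
# clinical records


@dataclass
class ClinicalRecord:
    """Per-patient staging inputs and longitudinal biomarkers.

    Series are lists of (month_offset, value) with strictly increasing
    offsets; the month-0 entry, when present, is the baseline. ``ttp_months``
    is time from diagnosis to documented progression (or censoring).
    Staging fields may be None (missing).
    """

    patient_id: str
    m_protein_baseline: float | None = None
    flc_ratio: float | None = None
    bmpc_percent: float | None = None
    hemoglobin_baseline: float | None = None
    mp_series: list[tuple[float, float]] = field(default_factory=list)
    hb_series: list[tuple[float, float]] = field(default_factory=list)
    ttp_months: float | None = None
    progressed: bool | None = None

    def __post_init__(self) -> None:
        for name, series, baseline in (
            ("mp_series", self.mp_series, self.m_protein_baseline),
            ("hb_series", self.hb_series, self.hemoglobin_baseline),
        ):
            months = [m for m, _ in series]
            if any(m < 0 for m in months):
                raise ValueError(f"{name}: negative month offset for {self.patient_id}")
            if any(b <= a for a, b in zip(months, months[1:])):
                raise ValueError(
                    f"{name}: month offsets not strictly increasing for {self.patient_id}"
                )
            if series and months[0] == 0 and baseline is not None:
                if abs(series[0][1] - baseline) > 1e-9:
                    raise ValueError(
                        f"{name}: month-0 value {series[0][1]} disagrees with "
                        f"baseline {baseline} for {self.patient_id}"
                    )
        if self.ttp_months is not None and self.ttp_months <= 0:
            raise ValueError(f"ttp_months must be > 0 for {self.patient_id}")


CLINICAL_COLUMNS = [
    "patient_id",
    "m_protein_baseline",
    "flc_ratio",
    "bmpc_percent",
    "hemoglobin_baseline",
    "ttp_months",
    "progressed",
]


def load_clinical(
    clinical_path: str | Path, series_path: str | Path | None = None
) -> list[ClinicalRecord]:
    """Read a clinical CSV (one row per patient) plus an optional long-format
    series CSV (patient_id, marker, month, value; marker in {mp, hb})."""
    df = pd.read_csv(Path(clinical_path))
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"clinical table lacks columns {missing}")
    series: dict[tuple[str, str], list[tuple[float, float]]] = {}
    if series_path is not None:
        long_df = pd.read_csv(Path(series_path))
        long_df = long_df.sort_values(["patient_id", "marker", "month"])
        for (pid, marker), grp in long_df.groupby(["patient_id", "marker"]):
            series[(str(pid), str(marker))] = list(
                zip(grp["month"].astype(float), grp["value"].astype(float))
            )
    records = []
    for _, r in df.iterrows():
        pid = str(r["patient_id"])
        records.append(
            ClinicalRecord(
                patient_id=pid,
                m_protein_baseline=_opt(r["m_protein_baseline"]),
                flc_ratio=_opt(r["flc_ratio"]),
                bmpc_percent=_opt(r["bmpc_percent"]),
                hemoglobin_baseline=_opt(r["hemoglobin_baseline"]),
                mp_series=series.get((pid, "mp"), []),
                hb_series=series.get((pid, "hb"), []),
                ttp_months=_opt(r["ttp_months"]),
                progressed=None if pd.isna(r["progressed"]) else bool(r["progressed"]),
            )
        )
    return records


def _opt(x) -> float | None:
    return None if pd.isna(x) else float(x)
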
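"""Reading, writing and validation of methylation matrices and annotation tables.

The central container is :class:`BetaMatrix`, a probes x samples grid of
methylation fractions (beta values, methylated signal over total signal,
in [0, 1]) in the style of the Illumina HumanMethylation27 array.  Missing
measurements are empty cells on disk and ``NaN`` in memory; no sentinel
value inside [0, 1] is ever used for missingness.

The module also ships, as first-class packaged data, transcriptions of the
printed clinico-histological and clonality-score tables of the study this
package re-implements: the 17 primary-tumor/local-recurrence (PT/LR) pairs,
the 10 printed PT/contralateral (PT/CL) pairs (the accompanying text counts
11 pairs; the fixture carries what is printed and the discrepancy is
surfaced here rather than resolved), the 20 PT/axillary-metastasis (PT/AM)
pairs, and the per-pair clonality scores with their three TR/NP labels.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "BetaMatrix",
    "SampleAnnotation",
    "ClinicalRecord",
    "PairRecord",
    "BetaMatrixParseError",
    "read_beta_matrix",
    "write_beta_matrix",
    "filter_complete_probes",
    "load_fixture_tables",
    "FixtureTables",
    "clinical_records_from_row",
    "ROLES",
    "COHORTS",
]

ROLES = ("PT", "AM", "LR", "CL", "NORMAL")
COHORTS = ("PT/AM", "PT/LR", "PT/CL", "NORMAL")

#: recurrence-type role for each paired cohort
RECURRENCE_ROLE = {"PT/AM": "AM", "PT/LR": "LR", "PT/CL": "CL"}

_TYPE_CODES = {
    "D": "ductal",
    "L": "lobular",
    "Med": "medullary",
    "Meta": "metaplastic",
    "D-L": "mixed",
}


class BetaMatrixParseError(ValueError):
    """Raised when a beta-matrix file violates the format contract."""


@dataclass
class BetaMatrix:
    """Probes x samples matrix of beta values in [0, 1], NaN = missing."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique()
            raise BetaMatrixParseError(f"duplicate probe ids: {list(dupes)[:5]}")
        if self.values.columns.has_duplicates:
            dupes = self.values.columns[self.values.columns.duplicated()].unique()
            raise BetaMatrixParseError(f"duplicate sample ids: {list(dupes)[:5]}")
        arr = self.values.to_numpy()
        bad = (arr < 0.0) | (arr > 1.0)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise BetaMatrixParseError(
                f"beta value {arr[i, j]!r} outside [0, 1] at probe "
                f"{self.values.index[i]!r}, sample {self.values.columns[j]!r}"
            )

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def sample(self, sample_id: str) -> np.ndarray:
        """Beta vector of one sample across all probes (order preserved)."""
        return self.values[sample_id].to_numpy()

    def n_missing_per_probe(self) -> pd.Series:
        return self.values.isna().sum(axis=1)


@dataclass
class SampleAnnotation:
    """Sample sheet: one row per sample with pair membership and role.

    ``role`` is PT, AM, LR, CL or NORMAL; ``cohort`` is PT/AM, PT/LR,
    PT/CL or NORMAL.  Within a paired cohort every pair id carries exactly
    one PT and exactly one recurrence-role sample.
    """

    table: pd.DataFrame  # columns: sample_id, pair_id, role, cohort

    def __post_init__(self) -> None:
        required = {"sample_id", "pair_id", "role", "cohort"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"annotation table missing columns: {sorted(missing)}")
        bad_roles = set(self.table["role"]) - set(ROLES)
        if bad_roles:
            raise ValueError(f"unknown roles: {sorted(bad_roles)}")
        bad_cohorts = set(self.table["cohort"]) - set(COHORTS)
        if bad_cohorts:
            raise ValueError(f"unknown cohorts: {sorted(bad_cohorts)}")
        for cohort, rec_role in RECURRENCE_ROLE.items():
            sub = self.table[self.table["cohort"] == cohort]
            for pair_id, grp in sub.groupby("pair_id"):
                roles = sorted(grp["role"])
                if roles != sorted(["PT", rec_role]):
                    raise ValueError(
                        f"pair {pair_id!r} in cohort {cohort} has roles {roles}; "
                        f"expected exactly one PT and one {rec_role}"
                    )

    def complete_pairs(self, cohort: str) -> list[tuple[str, str, str]]:
        """(pair_id, pt_sample, rec_sample) triples for one paired cohort."""
        rec_role = RECURRENCE_ROLE[cohort]
        sub = self.table[self.table["cohort"] == cohort]
        out = []
        for pair_id, grp in sub.groupby("pair_id", sort=True):
            pt = grp.loc[grp["role"] == "PT", "sample_id"].iloc[0]
            rec = grp.loc[grp["role"] == rec_role, "sample_id"].iloc[0]
            out.append((pair_id, pt, rec))
        return out

    def normals(self) -> list[str]:
        return list(self.table.loc[self.table["role"] == "NORMAL", "sample_id"])


@dataclass
class ClinicalRecord:
    """Clinico-histological features of one tumor.

    ``histological_type`` uses the long names (ductal, lobular, medullary,
    metaplastic, mixed); ``er``/``pr``/``her2`` are "+", "-" or None;
    ``location_within_4cm`` is 1 when a recurrence arose less than 4 cm
    from the primary (only meaningful on recurrence records).
    """

    histological_type: str | None = None
    grade: int | None = None
    er: str | None = None
    pr: str | None = None
    her2: str | None = None
    location_within_4cm: int | None = None
    age_years: float | None = None

    def __post_init__(self) -> None:
        if self.histological_type is not None and self.histological_type not in _TYPE_CODES.values():
            raise ValueError(f"unknown histological type {self.histological_type!r}")
        if self.grade is not None and self.grade not in (1, 2, 3):
            raise ValueError(f"grade {self.grade!r} not in 1..3")
        for name in ("er", "pr", "her2"):
            v = getattr(self, name)
            if v is not None and v not in ("+", "-"):
                raise ValueError(f"{name} status {v!r} not in {{'+', '-'}}")
        if self.location_within_4cm is not None and self.location_within_4cm not in (0, 1):
            raise ValueError("location flag must be 0, 1 or None")


@dataclass
class PairRecord:
    """One matched PT/recurrence pair with clonality scores and labels.

    ``ms_score`` is the methylation-similarity score in natural (inverse
    Manhattan-distance) units, i.e. the printed "x 10^-4" column divided by
    10^4.  ``pis_score`` is the copy-number Partial Identity Score in [0, 1].
    Labels are "TR" (true recurrence), "NP" (new primary) or None.
    """

    pair_id: str
    pt_sample: str | None = None
    rec_sample: str | None = None
    ms_score: float | None = None
    pis_score: float | None = None
    time_to_recurrence_years: float | None = None
    label_ms: str | None = None
    label_pis: str | None = None
    label_clinical: str | None = None

    def __post_init__(self) -> None:
        if self.ms_score is not None and not self.ms_score > 0:
            raise ValueError("ms_score must be positive when present")
        for name in ("label_ms", "label_pis", "label_clinical"):
            v = getattr(self, name)
            if v is not None and v not in ("TR", "NP"):
                raise ValueError(f"{name} must be 'TR', 'NP' or None, got {v!r}")


def read_beta_matrix(path: str | Path) -> BetaMatrix:
    """Read a tab-separated beta matrix (probes in rows, samples in columns).

    The first column holds probe ids, the header row sample ids.  Empty
    cells become missing values; any numeric cell outside [0, 1] raises a
    :class:`BetaMatrixParseError` naming the offending probe and sample.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except Exception as exc:  # malformed delimiter structure / empty file
        raise BetaMatrixParseError(f"cannot parse {path}: {exc}") from exc
    if df.columns.size == 0:
        raise BetaMatrixParseError(f"{path}: header row has no sample ids")
    try:
        numeric = df.apply(pd.to_numeric, errors="raise")
    except Exception as exc:
        raise BetaMatrixParseError(f"{path}: non-numeric cell: {exc}") from exc
    numeric.index = numeric.index.astype(str)
    numeric.columns = numeric.columns.astype(str)
    return BetaMatrix(numeric)


def write_beta_matrix(m: BetaMatrix, path: str | Path, decimals: int = 6) -> None:
    """Write a beta matrix as tab-separated text; missing values as empty cells."""
    m.values.to_csv(Path(path), sep="\t", float_format=f"%.{decimals}f", na_rep="")


def filter_complete_probes(m: BetaMatrix) -> BetaMatrix:
    """Keep only probes with no missing value in any sample.

    Mirrors the pre-analysis step in which a handful of probes with missing
    measurements is dropped and all downstream work uses the complete rows.
    Sample set and probe order are preserved; the result may be empty.
    """
    keep = ~m.values.isna().any(axis=1)
    return BetaMatrix(m.values.loc[keep])


class FixtureTables(NamedTuple):
    ptlr_clinical: pd.DataFrame
    ptcl_clinical: pd.DataFrame
    ptam_clinical: pd.DataFrame
    pairs: list[PairRecord]


def _fixture_path(name: str) -> Path:
    res = importlib.resources.files("methclonal") / "data" / name
    p = Path(str(res))
    if not p.exists():
        raise FileNotFoundError(f"packaged fixture {name} not found at {p}")
    return p


def _read_fixture(name: str) -> pd.DataFrame:
    return pd.read_csv(_fixture_path(name), dtype=str).replace({np.nan: None})


def clinical_records_from_row(row: pd.Series, prefix: str, loc: str | None = None) -> ClinicalRecord:
    """Build a ClinicalRecord from one fixture row, e.g. prefix='pt' or 'lr'."""

    def get(col: str) -> str | None:
        v = row.get(col)
        return None if v in (None, "") else v

    grade = get(f"{prefix}_grade")
    age = get("age")
    type_code = get(f"{prefix}_type")
    loc_val = get(loc) if loc else None
    return ClinicalRecord(
        histological_type=_TYPE_CODES[type_code] if type_code else None,
        grade=int(grade) if grade else None,
        er=get(f"{prefix}_er"),
        pr=get(f"{prefix}_pr"),
        her2=get(f"{prefix}_her2"),
        location_within_4cm=int(loc_val) if loc_val is not None else None,
        age_years=float(age) if age else None,
    )


def load_fixture_tables() -> FixtureTables:
    """Load the packaged transcriptions of the printed study tables.

    Returns the PT/LR, PT/CL and PT/AM clinico-histological tables plus the
    17 PT/LR :class:`PairRecord` rows carrying the copy-number (PIS) score,
    the methylation-similarity (MS) score, time to recurrence and the three
    TR/NP label columns.
    """
    ptlr = _read_fixture("ptlr_clinical.csv")
    ptcl = _read_fixture("ptcl_clinical.csv")
    ptam = _read_fixture("ptam_clinical.csv")
    scores = _read_fixture("ptlr_scores.csv")

    pairs = []
    for _, row in scores.iterrows():
        pairs.append(
            PairRecord(
                pair_id=str(row["pair"]),
                ms_score=float(row["ms_e4"]) * 1e-4,
                pis_score=float(row["pis"]) if row["pis"] is not None else None,
                time_to_recurrence_years=float(row["time_years"]),
                label_ms=row["label_ms"],
                label_pis=row["label_pis"],
                label_clinical=row["label_clinical"],
            )
        )
    return FixtureTables(ptlr, ptcl, ptam, pairs)
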
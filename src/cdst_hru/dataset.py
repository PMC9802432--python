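"""In-memory container and delimited-text I/O for a longitudinal claims extract.

A :class:`ClaimsDataset` bundles the four joinable tables every downstream
stage consumes: a patient roster, insurance-enrollment spans, dated coded
claims with paid amounts, and dated laboratory results.  Tables are plain
:class:`pandas.DataFrame` objects; dates are ``datetime64[ns]``, billing codes
are strings (leading zeros are significant for revenue codes).
"""

from __future__ import annotations

from dataclasses import dataclass, fields as dc_fields
from pathlib import Path

import pandas as pd

PATIENT_COLUMNS = ["patient_id", "birth_year", "sex"]
ENROLLMENT_COLUMNS = ["patient_id", "start_date", "end_date"]
CLAIM_COLUMNS = ["patient_id", "service_date", "code_type", "code", "setting", "paid_amount", "service_year"]
LAB_COLUMNS = ["patient_id", "collection_date", "analyte", "value", "unit"]

_DATE_COLUMNS = {
    "patients": [],
    "enrollment": ["start_date", "end_date"],
    "claims": ["service_date"],
    "labs": ["collection_date"],
}
_STR_COLUMNS = {
    "patients": ["patient_id", "sex"],
    "enrollment": ["patient_id"],
    "claims": ["patient_id", "code_type", "code", "setting"],
    "labs": ["patient_id", "analyte", "unit"],
}

CODE_TYPES = frozenset({"diagnosis", "procedure", "revenue", "drug"})
SETTINGS = frozenset({"inpatient", "outpatient", "ED", "pharmacy"})


class DatasetError(ValueError):
    """A claims table violates the dataset contract or cannot be parsed."""


@dataclass
class ClaimsDataset:
    patients: pd.DataFrame
    enrollment: pd.DataFrame
    claims: pd.DataFrame
    labs: pd.DataFrame

    def table_names(self) -> list[str]:
        return [f.name for f in dc_fields(self)]

    def validate(self) -> None:
        """Raise :class:`DatasetError` on any contract violation."""
        for name, required in (
            ("patients", PATIENT_COLUMNS),
            ("enrollment", ENROLLMENT_COLUMNS),
            ("claims", CLAIM_COLUMNS),
            ("labs", LAB_COLUMNS),
        ):
            frame = getattr(self, name)
            for col in required:
                if col not in frame.columns:
                    raise DatasetError(f"table '{name}': missing required column '{col}'")
        known = set(self.patients["patient_id"])
        for name in ("enrollment", "claims", "labs"):
            unknown = set(getattr(self, name)["patient_id"]) - known
            if unknown:
                raise DatasetError(f"table '{name}': patient_id not in patients table: {sorted(unknown)[:5]}")
        if len(self.enrollment) and (self.enrollment["start_date"] > self.enrollment["end_date"]).any():
            raise DatasetError("table 'enrollment': start_date after end_date")
        if len(self.claims):
            if (self.claims["paid_amount"] < 0).any():
                raise DatasetError("table 'claims': negative paid_amount")
            bad = set(self.claims["code_type"]) - CODE_TYPES
            if bad:
                raise DatasetError(f"table 'claims': unknown code_type {sorted(bad)}")
            bad = set(self.claims["setting"]) - SETTINGS
            if bad:
                raise DatasetError(f"table 'claims': unknown setting {sorted(bad)}")
            self._check_claims_in_enrollment()
        if len(self.labs):
            units = self.labs.groupby("analyte")["unit"].unique()
            for analyte, expected in (("albumin", "g/L"), ("crp", "mg/L")):
                if analyte in units.index and set(units[analyte]) != {expected}:
                    raise DatasetError(f"table 'labs': analyte '{analyte}' must carry unit '{expected}'")

    def _check_claims_in_enrollment(self) -> None:
        # a claim is fine if any of the patient's spans covers it
        merged = (
            self.claims.reset_index()[["index", "patient_id", "service_date"]]
            .merge(self.enrollment, on="patient_id", how="left")
        )
        inside = (merged["service_date"] >= merged["start_date"]) & (merged["service_date"] <= merged["end_date"])
        covered = inside.groupby(merged["index"]).any()
        if not covered.all():
            bad = self.claims.loc[covered.index[~covered]]
            raise DatasetError(
                f"table 'claims': {len(bad)} claim(s) outside every enrollment span, "
                f"first for patient {bad.iloc[0]['patient_id']} on {bad.iloc[0]['service_date'].date()}"
            )

    def equals(self, other: "ClaimsDataset") -> bool:
        return all(
            getattr(self, name).reset_index(drop=True).equals(getattr(other, name).reset_index(drop=True))
            for name in self.table_names()
        )


def empty_dataset() -> ClaimsDataset:
    return ClaimsDataset(
        patients=pd.DataFrame(columns=PATIENT_COLUMNS).astype({"birth_year": "int64"}),
        enrollment=pd.DataFrame(columns=ENROLLMENT_COLUMNS).astype(
            {"start_date": "datetime64[ns]", "end_date": "datetime64[ns]"}
        ),
        claims=pd.DataFrame(columns=CLAIM_COLUMNS).astype(
            {"service_date": "datetime64[ns]", "paid_amount": "float64", "service_year": "int64"}
        ),
        labs=pd.DataFrame(columns=LAB_COLUMNS).astype({"collection_date": "datetime64[ns]", "value": "float64"}),
    )


def write_dataset(dataset: ClaimsDataset, directory: str | Path) -> list[Path]:
    """Write one UTF-8 CSV per table (ISO-8601 dates); returns the paths written."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for name in dataset.table_names():
        frame = getattr(dataset, name).copy()
        for col in _DATE_COLUMNS[name]:
            frame[col] = pd.to_datetime(frame[col]).dt.strftime("%Y-%m-%d")
        path = directory / f"{name}.csv"
        frame.to_csv(path, index=False)
        paths.append(path)
    return paths


def _read_table(path: Path, name: str, required: list[str]) -> pd.DataFrame:
    if not path.exists():
        raise DatasetError(f"{path}: file not found")
    try:
        frame = pd.read_csv(path, dtype={c: "string" for c in _STR_COLUMNS[name]})
    except pd.errors.ParserError as exc:  # pragma: no cover - depends on malformed input
        raise DatasetError(f"{path}: {exc}") from exc
    for col in required:
        if col not in frame.columns:
            raise DatasetError(f"{path}: missing required column '{col}'")
    for col in _STR_COLUMNS[name]:
        frame[col] = frame[col].astype(object)
    for col in _DATE_COLUMNS[name]:
        try:
            frame[col] = pd.to_datetime(frame[col], format="%Y-%m-%d")
        except (ValueError, TypeError) as exc:
            raise DatasetError(f"{path}: column '{col}': unparseable ISO date ({exc})") from exc
    return frame


def read_dataset(directory: str | Path) -> ClaimsDataset:
    """Read the four table CSVs written by :func:`write_dataset`."""
    directory = Path(directory)
    tables = {}
    for name, required in (
        ("patients", PATIENT_COLUMNS),
        ("enrollment", ENROLLMENT_COLUMNS),
        ("claims", CLAIM_COLUMNS),
        ("labs", LAB_COLUMNS),
    ):
        tables[name] = _read_table(directory / f"{name}.csv", name, required)
    if len(tables["patients"]):
        tables["patients"]["birth_year"] = tables["patients"]["birth_year"].astype("int64")
    if len(tables["claims"]):
        tables["claims"]["service_year"] = tables["claims"]["service_year"].astype("int64")
        tables["claims"]["paid_amount"] = tables["claims"]["paid_amount"].astype("float64")
    if len(tables["labs"]):
        tables["labs"]["value"] = tables["labs"]["value"].astype("float64")
    dataset = ClaimsDataset(**tables)
    if not len(dataset.patients):
        return empty_dataset()
    return dataset
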
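"""Cohort records, eligibility filtering and reproduction of the study tables.

Ships three plain-text fixtures under ``petbtv/data``:

* ``table1.csv`` — per-patient SUVmax and segmented volumes (cm³) for all 17
  patients, transcribed verbatim including the symbols ``mCR``, ``±``, ``§``,
  ``¢``, ``¤`` used as missing-data codes in print;
* ``table2.csv`` — per-patient overlap fractions for the 9 analysis-set
  patients;
* ``cohort_flags_synthetic.csv`` — eligibility flags for the 17 patients.
  The mapping of each symbol row to an exclusion reason and the individual
  glucose values are synthetic reconstructions: only the published reason
  counts (4 complete metabolic responses, 1 non-avid, 1 missing post scan,
  1 inseparable uptake, 1 elevated glucose; 9 included) are authoritative.

The analysis set for summary statistics is the set of patients with a full
overlap row (patients 1, 2, 4, 5, 7, 8, 14, 16, 17).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import json

import numpy as np
import pandas as pd

from .overlap import OVERLAP_KEYS, cohort_summary, round_half_up
from .suv import check_eligibility

logger = logging.getLogger(__name__)

MISSING_CODES = ("mCR", "±", "§", "¢", "¤")
VOLUME_KEYS = ("GTV", "Pre40%", "Pre50%", "Post90%", "Post80%", "Post70%", "Post60%")


def data_path(name: str) -> Path:
    return Path(resources.files("petbtv").joinpath("data", name))


@dataclass
class PatientRecord:
    """One cohort row: eligibility flags, SUVmax and per-threshold volumes."""

    patient_id: int
    complete_metabolic_response: bool | None = None
    fdg_avid: bool | None = None
    has_post_scan: bool | None = None
    uptake_separable: bool | None = None
    glucose_baseline: float | None = None
    glucose_post: float | None = None
    suv_max_pre: float | None = None
    suv_max_post: float | None = None
    volumes_cc: dict = field(default_factory=dict)
    overlaps_pct: dict = field(default_factory=dict)
    missing_code: str | None = None


def _parse_cell(raw) -> tuple[float, str | None]:
    text = str(raw).strip()
    if text in ("", "nan", "None"):
        return np.nan, None
    if text in MISSING_CODES:
        return np.nan, text
    return float(text), None


def load_table1(path: str | Path | None = None) -> pd.DataFrame:
    """Per-patient SUVmax and volume table, symbols parsed as missing codes.

    Returns a DataFrame indexed by patient id with float columns (NaN where
    the print shows a symbol or blank) and a ``missing_code`` column holding
    the symbol, if any, seen in that row.
    """
    path = Path(path) if path else data_path("table1.csv")
    raw = pd.read_csv(path, dtype=str)
    if raw.columns[0] != "Patient number":
        raise ValueError(f"{path}: unexpected header {raw.columns[0]!r}")
    rows, codes = {}, {}
    for i, rec in raw.iterrows():
        try:
            pid = int(rec["Patient number"])
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: malformed patient id in data row {i + 1}") from exc
        values, row_code = {}, None
        for col in raw.columns[1:]:
            try:
                val, code = _parse_cell(rec[col])
            except ValueError as exc:
                raise ValueError(f"{path}: malformed cell in data row {i + 1}, column {col!r}") from exc
            values[col] = val
            row_code = row_code or code
        rows[pid] = values
        codes[pid] = row_code
    df = pd.DataFrame.from_dict(rows, orient="index").rename(
        columns={"Pre-treatment SUVmax": "SUVmax_pre", "Post-treatment SUVmax": "SUVmax_post"}
    )
    df["missing_code"] = pd.Series(codes)
    df.index.name = "Patient"
    return df


def load_table2(path: str | Path | None = None) -> pd.DataFrame:
    """Per-patient overlap-fraction table (percent), indexed by patient id."""
    path = Path(path) if path else data_path("table2.csv")
    df = pd.read_csv(path, index_col="Patient")
    missing = [k for k in OVERLAP_KEYS if k not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing overlap columns {missing}")
    return df[list(OVERLAP_KEYS)].astype(float)


def load_cohort_flags(path: str | Path | None = None) -> list[PatientRecord]:
    """Eligibility-flag fixture (synthetic reconstruction, see module docs)."""
    path = Path(path) if path else data_path("cohort_flags_synthetic.csv")
    df = pd.read_csv(path)
    records = []
    for _, rec in df.iterrows():
        records.append(
            PatientRecord(
                patient_id=int(rec["Patient number"]),
                complete_metabolic_response=bool(int(rec["complete_metabolic_response"])),
                fdg_avid=bool(int(rec["fdg_avid"])),
                has_post_scan=bool(int(rec["has_post_scan"])),
                uptake_separable=bool(int(rec["uptake_separable"])),
                glucose_baseline=float(rec["glucose_baseline"]),
                glucose_post=float(rec["glucose_post"]),
            )
        )
    return records


def load_published_summaries(path: str | Path | None = None) -> dict:
    path = Path(path) if path else data_path("published_summaries.json")
    return json.loads(Path(path).read_text())


def analysis_set(table2: pd.DataFrame | None = None) -> list[int]:
    """Patients entering the spatial analysis: those with a full overlap row."""
    t2 = table2 if table2 is not None else load_table2()
    complete = t2.dropna()
    return sorted(int(i) for i in complete.index)


def filter_cohort(records) -> tuple[list[PatientRecord], list[tuple[PatientRecord, str]]]:
    """Apply the eligibility screen to every record, preserving order.

    Returns (included, excluded-with-reason) and logs one line per exclusion.
    Duplicate patient ids are an error.
    """
    ids = [r.patient_id for r in records]
    if len(ids) != len(set(ids)):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate patient ids: {dupes}")
    included, excluded = [], []
    for rec in records:
        result = check_eligibility(rec)
        if result.included:
            included.append(rec)
        else:
            excluded.append((rec, result.reason))
            logger.info("patient %s excluded: %s", rec.patient_id, result.reason)
    return included, excluded


def table1_nesting_ok(table1: pd.DataFrame, patient_ids) -> bool:
    """Check the threshold-nesting volume ordering on the given rows."""
    sub = table1.loc[list(patient_ids)]
    post_ok = (
        (sub["Post90%"] <= sub["Post80%"])
        & (sub["Post80%"] <= sub["Post70%"])
        & (sub["Post70%"] <= sub["Post60%"])
    )
    pre_ok = sub["Pre50%"] <= sub["Pre40%"]
    return bool((post_ok & pre_ok).all())


def reproduce_tables(
    table1_path: str | Path | None = None,
    table2_path: str | Path | None = None,
    summaries_path: str | Path | None = None,
    tol: float = 0.05,
) -> pd.DataFrame:
    """Recompute the analysis-set summary statistics and compare to print.

    Means are computed at full precision over the analysis set, rounded
    half-up to one decimal (table formatting), and compared to the published
    values at ±``tol``.  Returns a report DataFrame with one row per
    quantity: computed value, published value, absolute difference and an
    ``ok`` flag.
    """
    t1 = load_table1(table1_path)
    t2 = load_table2(table2_path)
    published = load_published_summaries(summaries_path)
    ids = analysis_set(t2)

    rows: list[dict] = []

    def add(name: str, computed: float, printed: float) -> None:
        diff = abs(computed - printed)
        rows.append(
            {
                "quantity": name,
                "computed": computed,
                "published": printed,
                "abs_diff": diff,
                "ok": diff <= tol,
            }
        )

    add("analysis_set_size", float(len(ids)), float(published["analysis_set_size"]))
    for key in VOLUME_KEYS:
        summ = cohort_summary(t1.loc[ids, key])
        add(f"mean_{key}_cc", round_half_up(summ.mean), published["table1_mean_cc"][key])
    gtv = cohort_summary(t1.loc[ids, "GTV"])
    add("gtv_min_cc", round_half_up(gtv.min), published["gtv_range_cc"][0])
    add("gtv_max_cc", round_half_up(gtv.max), published["gtv_range_cc"][1])
    for key in OVERLAP_KEYS:
        summ = cohort_summary(t2.loc[ids, key])
        add(f"mean_OF_{key}_pct", round_half_up(summ.mean), published["table2_mean_pct"][key])
    n_partial = int((t2.loc[ids, "Pre40|Post90"] < 100.0).sum())
    add(
        "patients_without_full_post90_containment",
        float(n_partial),
        float(published["patients_without_full_post90_containment"]),
    )

    report = pd.DataFrame(rows)
    report.attrs["analysis_set"] = ids
    report.attrs["nesting_ok"] = table1_nesting_ok(t1, ids)
    return report
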
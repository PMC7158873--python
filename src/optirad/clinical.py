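"""Packaged clinical fixtures: cohort table and overlap/visual-field outcomes.

Two plain-text fixtures ship with the package:

``clinical_table.tsv``
    the published clinical characteristics of the 43-patient paediatric
    epilepsy surgery cohort (age at surgery, post-surgical scan and visual
    assessment intervals, gender, operation, seizure freedom at > 1 year,
    medication), transcribed verbatim including "No data"/"Unavailable"
    entries.
``vf_concordance.tsv``
    the 12 patients with complete pre- and post-operative visual-field
    assessments, with the presence of tract-resection overlap and the
    pre/post visual-field outcome.

Note on known internal inconsistencies of the source cohort description:
the transcribed table contains 21 male patients while the accompanying text
reports 22, and the seizure-freedom rate among the 36 patients with
available information is 25/36 (69%) against a reported 75%.  The fixture
is kept verbatim; summaries report what the table contains.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

__all__ = ["load_clinical_table", "load_concordance_table", "cohort_summary", "concordance"]

_VF_DEFICIT = {"HH", "HSQ", "abnormal"}
_VF_INCOMPLETE = {"abandoned", "none"}


def _fixture_path(name: str):
    path = resources.files("optirad.data").joinpath(name)
    if not path.is_file():
        raise FileNotFoundError(f"packaged fixture {name!r} is missing")
    return path


def load_clinical_table() -> pd.DataFrame:
    """The packaged 43-row clinical cohort table."""
    with resources.as_file(_fixture_path("clinical_table.tsv")) as p:
        df = pd.read_csv(p, sep="\t", dtype=str)
    expected = {
        "patient",
        "age_at_surgery",
        "scan_after_surgery_days",
        "visual_assessment_after_surgery_days",
        "gender",
        "surgery",
        "seizure_freedom",
        "medication",
    }
    if set(df.columns) != expected:
        raise ValueError("clinical fixture is corrupt: unexpected columns")
    if df["patient"].duplicated().any():
        raise ValueError("clinical fixture is corrupt: duplicate patient ids")
    df["age_at_surgery"] = df["age_at_surgery"].astype(float)
    if (df["age_at_surgery"] <= 0).any():
        raise ValueError("clinical fixture is corrupt: non-positive age")
    return df


def load_concordance_table() -> pd.DataFrame:
    """The packaged overlap/visual-field outcome table (complete assessments)."""
    with resources.as_file(_fixture_path("vf_concordance.tsv")) as p:
        df = pd.read_csv(p, sep="\t", dtype=str)
    df["overlap_present"] = df["overlap_present"].map({"True": True, "False": False})
    if df["overlap_present"].isna().any():
        raise ValueError("concordance fixture is corrupt: bad overlap flags")
    return df


def cohort_summary(records: pd.DataFrame) -> dict:
    """Counts, medians and availability for a clinical cohort table."""
    if records.empty:
        raise ValueError("empty clinical table")
    for i, row in records.iterrows():
        if not isinstance(row["patient"], str) or not row["patient"]:
            raise ValueError(f"malformed row {i}: missing patient id")
        if not np.isfinite(float(row["age_at_surgery"])):
            raise ValueError(f"malformed row {i}: bad age")
    available = records[records["seizure_freedom"] != "Unavailable"]
    n_available = len(available)
    n_free = int((available["seizure_freedom"] == "Yes").sum())
    ages = records["age_at_surgery"].astype(float)
    q1, q3 = np.percentile(ages, [25, 75])
    return {
        "n_total": len(records),
        "n_seizure_freedom_available": n_available,
        "n_seizure_free": n_free,
        "seizure_freedom_rate": n_free / n_available if n_available else float("nan"),
        "gender_counts": records["gender"].value_counts().to_dict(),
        "age_median": float(ages.median()),
        "age_iqr": float(q3 - q1),
    }


def concordance(records: pd.DataFrame) -> dict:
    """Overlap/visual-field concordance among complete assessments.

    Restricts to records whose pre- and post-operative assessments are both
    complete, computes the fraction with an acquired deficit (normal before,
    deficit after) together with tract-resection overlap, and checks the
    exact correspondence overlap <=> acquired deficit.
    """
    complete = records[
        ~records["preop_vf"].isin(_VF_INCOMPLETE) & ~records["postop_vf"].isin(_VF_INCOMPLETE)
    ]
    if complete.empty:
        raise ValueError("no records with complete pre- and post-operative assessments")
    acquired = (complete["preop_vf"] == "normal") & complete["postop_vf"].isin(_VF_DEFICIT)
    overlap = complete["overlap_present"].astype(bool)
    n = len(complete)
    n_deficit_overlap = int((acquired & overlap).sum())
    return {
        "n_complete": n,
        "n_acquired_deficit_with_overlap": n_deficit_overlap,
        "deficit_fraction": n_deficit_overlap / n,
        "correspondence_holds": bool((acquired == overlap).all()),
    }
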
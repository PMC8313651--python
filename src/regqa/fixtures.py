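"""Packaged machine-readable copies of the published cohort tables.

Four fixtures ship with the package:

* ``table1`` — the 22-patient expert landmark measurement table (mm
  distances for trachea/main bronchi, 0/1 in-lumen indicators elsewhere,
  NA/NULL missingness codes);
* ``table2`` — the corresponding weighted distance-type quantities and the
  score D per patient;
* ``table4`` — score D plus the six gamma-masked (dis)similarity parameters
  per patient (the printed 1e-7 / 1e-10 scaling of L1norm / L2norm2 is
  undone on load and flagged in ``DataFrame.attrs``);
* ``table5-constants`` — the published correlation/CI constants for the
  three significantly correlated parameters.

File contents are checksummed so silent fixture edits are caught.
"""

from __future__ import annotations

import hashlib
from importlib import resources

import pandas as pd

from .errors import ValidationError
from .landmarks import read_landmark_table

__all__ = ["load_fixture", "fixture_path", "FIXTURE_FILES"]

FIXTURE_FILES = {
    "table1": "table1_landmarks.csv",
    "table2": "table2_scores.csv",
    "table4": "table4_cohort.csv",
    "table5-constants": "table5_constants.csv",
}

_SHA256 = {
    "table1": "8a34168e79a7c29b5e99288bf94193e553c57768f481f8789f1c15dfc59a96d0",
    "table2": "6fdda967b4e2a4812094b1bd5ede6e70ee6af31064eb6d6d11879cda012ce6f2",
    "table4": "04f795a4495d172d083202fb694ec2f257d4ffc199e820df2cf84997cf8ba27d",
    "table5-constants": "d654093a6e84a58ab1e6677565c7fac40757bc8a564a334f1711e97b255bf073",
}


def fixture_path(table_id: str):
    if table_id not in FIXTURE_FILES:
        raise ValidationError(
            f"unknown fixture {table_id!r}; known: {sorted(FIXTURE_FILES)}")
    return resources.files("regqa.data") / FIXTURE_FILES[table_id]


def _verify(table_id: str, raw: bytes) -> None:
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _SHA256[table_id]:
        raise ValidationError(
            f"fixture {table_id} failed its checksum "
            f"(got {digest}, expected {_SHA256[table_id]})")


def load_fixture(table_id: str) -> pd.DataFrame:
    """Load one published table as a patient-indexed DataFrame."""
    path = fixture_path(table_id)
    _verify(table_id, path.read_bytes())
    if table_id == "table1":
        with resources.as_file(path) as p:
            return read_landmark_table(p)
    if table_id == "table2":
        df = pd.read_csv(path, index_col="patient",
                         na_values=["NA"], keep_default_na=False)
        return df.astype(float)
    if table_id == "table4":
        df = pd.read_csv(path, index_col="patient")
        df["l1norm"] = df.pop("l1norm_x1e-7") * 1e7
        df["l2norm2"] = df.pop("l2norm2_x1e-10") * 1e10
        df.attrs["l1norm_scaled_from"] = "printed value x 1e-7"
        df.attrs["l2norm2_scaled_from"] = "printed value x 1e-10"
        return df
    return pd.read_csv(path, index_col="parameter")
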
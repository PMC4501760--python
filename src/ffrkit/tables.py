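"""Subject-table reading/writing and trial-matrix serialization.

Tables are CSV or multi-sheet XLSX (one sheet per figure, columns such as
``actual`` / ``predicted`` plus behavioral-test scores).  Trial matrices
travel as flat little-endian float32 binaries with a JSON sidecar
carrying sample rate, epoch window, and the polarity sequence.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import TrialSet

#: documented column dictionary; unknown columns are preserved but flagged
KNOWN_COLUMNS = {
    "id", "age_months", "sex", "nonverbal_iq", "group", "latent_ability",
    "phonological_awareness", "sentence_recall", "rapid_naming_time",
    "reading_composite", "actual", "predicted", "cin_score",
    "peak_21", "peak_31", "peak_41", "peak_51",
    "h4", "h5", "h6", "h7", "stability_z",
}

KEY_COLUMN = "id"


class SubjectTable:
    """A validated subject table plus any per-sheet extras."""

    def __init__(self, data: pd.DataFrame, unknown_columns=(),
                 bad_rows=(), sheets=None):
        self.data = data
        self.unknown_columns = tuple(unknown_columns)
        self.bad_rows = tuple(bad_rows)
        self.sheets = sheets or {}


def _coerce_numeric(df: pd.DataFrame):
    """Coerce non-key columns to numeric; report rows with malformed cells."""
    bad_rows = []
    out = df.copy()
    for col in out.columns:
        if col in (KEY_COLUMN, "group"):
            continue
        coerced = pd.to_numeric(out[col], errors="coerce")
        newly_bad = coerced.isna() & out[col].notna()
        bad_rows.extend(out.index[newly_bad].tolist())
        out[col] = coerced
    return out, sorted(set(bad_rows))


def read_subject_table(path, layout: str | None = None) -> SubjectTable:
    """Read a subject table from CSV or a sheet-per-figure XLSX workbook.

    Malformed numeric cells are reported per row (and set missing); other
    rows load normally.  The key column ``id`` is mandatory in the main
    table.  For XLSX, every sheet is retained under ``.sheets`` and the
    first sheet containing the key column becomes the main table.
    """
    path = Path(path)
    if layout is None:
        layout = "xlsx-multisheet" if path.suffix.lower() in (".xlsx", ".xls") \
            else "csv"
    if layout == "csv":
        raw = {"main": pd.read_csv(path)}
    elif layout == "xlsx-multisheet":
        raw = pd.read_excel(path, sheet_name=None)
    else:
        raise ValueError(f"unknown layout {layout!r}")

    sheets = {}
    main = None
    bad_all = []
    for name, df in raw.items():
        df, bad = _coerce_numeric(df)
        bad_all.extend((name, r) for r in bad)
        sheets[name] = df
        if main is None and KEY_COLUMN in df.columns:
            main = df
    if main is None:
        # figure-style sheets (paired actual/predicted values) carry no
        # subject key; accept the first such sheet as the main table
        for name, df in sheets.items():
            if {"actual", "predicted"} <= set(df.columns):
                main = df
                break
    if main is None:
        raise KeyError(
            f"no sheet contains the mandatory key column {KEY_COLUMN!r}"
        )
    unknown = [c for c in main.columns if c not in KNOWN_COLUMNS]
    return SubjectTable(main, unknown_columns=unknown, bad_rows=bad_all,
                        sheets=sheets)


def write_subject_table(df: pd.DataFrame, path) -> None:
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        df.to_excel(path, index=False)
    else:
        df.to_csv(path, index=False)


def save_trials(trials: TrialSet, path) -> None:
    """Flat little-endian float32 binary + JSON sidecar."""
    path = Path(path)
    trials.trials.astype("<f4").tofile(path)
    sidecar = {
        "n_trials": trials.n_trials,
        "n_samples": trials.n_samples,
        "sample_rate": trials.sample_rate,
        "epoch_window": list(trials.epoch_window),
        "polarity": trials.polarity.tolist(),
        "dtype": "<f4",
        "units": "uV",
    }
    with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
        json.dump(sidecar, fh)


def load_trials(path) -> TrialSet:
    path = Path(path)
    with open(path.with_suffix(path.suffix + ".json")) as fh:
        sidecar = json.load(fh)
    data = np.fromfile(path, dtype=sidecar["dtype"]).reshape(
        sidecar["n_trials"], sidecar["n_samples"]).astype(float)
    return TrialSet(data, np.array(sidecar["polarity"], dtype=object),
                    sidecar["sample_rate"], tuple(sidecar["epoch_window"]))
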
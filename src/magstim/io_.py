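"""CSV / JSON schemas shared by the pipeline stages.

All tabular artifacts are plain CSV with units spelled out in the column
names (``amplitude_mt``, ``frequency_hz`` ...), so re-ingesting a written
file reproduces the in-memory objects exactly.
"""

from __future__ import annotations

import csv
import json
import warnings
from pathlib import Path

import pandas as pd

from .population import SubjectThreshold
from .psychometric import StimResponse

__all__ = [
    "read_titration_csv",
    "write_titration_csv",
    "read_thresholds_csv",
    "write_thresholds_csv",
    "write_field_map_csv",
    "write_json",
]

TITRATION_COLUMNS = ["subject_id", "run_id", "frequency_hz", "amplitude_mt", "response"]
THRESHOLD_COLUMNS = ["subject_id", "frequency_hz", "b_th_mt", "censored_at_mt"]


def read_titration_csv(path) -> list[StimResponse]:
    """Read titration records, validating each row.

    Malformed rows (missing column, non-binary response, non-positive
    amplitude) raise ``ValueError`` naming the offending line; an empty file
    yields an empty list with a warning.
    """
    path = Path(path)
    out: list[StimResponse] = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            warnings.warn(f"{path}: empty titration file", stacklevel=2)
            return out
        missing = [c for c in TITRATION_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise ValueError(f"{path}: missing required column(s) {missing}")
        for ln, row in enumerate(reader, start=2):
            try:
                resp = int(row["response"])
                if resp not in (0, 1):
                    raise ValueError(f"response must be 0 or 1, got {row['response']}")
                rec = StimResponse(
                    subject_id=row["subject_id"],
                    run_id=row["run_id"],
                    frequency=float(row["frequency_hz"]),
                    amplitude=float(row["amplitude_mt"]),
                    response=resp,
                )
            except (ValueError, KeyError) as exc:
                raise ValueError(f"{path}, line {ln}: {exc}") from exc
            out.append(rec)
    if not out:
        warnings.warn(f"{path}: no titration records", stacklevel=2)
    return out


def write_titration_csv(path, records) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(TITRATION_COLUMNS)
        for r in records:
            w.writerow([r.subject_id, r.run_id, repr(r.frequency), repr(r.amplitude), r.response])


def read_thresholds_csv(path) -> list[SubjectThreshold]:
    """Read the per-(subject, frequency) threshold table (censoring-aware)."""
    df = pd.read_csv(path)
    missing = [c for c in THRESHOLD_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    out = []
    for _, row in df.iterrows():
        b = row["b_th_mt"]
        c = row["censored_at_mt"]
        out.append(
            SubjectThreshold(
                subject_id=str(row["subject_id"]),
                frequency=float(row["frequency_hz"]),
                b_th=None if pd.isna(b) else float(b),
                censored_at=None if pd.isna(c) else float(c),
            )
        )
    return out


def write_thresholds_csv(path, thresholds) -> None:
    rows = [
        {
            "subject_id": t.subject_id,
            "frequency_hz": t.frequency,
            "b_th_mt": t.b_th,
            "censored_at_mt": t.censored_at,
        }
        for t in thresholds
    ]
    pd.DataFrame(rows, columns=THRESHOLD_COLUMNS).to_csv(path, index=False)


def write_field_map_csv(path, samples) -> None:
    """Field-efficiency samples as r_m, z_m, Br_uT_per_A, Bz_uT_per_A, mag_uT_per_A."""
    rows = [
        {
            "r_m": s.r,
            "z_m": s.z,
            "Br_uT_per_A": s.B_r,
            "Bz_uT_per_A": s.B_z,
            "mag_uT_per_A": s.efficiency,
        }
        for s in samples
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
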
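"""Plain-text cohort persistence.

A cohort directory holds one ``metadata.csv`` (subject_id, age, gender, hb_ref,
spo2, heart_rate, fs) and one channel matrix per subject,
``<subject_id>.csv``: a time x 8 table whose header row is the wavelength in
nm.  Everything round-trips losslessly enough for analysis (full float repr).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .synth import MultiChannelPPG, SubjectRecord


def write_cohort(records: list[SubjectRecord], directory: str | Path) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta_rows = []
    for rec in records:
        meta_rows.append({
            "subject_id": rec.subject_id,
            "age": rec.age,
            "gender": rec.gender,
            "hb_ref": rec.hb_ref,
            "spo2": rec.spo2,
            "heart_rate": rec.heart_rate,
            "fs": rec.ppg.fs,
        })
        cols = [f"{int(round(w))}" for w in rec.ppg.wavelengths]
        df = pd.DataFrame(rec.ppg.channels, columns=cols)
        df.to_csv(directory / f"{rec.subject_id}.csv", index=False,
                  float_format="%.10g")
    pd.DataFrame(meta_rows).to_csv(directory / "metadata.csv", index=False)
    return directory


def read_cohort(directory: str | Path) -> list[SubjectRecord]:
    directory = Path(directory)
    meta = pd.read_csv(directory / "metadata.csv")
    records = []
    for _, row in meta.iterrows():
        df = pd.read_csv(directory / f"{row.subject_id}.csv")
        wavelengths = tuple(float(c) for c in df.columns)
        ppg = MultiChannelPPG(channels=df.to_numpy(dtype=float),
                              fs=float(row.fs), wavelengths=wavelengths)
        records.append(SubjectRecord(
            subject_id=str(row.subject_id), ppg=ppg, age=float(row.age),
            gender=int(row.gender), hb_ref=float(row.hb_ref),
            spo2=float(row.get("spo2", np.nan)),
            heart_rate=float(row.get("heart_rate", np.nan)),
        ))
    return records
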
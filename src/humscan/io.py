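"""Readers and writers for the toolkit's tabular and audio formats.

Threshold tables travel as long-format CSV with the header
``participant_id,group,ear,spf_hz,frequency_hz,threshold_db_spl`` (UTF-8,
comma-separated, "." decimal). Ear-canal audio is WAV plus a JSON sidecar
carrying the microphone calibration (pascals per digital unit) and the ear —
there is never a silent default calibration. Supplementary spreadsheets are
converted once into the CSV dialect by :func:`import_supplementary`.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.io import wavfile

from humscan.soae import CalibratedRecording, SoaeCandidate
from humscan.thresholds import ThresholdProfile

THRESHOLD_COLUMNS = [
    "participant_id",
    "group",
    "ear",
    "spf_hz",
    "frequency_hz",
    "threshold_db_spl",
]


def read_threshold_table(path: str | Path) -> list[ThresholdProfile]:
    """Read a long-format threshold CSV into per-(participant, ear) profiles."""
    df = pd.read_csv(path, dtype={"participant_id": str, "group": str, "ear": str})
    missing = set(THRESHOLD_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    for col in ("frequency_hz", "threshold_db_spl"):
        bad = df[pd.to_numeric(df[col], errors="coerce").isna()]
        if len(bad):
            raise ValueError(f"{path}: non-numeric {col} at row {bad.index[0] + 2}")
        df[col] = pd.to_numeric(df[col])
    dup = df.duplicated(subset=["participant_id", "ear", "frequency_hz"])
    if dup.any():
        raise ValueError(
            f"{path}: duplicate (participant, ear, frequency) at row "
            f"{int(np.flatnonzero(dup)[0]) + 2}"
        )
    profiles = []
    for (pid, ear), sub in df.groupby(["participant_id", "ear"], sort=True):
        sub = sub.sort_values("frequency_hz")
        spf_vals = pd.to_numeric(sub["spf_hz"], errors="coerce").dropna().unique()
        if len(spf_vals) > 1:
            raise ValueError(f"{path}: inconsistent spf_hz for {pid}/{ear}")
        group_vals = sub["group"].dropna().unique()
        profiles.append(
            ThresholdProfile(
                participant_id=str(pid),
                ear=str(ear),
                frequencies=sub["frequency_hz"].to_numpy(),
                thresholds=sub["threshold_db_spl"].to_numpy(),
                spf=float(spf_vals[0]) if len(spf_vals) else None,
                group=str(group_vals[0]) if len(group_vals) else "",
            )
        )
    return profiles


def write_threshold_table(profiles: Sequence[ThresholdProfile], path: str | Path) -> None:
    rows = []
    for p in profiles:
        for f, t in zip(p.frequencies, p.thresholds):
            rows.append(
                {
                    "participant_id": p.participant_id,
                    "group": p.group,
                    "ear": p.ear,
                    "spf_hz": "" if p.spf is None else p.spf,
                    "frequency_hz": f,
                    "threshold_db_spl": t,
                }
            )
    pd.DataFrame(rows, columns=THRESHOLD_COLUMNS).to_csv(path, index=False)


def read_recording(wav_path: str | Path, sidecar_path: str | Path) -> CalibratedRecording:
    """Read a mono/stereo WAV and its JSON calibration sidecar.

    Integer WAVs are normalised to full scale before the calibration constant
    (Pa per full-scale unit) is applied; a missing calibration is an error.
    """
    with open(sidecar_path) as fh:
        sidecar = json.load(fh)
    if "calibration_pa_per_unit" not in sidecar:
        raise ValueError(f"{sidecar_path}: calibration_pa_per_unit is required")
    if "ear" not in sidecar:
        raise ValueError(f"{sidecar_path}: ear is required")
    calib = float(sidecar["calibration_pa_per_unit"])
    rate, data = wavfile.read(wav_path)
    data = np.asarray(data)
    if data.dtype.kind == "i":
        data = data / float(2 ** (8 * data.dtype.itemsize - 1))
    elif data.dtype.kind == "u":  # 8-bit WAV is unsigned
        data = (data.astype(float) - 128.0) / 128.0
    samples = data.T if data.ndim == 2 else data[np.newaxis, :]
    return CalibratedRecording(
        samples=samples * calib,
        sampling_rate=float(rate),
        ear=sidecar["ear"],
        calibration=calib,
    )


def write_recording(rec: CalibratedRecording, wav_path: str | Path, sidecar_path: str | Path | None = None) -> None:
    """Write a recording as 32-bit float WAV (samples in pascals) + sidecar."""
    wavfile.write(wav_path, int(rec.sampling_rate), rec.samples.T.astype(np.float32))
    if sidecar_path is not None:
        with open(sidecar_path, "w") as fh:
            json.dump({"calibration_pa_per_unit": 1.0, "ear": rec.ear}, fh, indent=2)


def write_soae_table(candidates: Sequence[SoaeCandidate], path: str | Path) -> None:
    rows = [
        {
            "ear": c.ear,
            "frequency_hz": c.frequency,
            "level_db_spl": c.level,
            "f_statistic": c.f_statistic,
            "noise_floor_db_spl": c.noise_floor_level,
            "source": c.source,
            "valid": c.valid,
        }
        for c in candidates
    ]
    pd.DataFrame(
        rows,
        columns=[
            "ear",
            "frequency_hz",
            "level_db_spl",
            "f_statistic",
            "noise_floor_db_spl",
            "source",
            "valid",
        ],
    ).to_csv(path, index=False)


def import_supplementary(
    xlsx_path: str | Path,
    out_csv: str | Path,
    column_map: dict[str, str] | None = None,
    group: str = "",
    sheet: int | str = 0,
) -> Path:
    """Convert a supplementary spreadsheet into the long CSV dialect.

    ``column_map`` maps spreadsheet column names to the dialect's columns
    (``participant_id``, ``ear``, ``spf_hz``, ``frequency_hz``,
    ``threshold_db_spl``); unmapped dialect columns are filled with defaults.
    Decimal commas (German-locale exports) are normalised to ".".
    """
    df = pd.read_excel(xlsx_path, sheet_name=sheet)
    if column_map:
        df = df.rename(columns=column_map)
    for col in ("spf_hz", "frequency_hz", "threshold_db_spl"):
        if col in df.columns and df[col].dtype == object:
            df[col] = pd.to_numeric(
                df[col].astype(str).str.replace(",", ".", regex=False),
                errors="coerce",
            )
    if "participant_id" not in df.columns or "frequency_hz" not in df.columns:
        raise ValueError("column_map must provide participant_id and frequency_hz")
    if "ear" not in df.columns:
        df["ear"] = "left"
    if "spf_hz" not in df.columns:
        df["spf_hz"] = ""
    df["group"] = group
    out = Path(out_csv)
    df[THRESHOLD_COLUMNS].to_csv(out, index=False)
    return out


def write_provenance(path: str | Path, config: dict, seed: int | None = None) -> None:
    """Record how an output was produced (config, seed, versions)."""
    import humscan

    record = {
        "humscan_version": humscan.__version__,
        "numpy_version": np.__version__,
        "seed": seed,
        "config": config,
    }
    with open(path, "w") as fh:
        json.dump(record, fh, indent=2, default=str)
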
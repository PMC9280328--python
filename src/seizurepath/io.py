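"""CSV/JSON interchange for cohorts, matrices, durations and reports.

All numeric artefacts are plain text: square matrices as CSV with a seizure
id header row and column, durations as two-column CSV, FC feature series as
windows-by-features CSV, and reports/configs as JSON.  Readers validate
(symmetry, positive durations) so malformed files fail at load time.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .connectivity import ConnectivityTimeSeries
from .dissimilarity import DissimilarityMatrix
from .synthetic import SyntheticCohort

__all__ = [
    "write_matrix_csv",
    "read_matrix_csv",
    "write_durations_csv",
    "read_durations_csv",
    "write_fc_csv",
    "read_fc_csv",
    "write_json",
    "read_json",
    "save_cohort",
    "load_cohort_fc",
]


def write_matrix_csv(path, D: DissimilarityMatrix) -> None:
    df = pd.DataFrame(D.values, index=D.seizure_ids, columns=D.seizure_ids)
    df.to_csv(path, index_label="seizure_id")


def read_matrix_csv(path, kind: str = "pathway") -> DissimilarityMatrix:
    df = pd.read_csv(path, index_col=0)
    values = df.to_numpy(dtype=float)
    if values.shape[0] != values.shape[1]:
        raise ValueError(f"{path}: matrix is not square")
    if list(df.index.astype(str)) != list(df.columns.astype(str)):
        raise ValueError(f"{path}: row and column seizure ids disagree")
    if not np.allclose(values, values.T, atol=1e-12):
        raise ValueError(f"{path}: matrix is not symmetric")
    return DissimilarityMatrix(values, list(df.index), kind=kind)


def write_durations_csv(path, durations: dict) -> None:
    pd.DataFrame(
        {"seizure_id": list(durations), "duration_s": list(durations.values())}
    ).to_csv(path, index=False)


def read_durations_csv(path) -> dict:
    df = pd.read_csv(path)
    if list(df.columns) != ["seizure_id", "duration_s"]:
        raise ValueError(f"{path}: expected columns seizure_id,duration_s")
    if (df["duration_s"] <= 0).any():
        raise ValueError(f"{path}: durations must be positive (log transform)")
    return dict(zip(df["seizure_id"], df["duration_s"].astype(float)))


def write_fc_csv(path, fc: ConnectivityTimeSeries) -> None:
    df = pd.DataFrame(fc.features)
    df.insert(0, "window_time_s", fc.window_times)
    df.insert(1, "missing", fc.missing_windows.astype(int))
    df.to_csv(path, index=False)


def read_fc_csv(path, n_channels: int, band_names=None) -> ConnectivityTimeSeries:
    df = pd.read_csv(path)
    kwargs = {} if band_names is None else {"band_names": tuple(band_names)}
    return ConnectivityTimeSeries(
        features=df.drop(columns=["window_time_s", "missing"]).to_numpy(float),
        n_channels=n_channels,
        window_times=df["window_time_s"].to_numpy(float),
        missing_windows=df["missing"].to_numpy(bool),
        **kwargs,
    )


class _NumpyEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        return super().default(o)


def write_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, cls=_NumpyEncoder) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())


def save_cohort(directory, cohort: SyntheticCohort) -> None:
    """Serialise a synthetic cohort as one directory of text files.

    Layout: ``cohort.json`` (config, seed, truth labels), per-seizure
    ``fc_XXXX.csv`` feature series and ``durations.csv``.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = {
        "seed": cohort.seed,
        "config": dataclasses.asdict(cohort.config),
        "seizure_ids": cohort.seizure_ids,
        "n_channels": cohort.config.n_channels,
        "pair_labels": cohort.pair_labels.tolist(),
    }
    write_json(directory / "cohort.json", meta)
    write_durations_csv(directory / "durations.csv", cohort.durations_s)
    for sid in cohort.seizure_ids:
        write_fc_csv(directory / f"fc_{sid:04d}.csv", cohort.fc[sid])


def load_cohort_fc(directory):
    """Load the FC series, durations and truth labels of a saved cohort."""
    directory = Path(directory)
    meta = read_json(directory / "cohort.json")
    durations = read_durations_csv(directory / "durations.csv")
    fc = {
        sid: read_fc_csv(directory / f"fc_{sid:04d}.csv", meta["n_channels"])
        for sid in meta["seizure_ids"]
    }
    labels = np.array(meta["pair_labels"], dtype=object)
    return fc, durations, labels, meta
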
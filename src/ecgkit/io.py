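"""Plain-text readers/writers: record CSV, annotation sidecar, tree bundle,
feature tables and model files.

Record CSV is two columns ``time_s,amplitude_mV`` with a header row (UTF-8);
a headerless two-column file is accepted with a logged warning, assuming
seconds and millivolts.  The annotation sidecar is
``beat_index,mark_name,sample_index``.  A wavelet-packet tree serializes to
a directory of per-node CSV files named ``L{level}_N{position}.csv`` plus a
``meta.json``.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import EmptyInputError, FormatError, IoError
from .features import BEAT_FEATURE_NAMES, FeatureVector
from .record import MARK_NAMES, EcgRecord, FiducialMarks
from .wpt import WptTree

log = logging.getLogger("ecgkit.io")

__all__ = [
    "read_csv_record",
    "write_csv_record",
    "read_annotations",
    "write_annotations",
    "write_tree",
    "read_tree",
    "write_feature_table",
    "read_feature_table",
]

MAX_JITTER_FRACTION = 0.01


def write_csv_record(record: EcgRecord, path) -> None:
    path = Path(path)
    df = pd.DataFrame({"time_s": record.time, "amplitude_mV": record.samples})
    df.to_csv(path, index=False, float_format="%.9g")


def read_csv_record(path) -> EcgRecord:
    """Read a two-column time/amplitude CSV and verify uniform sampling.

    The maximum deviation of consecutive time steps from the median period
    must stay below 1% of the period, otherwise a format error is raised.
    """
    path = Path(path)
    if not path.exists():
        raise IoError(f"no such file: {path}")
    with open(path, "r", encoding="utf-8") as fh:
        first_line = fh.readline().strip()
    if not first_line:
        raise EmptyInputError(f"{path} is empty")
    first_fields = first_line.split(",")
    try:
        [float(v) for v in first_fields[:2]]
        headerless = True
    except ValueError:
        headerless = False
    try:
        if headerless:
            log.warning("%s: no header row; assuming columns time_s,amplitude_mV",
                        path)
            df = pd.read_csv(path, header=None)
        else:
            df = pd.read_csv(path)
            cols = [str(c).strip().lower() for c in df.columns]
            if cols[:2] != ["time_s", "amplitude_mv"]:
                raise FormatError(
                    f"{path}: unrecognized header {list(df.columns)!r}")
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"{path} is empty") from None
    if df.shape[1] < 2:
        raise FormatError(f"{path} must have two columns (time, amplitude)")
    data = df.iloc[:, :2].to_numpy(dtype=np.float64)
    if data.shape[0] == 0:
        raise EmptyInputError(f"{path} contains no samples")
    t, x = data[:, 0], data[:, 1]
    if t.size < 2:
        raise FormatError(f"{path}: need at least two samples")
    dt = np.diff(t)
    period = float(np.median(dt))
    if period <= 0 or np.any(dt <= 0):
        raise FormatError(f"{path}: time column is not strictly increasing")
    if np.max(np.abs(dt - period)) > MAX_JITTER_FRACTION * period:
        raise FormatError(f"{path}: sampling is not uniform (jitter > 1% of period)")
    return EcgRecord(samples=x, sampling_rate=1.0 / period)


def write_annotations(marks: FiducialMarks, path) -> None:
    rows = []
    for beat in range(marks.n_beats):
        for name in MARK_NAMES:
            rows.append((beat, name, int(getattr(marks, name)[beat])))
    pd.DataFrame(rows, columns=["beat_index", "mark_name", "sample_index"]).to_csv(
        Path(path), index=False)


def read_annotations(path) -> FiducialMarks:
    path = Path(path)
    if not path.exists():
        raise IoError(f"no such file: {path}")
    df = pd.read_csv(path)
    expected = {"beat_index", "mark_name", "sample_index"}
    if not expected.issubset(df.columns):
        raise FormatError(f"{path}: annotation sidecar needs columns {sorted(expected)}")
    n_beats = int(df["beat_index"].max()) + 1 if len(df) else 0
    arrays = {name: np.full(n_beats, -1, dtype=np.int64) for name in MARK_NAMES}
    for _, row in df.iterrows():
        name = str(row["mark_name"])
        if name not in arrays:
            raise FormatError(f"{path}: unknown mark name {name!r}")
        arrays[name][int(row["beat_index"])] = int(row["sample_index"])
    return FiducialMarks(**arrays)


def write_tree(tree: WptTree, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = {
        "levels": tree.levels,
        "source_length": tree.source_length,
        "sampling_rate": tree.sampling_rate,
        "boundary_mode": tree.boundary_mode,
        "wavelet_order": tree.wavelet_order,
    }
    (directory / "meta.json").write_text(json.dumps(meta, indent=2))
    for (level, pos), arr in tree.nodes.items():
        np.savetxt(directory / f"L{level}_N{pos}.csv", arr, fmt="%.17g")


def read_tree(directory) -> WptTree:
    directory = Path(directory)
    meta_path = directory / "meta.json"
    if not meta_path.exists():
        raise IoError(f"no tree bundle at {directory}")
    meta = json.loads(meta_path.read_text())
    nodes: Dict[Tuple[int, int], np.ndarray] = {}
    for level in range(meta["levels"] + 1):
        for pos in range(2**level):
            f = directory / f"L{level}_N{pos}.csv"
            if not f.exists():
                raise IoError(f"tree bundle missing node file {f.name}")
            nodes[(level, pos)] = np.atleast_1d(np.loadtxt(f, dtype=np.float64))
    tree = WptTree(levels=meta["levels"], nodes=nodes,
                   source_length=meta["source_length"],
                   sampling_rate=meta["sampling_rate"],
                   boundary_mode=meta["boundary_mode"],
                   wavelet_order=meta["wavelet_order"])
    tree.validate()
    return tree


def write_feature_table(features: Sequence[FeatureVector], path,
                        labels: Optional[Sequence[str]] = None) -> None:
    rows = [{name: getattr(fv, name) for name in BEAT_FEATURE_NAMES}
            for fv in features]
    df = pd.DataFrame(rows, columns=list(BEAT_FEATURE_NAMES))
    if labels is not None:
        df["label"] = list(labels)
    df.to_csv(Path(path), index=False)


def read_feature_table(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise IoError(f"no such file: {path}")
    df = pd.read_csv(path)
    missing = [c for c in BEAT_FEATURE_NAMES if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: feature table missing columns {missing}")
    return df
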
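"""Readers/writers for every on-disk artefact of the pipeline.

All exchange formats are plain text: tab-separated tables for time series,
motion parameters and matrices (the convention used for neuroimaging
derivatives such as BIDS confound files), JSON for community partitions, and
YAML for run configuration.  Readers validate strictly and never silently
drop rows or columns; writers and readers are mutually inverse at full float
precision.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "RoiTimeSeries",
    "MotionTrace",
    "ParseError",
    "ValidationError",
    "NETWORK_NAMES",
    "SESSION_IDS",
    "validate_roi_table",
    "read_timeseries",
    "write_timeseries",
    "read_matrix",
    "write_matrix",
    "read_motion",
    "write_motion",
    "write_partitions",
    "read_partitions",
    "read_config",
]

#: The eight canonical functional networks used for node grouping, in the
#: fixed reporting order (default mode, somatomotor, visual, salience,
#: dorsal attention, frontoparietal, language, cerebellar).
NETWORK_NAMES: tuple[str, ...] = (
    "DMN", "SMN", "Visual", "SN", "DA", "FP", "LN", "CN",
)

SESSION_IDS = frozenset({"task1", "task2", "rest", "custom"})

MOTION_COLUMNS = ("trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z")


class ParseError(ValueError):
    """A text file could not be parsed into the expected table."""


class ValidationError(ValueError):
    """A parsed object violates a structural invariant."""


@dataclass
class RoiTimeSeries:
    """A volumes-by-ROIs BOLD signal matrix.

    Parameters
    ----------
    data
        Real matrix of shape ``(n_vols, n_rois)``; arbitrary signal units.
    tr_s
        Repetition time in seconds (time between consecutive volumes).
    roi_labels
        One unique label per column, order preserved.
    subject_id, session_id
        Provenance labels; ``session_id`` is one of ``task1``, ``task2``,
        ``rest`` or ``custom``.
    """

    data: np.ndarray
    tr_s: float
    roi_labels: list[str]
    subject_id: str = "sub-01"
    session_id: str = "custom"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.roi_labels = [str(x) for x in self.roi_labels]
        if self.data.ndim != 2:
            raise ValidationError("time-series data must be 2-D (volumes x ROIs)")
        if self.data.shape[0] < 2:
            raise ValidationError("time series needs at least 2 volumes")
        if not np.all(np.isfinite(self.data)):
            raise ValidationError("time series contains non-finite values")
        if len(self.roi_labels) != self.data.shape[1]:
            raise ValidationError(
                f"{len(self.roi_labels)} labels for {self.data.shape[1]} columns"
            )
        if len(set(self.roi_labels)) != len(self.roi_labels):
            raise ValidationError("duplicate ROI labels")
        if not self.tr_s > 0:
            raise ValidationError("tr_s must be positive")
        if self.session_id not in SESSION_IDS:
            raise ValidationError(
                f"session_id {self.session_id!r} not in {sorted(SESSION_IDS)}"
            )

    @property
    def n_vols(self) -> int:
        return self.data.shape[0]

    @property
    def n_rois(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_vols * self.tr_s

    def with_data(self, data: np.ndarray, **changes) -> "RoiTimeSeries":
        return replace(self, data=data, **changes)


@dataclass
class MotionTrace:
    """Six rigid-body realignment parameters per volume.

    Columns are x/y/z translations in millimetres followed by x/y/z
    rotations in radians.
    """

    data: np.ndarray
    tr_s: float = 2.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[1] != 6:
            raise ValidationError("motion trace must have 6 columns")
        if self.data.shape[0] < 2:
            raise ValidationError("motion trace needs at least 2 volumes")
        if not np.all(np.isfinite(self.data)):
            raise ValidationError("motion trace contains non-finite values")

    @property
    def n_vols(self) -> int:
        return self.data.shape[0]

    @property
    def translations(self) -> np.ndarray:
        return self.data[:, :3]

    @property
    def rotations(self) -> np.ndarray:
        return self.data[:, 3:]


ROI_TABLE_COLUMNS = (
    "label", "hemisphere", "network", "brodmann_area", "x", "y", "z",
)


def validate_roi_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the structural invariants of an ROI definition table.

    Required columns: label, hemisphere (L/R), network (one of the eight
    canonical names), brodmann_area (integer or missing), and MNI x/y/z in
    millimetres.  Labels must be unique.
    """
    missing = set(ROI_TABLE_COLUMNS) - set(table.columns)
    if missing:
        raise ValidationError(f"ROI table missing columns: {sorted(missing)}")
    if table["label"].duplicated().any():
        dupes = table.loc[table["label"].duplicated(), "label"].tolist()
        raise ValidationError(f"duplicate ROI labels: {dupes}")
    bad_hemi = set(table["hemisphere"]) - {"L", "R"}
    if bad_hemi:
        raise ValidationError(f"hemisphere values outside L/R: {sorted(bad_hemi)}")
    bad_net = set(table["network"]) - set(NETWORK_NAMES)
    if bad_net:
        raise ValidationError(f"unknown network names: {sorted(bad_net)}")
    return table


#: %.17g guarantees bit-exact float round trips through text.
_FLOAT_FORMAT = "%.17g"


def _read_numeric_tsv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if len(set(header)) != len(header):
        raise ValidationError(f"{path}: duplicate column labels in header")
    df = pd.read_csv(path, sep="\t", skiprows=1, header=None, dtype=str,
                     keep_default_na=False)
    if df.shape[1] != len(header):
        raise ParseError(
            f"{path}: {df.shape[1]} data columns for {len(header)} header labels"
        )
    out = pd.DataFrame(index=df.index)
    for i, col in enumerate(header):
        values = np.empty(len(df), dtype=float)
        for row, cell in enumerate(df[i]):
            try:
                values[row] = float(cell)  # exact, unlike pandas' fast parser
            except (TypeError, ValueError):
                values[row] = np.nan
            if not np.isfinite(values[row]):
                raise ParseError(
                    f"{path}: non-numeric value {cell!r} "
                    f"at row {row + 1}, column {col!r}"
                )
        out[col] = values
    return out


def read_timeseries(
    path: str | Path,
    tr_s: float,
    subject_id: str = "sub-01",
    session_id: str = "custom",
) -> RoiTimeSeries:
    """Read an ROI time series from a TSV file (header row = ROI labels)."""
    df = _read_numeric_tsv(path)
    return RoiTimeSeries(
        data=df.to_numpy(dtype=float),
        tr_s=tr_s,
        roi_labels=list(df.columns),
        subject_id=subject_id,
        session_id=session_id,
    )


def write_timeseries(ts: RoiTimeSeries, path: str | Path) -> Path:
    """Write a time series as TSV with ROI labels as the header row."""
    path = Path(path)
    pd.DataFrame(ts.data, columns=ts.roi_labels).to_csv(
        path, sep="\t", index=False, float_format=_FLOAT_FORMAT
    )
    return path


def write_matrix(
    m: np.ndarray, labels: Sequence[str], path: str | Path
) -> Path:
    """Write a square labelled matrix as TSV at full float precision."""
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValidationError(f"matrix must be square, got shape {m.shape}")
    if len(labels) != m.shape[0]:
        raise ValidationError(
            f"{len(labels)} labels for a {m.shape[0]}x{m.shape[0]} matrix"
        )
    path = Path(path)
    df = pd.DataFrame(m, index=list(labels), columns=list(labels))
    df.to_csv(path, sep="\t", index=True, index_label="roi",
              float_format=_FLOAT_FORMAT)
    return path


def read_matrix(path: str | Path) -> tuple[np.ndarray, list[str]]:
    """Read a labelled square matrix written by :func:`write_matrix`."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    if list(df.index) != list(df.columns):
        raise ValidationError(f"{path}: row labels differ from column labels")
    return df.to_numpy(dtype=float), list(df.columns)


def write_motion(m: MotionTrace, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(m.data, columns=list(MOTION_COLUMNS)).to_csv(
        path, sep="\t", index=False, float_format=_FLOAT_FORMAT
    )
    return path


def read_motion(path: str | Path, tr_s: float = 2.0) -> MotionTrace:
    df = _read_numeric_tsv(path)
    if list(df.columns) != list(MOTION_COLUMNS):
        raise ValidationError(
            f"{path}: expected columns {MOTION_COLUMNS}, got {list(df.columns)}"
        )
    return MotionTrace(data=df.to_numpy(dtype=float), tr_s=tr_s)


def write_partitions(seq, path: str | Path) -> Path:
    """Write a :class:`~dynfc.dynamics.CommunitySequence` as a JSON array.

    One object per window: window index, start/end time in seconds, the
    node-to-community assignment, and the modularity Q of that partition.
    Community ids are 0-based integers, stable only within one document.
    """
    if not seq.partitions:
        raise ValidationError("empty community sequence")
    records = []
    for i, (part, start) in enumerate(zip(seq.partitions, seq.window_starts_s)):
        records.append(
            {
                "window_index": i,
                "window_start_s": float(start),
                "window_end_s": float(start + seq.window_length_s),
                "assignment": {k: int(v) for k, v in part.assignment.items()},
                "modularity_Q": float(part.Q),
            }
        )
    path = Path(path)
    path.write_text(json.dumps(records, indent=1))
    return path


def read_partitions(path: str | Path):
    """Read a partition JSON back into a CommunitySequence (unaligned)."""
    from .communities import Partition
    from .dynamics import CommunitySequence

    records = json.loads(Path(path).read_text())
    if not records:
        raise ValidationError(f"{path}: empty partition document")
    parts = [
        Partition.from_assignment(r["assignment"], Q=r["modularity_Q"],
                                  canonical=False)
        for r in records
    ]
    starts = [r["window_start_s"] for r in records]
    length = records[0]["window_end_s"] - records[0]["window_start_s"]
    return CommunitySequence(
        partitions=parts, window_starts_s=starts,
        window_length_s=length, aligned=False,
    )


CONFIG_KEYS = {"tr_s", "window_s", "step_vols", "fdr_q", "seed"}


def read_config(path: str | Path) -> dict:
    """Load a YAML run configuration (tr_s, window_s, step_vols, fdr_q, seed)."""
    cfg = yaml.safe_load(Path(path).read_text())
    if not isinstance(cfg, dict):
        raise ParseError(f"{path}: config must be a mapping")
    unknown = set(cfg) - CONFIG_KEYS
    if unknown:
        raise ValidationError(f"{path}: unknown config keys {sorted(unknown)}")
    return cfg
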
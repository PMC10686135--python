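"""On-disk representation of single-cell tracking datasets.

A dataset is a pair of UTF-8 CSV files:

* a **track table** with header ``cell_id,frame,time_h,x,y`` — one row per
  cell per observed frame, positions in the spatial unit recorded in the
  metadata (micrometres by default, image convention: x rightward, y
  downward);
* a **cell table** with header ``cell_id,parent_id,birth_time_h,end_time_h,fate``
  — one row per cell, the empty string in ``parent_id`` marking a root
  (a cell already present at the start of recording).

A cell's *fate* is the terminal event of its track: ``DIVIDED`` (binary
division into exactly two daughters), ``DEATH_APOPTOTIC`` or
``DEATH_NECROTIC`` (the two death morphologies distinguished by the
tracking annotation), ``ALIVE_AT_END`` (still alive when recording stops),
or ``LOST`` (left the field of view / tracking failure).  Lost cells are
admitted because they are unavoidable in real tracking data; downstream
census statistics treat them as leaving the population without dying.

Times are hours since the start of recording.  The integer frame index is
retained for traceability (frame 0 at time 0); statistics use hours only.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import FormatError, LineageError, OrderingError, DatasetValidationError

TRACK_COLUMNS = ["cell_id", "frame", "time_h", "x", "y"]
CELL_COLUMNS = ["cell_id", "parent_id", "birth_time_h", "end_time_h", "fate"]

FATE_DIVIDED = "DIVIDED"
FATE_DEATH_APOPTOTIC = "DEATH_APOPTOTIC"
FATE_DEATH_NECROTIC = "DEATH_NECROTIC"
FATE_ALIVE_AT_END = "ALIVE_AT_END"
FATE_LOST = "LOST"

FATES = frozenset(
    {FATE_DIVIDED, FATE_DEATH_APOPTOTIC, FATE_DEATH_NECROTIC, FATE_ALIVE_AT_END, FATE_LOST}
)
DEATH_FATES = frozenset({FATE_DEATH_APOPTOTIC, FATE_DEATH_NECROTIC})

#: tolerance for comparing event times that should coincide (division/birth)
TIME_TOL = 1e-9


@dataclass
class DatasetMeta:
    """Recording metadata: frame interval and duration in hours, an
    exposure label (free text, e.g. a toxin concentration), and the
    spatial unit of the coordinates."""

    frame_interval_h: float = 0.1
    duration_h: float = 94.0
    exposure: str = ""
    spatial_unit: str = "um"


@dataclass
class Dataset:
    """In-memory tracking dataset: per-frame positions plus lineage records.

    ``tracks`` has columns ``cell_id, frame, time_h, x, y`` and
    ``cells`` has columns ``cell_id, parent_id, birth_time_h, end_time_h,
    fate`` with ``parent_id`` equal to ``None`` for roots.
    """

    tracks: pd.DataFrame
    cells: pd.DataFrame
    meta: DatasetMeta = field(default_factory=DatasetMeta)

    def copy(self) -> "Dataset":
        return Dataset(self.tracks.copy(), self.cells.copy(), replace(self.meta))

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def root_ids(self) -> list[str]:
        mask = self.cells["parent_id"].isna()
        return list(self.cells.loc[mask, "cell_id"])

    def cell_tracks(self, cell_id: str) -> pd.DataFrame:
        return self.tracks[self.tracks["cell_id"] == cell_id]


@dataclass(frozen=True)
class Violation:
    """One invariant violation found by :func:`validate_dataset`."""

    cell_id: str
    rule: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.rule}] {self.cell_id}: {self.message}"


def _empty_tracks() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cell_id": pd.Series(dtype=object),
            "frame": pd.Series(dtype=np.int64),
            "time_h": pd.Series(dtype=float),
            "x": pd.Series(dtype=float),
            "y": pd.Series(dtype=float),
        }
    )


def _empty_cells() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cell_id": pd.Series(dtype=object),
            "parent_id": pd.Series(dtype=object),
            "birth_time_h": pd.Series(dtype=float),
            "end_time_h": pd.Series(dtype=float),
            "fate": pd.Series(dtype=object),
        }
    )


def _read_csv(path, columns: list[str], dtypes: dict) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed CSV
        raise FormatError(f"{path}: cannot parse CSV: {exc}") from exc
    if list(df.columns) != columns:
        raise FormatError(
            f"{path}: expected header {','.join(columns)!r}, found {','.join(map(str, df.columns))!r}"
        )
    for col, dt in dtypes.items():
        try:
            df[col] = df[col].astype(dt)
        except (TypeError, ValueError) as exc:
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
            line = int(bad[0]) + 2 if len(bad) else "?"
            raise FormatError(f"{path}: column {col!r} not numeric at line {line}") from exc
    return df


def read_dataset(track_path, cell_path, meta: DatasetMeta | None = None) -> Dataset:
    """Read and validate a dataset from its two canonical CSV files.

    Raises :class:`FormatError` on malformed files, and
    :class:`OrderingError` / :class:`LineageError` /
    :class:`DatasetValidationError` when the content violates the dataset
    invariants (the message names the offending cell).
    """
    tracks = _read_csv(
        track_path, TRACK_COLUMNS, {"frame": np.int64, "time_h": float, "x": float, "y": float}
    )
    cells = _read_csv(
        cell_path, CELL_COLUMNS, {"birth_time_h": float, "end_time_h": float}
    )
    cells["parent_id"] = cells["parent_id"].where(cells["parent_id"] != "", other=None)
    if len(tracks) == 0:
        tracks = _empty_tracks()
    if len(cells) == 0:
        cells = _empty_cells()
    ds = Dataset(tracks.reset_index(drop=True), cells.reset_index(drop=True),
                 meta or DatasetMeta())
    violations = validate_dataset(ds)
    if violations:
        rules = {v.rule for v in violations}
        if rules & {"track-order", "time-order"}:
            raise OrderingError(str(DatasetValidationError(violations)))
        if rules & {"orphan-parent", "parent-cycle"}:
            raise LineageError(str(DatasetValidationError(violations)))
        raise DatasetValidationError(violations)
    return ds


def write_dataset(ds: Dataset, track_path, cell_path) -> None:
    """Write a dataset to the two canonical CSV files.

    Floats are written with ``repr`` precision, so
    ``read_dataset(write_dataset(ds))`` reproduces coordinates exactly.
    """
    tracks = ds.tracks[TRACK_COLUMNS]
    cells = ds.cells[CELL_COLUMNS].copy()
    cells["parent_id"] = cells["parent_id"].fillna("")
    tracks.to_csv(track_path, index=False)
    cells.to_csv(cell_path, index=False)


def dataset_to_strings(ds: Dataset) -> tuple[str, str]:
    """Serialize a dataset to its two canonical CSV texts (tracks, cells)."""
    tbuf, cbuf = io.StringIO(), io.StringIO()
    write_dataset(ds, tbuf, cbuf)
    return tbuf.getvalue(), cbuf.getvalue()


def validate_dataset(ds: Dataset) -> list[Violation]:
    """Check every dataset invariant and return the violations found.

    Violations are data, not exceptions: an empty list means the dataset is
    valid.  The report is deterministic, sorted by (cell_id, rule).
    """
    out: list[Violation] = []
    cells = ds.cells
    tracks = ds.tracks

    dup = cells["cell_id"][cells["cell_id"].duplicated()]
    for cid in dup.unique():
        out.append(Violation(cid, "duplicate-id", "cell_id appears more than once in cell table"))

    by_id = cells.set_index("cell_id", drop=False)
    ids = set(cells["cell_id"])

    for row in cells.itertuples(index=False):
        cid = row.cell_id
        if row.fate not in FATES:
            out.append(Violation(cid, "bad-fate", f"unknown fate {row.fate!r}"))
        if not (row.birth_time_h < row.end_time_h):
            out.append(
                Violation(cid, "lifespan", f"birth {row.birth_time_h} not before end {row.end_time_h}")
            )
        pid = row.parent_id
        if pid is not None and not (isinstance(pid, float) and math.isnan(pid)):
            if pid not in ids:
                out.append(Violation(cid, "orphan-parent", f"parent {pid!r} not in cell table"))

    children: dict[str, list] = {}
    for row in cells.itertuples(index=False):
        pid = row.parent_id
        if pid is not None and not (isinstance(pid, float) and math.isnan(pid)) and pid in ids:
            children.setdefault(pid, []).append(row)
    for row in cells.itertuples(index=False):
        cid = row.cell_id
        kids = children.get(cid, [])
        if row.fate == FATE_DIVIDED:
            if len(kids) != 2:
                out.append(
                    Violation(cid, "divided-children", f"DIVIDED cell has {len(kids)} children, expected 2")
                )
            else:
                for k in kids:
                    if abs(k.birth_time_h - row.end_time_h) > TIME_TOL:
                        out.append(
                            Violation(
                                cid,
                                "division-time",
                                f"child {k.cell_id} born at {k.birth_time_h}, mother ends at {row.end_time_h}",
                            )
                        )
        elif kids:
            out.append(
                Violation(cid, "divided-children", f"fate {row.fate} but has {len(kids)} children")
            )

    track_ids = set(tracks["cell_id"].unique()) if len(tracks) else set()
    for cid in sorted(track_ids - ids):
        out.append(Violation(cid, "missing-cell", "cell_id in track table but not in cell table"))
    for cid in sorted(ids - track_ids):
        out.append(Violation(cid, "missing-track", "cell_id in cell table but has no track points"))

    if len(tracks):
        bad = ~np.isfinite(tracks[["x", "y"]].to_numpy()).all(axis=1)
        for cid in sorted(tracks.loc[bad, "cell_id"].unique()):
            out.append(Violation(cid, "coord-finite", "non-finite x or y"))
        neg = tracks["time_h"].to_numpy() < 0
        for cid in sorted(tracks.loc[neg, "cell_id"].unique()):
            out.append(Violation(cid, "time-negative", "track time before start of recording"))
        for cid, grp in tracks.groupby("cell_id", sort=True):
            f = grp["frame"].to_numpy()
            t = grp["time_h"].to_numpy()
            if len(f) > 1 and not (np.diff(f) > 0).all():
                out.append(Violation(cid, "track-order", "frames not strictly increasing"))
            if len(t) > 1 and not (np.diff(t) > 0).all():
                out.append(Violation(cid, "time-order", "times not strictly increasing"))
            if cid in ids:
                rec = by_id.loc[cid]
                if isinstance(rec, pd.DataFrame):  # duplicated id, already reported
                    continue
                lo = float(rec["birth_time_h"]) - TIME_TOL
                hi = float(rec["end_time_h"]) + TIME_TOL
                if (t < lo).any() or (t > hi).any():
                    out.append(
                        Violation(cid, "points-outside-lifespan", "track points outside [birth, end]")
                    )

    out.sort(key=lambda v: (v.cell_id, v.rule))
    return out
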
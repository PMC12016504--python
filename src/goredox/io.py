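"""Structured file I/O: point CSVs, series tables, simulated image dirs.

Formats are deliberately plain: comma-separated UTF-8 with a mandatory
header row and ``.`` decimal separator.

* points CSV:  ``sample_id,row,col`` — 0-based full-image pixel coordinates
* series CSV:  ``sample_id,time_h,mean_value,sd_value,n_points`` plus
  optional ``group`` (replicate grouping) and ``baseline_subtracted``
* replicate series CSV (onset input): ``time_h,value``, one row per
  replicate per timepoint
* simulated images: ``{sample}_{time_h}h_{rep}.png`` plus ``truth.csv``
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .errors import GoredoxError
from .sampling import PointSet

SERIES_COLUMNS = ["sample_id", "time_h", "mean_value", "sd_value", "n_points"]
_SIM_NAME_RE = re.compile(r"^(?P<sample>.+)_(?P<time>[0-9]+(?:\.[0-9]+)?)h_(?P<rep>\d+)$")


def read_points_csv(path: str | Path) -> dict[str, PointSet]:
    """Read a ``sample_id,row,col`` CSV into one PointSet per sample."""
    try:
        df = pd.read_csv(path)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise GoredoxError(f"malformed points CSV {path}: {exc}") from exc
    required = {"sample_id", "row", "col"}
    if set(df.columns) < required:
        raise GoredoxError(
            f"points CSV {path} must have columns {sorted(required)}, "
            f"got {list(df.columns)}"
        )
    out: dict[str, PointSet] = {}
    for sid, grp in df.groupby("sample_id", sort=False):
        pts = tuple((int(r), int(c)) for r, c in zip(grp["row"], grp["col"]))
        out[str(sid)] = PointSet(str(sid), pts)
    return out


def write_points_csv(points: PointSet, path: str | Path) -> None:
    rows = [{"sample_id": points.sample_id, "row": r, "col": c} for r, c in points.points]
    pd.DataFrame(rows, columns=["sample_id", "row", "col"]).to_csv(path, index=False)


def read_series_csv(path: str | Path) -> pd.DataFrame:
    """Read and validate a series table (one row per sample × timepoint)."""
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise GoredoxError(f"malformed series CSV {path}: {exc}") from exc
    missing = [c for c in SERIES_COLUMNS if c not in df.columns]
    if missing:
        raise GoredoxError(f"series CSV {path} missing columns {missing}")
    if df.duplicated(subset=["sample_id", "time_h"]).any():
        raise GoredoxError(f"series CSV {path}: duplicate (sample_id, time_h) rows")
    return df


def write_series_csv(table: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in SERIES_COLUMNS + ["group", "baseline_subtracted"] if c in table.columns]
    table.to_csv(path, index=False, columns=cols)


def read_replicate_series_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a ``time_h,value`` replicate CSV into (times, (T, n_rep) array).

    Every timepoint must carry the same number of replicate rows.
    """
    try:
        df = pd.read_csv(path)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise GoredoxError(f"malformed replicate CSV {path}: {exc}") from exc
    if not {"time_h", "value"} <= set(df.columns):
        raise GoredoxError(f"replicate CSV {path} needs columns time_h,value")
    counts = df.groupby("time_h")["value"].count()
    if counts.nunique() != 1:
        raise GoredoxError(
            f"replicate CSV {path}: unequal replicate counts across timepoints"
        )
    times = np.array(sorted(counts.index), dtype=float)
    reps = np.stack(
        [df.loc[df["time_h"] == t, "value"].to_numpy(dtype=float) for t in times]
    )
    return times, reps


def read_values_file(path: str | Path) -> np.ndarray:
    """Read a one-value-per-line text file of floats."""
    try:
        vals = [float(line) for line in Path(path).read_text().split()]
    except ValueError as exc:
        raise GoredoxError(f"non-numeric entry in {path}: {exc}") from exc
    if not vals:
        raise GoredoxError(f"no values in {path}")
    return np.array(vals)


def parse_sim_filename(path: str | Path) -> tuple[str, float, int] | None:
    """Parse ``{sample}_{time_h}h_{rep}`` from a filename stem, else None."""
    m = _SIM_NAME_RE.match(Path(path).stem)
    if m is None:
        return None
    return m.group("sample"), float(m.group("time")), int(m.group("rep"))


def sim_filename(sample: str, time_h: float, rep: int) -> str:
    t = f"{time_h:g}"
    return f"{sample}_{t}h_{rep}.png"


def save_image(image: np.ndarray, path: str | Path) -> None:
    Image.fromarray(np.asarray(image, dtype=np.uint8), mode="RGB").save(path)
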
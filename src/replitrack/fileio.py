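"""File formats: multi-page TIFF stacks, schema-checked CSV tables, YAML
configuration and JSON summaries.

Conventions: image stacks are 16-bit unsigned TIFF; coordinates are 0-based
pixels; axial positions are µm from the old pole; times are minutes.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .detect import FOCI_COLUMNS

__all__ = [
    "write_stack", "read_stack",
    "write_table", "read_table",
    "write_summary", "read_summary",
    "save_cell", "load_cell",
    "FOCI_COLUMNS", "EVENT_COLUMNS", "SEGREGATION_COLUMNS", "STEP_COLUMNS",
    "GROWTH_COLUMNS",
]

EVENT_COLUMNS = ["cell_id", "kind", "onset_frame", "onset_tau", "duration",
                 "rel_duration", "first_onset_tau", "merged"]
SEGREGATION_COLUMNS = ["cell_id", "T_seg", "dim_class"]
STEP_COLUMNS = ["cell_id", "track_id", "frame", "step_nm", "location_class"]
GROWTH_COLUMNS = ["time_min", "absorbance"]
GEOMETRY_COLUMNS = ["frame", "length_um", "old_pole_x", "old_pole_y",
                    "new_pole_x", "new_pole_y", "constriction_um"]


def write_stack(path, stack: np.ndarray) -> None:
    """Write a (T, H, W) stack as multi-page 16-bit unsigned TIFF."""
    data = np.clip(np.round(stack), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    tifffile.imwrite(str(path), data)


def read_stack(path) -> np.ndarray:
    return tifffile.imread(str(path))


def _check_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    for col in required:
        if col not in df.columns:
            raise ValueError(f"{what} table is missing required column {col!r}")


def write_table(path, df: pd.DataFrame, columns: list[str] | None = None,
                what: str = "data") -> None:
    if columns is not None:
        _check_columns(df, columns, what)
        df = df[columns]
    df.to_csv(path, index=False)


def read_table(path, columns: list[str] | None = None, what: str = "data") -> pd.DataFrame:
    df = pd.read_csv(path)
    if columns is not None:
        _check_columns(df, columns, what)
    # empty strings round-trip as NaN; restore them for label columns
    for col in ("reject_reason",):
        if col in df.columns:
            df[col] = df[col].fillna("").astype(str)
    return df


def write_summary(path, summary: dict) -> None:
    """Deterministically serialized JSON summary (sorted keys)."""
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_summary(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


# ---------------------------------------------------------------------------
# cell round trip (used by the CLI's simulate -> detect handoff)
# ---------------------------------------------------------------------------

def save_cell(cell, outdir) -> None:
    """Write one cell's image stacks and geometry metadata under ``outdir``."""
    d = Path(outdir) / cell.cell_id
    d.mkdir(parents=True, exist_ok=True)
    for channel, stack in cell.images.items():
        write_stack(d / f"{channel}.tif", stack)
    geom = pd.DataFrame({
        "frame": np.arange(cell.n_frames),
        "length_um": cell.lengths_um,
        "old_pole_x": cell.old_pole_px[:, 0],
        "old_pole_y": cell.old_pole_px[:, 1],
        "new_pole_x": cell.new_pole_px[:, 0],
        "new_pole_y": cell.new_pole_px[:, 1],
        "constriction_um": cell.constriction_um,
    })
    write_table(d / "geometry.csv", geom, GEOMETRY_COLUMNS, "geometry")
    with open(d / "meta.yaml", "w") as fh:
        yaml.safe_dump(dict(cell_id=cell.cell_id,
                            frame_interval=float(cell.frame_interval),
                            pixel_size=float(cell.pixel_size)), fh)
    for f in range(cell.n_frames):
        np.savetxt(d / f"boundary_{f:03d}.csv", cell.boundaries[f],
                   delimiter=",", header="x_px,y_px", comments="")


def load_cell(cell_dir):
    """Rebuild a :class:`~replitrack.simulate.CellSeries` written by
    :func:`save_cell`."""
    from .simulate import CellSeries

    d = Path(cell_dir)
    with open(d / "meta.yaml") as fh:
        meta = yaml.safe_load(fh)
    geom = read_table(d / "geometry.csv", GEOMETRY_COLUMNS, "geometry")
    images = {}
    for tif in sorted(d.glob("*.tif")):
        images[tif.stem] = read_stack(tif).astype(np.float32)
    n = len(geom)
    boundaries = [np.loadtxt(d / f"boundary_{f:03d}.csv", delimiter=",", skiprows=1)
                  for f in range(n)]
    first = next(iter(images.values()))
    return CellSeries(
        cell_id=meta["cell_id"],
        frame_interval=meta["frame_interval"],
        pixel_size=meta["pixel_size"],
        lengths_um=geom["length_um"].to_numpy(),
        old_pole_px=geom[["old_pole_x", "old_pole_y"]].to_numpy(),
        new_pole_px=geom[["new_pole_x", "new_pole_y"]].to_numpy(),
        boundaries=boundaries,
        constriction_um=geom["constriction_um"].to_numpy(),
        img_shape=first.shape[1:],
        images=images,
    )
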
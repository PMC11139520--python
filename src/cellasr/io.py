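"""Readers and writers: multi-page TIFF volumes/labels, CSV point sets, JSON atlases.

Coordinate conventions are centralized here: files store points as
``id,x,y,z`` rows (x fastest axis of the image), while in-memory volumes
are indexed ``(z, y, x)``.  The :class:`~cellasr.synthetic.PointSet`
container also stores (x, y, z) rows, so CSV round trips are direct.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .atlas import ShapeContextParams, StatisticalAtlas
from .synthetic import PointSet


def read_volume(path: str | Path) -> np.ndarray:
    """Multi-page TIFF -> (z, y, x) float volume; 2D files become depth 1."""
    arr = tifffile.imread(str(path))
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError(f"expected 2D/3D TIFF, got shape {arr.shape}")
    return np.asarray(arr)


def write_volume(path: str | Path, vol: np.ndarray) -> None:
    vol = np.asarray(vol)
    if vol.dtype == np.float64:
        vol = vol.astype(np.float32)
    tifffile.imwrite(str(path), vol)


def read_labels(path: str | Path) -> np.ndarray:
    lab = read_volume(path)
    if not np.issubdtype(lab.dtype, np.integer):
        raise ValueError("label TIFF must be integer-valued")
    return lab.astype(np.int32)


def write_labels(path: str | Path, labels: np.ndarray) -> None:
    labels = np.asarray(labels)
    if labels.min() < 0:
        raise ValueError("labels must be non-negative")
    dtype = np.uint16 if labels.max() <= 65535 else np.uint32
    tifffile.imwrite(str(path), labels.astype(dtype))


def write_field(path: str | Path, field: np.ndarray) -> None:
    """Displacement field as a 4D (channel, z, y, x) float32 TIFF."""
    field = np.asarray(field, dtype=np.float32)
    if field.ndim != 4 or field.shape[0] != 3:
        raise ValueError("field must be (3, z, y, x)")
    tifffile.imwrite(str(path), field)


def read_field(path: str | Path) -> np.ndarray:
    arr = tifffile.imread(str(path))
    if arr.ndim != 4 or arr.shape[0] != 3:
        raise ValueError(f"expected (3, z, y, x) TIFF, got {arr.shape}")
    return np.asarray(arr, dtype=np.float64)


def read_points(path: str | Path) -> PointSet:
    """CSV ``id,x,y,z`` -> PointSet. Duplicate ids are rejected by name."""
    df = pd.read_csv(path, skipinitialspace=True)
    df.columns = [c.strip().lower() for c in df.columns]
    required = {"id", "x", "y", "z"}
    if not required.issubset(df.columns):
        raise ValueError(f"point CSV must have columns id,x,y,z; got {list(df.columns)}")
    ids = [str(i) for i in df["id"]]
    dup = {i for i in ids if ids.count(i) > 1}
    if dup:
        raise ValueError(f"duplicate point ids: {sorted(dup)}")
    pts = df[["x", "y", "z"]].to_numpy(dtype=np.float64)
    return PointSet(pts, ids)


def write_points(path: str | Path, ps: PointSet) -> None:
    ids = ps.ids if ps.ids is not None else [str(i) for i in range(len(ps))]
    pd.DataFrame(
        {"id": ids, "x": ps.points[:, 0], "y": ps.points[:, 1], "z": ps.points[:, 2]}
    ).to_csv(path, index=False)


def points_to_grid(ps: PointSet) -> np.ndarray:
    """(x, y, z) file-order points -> (z, y, x) grid-order array."""
    return ps.points[:, ::-1].copy()


def grid_to_points(arr: np.ndarray, ids: list[str] | None = None) -> PointSet:
    return PointSet(np.asarray(arr)[:, ::-1], ids)


def write_atlas(path: str | Path, atlas: StatisticalAtlas) -> None:
    payload = {
        "ids": atlas.ids,
        "asp": atlas.asp.tolist(),
        "spv": atlas.spv.tolist(),
        "tsv": atlas.tsv.tolist(),
        "sc_params": {
            "n_shells": atlas.sc_params.n_shells,
            "n_azimuth": atlas.sc_params.n_azimuth,
            "n_polar": atlas.sc_params.n_polar,
            "r_min": atlas.sc_params.r_min,
            "r_max": atlas.sc_params.r_max,
        },
        "sc_ref": atlas.sc_ref.tolist() if atlas.sc_ref is not None else None,
    }
    Path(path).write_text(json.dumps(payload))


def read_atlas(path: str | Path) -> StatisticalAtlas:
    payload = json.loads(Path(path).read_text())
    return StatisticalAtlas(
        ids=list(payload["ids"]),
        asp=np.array(payload["asp"]),
        spv=np.array(payload["spv"]),
        tsv=np.array(payload["tsv"]),
        sc_params=ShapeContextParams(**payload["sc_params"]),
        sc_ref=np.array(payload["sc_ref"]) if payload.get("sc_ref") is not None else None,
    )
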
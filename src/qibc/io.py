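"""Disk formats: multi-page TIFF fields, JSON truth sidecars, CSV tables.

A field is stored as one multi-page TIFF (one page per channel, the channel
name in the page description tag), an optional 16-bit label TIFF with the
ground-truth mask, and a JSON sidecar holding acquisition metadata and, for
synthetic fields, the ground-truth cell records.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .simulate import FieldOfView, GroundTruthCell

__all__ = ["write_field", "read_field", "write_table", "read_table"]


def write_field(directory, name: str, fov: FieldOfView) -> dict:
    """Write one field; returns the paths written."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    img_path = directory / f"{name}.tif"
    with tifffile.TiffWriter(img_path) as tif:
        for channel, data in fov.channels.items():
            tif.write(
                np.clip(np.rint(data), 0, 65535).astype(np.uint16),
                description=channel,
                contiguous=False,
            )
    paths = {"image": str(img_path)}
    if fov.truth_mask is not None:
        mask_path = directory / f"{name}_labels.tif"
        tifffile.imwrite(mask_path, fov.truth_mask.astype(np.uint16))
        paths["labels"] = str(mask_path)
    sidecar = {
        "channels": list(fov.channels),
        "pixel_size_um": fov.pixel_size_um,
        "meta": fov.meta,
        "cells": [
            {**dataclasses.asdict(c)} for c in fov.cells
        ],
    }
    meta_path = directory / f"{name}.json"
    meta_path.write_text(json.dumps(sidecar, indent=1, default=float))
    paths["sidecar"] = str(meta_path)
    return paths


def read_field(directory, name: str) -> FieldOfView:
    """Read a field written by :func:`write_field`."""
    directory = Path(directory)
    sidecar = json.loads((directory / f"{name}.json").read_text())
    channels: dict[str, np.ndarray] = {}
    with tifffile.TiffFile(directory / f"{name}.tif") as tif:
        for i, page in enumerate(tif.pages):
            desc = page.description or sidecar["channels"][i]
            channels[desc] = page.asarray().astype(float)
    mask_path = directory / f"{name}_labels.tif"
    mask = tifffile.imread(mask_path) if mask_path.exists() else None
    cells = []
    for rec in sidecar.get("cells", []):
        rec = dict(rec)
        rec["axes"] = tuple(rec["axes"])
        if rec.get("centroid") is not None:
            rec["centroid"] = tuple(rec["centroid"])
        rec["foci_truth"] = [tuple(f) for f in rec["foci_truth"]]
        cells.append(GroundTruthCell(**rec))
    return FieldOfView(
        channels=channels,
        pixel_size_um=sidecar["pixel_size_um"],
        meta=sidecar["meta"],
        truth_mask=mask,
        cells=cells,
    )


def write_table(df: pd.DataFrame, path) -> None:
    """Write a feature/staged table as CSV (deterministic formatting)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.10g")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path)
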
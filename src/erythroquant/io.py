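"""File I/O: TIFF rasters, truth tables, label masks, deterministic CSV."""
from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .synth import CellSpec, SceneTruth
from .types import ImagePlane

CSV_FLOAT_FORMAT = "%.10g"   # fixed formatting keeps reruns byte-identical


def write_image(path, img: ImagePlane | np.ndarray) -> None:
    px = img.pixels if isinstance(img, ImagePlane) else np.asarray(img)
    tifffile.imwrite(str(path), px.astype(np.float32))


def read_image(path, pixel_size: float = 0.5) -> ImagePlane:
    arr = tifffile.imread(str(path)).astype(float)
    return ImagePlane(np.clip(arr, 0.0, None), pixel_size)


def write_labels(path, labels: np.ndarray) -> None:
    tifffile.imwrite(str(path), np.asarray(labels).astype(np.int32))


def read_labels(path) -> np.ndarray:
    return tifffile.imread(str(path)).astype(int)


def write_csv(path, df: pd.DataFrame) -> None:
    df.to_csv(path, index=False, float_format=CSV_FLOAT_FORMAT, lineterminator="\n")


def truth_table(truth: SceneTruth) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cell_id": np.arange(len(truth.cells)),
            "center_row": [c.center[0] for c in truth.cells],
            "center_col": [c.center[1] for c in truth.cells],
            "radius_px": [c.radius for c in truth.cells],
            "state": [c.state for c in truth.cells],
            "true_mdp_mv": [c.true_mdp for c in truth.cells],
        }
    )


def scene_manifest(truth: SceneTruth) -> dict:
    return {
        "shape": list(truth.shape),
        "n_cells": len(truth.cells),
        "background_level": truth.background_level,
        "noise_sd": truth.noise_sd,
        "seed": truth.seed,
        "pixel_size_um": truth.pixel_size,
    }


def write_scene(out_dir, img: ImagePlane, truth: SceneTruth,
                stem: str = "scene") -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_image(out / f"{stem}.tif", img)
    write_csv(out / f"{stem}_truth.csv", truth_table(truth))
    (out / f"{stem}_manifest.json").write_text(
        json.dumps(scene_manifest(truth), indent=2, sort_keys=True) + "\n"
    )


def write_config(path, config: dict) -> None:
    Path(path).write_text(json.dumps(config, indent=2, sort_keys=True) + "\n")


def read_config(path) -> dict:
    return json.loads(Path(path).read_text())
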
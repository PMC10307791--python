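"""File I/O: TIFF stacks with JSON sidecars, CSV traces, run manifests.

TIFF axis order and channel naming are carried in a JSON sidecar
(``<name>.json`` beside ``<name>.tif``) rather than in TIFF tags, which
keeps the convention dialect-proof. CSV outputs use a fixed dialect:
UTF-8, comma separator, ``.`` decimal, one header row.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import tifffile

from .scene import ImageScene

SIDECAR_SUFFIX = ".json"


def write_scene(path: str | Path, scene: ImageScene) -> Path:
    """Write a scene as multi-page TIFF plus a JSON sidecar.

    Pages are ordered z-major, channel-minor; the sidecar records the axes
    string, shape, channel names and pixel size.
    """
    path = Path(path)
    data = scene.data.astype(np.float32)
    pages = data.reshape(-1, *scene.shape_yx)
    tifffile.imwrite(path, pages)
    sidecar = {
        "axes": "ZCYX",
        "shape": list(scene.data.shape),
        "channel_names": scene.channel_names,
        "pixel_size_nm": scene.pixel_size,
    }
    path.with_suffix(SIDECAR_SUFFIX).write_text(json.dumps(sidecar, indent=2))
    return path


def read_scene(path: str | Path) -> ImageScene:
    """Read a TIFF written by :func:`write_scene` (sidecar required)."""
    path = Path(path)
    sidecar_path = path.with_suffix(SIDECAR_SUFFIX)
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    pages = tifffile.imread(path)
    data = np.asarray(pages, dtype=float).reshape(meta["shape"])
    return ImageScene(
        data, pixel_size=meta["pixel_size_nm"], channel_names=meta["channel_names"]
    )


def write_label_map(path: str | Path, label_map: np.ndarray) -> Path:
    """Write a label image as 16-bit TIFF (labels must fit in uint16)."""
    path = Path(path)
    labels = np.asarray(label_map)
    if labels.max() > np.iinfo(np.uint16).max:
        raise ValueError("more than 65535 labels; cannot store as 16-bit TIFF")
    tifffile.imwrite(path, labels.astype(np.uint16))
    return path


def read_label_map(path: str | Path) -> np.ndarray:
    return np.asarray(tifffile.imread(Path(path)), dtype=np.int32)


def write_trace_csv(path: str | Path, df: pd.DataFrame) -> Path:
    """Write a dataframe in the package's fixed CSV dialect."""
    path = Path(path)
    df.to_csv(path, index=False, encoding="utf-8")
    return path


def read_frap_csv(path: str | Path):
    """Read a FRAP trace CSV (time_min, roi, roi_bg, cell, cell_bg, phase)."""
    from .frap import FrapTrace

    df = pd.read_csv(path)
    required = {"time_min", "roi", "roi_bg", "cell", "cell_bg", "phase"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"FRAP CSV missing columns: {sorted(missing)}")
    n_pre = int((df["phase"] == "pre").sum())
    return FrapTrace(
        time=df["time_min"].to_numpy(),
        roi=df["roi"].to_numpy(),
        roi_background=df["roi_bg"].to_numpy(),
        cell_total=df["cell"].to_numpy(),
        cell_background=df["cell_bg"].to_numpy(),
        n_prebleach=n_pre,
    )


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    out_dir: str | Path,
    stage: str,
    parameters: dict[str, Any],
    inputs: list[str | Path] | None = None,
    seed: int | None = None,
) -> Path:
    """Write a reproducibility manifest beside a stage's outputs."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "stage": stage,
        "version": __version__,
        "seed": seed,
        "parameters": parameters,
        "inputs": {
            str(p): (sha256_file(p) if Path(p).is_file() else "directory")
            for p in (inputs or [])
            if Path(p).exists()
        },
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path
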
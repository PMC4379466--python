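"""File formats: localization tables, movies, control points, images.

Localization tables are plain CSV with ``#``-prefixed metadata header lines
(``# pixel_size_nm=80``) followed by a column header.  Coordinates are stored
in nm throughout; EM images are addressed in pixels and the registration
transform is the only bridge between the two systems, since the modalities
are calibrated independently.  Movies are multi-page TIFF with a JSON
metadata sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .camera import CameraModel
from .localize import TABLE_COLUMNS, LocalizationTable
from .movie import MovieStack
from .register import ControlPointSet

__all__ = [
    "read_localizations",
    "write_localizations",
    "read_movie",
    "write_movie",
    "read_control_points",
    "write_control_points",
    "write_image",
]

_FLOAT_FMT = "%.6g"  # decimal representation at 6 significant digits


def write_localizations(table: LocalizationTable, path: str | Path) -> None:
    """Write a localization table as CSV with ``#`` metadata lines."""
    path = Path(path)
    cols = TABLE_COLUMNS + [c for c in table.df.columns if c not in TABLE_COLUMNS]
    with path.open("w") as fh:
        for key, value in sorted(table.metadata.items()):
            fh.write(f"# {key}={value}\n")
        table.df[cols].to_csv(fh, index=False, float_format=_FLOAT_FMT)


def read_localizations(path: str | Path) -> LocalizationTable:
    """Read a localization table CSV.

    Raises
    ------
    ValueError
        If a mandatory column is missing (the error names the column) or a
        row is malformed (the error carries the line number).
    """
    path = Path(path)
    metadata: dict[str, object] = {}
    n_meta = 0
    with path.open() as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_meta += 1
            body = line.lstrip("#").strip()
            if "=" in body:
                key, _, value = body.partition("=")
                try:
                    metadata[key.strip()] = float(value)
                except ValueError:
                    metadata[key.strip()] = value.strip()
    try:
        df = pd.read_csv(path, comment="#", skip_blank_lines=True)
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed row in {path.name}: {exc}") from exc
    for col in TABLE_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"missing column {col}")
    bad = df[TABLE_COLUMNS].isna().any(axis=1)
    if bad.any():
        line_no = int(bad.idxmax()) + n_meta + 2  # header + 1-based
        raise ValueError(f"malformed row at line {line_no} of {path.name}")
    return LocalizationTable(df=df, metadata=metadata)


def write_movie(movie: MovieStack, path: str | Path) -> None:
    """Write a movie as multi-page TIFF plus a JSON metadata sidecar."""
    import tifffile

    path = Path(path)
    tifffile.imwrite(path, movie.data.astype(np.float32), photometric="minisblack")
    cam = movie.camera
    sidecar = {
        "pixel_size_nm": cam.pixel_size,
        "integration_ms": cam.integration_time,
        "fps": cam.frame_rate,
        "em_gain": cam.em_gain,
        "read_noise": cam.read_noise,
        "offset": cam.offset,
        "quantum_efficiency": cam.quantum_efficiency,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_movie(path: str | Path) -> MovieStack:
    """Read a multi-page TIFF movie and its metadata sidecar."""
    import tifffile

    path = Path(path)
    data = tifffile.imread(path).astype(float)
    if data.ndim == 2:
        data = data[None]
    sidecar_path = path.with_suffix(".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"metadata sidecar {sidecar_path.name} not found")
    meta = json.loads(sidecar_path.read_text())
    camera = CameraModel(
        pixel_size=meta["pixel_size_nm"],
        integration_time=meta["integration_ms"],
        frame_rate=meta["fps"],
        em_gain=meta.get("em_gain", 1.0),
        read_noise=meta.get("read_noise", 1.0),
        offset=meta.get("offset", 100.0),
        quantum_efficiency=meta.get("quantum_efficiency", 0.9),
    )
    return MovieStack(data=data, camera=camera)


CP_COLUMNS = ["smlm_x_nm", "smlm_y_nm", "em_x_px", "em_y_px"]


def write_control_points(points: ControlPointSet, path: str | Path) -> None:
    df = pd.DataFrame(
        np.c_[points.source, points.target], columns=CP_COLUMNS
    )
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_control_points(path: str | Path) -> ControlPointSet:
    df = pd.read_csv(path, comment="#")
    for col in CP_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"missing column {col}")
    return ControlPointSet(
        source=df[CP_COLUMNS[:2]].to_numpy(float),
        target=df[CP_COLUMNS[2:]].to_numpy(float),
    )


def write_image(image: np.ndarray, path: str | Path) -> None:
    """Write a raster: 16-bit grayscale TIFF or 8-bit RGB PNG by extension."""
    path = Path(path)
    img = np.asarray(image, dtype=float)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        peak = img.max() if img.max() > 0 else 1.0
        tifffile.imwrite(path, (img / peak * 65535).astype(np.uint16))
    elif path.suffix.lower() == ".png":
        import matplotlib.image

        if img.ndim == 2:
            peak = img.max() if img.max() > 0 else 1.0
            img = np.stack([img / peak] * 3, axis=-1)
        matplotlib.image.imsave(path, np.clip(img, 0.0, 1.0))
    else:
        raise ValueError(f"unsupported image extension {path.suffix!r}")
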
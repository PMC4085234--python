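"""Image and table I/O.

Images: 8/16-bit grayscale TIFF and PNG are read losslessly into float;
multi-channel files are rejected. When at least 0.5% of the pixels sit
exactly at the dtype maximum the image is treated as clipped and the
saturation level recorded.

Tables: comma-separated, header row, '.' decimal, UTF-8; floats are
written with 9 significant digits so a written table re-reads to exactly
the written values.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .comparators import AreaSpot, ODResult
from .compounding import Compound
from .detection import Peak
from .gaussian_fit import SpotFit
from .image import GelImage

__all__ = [
    "read_image",
    "write_image",
    "peaks_to_frame",
    "peaks_from_frame",
    "write_peaks",
    "read_peaks",
    "spots_to_frame",
    "write_spots",
    "read_spots",
    "write_compounds",
    "signals_to_frame",
    "write_signals",
]

FLOAT_FORMAT = "%.9g"
SATURATION_FRACTION = 0.005

_INTEGER_SATURATION = {
    np.dtype(np.uint8): 255.0,
    np.dtype(np.uint16): 65535.0,
    np.dtype(np.int16): 32767.0,
}


def read_image(path: str | Path) -> GelImage:
    """Load a grayscale TIFF/PNG into a float GelImage without rescaling."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        raw = tifffile.imread(path)
    else:
        raw = iio.imread(path)
    raw = np.asarray(raw)
    if raw.ndim != 2:
        raise ValueError(
            f"{path.name}: expected a single-channel grayscale image, got shape "
            f"{raw.shape}; convert multi-channel images to grayscale first"
        )
    if raw.dtype not in _INTEGER_SATURATION and not np.issubdtype(raw.dtype, np.floating):
        raise ValueError(
            f"{path.name}: unsupported dtype {raw.dtype}; use 8/16-bit integer or float"
        )

    saturation = None
    cap = _INTEGER_SATURATION.get(raw.dtype)
    if cap is not None and np.mean(raw == raw.dtype.type(cap)) >= SATURATION_FRACTION:
        saturation = cap
    return GelImage(pixels=raw.astype(float), saturation_level=saturation)


def write_image(path: str | Path, pixels: np.ndarray, *, dtype: str = "float32") -> None:
    """Write a raster as TIFF. 'uint16' clips and rounds; 'float32' is lossless."""
    path = Path(path)
    if dtype == "uint16":
        data = np.clip(np.rint(pixels), 0, 65535).astype(np.uint16)
    elif dtype == "float32":
        data = np.asarray(pixels, dtype=np.float32)
    else:
        raise ValueError("dtype must be 'uint16' or 'float32'")
    tifffile.imwrite(path, data)


def peaks_to_frame(peaks: list[Peak]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "peak_id": range(len(peaks)),
            "x": [p.x for p in peaks],
            "y": [p.y for p in peaks],
            "original_intensity": [p.original_intensity for p in peaks],
            "restored_intensity": [p.restored_intensity for p in peaks],
        }
    )


def peaks_from_frame(frame: pd.DataFrame) -> list[Peak]:
    return [
        Peak(
            x=int(r.x),
            y=int(r.y),
            restored_intensity=float(r.restored_intensity),
            original_intensity=float(r.original_intensity),
        )
        for r in frame.itertuples()
    ]


def write_peaks(path: str | Path, peaks: list[Peak]) -> None:
    peaks_to_frame(peaks).to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_peaks(path: str | Path) -> list[Peak]:
    return peaks_from_frame(pd.read_csv(path))


def spots_to_frame(fits: list[SpotFit], mu_bg: float) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "spot_id": range(len(fits)),
            "compound_id": [f.compound_id for f in fits],
            "peak_id": [f.peak_id for f in fits],
            "x0": [f.x0 for f in fits],
            "y0": [f.y0 for f in fits],
            "I": [f.I for f in fits],
            "sigma": [f.sigma for f in fits],
            "vus": [f.vus for f in fits],
            "mu_bg": mu_bg,
            "converged": [f.converged for f in fits],
            "discarded": [f.discarded for f in fits],
            "residual_norm": [f.residual_norm for f in fits],
        }
    )


def write_spots(path: str | Path, fits: list[SpotFit], mu_bg: float) -> None:
    spots_to_frame(fits, mu_bg).to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_spots(path: str | Path) -> list[SpotFit]:
    frame = pd.read_csv(path)
    return [
        SpotFit(
            peak_id=int(r.peak_id),
            compound_id=int(r.compound_id),
            x0=float(r.x0),
            y0=float(r.y0),
            I=float(r.I),
            sigma=float(r.sigma),
            converged=bool(r.converged),
            discarded=bool(r.discarded),
            residual_norm=float(r.residual_norm),
        )
        for r in frame.itertuples()
    ]


def _run_lengths(mask_row: np.ndarray) -> list[list[int]]:
    """Run-length encode one boolean row as [start, length] pairs."""
    runs = []
    padded = np.diff(np.concatenate(([0], mask_row.astype(np.int8), [0])))
    starts = np.nonzero(padded == 1)[0]
    ends = np.nonzero(padded == -1)[0]
    for s, e in zip(starts, ends):
        runs.append([int(s), int(e - s)])
    return runs


def write_compounds(
    csv_path: str | Path,
    peaks: list[Peak],
    compounds: list[Compound],
    *,
    mask_json_path: str | Path | None = None,
) -> None:
    """compounds.csv (compound_id, peak_id, x, y) plus optional RLE mask sidecar."""
    rows = []
    for cid, comp in enumerate(compounds):
        for pid in comp.peak_ids:
            rows.append(
                {"compound_id": cid, "peak_id": pid, "x": peaks[pid].x, "y": peaks[pid].y}
            )
    pd.DataFrame(rows, columns=["compound_id", "peak_id", "x", "y"]).to_csv(
        csv_path, index=False
    )
    if mask_json_path is not None:
        import json

        payload = {
            str(cid): {str(r): _run_lengths(comp.mask[r]) for r in np.nonzero(comp.mask.any(axis=1))[0]}
            for cid, comp in enumerate(compounds)
        }
        Path(mask_json_path).write_text(json.dumps(payload))


def signals_to_frame(
    method: str,
    results: list[SpotFit] | list[AreaSpot] | list[ODResult],
) -> pd.DataFrame:
    """Unified signals table: one row per spot with the method's signal measure."""
    if method == "fit":
        rows = [
            {"peak_id": f.peak_id, "method": "fit", "signal": f.vus, "discarded": f.discarded}
            for f in results
        ]
    elif method == "area":
        rows = [
            {"peak_id": a.peak_id, "method": "area", "signal": a.volume, "discarded": False}
            for a in results
        ]
    elif method == "od":
        rows = [
            {"peak_id": o.peak_id, "method": "od", "signal": o.od, "discarded": False}
            for o in results
        ]
    else:
        raise ValueError(f"unknown method {method!r}")
    return pd.DataFrame(rows, columns=["peak_id", "method", "signal", "discarded"])


def write_signals(path: str | Path, frames: list[pd.DataFrame]) -> None:
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format=FLOAT_FORMAT)
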
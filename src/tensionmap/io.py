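"""TIFF + JSON-sidecar serialization for montages, triplets and maps."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .orientation import AlphaTriplet, OrientationMap, PolarizationTriplet
from .preprocess import SimMontage

_MAP_CHANNELS = ("phi", "theta", "amplitude", "offset", "i_max", "valid")


def _sidecar(path) -> Path:
    return Path(path).with_suffix(".json")


def save_montage(montage: SimMontage, path) -> Path:
    """Write a montage as a multi-page float32 TIFF plus a JSON sidecar."""
    path = Path(path)
    tifffile.imwrite(path, montage.frames.astype(np.float32))
    meta = {
        "type": "montage",
        "alphas": list(montage.alphas.as_array()),
        "camera_baseline": montage.camera_baseline,
        "pixel_size_nm": montage.pixel_size_nm,
        "layout": montage.layout,
        "timestamp_min": montage.timestamp_min,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=2))
    return path


def load_montage(path) -> SimMontage:
    path = Path(path)
    frames = tifffile.imread(path).astype(float)
    meta = json.loads(_sidecar(path).read_text())
    return SimMontage(
        frames=frames,
        alphas=AlphaTriplet.from_sequence(meta["alphas"]),
        camera_baseline=meta.get("camera_baseline", 200.0),
        pixel_size_nm=meta.get("pixel_size_nm", 60.0),
        layout=meta.get("layout", "orientation-major"),
        timestamp_min=meta.get("timestamp_min"),
    )


def save_triplet(triplet: PolarizationTriplet, path) -> Path:
    """Write a polarization triplet as a 3-page TIFF plus a JSON sidecar."""
    path = Path(path)
    tifffile.imwrite(path, triplet.images.astype(np.float32))
    meta = {
        "type": "triplet",
        "alphas": list(triplet.alphas.as_array()),
        "pixel_size_nm": triplet.pixel_size_nm,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=2))
    return path


def load_triplet(path) -> PolarizationTriplet:
    path = Path(path)
    images = tifffile.imread(path).astype(float)
    meta = json.loads(_sidecar(path).read_text())
    return PolarizationTriplet(
        images=images,
        alphas=AlphaTriplet.from_sequence(meta["alphas"]),
        pixel_size_nm=meta.get("pixel_size_nm", 60.0),
    )


def save_orientation_map(omap: OrientationMap, path) -> Path:
    """Write an orientation map as a 6-channel TIFF plus a JSON sidecar."""
    path = Path(path)
    stack = np.stack(
        [
            omap.phi,
            omap.theta,
            omap.amplitude,
            omap.offset,
            omap.i_max,
            omap.valid.astype(float),
        ]
    ).astype(np.float32)
    tifffile.imwrite(path, stack)
    meta = {
        "type": "orientation_map",
        "channels": list(_MAP_CHANNELS),
        "alphas": list(omap.alphas.as_array()) if omap.alphas is not None else None,
        "b": omap.b,
        "mask_quantile": omap.mask_quantile,
        "pixel_size_nm": omap.pixel_size_nm,
        "n_theta_clipped": omap.n_theta_clipped,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=2))
    return path


def load_orientation_map(path) -> OrientationMap:
    path = Path(path)
    stack = tifffile.imread(path).astype(float)
    meta = json.loads(_sidecar(path).read_text())
    alphas = meta.get("alphas")
    return OrientationMap(
        phi=stack[0],
        theta=stack[1],
        amplitude=stack[2],
        offset=stack[3],
        i_max=stack[4],
        valid=stack[5] > 0.5,
        alphas=AlphaTriplet.from_sequence(alphas) if alphas is not None else None,
        b=meta.get("b", 0.069),
        mask_quantile=meta.get("mask_quantile", 60.0),
        pixel_size_nm=meta.get("pixel_size_nm", 60.0),
        n_theta_clipped=meta.get("n_theta_clipped", 0),
    )


def save_map_table(omap: OrientationMap, path) -> Path:
    """Export the per-pixel fit table to CSV."""
    path = Path(path)
    omap.to_table().to_csv(path, index=False)
    return path
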
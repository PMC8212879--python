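"""Reading and writing image stacks with a structured-text sidecar.

On-disk layout
--------------
Images are plain multi-page grayscale TIFF (uint16 or float32). Acquisition
metadata lives in a YAML sidecar next to the TIFF, with one schema covering the
three stack kinds::

    kind: pshg | chiral | depth
    pixel_size_um: 0.332
    # kind == pshg
    angles_deg: [0, 10, ..., 170]
    channel: total | parallel | perpendicular
    wavelength_nm: 890
    # kind == chiral  (page order is fixed: LHCP first, RHCP second)
    # kind == depth
    z_step_um: 2.0
    z0_um: 0.0

This deliberately avoids vendor metadata: TIFF is the lingua franca of
microscopy and a sidecar keeps the reader trivial and auditable.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import tifffile
import yaml

from .errors import FormatError, StackValidationError
from .stacks import ChiralPair, DepthSeries, PolStack

__all__ = ["read_stack", "write_stack", "read_sidecar"]


def read_sidecar(sidecar: str | Path) -> dict:
    with open(sidecar) as fh:
        meta = yaml.safe_load(fh)
    if not isinstance(meta, dict) or "kind" not in meta:
        raise FormatError(f"sidecar {sidecar} is not a mapping with a 'kind' key")
    return meta


def read_stack(path: str | Path, sidecar: str | Path) -> PolStack | ChiralPair | DepthSeries:
    """Load a multi-page TIFF plus its sidecar into the matching typed stack.

    The frame count is validated against the sidecar's angle/depth bookkeeping and
    intensities against the nonnegativity invariant; violations raise
    :class:`~shgmetrics.errors.FormatError` / ``StackValidationError``.
    """
    meta = read_sidecar(sidecar)
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    kind = meta["kind"]
    pixel = float(meta.get("pixel_size_um", 0.332))
    if kind == "pshg":
        angles = meta.get("angles_deg")
        if angles is None:
            raise FormatError("pshg sidecar must list angles_deg")
        if len(frames) != len(angles):
            raise FormatError(
                f"{len(frames)} TIFF pages but sidecar lists {len(angles)} angles"
            )
        return PolStack(
            frames=frames,
            angles_deg=np.asarray(angles, float),
            channel=meta.get("channel", "total"),
            pixel_size_um=pixel,
            wavelength_nm=float(meta.get("wavelength_nm", 890.0)),
        )
    if kind == "chiral":
        if len(frames) != 2:
            raise FormatError(f"chiral stack must have exactly 2 pages, got {len(frames)}")
        return ChiralPair(lhcp=frames[0], rhcp=frames[1], pixel_size_um=pixel)
    if kind == "depth":
        if "z_step_um" not in meta:
            raise FormatError("depth sidecar must declare z_step_um")
        n_meta = meta.get("n_sections")
        if n_meta is not None and int(n_meta) != len(frames):
            raise FormatError(
                f"{len(frames)} TIFF pages but sidecar declares {n_meta} sections"
            )
        return DepthSeries(
            sections=frames,
            z_step_um=float(meta["z_step_um"]),
            z0_um=float(meta.get("z0_um", 0.0)),
            pixel_size_um=pixel,
        )
    raise FormatError(f"unknown stack kind {kind!r}")


def _frames_for_disk(frames: np.ndarray) -> np.ndarray:
    if np.issubdtype(frames.dtype, np.integer):
        return frames.astype(np.uint16)
    return frames.astype(np.float32)


def write_stack(stack: PolStack | ChiralPair | DepthSeries, path: str | Path,
                sidecar_path: str | Path) -> None:
    """Write a typed stack as multi-page TIFF + YAML sidecar.

    Round trip through :func:`read_stack` is bit-exact for integer data and
    float32-exact for floating data.
    """
    if isinstance(stack, PolStack):
        frames = stack.frames
        meta = {
            "kind": "pshg",
            "angles_deg": [float(a) for a in stack.angles_deg],
            "channel": stack.channel,
            "pixel_size_um": float(stack.pixel_size_um),
            "wavelength_nm": float(stack.wavelength_nm),
        }
    elif isinstance(stack, ChiralPair):
        frames = np.stack([stack.lhcp, stack.rhcp])
        meta = {"kind": "chiral", "pixel_size_um": float(stack.pixel_size_um)}
    elif isinstance(stack, DepthSeries):
        frames = stack.sections
        meta = {
            "kind": "depth",
            "z_step_um": float(stack.z_step_um),
            "z0_um": float(stack.z0_um),
            "n_sections": int(len(stack.sections)),
            "pixel_size_um": float(stack.pixel_size_um),
        }
    else:
        raise StackValidationError(f"cannot write object of type {type(stack).__name__}")
    tifffile.imwrite(path, _frames_for_disk(np.asarray(frames)),
                     photometric="minisblack")
    with open(sidecar_path, "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)
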
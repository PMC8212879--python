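"""In-memory containers for the three acquisition geometries.

All intensities are photon-count-like (nonnegative, arbitrary units). Image axes
follow the usual raster convention: row 0 is the top of the field, the x-axis runs
along columns. Excitation polarization angle 0° is parallel to the image x-axis and
increases counterclockwise; angles are stored in degrees and converted to radians
only inside numerical code.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import StackValidationError

CHANNELS = ("total", "parallel", "perpendicular")


def _as_float_stack(frames) -> np.ndarray:
    arr = np.asarray(frames)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise StackValidationError(f"expected a stack of 2D frames, got ndim={arr.ndim}")
    if np.any(arr < 0):
        raise StackValidationError("negative intensities are not allowed")
    return arr


@dataclass
class PolStack:
    """Stack of SHG images acquired while rotating the excitation linear polarization.

    Parameters
    ----------
    frames
        ``(n_angles, H, W)`` nonnegative intensities.
    angles_deg
        Strictly increasing excitation polarization angles in ``[0, 180)`` degrees,
        one per frame.
    channel
        Analyzer state of the detected SHG: ``"total"`` (no analyzer),
        ``"parallel"`` or ``"perpendicular"`` to the excitation polarization.
    pixel_size_um
        Lateral sampling in µm/pixel.
    wavelength_nm
        Excitation wavelength (informational only).
    """

    frames: np.ndarray
    angles_deg: np.ndarray
    channel: str = "total"
    pixel_size_um: float = 0.332
    wavelength_nm: float = 890.0

    def __post_init__(self):
        self.frames = _as_float_stack(self.frames)
        self.angles_deg = np.asarray(self.angles_deg, dtype=float)
        if self.angles_deg.ndim != 1:
            raise StackValidationError("angles_deg must be a 1D sequence")
        if len(self.frames) != len(self.angles_deg):
            raise StackValidationError(
                f"{len(self.frames)} frames but {len(self.angles_deg)} angles"
            )
        if np.any(np.diff(self.angles_deg) <= 0):
            raise StackValidationError("angles must be strictly increasing")
        if self.channel not in CHANNELS:
            raise StackValidationError(f"unknown channel {self.channel!r}")
        if not self.pixel_size_um > 0:
            raise StackValidationError("pixel_size_um must be > 0")

    @property
    def n_angles(self) -> int:
        return len(self.angles_deg)

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


@dataclass
class ChiralPair:
    """Co-registered SHG images under left- and right-handed circular excitation."""

    lhcp: np.ndarray
    rhcp: np.ndarray
    pixel_size_um: float = 0.332

    def __post_init__(self):
        self.lhcp = np.asarray(self.lhcp)
        self.rhcp = np.asarray(self.rhcp)
        if self.lhcp.shape != self.rhcp.shape:
            raise StackValidationError("LHCP and RHCP images must share a shape")
        if self.lhcp.ndim != 2:
            raise StackValidationError("chiral images must be 2D")
        if np.any(self.lhcp < 0) or np.any(self.rhcp < 0):
            raise StackValidationError("negative intensities are not allowed")
        if not self.pixel_size_um > 0:
            raise StackValidationError("pixel_size_um must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.lhcp.shape


@dataclass
class DepthSeries:
    """z-ordered stack of optical sections with uniform spacing."""

    sections: np.ndarray
    z_step_um: float
    z0_um: float = 0.0
    pixel_size_um: float = 0.332

    def __post_init__(self):
        self.sections = _as_float_stack(self.sections)
        if len(self.sections) < 3:
            raise StackValidationError("a depth series needs at least 3 sections")
        if not self.z_step_um > 0:
            raise StackValidationError("z_step_um must be > 0")
        if not self.pixel_size_um > 0:
            raise StackValidationError("pixel_size_um must be > 0")

    @property
    def depths_um(self) -> np.ndarray:
        return self.z0_um + self.z_step_um * np.arange(len(self.sections), dtype=float)
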
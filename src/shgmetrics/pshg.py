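"""Per-pixel polarization-resolved SHG fitting and pitch-angle conversion.

Model
-----
For a cylindrically symmetric (C∞v) harmonophore under Kleinman symmetry the SHG
intensity as the excitation linear polarization angle θ rotates is

    I(θ) = A · { sin²[2(θ−φ)] + [ sin²(θ−φ) + b·cos²(θ−φ) ]² } + c

with b = χ_ZZZ / χ_ZXX the ratio of the two independent susceptibility tensor
elements, φ the in-plane fiber orientation, A an amplitude and c an additive
background. The effective α-helical pitch angle of the emitting peptide dipoles
follows from the single-axis molecular picture as

    θ_p = arctan( sqrt(2 / b) ).

Fitting is bounded nonlinear least squares per pixel, initialized from the
discrete cos2θ Fourier phase of the angular response (which locates φ up to the
90° branch that both starting points cover) and a max/min intensity-ratio
heuristic for b.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from ._util import sem
from .errors import GeometryError, ParameterError
from .stacks import PolStack

__all__ = [
    "polarization_response",
    "pitch_angle_from_ratio",
    "fit_pshg",
    "pitch_map",
    "reconstruct_polar_response",
    "PixelFitResult",
    "PitchMap",
]

B_BOUNDS = (0.05, 10.0)


def polarization_response(theta_rad, amplitude, phi_rad, b, offset=0.0):
    """Forward model I(θ); arguments may broadcast."""
    d = np.asarray(theta_rad) - phi_rad
    s2 = np.sin(d) ** 2
    c2 = np.cos(d) ** 2
    return amplitude * (np.sin(2 * d) ** 2 + (s2 + b * c2) ** 2) + offset


def pitch_angle_from_ratio(b):
    """Effective helical pitch angle θ_p = arctan√(2/b), in degrees.

    Strictly decreasing in b; θ_p ∈ (0°, 90°) for b ∈ (0, ∞).
    """
    b = np.asarray(b, dtype=float)
    if np.any(b <= 0):
        raise ParameterError("tensor ratio b must be > 0")
    out = np.degrees(np.arctan(np.sqrt(2.0 / b)))
    return float(out) if out.ndim == 0 else out


@dataclass
class PixelFitResult:
    """Per-pixel maps from the angular fit; NaN outside ``valid_mask``."""

    b_map: np.ndarray
    phi_map: np.ndarray          # degrees in [0, 180)
    amplitude_map: np.ndarray
    offset_map: np.ndarray
    r2_map: np.ndarray
    valid_mask: np.ndarray
    angles_deg: np.ndarray
    threshold: float

    @property
    def n_valid(self) -> int:
        return int(self.valid_mask.sum())


@dataclass
class PitchMap:
    theta_p_map: np.ndarray      # degrees, NaN outside mask
    valid_mask: np.ndarray
    mean_deg: float
    sem_deg: float
    n_valid: int


def _fourier_phi_deg(intensities: np.ndarray, angles_rad: np.ndarray) -> float:
    c2 = float(np.sum(intensities * np.cos(2 * angles_rad)))
    s2 = float(np.sum(intensities * np.sin(2 * angles_rad)))
    return np.degrees(0.5 * np.arctan2(s2, c2)) % 180.0


def _fit_single(intensities: np.ndarray, angles_rad: np.ndarray, angles_deg: np.ndarray,
                fit_offset: bool) -> tuple[float, float, float, float, float]:
    """Return (A, phi_deg, b, c, r2) for one pixel's angular response."""
    imin = float(intensities.min())
    imax = float(intensities.max())
    sstot = float(np.sum((intensities - intensities.mean()) ** 2))
    if sstot <= 0 or imax <= imin * (1 + 1e-9):
        return np.nan, np.nan, np.nan, np.nan, -np.inf

    phi0 = _fourier_phi_deg(intensities, angles_rad)
    # intensity near a candidate orientation, from the nearest sampled angle
    def near(angle_deg):
        idx = int(np.argmin(np.minimum(np.abs(angles_deg - angle_deg % 180.0),
                                       180.0 - np.abs(angles_deg - angle_deg % 180.0))))
        return float(intensities[idx])

    def initial(phi_init):
        i_par = max(near(phi_init), 1e-12)
        i_perp = max(near(phi_init + 90.0), 1e-12)
        b0 = float(np.clip(np.sqrt(i_par / i_perp), 0.2, 8.0))
        c0 = 0.5 * imin if fit_offset else 0.0
        a0 = max(i_perp - c0, 1e-9)
        return a0, np.radians(phi_init), b0, c0

    lo = [0.0, -4 * np.pi, B_BOUNDS[0]] + ([0.0] if fit_offset else [])
    hi = [np.inf, 4 * np.pi, B_BOUNDS[1]] + ([np.inf] if fit_offset else [])

    def residuals(p):
        c = p[3] if fit_offset else 0.0
        return polarization_response(angles_rad, p[0], p[1], p[2], c) - intensities

    # the 180°-periodic landscape has two candidate orientations 90° apart
    # (mapping roughly b ↔ 1/b); both are fitted and the lower-cost one kept
    best = None
    for phi_init in (phi0, phi0 + 90.0):
        a0, ph0, b0, c0 = initial(phi_init)
        x0 = [a0, ph0, b0] + ([c0] if fit_offset else [])
        try:
            res = least_squares(residuals, x0, bounds=(lo, hi),
                                xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=400)
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        return np.nan, np.nan, np.nan, np.nan, -np.inf
    a, phi_rad, b = best.x[:3]
    c = best.x[3] if fit_offset else 0.0
    ssres = 2 * best.cost
    r2 = 1.0 - ssres / sstot
    return float(a), float(np.degrees(phi_rad) % 180.0), float(b), float(c), float(r2)


def fit_pshg(stack: PolStack, min_mean_intensity: float = 0.0, *,
             fit_offset: bool = True, r2_min: float = 0.5) -> PixelFitResult:
    """Fit the angular model at every sufficiently bright pixel of a total-channel stack.

    Parameters
    ----------
    stack
        Polarization stack with ≥ 5 distinct excitation angles (``channel="total"``).
    min_mean_intensity
        Pixels whose mean intensity over angles falls below this value are masked
        invalid without fitting. A sensible data-driven choice is background mean
        + 3·SD (see :func:`shgmetrics._util.ksigma_threshold`).
    fit_offset
        Whether the additive background c is a free parameter (it can be pinned to
        zero for background-subtracted data).
    r2_min
        Pixels whose fit explains less than this fraction of the angular variance
        are masked invalid.

    Returns
    -------
    PixelFitResult
        Per-pixel b, φ, A, c, r² maps plus the validity mask. Pixels with no
        angular modulation (numerically constant response) are invalid rather
        than being assigned an arbitrary orientation.
    """
    if stack.n_angles < 5:
        raise GeometryError(f"need ≥ 5 angles, got {stack.n_angles}")
    if min_mean_intensity < 0:
        raise ParameterError("min_mean_intensity must be ≥ 0")
    frames = stack.frames.astype(float)
    angles_rad = np.radians(stack.angles_deg)
    h, w = stack.shape
    shape = (h, w)
    b_map = np.full(shape, np.nan)
    phi_map = np.full(shape, np.nan)
    a_map = np.full(shape, np.nan)
    c_map = np.full(shape, np.nan)
    r2_map = np.full(shape, np.nan)
    valid = np.zeros(shape, dtype=bool)

    bright = frames.mean(axis=0) >= min_mean_intensity
    if not bright.any():
        warnings.warn("all pixels below intensity threshold; returning empty fit mask")
    for i, j in zip(*np.nonzero(bright)):
        a, phi, b, c, r2 = _fit_single(frames[:, i, j], angles_rad, stack.angles_deg,
                                       fit_offset)
        r2_map[i, j] = r2 if np.isfinite(r2) else np.nan
        if not np.isfinite(b):
            continue
        b_map[i, j], phi_map[i, j] = b, phi
        a_map[i, j], c_map[i, j] = a, c
        if r2 >= r2_min and b > 0:
            valid[i, j] = True
    return PixelFitResult(b_map, phi_map, a_map, c_map, r2_map, valid,
                          np.asarray(stack.angles_deg, float), float(min_mean_intensity))


def pitch_map(fit: PixelFitResult) -> PitchMap:
    """Convert a tensor-ratio map to a pitch-angle map with mean ± SEM over valid pixels."""
    theta = np.full(fit.b_map.shape, np.nan)
    mask = fit.valid_mask & np.isfinite(fit.b_map) & (fit.b_map > 0)
    if mask.any():
        theta[mask] = pitch_angle_from_ratio(fit.b_map[mask])
        vals = theta[mask]
        mean, err = float(vals.mean()), sem(vals)
    else:
        warnings.warn("empty validity mask; pitch summary is undefined")
        mean, err = float("nan"), float("nan")
    return PitchMap(theta, mask, mean, err, int(mask.sum()))


def reconstruct_polar_response(fit: PixelFitResult, angles_deg) -> np.ndarray:
    """Mean fitted angular response over valid pixels, normalized to peak 1."""
    angles_rad = np.radians(np.asarray(angles_deg, dtype=float))
    mask = fit.valid_mask
    if not mask.any():
        warnings.warn("empty validity mask; reconstruction is undefined")
        return np.full(len(angles_rad), np.nan)
    a = fit.amplitude_map[mask][:, None]
    phi = np.radians(fit.phi_map[mask])[:, None]
    b = fit.b_map[mask][:, None]
    c = fit.offset_map[mask][:, None]
    curves = polarization_response(angles_rad[None, :], a, phi, b, c)
    mean_curve = curves.mean(axis=0)
    return mean_curve / mean_curve.max()
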
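"""SHG signal anisotropy β from parallel/perpendicular analyzed channels.

β = (I∥ − I⊥) / (I∥ + 2·I⊥) measures the alignment of dipole moments within the
focal volume: 1 for perfectly aligned structures, 0 for totally random ones, with
an analytic lower bound of −0.5. Negative per-pixel values can occur in real data
through subtraction errors at low counts; they are reported, not clipped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._util import ksigma_threshold, sem
from .errors import AngleLookupError, GeometryError, ParameterError
from .stacks import PolStack

__all__ = ["beta_pixel", "anisotropy_curve", "beta_at", "AnisotropyCurve"]


def beta_pixel(i_par: float, i_perp: float) -> float:
    """Anisotropy of a single pixel; requires a positive denominator."""
    if i_par < 0 or i_perp < 0:
        raise ParameterError("intensities must be ≥ 0")
    denom = i_par + 2.0 * i_perp
    if denom <= 0:
        raise ParameterError("undefined anisotropy: I_par + 2·I_perp must be > 0")
    return (i_par - i_perp) / denom


@dataclass
class AnisotropyCurve:
    """Mask-aggregated anisotropy per excitation angle."""

    angles_deg: np.ndarray
    beta_mean: np.ndarray
    beta_sem: np.ndarray
    n_valid: np.ndarray
    beta_maps: np.ndarray | None = None      # (n_angles, H, W), NaN outside mask
    valid_masks: np.ndarray | None = None


def anisotropy_curve(par: PolStack, perp: PolStack, threshold: float | None = None,
                     k_sigma: float = 3.0, keep_maps: bool = False) -> AnisotropyCurve:
    """Per-pixel β at every excitation angle, aggregated as mask-mean ± SEM.

    The joint validity mask at each angle keeps pixels whose denominator
    I∥ + 2·I⊥ exceeds ``threshold`` (or, when ``threshold`` is None, a
    darkest-decile background mean + ``k_sigma``·SD estimate per angle). Pixels
    are masked per angle independently; aggregation is the mean of per-pixel β
    values, not β of summed intensities.
    """
    if len(par.angles_deg) != len(perp.angles_deg) or np.any(par.angles_deg != perp.angles_deg):
        raise GeometryError("parallel and perpendicular stacks must share angles")
    if par.shape != perp.shape:
        raise GeometryError("channel stacks must share image shape")
    n = par.n_angles
    means = np.full(n, np.nan)
    sems = np.full(n, np.nan)
    counts = np.zeros(n, dtype=int)
    maps = np.full((n,) + par.shape, np.nan) if keep_maps else None
    masks = np.zeros((n,) + par.shape, dtype=bool) if keep_maps else None
    for k in range(n):
        p = par.frames[k].astype(float)
        q = perp.frames[k].astype(float)
        denom = p + 2.0 * q
        thr = ksigma_threshold(denom, k_sigma) if threshold is None else threshold
        mask = denom > max(thr, 0.0)
        counts[k] = int(mask.sum())
        if counts[k] == 0:
            warnings.warn(f"no pixels above threshold at {par.angles_deg[k]:g}°")
            continue
        beta = (p[mask] - q[mask]) / denom[mask]
        means[k] = beta.mean()
        sems[k] = sem(beta)
        if keep_maps:
            full = np.full(par.shape, np.nan)
            full[mask] = beta
            maps[k] = full
            masks[k] = mask
    return AnisotropyCurve(np.asarray(par.angles_deg, float), means, sems, counts,
                           maps, masks)


def beta_at(curve: AnisotropyCurve, angle_deg: float,
            tol_deg: float = 1.0) -> tuple[float, float]:
    """Aggregated (mean, SEM) at a reference excitation angle (default refs: 0°, 90°)."""
    diff = np.abs(curve.angles_deg - angle_deg)
    idx = int(np.argmin(diff))
    if diff[idx] > tol_deg:
        raise AngleLookupError(
            f"angle {angle_deg}° not sampled (nearest {curve.angles_deg[idx]}°)")
    return float(curve.beta_mean[idx]), float(curve.beta_sem[idx])
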
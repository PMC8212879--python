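"""Synthetic acquisition generator with known ground truth.

Every input geometry the pipeline consumes can be produced here: polarization
sweeps of the total SHG channel, parallel/perpendicular analyzed channel pairs,
LHCP/RHCP circular-excitation pairs, exponentially attenuated z-series, and 2D
fiber phantoms with controlled length, width and straightness. Intensities are
photon-count-like; the default noise model is Poisson on the expected counts
(photon-counting detection), with optional additive Gaussian read noise.

The generators are deterministic: identical scene (including ``seed``) produces
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.optimize import brentq
from scipy.spatial import cKDTree

from .errors import ParameterError, PlacementError
from .pshg import polarization_response
from .stacks import ChiralPair, DepthSeries, PolStack

__all__ = [
    "SyntheticScene",
    "default_angles",
    "gen_pshg_stack",
    "gen_polarimetric_channels",
    "gen_chiral_pair",
    "gen_depth_series",
    "gen_fiber_phantom",
]


def default_angles() -> np.ndarray:
    """Excitation angles of a 10°-step sweep through 180° (18 frames, 0–170°)."""
    return np.arange(0.0, 180.0, 10.0)


@dataclass
class SyntheticScene:
    """Forward-model parameters for all generators.

    The defaults describe a bright, well-ordered collagen field: tensor ratio
    b = 2 (pitch angle 45°), peak signal ~10³ counts (amplitude 250 gives peak
    A·b² = 1000 for b = 2), zero background, no noise. ``b_true`` and
    ``phi_deg`` may be scalars or per-pixel maps matching ``shape``.
    """

    b_true: float | np.ndarray = 2.0
    phi_deg: float | np.ndarray = 30.0
    amplitude: float = 250.0
    offset: float = 0.0
    beta_true: float = 0.7
    noise: str = "none"                 # none | poisson | gaussian
    gaussian_sigma: float = 0.0
    seed: int = 0
    shape: tuple[int, int] = (64, 64)
    pixel_size_um: float = 0.332
    wavelength_nm: float = 890.0
    mu_atten_per_um: float = 0.0
    cd_epsilon: float = 0.0
    fiber_spec: list = field(default_factory=list)

    def __post_init__(self):
        if np.any(np.asarray(self.b_true) <= 0):
            raise ParameterError("b_true must be > 0")
        if not -0.5 <= self.beta_true <= 1.0:
            raise ParameterError("beta_true must lie in [-0.5, 1]")
        if not 0.0 <= self.cd_epsilon < 2.0:
            raise ParameterError("cd_epsilon must lie in [0, 2)")
        if self.mu_atten_per_um < 0:
            raise ParameterError("mu_atten_per_um must be ≥ 0")
        if self.amplitude <= 0:
            raise ParameterError("amplitude must be > 0")
        if self.offset < 0:
            raise ParameterError("offset must be ≥ 0")
        if self.noise not in ("none", "poisson", "gaussian"):
            raise ParameterError(f"unknown noise model {self.noise!r}")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _apply_noise(frames: np.ndarray, scene: SyntheticScene,
                 rng: np.random.Generator) -> np.ndarray:
    if scene.noise == "none":
        return frames
    if scene.noise == "poisson":
        return rng.poisson(frames).astype(float)
    noisy = frames + rng.normal(0.0, scene.gaussian_sigma, frames.shape)
    return np.clip(noisy, 0.0, None)


def gen_pshg_stack(scene: SyntheticScene, angles_deg=None) -> PolStack:
    """Total-channel polarization sweep obeying the angular model exactly before noise."""
    angles = default_angles() if angles_deg is None else np.asarray(angles_deg, float)
    if len(angles) < 5:
        raise ParameterError("need ≥ 5 angles")
    theta = np.radians(angles)[:, None, None]
    b = np.broadcast_to(np.asarray(scene.b_true, float), scene.shape)
    phi = np.radians(np.broadcast_to(np.asarray(scene.phi_deg, float), scene.shape))
    frames = polarization_response(theta, scene.amplitude, phi[None], b[None],
                                   scene.offset)
    frames = _apply_noise(frames, scene, scene.rng())
    return PolStack(frames=frames, angles_deg=angles, channel="total",
                    pixel_size_um=scene.pixel_size_um,
                    wavelength_nm=scene.wavelength_nm)


def gen_polarimetric_channels(scene: SyntheticScene,
                              angles_deg=None) -> tuple[PolStack, PolStack]:
    """Parallel/perpendicular analyzed channels with exact anisotropy ``beta_true``.

    The channel split solves (IPar − IPerp)/(IPar + 2·IPerp) = β with
    IPar + IPerp equal to the total-channel forward model, giving
    IPar = T·(1+2β)/(2+β) and IPerp = T·(1−β)/(2+β). Noise (if any) is applied
    to each channel independently.
    """
    beta = scene.beta_true
    total = gen_pshg_stack(
        SyntheticScene(**{**scene.__dict__, "noise": "none"}), angles_deg)
    par_frames = total.frames * (1.0 + 2.0 * beta) / (2.0 + beta)
    perp_frames = total.frames * (1.0 - beta) / (2.0 + beta)
    rng = scene.rng()
    par_frames = _apply_noise(par_frames, scene, rng)
    perp_frames = _apply_noise(perp_frames, scene, rng)
    kw = dict(angles_deg=total.angles_deg, pixel_size_um=scene.pixel_size_um,
              wavelength_nm=scene.wavelength_nm)
    return (PolStack(frames=par_frames, channel="parallel", **kw),
            PolStack(frames=perp_frames, channel="perpendicular", **kw))


def gen_chiral_pair(scene: SyntheticScene, base: np.ndarray | None = None) -> ChiralPair:
    """LHCP/RHCP pair with symmetric multiplicative asymmetry ±ε/2.

    LHCP = base·(1 + ε/2) and RHCP = base·(1 − ε/2), so the per-pixel normalized
    CD statistic |L−R|/((L+R)/2) equals ε exactly in the noise-free case.
    """
    eps = scene.cd_epsilon
    if base is None:
        base = np.full(scene.shape, float(scene.amplitude))
    base = np.asarray(base, dtype=float)
    lhcp = base * (1.0 + eps / 2.0)
    rhcp = base * (1.0 - eps / 2.0)
    rng = scene.rng()
    lhcp = _apply_noise(lhcp, scene, rng)
    rhcp = _apply_noise(rhcp, scene, rng)
    return ChiralPair(lhcp=lhcp, rhcp=rhcp, pixel_size_um=scene.pixel_size_um)


def gen_depth_series(scene: SyntheticScene, n_sections: int = 9,
                     z_step_um: float = 10.0, z0_um: float = 0.0,
                     base: np.ndarray | None = None) -> DepthSeries:
    """z-series whose section means decay as I(z) = I(0)·exp(−µ·z) before noise."""
    if n_sections < 3:
        raise ParameterError("need at least 3 sections")
    if base is None:
        base = np.full(scene.shape, float(scene.amplitude))
    base = np.asarray(base, dtype=float)
    z = z0_um + z_step_um * np.arange(n_sections)
    decay = np.exp(-scene.mu_atten_per_um * (z - z0_um))
    sections = base[None] * decay[:, None, None]
    sections = _apply_noise(sections, scene, scene.rng())
    return DepthSeries(sections=sections, z_step_um=z_step_um, z0_um=z0_um,
                       pixel_size_um=scene.pixel_size_um)


# ---------------------------------------------------------------------------
# fiber phantoms
# ---------------------------------------------------------------------------

def _arc_half_angle(straightness: float) -> float:
    """Solve 2·sin(ψ/2)/ψ = s for the arc angle ψ (radians)."""
    f = lambda psi: 2.0 * np.sin(psi / 2.0) / psi - straightness
    return brentq(f, 1e-9, 2.0 * np.pi - 1e-9)


def _centerline(kind: str, length_px: float, straightness: float,
                orientation_deg: float, rng: np.random.Generator) -> np.ndarray:
    """Dense (x, y) polyline of the requested family, centered at the origin."""
    step = 0.25
    n = max(int(np.ceil(length_px / step)) + 1, 8)
    t = np.linspace(0.0, length_px, n)
    if kind == "segment":
        pts = np.stack([t - length_px / 2.0, np.zeros_like(t)], axis=1)
    elif kind == "arc":
        psi = _arc_half_angle(straightness)
        r = length_px / psi
        ang = t / r - psi / 2.0
        pts = np.stack([r * np.sin(ang), r * (1.0 - np.cos(ang))], axis=1)
        pts -= pts.mean(axis=0)
    elif kind == "walk":
        # smoothed random heading walk; realized straightness is measured, not set
        wiggle = np.clip(1.0 - straightness, 0.0, 1.0)
        headings = np.cumsum(rng.normal(0.0, 2.5 * wiggle * np.sqrt(step), n))
        kernel = np.ones(9) / 9.0
        headings = np.convolve(headings, kernel, mode="same")
        pts = np.cumsum(
            np.stack([np.cos(headings), np.sin(headings)], axis=1) * step, axis=0)
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1).sum()
        pts *= length_px / seg
        pts -= pts.mean(axis=0)
    else:
        raise ParameterError(f"unknown fiber family {kind!r}")
    a = np.radians(orientation_deg)
    rot = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
    return pts @ rot.T


def _polyline_stats(pts: np.ndarray) -> tuple[float, float]:
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arc = float(seg.sum())
    chord = float(np.linalg.norm(pts[-1] - pts[0]))
    return arc, chord


def gen_fiber_phantom(scene: SyntheticScene, shape: tuple[int, int] | None = None,
                      blur_sigma_px: float | None = None):
    """Render the scene's ``fiber_spec`` onto a zero background.

    ``fiber_spec`` entries are ``(length_um, width_um, straightness,
    orientation_deg)`` with an optional fifth item choosing the curve family
    (``"segment"``, ``"arc"`` or ``"walk"``; by default straightness 1 renders a
    segment and anything else a circular arc). Fibers are constant-width curves,
    Gaussian-blurred with σ = min(width)/4 unless overridden, then noised.

    Returns
    -------
    image : 2D float array
    truth : list of dict
        One entry per fiber with keys ``length_um``, ``width_um``,
        ``straightness`` (chord/arc of the rendered centerline) and
        ``centerline_px`` (rows, cols).
    """
    if not scene.fiber_spec:
        raise ParameterError("fiber_spec is empty")
    shape = shape or scene.shape
    h, w = shape
    rng = scene.rng()
    px = scene.pixel_size_um
    canvas = np.zeros(shape, dtype=float)
    truth = []
    for spec in scene.fiber_spec:
        length_um, width_um, straightness, orient = spec[:4]
        kind = spec[4] if len(spec) > 4 else ("segment" if straightness >= 0.9999 else "arc")
        if not 0 < straightness <= 1:
            raise ParameterError("straightness must lie in (0, 1]")
        length_px = length_um / px
        width_px = width_um / px
        pts = _centerline(kind, length_px, straightness, orient, rng)
        margin = width_px / 2.0 + 3.0
        span = pts.max(axis=0) - pts.min(axis=0)
        if span[0] + 2 * margin > w or span[1] + 2 * margin > h:
            raise PlacementError(
                f"fiber of length {length_um} µm does not fit a {h}×{w} image")
        band = placed = None
        for _ in range(200):
            cx = rng.uniform(margin - pts[:, 0].min(), w - margin - pts[:, 0].max())
            cy = rng.uniform(margin - pts[:, 1].min(), h - margin - pts[:, 1].max())
            cand = pts + np.array([cx, cy])
            rows, cols = cand[:, 1], cand[:, 0]
            # constant-width band: pixel centers within width/2 of the
            # continuous centerline (sub-pixel accurate, no raster jitter)
            r0 = max(int(rows.min() - width_px) - 2, 0)
            r1 = min(int(rows.max() + width_px) + 3, h)
            c0 = max(int(cols.min() - width_px) - 2, 0)
            c1 = min(int(cols.max() + width_px) + 3, w)
            gr, gc = np.mgrid[r0:r1, c0:c1]
            tree = cKDTree(np.stack([rows, cols], axis=1))
            d, _ = tree.query(np.stack([gr.ravel(), gc.ravel()], axis=1))
            d = d.reshape(gr.shape)
            # reject placements that touch an already-drawn fiber, so phantom
            # fibers never merge into one connected structure
            if np.any((d <= width_px / 2.0 + 2.0) & (canvas[r0:r1, c0:c1] > 0)):
                continue
            band = (d <= width_px / 2.0, (r0, r1, c0, c1))
            placed = cand
            break
        if placed is None:
            raise PlacementError("could not place fiber inside the image "
                                 "without overlap")
        inside, (r0, r1, c0, c1) = band
        canvas[r0:r1, c0:c1] = np.maximum(canvas[r0:r1, c0:c1],
                                          inside.astype(float))
        arc, chord = _polyline_stats(placed)
        truth.append({
            "length_um": float(arc * px),
            "width_um": float(width_um),
            "straightness": float(chord / arc),
            "centerline_px": np.stack([rows, cols], axis=1),
        })
    widths = [s[1] / px for s in scene.fiber_spec]
    sigma = blur_sigma_px if blur_sigma_px is not None else min(widths) / 4.0
    image = gaussian_filter(canvas, sigma) * scene.amplitude
    image = _apply_noise(image, scene, rng)
    return image, truth
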
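"""Independent brute-force oracles used to cross-check the fitted estimators.

These deliberately avoid the package's optimization path: the angular-model
oracle is an exhaustive two-stage grid search over (b, φ) with the amplitude
solved in closed form per grid point (the model is linear in A for c = 0).
"""

import numpy as np


def angular_model(theta_rad, phi_rad, b):
    d = theta_rad - phi_rad
    s2 = np.sin(d) ** 2
    return np.sin(2 * d) ** 2 + (s2 + b * np.cos(d) ** 2) ** 2


def grid_fit_pixel(intensities, angles_deg, b_range=(0.2, 6.0),
                   coarse=(0.05, 0.25), fine=0.001):
    """Exhaustive (b, φ) grid search for one pixel's angular response (c = 0).

    Returns (b, phi_deg, amplitude) at the fine-grid SSE minimum. For each grid
    point the optimal amplitude is A* = Σ(I·M)/Σ(M²), so SSE minimization
    reduces to maximizing (Σ I·M)² / Σ M².

    Note: near b = 1 the model loses its 2θ harmonic and φ becomes degenerate;
    φ comparisons are only meaningful away from that point.
    """
    theta = np.radians(np.asarray(angles_deg, float))
    intens = np.asarray(intensities, float)

    def best_on(bs, phis):
        m = angular_model(theta[None, None, :], np.radians(phis)[None, :, None],
                          bs[:, None, None])
        num = np.tensordot(m, intens, axes=([2], [0])) ** 2
        den = np.sum(m * m, axis=2)
        score = num / den
        i, j = np.unravel_index(np.argmax(score), score.shape)
        a = float(np.tensordot(m[i, j], intens, axes=1) / den[i, j])
        return float(bs[i]), float(phis[j]), a

    db, dphi = coarse
    b0, p0, _ = best_on(np.arange(b_range[0], b_range[1] + db, db),
                        np.arange(0.0, 180.0, dphi))
    bs = np.arange(max(b_range[0], b0 - 1.5 * db), b0 + 1.5 * db + fine, fine)
    phis = np.arange(p0 - 1.5 * dphi, p0 + 1.5 * dphi + fine, fine)
    b1, p1, a1 = best_on(bs, phis)
    return b1, p1 % 180.0, a1


def circular_diff_deg(a, b, period=180.0):
    d = abs(a - b) % period
    return min(d, period - d)
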
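"""Axial (180°-periodic) circular arithmetic.

A fiber orientation and its reverse denote the same axis, so all orientation
angles in this package live on the half-circle [0, 180) degrees and are
analysed by doubling onto the full circle (θ → 2θ), the standard device for
axial data.
"""

from __future__ import annotations

import numpy as np
from scipy import special

__all__ = [
    "wrap_axial",
    "axial_difference",
    "axial_mean",
    "kappa_from_resultant",
    "vonmises_logpdf",
]

#: Concentration ceiling: beyond this the von Mises is numerically a spike.
KAPPA_MAX = 1e3


def wrap_axial(angles_deg):
    """Map angles in degrees onto the axial half-circle [0, 180)."""
    r = np.asarray(angles_deg, dtype=float) % 180.0
    # tiny negative inputs can round the modulo up to exactly 180.0
    return np.where(r >= 180.0, 0.0, r)


def axial_difference(a_deg, b_deg):
    """Smallest angle between two axes, in [0, 90] degrees.

    min(|d|, 180-|d|) with d taken mod 180 — the brute-force definition.
    """
    d = np.abs(np.asarray(a_deg, dtype=float) - np.asarray(b_deg, dtype=float)) % 180.0
    return np.minimum(d, 180.0 - d)


def axial_mean(angles_deg, weights=None):
    """Mean axis direction in [0, 180) via the doubled-angle resultant.

    Returns (mean_deg, resultant_length) where resultant_length in [0, 1]
    measures concentration (1 = all angles on one axis).
    """
    theta = np.asarray(angles_deg, dtype=float)
    if theta.size == 0:
        raise ValueError("axial_mean requires at least one angle")
    w = np.ones_like(theta) if weights is None else np.asarray(weights, dtype=float)
    phi = np.deg2rad(2.0 * theta)
    c = np.sum(w * np.cos(phi))
    s = np.sum(w * np.sin(phi))
    r = np.hypot(c, s) / np.sum(w)
    mean = np.rad2deg(np.arctan2(s, c)) / 2.0
    return float(mean % 180.0), float(r)


def kappa_from_resultant(r: float) -> float:
    """Invert A(κ) = I₁(κ)/I₀(κ) ≈ r (Best & Fisher approximation).

    Capped at KAPPA_MAX: r → 1 corresponds to a degenerate spike.
    """
    r = float(r)
    if r < 0:
        raise ValueError("resultant length must be >= 0")
    if r >= 1.0 - 1e-9:  # spike: the approximation's denominator vanishes at r=1
        return KAPPA_MAX
    if r < 0.53:
        k = 2.0 * r + r**3 + 5.0 * r**5 / 6.0
    elif r < 0.85:
        k = -0.4 + 1.39 * r + 0.43 / (1.0 - r)
    else:
        k = 1.0 / (r**3 - 4.0 * r**2 + 3.0 * r)
    return float(min(max(k, 0.0), KAPPA_MAX))


def vonmises_logpdf(phi, mu, kappa):
    """Log density of the von Mises distribution on the full circle (radians).

    Uses the exponentially scaled Bessel function for stability at large κ.
    """
    kappa = np.asarray(kappa, dtype=float)
    return (
        kappa * (np.cos(np.asarray(phi) - mu) - 1.0)
        - np.log(2.0 * np.pi)
        - np.log(special.i0e(kappa))
    )
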
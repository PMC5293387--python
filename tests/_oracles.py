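"""Independent brute-force volume oracles used to validate the closed forms.

These deliberately avoid the package's formulas: the cap and ellipsoid
oracles count uniform random points in a tight bounding box, the sphere
oracle integrates the solid-of-revolution cross-section numerically.
"""

import math

import numpy as np
from scipy import integrate


def quad_sphere_volume(radius: float) -> float:
    """Sphere volume as the quadrature of pi*(r^2 - x^2) over [-r, r]."""
    val, _ = integrate.quad(lambda x: math.pi * (radius**2 - x**2), -radius, radius)
    return val


def mc_cap_volume(a: float, h: float, rng: np.random.Generator, n: int = 1_000_000) -> float:
    """Cap volume by point counting in the cap's own bounding box.

    The cap is {x^2+y^2+z^2 <= a^2, x >= a-h}; its bounding box is
    x in [a-h, a], |y|,|z| <= rho with rho the widest cap radius.  Sampling
    the box (rather than the whole sphere) keeps the hit fraction above ~0.39
    in every regime, so 1e6 points give ~0.13% relative error.
    """
    h = min(h, 2.0 * a)
    if h == 0.0 or a == 0.0:
        return 0.0
    rho = a if h >= a else math.sqrt(a * a - (a - h) ** 2)
    x = rng.uniform(a - h, a, n)
    y = rng.uniform(-rho, rho, n)
    z = rng.uniform(-rho, rho, n)
    hits = (y * y + z * z) <= (a * a - x * x)
    box = h * (2.0 * rho) ** 2
    return box * float(np.count_nonzero(hits)) / n


def mc_ellipsoid_volume(
    length: float, width: float, height: float, rng: np.random.Generator, n: int = 1_000_000
) -> float:
    """Ellipsoid volume by rejection sampling in the bounding box (full axes)."""
    sa, sb, sc = length / 2.0, width / 2.0, height / 2.0
    x = rng.uniform(-sa, sa, n)
    y = rng.uniform(-sb, sb, n)
    z = rng.uniform(-sc, sc, n)
    hits = (x / sa) ** 2 + (y / sb) ** 2 + (z / sc) ** 2 <= 1.0
    box = length * width * height
    return box * float(np.count_nonzero(hits)) / n
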
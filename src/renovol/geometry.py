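"""Sphere-in-ellipsoid geometric model of partial nephrectomy.

The kidney is idealized as an ellipsoid (axes reported as full lengths, the
way calipers and CT reports give them) and the tumor as a sphere that has
invaded a depth ``d`` below the renal surface.  Excising the tumor with a
uniform peritumoral margin ``w`` removes (or devitalizes) the spherical cap
of the margin-enlarged sphere (radius ``a = r + w``) that lies below the
renal surface, cut at height ``h = d + w``.  That cap volume is the
resected-and-ischemic volume, RAIV.  Dividing RAIV by the functional renal
volume — twice the single-kidney ellipsoid (kidneys assumed bilaterally
equal) minus the non-functional tumor sphere — and multiplying by 100 gives
PRAIV, the percentage of functional parenchyma lost to the resection.

All lengths are centimeters, all volumes cm³.  The renal surface is treated
as locally planar at the cut (tumor small relative to the kidney); the
ellipsoid enters only through total volume.  The cap integrand is a
swappable strategy (``cap_volume=`` argument of :func:`raiv`) so an
alternative resection shape can be substituted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

__all__ = [
    "GeometryError",
    "TumorGeometry",
    "KidneyGeometry",
    "ResectionSpec",
    "VolumeResult",
    "sphere_volume",
    "ellipsoid_volume",
    "spherical_cap_volume",
    "raiv",
    "functional_renal_volume",
    "praiv",
    "volume_analysis",
    "DEFAULT_MARGIN_CM",
]

#: Empirical width (cm) of peritumoral parenchyma resected/ischemized.
DEFAULT_MARGIN_CM = 0.5


class GeometryError(ValueError):
    """Raised for geometrically inadmissible inputs."""


def _require_finite(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise GeometryError(f"{name} must be finite, got {value!r}")
    return value


@dataclass(frozen=True)
class TumorGeometry:
    """Spherical renal tumor: radius and endophytic invasion depth, cm."""

    radius_cm: float
    invasion_depth_cm: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "radius_cm", _require_finite("radius_cm", self.radius_cm))
        object.__setattr__(
            self, "invasion_depth_cm", _require_finite("invasion_depth_cm", self.invasion_depth_cm)
        )
        if self.radius_cm <= 0:
            raise GeometryError(f"tumor radius must be positive, got {self.radius_cm}")
        if self.invasion_depth_cm < 0:
            raise GeometryError(
                f"invasion depth must be non-negative, got {self.invasion_depth_cm}"
            )

    @classmethod
    def from_diameter(cls, diameter_cm: float, invasion_depth_cm: float) -> "TumorGeometry":
        """Build from the reported tumor diameter (cm)."""
        return cls(radius_cm=float(diameter_cm) / 2.0, invasion_depth_cm=invasion_depth_cm)


@dataclass(frozen=True)
class KidneyGeometry:
    """Ellipsoidal kidney; the three orthogonal axes are FULL lengths, cm."""

    length_cm: float
    width_cm: float
    height_cm: float

    def __post_init__(self) -> None:
        for name in ("length_cm", "width_cm", "height_cm"):
            value = _require_finite(name, getattr(self, name))
            object.__setattr__(self, name, value)
            if value <= 0:
                raise GeometryError(f"kidney {name} must be positive, got {value}")


@dataclass(frozen=True)
class ResectionSpec:
    """Width (cm) of the peritumoral resection/ischemization margin."""

    margin_cm: float = DEFAULT_MARGIN_CM

    def __post_init__(self) -> None:
        object.__setattr__(self, "margin_cm", _require_finite("margin_cm", self.margin_cm))
        if self.margin_cm < 0:
            raise GeometryError(f"margin must be non-negative, got {self.margin_cm}")


@dataclass(frozen=True)
class VolumeResult:
    """Bundle of the three derived volumes for one patient."""

    raiv_cm3: float
    functional_volume_cm3: float
    praiv_pct: float


def sphere_volume(radius: float) -> float:
    """Volume of a sphere, (4/3)πr³."""
    radius = _require_finite("radius", radius)
    if radius < 0:
        raise GeometryError(f"sphere radius must be non-negative, got {radius}")
    return (4.0 / 3.0) * math.pi * radius**3


def ellipsoid_volume(kidney: KidneyGeometry) -> float:
    """Volume of an ellipsoid with full axis lengths L, W, H: (π/6)·L·W·H.

    Equivalent to (4/3)π·(L/2)(W/2)(H/2) with semi-axes.
    """
    return (math.pi / 6.0) * kidney.length_cm * kidney.width_cm * kidney.height_cm


def spherical_cap_volume(sphere_radius: float, cap_height: float) -> float:
    """Volume of the spherical cap of height ``h`` cut from a sphere of radius ``a``.

    Evaluates the solid-of-revolution integral π∫_{a-h}^{a} (a² - x²) dx in
    closed form: πh²(3a - h)/3.  ``cap_height`` is clamped to [0, 2a], so the
    result saturates at the full sphere volume.
    """
    a = _require_finite("sphere_radius", sphere_radius)
    h = _require_finite("cap_height", cap_height)
    if a < 0:
        raise GeometryError(f"sphere radius must be non-negative, got {a}")
    if h < 0:
        raise GeometryError(f"cap height must be non-negative, got {h}")
    h = min(h, 2.0 * a)
    return math.pi * h * h * (3.0 * a - h) / 3.0


def raiv(
    tumor: TumorGeometry,
    spec: ResectionSpec | None = None,
    *,
    cap_volume: Callable[[float, float], float] = spherical_cap_volume,
) -> float:
    """Resected-and-ischemic volume (cm³).

    The excised region is the sphere enlarged by the margin, a = r + w,
    truncated at the (locally planar) renal surface, i.e. the cap of height
    h = d + w.  Independent of kidney dimensions.  ``cap_volume`` may be
    replaced to model a different resection shape.
    """
    if spec is None:
        spec = ResectionSpec()
    a = tumor.radius_cm + spec.margin_cm
    h = tumor.invasion_depth_cm + spec.margin_cm
    return cap_volume(a, h)


def functional_renal_volume(kidney: KidneyGeometry, tumor: TumorGeometry) -> float:
    """Bilateral functional parenchymal volume (cm³).

    Kidneys are assumed bilaterally equal, so the total is twice the measured
    ellipsoid; the tumor sphere contributes no function and is subtracted.
    """
    bilateral = 2.0 * ellipsoid_volume(kidney)
    tumor_vol = sphere_volume(tumor.radius_cm)
    if tumor_vol >= bilateral:
        raise GeometryError(
            f"tumor volume {tumor_vol:.3f} cm3 is not smaller than bilateral "
            f"renal volume {bilateral:.3f} cm3"
        )
    return bilateral - tumor_vol


def praiv(
    tumor: TumorGeometry,
    kidney: KidneyGeometry,
    spec: ResectionSpec | None = None,
    *,
    cap_volume: Callable[[float, float], float] = spherical_cap_volume,
) -> float:
    """Percentage of resected-and-ischemic volume: 100 · RAIV / functional volume."""
    return 100.0 * raiv(tumor, spec, cap_volume=cap_volume) / functional_renal_volume(
        kidney, tumor
    )


def volume_analysis(
    tumor: TumorGeometry,
    kidney: KidneyGeometry,
    spec: ResectionSpec | None = None,
) -> VolumeResult:
    """Compute RAIV, functional renal volume and PRAIV in one pass."""
    r = raiv(tumor, spec)
    fv = functional_renal_volume(kidney, tumor)
    return VolumeResult(raiv_cm3=r, functional_volume_cm3=fv, praiv_pct=100.0 * r / fv)
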
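"""Semisolid-pool absorption lineshapes and the RF saturation rate Rrfb.

The saturation rate of the macromolecular pool under off-resonance
irradiation of amplitude ``omega1`` at offset ``delta`` is

    Rrfb = pi * omega1**2 * g(delta)

with ``g`` the absorption lineshape (units s/rad), normalized to unit area
over the offset axis.  Three standard forms are provided:

* Gaussian — solids and gels:       g = (T2b/sqrt(2*pi)) * exp(-(delta*T2b)**2/2)
* Lorentzian — liquids (testing):   g = (T2b/pi) / (1 + (delta*T2b)**2)
* super-Lorentzian — living tissue: orientational average of Gaussian
  components with angle-dependent width, singular on resonance.

The super-Lorentzian diverges as ``delta -> 0``; offsets used by pulsed
spin-lock MT protocols are >= 2*pi*800 rad/s, well outside the singular
region.  Requests inside ``|delta| < ON_RESONANCE_GUARD`` raise by default;
an opt-in cubic interpolation across the singularity (anchored at
+-2*pi*1 kHz, the standard practice when on-resonance values are needed)
is available via ``on_resonance="interpolate"``.
"""

from __future__ import annotations

import math
from functools import lru_cache

import numpy as np
from scipy.integrate import quad
from scipy.interpolate import CubicSpline

from .params import TWO_PI, LineshapeKind

#: Guard radius around delta = 0 inside which the super-Lorentzian is not
#: evaluated directly (rad/s).
ON_RESONANCE_GUARD = TWO_PI * 500.0

#: Anchor offset for the on-resonance interpolation (rad/s).
_INTERP_ANCHOR = TWO_PI * 1000.0

#: Magic-angle location of the super-Lorentzian integrand singularity.
_PHI_MAGIC = math.acos(1.0 / math.sqrt(3.0))

_SQRT_2_OVER_PI = math.sqrt(2.0 / math.pi)


def _gaussian(delta: float, t2b: float) -> float:
    x = delta * t2b
    return t2b / math.sqrt(TWO_PI) * math.exp(-0.5 * x * x)


def _lorentzian(delta: float, t2b: float) -> float:
    x = delta * t2b
    return (t2b / math.pi) / (1.0 + x * x)


def _super_lorentzian_integrand(phi: float, delta: float, t2b: float) -> float:
    u = 3.0 * math.cos(phi) ** 2 - 1.0
    if u == 0.0:
        return 0.0
    w = delta * t2b / u
    return math.sin(phi) * _SQRT_2_OVER_PI * (t2b / abs(u)) * math.exp(-2.0 * w * w)


@lru_cache(maxsize=65536)
def _super_lorentzian_quad(delta: float, t2b: float) -> float:
    val, _ = quad(
        _super_lorentzian_integrand,
        0.0,
        math.pi / 2.0,
        args=(delta, t2b),
        epsabs=1e-12,
        epsrel=1e-10,
        points=[_PHI_MAGIC],
        limit=200,
    )
    return val


def _super_lorentzian_interpolated(delta: float, t2b: float) -> float:
    # Cubic spline through directly evaluable anchors on both sides of the
    # singularity; even in delta by construction of the anchor set.
    anchors = np.array([1.0, 1.25, 1.5, 2.0]) * _INTERP_ANCHOR
    nodes = np.concatenate([-anchors[::-1], anchors])
    values = np.array([_super_lorentzian_quad(d, t2b) for d in nodes])
    return float(CubicSpline(nodes, values)(delta))


def lineshape_value(
    delta: float,
    T2b: float,
    kind: LineshapeKind | str,
    on_resonance: str = "raise",
) -> float:
    """Absorption lineshape g(delta) in s/rad.

    Parameters
    ----------
    delta : float
        Angular frequency offset (rad/s).
    T2b : float
        Semisolid transverse relaxation time (s).
    kind : LineshapeKind or str
        Which lineshape to evaluate.
    on_resonance : {"raise", "interpolate"}
        Policy for super-Lorentzian evaluation inside the on-resonance guard
        band ``|delta| < 2*pi*500`` rad/s.
    """
    if T2b <= 0:
        raise ValueError("T2b must be positive")
    if not math.isfinite(delta):
        raise ValueError("delta must be finite")
    kind = LineshapeKind(kind)
    if kind is LineshapeKind.GAUSSIAN:
        return _gaussian(delta, T2b)
    if kind is LineshapeKind.LORENTZIAN:
        return _lorentzian(delta, T2b)
    # super-Lorentzian
    if abs(delta) < ON_RESONANCE_GUARD:
        if on_resonance == "interpolate":
            return _super_lorentzian_interpolated(delta, T2b)
        raise ValueError(
            f"super-Lorentzian lineshape is singular near resonance "
            f"(|delta| = {abs(delta):.3g} < {ON_RESONANCE_GUARD:.3g} rad/s); "
            "pass on_resonance='interpolate' to bridge the singular region"
        )
    return _super_lorentzian_quad(delta, T2b)


def saturation_rate_rrfb(
    omega1: float,
    delta: float,
    T2b: float,
    kind: LineshapeKind | str,
    on_resonance: str = "raise",
) -> float:
    """RF saturation rate of the semisolid pool, ``pi * omega1**2 * g(delta)`` (1/s)."""
    if omega1 < 0:
        raise ValueError("omega1 must be non-negative")
    if omega1 == 0.0:
        return 0.0
    return math.pi * omega1 * omega1 * lineshape_value(
        delta, T2b, kind, on_resonance=on_resonance
    )
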
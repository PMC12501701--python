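"""Domain parameter types for two-pool magnetization-transfer spin-lock MRI.

Conventions
-----------
* All angular frequencies (``omega1``, ``delta``) are rad/s.
* All times are seconds; all rates are 1/s.
* Water-pool magnetization is normalized to ``M0a = 1``; the semisolid pool
  equilibrium is ``M0b = fb``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from enum import Enum

TWO_PI = 2.0 * math.pi

#: Minimum offset-to-amplitude ratio below which the water-pool cancellation
#: condition delta/omega1 >> 1 is considered poorly satisfied.
MIN_SAFE_RATIO = 5.0


class LineshapeKind(str, Enum):
    """Absorption lineshape of the semisolid (macromolecular) pool.

    ``super_lorentzian`` is the conventional choice for living tissue,
    ``gaussian`` for solids and gels such as agarose, ``lorentzian`` is kept
    for completeness/testing.
    """

    GAUSSIAN = "gaussian"
    SUPER_LORENTZIAN = "super_lorentzian"
    LORENTZIAN = "lorentzian"


@dataclass(frozen=True)
class TwoPoolParams:
    """Relaxation and exchange parameters of the two-pool MT system.

    Parameters
    ----------
    R1a, R2a : float
        Longitudinal / transverse relaxation rates of the free-water pool (1/s).
    R1b : float
        Longitudinal relaxation rate of the semisolid pool (1/s).  Commonly
        set equal to ``R1a``.
    T2b : float
        Transverse relaxation time of the semisolid pool (s), typically a few
        microseconds; enters only through the absorption lineshape.
    fb : float
        Pool-size fraction of the semisolid pool relative to water,
        ``M0b/M0a``.
    kba : float
        Exchange rate from the semisolid pool to water (1/s).  The reverse
        rate follows from detailed balance: ``kab = fb * kba``.
    lineshape : LineshapeKind
        Absorption lineshape used for the RF saturation rate of pool b.
    """

    R1a: float
    R2a: float
    R1b: float
    T2b: float
    fb: float
    kba: float
    lineshape: LineshapeKind = LineshapeKind.SUPER_LORENTZIAN

    def __post_init__(self) -> None:
        if self.R1a <= 0 or self.R2a <= 0 or self.R1b <= 0:
            raise ValueError("relaxation rates R1a, R2a, R1b must be positive")
        if self.T2b <= 0:
            raise ValueError("T2b must be positive")
        if not 0.0 <= self.fb <= 0.3:
            raise ValueError(f"fb={self.fb} outside the supported range [0, 0.3]")
        if self.kba <= 0:
            raise ValueError("kba must be positive")
        object.__setattr__(self, "lineshape", LineshapeKind(self.lineshape))

    @property
    def kab(self) -> float:
        """Water-to-semisolid exchange rate, ``fb * kba`` (1/s)."""
        return self.fb * self.kba

    @property
    def mpf(self) -> float:
        """Macromolecular proton fraction ``fb / (1 + fb)``."""
        return self.fb / (1.0 + self.fb)

    @classmethod
    def from_times(
        cls,
        T1a: float,
        T2a: float,
        T2b: float,
        fb: float,
        kba: float,
        T1b: float | None = None,
        lineshape: LineshapeKind = LineshapeKind.SUPER_LORENTZIAN,
    ) -> "TwoPoolParams":
        """Build from relaxation *times* in seconds (``T1b=None`` means T1b=T1a)."""
        r1a = 1.0 / T1a
        return cls(
            R1a=r1a,
            R2a=1.0 / T2a,
            R1b=1.0 / T1b if T1b is not None else r1a,
            T2b=T2b,
            fb=fb,
            kba=kba,
            lineshape=lineshape,
        )

    def with_(self, **kwargs) -> "TwoPoolParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


@dataclass(frozen=True)
class RfSetting:
    """A spin-lock RF setting: amplitude ``omega1`` and offset ``delta`` (rad/s).

    The spin-lock (effective-field) angle is ``theta = atan(omega1/delta)``.
    """

    omega1: float
    delta: float

    def __post_init__(self) -> None:
        if self.omega1 < 0:
            raise ValueError("omega1 must be non-negative")
        if not math.isfinite(self.omega1) or not math.isfinite(self.delta):
            raise ValueError("omega1 and delta must be finite")

    @property
    def theta(self) -> float:
        """Effective-field tilt angle from z (radians)."""
        return math.atan2(self.omega1, self.delta)

    @property
    def ratio(self) -> float:
        """Offset-to-amplitude ratio ``delta/omega1``."""
        if self.omega1 == 0:
            return math.inf
        return self.delta / self.omega1

    @classmethod
    def from_hz(cls, f1_hz: float, offset_hz: float) -> "RfSetting":
        """Build from amplitude and offset expressed in Hz."""
        return cls(omega1=TWO_PI * f1_hz, delta=TWO_PI * offset_hz)


@dataclass(frozen=True)
class RfPair:
    """Two RF settings sharing the offset-to-amplitude ratio delta/omega1.

    The shared ratio cancels the water-pool contribution in the difference of
    the two rotating-frame relaxation rates; the cancellation requires
    ``delta/omega1 >> 1`` (a warning is emitted below :data:`MIN_SAFE_RATIO`).
    """

    setting1: RfSetting
    setting2: RfSetting

    def __post_init__(self) -> None:
        r1, r2 = self.setting1.ratio, self.setting2.ratio
        if not (math.isfinite(r1) and math.isfinite(r2)):
            raise ValueError("both settings need omega1 > 0 to form a ratio-matched pair")
        if abs(r1 - r2) > 1e-6 * abs(r1):
            raise ValueError(
                f"offset/amplitude ratios differ: {r1:.8g} vs {r2:.8g}; "
                "the water-pool cancellation condition requires them equal"
            )
        if r1 < MIN_SAFE_RATIO:
            warnings.warn(
                f"delta/omega1 = {r1:.3g} < {MIN_SAFE_RATIO}: the >>1 condition for "
                "water-pool cancellation is weakly satisfied",
                stacklevel=2,
            )

    @property
    def N(self) -> float:
        """Amplitude scaling factor ``omega1(2)/omega1(1)``."""
        return self.setting2.omega1 / self.setting1.omega1

    @classmethod
    def from_hz(
        cls, f1_lo: float, offset_lo: float, f1_hi: float, offset_hi: float
    ) -> "RfPair":
        return cls(
            RfSetting.from_hz(f1_lo, offset_lo), RfSetting.from_hz(f1_hi, offset_hi)
        )

    def scaled_b1(self, b1_scale: float) -> "RfPair":
        """Pair with both amplitudes multiplied by a B1 scale (offsets fixed).

        Both settings scale identically, so the ratio match is preserved
        (the shared ratio itself changes by ``1/b1_scale``).
        """
        if b1_scale <= 0:
            raise ValueError("b1_scale must be positive")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return RfPair(
                RfSetting(self.setting1.omega1 * b1_scale, self.setting1.delta),
                RfSetting(self.setting2.omega1 * b1_scale, self.setting2.delta),
            )


@dataclass(frozen=True)
class PulseTrainParams:
    """Pulsed spin-lock train: n CW pulses of length Tp separated by gaps Tf.

    Derived quantities: total spin-lock time ``TSL = n*Tp`` and the inverse
    duty ratio ``IDR = (n-1)*Tf / (n*Tp)`` (total free precession over total
    spin-lock).  ``n = 1`` is a single continuous-wave block (IDR = 0).
    """

    Tp: float
    Tf: float
    n: int

    def __post_init__(self) -> None:
        if self.Tp <= 0:
            raise ValueError("Tp must be positive")
        if self.Tf < 0:
            raise ValueError("Tf must be non-negative")
        if int(self.n) != self.n or self.n < 1:
            raise ValueError("n must be a positive integer")
        object.__setattr__(self, "n", int(self.n))

    @property
    def tsl(self) -> float:
        """Total spin-lock time ``n * Tp`` (s)."""
        return self.n * self.Tp

    @property
    def idr(self) -> float:
        """Inverse duty ratio ``(n-1)*Tf / (n*Tp)``."""
        return (self.n - 1) * self.Tf / (self.n * self.Tp)

    def with_n(self, n: int) -> "PulseTrainParams":
        return PulseTrainParams(self.Tp, self.Tf, n)

    @classmethod
    def from_ms(cls, Tp_ms: float, Tf_ms: float, n: int) -> "PulseTrainParams":
        return cls(Tp_ms * 1e-3, Tf_ms * 1e-3, n)


# ---------------------------------------------------------------------------
# Tissue presets
# ---------------------------------------------------------------------------

def liver_preset() -> TwoPoolParams:
    """Liver tissue parameters (T1a=812 ms, T2a=42 ms, T2b=7.7 us, fb=6.9%,
    kba=51 1/s), super-Lorentzian lineshape."""
    return TwoPoolParams.from_times(
        T1a=0.812,
        T2a=0.042,
        T2b=7.7e-6,
        fb=0.069,
        kba=51.0,
        lineshape=LineshapeKind.SUPER_LORENTZIAN,
    )


def agarose_synthetic_preset(fb: float = 0.02) -> TwoPoolParams:
    """Synthetic agarose-gel-like parameters (Gaussian lineshape).

    A documented stand-in for gel vials: free-water relaxation typical of
    dilute agarose at 3T, fixed T2b and kba across concentrations, and fb
    proportional to concentration.  Not measured values.
    """
    return TwoPoolParams.from_times(
        T1a=2.5,
        T2a=0.08,
        T2b=9.0e-6,
        fb=fb,
        kba=50.0,
        lineshape=LineshapeKind.GAUSSIAN,
    )


def free_water_preset() -> TwoPoolParams:
    """Degenerate preset with no macromolecular pool (fb = 0)."""
    return TwoPoolParams.from_times(
        T1a=0.812,
        T2a=0.042,
        T2b=7.7e-6,
        fb=0.0,
        kba=51.0,
        lineshape=LineshapeKind.SUPER_LORENTZIAN,
    )


#: Presets addressable by name (config files, CLI).
PRESETS = {
    "liver": liver_preset,
    "agarose_synthetic": agarose_synthetic_preset,
    "free_water": free_water_preset,
}
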
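"""Closed-form relaxation models for CW and pulsed spin-lock with MT.

The model chain:

* ``r_water`` — water-pool rotating-frame relaxation,
  ``R1a*cos(theta)**2 + R2a*sin(theta)**2``;
* ``r_mt`` — MT-pool contribution,
  ``fb*kba*Rrfb / ((1+fb)*kba + Rrfb)`` (eigenvalue approximation of the
  two-pool system; saturating in Rrfb);
* ``beta_transient`` — the transient saturation-transfer factor linking the
  semisolid and water longitudinal magnetizations at the end of a CW pulse,
  ``beta = Rrfb/(kba+Rrfb) * (1 - exp(-(Rrfb+kba)*Tp))``;
* free-precession recovery of the water pool, as the full bi-exponential
  form and its first-order-in-fb mono-exponential reduction;
* ``train_magnetization`` — geometric-series closed form for the signal
  after n spin-lock modules;
* ``r1rho_pul`` — effective mono-exponential rate per unit spin-lock time of
  the pulsed train, ``R1rho + IDR*R1a + (IDR/Tf)*fb*beta``;
* ``rmpfsl_pul`` — the MT-specific rate measured as the difference of
  ``R1rho,pul`` between two RF settings sharing delta/omega1.  By
  construction it contains no R1a or R2a dependence.  An extended variant
  adds a water-independent semisolid longitudinal rate R1b to every
  denominator and exponent.

All magnetizations are in units of M0a = 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .lineshape import saturation_rate_rrfb
from .params import PulseTrainParams, RfPair, RfSetting, TwoPoolParams

#: Floor applied to rates in denominators to avoid 0/0 in degenerate sweeps.
_RATE_FLOOR = 1e-12


def rrfb(pools: TwoPoolParams, rf: RfSetting) -> float:
    """RF saturation rate of the semisolid pool for this setting (1/s)."""
    return saturation_rate_rrfb(rf.omega1, rf.delta, pools.T2b, pools.lineshape)


def r_water(pools: TwoPoolParams, rf: RfSetting) -> float:
    """Water-pool rotating-frame relaxation rate (1/s)."""
    c, s = math.cos(rf.theta), math.sin(rf.theta)
    return pools.R1a * c * c + pools.R2a * s * s


def r_mt(pools: TwoPoolParams, rf: RfSetting, r1b: float = 0.0) -> float:
    """MT-pool contribution to the rotating-frame relaxation rate (1/s).

    With ``r1b > 0`` the extended form
    ``fb*kba*(Rrfb+R1b) / ((1+fb)*kba + Rrfb + R1b)`` is used, whose
    pairwise differences reproduce the R1b-extended MT-difference term.
    """
    if pools.fb == 0.0:
        return 0.0
    rb = rrfb(pools, rf)
    denom = max((1.0 + pools.fb) * pools.kba + rb + r1b, _RATE_FLOOR)
    return pools.fb * pools.kba * (rb + r1b) / denom


def r1rho(pools: TwoPoolParams, rf: RfSetting, r1b: float = 0.0) -> float:
    """CW rotating-frame relaxation rate, ``Rwater + Rmt`` (1/s)."""
    return r_water(pools, rf) + r_mt(pools, rf, r1b=r1b)


def mza_ss(pools: TwoPoolParams, rf: RfSetting) -> float:
    """Steady-state water longitudinal magnetization under CW spin-lock,
    ``R1a*cos(theta)/R1rho`` (units of M0a)."""
    return pools.R1a * math.cos(rf.theta) / max(r1rho(pools, rf), _RATE_FLOOR)


def beta_transient(
    pools: TwoPoolParams, rf: RfSetting, Tp: float, r1b: float = 0.0
) -> float:
    """Transient saturation-transfer factor beta after a CW pulse of length Tp.

    ``Mzb = fb * (1 - beta) * Mza`` at the end of the pulse; ``beta`` grows
    from 0 toward the steady state ``Rrfb/(kba+Rrfb)`` with rate
    ``Rrfb + kba``.
    """
    if Tp <= 0:
        raise ValueError("Tp must be positive")
    rb = rrfb(pools, rf)
    k = pools.kba + rb + r1b
    if k <= _RATE_FLOOR:
        return 0.0
    return (rb + r1b) / k * (1.0 - math.exp(-k * Tp))


def mza_free_biexp(
    mza0: float, mzb0: float, pools: TwoPoolParams, t: float
) -> float:
    """Water longitudinal magnetization after free precession of duration t.

    Full bi-exponential two-pool recovery (first order in fb):

        Mza(t) = [fb e^{-kba t} + (1-fb) e^{-R1a t}] Mza(0)
               + [-fb e^{-kba t} + fb e^{-R1a t}] Mzb(0) M0a/M0b
               + (1 - e^{-R1a t}) M0a

    with ``M0b = fb`` so the cross term is ``(e^{-R1a t} - e^{-kba t}) Mzb(0)``.
    """
    if t < 0:
        raise ValueError("t must be non-negative")
    if pools.fb == 0.0:
        if mzb0 != 0.0:
            raise ValueError("fb = 0 makes M0b = 0; mzb0 must be 0")
        return mza0 * math.exp(-pools.R1a * t) + (1.0 - math.exp(-pools.R1a * t))
    ek = math.exp(-pools.kba * t)
    e1 = math.exp(-pools.R1a * t)
    fb = pools.fb
    water_term = (fb * ek + (1.0 - fb) * e1) * mza0
    cross_term = (-fb * ek + fb * e1) * mzb0 / fb
    return water_term + cross_term + (1.0 - e1)


def mza_free_transient(
    mza0: float, pools: TwoPoolParams, rf: RfSetting, Tp: float, t: float
) -> float:
    """Transient-state free-precession model.

    Substituting the end-of-pulse pool relationship
    ``Mzb(0) = fb (1 - beta) Mza(0)`` into the bi-exponential recovery gives

        Mza(t) = [(1 - fb*beta) e^{-R1a t} + fb*beta e^{-kba t}] Mza(0)
               + (1 - e^{-R1a t}),

    exact at t = 0 and tracking the transferred saturation as it unfolds on
    the 1/kba timescale.  This is the free-precession model the simulator
    validation compares against pure R1a recovery.
    """
    if t < 0:
        raise ValueError("t must be non-negative")
    fbb = pools.fb * beta_transient(pools, rf, Tp)
    e1 = math.exp(-pools.R1a * t)
    ek = math.exp(-pools.kba * t)
    return ((1.0 - fbb) * e1 + fbb * ek) * mza0 + (1.0 - e1)


def mza_free_reduced(
    mza0: float, pools: TwoPoolParams, rf: RfSetting, Tp: float, t: float
) -> float:
    """Reduced per-gap free-precession model.

    ``Mza(t) = Mza(0) e^{-fb*beta - R1a t} + (1 - e^{-R1a t})``: the
    transferred saturation is lumped into the single log-decrement
    ``fb*beta`` (the gap is long against 1/kba in supported protocols, so
    the transfer completes within it).  This is the per-gap factor the
    pulsed-train closed form composes; as a pointwise model of partial gaps
    prefer :func:`mza_free_transient`.
    """
    if t < 0:
        raise ValueError("t must be non-negative")
    beta = beta_transient(pools, rf, Tp)
    return mza0 * math.exp(-pools.fb * beta - pools.R1a * t) + (
        1.0 - math.exp(-pools.R1a * t)
    )


def _train_constants(
    pools: TwoPoolParams, rf: RfSetting, train: PulseTrainParams
) -> tuple[float, float, float, float]:
    """Per-module decay factors and steady states of the train recursion.

    Returns ``(g, rp, mss_a, mss_b)`` with ``g = R1a*Tf + fb*beta`` the
    per-gap log-decay, ``rp = R1rho*Tp`` the per-pulse log-decay, and the
    two steady-state constants of the closed form.
    """
    beta = beta_transient(pools, rf, train.Tp) if pools.fb > 0 else 0.0
    g = pools.R1a * train.Tf + pools.fb * beta
    rp = r1rho(pools, rf) * train.Tp
    mss = mza_ss(pools, rf)
    e_p = math.exp(-rp)
    e_g = math.exp(-g)
    e_f = math.exp(-pools.R1a * train.Tf)
    denom = 1.0 - e_g * e_p
    if abs(denom) < _RATE_FLOOR:
        denom = _RATE_FLOOR
    mss_a = (mss * (1.0 - e_p) * e_g + (1.0 - e_f)) / denom
    mss_b = (mss * (1.0 - e_p) + (1.0 - e_f) * e_p) / denom
    return g, rp, mss_a, mss_b


def train_magnetization(
    m_init: float, pools: TwoPoolParams, rf: RfSetting, train: PulseTrainParams
) -> float:
    """Water signal at the end of the n-th spin-lock module (closed form).

        M(n) = (Mini - Mss_a) e^{-(n-1)(R1a Tf + fb beta) - n R1rho Tp} + Mss_b

    For ``n = 1`` this reduces to the single-pulse mono-exponential
    ``Mini e^{-R1rho Tp} + Mzass (1 - e^{-R1rho Tp})``.
    """
    g, rp, mss_a, mss_b = _train_constants(pools, rf, train)
    n = train.n
    return (m_init - mss_a) * math.exp(-(n - 1) * g - n * rp) + mss_b


def train_magnetization_recursive(
    m_init: float, pools: TwoPoolParams, rf: RfSetting, train: PulseTrainParams
) -> float:
    """Explicit recursion over the n modules (oracle for the closed form)."""
    beta = beta_transient(pools, rf, train.Tp) if pools.fb > 0 else 0.0
    rp = r1rho(pools, rf) * train.Tp
    mss = mza_ss(pools, rf)
    e_p = math.exp(-rp)
    e_g = math.exp(-(pools.R1a * train.Tf + pools.fb * beta))
    e_f = math.exp(-pools.R1a * train.Tf)
    m = m_init * e_p + mss * (1.0 - e_p)  # first pulse
    for _ in range(train.n - 1):
        m = (m * e_g + (1.0 - e_f)) * e_p + mss * (1.0 - e_p)
    return m


def r1rho_pul(
    pools: TwoPoolParams, rf: RfSetting, train: PulseTrainParams, r1b: float = 0.0
) -> float:
    """Effective relaxation rate per unit spin-lock time of the pulsed train.

        R1rho,pul = R1rho + IDR*R1a + (IDR/Tf)*fb*beta

    with ``IDR = (n-1)*Tf/(n*Tp)``; for ``n = 1`` this is exactly R1rho.
    """
    if train.n > 1 and train.Tf == 0.0:
        raise ValueError("Tf = 0 with n > 1: IDR/Tf undefined (back-to-back CW)")
    base = r1rho(pools, rf, r1b=r1b)
    if train.n == 1:
        return base
    beta = beta_transient(pools, rf, train.Tp, r1b=r1b)
    idr = train.idr
    return base + idr * pools.R1a + idr / train.Tf * pools.fb * beta


def rmpfsl_pul(
    pools: TwoPoolParams,
    rf_pair: RfPair,
    train: PulseTrainParams,
    r1b: float | None = None,
) -> float:
    """MT-specific pulsed spin-lock rate (1/s).

    Difference of ``R1rho,pul`` between the two ratio-matched RF settings;
    the water terms cancel, leaving

        Rmpfsl,pul = kba^2 fb (1+fb) [1/D1 - 1/D2] + (IDR/Tf) fb (beta2 - beta1)

    with ``Di = (1+fb)*kba + Rrfb_i``.  Passing ``r1b`` adds that rate to
    every denominator and exponent (extension for R1b != R1a regimes,
    reducing exactly to the base form at ``r1b = 0``).  The result depends
    on fb, kba, T2b and the protocol only — never on R1a or R2a.
    """
    if train.n > 1 and train.Tf == 0.0:
        raise ValueError("Tf = 0 with n > 1: IDR/Tf undefined")
    if pools.fb == 0.0:
        return 0.0
    rb = 0.0 if r1b is None else r1b
    fb, kba = pools.fb, pools.kba
    r1 = rrfb(pools, rf_pair.setting1)
    r2 = rrfb(pools, rf_pair.setting2)
    d1 = (1.0 + fb) * kba + r1 + rb
    d2 = (1.0 + fb) * kba + r2 + rb
    cw_term = kba * kba * fb * (1.0 + fb) * (1.0 / d1 - 1.0 / d2)
    if train.n == 1:
        return cw_term
    k1 = kba + r1 + rb
    k2 = kba + r2 + rb
    beta1 = (r1 + rb) / k1 * (1.0 - math.exp(-k1 * train.Tp))
    beta2 = (r2 + rb) / k2 * (1.0 - math.exp(-k2 * train.Tp))
    fp_term = train.idr / train.Tf * fb * (beta2 - beta1)
    return cw_term + fp_term


@dataclass(frozen=True)
class RateDecomposition:
    """Decomposition of the pulsed spin-lock relaxation rate for one setting."""

    r_water: float
    r_mt: float
    r1rho: float
    r1rho_pul: float
    free_precession_mt_term: float

    def __post_init__(self) -> None:
        if not math.isclose(self.r1rho, self.r_water + self.r_mt, rel_tol=1e-9):
            raise ValueError("r1rho must equal r_water + r_mt")


def decompose(
    pools: TwoPoolParams, rf: RfSetting, train: PulseTrainParams
) -> RateDecomposition:
    """Split ``R1rho,pul`` into its water, MT, recovery and gap-MT parts."""
    rw = r_water(pools, rf)
    rm = r_mt(pools, rf)
    if train.n == 1:
        fp = 0.0
    else:
        fp = train.idr / train.Tf * pools.fb * beta_transient(pools, rf, train.Tp)
    return RateDecomposition(
        r_water=rw,
        r_mt=rm,
        r1rho=rw + rm,
        r1rho_pul=r1rho_pul(pools, rf, train),
        free_precession_mt_term=fp,
    )
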
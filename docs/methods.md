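# Methods

## The two-pool model and its simulator

Tissue is modelled as a free-water pool (a) exchanging longitudinal
magnetization with a semisolid macromolecular pool (b). Pool a carries
relaxation rates R₁a, R₂a; pool b a longitudinal rate R₁b (equal to R₁a by
default) and a transverse time T₂b of a few microseconds that enters only
through its absorption lineshape. The pool-size fraction f_b sets the
equilibrium magnetization M₀b = f_b·M₀a and, by detailed balance, the
forward exchange rate k_ab = f_b·k_ba. The reported biomarker is
MPF = f_b/(1+f_b).

Because T₂b is microseconds, the semisolid transverse components dephase
essentially instantaneously and are never represented; off-resonance
irradiation of amplitude ω₁ at offset Δω instead saturates the semisolid
longitudinal magnetization at the rate R_rfb = π·ω₁²·g(Δω). Three
lineshapes g are provided: Gaussian (gels/solids), Lorentzian (liquids;
mostly for testing), and super-Lorentzian (tissue), the last evaluated by
adaptive quadrature with absolute tolerance 10⁻¹² (g ≈ 10⁻⁶ s/rad, so a
tight absolute floor is needed) and split at the magic-angle singularity of
the integrand. The super-Lorentzian diverges on resonance; offsets below
2π·500 rad/s raise unless the caller opts into a cubic-spline bridge
anchored at ±1–2 kHz. All supported protocols use offsets ≥ 2π·800 rad/s,
so the guard never triggers in practice.

The simulator's state is (M_xa, M_ya, M_za, M_zb) in units of M₀a = 1,
evolving under a constant-coefficient affine system per block (CW pulse or
free gap). Propagation is by exact exponentiation of the 5×5 augmented
matrix, so simulator-vs-model comparisons carry no step-size error (the
propagator was cross-checked against adaptive ODE integration to 10⁻¹¹).
The pulsed sequence is idealized as: instantaneous lossless tips of the
water magnetization between z and the effective-field axis
(θ = atan(ω₁/Δω)) around every CW pulse; crusher gradients zeroing the
water transverse components in every gap; toggled preparation realized as
M_za(0) = ±1 with M_zb(0) = ±f_b (an ideal adiabatic inversion inverts both
pools). Relaxation during tips is neglected. These idealizations are the
model's definition of the sequence, not approximations fitted afterwards.

## The analytic chain

During a CW pulse the water signal decays mono-exponentially at
R₁ρ = R_water + R_mt, with R_water = R₁a·cos²θ + R₂a·sin²θ and

    R_mt = f_b·k_ba·R_rfb / ((1+f_b)·k_ba + R_rfb),

a saturating function of R_rfb whose pairwise differences equal
k_ba²f_b(1+f_b)[1/D⁽¹⁾ − 1/D⁽²⁾] with D = (1+f_b)k_ba + R_rfb — an identity
the test suite asserts to 10⁻¹². The end-of-pulse pool relationship is
M_zb = f_b(1−β)M_za with the transient factor
β = R_rfb/(k_ba+R_rfb)·(1−e^{−(R_rfb+k_ba)T_p}).

During a gap the water pool refills the saturated semisolid pool; the
transient-state model
M_za(t) = [(1−f_bβ)e^{−R₁a t} + f_bβ e^{−k_ba t}]M_za(0) + (1−e^{−R₁a t})
is exact at t = 0 and resolves the transfer on the 1/k_ba timescale. For
gaps long against 1/k_ba (T_f = 50 ms vs 1/k_ba ≈ 20 ms in liver) the
transfer is lumped into a single per-gap log-decrement f_b·β, giving the
per-module decay factor e^{−(R₁a T_f + f_bβ + R₁ρ T_p)} and, by geometric
summation, the closed-form signal after n modules and the effective rate
per unit spin-lock time

    R₁ρ,pul = R₁ρ + IDR·R₁a + (IDR/T_f)·f_b·β,   IDR = (n−1)T_f/(nT_p).

Subtracting two acquisitions with a shared offset-to-amplitude ratio
Δω/ω₁ ≫ 1 cancels every water term (θ is identical for both settings) and
leaves the MT-specific rate R_mpfsl,pul quoted in the README. An extended
variant adds a water-independent R₁b to every denominator and exponent for
regimes where R₁b ≠ R₁a; it reduces exactly to the base form at R₁b = 0.

Sign convention: the low-RF toggled difference decays more slowly than the
high-RF one, so the four-image estimator is written as the positive
quantity log[ΔM_lo/ΔM_hi]/TSL, consistent with
R_mpfsl,pul = R₁ρ,pul⁽²⁾ − R₁ρ,pul⁽¹⁾ > 0 whenever R_rfb⁽²⁾ > R_rfb⁽¹⁾.

## Known model error at short pulses, and why inversion uses a dictionary

The closed form charges every CW pulse the full asymptotic R₁ρ·T_p. In the
simulation, each pulse restarts the saturation transient (the gap largely
re-equilibrates the pools), so the realized MT decay per pulse is
R_water·T_p + f_b·k_ba·∫₀^{T_p}β(t)dt < R_mt·T_p. The closed form therefore
*overestimates* the measured rate at short T_p: for liver at
T_p = 10 ms/T_f = 50 ms/n = 10 the full-sequence simulated four-image rate
is ≈4.16 s⁻¹ against the closed form's 5.07 s⁻¹ (+22 %), shrinking to
+13 % at T_p = 20 ms and +0.6 % at T_p = 100 ms. When the reference is
instead built the way figure-level validations are constructed — CW R₁ρ
fitted from simulation per setting plus the analytic pulsed terms
(`numeric_rmpfsl(method="cw_fit")`) — closed form and simulation agree to
≈0.2 %.

Consequences for quantification: the mono-exponential *form* of the train
signal is unaffected (per-module decay is constant after the first module;
fits give R² > 0.9999), but inverting measured rates through the analytic
forward model at short T_p under-recovers f_b by roughly the same fraction.
The package therefore defaults phantom/map reconstruction to the
Bloch–McConnell dictionary mode, which tabulates the *simulated*
four-image rate on an (f_b, B1) grid (31 f_b points over the supported
interval; B1 slices at 0.1 spacing over the covered range, linearly
interpolated) and makes inversion∘forward an identity to well under 1 %.
The analytic root-find mode (Brent bracketing on the strictly increasing
forward model, tolerance 10⁻¹⁰ on f_b) remains the right tool when the
data themselves come from the closed form, and both modes treat k_ba and
T₂b as known constants — their misspecification is quantified by the
sensitivity sweep rather than estimated jointly.

## Estimators and noise

The four-image estimator divides toggled differences, cancelling
steady-state offsets and receiver gain exactly; pixels with non-positive
differences or ratios are flagged invalid rather than clipped, and the
validity channel propagates to all downstream maps. ROI-mean signals may
be passed as scalars (per-pixel estimation followed by ROI averaging is
the default path in the phantom pipeline).

The fitting estimator uses the toggled-difference series over module
counts, D(n) = D₀·e^{g}·e^{−rn} with r = R₁a T_f + f_bβ + R₁ρ T_p and
g = R₁a T_f + f_bβ: a two-parameter decay fit per setting yields r, and
the *difference* of the fitted log-amplitudes yields g⁽²⁾−g⁽¹⁾ without
knowing D₀ (receiver gain cancels), so the rate difference at the
protocol's n is [n·Δr − Δg]/(n·T_p), matching the closed-form convention.
A three-parameter single-series fit (A·e^{−rn}+C) is provided for
mono-exponentiality diagnostics (R²).

Simulation noise is zero-mean Gaussian added to each longitudinal signal,
with SNR_dB = 20·log₁₀(M₀a/σ) (a 10·log₁₀ alternative is selectable).
Rician/magnitude statistics are not modelled; consequently the Monte-Carlo
studies reproduce the precision behaviour of the estimator (RMP growing
with n, σ shrinking with n until the high-RF difference decays toward the
noise floor at n ≈ 1/r_hi) but not the scanner-observed elevation of the
mean at very small n, which in real magnitude data involves noise-floor
and system effects outside this noise model. Precision saturates rather
than improves indefinitely: past n ≈ 8 at liver rates the shrinking
denominator difference offsets the growing TSL.

## Synthetic phantoms

Vial phantoms place circular vials on an empty background with per-pixel
maps of f_b, T₁a, T₂a, T₂b, k_ba and B1 scale. The agarose analogue is a
documented stand-in, not a calibration: Gaussian lineshape, T₁a = 2.5 s,
T₂a = 80 ms, T₂b = 9 μs, k_ba = 50 s⁻¹ fixed across vials, f_b
proportional to nominal concentration (1–5 % ⇒ f_b = 0.01–0.05). A
paramagnetic-dopant analogue multiplies R₁a/R₂a only. Acquisition
simulates every distinct (tissue, B1) tuple once (vial phantoms have few)
and adds seeded Gaussian noise per pixel. Passing the end-to-end recovery
tests therefore demonstrates correctness of the pipeline under the stated
noise model — not robustness to motion, B₀ inhomogeneity, partial volume,
or magnitude statistics, none of which are simulated.

## Study conditions used by the tests and the acceptance script

Liver parameters T₁a = 812 ms, T₂a = 42 ms, T₂b = 7.7 μs, f_b = 6.9 %,
k_ba = 51 s⁻¹ with super-Lorentzian lineshape; RF pairs
(80, 800)/(350, 3500) Hz and (100, 1000)/(450, 4500) Hz; trains
[5 ms, 50 ms, 20], [10 ms, 50 ms, 10], [20 ms, 50 ms, 5] (all TSL =
100 ms) with the CW reference as the degenerate n = 1, T_f = 0, T_p =
100 ms case. Sensitivity sweeps cover T₁a ∈ [500, 1500] ms,
T₂a ∈ [20, 80] ms, T₂b ∈ [5, 12] μs, f_b ∈ [0.01, 0.12],
k_ba ∈ [20, 80] s⁻¹. Monte-Carlo precision uses 1000 repetitions per cell
at 30–60 dB; phantom studies use 48×48 grids with vial radius 5 at 60 dB.
These sizes keep the full suite and the acceptance script inside a few
seconds on one CPU while leaving Monte-Carlo standard errors well below
the asserted effects.

## Numerical choices and degenerate inputs

Rates in denominators are floored at 10⁻¹² to avoid 0/0 in degenerate
sweeps; T_f = 0 with n > 1 is rejected (IDR/T_f undefined) while n = 1
cleanly reduces to CW; f_b = 0 zeroes the MT chain exactly and makes the
bi-exponential cross term an error (M₀b = 0). Exponentials are evaluated
in log space in the fitting paths. The dictionary build asserts strict
monotonicity of every B1 slice and fails loudly on protocols where the
inversion would be ill-posed. Configuration files take Hz/ms/μs and are
converted to rad/s and seconds at parse time; unknown keys are rejected.

## Limitations

No B₀ inhomogeneity, chemical-exchange (CEST) pools, dipolar order,
diffusion, flow, readout simulation, or Rician statistics. Cartilage,
muscle and white-matter parameter sets are not shipped (no verified source
values); cross-tissue validation accepts user-supplied presets. The
closed-form model's short-T_p bias is inherent to its derivation and is
handled operationally by the dictionary inversion, not removed.
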
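# mpfpsl — macromolecular proton fraction mapping with pulsed spin-lock MRI

Quantitative magnetization-transfer (MT) imaging estimates the
macromolecular proton fraction, MPF = f_b/(1+f_b), a biomarker of
macromolecular content (e.g. collagen deposition in liver fibrosis).
Spin-lock-based MT quantification isolates the MT pool from the free-water
pool, but continuous-wave (CW) spin-lock at clinically useful amplitudes is
limited to short durations by RF-amplifier constraints. A *pulsed*
spin-lock train — n short CW pulses of duration T_p separated by n−1 free
precession gaps of duration T_f — circumvents the hardware limit and makes
long effective spin-lock times (TSL = n·T_p) routinely achievable.

`mpfpsl` implements the complete quantification chain for this acquisition,
for MR physicists and methods researchers:

* **Two-pool Bloch–McConnell simulator** (`mpfpsl.bm`) — the numerical
  ground truth. State (M_xa, M_ya, M_za, M_zb), exact matrix-exponential
  propagation over every piecewise-constant block, idealized adiabatic
  tips, crushers in every gap, RF saturation of the semisolid pool at
  R_rfb = π·ω₁²·g(Δω) with Gaussian, Lorentzian or super-Lorentzian
  lineshape g (`mpfpsl.lineshape`).
* **Analytic relaxation model** (`mpfpsl.analytic`) — the closed-form
  chain: R₁ρ = R_water + R_mt with R_water = R₁a·cos²θ + R₂a·sin²θ;
  the transient saturation-transfer factor
  β = R_rfb/(k_ba+R_rfb)·(1−e^{−(R_rfb+k_ba)T_p});
  the geometric-series signal after n modules;
  R₁ρ,pul = R₁ρ + IDR·R₁a + (IDR/T_f)·f_b·β with
  IDR = (n−1)T_f/(nT_p); and the MT-specific rate

      R_mpfsl,pul = k_ba² f_b (1+f_b) [1/((1+f_b)k_ba + R_rfb⁽¹⁾) − 1/((1+f_b)k_ba + R_rfb⁽²⁾)]
                  + (IDR/T_f) · f_b · (β⁽²⁾ − β⁽¹⁾)

  for two RF settings sharing Δω/ω₁ (so the water terms cancel —
  R_mpfsl,pul depends on f_b, k_ba, T₂b and the protocol only).
* **Estimators** (`mpfpsl.estimation`) — the fast four-image estimator
  (toggled ±M₀ preparations at each RF setting;
  R_mpfsl,pul = log[ΔM_lo/ΔM_hi]/TSL) and a fitting-based estimator over
  series of module counts, plus the relative measurement precision
  RMP = μ/σ.
* **MPF inversion** (`mpfpsl.inversion`) — monotone root finding on the
  analytic forward model, or a Bloch–McConnell dictionary over an
  (f_b, B1) grid.
* **Digital phantoms and simulation studies** (`mpfpsl.phantom`,
  `mpfpsl.experiments`) — agarose-like vial phantoms end-to-end, parameter
  sensitivity sweeps, Monte-Carlo precision studies, protocol
  optimization, analytic-vs-simulation validation.
* **Model/results interface** (`mpfpsl.model`) and a CLI (`mpfpsl`).

## Worked example

Simulate the four toggled liver acquisitions at a published protocol
(ω₁ = 100/450 Hz, Δω = 1000/4500 Hz, T_p/T_f/n = 10 ms/50 ms/10), add mild
noise, and fit:

```python
import numpy as np
from mpfpsl import (MPFPSLModel, PulseTrainParams, RfPair, bm, liver_preset)
from mpfpsl.inversion import InversionConfig

liver = liver_preset()                      # T1a=812 ms, T2a=42 ms, T2b=7.7 us,
pair = RfPair.from_hz(100, 1000, 450, 4500) # fb=6.9 %, kba=51 1/s
train = PulseTrainParams.from_ms(10, 50, 10)

rng, shape, imgs = np.random.default_rng(0), (8, 8), {}
for tag, rf in (("lo", pair.setting1), ("hi", pair.setting2)):
    for lab, m0 in (("m1", 1.0), ("m2", -1.0)):
        s = bm.simulate_pulse_train(liver, rf, train, m0)[-1]
        imgs[f"{tag}_{lab}"] = np.full(shape, s) + rng.normal(0, 1e-3, shape)

inv = InversionConfig(kba=51.0, T2b=7.7e-6, lineshape="super_lorentzian",
                      mode="dictionary_bm", fb_max=0.15)
res = MPFPSLModel.from_images(imgs["lo_m1"], imgs["lo_m2"],
                              imgs["hi_m1"], imgs["hi_m2"],
                              rf_pair=pair, train=train, inversion=inv).fit()
print(res.summary())
```

```
MPF-PSL quantification results
==============================================
protocol         Tp=10.0 ms  Tf=50.0 ms  n=10
                 TSL=100.0 ms  IDR=4.500
rf pair          omega1: 100/450 Hz, offset: 1000/4500 Hz
valid pixels     64/64
Rmpfsl,pul       mean=4.1651 1/s  sd=0.0302 1/s
RMP              138.04
inversion        kba=51.0 1/s  T2b=7.7 us  lineshape=super_lorentzian
MPF              mean=6.46 %
```

The estimated MT-specific rate is 4.17 s⁻¹; inverting it through the
Bloch–McConnell dictionary recovers MPF = 6.46 %, matching the generating
tissue (f_b = 6.9 % ⇒ MPF = 6.45 %). The RMP of 138 reflects the low noise
of this toy acquisition. Note that inverting the same rate through the
*analytic* forward model instead recovers ≈5.4 %: the closed form is an
asymptotic (long-T_p) approximation that overestimates the rate at
T_p = 10 ms, so quantitative inversion of simulated or measured data should
use the dictionary mode (see `docs/methods.md`).

The same pipeline is scriptable from the shell:

```bash
mpfpsl simulate --config config.yaml
mpfpsl phantom acquire --config config.yaml --snr-db 60
mpfpsl experiment sensitivity --config config.yaml --parameter fb
```

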
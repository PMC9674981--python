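# vimflow

Dual-wavelength static-light-scattering analysis of intermediate-filament
assembly kinetics.

## The problem

Vimentin tetramers, upon a jump in ionic strength, assemble in three
phases: lateral association into ~60 nm unit-length filaments (ULFs,
complete within ~1 s), end-to-end annealing of ULFs into growing filaments
(seconds to minutes), and a radial compaction in which immature filaments
shed loosely bound subunits.  A stopped-flow instrument that records
90° scattered light at two laser wavelengths (405 and 594 nm, 1 kHz
sampling, 3 ms dead time) can separate these processes, because the two
channels respond differently to filament *shape*:

* Rayleigh scattering grows with the mass of the scatterer regardless of
  wavelength — lateral assembly moves both channels together;
* once filaments elongate, the Rayleigh–Gans shape factor for a thin rod
  of length *l*,

      P(90°) = E²(z),   E²(z) = Si(2z)/z − (sin z / z)²,
      z = (2πl/λ)·sin(π/4),

  suppresses the short-wavelength channel first, so the intensity ratio
  r = I₅₉₄/I₄₀₅ rises from 1 toward the asymptote λ₅₉₄/λ₄₀₅ ≈ 1.47 and is
  a pure reporter of elongation, insensitive to filament thickness.

For a log-normal filament-length population whose geometric mean grows
linearly at rate r_la (ULFs/min) and whose width follows the empirical law
σ = 0.053·l_fil + 0.115 (σ = SD of log₁₀ length, l_fil in ULFs), the ratio
follows a saturating exponential

    r(t) = 1 + A·(1 − e^(−t/τ)),

and Monte Carlo calibration ties the fitted time constant to the rate:
**r_la = 2.32/τ** (τ in minutes).  `vimflow` implements the forward
optics, the calibration, a trace-processing pipeline (baseline
calibration → early-window channel normalization → ratio → exponential
fit), windowed cross-salt-condition comparisons that separate lateral
kinetics (20–40 ms window), combined kinetics (peak window), and mass per
cross section (500–600 s plateau), plus morphometry fits and a synthetic
stopped-flow generator with full ground truth, so the entire analysis is
testable without instrument data.

## Worked example

```python
import vimflow as vf
from vimflow.pipeline import RatioKineticsModel, normalize_channels
from vimflow.population import calibrate_for_pipeline

# a 600 s, 1 kHz synthetic recording: 0.2 mg/mL vimentin-like trace
# elongating at 2 ULFs/min, with compaction overshoot and noise
cfg = vf.TraceConfig(elongation_rate=2.0, salt=100.0, seed=42)
trace = vf.generate_trace(cfg)

cal = calibrate_for_pipeline()          # pipeline-matched rate calibration
model = RatioKineticsModel.from_trace(normalize_channels(trace), factor=cal)
print(model.fit().summary())
```

```
Ratio kinetics: r(t) = 1 + A(1 - exp(-t/tau))
==============================================
prefactor A               0.4222  +/- 0.0040
tau [min]                 1.2375  +/- 0.0329
rate r_la [ULFs/min]      2.1147
factor [ULFs]             2.6168  (calibration)
fit window [s]               1.1 - 549
points / resid RMS            34  / 8.83e-03
flags                       none
```

The fitted prefactor (0.42, within the plausible 0.3–0.5 band), the
1.24 min time constant and the recovered elongation rate of 2.11 ULFs/min
(truth: 2.0) come from the ratio of the two noisy channels alone.  With
the published factor 2.32 instead of the pipeline-matched calibration the
estimate would be 2.32/1.24 = 1.87 ULFs/min; `docs/methods.md` explains
the convention difference.

The same machinery is exposed on the command line:

```bash
vimflow shape-factor --length-nm 60 --wavelength-nm 405
# {"z": 0.6582, "E2": 0.9535, "P90": 0.9535}
vimflow simulate --config cfg.yaml --out trace.csv --truth truth.json
vimflow fit-ratio --trace trace.csv --out fit.json
vimflow compare-salt --num high1.csv --num high2.csv --den low1.csv --out cmp.json
vimflow calibrate-factor --rates 0.5,1,2,3,4,5 --seed 0
vimflow morphometry lengths.csv --unit ulf --out morpho.json
```

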
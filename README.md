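# mdisim

Desk-scale, reduced-order simulator of pressurized metered-dose inhaler
(MDI) drug delivery through a mouth–throat–lung airway model. It reproduces
the structure of a resolved-flow MDI delivery study — polydisperse droplet
generation, inverse calibration of the orifice discharge velocity against
downstream probe measurements, actuation–inhalation timing scenarios, and
mass-based dosimetry statistics — with the turbulence-resolving flow field
replaced by documented reduced-order closures.

## What it models

- **Aerosol source** (`mdisim.aerosol`): truncated volume-lognormal droplet
  size distribution (Dv50 11.0 µm, GSD 1.57, bounds 0.5–35.0 µm) sampled via
  the Hatch–Choate count-median conversion with rejection truncation;
  100k-droplet clouds released uniformly over a 0.2 s actuation step within
  a plume cone at the configured discharge speed.
- **Breathing waveforms** (`mdisim.breathing`): a deep-slow inhalation
  profile (5 s, 61.2 L/min peak at 1.23 s, quarter-sine rise / half-cosine
  decay, 1 s breath-hold) and the actuation step with a configurable offset —
  the coordination variable under study.
- **Jet calibration** (`mdisim.jet`): self-similar round-jet gas closure plus
  a Schiller–Naumann-corrected Stokes drag integrator (exact exponential
  update); predicts mean droplet speeds at probe stations 3 and 6 cm from the
  nozzle and reversely selects the discharge speed (40 m/s from {35, 40, 45})
  that best matches the measured 15.1 / 10.8 m/s pair.
- **Airway model** (`mdisim.airway`): idealized regionalized geometry —
  mouthpiece (1.28 cm²), mouth, pharynx, larynx, and a symmetric bifurcating
  tracheobronchial tree (classical morphometric dimensions) to G9 with 512
  outlets, partitioned into five lobes (LU/LL/RU/RM/RL) at the G3 level.
- **Transport & deposition** (`mdisim.transport`): three-phase reduced-order
  march — jet-phase back-throat impaction (timing-coupled through the
  instantaneous inhalation speed at release), a well-mixed mouth reservoir
  with plug-flow clearance by cumulative inhaled volume and settling races,
  then per-segment impaction/sedimentation Bernoulli draws down the tree,
  with breath-hold settle-or-survive for stranded droplets. Fully vectorized;
  a 100k-droplet scenario runs in about a second.
- **Dosimetry metrics** (`mdisim.dosimetry`): mass-based regional deposition
  fractions, deposition enhancement factor maps (area-weighted mean 1),
  lobar penetration rates, scenario comparisons, and an exact-fraction
  fixture generator for tests.

## CLI

```bash
# inverse calibration of the discharge speed
mdisim calibrate --candidates 35,40,45 --targets 15.1,10.8 --seed 0

# simulate delivery scenarios (one record CSV per actuation offset)
mdisim simulate --t-act 0.63 --t-act 0.0 --t-act 1.5 --t-act 2.5 \
    --n-droplets 10000 --seed 1 --out records.csv

# dosimetry report and scenario comparison
mdisim report records_t0.63.csv --out control.csv
mdisim compare records_t0.63.csv records_t0.csv --out comparison.csv
```

Scenario sets can also be declared in YAML (see
`mdisim.breathing.load_scenarios`).

## Notes on fidelity

The original study resolves the airway flow with large-eddy simulation on a
multi-million-cell mesh; this package deliberately replaces that field with
closures whose parameters are exposed in `JetModelParams` and
`TransportConfig`. Quantitative regional doses are therefore not expected to
match the resolved-flow values; the package targets the study's reproducible
arithmetic exactly and its mechanistic trends directionally (delayed
actuation raises mouth deposition, actuation before inhalation raises device
loss, large droplets stop in the throat while small ones reach the lung,
lower lobes receive more dose than upper lobes).
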
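# loopstate

Quantitative analyses for enzymes that polymerise into filaments and tune
their activity through the conformational ensemble of an active-site
gating loop — the situation of human glutamine synthetase (GS), whose
stacked pentameric rings (decamers) stack further into filaments with
altered Michaelis constants. The package serves enzymologists and
structural biologists who have (1) coupled-assay plate-reader kinetics,
(2) single- or multi-model atomic structures (e.g. cryo-EM consensus
models and Bayesian ensemble refinements), and (3) particle-class counts
from time-resolved cryo-EM, and who want the derived numbers: steady-state
kinetic parameters with honest uncertainties, filament twist and interface
rotations, loop RMSF and contact-distance distributions, and the time
trend of the filament fraction.

## What it computes

**Kinetics** (`loopstate.kinetics`). The catalytic cycle is the
three-step scheme

```
E + S  <=[k1]/[k-1]=>  ES  <=[k2]/[k-2]=>  EP  --[k3]-->  E + P
```

whose steady-state parameters follow from the elementary constants:

- kcat = k2·k3 / (k2 + k−2 + k3)
- kcat/KM = k1·k2·k3 / (k2·k3 + k−1·(k−2 + k3))
- KM = kcat / (kcat/KM)

The module calibrates the absorbance signal per experiment from an NADH
titration, converts NADH-depletion traces to product concentration, fits
initial rates to v0 = kcat[S]/(KM+[S]), simulates and globally fits full
progress curves (weighted least squares on log-transformed constants,
seeded multi-start), and propagates uncertainty to kcat, KM and kcat/KM by
the delta method (Monte-Carlo resampling available). Elementary constants
with flat likelihood profiles are flagged non-identifiable — full progress
curves constrain only the steady-state combinations.

**Ensemble geometry** (`loopstate.geometry`, `loopstate.structures`).
PDB/mmCIF reading and writing (via gemmi), least-squares superposition
with proper-rotation guarantee, rotation angle/axis extraction with
symmetry-modular reduction, filament twist and rise between stacked rings
(automatic cyclic chain correspondence), interface rotation between two
conformational states, per-monomer domain hinge rotation, ensemble RMSF
after iterative mean-structure alignment, per-chain minimum inter-residue
distance distributions with Scott-bandwidth KDE and 150-bin histograms,
and Cα distance-difference matrices with residue-range exclusions.

**Time-resolved fractions** (`loopstate.time_resolved`). Filament and
decamer fractions per quench-time dataset (unassigned particles excluded),
binomial standard errors, and trend inference sized for tiny n:
permutation p-value on |Pearson r| and an expanded-percentile bootstrap CI
for the slope.

**Synthetic data** (`loopstate.synthetic`). Seeded generators emitting
each input type with a machine-readable truth record: noisy progress
curves from the kinetic scheme, idealised Cα ring assemblies with known
twist/rise, two-state loop ensembles with known occupancy and
displacement, and binomial particle-count tables with a linear true
fraction. Recovery of the generating parameters is the backbone of the
test suite.

## Worked example

`examples/progress_curve_fit.py` simulates the assay at three starting
substrate concentrations (750/375/188 µM, 8 replicates, 1% noise),
averages replicates, globally refits the scheme and derives steady-state
parameters:

```
generating truth : kcat = 3.125 /s, KM = 59.4 uM
recovered        : kcat = 3.138 +- 0.010 /s, KM = 61.0 +- 0.9 uM
specificity      : kcat/KM = 5.14e+04 +- 6.6e+02 /M/s
non-identifiable elementary constants: ['k1', 'k_minus1', 'k2', 'k_minus2', 'k3']
```

The derived kcat and KM land within a few percent of the generating
values while all five elementary constants are flagged — exactly the
identifiability structure expected of progress-curve data. The other
examples exercise filament twist/interface rotation
(`filament_geometry.py`), loop RMSF and distance distributions
(`loop_ensemble_analysis.py`), and the particle-fraction time trend
(`particle_fraction_trend.py`); each prints the measured value next to
the constructed truth.

A thin CLI mirrors the library (`loopstate kinetics|geom|trcount|simulate
...`); see `loopstate --help`.

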
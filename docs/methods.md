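# Methods

## Kinetic model

The catalytic cycle is modelled as a three-step single-substrate scheme —
reversible binding, reversible chemistry, irreversible product release:

    E + S  <=[k1]/[k-1]=>  ES  <=[k2]/[k-2]=>  EP  --[k3]-->  E + P

with the mass-action ODE system (E recovered by conservation,
E = E0 − ES − EP):

    d[S]/dt  = −k1·E·S + k−1·ES
    d[ES]/dt =  k1·E·S + k−2·EP − (k−1 + k2)·ES
    d[EP]/dt =  k2·ES − (k−2 + k3)·EP
    d[P]/dt  =  k3·EP

The model assumes the varied substrate is limiting while all others are
saturating (so the multi-reactant mechanism collapses to pseudo-one-
substrate form), and that the coupled reporter system (pyruvate kinase /
lactate dehydrogenase reading ADP production as NADH oxidation at 340 nm)
is an instantaneous 1:1 reporter. Coupling-enzyme kinetics are not
modelled; analyses should crop curves before the coupling reagents
approach exhaustion (a 10%-consumption crop is the recommended default in
practice and is configurable by the caller through the time grid).

Steady-state parameters follow from the elementary constants:

    kcat    = k2·k3 / (k2 + k−2 + k3)
    kcat/KM = k1·k2·k3 / (k2·k3 + k−1·(k−2 + k3))
    KM      = kcat / (kcat/KM)

These closed forms are the unique steady-state algebra of the scheme;
they are validated in the test suite against a numerical oracle that
solves the species balance directly and fits the resulting velocity
curve to the hyperbolic rate law, agreeing to better than 1e-3 relative
over a six-decade random sweep of constants.

### Numerical choices

- Integration: LSODA (stiff-capable, adaptive) with analytic Jacobian,
  rtol 1e-8, atol 1e-12 M. The binding pseudo-rate k1·S can exceed the
  chemical rates by orders of magnitude, making the system stiff at high
  substrate. Enzyme and mass conservation hold to 1e-9 relative in every
  trajectory (tested).
- Progress-curve fitting: chi-square over all curves with per-point SDs
  as weights, trust-region least squares on log10-transformed constants
  (positivity for free, better conditioning), bounds log10 k1 ∈ [2, 9],
  others ∈ [−3, 5]. Multi-start (default 8 seeded starts) guards against
  local minima; later starts are skipped once a start reaches reduced
  chi-square ≤ 1.2. SDs below a floor of 0.1% of the curve's dynamic
  range are raised to the floor (with a warning) to avoid infinite
  weights on coincidentally zero-SD points.
- Covariance: computed from a central-difference Jacobian with a fixed
  1e-3 log10 step at the optimum. The optimiser's own finite-difference
  steps (~1e-8) sit below the ODE solver's noise floor and would fake
  curvature along flat directions. The normal matrix is inverted by
  eigendecomposition with a tiny relative eigenvalue floor (1e-14) so
  genuinely flat directions keep their very large variance instead of
  being truncated away. Log-space covariance is mapped to the natural
  scale by the diagonal scaling dk/dlog10 k = k·ln 10.
- Identifiability: a constant is flagged non-identifiable when the
  quadratic profile proxy — the chi-square change from moving its log10
  value by ±1 with the others re-optimised, which in the quadratic
  regime equals 1/Var(log10 k) — is below 2. Full progress curves
  constrain only kcat, KM and kcat/KM; all five elementary constants are
  expected to be flagged, and only the derived parameters are guaranteed
  deliverables. A full re-optimised profile would cost ~10 extra fits for
  the same answer in the quadratic regime.
- Uncertainty propagation: delta method with central-difference gradients
  by default; Monte-Carlo resampling of the constants from the covariance
  (seeded, default 10000 draws, invalid draws rejected) as a cross-check.
  The two agree within 25% for well-conditioned covariances; for the
  nearly singular covariances of progress-curve fits the multivariate
  normal does not respect the curved flat valley and the delta method is
  the meaningful number.
- Calibration: the signal coefficient (absorbance per molar NADH, i.e.
  extinction coefficient × pathlength) is fit per experiment from an
  NADH titration with a free intercept. The textbook extinction
  coefficient 6220 /M/cm is exposed as a constant for use only when no
  titration exists; an empirical calibration always takes precedence.
- Initial-rate fits flag "no curvature" (instead of returning boundary
  values) when KM escapes 100× beyond the sampled substrate range.

## Ensemble geometry

Superposition is the Kabsch least-squares solution via SVD with the
determinant correction, so a reflection is never returned; the rotation
angle is θ = arccos((trace(R) − 1)/2) and the axis comes from the
antisymmetric part of R (eigenvector fallback near 180°). Angles are
reported in degrees in [0, 180].

- Filament twist: ring A is superposed onto ring B under a chain
  correspondence. Deposited chain labels are arbitrary, so by default the
  cyclic assignment (of the n ring chains) minimising post-superposition
  RMSD is used; an explicit map can be supplied. The angle is reduced
  modulo 360/n into [0, 180/n] (for 5-fold rings, [0°, 36°]): under the
  ring symmetry any value outside that range is equivalent. Rise is the
  centroid displacement along the rotation axis.
- Interface rotation between two states: model B is anchored onto model A
  on one ring; the residual transform between the probe rings gives the
  rotation, with no symmetry reduction (the motions of interest are
  fractions of a degree). Domain ("crimping") rotation is the same
  construction per chain: align on the fixed domain, report the mobile
  domain's rotation. Both are invariant to global rigid transforms of
  either model (tested).
- RMSF: conformations are aligned to an evolving mean structure (align to
  the first conformation, recompute the mean, re-align; 2 iterations) on
  a caller-chosen alignment selection, and RMSF is the root-mean-square
  displacement of each reported atom about its mean position. The
  alignment selection should exclude the mobile loop so its motion is not
  absorbed into the fit; the loop-excluded default used throughout the
  examples is this package's choice of stable anchors, documented rather
  than asserted as the original analysis's selection. For a two-state
  displacement d with occupancy p and isotropic jitter σ the expected
  RMSF is sqrt(3σ² + p(1−p)d²), which the implementation reproduces to
  1%.
- Minimum-distance distributions: for each conformation and each chain,
  the minimum over all atom pairs of the distance between the two
  residues (a 10-chain ensemble yields 10 samples per conformation).
  Hydrogens are excluded by default for comparability between MD-derived
  ensembles (which have them) and deposited models (which may not);
  switchable. Cross-chain pairings are supported through an explicit
  chain map and the result records which pairing was used — intra-chain
  and cross-ring conventions are both legitimate and should never be
  picked silently. KDE uses a Gaussian kernel with Scott's-rule base
  bandwidth times a caller-visible adjustment factor (default 1) on a
  512-point grid spanning the data ± 3 bandwidths; histograms use 150
  equal-width bins over [min, max] with an inclusive right edge so
  counts are always conserved.
- Distance-difference matrices: D(i,j) = |CαA_i − CαA_j| − |CαB_i −
  CαB_j| for one chain after dropping excluded residue ranges (e.g. a
  heterogeneous loop and a frayed terminus); symmetric, zero diagonal,
  isometry-invariant, with the maximum-|D| pair reported.
- Structure I/O (gemmi): author residue numbering as deposited; alternate
  locations resolved to the highest occupancy, ties broken alphabetically
  by altloc id; multi-model files with identical topology become
  ensembles, topology mismatches are reported naming the first offending
  atom. PDB fixed-width output preserves coordinates to 1e-3 Å.

## Time-resolved fractions

Filament fraction per dataset is filament/(filament + decamer); particles
that could not be assigned either class are excluded from the
denominator. The binomial standard error sqrt(f(1−f)/n) accompanies each
row. Trend inference is deliberately non-parametric because such series
have ~5 points: the p-value is a two-sided permutation test shuffling
time labels (statistic |Pearson r|, add-one estimator), and the slope CI
is a bootstrap over rows. With five datasets there are only 120 distinct
permutations, so p-values below ~1/120 are unattainable — a floor, not a
bug. The bootstrap uses Hesterberg's expanded percentile interval: the
outer quantiles are set to Φ(−sqrt(n/(n−1))·t_{n−1,0.025}) rather than
2.5%, correcting the systematic narrowness of plain percentile intervals
at small n while keeping the nominal level at 95% (measured coverage on
the binomial generator: 97% vs 86% for the plain percentile interval).
Degenerate resamples with all-equal times carry no slope information and
are redrawn. Rows are unweighted by default, matching one-point-per-
dataset trend plots; inverse-variance weighting is available by flag.
Fractions and the trend are invariant to the unassigned counts (tested).

The package checks the permutation p-value's null uniformity with a
Kolmogorov–Smirnov test at the 5% level over 200 seeded null
simulations. A raw KS-distance threshold tighter than ~0.1 would be
meaningless at that sample size: 200 draws from an exactly uniform
distribution have a median KS distance of ~0.059, so the criterion is the
standard hypothesis test, not a fixed distance.

## Synthetic generators: what they emulate, and what they do not

Generators are deterministic given (config, seed) and emit truth records
consumed by the recovery tests.

- Progress curves: the assay's conditions — S0 ∈ {750, 375, 188} µM with
  8 replicates, 5-minute courses at 61 points, E0 = 2.4 µM active sites
  (0.1 mg/mL at ~42 kDa per monomer). Default constants k1 = 1e6 /M/s,
  k−1 = 150 /s, k2 = 10 /s, k−2 = 1 /s, k3 = 5 /s give kcat = 3.125 /s
  and KM ≈ 59 µM, in the range measured for the decameric enzyme.
  Noise is additive i.i.d. Gaussian with SD 1% of the full-scale signal
  S0, a plate-reader-like assumption, not a measured noise model. Real
  data additionally carry baseline drift, pipetting offsets between
  replicates and coupling-lag at early times, none of which are
  emulated — passing recovery tests demonstrates the estimator works
  under its stated noise model, not robustness to instrument artefacts.
- Ring assemblies: idealised Cα-only helical arcs on 5-fold rings
  (radius 45 Å), a second ring rotated by the configured twist and
  translated by the rise (defaults 26° / 40 Å). These are not protein
  folds; the geometry statistics consume only topology and coordinates,
  so a real fold would add no test power. The stacked rings share chain
  orientation rather than meeting head-to-head; twist and rotation
  measurements are insensitive to this simplification.
- Loop ensembles: each chain's loop (residues 9–14 of 24) is open or
  closed per conformation; open loops displace radially by 21 Å at
  occupancy 0.5 by default (expected tip RMSF ≈ 10.5 Å, emulating the
  >10 Å fluctuations of a gating loop's open ensemble), with 0.15 Å
  isotropic jitter and 20 conformations, matching the 20-replica
  ensembles this pipeline consumes. With `exact_occupancy` (default) the
  number of open instances equals round(p·n) exactly via a seeded
  shuffle, so closed-form RMSF checks are exact; i.i.d. Bernoulli draws
  are available for mixture-statistics tests. Real loop ensembles are
  continua, not two-state mixtures; the generator tests the measurement
  machinery, not the biology.
- Particle counts: five quench times spanning 57–517 s; true filament
  fraction intercept + slope·t with defaults 0.05 + 8.7e-4·t, rising
  from ~0.10 to ~0.50 across the series (the plateau observed at the
  standard enzyme concentration); filament counts are binomial draws
  from the true fraction at 10000 assigned particles per dataset;
  unassigned picks are drawn independently and never enter fractions.
  Real 2D-classification miscounts are not independent binomial draws;
  the generator provides calibrated noise for inference checks only.

## Problem sizes

The default validation sizes — 100-point algebra sweeps, 20 progress-
curve recovery repeats, 200 null simulations at 2000 permutations, 100
coverage repeats at 4000 bootstrap draws — were chosen to make Monte-
Carlo error comfortably smaller than the tolerances being checked while
keeping a full validation run around a minute on one CPU.

## Known limitations

- Elementary rate constants from progress curves are reported but almost
  never individually meaningful; use the derived parameters.
- The permutation p-value floor (~1/(n! permutations)) limits attainable
  significance for very short time series.
- No density-map analysis (local resolution, Q-scores, FSC) — map-space
  claims about loop density are upstream of this package.
- The automatic ring chain correspondence searches cyclic assignments
  only; label permutations that are not cyclic shifts (in selection
  order) need an explicit chain map.
- mmCIF writing is not implemented (reading is); synthetic fixtures are
  written as PDB.
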
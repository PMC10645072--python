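# Methods

## Centre of spectral mass

The CSM of an emission spectrum is the intensity-weighted mean emission
wavelength, CSM = Σ fᵢλᵢ / Σ fᵢ, evaluated as a plain discrete sum over
the native wavelength grid inside a closed window (default 325–500 nm).
It is computed in wavelength space, not wavenumber, because the model it
feeds is formulated on λ directly. On the uniform 1 nm grid the choice
of quadrature (rectangular vs trapezoid) changes the result beyond the
fourth significant figure only, so the plain sum is used. No
scatter masking is applied at the defaults: the emission window starts
15 nm above the longest excitation wavelength, and second-order scatter
(2·λ_Ex ≥ 584 nm) falls outside the window; an explicit `scatter_mask`
is available when non-default windows make this unsafe. Buffer-blank
subtraction is available at ingest but off by default, since the CSM is
scale-invariant and blanks mainly matter for heavily diluted samples.

CSM is shift-equivariant and intensity-scale invariant, and always lies
inside the support of the positive intensities; these invariants are
enforced by property tests.

## The two-state REES model

CSM as a function of excitation wavelength is modelled as a
Boltzmann-weighted two-state average,

    CSM(λ_Ex) = [CSM_FC + CSM_R e^x] / (1 + e^x),   x = m (λ_Ex − λ50) / RT,

with R = 8.3145 J mol⁻¹ K⁻¹ and T = 283.15 K (the measurement
temperature, 10 °C). CSM_FC is the blue asymptote (emission of the
fully excited Franck–Condon ensemble), CSM_R the red asymptote (fully
solvent-relaxed emission, physically reached only beyond the measurable
excitation range), λ50 the inflection and m the slope term, with units
J mol⁻¹ nm⁻¹ so that x is dimensionless. The implementation evaluates
the algebraically identical logistic form CSM_FC + (CSM_R − CSM_FC)·σ(x)
for overflow safety.

### Units of the slope term

Published tables in this field sometimes print ΔG_m ≈ 7 with a milli-
prefix on the unit. Taken literally (7 mJ mol⁻¹ nm⁻¹, or even 7 J mol⁻¹
nm⁻¹), x would change by less than 10⁻⁴ across an 18 nm excitation
window — no visible sigmoid, and CSM(292 nm) would sit halfway between
the asymptotes rather than near CSM_FC as observed. Slopes of order
several hundred J mol⁻¹ nm⁻¹ are required to reproduce measured profile
shapes. The fit therefore works entirely in J mol⁻¹ nm⁻¹, and a
configurable `m_display_scale` (default 1.0) is applied only in report
tables for users who need to match a particular table convention. The
printed ΔG_m numerals in the packaged reference table are used as-is
for summaries and correlations and are never re-entered into the
exponent.

### Fitting

Bounded least squares (scipy trust-region reflective, analytic
Jacobian, ftol/xtol/gtol 10⁻¹⁰) with CSM_R hard-constrained to
[387, 440] nm, the practical range for solvent-relaxed tryptophan
emission. The initial guess is deterministic: CSM_FC from the CSM at
the shortest excitation, CSM_R at the midpoint of its bounds, λ50 10 nm
beyond the longest excitation, m = RT/5 (a 5 nm characteristic width).
Because λ50 lies outside the measured range the objective surface is
shallow, so the fit is restarted from five fixed perturbations of the
initial guess (m scaled by ¼–4, λ50 shifted up to ±10 nm) and the best
objective kept; the whole procedure is deterministic.

Two levels are provided:

* `fit_single` — all four parameters free for one profile;
* `fit_group_global` — the recommended mode: one shared CSM_R per
  group, free (CSM_FC, m, λ50) per replicate. Sharing encodes the
  physical assumption that proteins with identical Trp content share a
  fully-solvated emission spectrum. By default every replicate of every
  sample is a fitting unit; `share_csm_r="sample_means"` instead fits
  replicate-averaged profiles, for workflows that treat the triplicate
  mean as the observation.

Per-sample parameter spread is reported as the mean ± sd (n−1) over
replicates; the shared CSM_R uncertainty is the covariance-based
standard error s²(JᵀJ)⁻¹ of the global fit. All CSM points are weighted
equally — the replicate noise level does not vary systematically across
the 19-point excitation grid.

### Identifiability

CSM_R is an extrapolation roughly 80 nm beyond the data and is weakly
identified: at a realistic 0.1 nm CSM noise its point estimate can miss
the generating value by several to ~20 nm even for 6–18 sample groups,
which is exactly why its reported standard errors are nm-to-tens-of-nm
while CSM_FC is recovered to a few hundredths of a nm. Tests therefore
check CSM_R against its own reported uncertainty (and exactly, on
noise-free data), never against a fixed small tolerance; they also
verify that the shared-parameter fit shrinks the CSM_R spread relative
to unshared per-replicate fits on the same cohorts. A constant (flat)
profile leaves m, λ50 and CSM_R unidentified; the fit flags this in its
diagnostics instead of failing silently.

## Synthetic data

The simulator is the inverse of the analysis: for each excitation
wavelength it takes the model CSM as a target, solves (by monotone
bisection, tolerance 10⁻⁶ nm) for the centre of a Gaussian emission
band whose *window-truncated, grid-sampled* CSM equals that target, and
emits the band. This makes forward/backward consistency exact by
construction rather than approximate: `build_profile(simulate_scan(p))`
reproduces `model_csm(·, p)` to the solver tolerance regardless of edge
truncation. The band is Gaussian with sd 25 nm (≈59 nm FWHM, the width
of tryptophan emission in proteins); the band family only needs to be
unimodal and positive, since the CSM is matched exactly whatever the
shape.

Noise can be injected two ways: additive Gaussian intensity noise
(fraction of band peak, clipped at zero — the realistic mode) or direct
Gaussian jitter of each target CSM (the fast mode used for fitter
benchmarking, where the noise level in nm is then exactly known).

`study_cohort_spec` encodes the study design used throughout the tests:
two groups of 18 and 3 samples (22 vs 24 Trp), triplicate replicates,
shared CSM_R of 418.9 and 423.3 nm, per-sample CSM_FC drawn from
N(352.9, 0.3) and N(353.9, 0.3) nm, λ50 from N(320, 2) nm, and slopes
from N(470, 30) / N(520, 30) J mol⁻¹ nm⁻¹ — chosen once so the rising
tail over 292–310 nm has the few-nm magnitude of measured antibody
profiles, with the more rigid 24-Trp group steeper. Replicates share
their sample's parameters; all replicate scatter comes from the noise
model. What the simulator does *not* emulate: instrument response,
inner-filter effects, Raman/Rayleigh scatter, photobleaching, and any
non-sigmoid fine structure of real CSM profiles. Passing recovery tests
therefore demonstrate correctness of the estimation machinery under the
model, not robustness to spectral artefacts.

Default problem sizes in the tests and acceptance script (full 21-sample
cohort in triplicate, 12-point noise-free recovery sweeps, 27-curve
consistency grids) were chosen as the smallest sets that exercise the
full study design while keeping every run in the seconds-to-a-minute
range.

## Solvent-accessible surface area

Shrake–Rupley dot counting: each atom's van der Waals sphere is
expanded by the probe radius (1.4 Å) and covered with a deterministic,
inversion-symmetric Fibonacci point set (default 960 points); the
accessible fraction times the expanded-sphere area is the atom's SASA.
Neighbour search uses a KD-tree at the maximal interaction distance.
Two deterministic refinements reduce discretization error: the point
set is closed under p → −p (cancelling odd-order error), and each
atom's point set is rotated by a fixed rotation indexed by the atom's
position within its residue and the residue's rank within its chain —
decorrelating errors between atoms so they average out in totals, while
keeping equivalent residues of identical chains bit-identical (so
symmetry and additivity hold exactly for duplicated molecules). With
this scheme the defaults deliver ≤0.3% deviation from closed-form one-
and two-sphere areas, rotation-invariance within 0.5% on multi-residue
fixtures, and 960-vs-3840-point agreement within 0.5%.

Radii are a Bondi-style element table (C 1.70, N 1.55, O 1.52, S 1.80 Å,
configurable); hydrogens, waters and heteroatoms are excluded by
default, matching heavy-atom homology models; for alternate locations
the highest-occupancy conformer is kept. Per-tryptophan SASA sums
backbone plus side-chain atoms of the residue. Relative exposure
divides by a reference maximum Trp SASA, default 264.0 Å² (theoretical
Gly-Trp-Gly maximum, Tien et al. 2013); values above 100% are possible
for unusually exposed models (or free amino acids) and are flagged, not
clipped. Published per-residue exposure percentages computed with other
tools depend on that tool's internal normalization and are not expected
to match numerically; group-level *differences* and the average SASA
per Trp are the quantities this module is meant to reproduce.

## Statistics

Group comparisons use classical (non-Welch) one-way ANOVA and Tukey HSD
pairwise comparisons at replicate granularity; correlations between
REES parameters and average SASA per Trp use per-sample triplicate
averages (n = 21 for the packaged table). Both granularities are
explicit function arguments. The packaged-table correlations come out
at r = 0.7383 and r = 0.7072 against published values of 0.7345 and
0.7030; the small differences are the expected effect of computing from
the table's rounded one-decimal entries.

## Known limitations

* The raw fluorescence scans behind the packaged per-allele table were
  never published as data tables, so the published per-allele fits are
  validated by simulation at the same design and parameter scales, not
  recomputed from raw spectra.
* CSM_R point estimates from 292–310 nm data are intrinsically
  uncertain (see Identifiability); compare groups via CSM_FC and ΔG_m.
* The SASA module reads PDB only (no mmCIF) and assumes heavy-atom
  models; it does not model conformational averaging, so values from a
  single static model can differ from solution-ensemble SASA.
* ANOVA assumes homoscedastic groups; with the very unbalanced 18-vs-3
  design a strong variance difference between groups would call for a
  Welch-type analysis, which is deliberately not the default here.
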
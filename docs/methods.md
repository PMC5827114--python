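# Methods

This note documents the models, estimators, parameter choices and known
limitations of the `didomain` pipeline.

## Structural stage

**SASA.** Shrake–Rupley quadrature with a deterministic golden-section
spiral point set (default 960 points/atom), probe radius 1.4 Å, and
NACCESS-style heavy-atom radii (C 1.70, N 1.55, O 1.52, S/P 1.80, Se 1.90 Å).
Hydrogens are excluded by default: the deposited reference structure is an
X-ray model without hydrogens, and including them with a separate radius
would make toy-structure and real-structure numbers incomparable. The
960-point quadrature agrees with a 10 000-point reference to ≲ 0.2 % on the
test structures, and per-atom areas match an independent Shrake–Rupley
implementation (biotite) in the test suite.

**Buried surface area.** Difference method, reported as the *total* buried
area over both faces, `SASA(A) + SASA(B) − SASA(A∪B)`. The per-side (PISA-
style) convention is exactly half; users comparing against per-side numbers
should divide by two. For the deposited two-domain structure the chain with
the most resolved residues is analysed (the two copies in the asymmetric
unit are essentially identical). The αββ-extension/core-RRM1 boundary is
read from the structure's annotated secondary structure when present — the
core fold starts at the third annotated β-strand of the extended domain
(sequence order eβ1, eβ2, β1) — with residue 160/161 as the fallback split
of the 121–243 span. The exact boundary moves the extension/core burial by
well under the 15 % comparison band used in the acceptance checks.

**Contacts.** Heavy-atom minimum-distance criterion, default 5.0 Å,
computed with a k-d tree and verified against a brute-force all-pairs scan.

**N–H vectors.** Taken from explicit amide protons when present; otherwise
an ideal proton is built on the bisector of the N→CA and N→C(i−1)
directions at 1.02 Å. Prolines and chain-start residues are skipped and
reported, never silently dropped.

## Relaxation stage

**Forward model.** Standard ¹⁵N dipole–dipole + CSA rates with a
single-Lorentzian spectral density J(ω) = (2/5)·τc/(1+ω²τc²), rNH = 1.02 Å,
Δσ(¹⁵N) = −160 ppm (both configurable), rigid-body order parameter 1.
Spectral densities are evaluated at frequency magnitudes; the sign of γN
enters only through the γH/γN ratio in the NOE.

**τc estimator.** The closed-form T1/T2-ratio estimator
τc = sqrt(6·T1/T2 − 7)/(4π·νN), valid for 6·T1/T2 − 7 > 0; smaller ratios
are flagged (NaN + warning) as outside the slow-tumbling regime. The
estimator neglects the high-frequency spectral-density terms, so the
simulate-then-invert roundtrip error is field- and τc-dependent: at
600 MHz it is below 1 % around 10–12 ns, below 2 % above ≈ 3.5 ns, and
grows to ≈ 3 % at 2 ns (≈ 5 % at 500 MHz). The test suite documents this
profile rather than hiding it.

**Per-domain aggregation.** Residues are first masked by hetNOE ≥ 0.65
(a common rigidity heuristic at 600 MHz); the domain τc is the 10 %-trimmed
mean of per-residue values (trimming absorbs exchange-broadened outliers
with anomalously short T2), and the quoted uncertainty is the standard
deviation of the included residues — matching the "τc ± sd" reporting style
per domain. Domain comparison uses Welch's t-test on the per-residue
values; α = 0.05.

## RDC stage

The alignment tensor is stored directly in Hz as a symmetric traceless 3×3
matrix A with D = vᵀAv. Conventions: eigenvalues ordered |Azz| ≥ |Ayy| ≥
|Axx|, Da = Azz/2 (sign carried by Da), R = (2/3)(Axx−Ayy)/Azz ∈ [0, 2/3].
Fitting is linear least squares over the five independent elements
(error-weighted when every record carries an error), solved by SVD; a
design-matrix condition number above 10⁴ raises a degenerate-geometry
error. Q = rms(obs−calc)/rms(obs). The two-tensor model fits each domain
independently and reports the Pearson correlation of the pooled
predictions; the residual-based Q is strictly non-increasing under the
richer model, and the pooled correlation behaves the same way on all tested
data. Which residues enter the fit is the caller's choice; a flexibility
mask from the relaxation stage can be applied but is off by default.

Different tensor-fitting programs differ in Da/R sign and scaling
conventions; ours is self-consistent (construct → back-calculate → refit
round-trips exactly) but may differ from other software by a fixed
convention factor.

## CSP stage

Combined CSP = sqrt(ΔδH² + (α·ΔδN)²) with the field-standard α = 0.154.
"Active" residues are those with endpoint CSP strictly greater than
0.02 ppm (the docking-input rule), evaluated at the highest titration
ratio. Surface consistency against crystal contacts is a Jaccard index —
a printed metric, not a verdict by itself. The optional shared-Kd fit uses
the exact 1:1 mass-balance (ligand-depletion quadratic) bound fraction;
for fixed Kd the per-residue Δδmax are profiled out analytically, leaving a
1-D bounded optimisation over log Kd; CIs are a bootstrap over residues
(default 200 draws — the resampling unit is the residue because residues
share one Kd but have independent Δδmax).

## Binding stage

Default model is the simple hyperbola R = Rmax·[P]/(Kd+[P]) — with RNA
immobilised on the sensor and protein in large excess, analyte depletion is
negligible, which is the standard BLI assumption; a depletion-aware
quadratic model is available via `model="depletion"`. Concentrations are
molar internally (µM/nM at I/O). Fits run on concentrations rescaled by the
top concentration so nM- and µM-range series are equally well conditioned.
CIs are a seeded parametric bootstrap (default 1000 draws) with the noise
scale taken as the dof-corrected residual standard deviation (n−2). A Kd
outside [min conc/100, max conc×100] is flagged poorly determined. Fold
changes are Kd ratios with CIs from paired bootstrap draws.

## SIA stage

Score of base b at a position = mean reporter CSP for the pool fixing b,
divided by the sum over the four bases (each position sums to 1 — the
relative column heights of a specificity logo). This linear CSP-share
statistic is the simplest transform consistent with how such data are
presented; reporter-to-reporter sensitivity differences cancel because each
reporter's factor is constant across a position's four pools. Aggregation
over reporters is the mean (median by flag). Consensus labels use
presentation-layer cutoffs: top score ≥ 0.4 → preferred ("strong"), score
< 0.15 → discriminated against ("not-X"); ties break alphabetically and
are flagged.

## Coupling verdict

Explicit decision rule over the three channels: rigidly-coupled iff the
single-tensor correlation r ≥ 0.9 *and* Δτc is not significant (α = 0.05);
otherwise detached iff the CSP/contact Jaccard < 0.2; otherwise
dynamically-coupled. The thresholds are deliberate presentation-layer
rules (the underlying argument is qualitative) and are printed in every
report. The verdict deliberately makes no claim about the *population* of
the detached state — no such fraction is identifiable from these data.

## Synthetic data

The generator emulates the study conditions with known ground truth:

* **Structure**: two pseudo-domains (three ideal 12-residue helices each,
  built with natural-extension-reference-frame geometry at φ/ψ = −57/−47°,
  axes mutually orthogonal for good orientational sampling of N–H vectors),
  an 8-residue extended linker containing one proline, and a defined
  helix–helix interface (facing-helix axis separation 7.2 Å → 13 interface
  residues with heavy-atom contacts at 3.2–5 Å; non-interface inter-domain
  pairs ≥ 8 Å). The structure is deterministic; the seed drives only noise.
* **Scenarios**: `rigid` (shared tensor, shared τc 11.8 ns), `dynamic`
  (tensors Da −17.7 Hz/R 0.22 and −18.0 Hz/0.31 with principal frames 90°
  apart; τc 10.0 vs 11.8 ns), `detached` (as dynamic but no interface
  CSPs). All at 600 MHz.
* **Noise defaults**: RDC σ = 1 Hz; 3 % fractional noise on T1/T2 and
  σ = 0.05 on hetNOE (domain NOE centred at 0.8, linker at 0.3); interface
  CSP magnitudes ~N(0.08, 0.02) ppm over background |N(0, 0.005)| ppm with
  2 % shift noise per titration point; BLI noise 3 % of Rmax; SIA reporter
  noise 10 % with reporter sensitivities U(0.5, 1.5).
* **Binding designs**: Kd 2.0 nM on a 2× series 50→0.78 nM, Kd 29 µM on
  400→6.25 µM, and a wild-type/mutant pair at a true 6-fold ratio;
  titrations at 50 µM protein, ratios 0–6, Kd 29 µM.

What the generator does *not* emulate — and what passing tests therefore do
not show about real data: peak overlap and assignment errors, anisotropic
diffusion (τc differences between domains of one rigid particle can arise
from shape anisotropy alone; real analyses should check this), internal
motion beyond a binary rigid/flexible split, exchange contributions to T2,
non-1:1 binding, and baseline drifts in BLI. The toy structure has no side
chains, so absolute SASA/BSA values are much smaller than for a real
protein; real-structure conclusions rest on the deposited-coordinates
analysis, not the toy.

## Problem sizes and reproducibility

Recovery statistics in the tests and the acceptance script use 100 seeded
replicates per claim (30 for the titration-Kd and CSP-overlap summaries,
whose per-replicate cost is highest), 300 bootstrap draws for fold-change
CIs, and 960-point SASA quadrature. All randomness flows through
`numpy.random.default_rng` seeded from the scenario seed (one independent
stream per measurement channel); there is no hidden global state. The
numbered scripts under `analysis/` are thin drivers over the library; the
same functions are exercised by the test suite and `scripts/acceptance.py`,
which serve as the package's command-line entry points.
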
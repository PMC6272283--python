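# Methods

This note documents the models, conventions and design choices behind
`cptqsar`, in the order the pipeline runs them.

## Structures and alignment

Each of the 28 derivatives is built from a SMILES string reconstructed from
its systematic name; every structure is validated against the molecular
formula printed in the compound's elemental-analysis line (a unit test
asserts all 29 formulas, including the parent alkaloid).  One 3D conformer
per compound is generated by ETKDG distance-geometry embedding with a fixed
seed (default 1234, configurable) and minimized with MMFF94 (UFF fallback)
to a force tolerance of 0.05 kcal·mol⁻¹·Å⁻¹ with a 2000-step cap.  Partial
charges are plain Gasteiger PEOE charges.  Two substitutions relative to
the original study are deliberate: the Tripos force field and the
Gasteiger–Hückel charge scheme are proprietary to SYBYL, so MMFF94 and pure
PEOE stand in for them, and the original multi-conformer search is replaced
by single-conformer embedding — defensible because the pentacyclic scaffold
is rigid and the side chains are carried into a common frame by the
scaffold fit, but a real fidelity gap for the field values (see
*Limitations*).

The common scaffold is the full camptothecin heavy-atom skeleton plus the
C-7 exocyclic methylidene carbon and the first hydrazone nitrogen — 28
atoms, shipped as a SMARTS query (`data/scaffold.smarts`) that matches each
derivative exactly once.  Alignment is a proper rigid-body least-squares
(Kabsch) superposition of the matched atoms onto compound **4d**, the most
active derivative; symmetric substructure matches, should a query admit
them, are resolved by the lowest canonical-rank tuple, making the
correspondence deterministic and platform-independent.  Superposition never
alters internal geometry (asserted to 10⁻⁶ Å on all pairwise distances).

## Molecular fields

A rectangular grid in the template frame encloses the aligned ensemble with
a 4 Å margin at 2 Å spacing (the study's grid step; the margin is the
conventional default).  The probe is an sp³ carbon, vdW radius 1.7 Å, well
depth 0.107 kcal/mol, charge +1 e — all configurable.  Per molecule and
grid point:

* steric: `Σᵢ εᵢ[(Rᵢ/rᵢ)¹² − 2(Rᵢ/rᵢ)⁶]`, minimum at `Rᵢ = r_probe + rᵢ`
  of depth `εᵢ = √(ε_probe·εᵢ_atom)`; per-element radii/depths ship as a
  small table and hydrogens are included (they carry charge and bulk);
* electrostatic: `Σᵢ 332.0·qᵢ·q_probe/(D(rᵢ)·rᵢ)` with the
  distance-dependent dielectric `D(r) = r`, i.e. a 1/r² law, matching the
  dielectric used during minimization (the study does not state the
  field-stage dielectric).

Both fields are truncated at ±30 kcal/mol (the study's cutoff).  A point
whose steric energy reaches the positive cutoff is sterically excluded; the
electrostatic value there is replaced by the column mean over non-excluded
compounds (the SYBYL-compatible dialect; plain clamping is a flag).  Note
the steric energy is not monotone in distance — it falls to −ε at the
contact minimum and rises back to zero — so the tested radial property is
that its magnitude decays monotonically beyond the minimum.

## PLS model

Columns with standard deviation below 2.0 kcal/mol (SYBYL's minimum-sigma
default) are dropped; remaining columns are centered and each field block
is divided by its pooled standard deviation (square root of the mean column
variance), so both blocks enter with equal total weight ("CoMFA standard"
scaling; autoscaling and centering-only are flags).  PLS1 is fitted by
NIPALS; it is deterministic, reproduces coefficients bitwise on refit, and
collapses to ordinary least squares on full-rank problems (tested against
the normal equations at 10⁻⁶ and against scikit-learn's NIPALS at 10⁻⁸ —
scikit-learn is used only as a cross-check, never in the pipeline).

Leave-one-out cross-validation repeats the *entire* preprocessing (filter +
scaling) inside each fold.  `q²(c) = 1 − PRESS(c)/Σ(yᵢ − ȳ₋ᵢ)²` uses the
fold-honest denominator (per-fold training mean); the common fixed-mean
variant is a flag.  The component count is the argmax of q², ties going to
fewer components.  Model statistics follow the conventions that reproduce
the study's printed numbers from its own table: `SEE = √(SSres/(n−c−1))`,
and external `r²pred` is the squared Pearson correlation between predicted
and observed test activities (verified: 0.993 from the five printed test
pairs; the PRESS/SD form is reported alongside, and is much harsher —
−1.2 on this reconstruction — because it also penalizes calibration
offset).  Field contributions are `Σ|βⱼ|·sdⱼ` per block, normalized; they
sum to one by construction.

Contours use the stdev*coeff field: per retained column, the training
standard deviation times the PLS coefficient (both in the scaled design
space), mapped back to its grid point with NaN sentinels for dropped
columns.  The "80%/20% contribution" display levels are read as the 80th
and 20th percentiles of the signed score distribution over retained points
— SYBYL's exact semantics are unpublished, so this standard reading is an
approximation.  Points strictly above the high threshold are favored,
strictly below the low one disfavored; strict inequalities keep a constant
volume from producing spurious contours.

## Bioassay statistics

Observed per-dose mortalities are Abbott-corrected with the observed
control mortality and floored at zero.  The probit model
`Φ⁻¹(p) = α + β·log₁₀(dose)` is fitted as a quasi-binomial GLM (IRLS via
statsmodels) with exposed counts as weights; the classic "+5" probit offset
is omitted (equivalent model, different intercept convention) and the dose
metameter is log₁₀.  `LC50 = 10^(−α/β)`; its 95% CI comes from the delta
method on log₁₀ LC50 and is suppressed when the fitted slope is
non-positive.  The correction is applied to proportions before the
likelihood because raw control-adjusted counts are never published;
estimating natural response inside the likelihood would be the main
alternative.  Consequences of this choice are visible in the validation:
the estimator is consistent (α, β recovered to 1% at n = 10⁵ per dose), but
with realistic control sizes the unmodelled control-estimation noise costs
a little coverage (≈93% achieved by the nominal 95% interval under the
default design).

## Synthetic data

The QSAR generator emulates the structure of a real field matrix over an
aligned congeneric series, where molecules differ by a few substituent
features: `X = Z·P + E`, with `Z` (molecules × 3 factors) standard-normal
loadings shared by both blocks, `P` smooth spatial patterns (random
atom-like deposits of amplitude sd 20 kcal/mol, Gaussian-blurred with sd of
one grid step), and `E` sharp short-range noise (sd 1 kcal/mol) of the kind
steric potentials show at molecular surfaces.  Activity is a planted linear
function of a few columns plus Gaussian noise; by default the signal sits
at each factor's strongest column — the pocket where that substituent
feature actually moves the field.  The low-rank smooth part supplies
realistic collinearity and minimum-sigma behavior and makes the factor
count a well-defined "true dimensionality" for cross-validation; the sharp
part keeps the design full-rank so the planted coefficients are
statistically identifiable (with a purely smooth design even exact least
squares cannot recover them).  What the generator does *not* emulate:
cutoff saturation plateaus, excluded-volume masks, non-Gaussian activity
noise, and any relationship between the two blocks beyond shared loadings —
so passing recovery tests validates the estimators, not the chemistry.

Validation sizes were chosen so each check is statistically meaningful on
one CPU in seconds: coefficient recovery and q² at the true dimensionality
use 200 molecules on a 4×4×4 grid (128 columns), where worst-case recovery
error over 30 generator seeds is 5.9% and worst q²(3) is 0.974.  The
pure-noise control also uses 200 molecules: at congeneric-series sizes
(n ≈ 25–30) the maximum-over-components LOO q² of pure noise has a heavy
right tail — chance correlations up to +0.5 were observed and confirmed
with an independent scikit-learn LOO oracle.  That tail is a real
small-sample phenomenon (and the reason the field treats small-n q² values
below ~0.5 as unconvincing), so the null calibration is run at a size where
the null distribution is concentrated.

The bioassay generator draws dead counts binomially from
`p = c + (1−c)·Φ(β(log₁₀d − log₁₀LC50))` with the design defaults of the
study: 5 doses on a factor-2 ladder centered on the true LC50 (0.05 mM),
30 organisms per dose, a triplicate control group (90 organisms) and 5%
natural mortality.

## Numerical choices

* All randomness flows through `numpy.random.default_rng` with explicit
  seeds; the conformer embedding seed is part of the run configuration, so
  identical configurations give byte-identical output files.
* Design matrices are forced C-contiguous before BLAS products so fitted
  values, predictions and serialized-model reloads agree bitwise.
* NIPALS stops early if the residual weight norm falls below 10⁻¹²
  (rank exhaustion) and flags the model; requesting more components than
  `min(n−1, p)` is an error.
* Superposition RMSD is recomputed from residuals rather than taken from
  the SVD (the latter loses precision to cancellation near zero).
* Degenerate inputs: identical rows in LOO give a flagged degenerate
  result; zero probe–atom distance clamps to the cutoff instead of raising;
  an all-dropped column filter and a non-bracketing dose ladder raise
  immediately.

## Limitations

* The cross-validated q², optimal component count and field contributions
  of the full pipeline are **not** expected to match the published 0.580 /
  6 / 0.709:0.291.  Those depend on SYBYL's conformers, charges and field
  implementation; this reconstruction's single-conformer geometries yield a
  lower (negative) q² with 2 components while reproducing every
  desk-checkable printed statistic exactly.  The side-chain conformation,
  which single-seed embedding fixes arbitrarily, is the dominant unmodelled
  degree of freedom.
* Two printed activity values (4j, 5e) are internally inconsistent between
  the source tables, and one printed residual (5g) contradicts its own
  row.  The fixtures preserve the tables as printed with data-quality
  flags; derived statistics use predicted-minus-actual.
* The published global LC50 range (upper end 0.35496 mM) conflicts with two
  table entries above 0.4 mM; summaries report what the table implies.
* No conformational ensembles, tautomers, protonation states, CoMSIA-style
  fields, region focusing or bootstrapped coefficient errors.
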
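# Methods

## The model

`hgfdyn` implements a mass-action reaction network of HGF-induced signal
transduction in primary hepatocytes with 23 species and 26 reactions.  The
ligand HGF activates the MET receptor tyrosine kinase; the signal propagates
through two branches — the MAPK cascade (MEK → ERK) and the PI3K/AKT axis —
coupled to mTOR signaling.  AKT is phosphorylated on Thr308 downstream of
PI3K and on Ser473 by active mTORC2; active mTORC1 drives S6K → S6; two
negative feedbacks emanate from phosphorylated S6K: inhibition of mTORC2
complex formation and inactivation of IRS1, which gates PI3K activation.

The receptor pool turns over: MET is synthesized and degraded, and the
phosphorylated receptor is degraded at its own (faster) rate.  MET is
phosphorylated both ligand-independently — the basal rate `k_basal_MET`, the
model's central quantity — and by an HGF-dependent reaction with the ligand
as a non-depleting modifier (media stimulation at a fixed dose; no
ligand-depletion data exist to constrain consumption).

Every rate law is mass action: rate constant times the product of reactant
and modifier concentrations.  Two deliberate condensations keep the network
at its printed size while preserving all mechanisms that carry the biology:

* AKT dephosphorylation is a three-reaction cycle AKT → pAKT → ppAKT → AKT
  (no separate pAKT → AKT step; Thr308-only dephosphorylation is subsumed in
  the cycle).  No explicit pMET → MET dephosphorylation exists either — the
  phosphorylated receptor is cleared by degradation, with synthesis
  replenishing the pool, which is the canonical fate of the activated
  receptor.
* TSC inactivation is carried by phosphorylated ERK.  This keeps the
  MAPK → mTOR crosstalk explicit and, as a welcome side effect, makes the
  pre-stimulation network *triangular*: every basal steady-state pool follows
  in closed form from the pools upstream (see below).  AKT's influence on
  mTORC1 still exists in the data through the shared PI3K branch.
* The S6K → IRS1 feedback is condensed into a single degradation reaction
  with pS6K entering quadratically, a stand-in for multi-site inhibitory
  serine phosphorylation of IRS1.  The cooperative form is what lets a
  chronically elevated basal MET activity (Western diet) suppress the
  HGF-induced AKT response — the model's headline mechanism — because
  plain first-order mass-action cascades cannot amplify a basal shift enough
  to overcome the increased PI3K drive.

Units are molecules/cell and minutes throughout.

## Parameters and steady-state reparameterization

The model carries three parameter classes:

* **24 kinetic rate constants** (`k_act_*`, `k_deact_*`, `k_deg_*`,
  `k_basal_MET`, …), shared between conditions except `k_basal_MET`.
* **2 ligand-input parameters**: `hgf_scale` (dose in ng/ml → intracellular
  stimulus units, default 1) and `hgf_basal` (residual autocrine ligand
  before stimulation, default 1e-6, i.e. effectively zero but strictly
  positive so every parameter lives on log scale).  Both are ordinarily
  fixed in fits.
* **11 protein-abundance parameters** `k_total_X` (molecules/cell) for MET,
  MEK, ERK, PI3K, AKT, TSC, mTORC1, S6K, S6, mTORC2 (SIN1) and IRS1.

For the nine conserved proteins the abundance is the conserved pool total.
MET and IRS1 turn over, so their synthesis fluxes are *derived* from the
abundance parameters (the steady-state reparameterization common in ODE
calibration frameworks): MET
synthesis holds the pre-ligand receptor pool at `k_total_MET`; IRS1 synthesis
holds the active IRS1 pool at `k_total_IRS1` at a reference S6K occupancy
(6% of the S6K pool, `S6K_REFERENCE_FRACTION`).  Above that reference,
chronic S6K activity depletes IRS1 — the basal arm of the feedback.

In the two-diet reference hypothesis exactly 12 parameters are
diet-specific: `k_basal_MET` plus the 11 abundances.  Counting each
parameter once per distinct value it takes across the two diets gives
22 initial-concentration values and 27 dynamical values (23 shared kinetic +
2 × `k_basal_MET` + 2 input).

The basal steady state is evaluated analytically: with the ERK-carried TSC
arm the basal network is a directed chain (MET → MAPK → TSC → mTORC1 → S6K →
{S6, mTORC2, IRS1} → PI3K → AKT), so each pool is a closed-form function of
its upstream pools.  A generic Newton solver on the moiety-reduced system
(conservation relations replacing the redundant ODE rows, numeric
pre-equilibration as fallback) covers arbitrary networks and cross-checks
the closed form.

## Simulation

Trajectories start at the pre-stimulation steady state; the ligand input is
applied as a constant species concentration from t = 0.  Integration uses a
compiled (numba) adaptive Dormand–Prince 5(4) loop with relative tolerance
1e-8 and absolute tolerance 1e-10 molecules/cell by default, validated
against scipy's LSODA in the test suite; scipy remains the fallback path.
Inside optimization the tolerances are relaxed to 1e-7/1e-9 and the step
budget is capped so that pathological parameter corners fail fast (the
objective returns a large penalty) instead of stalling the fit.

## Immunoblot alignment

Raw gel measurements follow the scaling model `Y_ij ~ y_i / s_j` with a
relative error `sigma_ij ~ e_rel · y_i / s_j`: a shared biological effect per
(target, condition, dose, time), divided by a per-(gel, target) scaling
factor.  On the log scale this is an additive two-way Gaussian model; the
maximum-likelihood solution is linear least squares.  The gauge freedom is
fixed by setting the geometric mean of each target's scaling factors to one
(symmetric in the experiments, unlike fixing the first gel).  `e_rel` is
estimated from the degrees-of-freedom-corrected residual variance, and
per-effect 1σ intervals come from the linear-model covariance.  Disconnected
designs (gels that share no biological effect) are detected by graph
connectivity and rejected with the offending blocks named.

Inference is two-stage, as is standard for this model class: align first,
then calibrate the ODE model against the aligned values and their 1σ
intervals.  The alignment-induced correlations between aligned values are
ignored by the second stage; downstream profile-CI coverage in the recovery
study therefore runs slightly below the nominal 95% on some seeds (observed
94–98% across study seeds), which the acceptance threshold (≥90%)
accommodates.

## Abundance anchoring

LFQ intensities are relative; one absolute anchor (AKT molecules/cell from
quantitative immunoblotting) converts all proteins to molecules/cell via a
shared factor.  Anchored abundances enter the likelihood as log2-scale
Gaussian observations of the `k_total_X` parameters; their standard
deviations combine the protein's replicate standard error with the AKT
anchor's own standard error, since the anchor error is inherited by every
converted value.

## Calibration, profiles, model selection

The objective is the Gaussian −2 log-likelihood (sum of squared standardized
residuals).  Immunoblot residuals are computed on log10 signals, matching
the multiplicative noise model; abundance residuals on log2.  Optimization
runs on the log10-parameter scale (positivity by construction) with
scipy's trust-region-reflective least-squares solver.  Multi-starts are a
seeded Latin hypercube over the bounds; every start is optimized with an
iteration cap, the leading starts are polished to tight tolerance, and the
sorted final objectives form the waterfall.  The convergence fraction counts
starts within 0.01 of the best objective.

Profile likelihood: one parameter fixed along an adaptive log10 grid
(initial step 0.02, step doubled where the profile is flat and shrunk where
it climbs, targeting ≈0.7 objective-units per step, at most 30 points per
side), all other parameters re-optimized warm-started from the neighboring
grid point.  The 95% CI is the region within 3.84 (χ²₁) of the optimum,
with linear interpolation at the crossings; a side that reaches its bound
without crossing is reported open (non-identifiable direction).

BIC = objective + k·ln(n) with n the number of aligned data points entering
the likelihood including abundance observations.  Hypotheses about which
parameters are condition-specific are compared on shared data; nested warm
starts (each larger hypothesis starts from the smaller one's optimum) keep
the comparison fair to the bigger models.

## Diet perturbation analysis

Three features discriminate the Western-diet phenotype: basal pMET, basal
phospho-ERK (both read at t = 0 of the pre-equilibrated simulation) and the
trapezoidal AUC of ppAKT (Thr308/Ser473) over the 0–240 min stimulation
window.  Single-parameter scans move one dysregulated parameter from its SD
to its WD estimate in 20% intervals, linearly on the log-parameter scale
(parameters live on log scale throughout; the interpolation scale is a
package choice).  `reoptimize_feature` lets one parameter take any value in
its [SD, WD] interval and minimizes the sum of squared relative feature
deviations (equal weights — the features have different units); ranking the
twelve candidates by achieved discrepancy isolates the driver.

## Patient adaptation and outcome correlation

The calibrated mouse model is carried to patient-derived hepatocytes with
all parameters fixed except a patient-specific subset (`k_basal_MET`,
`k_total_MET`, `k_total_AKT`) and two human-shared kinetics (HGF-induced MET
phosphorylation rate, pMET degradation rate), re-estimated by multi-start
maximum likelihood on log10 residuals (patient data are analyzed on log
scale).  Patients without any unstimulated measurement are rejected because
`k_basal_MET` is then unidentifiable.

Model features per patient — `k_basal`, AUC of ppAKT over 0–120 min,
`k_total_MET`, and the ratios k_basal/AUC and k_basal/MET-abundance — are
correlated with clinical variables by Spearman's rank correlation.
P-values follow algorithm AS 89 (Best & Roberts 1975): the exact null
distribution of S = Σd² for n ≤ 9, the published Edgeworth series beyond,
two-sided by reflection symmetry; tied data fall back to the t
approximation, as the reference implementations do.  Partial Spearman
correlations for the outcome block rank-transform all variables, residualize
on the confounder ranks (age, BMI, fibrosis score, Charlson comorbidity
index) and use the t approximation with n − 2 − k degrees of freedom.
Significance stars are *p<0.05, **p<0.01, ***p<0.001.

## FUCCI trace classification

Two-channel reporter traces (mCherry-hCdt1 = RFP, mVenus-hGeminin = YFP)
are classified per frame into quadrants — RFP-high/YFP-low G1, both high S,
RFP-low/YFP-high G2, both low M/early G1 — with "high" meaning strictly
above the channel threshold.  Thresholds default to per-channel Otsu splits
of an unstimulated reference snapshot and can be overridden.  Missing frames
carry the last observation forward.  A cell-cycle entry is an S → G2
transition between consecutive frames; no smoothing or debouncing is
applied beyond that definition.  Snapshot population fractions are the four
quadrant shares of all cells in a time window.

## Synthetic data: what it emulates and what it does not

The generators are pure functions of their parameters and a seed.

* **Ground truth**: SD and WD parameter vectors differ in exactly the twelve
  dysregulated parameters — `k_basal_MET` 5-fold higher under WD, MET ×0.6,
  SIN1/mTORC2 ×0.7, S6 ×0.7, TSC ×1.4, the remaining abundances
  diet-specific but numerically equal.  The kinetic defaults are
  order-of-magnitude plausible values chosen so the simulated dynamics show
  the qualitative hallmarks of HGF-stimulated hepatocytes (pMET peak near
  10 min with partial adaptation by 240 min, low basal phospho-fractions,
  severalfold ppAKT induction, reduced WD ppAKT response); they are synthetic
  defaults, not fitted estimates from any experiment.
* **Blots**: simulate → observe → divide by a lognormal per-(gel, target)
  scaling factor (spread 0.3) → multiply by relative Gaussian noise
  (e_rel = 0.1).  Default design: 0 and 40 ng/ml, eleven time points to
  240 min, three gels, ten antibody targets.
* **Abundances**: log2 intensities with 0.25 log2 replicate noise, nine mice
  per diet, AKT anchor exact.
* **Patients**: seven patients, per-patient `k_basal_MET` log-uniform over a
  10-fold range, mild abundance variability, human-shared MET kinetics
  shifted from the mouse values; outcomes are linear functions of
  log k_basal plus noise (ordinal discretization for the Clavien-Dindo
  analogue — the weakest structure consistent with a rank correlation);
  confounders independent; one blood metric (PDGF analogue) anti-correlated.
* **FUCCI**: piecewise-phase traces with the requested number of S → G2
  transitions, intensities placed in the generating quadrant with noise
  bounded away from the thresholds.

Passing tests on these data show that the pipeline recovers what it assumes:
multiplicative gel scaling, relative noise, a correctly specified reaction
network, independent Gaussian abundance observations.  Real data violate all
of these to some degree (saturating antibodies, correlated gel effects,
model misspecification, batch structure in proteomics), so the recovery and
coverage numbers here are upper bounds on what the same pipeline achieves on
experimental data.

## Problem sizes and numerical choices

The recovery study fits the 12 WD parameters (SD fixed at the generating
reference, per-target observation scales free and pinned by the SD data)
on one stimulated time course per diet plus anchored abundances; 20 seeded
replicates; the first replicate runs the full 50-start multi-start, the rest
reuse the established start density with 8 starts (the landscape's
convergence fraction is ≈1).  Profile grids use the adaptive stepping
described above.  The BIC comparison fits three nested hypotheses (19, 31
and 77 free parameters).  Tie-breaks: patient ranking breaks ties by patient
id; the scan grid always contains both endpoints; equality with a FUCCI
threshold counts as "low".

## Known limitations

* The reaction set is a condensed literature topology, not a reconciliation
  against any deposited model file; insulin-receptor crosstalk and spatial
  zonation of the liver lobule are out of scope.
* Two-stage alignment-then-fit slightly underestimates parameter
  uncertainty (see above); a joint one-stage fit would remove this at
  considerable cost.
* The AS 89 Edgeworth branch inherits the algorithm's documented
  small-sample error (observed ≲0.02 absolute at n = 7–9 against exact
  enumeration); the exact branch is used there instead.
* `adapt_to_patients` estimates a fixed patient-specific subset; it does not
  search over subsets (the BIC machinery can be used for that manually).
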
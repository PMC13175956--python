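# Methods

This note documents the models, the synthetic data they are exercised on,
and the numerical choices made where the design was genuinely open.

## Planning model

A plan is a pair (t, z): beam-on-times t_isc ≥ 0 (minutes) for every
(isocenter i, sector s ∈ 1..8, collimator c ∈ {4, 8, 16 mm}) and binary
indicators z_i for isocenter selection. Dose is linear in t through the
rate kernels, f_r(t) = Σ_isc φ_risc t_isc (Gy), so the objective's five
penalty terms are piecewise-linear hinges:

* target underdose below the prescription D_T, normalized by D_T·N_T;
* target overdose above 2·D_T, normalized by 2·D_T·N_T;
* overdose above D_S on a selectivity shell (a 2 mm morphological ring
  outside the target, D_S = D_T by default), normalized by D_S·N_S;
* dose above D_G on a gradient shell (the 2–6 mm ring, D_G = D_T/2 by
  default, matching the gradient index's half-isodose), normalized by
  D_G·N_G;
* beam-on-time τ_p = Σ_i max_s Σ_c t_isc, scaled by D_T/D_cal with
  calibration dose D_cal = 18 Gy by default.

Each term carries a nonnegative weight (w_Tmin, w_Tmax, w_S, w_G, w_BOT).
Hinges are linearized with one nonnegative slack per voxel; the per-
isocenter sector maximum with one auxiliary u_i ≥ Σ_c t_isc per sector.
Constraints: Σ_{i∈p} z_i ≤ H_p (isocenter limit) and the big-M coupling.

**Big-M form.** The coupling is aggregated per isocenter,
Σ_{s,c} t_isc ≤ M·z_i, rather than one constraint per beam. This form is
the exact primal counterpart of the inverse model below, whose dual carries
a single q_Z variable per isocenter and the coupling q_H − M·q_Z ≤ 0; with
per-beam coupling the dual normalization would no longer certify a valid
lower bound and the inverse problem degenerates. Since M is scaled to total
per-isocenter time (8 sectors × twice the beam-on-time regression estimate,
floored at 8 × 30 min), the aggregated form is also the physically natural
budget. The default is instance-scaled because the model's solution quality
and solve time are sensitive to M.

Solved with HiGHS through `scipy.optimize.milp` (MIP gap 1e-4 by default);
the LP relaxation (z ∈ [0,1]) and a fixed-isocenter mode (z pinned,
emulating manually selected isocenters) reuse the same matrix. Returned
objectives are always re-evaluated from t by direct summation, independent
of the solver; when w_BOT = 0 the sector-max auxiliary is not pinned by the
objective, so τ is always recomputed from t rather than read from u.

## Inverse weight estimation

Predictions carry no weights, so weights are estimated in two stages.

**Approximate weights.** The hinge penalties ŷ of the predicted dose
(underdose vs D_T, overdose vs 2·D_T, shell slacks vs D_S and D_G) together
with a beam-on-time estimate τ̂ define the planning objective at the
prediction as a linear function a·w of the weights. The inverse LP
minimizes a·w over w ≥ 0 and dual variables (q_T, q_M, q_S, q_G, q_BOT,
q_Z, q_H) of the relaxation satisfying dual feasibility, with the dual
objective normalized to 1. Any feasible point certifies that the best
achievable relaxation objective under w is at least 1, so minimizing a·w
minimizes the prediction's sub-optimality. The reported relative duality
gap is (a·w − F*)/max(F*, 1e-9) with F* from an actual forward solve of
the relaxation under the recovered weights.

τ̂ defaults to the clinical regression below evaluated at N_I = H_p. For
synthetic predictions whose true delivery time is recorded in their
provenance, `penalties_from_prediction` accepts that time directly: the
regression was fit to a clinical population, its error lands entirely in
the beam-on-time coordinate of a, and because desk-scale objectives are
dominated by the beam-on-time term, a minute of τ̂ error visibly biases the
recovered w_BOT. Validation of the inverse machinery uses the known time;
the pipeline itself uses the regression.

**Cutting plane.** The approximate weights initialize an iterative scheme:
forward-solve the integer model at the current weights (the MILP when it
fits a per-iteration budget, else its LP relaxation, flagged as such),
record the solution's normalized term vector b_k as a cut, then re-solve a
master LP choosing new weights. The master minimizes α subject to
w·(a − b_k) ≤ α for all cuts **and the same dual-feasibility/normalization
system as the approximate-weights LP**. Keeping the dual normalization in
the master (instead of a simplex constraint on w) makes the zero-cut master
coincide with stage one and excludes degenerate weight vectors that put all
mass on penalty families where the prediction has no slack — with a bare
simplex master those directions achieve spuriously zero gap and produce
useless plans. α is clamped at 0: a feasible prediction's true
sub-optimality is nonnegative and cuts only under-estimate it, which also
keeps the master bounded. The regularized variant adds λ‖w − w_best‖₁ with
λ = 10% of the incumbent gap, recomputed each master solve.

Termination: the newest forward solution no longer violates the master
bound (within tol, default 1e-4), the incumbent gap stops improving for two
consecutive iterations, an iteration cap (default 100), or the time budget
— in which case the pipeline falls back to the approximate weights, tagged
`approximate (fallback)`. The incumbent (lowest observed gap) is returned,
so the logged gap history is non-increasing by construction.

## Synthetic data

The phantom module emulates the clinical inputs end to end.

* **Geometry.** Ellipsoidal skull (default 1 mm isotropic grid in tests'
  1.5 mm variants; the smallest collimator is 4 mm, so spacing ≤ 2 mm is
  enforced) and ellipsoidal targets specified by volume and axis ratios.
  Rasterized volumes land within 10% of the request (checked above ~200
  voxels, where the lattice permits it). Axis ratios from 1:1:1 to ~11:0.5:0.4
  span discrete sphericities from ≈1.0 down to below 0.48, the range
  reported for clinical cohorts. Sphericity is self-normalized: the
  6-connected exposed-face surface area of the equal-volume digital sphere
  divided by that of the target, clipped at 1 — at these voxel counts the
  estimator's quantization noise is a few percent, so only differences
  larger than that are meaningful.
* **Kernels.** Each (sector, collimator) sub-kernel is an anisotropic
  Gaussian centered at the skull center, in-plane axes rotated to the
  sector angle and scaled by 1 ± 0.15 so sectors are distinguishable. A
  numeric width calibration makes the 8-sector sum's FWHM equal the
  collimator size exactly (the mixture of rotated anisotropic Gaussians is
  ~2.7% wider than its base Gaussian). The 8-sector center rate is
  normalized to the configured dose-rate scale (default 2.5 Gy/min, a
  mid-life cobalt source; aperture output factors are folded into the
  scale). Values below 1e-4 of the peak are truncated: the far Gaussian
  tail carries no dose but its ~1e-30 coefficients destabilize the LPs.
  Kernels are translated to candidate positions by nearest-voxel shift (no
  interpolation, so in-skull values are preserved exactly) and zeroed
  outside the skull; the kernel set stores one central stack plus integer
  offsets and materializes rate matrices on demand.
* **Predictions.** A synthetic prediction is the rendered dose of a plan
  solved under known generating weights — either with isocenter selection
  free (emulating a well-planned historical dose) or restricted to a given
  subset (emulating manual isocenters) — optionally corrupted by truncated
  zero-mean Gaussian noise. Provenance records the generating solution,
  so downstream validation has ground truth. Default generating weights
  (0.45, 0.05, 0.25, 0.25, 0.002): the four hinge terms are bounded by
  their weights while the beam-on-time term grows with minutes delivered,
  so a plausible plan (full coverage in ~10–15 min) requires
  w_BOT ≪ the hinge weights; 0.002 puts the time cost at the same order as
  the residual hinge terms.

What passing tests on these phantoms do **not** show: behavior under real
TMR10 beam physics (heterogeneity, skull-shape attenuation, output
factors), prediction noise of a learned model, multi-target interplay at
clinical scale, or OAR sparing (not modeled). The synthetic stack preserves
the linear-superposition structure the optimization needs; it does not
reproduce clinical dose values.

## Evaluation

With TV the target volume, PIV = {dose ≥ D_T} and PIV_half = {dose ≥ D_T/2}
(counted over the whole volume): coverage = |TV∩PIV|/|TV|, selectivity =
|TV∩PIV|/|PIV|, Paddick CI = |TV∩PIV|²/(|TV||PIV|) = coverage×selectivity,
gradient index = |PIV_half|/|PIV|. An empty PIV is flagged, never silently
zeroed. Treatment time is Σ_p τ_p; the adjusted time adds 8 s (configurable)
per isocenter that actually delivers beam time.

Shot decomposition peels the residual sector×collimator matrix of each
isocenter greedily: every pass assigns each sector its largest-residual
collimator (blocked when exhausted) and fires for the smallest positive
assigned residual. Each pass zeroes at least one entry, so at most 24 shots
arise per isocenter and the shot durations sum back to t exactly. This is a
documented stand-in for a dedicated shot-sequencing optimizer; it
guarantees exact reconstruction, not minimal shot count.

Clinical regressions: beam-on-time estimate
τ̂ = −0.3663·D_T − 9.595·V + 3.438·N_I + 14.94 (minutes; floored at 0.1 min
since the fit goes negative for large V at small N_I) and isocenter-limit
predictor I_pred = 0.0024·D_T³ − 0.0843·D_T² − 0.0052·D_T + 0.0009·V +
17.354, rounded to the nearest integer and floored at 1.

The limit sweep plans under I0/I1/I2 (ceil of 60%/100%/140% of the
reference isocenter count, floored at 1) and optionally I_pred, then applies
the dominance rule pairwise in order with the incumbent preferred on ties:
a challenger wins with ≥ 3% better conformity (relative by default;
absolute switchable) at ≤ 3 min extra time, or ≥ 3 min less time at ≤ 3%
conformity loss.

## Problem sizes and tolerances

Tests and the acceptance script run on 32³–44³ grids (1–2 mm spacing) with
targets of 0.1–2 cc, 6–20 candidate isocenters and isocenter limits of 1–6;
planning MILPs then solve in seconds at MIP gap 1e-4 (1e-6 – 1e-7 where a
brute-force comparison needs it). The subset-enumeration oracle uses ≤ 4
candidates and ≤ 200 optimization voxels so exhaustive enumeration stays
exact and cheap. LP feasibility/duality checks use 1e-6 – 1e-8; dose
linearity and shot reconstruction are exact to 1e-9. Cutting-plane budgets
in tests are 60–120 s with 20–30 s forward solves and ≤ 10 iterations;
the pipeline default budget is one hour with fallback to approximate
weights.

## Known limitations

* The dose engine is a Gaussian surrogate; absolute dose values and
  off-axis effects are not clinically meaningful.
* The inverse problem is non-unique: recovered weight vectors are
  functionally, not parametrically, comparable to generating weights.
* The clinical beam-on-time regression extrapolates poorly to synthetic
  conditions far from its fitting population (large volumes at small
  isocenter counts can make the prediction look better than achievable,
  i.e. a negative gap).
* No organs-at-risk, sector-motion dynamics, source decay, or DICOM-RT
  interfaces.
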
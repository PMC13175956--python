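# gkplan

Knowledge-based treatment planning for Gamma Knife radiosurgery with
simultaneous isocenter selection and beam-on-time optimization, exercisable
entirely on synthetic voxel phantoms.

In Gamma Knife radiosurgery, 192 cobalt beams from 8 independently
collimated sectors converge on an isocenter; a plan is a set of isocenter
positions and per-sector/per-collimator beam-on-times. Knowledge-based
planning (KBP) predicts a desirable 3D dose from historical plans, then
solves an inverse-planning problem to find a deliverable plan that matches
it. This package implements a complete KBP pipeline in which the isocenter
locations themselves are optimization variables rather than manual inputs:

* **Synthetic patients** — ellipsoidal skull and lesion masks on a voxel
  grid with morphological optimization shells, plus synthetic per-sector,
  per-collimator dose-rate kernels (anisotropic Gaussian profiles with FWHM
  equal to the 4/8/16 mm collimator sizes) translated to candidate
  locations, and achievable "predicted" doses with known provenance.
* **Candidate isocenters** — iterative hexagonal-close-packed sphere packing
  (4 mm spheres, shrinking by 0.5 mm until at least max(⌈1.4·n_ref⌉, 6)
  candidates exist) and a grassfire + sphere-packing alternative.
* **Planning model** — a mixed-integer program over beam-on-times t ≥ 0 and
  binary isocenter indicators z:

      min Σ_p [ w_Tmin/(D_T N_T) Σ_{j∈N_T} (D_T − f_j(t))⁺
              + w_Tmax/(2 D_T N_T) Σ_{j∈N_T} (f_j(t) − 2D_T)⁺
              + w_S/(D_S N_S) Σ_{k∈N_S} (f_k(t) − D_S)⁺
              + w_G/(D_G N_G) Σ_{l∈N_G} (f_l(t) − D_G)⁺
              + w_BOT (D_T/D_cal) τ_p ]
      s.t.  f_r(t) = Σ_{isc} φ_risc t_isc,
            τ_p = Σ_{i∈N_I^p} max_s Σ_c t_isc,
            Σ_{i∈N_I^p} z_i ≤ H_p,   Σ_{s,c} t_isc ≤ M z_i,   z binary,

  solved with HiGHS (scipy), with an LP relaxation and a fixed-isocenter
  mode for comparison arms.
* **Weight inference** — an inverse LP over the relaxation's dual that finds
  weights minimizing the prediction's relative duality gap (dual objective
  normalized to 1), refined by a cutting-plane algorithm against the integer
  model, with an optional ℓ1 regularization (λ = 10% of the current gap) and
  fallback to the approximate weights on timeout or infeasibility.
* **Evaluation** — coverage, selectivity, Paddick conformity index
  (= coverage × selectivity) and gradient index; treatment time with an 8 s
  per-isocenter transition penalty; greedy exact shot decomposition; beam-on-
  time regression τ̂ = −0.3663·D_T − 9.595·V + 3.438·N_I + 14.94 (min) and the
  cubic isocenter-limit predictor I_pred = 0.0024·D_T³ − 0.0843·D_T² −
  0.0052·D_T + 0.0009·V + 17.354; an isocenter-limit sweep (60%/100%/140% of
  the reference count, or I_pred) with the 3%-conformity / 3-minute
  best-plan dominance rule.

## Worked example

`examples/03_plan_and_shots.py` builds a 0.3 cc spherical target inside an
18 mm skull, generates HCP candidates and kernels, solves the planning MILP
with at most 2 isocenters, and prints:

```
solver: optimal, objective 0.02602
selected 1 of 9 candidate isocenters
beam-on-time tau = 12.5 min
coverage 0.951, selectivity 1.000, Paddick CI 0.951, gradient index 2.64
treatment time 12.5 min (12.6 min with 8 s isocenter transitions)
2 shots; first: (8.0, 8.0, 8.0, 8.0, 8.0, 8.0, 8.0, 8.0) for 9.35 min
shots reproduce beam-on-times exactly: True
```

Coverage/selectivity are the fractions of target inside the prescription
isodose volume and vice versa; a Paddick CI of 0.95 with a gradient index
below 3 is a tight plan with fast dose falloff. The shot list is an exact
decomposition of the optimized beam-on-times into deliverable
(isocenter, per-sector collimator state, duration) triples.

The other examples cover phantom construction and sphericity
(`01_build_phantom.py`), the two candidate generators (`02_candidates.py`),
inverse weight estimation with the cutting plane (`04_weight_inference.py`)
and the isocenter-limit sweep with best-plan selection
(`05_limit_sweep.py`).

## Command line

The same pipeline is scriptable via the `gkplan` CLI:

```bash
gkplan run   --config examples/config/micro.yaml --out runs/demo --seed 1
gkplan sweep --config examples/config/micro.yaml --out runs/sweep --seed 1
gkplan evaluate --run-dir runs/demo
```

A run directory contains the phantom and dose volumes (NIfTI), candidates,
weights, plan and shots (JSON), a quality report (CSV), a stage log and a
hashed artifact manifest; reruns with the same seed reproduce the plan
byte-for-byte.

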
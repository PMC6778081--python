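# Methods

## Model

The simulator advances individual ligand particles through an axis-aligned
2D (or extruded 3D) representation of a pre-gastrulation embryo: a row of
secreting ExE cell columns and receptor-bearing epiblast columns between a
large apical cavity and a narrow basolateral interstitial space. The
origin sits at the proximal-bottom-left corner of the interstitial space;
x runs proximal→distal, y apicobasal, z (3D) anterior→posterior with
periodic wrap. All boundaries are half-open (lower/left edge inclusive).

Positions update as `r(t+h) = r(t) + Γ(t)` with i.i.d. Gaussian
increments of zero mean and total second moment `c·D·h`, `c = 2·dim`
(per-axis variance `2Dh`). Only the first two moments of the increment
are constrained by the transport model; Gaussian increments are the
standard Brownian-dynamics realization of those constraints. Defaults:
`D = 20 µm²/s`, `h = 3 ms` (per-axis step σ ≈ 0.35 µm, well below every
geometric feature).

Collisions are resolved by exact segment tracing: the step displacement is
intersected with all candidate surfaces (bucketed along x, with per-surface
bounding-box rejection), the earliest hit is processed, and the remaining
displacement continues, up to a hard cap of 32 reflections per step
(exceeding the cap is reported as an error; it does not occur under the
study parameters). After any reflection or failed binding trial the
position is nudged 10⁻⁶ µm off the surface so later steps never start on a
plane. Two analytic shortcuts (reflection at the interstitial floor and at
the cavity ceiling when the step provably cannot touch anything else) and
an interior fast path make the common cavity/interstitial moves cheap;
they are exact, not approximations.

Receptors are well-mixed pools per membrane: each epiblast cell has one
lateral pool (80 receptors, shared by its lateral faces — left/right, plus
front/back in 3D) and one basal pool (20), following the statement of the
binding rule in terms of a membrane's unbound fraction rather than
receptor coordinates. On membrane contact the ligand binds with
probability `P_binding · R_unbound` (one Bernoulli trial per contact, in
contact order); failure reflects. The apical mis-localization variant
moves all 100 receptors of a cell to its apical face. ExE cells carry no
receptors, and their apical faces reflect exactly like epiblast ones.

Bound pairs dissolve exactly `T_t = 45 min` after binding (checked once
per step). Under `constant_total` turnover, the ligand is re-secreted at
its originating ExE cell's secretion face (the face recorded at its
original secretion); ligands without an origin (uniform-cavity initial
condition, colony mode) re-seed uniformly in the cavity. `decreasing`
clears the ligand; `increasing` additionally spawns fresh ligands at the
constant rate `n_ligands / T_t` (the "constantly secreted" control's rate
is not otherwise pinned down; this choice makes the influx balance one
turnover generation per T_t), implemented with a deterministic fractional
accumulator.

Tight junctions are zero-thickness reflecting caps across the apical end
of every same-tissue gap. The ExE–epiblast border gap carries no cap and
is the sole passage ("channel") between cavity and interstitial space; the
wall beyond the distal epiblast column and beyond the proximal ExE column
is reflecting, and the 2-µm dead-end gap at the distal wall is apically
capped like an ordinary gap. In colony mode (no ExE) the 2-µm gaps at both
colony edges are open and `d_edge` is the distance to the nearer edge. In
3D the cross-section is extruded at the same 8-µm cell / 2-µm gap pitch;
between-array gaps are accessible and apically capped; the channel slot is
open at all z, or only over the posterior `posterior_open_arrays` pitches
(default 2) in `posterior_only` mode.

A ligand's interstitial entry time (for the capture statistic
`T_L = t_bind − t_entered`) is stamped on the first step whose end
position lies below the cell-band floor (y < H_I), i.e. when the ligand
actually reaches the interstitial slab whose height the statistic probes;
transit through the channel mouth or a lateral gap alone does not start
the clock, and sub-step transient crossings are below the model's time
resolution. Basolateral secretion stamps entry at secretion. (For
compartment occupancy, by contrast, gap- and channel-resident ligands do
count as interstitial-side.) The event log records binds, turnover
releases, and the first interstitial entry per free episode; repeated
back-and-forth crossings are deliberately not logged (their count is
unbounded and carries no information the statistics use).

Randomness: one `numpy` PCG64 generator per replicate, seeded
`seed + replicate`. Draw order is fixed (seeding draws, then per step: per
ligand two/three increment draws followed by binding-trial draws in
contact order), making runs bit-for-bit reproducible; the determinism is
asserted in the tests.

In-engine checks after every step: the number of bound ligands equals the
sum of per-pool bound counters, and the active-ligand count obeys the
variant's law (constant / non-increasing / non-decreasing). Violations
abort the run; snapshots additionally recount from scratch.

## Parameters that matter

| parameter | default | units | role |
|---|---|---|---|
| D | 20 | µm²/s | ligand diffusion coefficient (local, FCS-type) |
| h | 0.003 | s | integration step; σ_axis = √(2Dh) |
| P_binding | 0.002 | — | per-contact binding scale; 0 disables capture |
| T_t | 2700 | s | ligand–receptor turnover time |
| H_P × W | 30 × 260 | µm | cavity; sets the entropic reservoir size |
| H_I | 2 | µm | interstitial height; throttles capture time T_L |
| cell, gap | 8×18, 2 | µm | column footprint and junctional gap |
| receptors/cell | 100 (80 lat + 20 bas) | — | capture capacity |
| n_ligands | 1000 (2D) | — | source strength; ratio 0.1 ≙ 0.16 ng/mL |

The ligand/receptor ratio ↔ concentration map is linear and anchored at
ratio 0.1 ↔ 0.16 ng/mL.

## Reduced-scale study conditions

The tests and the acceptance script run every condition at a documented
reduced scale chosen so the full battery completes on one CPU:

* gradient formation: 200 ligands, 30 min, 5 replicates (default
  basolateral condition);
* entropic partition: 200 ligands, binding disabled, h = 10 ms, 5
  replicates, evaluated at the 90-min steady state. A shorter horizon is
  not meaningful here: the cavity↔interstitial exchange time through the
  single 2-µm channel is itself ~15 min, so only the 90-min state is
  "long-run";
* source robustness: apically secreted ligands at ligand/receptor ratio
  0.1 (200 ligands vs 2000 receptors, ≙ 0.16 ng/mL) versus ratio 1.0
  (2000 ligands), evaluated at 90 min; the same tenfold increase is
  repeated with apical receptors and without tight junctions;
* capture-time sweep: apically secreted, 200 ligands, 30 min, 10
  replicates per interstitial height H_I ∈ {1, 2, 4, 8} µm. The
  capture clock starts when a ligand first drops below the cell-band
  floor into the H_I slab; transit through the channel mouth or a
  lateral gap alone does not start it, so T_L isolates the leg of the
  journey whose duration H_I controls. A longer window and replicate
  count keep the pooled median clear of right-censoring;
* free-diffusion oracle: 1000 ligands, 10⁴ steps in a 1-mm open box.

At ligand/receptor ratio exactly 1.0 the binding–turnover balance sets a
steady-state occupancy near one half: with all ligands either bound or
free, capture flux ∝ (1−B)² must equal release flux B/T_t, which under
the study kinetics equilibrates around B ≈ 0.45–0.7 depending on a cell's
access to the ligand pool. The robust consequence of mis-localizing
receptors (or removing junctions) is therefore ectopic interior
signaling: tissue-interior cells that the compartmentalization keeps
nearly unoccupied even at a tenfold source jump to roughly half
occupancy once they can sense the cavity pool. A strict "minimum
per-cell occupancy > 50 %" reading of receptor saturation sits exactly
on that balance point: it holds before the first turnover wave
(t ≤ T_t) and for any ligand excess (ratio > 1), but at ratio 1.0 and
the 90-min steady state the minimum hovers at ≈ 0.42–0.53 and the
threshold check can stay red under apical receptors. The acceptance
checks state the strict threshold; the measured values are in the test
outputs.

## What the synthetic generators emulate — and what they do not

`synthetic_colony_table` emulates a segmented-microscopy cell table:
uniformly scattered cells in a rectangular colony, a marker decaying
logistically with d_edge over a configurable depth (plus optional linear
d_source dependence and Gaussian noise), coordinates in cell widths
(13 µm). It reproduces the *dependence structure* used by the information
statistics, not cell shapes, segmentation errors, spatial correlations of
real colonies, or marker distributions beyond a monotone edge response —
tests against it certify the estimator chain, not biological claims.
`sample_known_joint` draws labels from an explicit joint table whose
entropy/MI/proficiency are computed in closed form from the table itself,
giving an oracle that is independent of the estimators under test.
`open_box_config` provides a receptor-free reflecting box for the
diffusion-law and uniformity oracles.

## Numerical choices

* Entropies in bits (base 2); proficiency is base-invariant; `0·log 0 = 0`.
* Plug-in estimators only, as the statistic is defined — no Miller–Madow
  or jackknife correction; the O(1/n) positive MI bias under independence
  is documented and tested.
* Percentile-bin ties go to the lower bin (determinism on discrete data);
  fixed-edge and Gaussian-null bins are half-open with the upper branch
  taken at the threshold.
* The Gaussian null for marker binning uses plain sample moments of the
  designated null sample.
* Joint predictors are flattened to a single categorical label
  (e.g. 6 × 3 = 18 cells for d_source × d_edge).
* Bootstrap: rows resampled with replacement, percentile edges
  re-estimated per resample, 2.5/97.5 percentile interval, deterministic
  given the seed.
* Gradient half-depth: smallest d_edge whose bound fraction falls below
  half of the d_edge = 1 value, linearly interpolated; an all-zero profile
  has no depth (error); a profile that never crosses returns the maximal
  d_edge flagged "saturated".
* Collision tie-breaks (two surfaces at exactly the same hit parameter)
  resolve to the first candidate in surface order; with the EPS nudges
  this is measure-zero.

## Known limitations

* No ligand–ligand exclusion, hydrodynamics, matrix hindrance, or
  explicit inhibitors/activators; bound-receptor fraction stands in for
  downstream signaling.
* The geometry is an unrolled rectangle; curvature of the egg cylinder is
  not represented (the 3D periodic wrap emulates rotational closure).
* Receptor pools are continuous-fraction approximations of 80/20 discrete
  receptors only in the sense that binding uses the pool fraction; counts
  themselves stay integral.
* The cavity↔interstitial exchange time at default geometry (~15 min)
  bounds how quickly any initial condition forgets its secretion side;
  transient observables before ~45 min retain secretion-side memory.
* 3D runs are supported and tested at small array counts; the full
  20-array condition is exercised for geometry censuses but not for long
  transport runs in the default test battery (cost).
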
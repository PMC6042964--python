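# Methods

This note documents the models, estimators and numerical choices behind
`solvbox`, what the synthetic generators do and do not emulate, and the
design decisions taken where more than one convention exists.

## Units and conventions

Coordinates and box edges are in Å; the trajectory time step `dt` is in ps;
reported time axes are in ns; diffusion coefficients cross the API in
cm²/s, with the single conversion constant 1 cm²/s = 10⁴ Ų/ps defined once
in `solvbox.model`. Boxes are cubic only — non-cubic input is rejected
rather than silently mishandled — and all periodic distances use the
minimum-image convention, which is valid for cutoff searches only up to
L/2 (enforced).

## Self-diffusion from mean-squared displacements

`compute_msd` evaluates `MSD(τ) = ⟨|r(t₀+τ) − r(t₀)|²⟩` over all selected
particles and all time origins `t₀`. With origin stride 1 the all-origin
average is computed with the FFT (Wiener–Khinchin) decomposition
`MSD(τ) = S₁(τ) − 2·S₂(τ)`, where `S₂` is the position autocorrelation via
zero-padded FFT and `S₁` follows from a cumulative-sum recursion; this is
algebraically identical to the double loop over origins (asserted against
it in the tests) at O(T log T) instead of O(T²) cost. Wrapped coordinates
are refused: image jumps corrupt displacements, so trajectories carry a
`wrapped` flag and the Brownian generator returns unwrapped positions.

`fit_diffusion` takes the ordinary least-squares slope of `MSD(τ)` over a
window and reports `D = slope/6`. The default window is [10%, 50%] of the
maximum lag — late enough to skip short-lag transients in real data, early
enough that origin statistics remain good — and the default maximum lag is
half the trajectory span. The quoted error is the absolute difference
between `D` fitted on the first and on the second half of the window (each
half must contain ≥ 4 points). Mass weighting is applied only when masses
are supplied; for an all-oxygen water selection uniform weights are exact.

Under these defaults, at the benchmark conditions (N = 1000 particles,
1000 frames, dt = 1 ps) the estimator is unbiased to below 1% with a
per-realization statistical spread of about 1% (SD), so individual
estimates typically land within ~2% of truth and always well within 5%
across the tested seeds. These are properties of the estimator at this
problem size, not tuned tolerances.

### Finite-size correction

Periodic boundary conditions depress the measured `D` through the
hydrodynamic interaction of a particle with its own images. For a cubic
box the leading correction is `D0 = D_PBC + kB·T·ξ/(6π·η·L)` with
`ξ = 2.837297` (cubic-lattice Ewald constant). Defaults: T = 298 K and
η = 3.21×10⁻⁴ Pa·s, a literature shear viscosity for TIP3P-like water near
ambient conditions; both are explicit parameters. The correction is exact
to leading order in 1/L, so `scaling_fit` (least squares of `D` against
1/L) recovers the same `D0` as its intercept — a self-consistency the
tests assert. The bulk reference used for adequacy comparisons is the
corrected TIP3P value 5.95×10⁻⁵ cm²/s, treated as a given constant. An
alternative correction recipe expressed as κ = L×(D0 − D_PBC) circulates
in the literature; it is dimensionally irregular as written, so this
package implements only the standard form above.

`extrapolate_transition_time` fits a straight line to (D, first-transition
time) pairs from several box sizes and evaluates it at a query D (e.g. the
bulk value). It is a purely empirical linear model: the observed
correlation between water mobility and state lifetime, with residuals
returned so the linearity assumption can be inspected.

## Hydrogen-bond statistics

A water–water hydrogen bond is an O–O (donor–acceptor) pair within a
distance cutoff: 2.8 Å (strong), 3.0 Å (medium) or 3.3 Å (weak). No
angular criterion is applied by default because hydrogen positions are
absent from coarse fixtures; an optional donor-H…acceptor angle filter
(default threshold 140°) is available when hydrogens are supplied. Pair
search uses a cell list with ≥ cutoff-sized cells and 27-neighbour sweeps,
falling back to all-pairs when fewer than 3 cells fit per edge; the result
set is identical to brute force (property-tested).

`⟨N_H-bonds⟩/molecule` credits each bond to both partners (2·pairs/N) by
default; the pairs/N convention is selectable. The choice rescales the
absolute level only — interval-to-interval drops and fluctuation trends,
which are the diagnostics, are unaffected. On the periodic simple-cubic
lattice fixture every site has exactly six nearest neighbours, giving the
exact values 6.0 (both) and 3.0 (single). Interval statistics report
per-interval mean, SD and successive mean differences ("drops"); intervals
are inclusive of their left boundary.

## Transition detection

`detect_transitions` fits a piecewise-constant-mean model by binary
segmentation: recursively split at the point maximizing the reduction in
within-segment squared deviation, computed in closed form from cumulative
sums as `n_l·n_r/(n_l+n_r)·(mean_l − mean_r)²`; accept a split only if the
gain exceeds a penalty. Default penalty `3·σ̂²·log n` (BIC-like), with σ̂
estimated robustly from first differences (MAD/(0.6745·√2)) so plateaus do
not inflate the noise estimate; default minimum segment length 10 samples.
A constant series yields an empty transition set; a noiseless step is
located exactly; a transition smeared over ~10 ns is localized inside the
ramp. Planted 10σ steps are recovered at the sampling resolution across
all tested seeds (the ±5 ns tolerance in the acceptance suite is
conservative).

## Superposition and structural metrics

`kabsch_rmsd` computes the optimal proper rigid superposition via SVD of
the cross-covariance, flipping the smallest singular direction when the
determinant would be −1 (reflections rejected); degenerate (collinear)
geometries raise. It agrees with an independent quaternion-eigenvector
oracle to numerical precision. Structure pairs are matched on the
(chain, residue number) intersection of their Cα atoms; unmatched residues
are dropped and reported. Residue-pair distances are computed without
minimum-image wrapping because the intended pairs are intra-protein and
the molecule is assumed kept whole (center-of-mass restrained protocols).
Since reference-structure chain naming varies between depositions, residue
addressing is fully explicit — (chain, resid, atom name) — rather than
hard-coding which chains are β1/β2.

## Hydration structure

`radial_distribution` histograms minimum-image distances and normalizes by
the ideal-gas shell expectation `4πr²·dr·ρ_target` per reference atom and
frame, excluding self-pairs; a uniform target gives g(r) = 1 within
counting noise (±3/√pairs per bin). Default dr is 0.1 Å for residue-scale
RDFs. A delta-function shell planted exactly on a bin edge falls into the
upper bin, so its peak is reported at the bin centre within half a bin of
the true radius.

`density_profile` measures water density versus distance from the solute
surface: distance to the per-frame solute centre of geometry minus an
effective radius R, binned (default dr 0.5 Å) and divided by the bulk
density measured in the outermost 10% of valid distances (valid up to
L/2 − R). R defaults to the radius of the sphere containing 99% of solute
atoms about the centre — one concrete choice among several reasonable
definitions of "solute radius" — and can be overridden. When no bulk
region exists the profile is returned unnormalized with a warning rather
than silently misnormalized.

Region counters (sphere; finite cylinder given centre, axis, radius,
half-height) are minimum-image aware and exact; `water_count_distribution`
returns the per-frame counts, their normalized histogram, mean and SD. For
independently re-drawn uniform configurations the counts are binomial,
hence mean ≈ variance in the dilute limit (property-tested).

## Adequacy report

`assess_box` runs three stages and combines per-criterion flags into a
verdict: (i) diffusion — fitted D (optionally finite-size corrected)
within a tolerance of the bulk reference, default 2%, the magnitude by
which physiological ion concentrations shift water self-diffusion;
(ii) H-bond fluctuation — SD of the per-frame `⟨N⟩/molecule` below a
threshold, default 0.02, an explicitly heuristic value appropriate for
production-size boxes (N ≳ 10⁴ waters; the fluctuation scales as 1/√N, so
desk-scale fixtures need a proportionally larger threshold); (iii)
stability — no change point detected in a supplied structural series
(vacuously true, and flagged as unevaluated, when none is given). Stage
errors are collected per stage and yield a failed criterion plus a partial
report. The verdict is a pure function of the recorded metrics and
thresholds, so reports are reproducible byte for byte, and relaxing every
threshold can only move criteria from fail to pass (tested monotonicity).
The report is advisory: it asserts observable bulk-likeness and stability
on the supplied data, never thermodynamic stability.

## Synthetic generators: scope and limits

The generators are statistical stand-ins, not physical water. Brownian
water is an independent Gaussian random walk with per-step, per-dimension
variance 2·D·dt — no inertia, no hydrodynamics, no structure, so it
exercises the MSD estimator but not, e.g., short-lag ballistic transients.
The ideal gas has g(r) ≡ 1; the H-bond lattice has exact integer neighbour
counts; layered-solute fixtures place delta shells plus uniform bulk;
transition traces have i.i.d. Gaussian noise, whereas real structural
traces are autocorrelated — detection thresholds validated here will be
somewhat optimistic for strongly autocorrelated data. Every generator
records its ground truth (true D, planted counts, radii, change points,
seed) in the returned object's metadata, and identical seeds reproduce
output bit for bit.

Problem sizes used in the test and benchmark suites (N = 1000 waters and
1000 frames for diffusion; 10⁴-sample traces; ~10³-point hydration
fixtures) are the package's chosen desk-scale study conditions: large
enough that each estimator's statistical error is well inside its asserted
tolerance, small enough to iterate on freely.

## Known limitations

- Cubic boxes only; no triclinic support.
- H-bond detection is distance-only by default; donors and acceptors are
  not distinguished chemically.
- Binary segmentation is greedy; for pathological change-point
  configurations an exact dynamic-programming search could differ.
- PDB handling covers the ATOM/HETATM/TER subset (first model only); no
  topology, bond perception or hydrogen placement.
- The D-versus-transition-time extrapolation is an empirical linear model
  with no mechanistic content.
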
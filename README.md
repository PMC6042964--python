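# solvbox

Solvent-box adequacy diagnostics for molecular dynamics trajectories.

## The problem

Long MD simulations of large proteins in periodic water boxes can give
qualitatively wrong answers when the box is too small: the hydration water
stops behaving like bulk water, the water–water hydrogen-bond network is
subtly degraded, and conformational states that are stable in solution decay
in silico. The canonical case is the unliganded hemoglobin tetramer, whose
tense (T) quaternary state survives a microsecond of dynamics only in boxes
holding roughly ten times more water than the usual solvation rule of thumb
provides. `solvbox` packages the diagnostics used to detect this failure
mode, so a box size can be validated (or rejected) from the observables of
the simulation itself:

1. **Water self-diffusion.** From the Einstein relation
   `D_PBC = lim (1/6) d⟨|r(t) − r(0)|²⟩/dt`, with the average over all
   water oxygens and all time origins, and the hydrodynamic finite-size
   correction for a cubic periodic box of edge `L`:
   `D0 = D_PBC + kB·T·ξ/(6π·η·L)`, `ξ = 2.837297`. Water whose corrected
   `D` falls short of the bulk value for the water model (e.g.
   5.95×10⁻⁵ cm²/s for corrected TIP3P) is not yet bulk-like.
2. **Hydrogen-bond network.** Per-frame `⟨N_H-bonds⟩/molecule` from O–O
   donor–acceptor distance cutoffs (2.8 / 3.0 / 3.3 Å = strong / medium /
   weak), with interval averages, per-interval fluctuations, and the small
   (10⁻³–10⁻⁴) drops that accompany structural transitions.
3. **Structural transitions.** Change points in distance/RMSD traces by
   penalized binary segmentation (default penalty `3·σ̂²·log n`), plus
   Kabsch Cα RMSD against reference structures and salt-bridge contact
   fractions.
4. **Hydration structure.** Radial distribution functions `g(r)`,
   solute-centred density profiles `ρ(d)/ρ_bulk` (the dewetting
   diagnostic), and exact water counts in spherical/cylindrical regions.

A synthetic module generates every input with exactly known ground truth —
Brownian water with a prescribed `D`, ideal-gas configurations (`g(r) = 1`),
periodic H-bond lattices with exact neighbour counts, delta-function
hydration shells, and piecewise-constant transition traces — so the whole
pipeline is testable without production trajectories.

## Worked example

```python
from solvbox import compute_msd, fit_diffusion, gen_brownian_water

traj = gen_brownian_water(N=1000, L=75.0, D=5.95e-5, dt=1.0,
                          n_frames=1000, seed=1)
est = fit_diffusion(compute_msd(traj), L=traj.box)
print(f"{est.D_pbc_cm2_s:.3e}")
```

prints `6.081e-05`: the MSD-slope estimator recovers the generator's
5.95×10⁻⁵ cm²/s within its few-percent statistical error (+2.2% at this
seed; unbiased to &lt;1% over 20 seeds). The `examples/` directory has one
short script per capability (`diffusion_recovery.py`,
`box_size_scaling.py`, `hbond_statistics.py`, `transition_detection.py`,
`hydration_profiles.py`, `adequacy_report.py`); for instance
`python examples/transition_detection.py` prints

```
penalty used : 27.92 (3*sigma^2*log n)
change points: ['140.0 ns', '530.0 ns']
segment means: ['30.8 A', '20.9 A', '10.9 A']
```

— both planted quaternary-transition times recovered exactly at the
sampling step, with the plateau levels of the distance trace.

A thin CLI mirrors the library (`solvbox generate | diffusion | hbonds |
rmsd | distance | transitions | report`); `solvbox report traj.xyz` exits
non-zero when the box fails a criterion.

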
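"""Combined box-adequacy verdict for a water trajectory.

Runs the diffusion, hydrogen-bond and transition stages on two Brownian
fixtures: one at the bulk diffusion reference (adequate) and one at the
depressed D typical of an undersized box (diffusion criterion fails).
Thresholds here are scaled to the fixture size (N=400 water sites).
"""

from solvbox import (
    AssessmentConfig,
    assess_box,
    gen_brownian_water,
    gen_transition_trace,
)

cfg = AssessmentConfig(D_tolerance=0.05, hbond_fluctuation_threshold=0.1,
                       hbond_stride=5)

bulk = gen_brownian_water(N=400, L=40.0, D=5.95e-5, dt=1.0,
                          n_frames=600, seed=3)
stable_trace = gen_transition_trace([], [30.9], sigma=1.0, dt_ns=0.5,
                                    T_ns=1000.0, seed=2)
print(assess_box(bulk, cfg, structural_series=stable_trace).summary())

print()

slow = gen_brownian_water(N=400, L=40.0, D=4.25e-5, dt=1.0,
                          n_frames=600, seed=3)
print(assess_box(slow, cfg).summary())
# The first box passes all three criteria; the second fails the
# diffusion criterion (D/D_bulk ≈ 0.71), the signature of water that is
# not yet bulk-like.
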
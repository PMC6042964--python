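"""Finite-size behaviour of D and the transition-time extrapolation.

Shows the 1/L hydrodynamic correction D0 = D_PBC + kB*T*xi/(6*pi*eta*L),
a linear fit of D against 1/L whose intercept extrapolates to the
infinite box, and the linear relation between a box's water D and the
time of the first structural transition observed in it.
"""

import numpy as np

from solvbox import (
    extrapolate_transition_time,
    finite_size_correct,
    finite_size_correction,
    scaling_fit,
)

boxes = [75.0, 90.0, 120.0, 150.0]  # Å
D0 = 6.1e-5  # cm²/s, infinite-system value used to build the demo data

print("L (A)   correction     D_PBC        D0 after correction")
pairs = []
for L in boxes:
    d_pbc = D0 - finite_size_correction(L)  # exact 1/L depression
    pairs.append((L, d_pbc))
    print(f"{L:5.0f}   {finite_size_correction(L):.3e}   {d_pbc:.3e}   "
          f"{finite_size_correct(d_pbc, L):.3e}")

slope, intercept = scaling_fit(pairs)
print(f"\nD vs 1/L fit: intercept {intercept:.3e} cm^2/s "
      f"(infinite-box extrapolation), slope {slope:.3e}")
# The intercept recovers D0: measuring D in several box sizes and
# extrapolating in 1/L is equivalent to applying the analytic correction.

# Boxes with slower (less bulk-like) water lose their starting structure
# earlier; a linear fit of first-transition time against D predicts when
# an adequately solvated system would first leave its state.
observed = [(4.25e-5, 140.0), (4.8e-5, 470.0), (5.3e-5, 620.0)]  # (D, ns)
res = extrapolate_transition_time(observed, D_query=5.95e-5)
print(f"\npredicted first transition at bulk D: {res.t_predicted:.0f} ns "
      f"(slope {res.slope:.2e} ns per cm^2/s)")
print("residuals (ns):", np.round(res.residuals, 1))
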
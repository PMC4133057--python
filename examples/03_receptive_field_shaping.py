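"""Shaping the orthogonal degeneracy: which constraint gives retinal fields?

Every orthogonal recombination of the optimal encoder attains the same
reconstruction error, so receptive-field shape is decided by resource
costs.  This script shapes a 15×15 complete population at 20 dB sensory
SNR under the spatial-locality cost (warm-started from the identity-target
/ ZCA-like solution) and under weight sparsity (random start), then
reports the fraction of units classified as concentric center-surround —
the structure seen in retinal ganglion cells — along with the per-neuron
power violation and the (identical) expected error of both populations.
"""

import warnings

import numpy as np

from popcode import (
    BlurModel,
    CodingProblem,
    ConstraintSpec,
    GridGeometry,
    center_surround_fraction,
    make_powerlaw_spectrum,
    shape_population,
    waterfill_allocation,
    wiener_decoder,
)

warnings.simplefilter("ignore", RuntimeWarning)

grid = GridGeometry(15, 15)
cov = make_powerlaw_spectrum(grid, 2.0)
blur = BlurModel.gaussian(cov, 1.0)
problem = CodingProblem.from_snr(cov, blur, 225, sensory_snr_db=20.0, neural_snr_db=10.0)
alloc = waterfill_allocation(problem)

for kind, init in (("locality", "target"), ("weight_sparsity", "random")):
    enc, state = shape_population(
        problem, alloc, ConstraintSpec(kind=kind, gamma=0.1),
        seed=1, max_iter=600, init=init,
    )
    frac = center_surround_fraction(enc.W, grid)
    err = wiener_decoder(enc, problem).percent_error
    print(f"{kind:16s}: center-surround fraction {frac:.2f}, "
          f"power violation {100*state.individual_power_violation:.3f}%, "
          f"expected error {err:.1f}%")

print(
    "\nOnly the locality cost concentrates each unit's weights around its peak\n"
    "with an antagonistic annulus; both populations reconstruct equally well."
)
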
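"""Lead matrix of phase-shifted sinusoids and recovery of their offsets.

Eight channels share one oscillation but start at different phases; white
noise is added at a signal-to-noise power ratio of 20.  The lead matrix
collects the pairwise signed areas of the (closed) multichannel path, and
the argument of each component of its leading eigenvector recovers each
channel's position in the cycle — up to one global rotation and sign,
because the direction of the cycle is not identifiable.
"""

import numpy as np

from cyclicity import (
    SinusoidSpec,
    circular_rmse,
    gen_phase_shifted_sinusoids,
    lead_matrix,
    recover_phase_offsets,
    spectral_decomposition,
)

spec = SinusoidSpec(n_channels=8, n_periods=4, n_samples=600, snr=20)
tc = gen_phase_shifted_sinusoids(spec, seed=1)

lm = lead_matrix(tc)
ss = spectral_decomposition(lm)
recovered = recover_phase_offsets(ss, reference_channel="ch0")

print("true phases   :", np.round(spec.phases, 3))
print("recovered     :", np.round(recovered, 3))
print("circular RMSE :", round(circular_rmse(recovered, spec.phases), 4), "rad")
print("leading |mu|  :", round(float(ss.eigen_magnitudes[0]), 3))
# The RMSE (a few hundredths of a radian) shows near-perfect recovery of
# the phase ordering despite the noise; the recovered sequence may appear
# reversed, which is the undetermined cycle direction.
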
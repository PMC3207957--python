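"""Variable-flip-angle T1 mapping on simulated SPGR images.

Three spoiled-gradient-echo volumes (flip angles 2, 8, 14 degrees) are
synthesized from the phantom with Rician noise and fitted voxelwise:
linearized DESPOT1 initializes a bounded nonlinear least-squares fit of
the SPGR signal equation.
"""

import numpy as np

from cardiot1.phantom import PhantomSpec, make_heart_phantom, synthesize_vfa_images
from cardiot1.relaxometry import fit_t1_vfa

spec = PhantomSpec()
truth = make_heart_phantom(spec)
series = synthesize_vfa_images(truth, tr_ms=10.0, flip_angles_deg=(2, 8, 14),
                               noise_sigma=spec.noise_sigma, seed=1)
fit = fit_t1_vfa(series, mask=truth.mask_ed != 0)

myo = (truth.mask_ed == 2) & fit.valid_mask
lesion = np.isclose(truth.t1_pre_map, spec.t1_infarct_ms) & myo
remote = myo & ~lesion
print(f"fitted voxels: {fit.valid_mask.sum()} of {int((truth.mask_ed != 0).sum())}")
print(f"lesion T1: fitted {fit.value[lesion].mean():7.1f} ms  (truth {spec.t1_infarct_ms:.0f} ms)")
print(f"remote T1: fitted {fit.value[remote].mean():7.1f} ms  (truth {spec.t1_remote_ms:.0f} ms)")
print(f"median fit R^2 over myocardium: {np.nanmedian(fit.fit_r2[myo]):.4f}")
print("Fitted segment-mean T1 tracks the piecewise-constant truth to within "
      "a few per cent at the default noise level (0.5% of M0).")
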
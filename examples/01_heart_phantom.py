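"""Build the digital LV phantom and inspect its ground truth.

The phantom is an annular left-ventricular myocardium with an anterolateral
infarct sector: elevated pre-contrast T1, concentrated contrast agent, and
reduced systolic thickening.  Everything downstream is validated against
these known-truth fields.
"""

import numpy as np

from cardiot1.phantom import PhantomSpec, make_heart_phantom

spec = PhantomSpec()
truth = make_heart_phantom(spec)

myo = truth.mask_ed == 2
lesion = np.isclose(truth.t1_pre_map, spec.t1_infarct_ms) & myo
remote = myo & ~lesion

print(f"myocardial voxels: {myo.sum()}  (lesion {lesion.sum()}, remote {remote.sum()})")
print(f"pre-contrast T1:  lesion {truth.t1_pre_map[lesion].mean():7.1f} ms, "
      f"remote {truth.t1_pre_map[remote].mean():7.1f} ms")
print(f"post-contrast T1: lesion {truth.t1_post_map[lesion].mean():7.1f} ms, "
      f"remote {truth.t1_post_map[remote].mean():7.1f} ms")
dr1_lesion = 1000 / truth.t1_post_map[lesion].mean() - 1000 / truth.t1_pre_map[lesion].mean()
print(f"lesion delta-R1 from truth maps: {dr1_lesion:.3f} 1/s")
print("The lesion shortens post-contrast T1 via R1_post = R1_pre + r1 * [Gd]; "
      "its delta-R1 is set to sit near the values reported for severe infarcts.")
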
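"""AHA 17-segment analysis: wall thickness, systolic thickening, classes.

The ED mask is labelled into the 17 AHA segments (six 60-degree sectors at
the basal and mid levels, four 90-degree apical sectors, plus the apex),
wall thickness is measured by radial ray casting in both phases, and each
segment is classified from its systolic wall thickening: SWT < 15% infarct,
> 45% remote, otherwise intermediate.
"""

from cardiot1.geometry import LVMask, aha17_labels, systolic_wall_thickening, wall_thickness
from cardiot1.phantom import PhantomSpec, make_heart_phantom
from cardiot1.quantify import classify_tissue

truth = make_heart_phantom(PhantomSpec())
kw = dict(spacing_mm=truth.spacing_mm, rv_insertion_angle_deg=truth.rv_insertion_angle_deg)
ed = LVMask(truth.mask_ed, "ED", **kw)
es = LVMask(truth.mask_es, "ES", **kw)

seg = aha17_labels(ed)
swt = systolic_wall_thickening(wall_thickness(ed, seg), wall_thickness(es, seg))
swt["tissue_class"] = classify_tissue(swt.swt_percent.to_numpy())
names = seg.segment_table.set_index("segment_id")["name"]
swt.insert(1, "name", swt.segment_id.map(names))

print(swt[["segment_id", "name", "wt_ed_mm", "wt_es_mm", "swt_percent", "tissue_class"]]
      .round(3).to_string(index=False))
print("\nRemote segments thicken ~65% in systole; the anterolateral lesion "
      "segments barely thicken and classify as infarct; segments straddling "
      "the lesion border come out intermediate.  The apex has no annulus and "
      "is not measured.")
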
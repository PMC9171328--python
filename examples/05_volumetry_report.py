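"""Multiscale volumetry: tissues, lobes, asymmetry, thickness.

Builds a phantom's report from its ground-truth labels, supplying a
synthetic constant-thickness map for the cortical ribbon, and prints the
full CSV report plus the asymmetry of each paired structure.
"""

import numpy as np

from densefuse.reporting import asymmetry_ratios, build_report, structure_volumes
from densefuse.synthdata import PhantomSpec, make_phantom

spec = PhantomSpec(shape=(48, 48, 48), seed=13)
img, labels, scheme = make_phantom(spec)

# synthetic thickness map: 2.5 mm wherever there is cortical GM
cgm_ids = scheme.ids_of_tissue("cGM")
thickness = np.where(np.isin(labels.labels, cgm_ids), 2.5, 0.0)

report = build_report(labels, scheme, native_affine_det=1.1, thickness_map=thickness)
print(report.table.to_string(index=False))

asym = asymmetry_ratios(structure_volumes(labels), scheme)
print("\nper-pair asymmetry (% of mean, positive = right larger):")
print(asym.to_string(index=False))
print(
    "\nTissue rows partition the ICC volume exactly; native volumes are the"
    "\ntemplate volumes scaled by the native-affine determinant (1.1 here)."
)
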
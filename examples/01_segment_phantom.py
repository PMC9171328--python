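"""Leave-one-out segmentation of a synthetic brain phantom.

Builds a 10-member library of deformed, noisy labeled phantoms, segments
member 0 using the other nine, and prints the per-structure Dice overlap
with the ground truth plus the first rows of the volumetry report.
"""

from densefuse import AtlasLibrary, FusionParams, dice, segment_volume
from densefuse.synthdata import PhantomSpec, make_library

spec = PhantomSpec(shape=(48, 48, 48), seed=3)
library, scheme = make_library(spec, 10, seed=11)
subject_img, subject_truth = library.members[0]
rest = AtlasLibrary(members=library.members[1:])

result = segment_volume(subject_img, rest, scheme, params=FusionParams(seed=7))

table = dice(result.structures, subject_truth)
print(table.rename(index={i: scheme[i].name for i in table.index}).to_string())
print(f"\nmean structure Dice: {table.mean():.4f}")
print("\nreport (ICC + tissue rows):")
print(result.report.table.head(9).to_string(index=False))
print(
    "\nEach Dice value is the overlap between the automatic and true label"
    "\nmasks (1 = identical); the report gives each region's volume and its"
    "\nshare of the intracranial cavity."
)
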
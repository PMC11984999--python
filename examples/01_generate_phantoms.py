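"""Generate phantom mammograms with known ground truth.

Builds one phantom per BIRADS class for an artifact-heavy hospital profile
and prints what the generator controls: breast-mask size, lesion burden,
artifact geometry and the raw intensity range.
"""

import numpy as np

from fedmammo import HospitalProfile, PhantomSpec, generate_phantom

profile = HospitalProfile(
    "H1",
    intensity_range=(50, 1050),   # raw stored-pixel units of this scanner
    label_prob=1.0,               # every image carries a printed label
    clip_prob=0.5,
)

for birads in range(1, 6):
    spec = PhantomSpec(image_size=(128, 128), laterality="R", birads=birads, seed=birads)
    rec = generate_phantom(spec, profile)
    bright = (rec.pixels > np.percentile(rec.pixels, 99)).sum()
    print(
        f"BIRADS {birads}: {spec.lesion_count} lesions, "
        f"breast covers {rec.mask.mean():.0%} of the frame, "
        f"label box {rec.artifacts.label_box}, "
        f"pixel range [{rec.pixels.min()}, {rec.pixels.max()}], "
        f"{bright} near-saturated pixels"
    )

# The lesion count (birads - 1) and brightness grow with the class, so a
# classifier trained on these cohorts has a real image property to recover.
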
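"""Voxelwise two-factor group ANOVA on lag maps with FDR control.

Constructs a 2 (group) x 2 (timepoint) cohort of lag maps, injects a
+0.5 s group offset into the lesion region for the patient group, fits the
voxelwise OLS ANOVA with effect coding, and applies Benjamini-Hochberg FDR
at q = 0.1 per term.
"""

import numpy as np

import lagcvr as lc
from lagcvr.stats import voxelwise_group_anova

anatomy = lc.make_phantom_anatomy()
region = anatomy.lesion_mask
rng = np.random.default_rng(4)

maps, groups, times = [], [], []
for g in ("patient", "control"):
    for t in ("v1", "v2"):
        for _ in range(5):
            m = rng.normal(0.0, 0.1, anatomy.shape)
            if g == "patient":
                m[region] += 0.5
            maps.append(m)
            groups.append(g)
            times.append(t)

res = voxelwise_group_anova(maps, groups, times, q=0.1)
inside = res.sig_group[region].mean()
outside = res.sig_group[~region & res.analysis_mask].mean()

print(f"analysis mask voxels          : {int(res.analysis_mask.sum())}")
print(f"group effect flagged inside   : {100 * inside:.1f} % of the region")
print(f"group effect flagged outside  : {100 * outside:.2f} % (false positives)")
print(f"adaptive FDR p threshold      : {res.threshold_group:.2e}")
# The injected +0.5 s offset (5x the between-subject noise SD) is detected
# in essentially the whole region, while rejections elsewhere stay at the
# false-discovery level the q = 0.1 correction permits.
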
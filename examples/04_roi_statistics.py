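"""Regional statistics on elastograms: ROI means, group averages, t-tests.

Builds a toy cohort of aligned |G*|/phi maps with two labeled regions of
different stiffness, averages them subject-wise, and tests the regional
difference with the paired two-tailed t-test used for atlas comparisons.
"""

import numpy as np

from mdevmre import ElastogramPair, group_average, region_compare, roi_stats
from mdevmre.atlas_stats import roi_stats_frame

rng = np.random.default_rng(0)
shape = (6, 20, 20)
labels = np.zeros(shape, int)
labels[:, :10] = 1   # "stiff" region
labels[:, 10:] = 2   # "soft" region

subjects = []
stiff_means, soft_means = [], []
for _ in range(23):
    gabs = np.where(labels == 1, rng.normal(1250, 110), rng.normal(650, 100))
    gabs = gabs + rng.normal(0, 60, shape)  # voxel-level heterogeneity
    phi = np.clip(rng.normal(0.9, 0.05, shape), 0, np.pi)
    pair = ElastogramPair(gabs=gabs, phi=phi, mask=np.ones(shape, bool))
    subjects.append(pair)
    by = {s.label: s for s in roi_stats(pair, labels, legend={1: "stiff", 2: "soft"})}
    stiff_means.append(by["stiff"].mean_gabs)
    soft_means.append(by["soft"].mean_gabs)

atlas, sd_gabs, sd_phi, count = group_average(subjects)
print("group-average atlas of 23 subjects:")
print(roi_stats_frame(roi_stats(atlas, labels, legend={1: "stiff", 2: "soft"})).round(2))

res = region_compare(np.array(stiff_means), np.array(soft_means), paired=True)
print(f"\npaired two-tailed t-test, stiff vs soft: t = {res.t:.2f}, "
      f"p = {res.p:.3g}, significant at 5%: {res.significant}")
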
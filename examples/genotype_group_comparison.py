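"""Wild-type vs knockout comparison of puncta density across ROIs.

Generates ROI-level scaffold-puncta densities for a wild-type group and a
knockout group with a planted 40% density reduction (lognormal ROI-to-ROI
noise, 25 ROIs per genotype), then runs the two-tailed Mann-Whitney U
test on the ROI values.
"""

import numpy as np

from synprox import compare_groups, summarize_rois

rng = np.random.default_rng(0)
rows = []
for genotype, mean_density in (("WT", 0.15), ("KO", 0.09)):
    for i in range(25):
        rows.append({
            "genotype": genotype,
            "image": f"{genotype.lower()}_retina",
            "roi": f"roi{i}",
            "density_per_um2": rng.lognormal(np.log(mean_density), 0.35),
            "mean_size_um2": rng.lognormal(np.log(0.25), 0.2),
        })

metrics = summarize_rois(rows)
for metric in ("density_per_um2", "mean_size_um2"):
    res = compare_groups(metrics, metric)
    wt, ko = res.group_summaries["WT"], res.group_summaries["KO"]
    print(f"{metric}:")
    print(f"  WT {wt['mean']:.4f} +/- {wt['sem']:.4f} (n={wt['n']}), "
          f"KO {ko['mean']:.4f} +/- {ko['sem']:.4f} (n={ko['n']})")
    print(f"  {res.test_name}: U = {res.statistic:.0f}, p = {res.p_value:.2e}")
print()
print("Density carries a planted 40% knockout reduction and is detected;")
print("punctum size carries no effect and its p-value is non-significant.")
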
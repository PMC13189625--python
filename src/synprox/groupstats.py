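"""Genotype (e.g. wild-type vs connexin-knockout) comparison of per-ROI
puncta metrics: density, size and pairwise scaffold colocalization.

The unit of analysis is the ROI. Two groups are compared with a two-tailed
Mann-Whitney U test (exact null enumeration for small tie-free samples,
midrank/normal approximation with continuity correction otherwise, as
implemented in scipy); more than two groups route to a one-way ANOVA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

METRICS = ("density_per_um2", "mean_size_um2", "coloc_percent")


@dataclass
class GroupTestResult:
    """Between-group test outcome for one metric."""

    metric: str
    test_name: str
    statistic: float
    p_value: float
    group_summaries: dict[str, dict]

    def to_dict(self) -> dict:
        return {
            "metric": self.metric,
            "test": self.test_name,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "groups": self.group_summaries,
        }


def summarize_rois(per_roi: list[dict]) -> pd.DataFrame:
    """Assemble per-ROI measurement dicts into the metrics table.

    Each input dict carries ``genotype``, ``image``, ``roi`` and any of
    ``density_per_um2``, ``mean_size_um2``, ``coloc_percent``. Rows missing
    a genotype/image/roi key are flagged incomplete and dropped. Averaging
    across ROIs is deferred to the test stage.
    """
    rows = []
    for rec in per_roi:
        if not all(k in rec for k in ("genotype", "image", "roi")):
            continue
        rows.append({
            "genotype": rec["genotype"],
            "image": rec["image"],
            "roi": rec["roi"],
            "density_per_um2": rec.get("density_per_um2", np.nan),
            "mean_size_um2": rec.get("mean_size_um2", np.nan),
            "coloc_percent": rec.get("coloc_percent", np.nan),
        })
    return pd.DataFrame(rows, columns=["genotype", "image", "roi", *METRICS])


def compare_groups(metrics: pd.DataFrame, metric: str) -> GroupTestResult:
    """Compare one metric between genotypes at the ROI level.

    Two groups: two-tailed Mann-Whitney U. More than two: one-way ANOVA.
    Requires at least 3 non-missing ROI values per group.
    """
    if metric not in metrics.columns:
        raise ValueError(f"unknown metric {metric!r}")
    sub = metrics.dropna(subset=[metric])
    groups = {g: d[metric].to_numpy(float) for g, d in sub.groupby("genotype")}
    if len(groups) < 2:
        raise ValueError("need at least two genotypes to compare")
    for g, v in groups.items():
        if len(v) < 3:
            raise ValueError(f"group {g!r} has fewer than 3 ROIs ({len(v)})")

    names = sorted(groups)
    values = [groups[g] for g in names]
    if len(names) == 2:
        res = stats.mannwhitneyu(values[0], values[1], alternative="two-sided",
                                 method="auto")
        test_name = "mann_whitney_u"
    else:
        res = stats.f_oneway(*values)
        test_name = "anova"
    summaries = {
        g: {
            "n": int(len(v)),
            "mean": float(np.mean(v)),
            "sem": float(np.std(v, ddof=1) / np.sqrt(len(v))) if len(v) > 1 else float("nan"),
        }
        for g, v in zip(names, values)
    }
    return GroupTestResult(
        metric=metric, test_name=test_name,
        statistic=float(res.statistic), p_value=float(res.pvalue),
        group_summaries=summaries,
    )
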
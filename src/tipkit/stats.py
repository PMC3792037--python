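"""Group comparisons used in the study's analyses.

Thin, explicit wrappers over scipy's implementations: two-sided t-test
(classic pooled-variance by default, Welch optional), one-way ANOVA with
Tukey's HSD for all pairs, and the Mann-Whitney rank-sum test (exact
enumeration for small tie-free samples).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps


@dataclass
class GroupComparison:
    test: str
    group_names: list[str]
    group_n: list[int]
    group_mean: list[float]
    group_sd: list[float]
    statistic: float
    p_value: float
    pairwise: list[tuple[str, str, float]] = field(default_factory=list)  # Tukey p per pair
    degenerate: bool = False

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "group": self.group_names,
                "n": self.group_n,
                "mean": self.group_mean,
                "sd": self.group_sd,
                "test": self.test,
                "statistic": self.statistic,
                "p_value": self.p_value,
            }
        )


def compare_groups(
    values_by_group: dict[str, np.ndarray],
    test: str = "t",
    welch: bool = False,
) -> GroupComparison:
    """Two-sided comparison of measurement groups.

    ``test``: ``"t"`` (two groups), ``"anova_tukey"`` (>= 2 groups; Tukey
    HSD p-values for all pairs), or ``"ranksum"`` (two groups; exact
    enumeration when both n <= 8 and there are no ties, normal
    approximation with tie correction otherwise).  Groups with identical
    values in both samples report p = 1 with the ``degenerate`` flag.
    """
    names = list(values_by_group)
    groups = [np.asarray(values_by_group[k], dtype=float) for k in names]
    min_n = 3 if test == "ranksum" else 2
    if any(len(g) < min_n for g in groups):
        raise ValueError(f"each group needs >= {min_n} values for test {test!r}")
    summary = dict(
        group_names=names,
        group_n=[len(g) for g in groups],
        group_mean=[float(g.mean()) for g in groups],
        group_sd=[float(g.std(ddof=1)) for g in groups],
    )
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return GroupComparison(test=test, statistic=0.0, p_value=1.0, degenerate=True, **summary)

    if test == "t":
        if len(groups) != 2:
            raise ValueError("t-test compares exactly 2 groups")
        res = sps.ttest_ind(groups[0], groups[1], equal_var=not welch)
        return GroupComparison(test=test, statistic=float(res.statistic),
                               p_value=float(res.pvalue), **summary)
    if test == "ranksum":
        if len(groups) != 2:
            raise ValueError("rank-sum test compares exactly 2 groups")
        exact = (
            len(groups[0]) <= 8
            and len(groups[1]) <= 8
            and len(np.unique(pooled)) == len(pooled)
        )
        res = sps.mannwhitneyu(
            groups[0], groups[1], alternative="two-sided",
            method="exact" if exact else "asymptotic",
        )
        return GroupComparison(test=test, statistic=float(res.statistic),
                               p_value=float(res.pvalue), **summary)
    if test == "anova_tukey":
        res = sps.f_oneway(*groups)
        comp = GroupComparison(test=test, statistic=float(res.statistic),
                               p_value=float(res.pvalue), **summary)
        tuk = sps.tukey_hsd(*groups)
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                comp.pairwise.append((names[i], names[j], float(tuk.pvalue[i, j])))
        return comp
    raise ValueError(f"unknown test {test!r}")
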
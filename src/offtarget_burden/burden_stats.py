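"""Per-sample candidate de novo counts and nonparametric group comparisons.

Counts of cascade-surviving calls per sample are compared between injection
arms with a two-sided Wilcoxon rank-sum test (two groups; exact enumeration
for combined n <= 20 without ties, otherwise the normal approximation with
tie correction) or a Kruskal-Wallis rank test (more than two groups,
chi-square approximation with tie correction).  Significance is declared
against a Bonferroni critical value of alpha_family / n_groups; the report
string shows the threshold truncated to three decimals, matching how such
critical values are conventionally printed (0.05/4 -> "0.012").
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from scipy import stats

from offtarget_burden.denovo_filter import FilterReport
from offtarget_burden.vario import Cohort

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class GroupComparison:
    grouping: str
    group_sizes: Mapping[str, int]
    test_name: str  # "wilcoxon" | "kruskal_wallis"
    statistic: float
    p_value: float
    alpha_family: float
    n_groups: int
    alpha_per_comparison: float
    significant: bool

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p_value out of [0,1]: {self.p_value}")

    def to_dict(self) -> dict:
        return {
            "grouping": self.grouping,
            "group_sizes": dict(self.group_sizes),
            "test": self.test_name,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "alpha_family": self.alpha_family,
            "n_groups": self.n_groups,
            "alpha_per_comparison": self.alpha_per_comparison,
            "alpha_display": bonferroni_display(self.alpha_per_comparison),
            "significant": self.significant,
        }


def count_denovo_per_sample(
    filter_report: FilterReport,
    cohort: Cohort,
    include_suspect: bool = True,
    generation: Optional[str] = None,
) -> dict[str, int]:
    """Surviving-call counts per cohort sample (parents excluded).

    Suspect-flagged calls are included or dropped per ``include_suspect``;
    a cohort sample absent from the call sets counts 0 with a warning.
    """
    counts: dict[str, int] = {}
    for sample in cohort:
        if sample.generation == "parent":
            continue
        if generation is not None and sample.generation != generation:
            continue
        calls = filter_report.final_calls.get(sample.sample_id)
        if calls is None:
            log.warning("sample %s absent from call sets; count 0",
                        sample.sample_id)
            counts[sample.sample_id] = 0
            continue
        counts[sample.sample_id] = sum(
            1 for c in calls if include_suspect or not c.suspect
        )
    return counts


def bonferroni_threshold(n_groups: int, alpha_family: float = 0.05) -> float:
    """Per-comparison alpha: alpha_family / n_groups."""
    if n_groups < 1:
        raise ValueError("n_groups must be >= 1")
    return alpha_family / n_groups


def bonferroni_display(alpha: float) -> str:
    """The critical value truncated (not rounded) to three decimals, as
    printed in reports: 0.0125 -> \"0.012\"."""
    return f"{math.floor(alpha * 1000) / 1000:.3f}"


def compare_groups(
    counts: Mapping[str, float],
    group_assignment: Mapping[str, str],
    alpha_family: float = 0.05,
    grouping: str = "condition",
) -> GroupComparison:
    """Nonparametric burden comparison across groups of samples.

    Two groups -> two-sided Wilcoxon rank-sum (exact when the combined n is
    <= 20 and the data are tie-free, else normal approximation with tie
    correction).  More than two -> Kruskal-Wallis with tie correction.  The
    Bonferroni divisor is the number of groups compared.
    """
    groups: dict[str, list[float]] = {}
    for sid, value in counts.items():
        label = group_assignment.get(sid)
        if label is None:
            continue
        groups.setdefault(label, []).append(float(value))
    if len(groups) < 2:
        raise ValueError("need >= 2 non-empty groups")
    for label, values in groups.items():
        if len(values) < 2:
            log.warning("group %r has < 2 samples; p-value exactness degraded",
                        label)
    labels = sorted(groups)
    data = [groups[lab] for lab in labels]
    n_groups = len(labels)
    alpha_per = bonferroni_threshold(n_groups, alpha_family)

    if n_groups == 2:
        x, y = data
        pooled = x + y
        has_ties = len(set(pooled)) < len(pooled)
        method = "exact" if (len(pooled) <= 20 and not has_ties) else "asymptotic"
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
        stat, p = float(res.statistic), float(res.pvalue)
        test_name = "wilcoxon"
    else:
        flat = [v for vals in data for v in vals]
        if len(set(flat)) == 1:
            stat, p = 0.0, 1.0  # all observations identical: H = 0
        else:
            res = stats.kruskal(*data)
            stat, p = float(res.statistic), float(res.pvalue)
        test_name = "kruskal_wallis"

    p = min(p, 1.0)
    return GroupComparison(
        grouping=grouping,
        group_sizes={lab: len(groups[lab]) for lab in labels},
        test_name=test_name,
        statistic=stat,
        p_value=p,
        alpha_family=alpha_family,
        n_groups=n_groups,
        alpha_per_comparison=alpha_per,
        significant=p < alpha_per,
    )


def control_vs_edited_assignment(cohort: Cohort, generation: str) -> dict[str, str]:
    """Two-group labelling: edited vs pooled controls, one generation."""
    out = {}
    for s in cohort:
        if s.generation != generation:
            continue
        out[s.sample_id] = "edited" if s.condition == "edited" else "control"
    return out


def condition_assignment(cohort: Cohort, generation: str) -> dict[str, str]:
    """Four-group labelling by injection condition, one generation."""
    return {
        s.sample_id: s.condition for s in cohort if s.generation == generation
    }


def exact_wilcoxon_enumeration(x: Sequence[float], y: Sequence[float]) -> float:
    """Independent oracle: two-sided rank-sum p by full enumeration of all
    C(n_x + n_y, n_x) group assignments (midranks for ties).

    Intended for small inputs in validation; complexity is combinatorial.
    """
    from itertools import combinations

    pooled = list(x) + list(y)
    n, nx = len(pooled), len(x)
    ranks = stats.rankdata(pooled)
    observed = sum(ranks[:nx])
    mean_w = nx * (n + 1) / 2.0
    obs_dev = abs(observed - mean_w)
    total = 0
    extreme = 0
    for idx in combinations(range(n), nx):
        w = sum(ranks[i] for i in idx)
        total += 1
        if abs(w - mean_w) >= obs_dev - 1e-9:
            extreme += 1
    return extreme / total


def type_i_error_rate(
    p_values: Sequence[float], alpha: float
) -> tuple[float, float]:
    """Observed rejection fraction and its binomial standard error."""
    rejections = sum(1 for p in p_values if p < alpha)
    n = len(p_values)
    rate = rejections / n
    se = math.sqrt(alpha * (1 - alpha) / n)
    return rate, se
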
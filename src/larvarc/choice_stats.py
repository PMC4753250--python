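"""Preference-index statistics for two-choice plate assays.

The preference index of one plate is

    PI = (N_stimulus - N_control) / (N_stimulus + N_control)

counting the larvae on the stimulus-substrate and control-substrate sides;
animals still in the neutral midline zone are excluded from the index (an
alternative including them in the denominator is available).  PI is +1 for
complete attraction, -1 for complete avoidance.  Group comparisons use the
Wilcoxon rank-sum test for independent groups and the Wilcoxon signed-rank
test for paired designs, with exact p-values for small tie-free samples and
the normal approximation otherwise.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .calcium import significance_stars
from .containers import ChoiceAssayResult
from .errors import DataError, InsufficientDataError, ParameterError

__all__ = [
    "compute_pi",
    "assay_pi",
    "GroupComparison",
    "compare_groups",
    "pairwise_comparisons",
]


def compute_pi(
    n_stimulus_side: int,
    n_control_side: int,
    n_neutral: int = 0,
    denominator: str = "sides",
) -> float:
    """Preference index from side counts.

    ``denominator="sides"`` (default) excludes neutral-zone animals;
    ``denominator="total"`` includes them, compressing the index toward 0.
    """
    if n_stimulus_side < 0 or n_control_side < 0 or n_neutral < 0:
        raise ParameterError("counts must be >= 0")
    if denominator not in ("sides", "total"):
        raise ParameterError(f"unknown denominator {denominator!r}")
    n_sides = n_stimulus_side + n_control_side
    if n_sides == 0:
        raise DataError("PI undefined: no larvae on either side")
    denom = n_sides if denominator == "sides" else n_sides + n_neutral
    return (n_stimulus_side - n_control_side) / denom


def assay_pi(assay: ChoiceAssayResult, denominator: str = "sides") -> float:
    """PI of one assay row."""
    return compute_pi(assay.n_stimulus_side, assay.n_control_side,
                      assay.n_neutral, denominator)


@dataclass(frozen=True)
class GroupComparison:
    """Wilcoxon comparison of two groups of per-assay PIs."""

    statistic: float
    p_value: float
    stars: str
    method: str
    n_a: int
    n_b: int


def compare_groups(
    pis_a: np.ndarray,
    pis_b: np.ndarray,
    paired: bool = False,
    alternative: str = "two-sided",
) -> GroupComparison:
    """Compare two samples of preference indices.

    Rank-sum for independent groups (e.g. genotypes), signed-rank for
    paired designs (same plates under two conditions).
    """
    a = np.asarray(pis_a, dtype=np.float64).ravel()
    b = np.asarray(pis_b, dtype=np.float64).ravel()
    if min(a.size, b.size) < 3:
        raise InsufficientDataError("need >= 3 assays per group")
    if paired:
        if a.size != b.size:
            raise ParameterError("paired comparison requires equal group sizes")
        if np.all(a == b):
            return GroupComparison(0.0, 1.0, "", "wilcoxon-signed-rank", a.size, b.size)
        mode = "exact" if a.size < 25 else "approx"
        res = stats.wilcoxon(a, b, alternative=alternative, method=mode,
                             zero_method="wilcox")
        method = "wilcoxon-signed-rank"
    else:
        has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
        mode = "exact" if (min(a.size, b.size) < 25 and not has_ties) else "asymptotic"
        res = stats.mannwhitneyu(a, b, alternative=alternative, method=mode)
        method = "wilcoxon-rank-sum"
    p = float(res.pvalue)
    return GroupComparison(float(res.statistic), p, significance_stars(p),
                           method, a.size, b.size)


def pairwise_comparisons(
    groups: dict[str, np.ndarray],
    paired: bool = False,
) -> pd.DataFrame:
    """All pairwise group comparisons as a tidy report table.

    Typical use: a genetic-ablation design (effector control, driver
    control, ablated) compared pairwise.  One row per unordered pair, in
    input order.
    """
    rows = []
    for (name_a, pis_a), (name_b, pis_b) in itertools.combinations(groups.items(), 2):
        cmp_ = compare_groups(pis_a, pis_b, paired=paired)
        rows.append({
            "group_a": name_a,
            "group_b": name_b,
            "n_a": cmp_.n_a,
            "n_b": cmp_.n_b,
            "statistic": cmp_.statistic,
            "p_value": cmp_.p_value,
            "stars": cmp_.stars,
            "method": cmp_.method,
        })
    return pd.DataFrame(rows)
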
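"""Group comparison and normalization utilities.

Comparisons between conditions use the two-tailed Mann–Whitney U test
(exact for small tie-free samples, tie-corrected normal approximation
otherwise).  P values below the numerical precision floor are flagged as
upper bounds.  Metric values are routinely normalized to the mean of a
reference (control) group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["MannWhitneyResult", "compare_groups", "normalize_to_reference", "significance_stars"]

# below this the p value is reported as an upper bound
P_PRECISION_FLOOR = 1e-15

# exact null distribution is enumerated up to this per-group size (no ties)
EXACT_N_MAX = 25


@dataclass(frozen=True)
class MannWhitneyResult:
    u_statistic: float
    p_value: float
    is_upper_bound: bool
    method: str

    def __iter__(self):
        return iter((self.u_statistic, self.p_value))


def compare_groups(values_a, values_b) -> MannWhitneyResult:
    """Two-tailed Mann–Whitney U test between two groups.

    The U statistic is reported for the first group.  The exact null
    distribution is used for small tie-free samples; otherwise the
    tie-corrected normal approximation.  When p falls below the floating
    precision floor it is clamped there and flagged as an upper bound.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    if not has_ties and max(len(a), len(b)) <= EXACT_N_MAX:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    p = float(res.pvalue)
    bound = p < P_PRECISION_FLOOR
    return MannWhitneyResult(
        u_statistic=float(res.statistic),
        p_value=max(p, P_PRECISION_FLOOR) if bound else p,
        is_upper_bound=bound,
        method=method,
    )


def normalize_to_reference(values, reference_group) -> np.ndarray:
    """Divide each value by the mean of the reference group."""
    ref = np.asarray(reference_group, dtype=float)
    if len(ref) == 0:
        raise ValueError("empty reference group")
    m = ref.mean()
    if m == 0:
        raise ValueError("zero reference mean")
    return np.asarray(values, dtype=float) / m


def significance_stars(p: float) -> str:
    """Conventional significance annotation: NS, *, **, ***, ****."""
    if p > 0.05:
        return "NS"
    if p <= 1e-4:
        return "****"
    if p <= 1e-3:
        return "***"
    if p <= 1e-2:
        return "**"
    return "*"
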
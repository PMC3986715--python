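"""The f2 similarity factor for comparing dissolution profiles.

For reference and test profiles R_t, T_t sampled at the same n times,

    f2 = 50 * log10( 100 * [1 + (1/n) * sum_t (R_t - T_t)^2]^(-1/2) )
       = 100 - 25 * log10(1 + mean squared difference)

Identical profiles score exactly 100; a uniform 10-percentage-point offset
scores about 50.  The statistic is symmetric in its arguments and depends
only on the multiset of squared per-time differences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .core import DissolutionProfile, ScheduleMismatchError

__all__ = ["SimilarityResult", "f2_similarity"]


@dataclass(frozen=True)
class SimilarityResult:
    """f2 score plus the per-time squared differences for audit."""

    f2: float
    n: int
    per_time_sq_diff: tuple[float, ...]


def f2_similarity(
    reference: DissolutionProfile,
    test: DissolutionProfile,
    min_points: int = 3,
    truncate_after_85: bool = False,
) -> SimilarityResult:
    """Compute f2 between two profiles on a shared sampling schedule.

    Parameters
    ----------
    reference, test
        Profiles with identical time schedules.  Values outside [0, 100]
        (possible for raw surrogate predictions) are accepted as given.
    min_points
        Minimum number of shared time points (default 3; the formula is
        defined for any n >= 1).
    truncate_after_85
        Apply the regulatory rule of keeping points only up to and
        including the first time the reference releases more than 85%.
        Off by default: the study compares full six-point profiles.
    """
    if not reference.same_schedule(test):
        raise ScheduleMismatchError(
            f"schedules differ: {reference.times_h} vs {test.times_h}"
        )
    if min_points < 1:
        raise ValueError("min_points must be >= 1")
    R = reference.release_pct
    T = test.release_pct
    if truncate_after_85:
        keep = len(R)
        for i, r in enumerate(R):
            if r > 85.0:
                keep = i + 1
                break
        R, T = R[:keep], T[:keep]
    n = len(R)
    if n < min_points:
        raise ValueError(f"only {n} shared time points, need >= {min_points}")
    sq = tuple((r - t) ** 2 for r, t in zip(R, T))
    msd = sum(sq) / n
    f2 = 50.0 * math.log10(100.0 / math.sqrt(1.0 + msd))
    return SimilarityResult(f2=f2, n=n, per_time_sq_diff=sq)
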
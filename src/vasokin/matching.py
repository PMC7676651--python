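"""Optimal 1:1 matching of patients across groups by risk score.

Mirrors matching on a one-dimensional pre-operative risk score
(EuroSCORE II estimated % mortality): select k patients per group so
that the total absolute score difference over the k pairs is minimal.
Because an optimal matching on a single dimension never crosses (an
exchange argument on |a - b| + |c - d|), the optimum is found exactly by
dynamic programming over the two score-sorted lists in O(n1 * n2 * k);
ties in score order are broken by patient id for determinism.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import InfeasibleMatchError, ValidationError

__all__ = ["MatchResult", "match_by_score"]


@dataclass
class MatchResult:
    pairs: list[tuple[str, str, float]]  # (group1_id, group2_id, |score diff|)
    k: int
    total_distance: float
    caliper: float | None


def match_by_score(
    scores1: dict[str, float],
    scores2: dict[str, float],
    k: int,
    caliper: float | None = None,
) -> MatchResult:
    """Minimum-total-distance k-pair matching between two score lists.

    ``caliper``, if given, is the maximum allowed |score difference| of
    any pair; when no k-pair matching satisfies it, an
    :class:`InfeasibleMatchError` reports the largest feasible k.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    if k > min(len(scores1), len(scores2)):
        raise ValidationError(
            f"k={k} exceeds the smaller group size {min(len(scores1), len(scores2))}"
        )
    if caliper is not None and caliper < 0:
        raise ValidationError("caliper must be >= 0")

    a = sorted(scores1.items(), key=lambda kv: (kv[1], kv[0]))
    b = sorted(scores2.items(), key=lambda kv: (kv[1], kv[0]))
    n1, n2 = len(a), len(b)
    inf = math.inf

    def dist(i: int, j: int) -> float:
        d = abs(a[i][1] - b[j][1])
        return d if caliper is None or d <= caliper else inf

    # dp[i][j][t]: min cost of t pairs using the first i of a, j of b
    dp = [[[0.0] + [inf] * k for _ in range(n2 + 1)] for _ in range(n1 + 1)]
    for i in range(1, n1 + 1):
        for j in range(1, n2 + 1):
            cell = dp[i][j]
            up, left, diag = dp[i - 1][j], dp[i][j - 1], dp[i - 1][j - 1]
            d = dist(i - 1, j - 1)
            for t in range(1, k + 1):
                best = up[t] if up[t] < left[t] else left[t]
                if diag[t - 1] + d < best:
                    best = diag[t - 1] + d
                cell[t] = best

    if not math.isfinite(dp[n1][n2][k]):
        max_t = max(t for t in range(k + 1) if math.isfinite(dp[n1][n2][t]))
        raise InfeasibleMatchError(k, max_t)

    pairs: list[tuple[str, str, float]] = []
    i, j, t = n1, n2, k
    while t > 0:
        if i > 0 and dp[i][j][t] == dp[i - 1][j][t]:
            i -= 1
        elif j > 0 and dp[i][j][t] == dp[i][j - 1][t]:
            j -= 1
        else:
            d = dist(i - 1, j - 1)
            pairs.append((a[i - 1][0], b[j - 1][0], abs(a[i - 1][1] - b[j - 1][1])))
            i, j, t = i - 1, j - 1, t - 1
    pairs.sort(key=lambda p: (p[2], p[0], p[1]))
    total = sum(p[2] for p in pairs)
    return MatchResult(pairs=pairs, k=k, total_distance=total, caliper=caliper)
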
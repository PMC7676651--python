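"""Effect sizes and simulation-based power analysis.

Cohen's d is the standardized mean difference of the per-group log
fold-change distributions, (mean1 - mean2) / pooled SD, with the pooled
SD weighted by degrees of freedom.  Power is estimated by simulating
two-group normal data at a given d (unit SD, mean separation d) and
counting two-sided rejections; the noncentral-t closed form is provided
as an analytic check for the t-test variant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import ValidationError
from .stats import _u_counts

__all__ = [
    "pooled_sd",
    "EffectSize",
    "cohen_d",
    "PowerResult",
    "simulate_power",
    "analytic_power_t",
    "effect_size_table",
]


def pooled_sd(sd1: float, sd2: float, n1: int, n2: int) -> float:
    """Degrees-of-freedom-weighted pooled standard deviation."""
    if n1 < 2 or n2 < 2:
        raise ValidationError("pooled SD needs n >= 2 in both groups")
    if sd1 <= 0 or sd2 <= 0:
        raise ValidationError("group SDs must be > 0")
    return math.sqrt(((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2))


@dataclass
class EffectSize:
    mean1: float
    mean2: float
    sd1: float
    sd2: float
    n1: int
    n2: int
    pooled_sd: float
    d: float


def cohen_d(mean1, mean2, sd1, sd2, n1, n2) -> EffectSize:
    """Cohen's d = (mean1 - mean2) / pooled SD."""
    sp = pooled_sd(sd1, sd2, n1, n2)
    return EffectSize(mean1, mean2, sd1, sd2, n1, n2, sp, (mean1 - mean2) / sp)


@dataclass
class PowerResult:
    effect_size: float
    alpha: float
    n1: int
    n2: int
    reps: int
    test: str
    power: float
    mc_se: float
    seed: int


def _mw_two_sided_p_table(n1: int, n2: int) -> np.ndarray:
    """Exact two-sided Mann-Whitney p for each U value (tie-free)."""
    counts = np.array(_u_counts(n1, n2), dtype=float)
    total = counts.sum()
    cdf = np.cumsum(counts) / total
    sf = np.cumsum(counts[::-1])[::-1] / total
    return np.minimum(1.0, 2.0 * np.minimum(cdf, sf))


def simulate_power(
    d: float,
    n1: int,
    n2: int,
    alpha: float = 0.05,
    reps: int = 100,
    test: str = "t",
    seed: int = 0,
) -> PowerResult:
    """Monte-Carlo power of a two-sided two-group test at effect size d.

    Each replicate draws ``n1`` values from N(d, 1) and ``n2`` from
    N(0, 1) and applies the chosen test (``'t'`` pooled-variance t, or
    ``'mann-whitney'`` with its exact small-sample null).  Returns the
    rejection fraction and its binomial Monte-Carlo standard error.
    """
    if reps < 1:
        raise ValidationError("reps must be >= 1")
    if not 0 < alpha < 1:
        raise ValidationError("alpha must be in (0, 1)")
    if test not in ("t", "mann-whitney"):
        raise ValidationError(f"unknown test {test!r}; expected 't' or 'mann-whitney'")
    rng = np.random.default_rng(seed)
    x = rng.normal(d, 1.0, size=(reps, n1))
    y = rng.normal(0.0, 1.0, size=(reps, n2))

    if test == "t":
        mx, my = x.mean(axis=1), y.mean(axis=1)
        vx = x.var(axis=1, ddof=1)
        vy = y.var(axis=1, ddof=1)
        sp2 = ((n1 - 1) * vx + (n2 - 1) * vy) / (n1 + n2 - 2)
        t = (mx - my) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
        crit = sps.t.ppf(1 - alpha / 2, n1 + n2 - 2)
        reject = np.abs(t) > crit
    else:
        # U1 per replicate; continuous normals make ties a null event
        u1 = (x[:, :, None] > y[:, None, :]).sum(axis=(1, 2))
        p_table = _mw_two_sided_p_table(n1, n2)
        reject = p_table[u1] <= alpha

    power = float(np.mean(reject))
    mc_se = math.sqrt(power * (1 - power) / reps)
    return PowerResult(d, alpha, n1, n2, reps, test, power, mc_se, seed)


def analytic_power_t(d: float, n1: int, n2: int, alpha: float = 0.05) -> float:
    """Closed-form power of the two-sided pooled t-test via the noncentral t."""
    df = n1 + n2 - 2
    ncp = d * math.sqrt(n1 * n2 / (n1 + n2))
    crit = sps.t.ppf(1 - alpha / 2, df)
    return float(sps.nct.sf(crit, df, ncp) + sps.nct.cdf(-crit, df, ncp))


def effect_size_table(matrix, patients) -> "pd.DataFrame":
    """Per-(population, timepoint) group stats and Cohen's d from fold changes.

    Rows with fewer than two patients in either group are omitted (the
    pooled SD is undefined there).
    """
    import pandas as pd

    from .features import summarize_by_group

    summary = summarize_by_group(matrix, patients)
    rows = []
    for (pop, tp), sub in summary.groupby(["population", "timepoint"], sort=False):
        by_group = {r["group"]: r for _, r in sub.iterrows()}
        if "G1" not in by_group or "G2" not in by_group:
            continue
        g1, g2 = by_group["G1"], by_group["G2"]
        if g1["n"] < 2 or g2["n"] < 2:
            continue
        sd1 = g1["sem"] * math.sqrt(g1["n"])
        sd2 = g2["sem"] * math.sqrt(g2["n"])
        if sd1 <= 0 or sd2 <= 0:
            continue
        es = cohen_d(g1["mean_log_fc"], g2["mean_log_fc"], sd1, sd2, int(g1["n"]), int(g2["n"]))
        rows.append(
            {
                "population": pop,
                "timepoint": tp,
                "baseline": matrix.baseline,
                "mean_g1": es.mean1,
                "mean_g2": es.mean2,
                "sd_g1": es.sd1,
                "sd_g2": es.sd2,
                "n_g1": es.n1,
                "n_g2": es.n2,
                "pooled_sd": es.pooled_sd,
                "cohen_d": es.d,
            }
        )
    return pd.DataFrame(rows)
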
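"""Fold-change feature construction and vasoplegia group assignment.

The discriminative features of the analysis are per-patient natural-log
fold changes of progenitor counts against one of three baseline time
points: B1 (post-induction), B2 (sternotomy) or P0 (pump start).  Groups
are assigned from the total norepinephrine dose: at most 0.02 mg/kg is
clinically insignificant vasoplegia (G1), above it clinically significant
(G2); the boundary dose itself falls in G1 because G2 is defined strictly
by doses above the cutoff.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import DegenerateDataError, ValidationError
from .io import PatientRecord, baseline_for, records_from_frame
from .schema import NE_CUTOFF_MG_PER_KG, TIMEPOINTS

__all__ = [
    "assign_group",
    "log_fold_change",
    "FoldChangeMatrix",
    "build_fold_change_matrix",
    "summarize_by_group",
    "feature_vector",
]


def assign_group(ne_dose: float) -> str:
    """Vasoplegia group from total norepinephrine dose (mg/kg)."""
    if ne_dose < 0:
        raise ValidationError(f"ne_dose must be >= 0, got {ne_dose}")
    return "G1" if ne_dose <= NE_CUTOFF_MG_PER_KG else "G2"


def log_fold_change(count: float, baseline_count: float, pseudocount: float = 0.5) -> float:
    """Natural-log fold change of ``count`` over ``baseline_count``.

    The pseudocount is added to both counts, but only when either of them
    is zero; flow counts of zero are real observations, and this keeps
    nonzero ratios untouched.
    """
    if count < 0 or baseline_count < 0:
        raise ValidationError("counts must be non-negative")
    if count == 0 or baseline_count == 0:
        if pseudocount <= 0:
            raise DegenerateDataError(
                "log fold change undefined: zero count with pseudocount 0"
            )
        count += pseudocount
        baseline_count += pseudocount
    return math.log(count / baseline_count)


@dataclass
class FoldChangeMatrix:
    """Per-patient log fold changes against one baseline.

    ``entries`` has columns patient_id, population, timepoint, log_fc and
    contains every time point except the baseline's own (where the fold
    change would be identically zero).
    """

    baseline: str  # B1 | B2 | P0
    entries: pd.DataFrame


def build_fold_change_matrix(
    counts: pd.DataFrame, baseline: str, pseudocount: float = 0.5
) -> FoldChangeMatrix:
    baseline_tp = baseline_for(baseline)
    base = counts[counts["timepoint"] == baseline_tp].set_index(["patient_id", "population"])[
        "count"
    ]
    others = counts[counts["timepoint"] != baseline_tp]

    keys = others.set_index(["patient_id", "population"]).index
    missing = sorted({pid for pid, pop in keys if (pid, pop) not in base.index})
    if missing:
        raise ValidationError(
            f"missing {baseline} ({baseline_tp}) baseline counts for patients: "
            f"{', '.join(missing)}"
        )

    base_vals = base.loc[keys].to_numpy(dtype=float)
    vals = others["count"].to_numpy(dtype=float)
    log_fc = np.empty(len(vals))
    for i, (v, b) in enumerate(zip(vals, base_vals)):
        log_fc[i] = log_fold_change(v, b, pseudocount)
    entries = others[["patient_id", "population", "timepoint"]].copy()
    entries["log_fc"] = log_fc
    entries = entries.reset_index(drop=True)
    return FoldChangeMatrix(baseline=baseline, entries=entries)


def summarize_by_group(
    matrix: FoldChangeMatrix,
    patients: pd.DataFrame | Iterable[PatientRecord],
) -> pd.DataFrame:
    """Group mean +/- SEM of log fold change per (population, timepoint).

    SEM is the sample SD (ddof 1) over sqrt(n); a single-patient group
    gets SEM 0 with ``degenerate_n`` set, so toy inputs run end-to-end.
    """
    if isinstance(patients, pd.DataFrame):
        patients = records_from_frame(patients)
    groups = {p.patient_id: p.group for p in patients}
    unknown = sorted(set(matrix.entries["patient_id"]) - set(groups))
    if unknown:
        raise ValidationError(f"patients absent from patient table: {', '.join(unknown)}")
    unassigned = sorted(
        pid for pid in set(matrix.entries["patient_id"]) if groups[pid] is None
    )
    if unassigned:
        raise ValidationError(f"patients without assigned group: {', '.join(unassigned)}")

    df = matrix.entries.copy()
    df["group"] = df["patient_id"].map(groups)
    rows = []
    for (group, pop, tp), sub in df.groupby(
        ["group", "population", "timepoint"], sort=True
    ):
        vals = sub["log_fc"].to_numpy()
        n = len(vals)
        mean = float(np.mean(vals))
        sem = float(np.std(vals, ddof=1) / math.sqrt(n)) if n > 1 else 0.0
        rows.append(
            {
                "group": group,
                "population": pop,
                "timepoint": tp,
                "baseline": matrix.baseline,
                "n": n,
                "mean_log_fc": mean,
                "sem": sem,
                "degenerate_n": n == 1,
            }
        )
    out = pd.DataFrame(rows)
    tp_order = {tp: i for i, tp in enumerate(TIMEPOINTS)}
    out = out.sort_values(
        ["group", "population", "timepoint"],
        key=lambda s: s.map(tp_order) if s.name == "timepoint" else s,
        kind="stable",
    ).reset_index(drop=True)
    return out


def feature_vector(
    matrix: FoldChangeMatrix, population: str, timepoint: str
) -> pd.Series:
    """One (population, timepoint) fold-change feature indexed by patient."""
    sub = matrix.entries[
        (matrix.entries["population"] == population)
        & (matrix.entries["timepoint"] == timepoint)
    ]
    if sub.empty:
        raise ValidationError(
            f"no fold-change entries for population {population!r} at "
            f"timepoint {timepoint!r} (baseline {matrix.baseline})"
        )
    return sub.set_index("patient_id")["log_fc"].sort_index()
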
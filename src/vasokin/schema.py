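"""Shared vocabulary for the cohort tables.

Counts are expressed as cells per 10^6 lympho-monocytic flow-cytometry
events.  Six time points span the peri-operative window: after induction
of anesthesia, at sternotomy, and at 0, 1, 6 and 24 hours relative to the
start of cardiopulmonary bypass.  Fold changes are computed against three
reference time points: B1 (post-induction), B2 (sternotomy) and P0 (pump
start, 0 h).
"""

from __future__ import annotations

#: Ordered peri-operative sampling time points.
TIMEPOINTS: tuple[str, ...] = (
    "PostInduction",
    "Sternotomy",
    "H0",
    "H1",
    "H6",
    "H24",
)

#: Progenitor-cell populations gated from the lympho-monocytic events.
POPULATIONS: tuple[str, ...] = (
    "CD34",
    "CD133",
    "VEGFR2",
    "HSC",          # CD34+CD133+
    "EPC",          # CD34+VEGFR2+
    "CD133VEGFR2",  # CD133+VEGFR2+
)

#: Fold-change baselines and the time point each refers to.
BASELINES: dict[str, str] = {
    "B1": "PostInduction",
    "B2": "Sternotomy",
    "P0": "H0",
}

#: Total norepinephrine dose (mg/kg) separating clinically insignificant
#: (G1, dose <= cutoff) from clinically significant (G2, dose > cutoff)
#: vasoplegia.
NE_CUTOFF_MG_PER_KG: float = 0.02

GROUPS: tuple[str, str] = ("G1", "G2")
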
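"""Permeate classification from retention and permeation.

Compounds are assigned to the classical silicone/IPM-membrane permeate
groups using the compound-level (triplicate-mean) retention factor R and
permeation parameter C_A(t)/C_D(0):

* group I   — low retention and low permeation (both < 30%);
* group II  — low retention, high permeation (≥ 30%);
* group III — high retention (≥ 30%), low permeation: the membrane acts as
  a trap, the profile desired of a topical corticosteroid prodrug;
* UNDEFINED — high retention and high permeation, a cell the taxonomy does
  not name; labelling it explicitly avoids silent misclassification.

The −6 log Kp cutoff that originally motivated the groups is carried as an
annotation only: assignment here uses the (R, perm) thresholds alone, which
is what reproduces the published group memberships.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd

from .plate_model import CompoundSummary

__all__ = [
    "ClassificationRule",
    "classify",
    "classify_summaries",
    "summarize_groups",
    "GROUP_ORDER",
]

GROUP_ORDER = ("I", "II", "III", "UNDEFINED")


@dataclass(frozen=True)
class ClassificationRule:
    """Thresholds of the group I/II/III partition.

    ``logkp_cutoff`` is reported alongside results but plays no part in the
    default group assignment.
    """

    retention_threshold: float = 0.30
    permeation_threshold: float = 0.30
    logkp_cutoff: float = -6.0

    def __post_init__(self) -> None:
        for name in ("retention_threshold", "permeation_threshold"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1)")


def classify(
    R_mean: float,
    perm_mean: float,
    rule: ClassificationRule | None = None,
) -> str:
    """Assign a group label from mean retention and mean permeation.

    Boundary values (exactly at a threshold) go to the high side.
    """
    if rule is None:
        rule = ClassificationRule()
    if not 0 <= R_mean <= 1 or not 0 <= perm_mean <= 1:
        raise ValueError("R_mean and perm_mean must lie in [0, 1]")
    high_r = R_mean >= rule.retention_threshold
    high_p = perm_mean >= rule.permeation_threshold
    if high_r:
        return "UNDEFINED" if high_p else "III"
    return "II" if high_p else "I"


def classify_summaries(
    summaries: Sequence[CompoundSummary],
    rule: ClassificationRule | None = None,
) -> list[CompoundSummary]:
    """Set ``group`` on each summary in place (and return the list)."""
    for s in summaries:
        s.group = classify(s.R_mean, s.perm_mean, rule)
    return list(summaries)


def summarize_groups(
    summaries: Sequence[CompoundSummary],
    subset: Optional[Iterable[str]] = None,
) -> pd.DataFrame:
    """Per-group counts and (min, max) ranges of R and permeation.

    Parameters
    ----------
    summaries : sequence of CompoundSummary
        Classified summaries (``group`` must be set).
    subset : iterable of str, optional
        Restrict to these compound ids.

    Returns
    -------
    pandas.DataFrame
        One row per group in the fixed order I, II, III, UNDEFINED, with
        columns ``group, count, R_min, R_max, perm_min, perm_max`` (fractions;
        range columns are NaN for empty groups).
    """
    if subset is not None:
        wanted = set(subset)
        summaries = [s for s in summaries if s.compound_id in wanted]
    for s in summaries:
        if s.group is None:
            raise ValueError(
                f"{s.compound_id} is unclassified; run classify first")
    rows = []
    for group in GROUP_ORDER:
        members = [s for s in summaries if s.group == group]
        rs = [s.R_mean for s in members]
        ps = [s.perm_mean for s in members]
        rows.append({
            "group": group,
            "count": len(members),
            "R_min": min(rs) if rs else float("nan"),
            "R_max": max(rs) if rs else float("nan"),
            "perm_min": min(ps) if ps else float("nan"),
            "perm_max": max(ps) if ps else float("nan"),
        })
    return pd.DataFrame(rows)
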
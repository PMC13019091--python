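"""Weighted platelet aggregation (WPA) score.

The WPA statistic summarises a single imaging-flow-cytometry measurement of
platelet complexes.  Each acquired event is classified as a singlet, doublet,
triplet or multiplet (>= 4 platelets) and weighted by the number of platelets
it contains.  With per-class event counts ``m1..m4`` and total event count
``N = m1 + m2 + m3 + m4``::

    WPA = ((1*m1 + 2*m2 + 3*m3 + 4*m4) / N - 1) * 100   [percent]

Subtracting the singlet baseline of 1 anchors a pure-singlet measurement at
0 %; a measurement of exclusively multiplets attains the maximum of 300 %.
The multiplet weight is fixed at 4 regardless of the true aggregate size,
which is what bounds the score at 300 %.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ClassCounts",
    "MeasurementSummary",
    "CLASS_WEIGHTS",
    "compute_wpa",
    "summarize_measurement",
]

#: platelets contained per class (singlet, doublet, triplet, multiplet)
CLASS_WEIGHTS = (1, 2, 3, 4)


class UndefinedScoreError(ValueError):
    """Raised when WPA is requested for a measurement with zero events."""


@dataclass(frozen=True)
class ClassCounts:
    """Per-measurement event counts for the four aggregation classes."""

    m1: int
    m2: int
    m3: int
    m4: int

    def __post_init__(self) -> None:
        for name in ("m1", "m2", "m3", "m4"):
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def N(self) -> int:
        """Total number of platelet-complex events."""
        return self.m1 + self.m2 + self.m3 + self.m4

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.m1, self.m2, self.m3, self.m4)

    @classmethod
    def from_labels(cls, labels) -> "ClassCounts":
        """Tally per-event class labels (values in {1, 2, 3, 4})."""
        arr = np.asarray(labels, dtype=int)
        if arr.size and (arr.min() < 1 or arr.max() > 4):
            raise ValueError("class labels must lie in {1, 2, 3, 4}")
        counts = np.bincount(arr, minlength=5)[1:5]
        return cls(*(int(c) for c in counts))


def compute_wpa(counts: ClassCounts | tuple[int, int, int, int]) -> float:
    """Weighted platelet aggregation of one measurement, in percent.

    Parameters
    ----------
    counts
        Per-class event counts ``(m1, m2, m3, m4)``.

    Returns
    -------
    float
        WPA in percent, in ``[0, 300]``.

    Raises
    ------
    UndefinedScoreError
        If the measurement contains no events (``N == 0``); the score is
        undefined there, not zero.
    """
    if not isinstance(counts, ClassCounts):
        counts = ClassCounts(*counts)
    n = counts.N
    if n == 0:
        raise UndefinedScoreError("WPA is undefined for a measurement with zero events")
    weighted = sum(w * m for w, m in zip(CLASS_WEIGHTS, counts.as_tuple()))
    return (weighted / n - 1.0) * 100.0


@dataclass
class MeasurementSummary:
    """Gated counts, WPA and marker intensities for one technical replicate."""

    donor_id: str
    condition: str
    replicate: int
    acquisition_date: str
    counts: ClassCounts
    wpa: float = field(init=False)
    cd42b_mfi: float = float("nan")
    cd62p_mfi: float = float("nan")

    def __post_init__(self) -> None:
        self.wpa = compute_wpa(self.counts)

    def as_row(self) -> dict:
        m1, m2, m3, m4 = self.counts.as_tuple()
        return {
            "donor_id": self.donor_id,
            "condition": self.condition,
            "replicate": self.replicate,
            "acquisition_date": self.acquisition_date,
            "m1": m1,
            "m2": m2,
            "m3": m3,
            "m4": m4,
            "N": self.counts.N,
            "wpa": self.wpa,
            "cd42b_mfi": self.cd42b_mfi,
            "cd62p_mfi": self.cd62p_mfi,
        }


def summarize_measurement(events: pd.DataFrame) -> MeasurementSummary:
    """Summarise the gated, classified events of one measurement.

    ``events`` must contain one measurement's rows with columns ``donor_id``,
    ``condition``, ``replicate``, ``acquisition_date``, ``class``,
    ``cd42b_mfi`` and ``cd62p_mfi``.  Class counts are tallied from the
    per-event labels, WPA computed from the counts, and marker MFIs taken as
    arithmetic means over events.
    """
    if len(events) == 0:
        raise UndefinedScoreError("cannot summarise a measurement with zero gated events")
    keys = events[["donor_id", "condition", "replicate"]].drop_duplicates()
    if len(keys) != 1:
        raise ValueError("summarize_measurement expects events of exactly one measurement")
    counts = ClassCounts.from_labels(events["class"].to_numpy())
    return MeasurementSummary(
        donor_id=str(events["donor_id"].iloc[0]),
        condition=str(events["condition"].iloc[0]),
        replicate=int(events["replicate"].iloc[0]),
        acquisition_date=str(events["acquisition_date"].iloc[0]),
        counts=counts,
        cd42b_mfi=float(events["cd42b_mfi"].mean()),
        cd62p_mfi=float(events["cd62p_mfi"].mean()),
    )


def summarize_cohort(events: pd.DataFrame) -> pd.DataFrame:
    """Per-measurement summaries for a whole classified event table."""
    rows = []
    group_cols = ["donor_id", "condition", "replicate"]
    for _, grp in events.groupby(group_cols, sort=True):
        rows.append(summarize_measurement(grp).as_row())
    out = pd.DataFrame(rows)
    # carry donor covariates through if present
    for col in ("age", "sex"):
        if col in events.columns:
            meta = events.groupby("donor_id", sort=True)[col].first()
            out[col] = out["donor_id"].map(meta)
    return out
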
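"""Two-stage prefiltering of cohort measurements.

Stage 1 — technical-replicate concordance: for every donor and condition the
two replicate WPA values must both lie within 70–130 % of the pair mean
(closed interval); any violation excludes the donor entirely.

Stage 2 — consistency across experimental days: per-acquisition-date mean
baseline WPA values (over donors surviving stage 1) are screened with the
ROUT outlier test at Q = 1 %.  By default all donors measured on a flagged
date are excluded; a per-donor mode is also provided.

The ROUT variant here is the published robust-fit + FDR procedure
specialised to a constant model (K = 1): the robust center is the median,
the robust scale (RSDR) the 68.27th percentile of absolute residuals scaled
by n/(n−K), and residuals are tested from most to least extreme against
two-tailed t-tail probabilities with n−K degrees of freedom at the stepwise
levels αᵢ = Q·(n−i+1)/n, stopping at the first non-significant one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["QCConfig", "QCReport", "replicate_concordance_filter", "rout_outliers", "apply_qc"]


@dataclass(frozen=True)
class QCConfig:
    band_lower: float = 0.70
    band_upper: float = 1.30
    rout_q: float = 0.01
    min_rout_group: int = 3
    rout_condition: str = "baseline"   # condition whose per-date mean WPA feeds stage 2
    date_mode: str = "whole_date"      # "whole_date" | "per_donor"

    def __post_init__(self) -> None:
        if not (0.0 < self.band_lower < 1.0 < self.band_upper):
            raise ValueError("require 0 < band_lower < 1 < band_upper")
        if not (0.0 <= self.rout_q < 1.0):
            raise ValueError("rout_q must lie in [0, 1)")
        if self.date_mode not in ("whole_date", "per_donor"):
            raise ValueError("date_mode must be 'whole_date' or 'per_donor'")


@dataclass
class QCReport:
    n_input_donors: int = 0
    stage1_excluded: dict = field(default_factory=dict)   # donor -> offending (condition, values)
    incomplete: list = field(default_factory=list)        # donors with a missing replicate
    stage2_flagged_dates: list = field(default_factory=list)
    stage2_excluded: list = field(default_factory=list)
    retained: list = field(default_factory=list)

    @property
    def n_excluded(self) -> int:
        return len(self.stage1_excluded) + len(self.incomplete) + len(self.stage2_excluded)

    def as_dict(self) -> dict:
        d = asdict(self)
        d["n_excluded"] = self.n_excluded
        return d


def replicate_concordance_filter(summaries: pd.DataFrame, config: QCConfig | None = None
                                 ) -> tuple[set, QCReport]:
    """Stage 1: flag donors whose replicate WPA pair breaks the 70–130 % band.

    ``summaries`` is the per-measurement table (one row per donor ×
    condition × replicate with a ``wpa`` column).  A replicate exactly at
    the band edge is kept (closed interval).  Donors with a missing
    replicate in any condition are excluded and counted separately.
    """
    if config is None:
        config = QCConfig()
    report = QCReport(n_input_donors=summaries["donor_id"].nunique())
    for (donor, condition), grp in summaries.groupby(["donor_id", "condition"], sort=True):
        values = grp["wpa"].to_numpy(dtype=float)
        if len(values) != 2:
            if donor not in report.incomplete:
                report.incomplete.append(donor)
            continue
        mean = values.mean()
        lo, hi = config.band_lower * mean, config.band_upper * mean
        if np.any(values < lo) or np.any(values > hi):
            report.stage1_excluded.setdefault(donor, []).append(
                {"condition": condition, "replicates": values.tolist(), "pair_mean": mean})
    excluded = set(report.stage1_excluded) | set(report.incomplete)
    return excluded, report


def rout_outliers(values, q: float = 0.01, k: int = 1,
                  min_group: int = 3) -> np.ndarray:
    """Boolean outlier flags for a value vector under the constant-model ROUT test.

    Returns all-False (with a warning) when fewer than ``min_group`` values
    are supplied, and all-False when ``q <= 0`` (an empty FDR budget flags
    nothing).
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    flags = np.zeros(n, dtype=bool)
    if q <= 0:
        return flags
    if n < min_group:
        warnings.warn(f"ROUT needs at least {min_group} values; got {n}; no outliers flagged",
                      stacklevel=2)
        return flags

    center = np.median(values)
    residuals = values - center
    abs_res = np.abs(residuals)
    p6827 = np.percentile(abs_res, 68.27)
    rsdr = p6827 * n / (n - k)
    if rsdr <= 0:
        return flags

    order = np.argsort(-abs_res)  # most extreme first
    df = n - k
    for i, idx in enumerate(order, start=1):
        alpha_i = q * (n - i + 1) / n
        t_stat = abs_res[idx] / rsdr
        p = 2.0 * stats.t.sf(t_stat, df)
        if p < alpha_i:
            flags[idx] = True
        else:
            break
    return flags


def apply_qc(summaries: pd.DataFrame, config: QCConfig | None = None
             ) -> tuple[pd.DataFrame, QCReport]:
    """Run both QC stages on a per-measurement summary table.

    Stage 1 removes replicate-discordant (and incomplete) donors; stage 2
    computes the per-acquisition-date mean of the reference-condition WPA
    over the survivors and applies ROUT.  The returned table carries a
    ``qc_pass`` column; the report enumerates every exclusion with its cause.
    Donors excluded at stage 1 are not re-tested at stage 2.
    """
    if config is None:
        config = QCConfig()
    stage1_excluded, report = replicate_concordance_filter(summaries, config)

    survivors = summaries[~summaries["donor_id"].isin(stage1_excluded)]
    ref = survivors[survivors["condition"] == config.rout_condition]
    if len(ref) == 0:
        ref = survivors  # reference condition absent: fall back to everything

    date_means = ref.groupby("acquisition_date", sort=True)["wpa"].mean()
    flags = rout_outliers(date_means.to_numpy(), q=config.rout_q,
                          min_group=config.min_rout_group)
    flagged_dates = set(date_means.index[flags])
    report.stage2_flagged_dates = sorted(flagged_dates)

    if config.date_mode == "whole_date":
        stage2_donors = set(survivors.loc[
            survivors["acquisition_date"].isin(flagged_dates), "donor_id"])
    else:
        # per-donor mode: within flagged dates, drop only donors whose own
        # reference WPA mean is itself a ROUT outlier among that date's donors
        stage2_donors = set()
        for date in flagged_dates:
            donors_wpa = ref[ref["acquisition_date"] == date].groupby("donor_id")["wpa"].mean()
            dflags = rout_outliers(donors_wpa.to_numpy(), q=config.rout_q,
                                   min_group=config.min_rout_group)
            stage2_donors |= set(donors_wpa.index[dflags])
            if not dflags.any():
                stage2_donors |= set(donors_wpa.index)  # whole date after all
    report.stage2_excluded = sorted(stage2_donors)

    excluded_all = stage1_excluded | stage2_donors
    out = summaries.copy()
    out["qc_pass"] = ~out["donor_id"].isin(excluded_all)
    report.retained = sorted(set(out.loc[out["qc_pass"], "donor_id"]))
    return out, report
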
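import numpy as np
import pandas as pd
import pytest

from wpaflow.qc import (QCConfig, apply_qc, replicate_concordance_filter,
                        rout_outliers)


def _summaries(rows):
    return pd.DataFrame(rows, columns=["donor_id", "condition", "replicate",
                                       "acquisition_date", "wpa"])


def _pair(donor, wpa1, wpa2, date="2024-01-08", condition="baseline"):
    return [(donor, condition, 1, date, wpa1), (donor, condition, 2, date, wpa2)]


# ----------------------------------------------------- replicate concordance

@pytest.mark.parametrize("pair,excluded", [
    ((2.0, 4.0), True),    # 2.0/3.0 = 66.7 % of mean, below the band
    ((3.0, 3.0), False),   # both at 100 % of mean
    ((2.1, 3.9), False),   # 2.1/3.0 = 70 % exactly: inclusive boundary, kept
])
def test_concordance_band(pair, excluded):
    df = _summaries(_pair("D001", *pair))
    bad, report = replicate_concordance_filter(df, QCConfig())
    assert ("D001" in bad) is excluded


def test_any_discordant_condition_excludes_whole_donor():
    rows = _pair("D001", 3.0, 3.0, condition="baseline") + \
           _pair("D001", 2.0, 4.0, condition="ADP")
    bad, report = replicate_concordance_filter(_summaries(rows), QCConfig())
    assert "D001" in bad
    assert report.stage1_excluded["D001"][0]["condition"] == "ADP"


def test_missing_replicate_counted_separately():
    rows = _pair("D001", 3.0, 3.0) + [("D002", "baseline", 1, "2024-01-08", 2.5)]
    bad, report = replicate_concordance_filter(_summaries(rows), QCConfig())
    assert "D002" in bad and report.incomplete == ["D002"]
    assert "D002" not in report.stage1_excluded


def test_widening_band_never_excludes_more():
    rng = np.random.default_rng(0)
    rows = []
    for i in range(40):
        base = rng.uniform(1, 4)
        rows += _pair(f"D{i:03d}", base, base * rng.uniform(0.5, 1.5))
    df = _summaries(rows)
    n_narrow = len(replicate_concordance_filter(df, QCConfig(0.80, 1.20))[0])
    n_default = len(replicate_concordance_filter(df, QCConfig(0.70, 1.30))[0])
    n_wide = len(replicate_concordance_filter(df, QCConfig(0.50, 1.50))[0])
    assert n_narrow >= n_default >= n_wide


# ------------------------------------------------------------------- ROUT

def test_constant_vector_has_no_outliers():
    assert not rout_outliers([5.0, 5.0, 5.0, 5.0, 5.0]).any()


def test_single_gross_outlier_is_flagged():
    flags = rout_outliers([2.0, 2.1, 1.9, 2.05, 10.0], q=0.01)
    np.testing.assert_array_equal(flags, [False, False, False, False, True])


def test_hand_computed_rout_example():
    """Step-by-step check of the constant-model procedure on the vector
    (2.0, 2.1, 1.9, 2.05, 10.0): median 2.05, |residuals| (.05,.05,.15,0,7.95),
    RSDR = percentile(|r|, 68.27) * 5/4, then the stepwise FDR walk flags
    only the 10.0 (its t-tail is far below alpha_1 = Q) and stops at the
    next residual (p ~ 0.38 > alpha_2 = 0.008)."""
    from scipy import stats

    values = np.array([2.0, 2.1, 1.9, 2.05, 10.0])
    abs_res = np.abs(values - np.median(values))
    rsdr = np.percentile(abs_res, 68.27) * 5 / 4
    p_extreme = 2 * stats.t.sf(abs_res.max() / rsdr, 4)
    p_next = 2 * stats.t.sf(np.sort(abs_res)[-2] / rsdr, 4)
    assert p_extreme < 0.01 * 5 / 5          # flagged at alpha_1
    assert p_next > 0.01 * 4 / 5             # walk stops: nothing else flagged
    np.testing.assert_array_equal(rout_outliers(values, q=0.01),
                                  abs_res == abs_res.max())


def test_zero_q_flags_nothing():
    assert not rout_outliers([1.0, 2.0, 100.0], q=0.0).any()


def test_small_group_warns_and_flags_nothing():
    with pytest.warns(UserWarning):
        flags = rout_outliers([1.0, 100.0], q=0.01)
    assert not flags.any()


def test_increasing_q_never_flags_fewer():
    rng = np.random.default_rng(3)
    values = np.concatenate([rng.normal(2, 0.1, 20), [5.0, 8.0]])
    counts = [rout_outliers(values, q=q).sum() for q in (0.001, 0.01, 0.05, 0.2)]
    assert counts == sorted(counts)


# ------------------------------------------------------------------ apply_qc

def _clean_cohort(n_donors=24, n_dates=4, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_donors):
        date = f"2024-01-{8 + i % n_dates:02d}"
        for condition in ("baseline", "ADP"):
            center = 2.5 if condition == "baseline" else 8.0
            w = center + rng.normal(0, 0.05)
            rows += _pair(f"D{i:03d}", w, w + rng.normal(0, 0.02),
                          date=date, condition=condition)
    return _summaries(rows)


def test_clean_tight_cohort_fully_retained():
    filtered, report = apply_qc(_clean_cohort(), QCConfig())
    assert filtered["qc_pass"].all()
    assert report.n_excluded == 0


def test_planted_date_shift_is_caught_by_rout():
    df = _clean_cohort(n_donors=24, n_dates=6)
    shifted = df["acquisition_date"] == "2024-01-09"
    df.loc[shifted & (df["condition"] == "baseline"), "wpa"] += 5.0  # ~+10 SD of date means
    filtered, report = apply_qc(df, QCConfig())
    assert report.stage2_flagged_dates == ["2024-01-09"]
    excluded_donors = set(df.loc[shifted, "donor_id"])
    assert set(report.stage2_excluded) == excluded_donors
    clean = ~filtered["donor_id"].isin(excluded_donors)
    assert filtered.loc[clean, "qc_pass"].all()


def test_apply_qc_is_idempotent():
    df = _clean_cohort(n_donors=20, n_dates=5, seed=7)
    df.loc[(df["donor_id"] == "D003") & (df["replicate"] == 2), "wpa"] *= 3.0
    once, report1 = apply_qc(df, QCConfig())
    kept = once[once["qc_pass"]].drop(columns="qc_pass")
    twice, report2 = apply_qc(kept, QCConfig())
    assert report2.n_excluded == 0
    assert twice["qc_pass"].all()


def test_stage1_exclusions_are_not_retested_at_stage2():
    df = _clean_cohort(n_donors=12, n_dates=3)
    df.loc[(df["donor_id"] == "D000") & (df["replicate"] == 1), "wpa"] = 50.0
    _, report = apply_qc(df, QCConfig())
    assert "D000" in report.stage1_excluded
    assert "D000" not in report.stage2_excluded


def test_qc_config_validation():
    with pytest.raises(ValueError):
        QCConfig(band_lower=1.1)
    with pytest.raises(ValueError):
        QCConfig(rout_q=1.5)
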
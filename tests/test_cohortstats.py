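from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from wpaflow.cohortstats import (age_regression, condition_response, contrast,
                                 median_ci)
from wpaflow.synthcyto import CohortConfig, simulate_cohort
from wpaflow.wpa import compute_wpa


# ------------------------------------------------------------------ contrast

def test_mannwhitney_fully_separated_small_groups():
    res = contrast([1, 2, 3], [4, 5, 6], mode="mannwhitney")
    assert res.statistic == 0.0
    assert res.p_value == pytest.approx(0.1)  # 2 of the 20 rank assignments


def test_identical_groups_give_p_one():
    res = contrast([2.0, 2.0, 2.0], [2.0, 2.0, 2.0], mode="mannwhitney")
    assert res.estimate == 0.0
    assert res.p_value == 1.0


def test_welch_equal_means_unequal_variances():
    a = np.array([1.0, 2.0, 3.0])              # mean 2
    b = np.array([-4.0, 2.0, 8.0])             # mean 2, much larger variance
    res = contrast(a, b, mode="welch")
    assert res.statistic == pytest.approx(0.0, abs=1e-12)
    assert res.p_value == pytest.approx(1.0)


def test_auto_mode_picks_mannwhitney_for_skewed_data(rng):
    normal = rng.normal(10, 1, 30)
    skewed = np.exp(rng.normal(2, 1.5, 30))
    assert contrast(normal, normal + 0.1, mode="auto").test == "welch_t"
    assert contrast(normal, skewed, mode="auto").test == "mannwhitney"


def test_small_groups_rejected():
    with pytest.raises(ValueError):
        contrast([1, 2], [3, 4, 5])


def _exact_mw_p_by_enumeration(a, b):
    """Independent oracle: full enumeration over group assignments."""
    from scipy.stats import rankdata

    pooled = np.concatenate([a, b])
    n1 = len(a)
    ranks = rankdata(pooled)
    mu = n1 * len(b) / 2.0
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    hits = total = 0
    for idx in combinations(range(len(pooled)), n1):
        u = ranks[list(idx)].sum() - n1 * (n1 + 1) / 2
        hits += abs(u - mu) >= abs(u_obs - mu) - 1e-12
        total += 1
    return hits / total


@pytest.mark.parametrize("seed", range(6))
def test_mannwhitney_exact_matches_enumeration(seed):
    rng = np.random.default_rng(seed)
    a = rng.normal(0, 1, rng.integers(3, 6))
    b = rng.normal(0.5, 1, rng.integers(3, 6))
    res = contrast(a, b, mode="mannwhitney")
    assert res.p_value == pytest.approx(_exact_mw_p_by_enumeration(a, b), abs=1e-12)


def test_median_ci_brackets_median(rng):
    x = rng.normal(5, 1, 81)
    lo, hi = median_ci(x)
    assert lo <= np.median(x) <= hi


# ---------------------------------------------------------------- regression

def test_exact_line_recovered():
    x = np.array([20.0, 30.0, 40.0, 50.0, 60.0])
    res = age_regression(x, 2 * x + 1)
    assert res.estimate == pytest.approx(2.0, abs=1e-12)
    assert res.r_squared == pytest.approx(1.0, abs=1e-12)
    assert res.p_value < 1e-6
    assert res.extra["intercept"] == pytest.approx(1.0, abs=1e-10)


def test_regression_agrees_with_normal_equations(rng):
    x = rng.uniform(18, 70, 50)
    y = 0.03 * x + rng.normal(0, 0.5, 50)
    res = age_regression(x, y)
    xc = x - x.mean()
    slope = np.dot(xc, y - y.mean()) / np.dot(xc, xc)
    r2 = np.corrcoef(x, y)[0, 1] ** 2
    assert res.estimate == pytest.approx(slope, abs=1e-10)
    assert res.r_squared == pytest.approx(r2, abs=1e-10)


def test_zero_age_variance_rejected():
    with pytest.raises(ValueError):
        age_regression([40, 40, 40], [1, 2, 3])


def test_null_rejection_rate_is_calibrated():
    """Type-I error: with no planted effect, the age regression rejects at
    alpha = 0.05 at its nominal rate (binomial 3-sigma band, 600 trials)."""
    rejections = 0
    n_trials = 600
    for seed in range(n_trials):
        rng = np.random.default_rng(seed)
        ages = rng.uniform(18, 70, 40)
        outcome = rng.normal(2.5, 0.8, 40)
        rejections += age_regression(ages, outcome).p_value < 0.05
    rate = rejections / n_trials
    sigma = np.sqrt(0.05 * 0.95 / n_trials)
    assert abs(rate - 0.05) < 3 * sigma


def test_planted_male_age_slope_recovered_by_stratum():
    """A male-only per-year increase in aggregate means shows up as a
    positive triplet-count slope in the male stratum and ~zero in the
    female stratum (sign recovery over 20 seeds)."""
    male_pos = 0
    female_slopes, male_slopes = [], []
    for seed in range(20):
        config = CohortConfig(n_donors=48, events_per_measurement=8610,
                              inter_donor_dispersion=0.01, male_age_slope=0.03,
                              coincidence_fraction=0.0, seed=seed)
        _, truth, donors = simulate_cohort(config, conditions=("baseline",),
                                           n_replicates=1, counts_only=True)
        male = truth[truth["sex"] == "M"]
        female = truth[truth["sex"] == "F"]
        sm = age_regression(male["age"], male["true_m3"], stratum="male")
        sf = age_regression(female["age"], female["true_m3"], stratum="female")
        male_pos += sm.estimate > 0
        male_slopes.append(sm.estimate)
        female_slopes.append(sf.estimate)
    assert male_pos >= 18  # positive male slope in >= 90 % of seeds
    assert abs(np.mean(female_slopes)) < 0.2 * np.mean(male_slopes)


# -------------------------------------------------------- condition response

def _zero_dispersion_summaries():
    config = CohortConfig(n_donors=6, baseline_class_means=(8400, 200, 10, 0),
                          events_per_measurement=8610, inter_donor_dispersion=0.0,
                          coincidence_fraction=0.0)
    _, truth, _ = simulate_cohort(config, counts_only=True)
    truth = truth.rename(columns={f"true_m{k}": f"m{k}" for k in range(1, 5)})
    truth["N"] = truth[["m1", "m2", "m3", "m4"]].sum(axis=1)
    truth["wpa"] = [compute_wpa((r.m1, r.m2, r.m3, r.m4)) for r in truth.itertuples()]
    return truth


def test_fold_changes_flow_through_pipeline_exactly():
    out = condition_response(_zero_dispersion_summaries())
    assert out["fold_change"]["m2"] == pytest.approx(2.5)
    assert out["fold_change"]["m3"] == pytest.approx(7.0)
    assert np.isnan(out["fold_change"]["m4"])  # baseline multiplet mean is 0


def test_no_stimulation_effect_gives_unit_folds():
    df = _zero_dispersion_summaries()
    base = df[df["condition"] == "baseline"].copy()
    fake_adp = base.copy()
    fake_adp["condition"] = "ADP"
    out = condition_response(pd.concat([base, fake_adp], ignore_index=True))
    for col in ("m1", "m2", "m3", "wpa"):
        assert out["fold_change"][col] == pytest.approx(1.0)


def test_wpa_fold_change_matches_closed_form():
    df = _zero_dispersion_summaries()
    out = condition_response(df)
    wb = df[df["condition"] == "baseline"]["wpa"].iloc[0]
    wa = df[df["condition"] == "ADP"]["wpa"].iloc[0]
    assert out["fold_change"]["wpa"] == pytest.approx(wa / wb)
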
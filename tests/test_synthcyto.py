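import dataclasses

import numpy as np
import pytest

from wpaflow.synthcyto import (CohortConfig, ConfigurationError, RenderParams,
                               adp_class_means, render_background_event,
                               render_event, simulate_cohort,
                               simulate_measurement, substream, wpa_of_probs,
                               _make_donor)


# ------------------------------------------------------------------ rendering

def test_singlet_renders_one_connected_cd42b_region(noiseless_params):
    from scipy.ndimage import label

    img = render_event(1, noiseless_params, np.random.default_rng(0))
    n_regions = label(img.cd42b > 0.1 * img.cd42b.max())[1]
    assert n_regions == 1
    assert img.annotation.n_platelets == 1


@pytest.mark.parametrize("n", [1, 2, 3, 4, 6])
def test_annotation_lists_exactly_n_centers(n, noiseless_params):
    img = render_event(n, noiseless_params, np.random.default_rng(n))
    assert img.annotation.n_platelets == n
    assert len(img.annotation.centers) == n


def test_cd42b_positive_over_every_platelet_footprint(noiseless_params):
    img = render_event(3, noiseless_params, np.random.default_rng(5))
    for cy, cx in img.annotation.centers:
        assert img.cd42b[int(round(cy)), int(round(cx))] > 0


def test_render_is_seed_deterministic():
    a = render_event(4, RenderParams(), np.random.default_rng(7))
    b = render_event(4, RenderParams(), np.random.default_rng(7))
    np.testing.assert_array_equal(a.cd42b, b.cd42b)
    np.testing.assert_array_equal(a.brightfield, b.brightfield)


def test_channels_share_dimensions_and_nonnegative():
    img = render_event(2, RenderParams(), np.random.default_rng(3))
    assert img.brightfield.shape == img.cd42b.shape == img.cd62p.shape
    for chan in (img.brightfield, img.cd42b, img.cd62p):
        assert (chan >= 0).all()


def test_invalid_render_params_rejected():
    with pytest.raises(ConfigurationError):
        RenderParams(image_size=0)
    with pytest.raises(ConfigurationError):
        RenderParams(platelet_diameter_um=(0.0, 3.0))
    with pytest.raises(ConfigurationError):
        render_event(0, RenderParams(), np.random.default_rng(0))


def test_erythrocyte_is_cd42b_negative(noiseless_params):
    img = render_background_event("erythrocyte", noiseless_params, np.random.default_rng(0))
    assert img.cd42b.max() == 0.0
    assert img.annotation.contains_erythrocyte


def test_coincidence_contains_platelet_and_flag(noiseless_params):
    img = render_background_event("coincidence", noiseless_params, np.random.default_rng(1))
    assert img.annotation.contains_erythrocyte
    assert img.annotation.n_platelets >= 1
    assert img.cd42b.max() > 0


def test_debris_is_reproducible():
    a = render_background_event("debris", RenderParams(), np.random.default_rng(2))
    b = render_background_event("debris", RenderParams(), np.random.default_rng(2))
    np.testing.assert_array_equal(a.brightfield, b.brightfield)


def test_unknown_background_kind_rejected():
    with pytest.raises(ConfigurationError):
        render_background_event("leukocyte", RenderParams(), np.random.default_rng(0))


# ------------------------------------------------------------- count model

def test_zero_dispersion_reproduces_class_means_exactly(small_cohort_config):
    donor = _make_donor(0, small_cohort_config)
    _, truth = simulate_measurement(donor, "baseline", 1, small_cohort_config)
    assert truth.class_counts.as_tuple() == (8400, 200, 10, 0)


def test_adp_update_rule_arithmetic():
    """Multipliers (2.5, 7, 5) on means (8400, 200, 10, 0): doublets 500,
    triplets 70, multiplets stay 0, and singlets lose 2*300 + 3*60 = 780."""
    out = adp_class_means((8400, 200, 10, 0), (2.5, 7, 5))
    assert out[1] == 500 and out[2] == 70 and out[3] == 0
    assert out[0] == 8400 - 780


def test_adp_counts_through_simulation(small_cohort_config):
    donor = _make_donor(0, small_cohort_config)
    _, truth = simulate_measurement(donor, "ADP", 1, small_cohort_config)
    m = truth.class_counts
    assert (m.m2, m.m3, m.m4) == (500, 70, 0)
    assert m.m1 == 8400 - 780


def test_excessive_depletion_raises_with_message():
    with pytest.raises(ConfigurationError, match="depletion"):
        adp_class_means((100, 200, 10, 0), (2.5, 7, 5))


def test_degenerate_event_count_rejected():
    with pytest.raises(ConfigurationError):
        CohortConfig(events_per_measurement=0)


def test_event_labels_aggregate_to_true_counts():
    config = CohortConfig(n_donors=2, events_per_measurement=2000,
                          inter_donor_dispersion=0.1)
    events, truth, _ = simulate_cohort(config)
    for row in truth.itertuples():
        sel = events[(events["donor_id"] == row.donor_id)
                     & (events["condition"] == row.condition)
                     & (events["replicate"] == row.replicate)
                     & (~events["contains_erythrocyte"])]
        tallied = np.bincount(sel["gt_class"].to_numpy(), minlength=5)[1:5]
        assert tuple(tallied) == (row.true_m1, row.true_m2, row.true_m3, row.true_m4)


# ---------------------------------------------------------------- cohorts

def test_sex_assignment_is_deterministic_61_35():
    config = CohortConfig(n_donors=96, sex_fraction_male=61 / 96,
                          events_per_measurement=10)
    donors = [_make_donor(i, config) for i in range(96)]
    sexes = [d.sex for d in donors]
    assert sexes.count("M") == 61 and sexes.count("F") == 35


def test_zero_dispersion_gives_identical_true_wpa(small_cohort_config):
    _, truth, _ = simulate_cohort(small_cohort_config, counts_only=True)
    baseline = truth[truth["condition"] == "baseline"]["true_wpa"]
    assert baseline.nunique() == 1


def test_same_seed_gives_bit_identical_cohorts():
    config = CohortConfig(n_donors=3, events_per_measurement=500)
    events_a, truth_a, _ = simulate_cohort(config)
    events_b, truth_b, _ = simulate_cohort(config)
    assert events_a.equals(events_b)
    assert truth_a.equals(truth_b)


def test_different_seeds_differ():
    config = CohortConfig(n_donors=2, events_per_measurement=500)
    events_a, _, _ = simulate_cohort(config)
    events_b, _, _ = simulate_cohort(dataclasses.replace(config, seed=1))
    assert not events_a.equals(events_b)


def test_n_donors_below_one_rejected():
    with pytest.raises(ConfigurationError):
        CohortConfig(n_donors=0)


def test_acquisition_dates_batch_up_to_12_donors():
    config = CohortConfig(n_donors=30, events_per_measurement=10)
    donors = [_make_donor(i, config) for i in range(30)]
    from collections import Counter
    per_date = Counter(d.acquisition_date for d in donors)
    assert all(v <= 12 for v in per_date.values())
    assert len(per_date) == 3


def test_doublet_multiplier_monotonically_raises_true_wpa():
    base = np.array([8400.0, 200.0, 10.0, 1.0])
    wpas = []
    for mult in (1.5, 2.5, 4.0):
        mu = adp_class_means(base, (mult, 7, 5))
        wpas.append(wpa_of_probs(mu / mu.sum()))
    assert wpas[0] < wpas[1] < wpas[2]


def test_closed_form_wpa_matches_count_wpa_at_zero_dispersion(small_cohort_config):
    from wpaflow.wpa import compute_wpa

    donor = _make_donor(0, small_cohort_config)
    _, truth = simulate_measurement(donor, "baseline", 1, small_cohort_config)
    assert compute_wpa(truth.class_counts) == pytest.approx(truth.true_wpa, abs=1e-9)


def test_substream_keys_are_order_independent():
    a = substream(42, 2, 5, 0, 1).integers(0, 10**9, 4)
    b = substream(42, 2, 5, 0, 1).integers(0, 10**9, 4)
    c = substream(42, 2, 5, 0, 2).integers(0, 10**9, 4)
    np.testing.assert_array_equal(a, b)
    assert not np.array_equal(a, c)
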
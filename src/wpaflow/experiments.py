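"""Reference experiments on synthetic data.

Each function generates its own inputs from a seed, runs the relevant part
of the pipeline, and returns measured quantities.  They are used by the
acceptance checks and are convenient entry points for exploring how the
pipeline behaves under the default study conditions.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .classifier import ClassifierConfig, classify, train
from .gating import GatingConfig, focus_score, gate_events
from .synthcyto import (CohortConfig, RenderParams, render_event_for_row,
                        render_training_set, simulate_cohort,
                        simulate_whole_blood_stream, substream)
from .wpa import summarize_measurement

__all__ = ["gate_rate_experiment", "baseline_recovery_experiment"]

#: unstimulated per-measurement class composition used as the reference state
BASELINE_CLASS_MEANS = (8400.0, 200.0, 10.0, 0.0)


def gate_rate_experiment(seed: int, n_events: int = 100_000) -> dict:
    """Fraction of a whole-blood stream outside the CD42b gate.

    Simulates an ungated erythrocyte-dominated event stream at the default
    whole-blood composition and applies auto-threshold CD42b gating.
    Returns the percentage of events excluded by the CD42b gate.
    """
    stream = simulate_whole_blood_stream(n_events, seed=seed)
    _, report = gate_events(stream, GatingConfig(focus_threshold=1e-6))
    return {
        "percent_outside_cd42b_gate": 100.0 * report.n_outside_cd42b_gate / report.n_input,
        "n_events": report.n_input,
        "cd42b_threshold": report.cd42b_threshold,
    }


def baseline_recovery_experiment(seed: int, n_donors: int = 20,
                                 events_per_measurement: int = 2000,
                                 n_training_images: int = 2000,
                                 classifier_epochs: int = 24) -> dict:
    """Recover the baseline cohort WPA through the full image pipeline.

    Simulates ``n_donors`` donors × 2 technical replicates (baseline
    condition, zero inter-donor dispersion) whose ground-truth class
    proportions equal the unstimulated reference composition, renders every
    event image, gates on CD42b/focus, classifies with a network trained on
    ``n_training_images`` rendered synthetic images, scores each measurement,
    and returns the cohort mean WPA alongside the ground truth.
    """
    cohort_cfg = CohortConfig(
        n_donors=n_donors,
        baseline_class_means=BASELINE_CLASS_MEANS,
        events_per_measurement=events_per_measurement,
        inter_donor_dispersion=0.0,
        seed=seed,
    )
    render_params = RenderParams()

    rng = substream(seed, 101)
    images, labels = render_training_set(n_training_images, render_params,
                                         cohort_cfg, rng)
    clf_cfg = ClassifierConfig(epochs=classifier_epochs, seed=seed % (2**31))
    model = train(clf_cfg, images, labels, rng=np.random.default_rng(clf_cfg.seed))

    events, truth, _ = simulate_cohort(cohort_cfg, conditions=("baseline",),
                                       n_replicates=2)
    gating_cfg = GatingConfig(cd42b_threshold=300.0, focus_threshold="auto")

    wpas = []
    for mi, (_, grp) in enumerate(events.groupby(["donor_id", "replicate"], sort=True)):
        mrng = substream(seed, 201, mi)
        imgs = [render_event_for_row(row, render_params, mrng)
                for _, row in grp.iterrows()]
        grp = grp.copy()
        grp["focus"] = [focus_score(im) for im in imgs]
        retained, _ = gate_events(grp, gating_cfg)
        kept = [imgs[i] for i in np.flatnonzero(grp.index.isin(retained.index))]
        pred, _ = classify(model, kept)
        retained["class"] = pred
        wpas.append(summarize_measurement(retained).wpa)

    return {
        "cohort_mean_wpa": float(np.mean(wpas)),
        "cohort_sd_wpa": float(np.std(wpas, ddof=1)),
        "true_mean_wpa": float(truth["true_wpa"].mean()),
        "n_measurements": len(wpas),
        "holdout_accuracy": model.holdout_accuracy,
    }
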
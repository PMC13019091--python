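"""Synthetic imaging-flow-cytometry (IFC) data with known ground truth.

This module emulates the statistical structure of single-event platelet
aggregation measurements in antibody-labelled whole blood:

* per-event images — platelet singlets/doublets/triplets/multiplets rendered
  as clusters of mutually tangent disks on a brightfield + CD42b (+ CD62P)
  pixel grid, plus background objects (erythrocytes, platelet–erythrocyte
  coincidences, debris);
* per-measurement event streams — ~10^4 platelet complexes per measurement
  with a configurable class composition (default ≈ 8400 singlets / 200
  doublets / 10 triplets / ~1 multiplet), embedded on demand in a whole-blood
  background where ~99 % of objects are CD42b-negative erythrocytes;
* full cohorts — donors with age and sex, technical duplicates per condition
  (baseline and ADP-stimulated), acquisition dates assigned in batches, and
  optional planted effects (a male-only age slope on aggregate classes, an
  age-related decline in total platelet events).

ADP stimulation multiplies the doublet/triplet/multiplet means by
configurable factors (defaults 2.5× / 7× / 5×) and depletes singlets by the
platelets consumed, ``2·Δm2 + 3·Δm3 + 4·Δm4``.

Randomness follows one master seed; per-donor/per-measurement substreams are
derived through fixed ``SeedSequence`` keys so output is independent of
iteration order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .wpa import CLASS_WEIGHTS, ClassCounts, compute_wpa

__all__ = [
    "ConfigurationError",
    "RenderParams",
    "EventAnnotation",
    "EventImage",
    "CohortConfig",
    "DonorState",
    "MeasurementTruth",
    "render_event",
    "render_background_event",
    "render_event_for_row",
    "render_training_set",
    "simulate_measurement",
    "simulate_whole_blood_stream",
    "simulate_cohort",
    "substream",
    "wpa_of_probs",
]

CONDITIONS = ("baseline", "ADP")


class ConfigurationError(ValueError):
    """Invalid generator or render configuration."""


# --------------------------------------------------------------------------
# seeding

def substream(master_seed: int, *key: int) -> np.random.Generator:
    """Derive a reproducible child RNG from the master seed and a fixed key."""
    return np.random.default_rng(np.random.SeedSequence([int(master_seed), *map(int, key)]))


# --------------------------------------------------------------------------
# image rendering

@dataclass(frozen=True)
class RenderParams:
    """Forward model for one event image.

    Geometry uses a 48×48 px grid at 0.33 µm/px (typical 60× IFC platelet
    appearance); platelet diameters are drawn uniformly from 2–3 µm.  Noise
    is Poisson shot noise on the signal plus additive Gaussian read noise;
    optics are an isotropic Gaussian blur, 3× wider for out-of-focus events.
    """

    image_size: int = 48
    pixel_size_um: float = 0.33
    platelet_diameter_um: tuple[float, float] = (2.0, 3.0)
    erythrocyte_diameter_um: tuple[float, float] = (6.5, 8.0)
    center_jitter_frac: float = 0.10
    blur_sigma_px: float = 1.0
    defocus_factor: float = 3.0
    cd42b_peak: float = 1500.0
    cd62p_peak: float = 60.0
    brightfield_level: float = 500.0
    brightfield_absorption: float = 0.35
    shot_noise: bool = True
    read_noise: float = 3.0

    def __post_init__(self) -> None:
        if self.image_size <= 0:
            raise ConfigurationError("image_size must be positive")
        lo, hi = self.platelet_diameter_um
        if lo <= 0 or hi < lo:
            raise ConfigurationError("platelet_diameter_um must be a positive (lo, hi) range")
        if self.pixel_size_um <= 0:
            raise ConfigurationError("pixel_size_um must be positive")

    def noiseless(self) -> "RenderParams":
        """Copy with all stochastic noise terms switched off."""
        return replace(self, shot_noise=False, read_noise=0.0)


@dataclass
class EventAnnotation:
    """Ground-truth annotation attached to a rendered event."""

    n_platelets: int
    centers: list[tuple[float, float]]
    contains_erythrocyte: bool = False

    def __post_init__(self) -> None:
        if self.n_platelets != len(self.centers):
            raise ValueError("n_platelets must equal the number of listed centers")


@dataclass
class EventImage:
    """Multi-channel pixel grid for one IFC event."""

    brightfield: np.ndarray
    cd42b: np.ndarray
    cd62p: np.ndarray
    pixel_size_um: float
    annotation: EventAnnotation | None = None

    def __post_init__(self) -> None:
        if not (self.brightfield.shape == self.cd42b.shape == self.cd62p.shape):
            raise ValueError("all channels must share identical dimensions")

    @property
    def shape(self) -> tuple[int, int]:
        return self.brightfield.shape


def _place_cluster(n: int, radii_px: np.ndarray, jitter: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Centers of ``n`` mutually tangent disks; each new disk attaches to a
    uniformly chosen existing member at a random angle with ±jitter on the
    center distance.  Returned centers are centroid-shifted to the origin."""
    centers = np.zeros((n, 2))
    for i in range(1, n):
        for _ in range(100):
            anchor = rng.integers(i)
            theta = rng.uniform(0.0, 2.0 * math.pi)
            dist = (radii_px[anchor] + radii_px[i]) * (1.0 + rng.uniform(-jitter, jitter))
            cand = centers[anchor] + dist * np.array([math.cos(theta), math.sin(theta)])
            # reject placements that interpenetrate a non-anchor member
            gaps = np.hypot(*(centers[:i] - cand).T) - 0.85 * (radii_px[:i] + radii_px[i])
            if np.all(np.delete(gaps, anchor) > 0):
                break
        centers[i] = cand
    return centers - centers.mean(axis=0)


def _soft_disks(size: int, centers: np.ndarray, radii: np.ndarray) -> np.ndarray:
    """Sum of unit-height disks with a ~1 px anti-aliased edge."""
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    img = np.zeros((size, size))
    for (cy, cx), r in zip(centers, radii):
        d = np.hypot(yy - cy, xx - cx)
        img += np.clip(r + 0.5 - d, 0.0, 1.0)
    return img


def _apply_noise(img: np.ndarray, params: RenderParams, rng: np.random.Generator) -> np.ndarray:
    out = img
    if params.shot_noise:
        out = rng.poisson(np.clip(out, 0.0, None)).astype(float)
    if params.read_noise > 0:
        out = out + rng.normal(0.0, params.read_noise, size=out.shape)
    return np.clip(out, 0.0, None)


def render_event(n_platelets: int, params: RenderParams | None = None,
                 rng: np.random.Generator | None = None, *,
                 out_of_focus: bool = False,
                 cd42b_scale: float = 1.0,
                 cd62p_scale: float = 1.0) -> EventImage:
    """Render a platelet complex of ``n_platelets`` members.

    The CD42b channel is positive over every platelet footprint; the
    annotation records exactly ``n_platelets`` centers (image coordinates).
    ``cd42b_scale``/``cd62p_scale`` rescale the fluorescence amplitudes so
    per-event MFI variation can be injected from a cohort model.
    """
    if params is None:
        params = RenderParams()
    if rng is None:
        rng = np.random.default_rng()
    if n_platelets < 1:
        raise ConfigurationError("n_platelets must be >= 1")

    size = params.image_size
    lo, hi = params.platelet_diameter_um
    radii_px = rng.uniform(lo, hi, size=n_platelets) / 2.0 / params.pixel_size_um
    centers = _place_cluster(n_platelets, radii_px, params.center_jitter_frac, rng)
    centers += (size - 1) / 2.0  # centroid at image center

    disks = _soft_disks(size, centers, radii_px)
    sigma = params.blur_sigma_px * (params.defocus_factor if out_of_focus else 1.0)

    # per-platelet brightness variation (~±20 %)
    gains = rng.uniform(0.8, 1.2, size=n_platelets) if params.shot_noise else np.ones(n_platelets)
    fluor = np.zeros((size, size))
    for (cy, cx), r, g in zip(centers, radii_px, gains):
        yy, xx = np.mgrid[0:size, 0:size].astype(float)
        fluor += g * np.clip(r + 0.5 - np.hypot(yy - cy, xx - cx), 0.0, 1.0)

    cd42b = gaussian_filter(params.cd42b_peak * cd42b_scale * fluor, sigma)
    cd62p = gaussian_filter(params.cd62p_peak * cd62p_scale * fluor, sigma)
    bf = params.brightfield_level * (1.0 - params.brightfield_absorption * np.clip(disks, 0.0, 1.0))
    bf = gaussian_filter(bf, sigma)

    return EventImage(
        brightfield=_apply_noise(bf, params, rng),
        cd42b=_apply_noise(cd42b, params, rng),
        cd62p=_apply_noise(cd62p, params, rng),
        pixel_size_um=params.pixel_size_um,
        annotation=EventAnnotation(n_platelets, [tuple(c) for c in centers]),
    )


_BACKGROUND_KINDS = ("erythrocyte", "coincidence", "debris")


def render_background_event(kind: str, params: RenderParams | None = None,
                            rng: np.random.Generator | None = None) -> EventImage:
    """Render a non-platelet or contaminated event.

    ``erythrocyte``: a large CD42b-negative annulus (simple biconcave proxy).
    ``coincidence``: a platelet next to a larger CD42b-negative object,
    flagged ``contains_erythrocyte`` — the class excluded from analysis.
    ``debris``: small dim brightfield speckle, CD42b-negative.
    """
    if params is None:
        params = RenderParams()
    if rng is None:
        rng = np.random.default_rng()
    if kind not in _BACKGROUND_KINDS:
        raise ConfigurationError(f"unknown background kind {kind!r}; expected one of {_BACKGROUND_KINDS}")

    size = params.image_size
    center = np.array([(size - 1) / 2.0, (size - 1) / 2.0])
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    bf_obj = np.zeros((size, size))
    cd42b = np.zeros((size, size))
    cd62p = np.zeros((size, size))
    annotation = EventAnnotation(0, [], contains_erythrocyte=False)

    def _erythro(at: np.ndarray) -> np.ndarray:
        r = rng.uniform(*params.erythrocyte_diameter_um) / 2.0 / params.pixel_size_um
        d = np.hypot(yy - at[0], xx - at[1])
        disk = np.clip(r + 0.5 - d, 0.0, 1.0)
        dimple = 0.5 * np.clip(0.45 * r + 0.5 - d, 0.0, 1.0)  # central pallor
        return disk - dimple

    if kind == "erythrocyte":
        bf_obj = _erythro(center)
        annotation.contains_erythrocyte = True
    elif kind == "debris":
        r = rng.uniform(0.5, 1.0) / params.pixel_size_um
        off = center + rng.uniform(-3, 3, size=2)
        bf_obj = 0.4 * np.clip(r + 0.5 - np.hypot(yy - off[0], xx - off[1]), 0.0, 1.0)
    else:  # coincidence: erythrocyte plus an adjacent platelet
        ery_r = rng.uniform(*params.erythrocyte_diameter_um) / 2.0 / params.pixel_size_um
        ery_at = center + np.array([0.0, -0.35 * size / 2])
        bf_obj = _erythro(ery_at)
        plat_r = rng.uniform(*params.platelet_diameter_um) / 2.0 / params.pixel_size_um
        theta = rng.uniform(0.0, 2.0 * math.pi)
        plat_at = ery_at + (ery_r + plat_r) * np.array([math.sin(theta) * 0.3, abs(math.cos(theta))])
        plat = np.clip(plat_r + 0.5 - np.hypot(yy - plat_at[0], xx - plat_at[1]), 0.0, 1.0)
        bf_obj = bf_obj + plat
        cd42b = params.cd42b_peak * plat
        cd62p = params.cd62p_peak * plat
        annotation = EventAnnotation(1, [tuple(plat_at)], contains_erythrocyte=True)

    sigma = params.blur_sigma_px
    bf = gaussian_filter(params.brightfield_level * (1.0 - params.brightfield_absorption * np.clip(bf_obj, 0.0, 1.0)), sigma)
    cd42b = gaussian_filter(cd42b, sigma)
    cd62p = gaussian_filter(cd62p, sigma)
    return EventImage(
        brightfield=_apply_noise(bf, params, rng),
        cd42b=_apply_noise(cd42b, params, rng),
        cd62p=_apply_noise(cd62p, params, rng),
        pixel_size_um=params.pixel_size_um,
        annotation=annotation,
    )


# --------------------------------------------------------------------------
# cohort configuration

@dataclass(frozen=True)
class CohortConfig:
    """Parameters of a synthetic donor cohort.

    Class means are per-measurement expected event counts for singlets,
    doublets, triplets and multiplets at baseline; the ADP condition applies
    the multipliers to classes 2–4 and removes ``2·Δµ2 + 3·Δµ3 + 4·Δµ4``
    singlets (the platelets consumed by new aggregates).
    ``inter_donor_dispersion`` is the scale of a donor-level Dirichlet
    perturbation of the class probabilities; 0 makes the cohort fully
    deterministic (counts equal the configured means).
    """

    n_donors: int = 96
    sex_fraction_male: float = 61 / 96
    age_min: float = 18.0
    age_max: float = 70.0
    age_median: float = 39.0
    baseline_class_means: tuple[float, float, float, float] = (8400.0, 200.0, 10.0, 1.0)
    adp_multipliers: tuple[float, float, float] = (2.5, 7.0, 5.0)
    inter_donor_dispersion: float = 0.05
    male_age_slope: float = 0.0          # per-year fractional multiplier on µ2..µ4, males only
    total_events_age_slope: float = 0.0  # per-year fractional change in events per measurement
    events_per_measurement: int = 10_000
    whole_blood_platelet_fraction: float = 0.01
    coincidence_fraction: float = 0.01   # platelet+erythrocyte images among recorded events
    out_of_focus_fraction: float = 0.02
    multiplet_sizes: tuple[int, ...] = (4, 5, 6)
    cd42b_log_mean: float = math.log(5000.0)
    cd42b_log_sigma: float = 0.40
    cd42b_bg_log_mean: float = math.log(30.0)
    cd42b_bg_log_sigma: float = 0.50
    cd62p_log_mean: float = math.log(200.0)
    cd62p_log_sigma: float = 0.50
    cd62p_adp_log_shift: float = 1.0
    cd62p_masking_per_class: float = 0.0  # optional linear attenuation with aggregate size
    batch_size: int = 12                 # donors per acquisition date
    seed: int = 0

    def __post_init__(self) -> None:
        problems = []
        if self.n_donors < 1:
            problems.append("n_donors must be >= 1")
        if not (0.0 <= self.sex_fraction_male <= 1.0):
            problems.append("sex_fraction_male must lie in [0, 1]")
        if any(m < 0 for m in self.baseline_class_means):
            problems.append("baseline_class_means must be non-negative")
        if any(m < 0 for m in self.adp_multipliers):
            problems.append("adp_multipliers must be non-negative")
        if self.events_per_measurement < 1:
            problems.append("events_per_measurement must be >= 1")
        if not (0.0 < self.whole_blood_platelet_fraction <= 1.0):
            problems.append("whole_blood_platelet_fraction must lie in (0, 1]")
        if self.inter_donor_dispersion < 0:
            problems.append("inter_donor_dispersion must be >= 0")
        if not (0.0 <= self.coincidence_fraction < 1.0):
            problems.append("coincidence_fraction must lie in [0, 1)")
        if self.batch_size < 1:
            problems.append("batch_size must be >= 1")
        if problems:
            raise ConfigurationError("; ".join(problems))


@dataclass
class DonorState:
    donor_id: str
    index: int
    age: float
    sex: str                        # "M" | "F"
    acquisition_date: str           # ISO 8601
    class_probs: dict               # condition -> probability 4-vector
    class_means: dict               # condition -> expected per-measurement counts
    events_per_measurement: int     # baseline-condition platelet complexes

    def true_wpa(self, condition: str) -> float:
        return wpa_of_probs(self.class_probs[condition])


@dataclass
class MeasurementTruth:
    donor_id: str
    condition: str
    replicate: int
    class_counts: ClassCounts
    true_wpa: float                 # closed-form WPA of the donor's class probabilities


def wpa_of_probs(p: Sequence[float]) -> float:
    """Closed-form WPA (in percent) of a class-probability vector."""
    p = np.asarray(p, dtype=float)
    return (float(np.dot(CLASS_WEIGHTS, p)) / p.sum() - 1.0) * 100.0


def adp_class_means(baseline: Sequence[float], multipliers: Sequence[float]) -> np.ndarray:
    """Apply ADP stimulation to baseline class means.

    Classes 2–4 are multiplied; singlets are depleted by the platelets the
    new aggregates consume, ``2·Δµ2 + 3·Δµ3 + 4·Δµ4``.
    """
    mu = np.asarray(baseline, dtype=float)
    out = mu.copy()
    out[1:] = mu[1:] * np.asarray(multipliers, dtype=float)
    delta = out[1:] - mu[1:]
    depletion = float(np.dot([2.0, 3.0, 4.0], delta))
    out[0] = mu[0] - depletion
    if out[0] < 0:
        raise ConfigurationError(
            f"ADP singlet depletion ({depletion:.1f}) exceeds the available "
            f"singlet mean ({mu[0]:.1f}); lower the multipliers or raise µ1"
        )
    return out


def _round_preserving_total(fractional: np.ndarray, total: int) -> np.ndarray:
    """Largest-remainder rounding of ``fractional`` so the result sums to ``total``."""
    floors = np.floor(fractional).astype(int)
    remainder = total - int(floors.sum())
    order = np.argsort(-(fractional - floors))
    floors[order[:remainder]] += 1
    return floors


def _make_donor(index: int, config: CohortConfig) -> DonorState:
    """Deterministic donor covariates plus seeded donor-level random effects."""
    rng = substream(config.seed, 1, index)
    n_male = int(round(config.sex_fraction_male * config.n_donors))
    sex = "M" if index < n_male else "F"

    # age ~ scaled Beta(2, b) with b solved so the median hits the target
    span = config.age_max - config.age_min
    q = (config.age_median - config.age_min) / span
    a = 2.0
    b = max(0.5, (a - 1.0 / 3.0) / q + 2.0 / 3.0 - a)  # median approx (a-1/3)/(a+b-2/3)
    age = config.age_min + span * rng.beta(a, b)

    mu = np.asarray(config.baseline_class_means, dtype=float)
    if sex == "M" and config.male_age_slope != 0.0:
        factor = max(0.0, 1.0 + config.male_age_slope * (age - config.age_median))
        mu = mu.copy()
        mu[1:] *= factor

    p_base = mu / mu.sum()
    if config.inter_donor_dispersion > 0:
        alpha = np.clip(p_base, 1e-12, None) / config.inter_donor_dispersion * 100.0
        p_base = rng.dirichlet(alpha)

    mu_donor = p_base * mu.sum()
    mu_adp = adp_class_means(mu_donor, config.adp_multipliers)

    n_events = config.events_per_measurement
    if config.total_events_age_slope != 0.0:
        n_events = int(round(n_events * max(0.05, 1.0 + config.total_events_age_slope * (age - config.age_median))))

    batch = index // config.batch_size
    date = (pd.Timestamp("2024-01-08") + pd.Timedelta(days=batch)).date().isoformat()
    return DonorState(
        donor_id=f"D{index + 1:03d}",
        index=index,
        age=float(age),
        sex=sex,
        acquisition_date=date,
        class_probs={
            "baseline": mu_donor / mu_donor.sum(),
            "ADP": mu_adp / mu_adp.sum(),
        },
        class_means={"baseline": mu_donor, "ADP": mu_adp},
        events_per_measurement=int(n_events),
    )


# --------------------------------------------------------------------------
# event-stream simulation

_EVENT_COLUMNS = [
    "donor_id", "age", "sex", "condition", "replicate", "acquisition_date",
    "event_id", "cd42b_mfi", "cd62p_mfi", "focus", "contains_erythrocyte",
    "gt_class", "gt_n_platelets",
]


def simulate_measurement(donor: DonorState, condition: str, replicate: int,
                         config: CohortConfig,
                         rng: np.random.Generator | None = None,
                         include_background: bool = False,
                         counts_only: bool = False) -> tuple[pd.DataFrame, MeasurementTruth]:
    """One technical replicate of one donor/condition as a per-event table.

    Returns the recorded event stream (platelet complexes plus any
    platelet–erythrocyte coincidence images; with ``include_background`` also
    the CD42b-negative whole-blood background at the configured platelet
    fraction) and the measurement's ground truth.  ``gt_class`` is 1–4 for
    platelet complexes and 0 for non-platelet objects.
    """
    if condition not in CONDITIONS:
        raise ConfigurationError(f"condition must be one of {CONDITIONS}")
    if rng is None:
        rng = substream(config.seed, 2, donor.index, CONDITIONS.index(condition), replicate)

    # singlet depletion under ADP shrinks the recorded complex total: the
    # baseline condition anchors events_per_measurement, other conditions
    # scale by the ratio of their expected totals
    mu = donor.class_means[condition]
    scale = mu.sum() / donor.class_means["baseline"].sum()
    n_recorded = int(round(donor.events_per_measurement * scale))
    p = donor.class_probs[condition]

    deterministic = config.inter_donor_dispersion == 0
    if deterministic:
        n_coincidence = int(round(config.coincidence_fraction * n_recorded))
    else:
        n_coincidence = int(rng.binomial(n_recorded, config.coincidence_fraction))
    n_complex = n_recorded - n_coincidence
    if n_complex < 1:
        raise ConfigurationError("coincidence_fraction leaves no platelet complexes")

    if deterministic:
        counts = _round_preserving_total(p * n_complex, n_complex)
    else:
        counts = rng.multinomial(n_complex, p)
    truth = MeasurementTruth(
        donor_id=donor.donor_id,
        condition=condition,
        replicate=replicate,
        class_counts=ClassCounts(*(int(c) for c in counts)),
        true_wpa=wpa_of_probs(p),
    )
    if counts_only:
        return pd.DataFrame(columns=_EVENT_COLUMNS), truth

    labels = np.repeat(np.arange(1, 5), counts)
    rng.shuffle(labels)
    n_platelets = labels.copy()
    is_multi = labels == 4
    n_platelets[is_multi] = rng.choice(config.multiplet_sizes, size=int(is_multi.sum()))

    if n_coincidence:
        labels = np.concatenate([labels, np.full(n_coincidence, 1)])
        n_platelets = np.concatenate([n_platelets, np.full(n_coincidence, 1)])
    coincidence = np.zeros(labels.size, dtype=bool)
    coincidence[n_complex:] = True

    n_events = labels.size
    cd42b = rng.lognormal(config.cd42b_log_mean, config.cd42b_log_sigma, size=n_events)
    cd62p_mean = config.cd62p_log_mean + (config.cd62p_adp_log_shift if condition == "ADP" else 0.0)
    cd62p = rng.lognormal(cd62p_mean, config.cd62p_log_sigma, size=n_events)
    if config.cd62p_masking_per_class > 0:
        cd62p *= np.clip(1.0 - config.cd62p_masking_per_class * (labels - 1), 0.0, None)

    out_of_focus = rng.random(n_events) < config.out_of_focus_fraction
    focus = np.where(out_of_focus,
                     np.clip(rng.normal(0.05, 0.01, n_events), 1e-4, None),
                     np.clip(rng.normal(0.40, 0.05, n_events), 0.15, None))

    if include_background:
        f = config.whole_blood_platelet_fraction
        n_bg = int(round(n_events * (1.0 - f) / f))
        cd42b = np.concatenate([cd42b, rng.lognormal(config.cd42b_bg_log_mean,
                                                     config.cd42b_bg_log_sigma, size=n_bg)])
        cd62p = np.concatenate([cd62p, rng.lognormal(math.log(20.0), 0.5, size=n_bg)])
        labels = np.concatenate([labels, np.zeros(n_bg, dtype=int)])
        n_platelets = np.concatenate([n_platelets, np.zeros(n_bg, dtype=int)])
        coincidence = np.concatenate([coincidence, np.zeros(n_bg, dtype=bool)])
        focus = np.concatenate([focus, np.clip(rng.normal(0.40, 0.05, n_bg), 0.15, None)])
        order = rng.permutation(labels.size)
        cd42b, cd62p, labels = cd42b[order], cd62p[order], labels[order]
        n_platelets, coincidence, focus = n_platelets[order], coincidence[order], focus[order]
        n_events = labels.size

    table = pd.DataFrame({
        "donor_id": donor.donor_id,
        "age": donor.age,
        "sex": donor.sex,
        "condition": condition,
        "replicate": replicate,
        "acquisition_date": donor.acquisition_date,
        "event_id": np.arange(n_events),
        "cd42b_mfi": cd42b,
        "cd62p_mfi": cd62p,
        "focus": focus,
        "contains_erythrocyte": coincidence | (labels == 0),
        "gt_class": labels,
        "gt_n_platelets": n_platelets,
    })
    return table, truth


def simulate_whole_blood_stream(n_events: int, config: CohortConfig | None = None,
                                seed: int = 0) -> pd.DataFrame:
    """An ungated whole-blood event stream of ~``n_events`` objects.

    Erythrocytes dominate according to ``1 - whole_blood_platelet_fraction``
    (≈ 99 % by default); platelet complexes follow the baseline class
    composition.  This is the stream the acquisition-side CD42b gate sees.
    """
    if config is None:
        config = CohortConfig()
    n_platelet = max(1, int(round(n_events * config.whole_blood_platelet_fraction)))
    cfg = replace(config, events_per_measurement=n_platelet, seed=seed)
    donor = _make_donor(0, cfg)
    donor.events_per_measurement = n_platelet
    stream, _ = simulate_measurement(donor, "baseline", 1, cfg, include_background=True)
    return stream


def simulate_cohort(config: CohortConfig,
                    conditions: Iterable[str] = CONDITIONS,
                    n_replicates: int = 2,
                    counts_only: bool = False
                    ) -> tuple[pd.DataFrame, pd.DataFrame, list[DonorState]]:
    """Simulate a full cohort: each donor × condition × technical replicate.

    Returns ``(events, truth, donors)`` where ``events`` is the concatenated
    per-event table, ``truth`` one row per measurement (true class counts and
    closed-form WPA), and ``donors`` the generated donor states.  With
    ``counts_only`` the per-event table is skipped (empty frame returned) and
    only class counts are drawn — much faster for count-level experiments.
    """
    donors = [_make_donor(i, config) for i in range(config.n_donors)]
    tables, truth_rows = [], []
    for donor in donors:
        for condition in conditions:
            for rep in range(1, n_replicates + 1):
                tab, truth = simulate_measurement(donor, condition, rep, config,
                                                  counts_only=counts_only)
                if not counts_only:
                    tables.append(tab)
                row = {
                    "donor_id": truth.donor_id,
                    "condition": truth.condition,
                    "replicate": truth.replicate,
                    "age": donor.age,
                    "sex": donor.sex,
                    "acquisition_date": donor.acquisition_date,
                    "true_wpa": truth.true_wpa,
                }
                for k, v in zip(("m1", "m2", "m3", "m4"), truth.class_counts.as_tuple()):
                    row[f"true_{k}"] = v
                truth_rows.append(row)
    events = (pd.concat(tables, ignore_index=True) if tables
              else pd.DataFrame(columns=_EVENT_COLUMNS))
    return events, pd.DataFrame(truth_rows), donors


def render_training_set(n_images: int, params: RenderParams, config: CohortConfig,
                        rng: np.random.Generator) -> tuple[list[EventImage], np.ndarray]:
    """A class-balanced labelled image set for classifier training.

    Classes 1–4 are drawn uniformly; multiplet member counts come from
    ``config.multiplet_sizes`` and fluorescence amplitudes from the cohort's
    CD42b/CD62P intensity model, so training images match the cohort's
    rendering distribution.
    """
    if n_images < 4:
        raise ConfigurationError("need at least 4 training images (one per class)")
    labels = np.tile(np.arange(1, 5), n_images // 4 + 1)[:n_images]
    images = []
    for lab in labels:
        n = int(lab) if lab < 4 else int(rng.choice(config.multiplet_sizes))
        cd42b = rng.lognormal(config.cd42b_log_mean, config.cd42b_log_sigma)
        cd62p = rng.lognormal(config.cd62p_log_mean, config.cd62p_log_sigma)
        images.append(render_event(n, params, rng,
                                   cd42b_scale=cd42b / 5000.0,
                                   cd62p_scale=cd62p / 200.0))
    return images, labels


def render_event_for_row(row, params: RenderParams, rng: np.random.Generator) -> EventImage:
    """Render the image matching one simulated event-table row.

    Coincidence rows render as platelet+erythrocyte images; ``gt_class == 0``
    rows as plain erythrocytes.  Fluorescence amplitudes follow the row's
    MFIs so tabular and pixel data agree; out-of-focus rows (low simulated
    focus score) are rendered with the defocus blur.
    """
    if row["gt_class"] == 0:
        return render_background_event("erythrocyte", params, rng)
    if row["contains_erythrocyte"]:
        return render_background_event("coincidence", params, rng)
    defocused = row["focus"] < 0.15
    return render_event(
        int(row["gt_n_platelets"]), params, rng,
        out_of_focus=bool(defocused),
        cd42b_scale=float(row["cd42b_mfi"]) / 5000.0,
        cd62p_scale=float(row["cd62p_mfi"]) / 200.0,
    )
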
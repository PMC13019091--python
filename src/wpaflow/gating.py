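"""Acquisition-side conditional gating.

Keeps camera-focused, CD42b-positive platelet events and drops the
whole-blood background (mainly erythrocytes, ~99 % of objects) plus
platelet–erythrocyte coincidence images.  Thresholds may be numeric or
``"auto"``: the CD42b auto threshold is a minimum-error bimodal split (Otsu
criterion on log-MFI), the focus auto threshold the 5th percentile of focus
scores among CD42b-positive events.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label, regionprops

from .synthcyto import EventImage

__all__ = ["GatingConfig", "GatingReport", "focus_score", "gate_events",
           "auto_cd42b_threshold", "detect_coincidence"]

_MIN_EVENTS_FOR_AUTO = 50


@dataclass(frozen=True)
class GatingConfig:
    cd42b_threshold: float | str = "auto"
    focus_threshold: float | str = "auto"
    coincidence_exclusion: bool = True

    def __post_init__(self) -> None:
        for name in ("cd42b_threshold", "focus_threshold"):
            v = getattr(self, name)
            if isinstance(v, str):
                if v != "auto":
                    raise ValueError(f"{name} must be numeric or 'auto', got {v!r}")
            elif v <= 0:
                raise ValueError(f"{name} must be positive when numeric")


@dataclass
class GatingReport:
    n_input: int
    n_outside_cd42b_gate: int
    n_out_of_focus: int
    n_coincidence_excluded: int
    n_retained: int
    cd42b_threshold: float
    focus_threshold: float

    @property
    def fraction_excluded(self) -> float:
        return 0.0 if self.n_input == 0 else 1.0 - self.n_retained / self.n_input

    def as_dict(self) -> dict:
        d = asdict(self)
        d["fraction_excluded"] = self.fraction_excluded
        return d


def focus_score(image: EventImage | np.ndarray, denoise_sigma: float = 1.0) -> float:
    """Sharpness of the brightfield channel.

    Root-mean-square of the discrete gradient magnitude, normalised by the
    mean intensity — zero for a uniform image, invariant under positive
    rescaling of all pixels, and monotonically decreasing under blur.  The
    channel is lightly smoothed first (``denoise_sigma``): on shot-noise-
    limited images the raw pixel-to-pixel gradient is dominated by Poisson
    noise rather than by edges, which would make sharp and defocused events
    indistinguishable.
    """
    bf = image.brightfield if isinstance(image, EventImage) else np.asarray(image, dtype=float)
    if bf.size == 0:
        raise ValueError("cannot score an empty image")
    mean = bf.mean()
    if mean <= 0:
        return 0.0
    if denoise_sigma > 0:
        bf = gaussian_filter(bf.astype(float), denoise_sigma)
    gy, gx = np.gradient(bf.astype(float))
    return float(np.sqrt(np.mean(gy**2 + gx**2)) / mean)


def auto_cd42b_threshold(cd42b_mfi: np.ndarray) -> float:
    """Minimum-error bimodal split: Otsu criterion on log-MFI."""
    values = np.asarray(cd42b_mfi, dtype=float)
    values = values[values > 0]
    if values.size < _MIN_EVENTS_FOR_AUTO:
        raise ValueError(
            f"auto CD42b threshold needs >= {_MIN_EVENTS_FOR_AUTO} events, got {values.size}"
        )
    return float(np.exp(threshold_otsu(np.log(values))))


def detect_coincidence(image: EventImage, max_object_diameter_um: float = 6.0) -> bool:
    """Image-mode coincidence rule: any CD42b-negative connected brightfield
    object larger than ``max_object_diameter_um`` equivalent diameter."""
    bf = image.brightfield.astype(float)
    dark = bf < 0.85 * np.median(bf)  # absorbing objects on bright background
    cd42b_pos = image.cd42b > 0.2 * max(image.cd42b.max(), 1e-9)
    labels = cc_label(dark & ~cd42b_pos)
    for region in regionprops(labels):
        if region.equivalent_diameter * image.pixel_size_um > max_object_diameter_um:
            return True
    return False


def gate_events(events: pd.DataFrame, config: GatingConfig | None = None
                ) -> tuple[pd.DataFrame, GatingReport]:
    """Partition an event stream into retained platelet events and exclusions.

    ``events`` must carry ``cd42b_mfi`` and ``focus`` columns (computed with
    :func:`focus_score` from images if absent) and, for coincidence
    exclusion, a boolean ``contains_erythrocyte`` column.  Exclusion is
    tested in order CD42b → focus → coincidence, each event counted once;
    retained events keep their original order.
    """
    if config is None:
        config = GatingConfig()
    n_input = len(events)
    if n_input == 0:
        report = GatingReport(0, 0, 0, 0, 0, float("nan"), float("nan"))
        return events.copy(), report

    cd42b = events["cd42b_mfi"].to_numpy(dtype=float)
    focus = events["focus"].to_numpy(dtype=float)

    if config.cd42b_threshold == "auto":
        cd42b_thr = auto_cd42b_threshold(cd42b)
    else:
        cd42b_thr = float(config.cd42b_threshold)

    in_gate = cd42b >= cd42b_thr

    if config.focus_threshold == "auto":
        if int(in_gate.sum()) < _MIN_EVENTS_FOR_AUTO:
            raise ValueError(
                f"auto focus threshold needs >= {_MIN_EVENTS_FOR_AUTO} CD42b-positive events"
            )
        focus_thr = float(np.percentile(focus[in_gate], 5.0))
    else:
        focus_thr = float(config.focus_threshold)

    in_focus = focus >= focus_thr
    if config.coincidence_exclusion and "contains_erythrocyte" in events.columns:
        coincidence = events["contains_erythrocyte"].to_numpy(dtype=bool)
    else:
        coincidence = np.zeros(n_input, dtype=bool)

    excl_cd42b = ~in_gate
    excl_focus = in_gate & ~in_focus
    excl_coinc = in_gate & in_focus & coincidence
    retained_mask = in_gate & in_focus & ~coincidence

    report = GatingReport(
        n_input=n_input,
        n_outside_cd42b_gate=int(excl_cd42b.sum()),
        n_out_of_focus=int(excl_focus.sum()),
        n_coincidence_excluded=int(excl_coinc.sum()),
        n_retained=int(retained_mask.sum()),
        cd42b_threshold=cd42b_thr,
        focus_threshold=focus_thr,
    )
    return events[retained_mask].copy(), report
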
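"""Relative perfusion units, hypoperfusion segmentation and flap flags.

The raw plateau-phase intensity (absolute perfusion units, the 0-255 gray
scale of the NIR camera) is normalized to relative perfusion units (RPU):
the brightest point of the breast ROI is set to 100 and every pixel is
expressed as a percentage of it.  A flap region outside the nipple with RPU
strictly below the 30% cutoff is hypoperfused; the hypoperfused-area percent
ratio divides that area by the full ipsilateral breast ROI.  Two thresholds
act on the ratio: above 15% a change of reconstruction strategy (or close
follow-up) is advised, and above one third of the breast area the case is
outside the intended-use population (screened out before analysis).

The nipple-areolar complex routinely reads below 30% without necrosis
(dye-injection interference), so it is excluded from the numerator and never
counted hypoperfused; the denominator keeps the whole breast ROI.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .kinetics import PerfusionMap

__all__ = [
    "RPUMap",
    "FlapAssessment",
    "compute_rpu",
    "segment_hypoperfused",
    "area_percent_ratio",
    "assess_flap",
    "DEFAULT_CUTOFF",
    "DEFAULT_DECISION_THRESHOLD",
    "ELIGIBILITY_THRESHOLD",
]

DEFAULT_CUTOFF = 30.0
DEFAULT_DECISION_THRESHOLD = 15.0
ELIGIBILITY_THRESHOLD = 100.0 / 3.0
DEFAULT_MIN_COMPONENT_PX = 25


@dataclass(frozen=True)
class RPUMap:
    """Per-pixel relative perfusion on a 0-100 scale within the breast ROI.

    ``normalizer`` is the absolute intensity mapped to RPU 100 (the given
    percentile of in-ROI intensities; percentile 100 = the single brightest
    point).  Values outside the ROI are 0 and carry no meaning.
    """

    values: np.ndarray
    normalizer: float
    percentile_used: float

    def __post_init__(self) -> None:
        if np.any(self.values < 0) or np.any(self.values > 100):
            raise ValueError("RPU values must lie in [0, 100]")


@dataclass(frozen=True)
class FlapAssessment:
    """Bundle of the segmentation, the area ratio and the clinical flags."""

    hypo_mask: np.ndarray
    area_percent_ratio: float
    is_hypoperfused_flap: bool
    decision_flag: str  # "proceed" or "change_strategy_or_close_followup"
    eligibility_excluded: bool
    cutoff_used: float
    decision_threshold_used: float


def compute_rpu(
    pmap: PerfusionMap | np.ndarray,
    breast_mask: np.ndarray,
    percentile: float = 100.0,
) -> RPUMap:
    """Normalize a perfusion map to relative perfusion units.

    The normalizer is the given ``percentile`` of intensities inside
    ``breast_mask`` (100 by default, i.e. the point with the highest
    perfusion in the target area maps to RPU 100).  Intensities above the
    normalizer -- possible for percentile < 100 -- clip at 100.
    """
    intensity = pmap.values if isinstance(pmap, PerfusionMap) else np.asarray(pmap, float)
    breast_mask = np.asarray(breast_mask, dtype=bool)
    if intensity.shape != breast_mask.shape:
        raise ValueError("perfusion map and breast_mask shapes differ")
    if not breast_mask.any():
        raise ValueError("breast_mask is empty")
    roi = intensity[breast_mask]
    if roi.max() <= 0:
        raise ValueError("no perfusion signal: ROI intensities are all zero")
    normalizer = float(np.percentile(roi, percentile))
    if normalizer <= 0:
        raise ValueError("normalizer percentile is zero; raise the percentile")
    values = np.zeros_like(intensity, dtype=float)
    values[breast_mask] = 100.0 * np.clip(roi / normalizer, 0.0, 1.0)
    return RPUMap(values=values, normalizer=normalizer, percentile_used=float(percentile))


def segment_hypoperfused(
    rpu: RPUMap,
    breast_mask: np.ndarray,
    nipple_mask: np.ndarray,
    cutoff: float = DEFAULT_CUTOFF,
    min_component_px: int = DEFAULT_MIN_COMPONENT_PX,
) -> np.ndarray:
    """Binary mask of hypoperfused flap pixels.

    A pixel is hypoperfused when it lies in the breast ROI, outside the
    nipple, and its RPU is *strictly* below ``cutoff`` (RPU exactly at the
    cutoff is adequately perfused).  Connected components (8-connectivity)
    smaller than ``min_component_px`` are discarded as speckle before the
    nipple is excluded, so a region contiguous with hypoperfused nipple skin
    is never mistaken for speckle even if the nipple splits it;
    ``min_component_px=1`` reproduces the raw per-pixel thresholding.
    """
    breast_mask = np.asarray(breast_mask, dtype=bool)
    nipple_mask = np.asarray(nipple_mask, dtype=bool)
    if not (rpu.values.shape == breast_mask.shape == nipple_mask.shape):
        raise ValueError("rpu, breast_mask and nipple_mask shapes differ")
    if not 0 < cutoff <= 100:
        raise ValueError("cutoff must lie in (0, 100]")
    mask = breast_mask & (rpu.values < cutoff)
    if min_component_px > 1 and mask.any():
        labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
        sizes = np.bincount(labels.ravel())
        keep = sizes >= min_component_px  # strictly smaller components dropped
        keep[0] = False
        mask = keep[labels]
    return mask & ~nipple_mask


def area_percent_ratio(hypo_mask: np.ndarray, breast_mask: np.ndarray) -> float:
    """Hypoperfused area as a percentage of the ipsilateral breast area.

    The denominator is the full breast ROI including the nipple; the
    numerator (the segmentation) already excludes it.
    """
    hypo_mask = np.asarray(hypo_mask, dtype=bool)
    breast_mask = np.asarray(breast_mask, dtype=bool)
    n_breast = int(breast_mask.sum())
    if n_breast == 0:
        raise ValueError("breast_mask is empty")
    if np.any(hypo_mask & ~breast_mask):
        raise ValueError("hypo_mask extends outside breast_mask")
    return 100.0 * int(hypo_mask.sum()) / n_breast


def assess_flap(
    rpu: RPUMap,
    breast_mask: np.ndarray,
    nipple_mask: np.ndarray,
    cutoff: float = DEFAULT_CUTOFF,
    decision_threshold: float = DEFAULT_DECISION_THRESHOLD,
    eligibility_threshold: float = ELIGIBILITY_THRESHOLD,
    min_component_px: int = DEFAULT_MIN_COMPONENT_PX,
) -> FlapAssessment:
    """Full flap assessment: segmentation, ratio, and the three flags.

    * ``is_hypoperfused_flap`` -- any hypoperfused region remains after
      nipple exclusion and speckle cleanup.
    * ``decision_flag`` -- ``change_strategy_or_close_followup`` when the
      area percent ratio exceeds ``decision_threshold`` (default 15%),
      otherwise ``proceed``.
    * ``eligibility_excluded`` -- ratio exceeds ``eligibility_threshold``
      (default one third of the breast area), the screening criterion for a
      prohibitively ischemic flap.
    """
    hypo = segment_hypoperfused(
        rpu, breast_mask, nipple_mask, cutoff=cutoff, min_component_px=min_component_px
    )
    ratio = area_percent_ratio(hypo, breast_mask)
    return FlapAssessment(
        hypo_mask=hypo,
        area_percent_ratio=ratio,
        is_hypoperfused_flap=bool(hypo.any()),
        decision_flag=(
            "change_strategy_or_close_followup"
            if ratio > decision_threshold
            else "proceed"
        ),
        eligibility_excluded=ratio > eligibility_threshold,
        cutoff_used=float(cutoff),
        decision_threshold_used=float(decision_threshold),
    )
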
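"""End-to-end convenience: raw frame stack -> flap assessment."""

from __future__ import annotations

import numpy as np

from .io import RunConfig
from .kinetics import FrameSequence, detect_phases, extract_perfusion_map, mean_roi_curve
from .perfusion import FlapAssessment, RPUMap, assess_flap, compute_rpu

__all__ = ["assess_recording"]


def assess_recording(
    seq: FrameSequence,
    breast_mask: np.ndarray,
    nipple_mask: np.ndarray,
    config: RunConfig | None = None,
) -> tuple[FlapAssessment, RPUMap]:
    """Run kinetics -> RPU normalization -> segmentation -> flags.

    The plateau window is detected on the breast-ROI mean curve, the plateau
    frames are aggregated into one perfusion map, normalized to relative
    perfusion units, and assessed against the hypoperfusion cutoff and the
    decision/eligibility thresholds of ``config``.
    """
    cfg = config or RunConfig()
    curve = mean_roi_curve(seq, breast_mask)
    seg = detect_phases(curve, rise_fraction=cfg.rise_fraction, fall_fraction=cfg.fall_fraction)
    pmap = extract_perfusion_map(seq, seg, aggregator=cfg.aggregator)
    rpu = compute_rpu(pmap, breast_mask, percentile=cfg.percentile)
    assessment = assess_flap(
        rpu,
        breast_mask,
        nipple_mask,
        cutoff=cfg.cutoff,
        decision_threshold=cfg.decision_threshold,
        eligibility_threshold=cfg.eligibility_threshold,
        min_component_px=cfg.min_component_px,
    )
    return assessment, rpu
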
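"""File formats and run configuration.

Frame stacks travel as multi-page 16-bit grayscale TIFF with a sidecar CSV
of frame timestamps (``frame_index,time_s``); masks as 8-bit 0/255 PNG;
cohorts as CSV with a fixed header; assessment reports and ground truth as
JSON.  Writers quantize intensities by rounding to uint16, which is
lossless for integer-valued stacks and immaterial for RPU results (which
are scale-invariant).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

from .kinetics import FrameSequence
from .perfusion import (
    DEFAULT_CUTOFF,
    DEFAULT_DECISION_THRESHOLD,
    DEFAULT_MIN_COMPONENT_PX,
    ELIGIBILITY_THRESHOLD,
    FlapAssessment,
)
from .simulate import COHORT_COLUMNS

__all__ = [
    "RunConfig",
    "read_frames",
    "write_frames",
    "read_mask",
    "write_mask",
    "read_cohort",
    "write_cohort",
    "assessment_to_dict",
    "write_report",
    "read_report",
]

_MASTECTOMY_TYPES = {"SSM", "NSM"}
_RECONSTRUCTION_TYPES = {"TE", "DTI"}


@dataclass
class RunConfig:
    """All tunable thresholds and parameters of one pipeline run.

    Round-trips through YAML unchanged; the CLI logs the fully resolved
    config so any run can be reproduced bit-identically.
    """

    cutoff: float = DEFAULT_CUTOFF
    decision_threshold: float = DEFAULT_DECISION_THRESHOLD
    eligibility_threshold: float = ELIGIBILITY_THRESHOLD
    percentile: float = 100.0
    min_component_px: int = DEFAULT_MIN_COMPONENT_PX
    rise_fraction: float = 0.95
    fall_fraction: float = 0.90
    aggregator: str = "median"
    seed: int = 0
    version: str = field(default="0.1.0")

    def __post_init__(self) -> None:
        if not 0 < self.cutoff <= 100:
            raise ValueError("cutoff must lie in (0, 100]")
        if not 0 <= self.decision_threshold <= 100:
            raise ValueError("decision_threshold must lie in [0, 100]")
        if not 0 < self.percentile <= 100:
            raise ValueError("percentile must lie in (0, 100]")
        if self.min_component_px < 1:
            raise ValueError("min_component_px must be >= 1")
        if not 0 < self.fall_fraction <= self.rise_fraction <= 1:
            raise ValueError("need 0 < fall_fraction <= rise_fraction <= 1")
        if self.aggregator not in ("median", "mean"):
            raise ValueError("aggregator must be 'median' or 'mean'")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


def write_frames(seq: FrameSequence, tiff_path: str | Path, times_path: str | Path) -> None:
    """Write a frame stack as multi-page uint16 TIFF + timestamp CSV."""
    data = np.clip(np.rint(seq.frames), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    tifffile.imwrite(str(tiff_path), data, photometric="minisblack")
    pd.DataFrame(
        {"frame_index": np.arange(seq.n_frames), "time_s": seq.times}
    ).to_csv(times_path, index=False)


def read_frames(tiff_path: str | Path, times_path: str | Path) -> FrameSequence:
    """Read a multi-page TIFF stack plus its timestamp sidecar CSV."""
    try:
        frames = tifffile.imread(str(tiff_path))
    except (FileNotFoundError, ValueError, tifffile.TiffFileError) as exc:
        raise ValueError(f"cannot read frame stack {tiff_path}: {exc}") from exc
    if frames.ndim == 2:
        frames = frames[None]
    times_df = pd.read_csv(times_path)
    if not {"frame_index", "time_s"} <= set(times_df.columns):
        raise ValueError("times CSV must have columns frame_index,time_s")
    if len(times_df) != frames.shape[0]:
        raise ValueError(
            f"times CSV has {len(times_df)} rows but the stack has "
            f"{frames.shape[0]} frames"
        )
    times = times_df.sort_values("frame_index")["time_s"].to_numpy(dtype=float)
    return FrameSequence(frames=frames.astype(float), times=times)


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a boolean mask as 8-bit 0/255 PNG."""
    iio.imwrite(str(path), (np.asarray(mask, bool) * np.uint8(255)))


def read_mask(path: str | Path) -> np.ndarray:
    """Read an 8-bit PNG as a boolean mask (any nonzero pixel is True)."""
    img = iio.imread(str(path))
    if img.ndim == 3:  # tolerate grayscale saved with an alpha/RGB layer
        img = img[..., 0]
    return np.asarray(img) > 0


def write_cohort(cohort: pd.DataFrame, path: str | Path) -> None:
    cohort.to_csv(path, index=False, columns=COHORT_COLUMNS)


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read and validate a cohort CSV (fixed, documented header)."""
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort CSV is missing columns {missing}")
    for col in ("predictor_positive", "necrosis"):
        bad = df.index[~df[col].isin([True, False, 0, 1])].tolist()
        if bad:
            raise ValueError(f"column {col!r}: non-boolean values in rows {bad}")
        df[col] = df[col].astype(bool)
    bad = df.index[~df["mastectomy_type"].isin(_MASTECTOMY_TYPES)].tolist()
    if bad:
        raise ValueError(f"column 'mastectomy_type': unknown values in rows {bad}")
    bad = df.index[~df["reconstruction_type"].isin(_RECONSTRUCTION_TYPES)].tolist()
    if bad:
        raise ValueError(f"column 'reconstruction_type': unknown values in rows {bad}")
    return df


def assessment_to_dict(assessment: FlapAssessment, config: RunConfig | None = None) -> dict:
    """JSON-serializable report of one flap assessment."""
    report = {
        "area_percent_ratio": assessment.area_percent_ratio,
        "is_hypoperfused_flap": assessment.is_hypoperfused_flap,
        "decision_flag": assessment.decision_flag,
        "eligibility_excluded": assessment.eligibility_excluded,
        "cutoff_used": assessment.cutoff_used,
        "decision_threshold_used": assessment.decision_threshold_used,
        "hypoperfused_pixels": int(np.asarray(assessment.hypo_mask).sum()),
    }
    if config is not None:
        report["config"] = asdict(config)
    return report


def write_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")


def read_report(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
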
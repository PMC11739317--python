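"""Synthetic ICG angiography recordings and cohorts with known ground truth.

No clinical recordings ship with this package, so every downstream stage is
exercised on simulated data: an elliptical breast-shaped domain carved into
perforator territories, a per-pixel arterial-rise / plateau / venous-washout
intensity course, optional "dropout" territories whose plateau is scaled
down to emulate perforator damage, truncated-Gaussian sensor noise, and
synthetic patient cohorts with configurable necrosis prevalence and
predictor operating characteristics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .kinetics import FrameSequence

__all__ = [
    "KineticProfile",
    "TerritoryModel",
    "SyntheticCase",
    "make_breast_domain",
    "make_territories",
    "simulate_recording",
    "simulate_case",
    "simulate_cohort",
    "COHORT_COLUMNS",
]

#: fraction of plateau_level used as constant background outside the breast
BACKGROUND_FRACTION = 0.01

COHORT_COLUMNS = [
    "case_id",
    "predictor_positive",
    "necrosis",
    "age",
    "bmi",
    "mastectomy_type",
    "reconstruction_type",
    "area_percent_ratio",
]


@dataclass(frozen=True)
class KineticProfile:
    """Piecewise time-course of fluorescence after the ICG bolus.

    Intensity rises linearly from 0 to ``plateau_level`` over
    ``time_to_peak`` seconds (arterial phase), stays constant until
    ``washout_start`` (plateau phase), then decays exponentially at
    ``washout_rate`` (venous phase).  Defaults emulate a 3-minute recording
    that starts at injection: peak at 30 s, washout from 120 s at 0.02 /s.
    """

    time_to_peak: float = 30.0
    plateau_level: float = 180.0
    washout_start: float = 120.0
    washout_rate: float = 0.02

    def __post_init__(self) -> None:
        if self.time_to_peak <= 0:
            raise ValueError("time_to_peak must be > 0")
        if self.plateau_level < 0:
            raise ValueError("plateau_level must be >= 0")
        if self.washout_start < self.time_to_peak:
            raise ValueError("washout_start must be >= time_to_peak")
        if self.washout_rate < 0:
            raise ValueError("washout_rate must be >= 0")

    def curve(self, times: np.ndarray) -> np.ndarray:
        """Noise-free intensity at each time; non-negative everywhere."""
        t = np.asarray(times, dtype=float)
        rise = np.clip(t / self.time_to_peak, 0.0, 1.0)
        decay = np.where(
            t > self.washout_start,
            np.exp(-self.washout_rate * (t - self.washout_start)),
            1.0,
        )
        return self.plateau_level * rise * decay


@dataclass(frozen=True)
class TerritoryModel:
    """Voronoi partition of the breast ROI into perforator territories."""

    labels: np.ndarray  # (H, W) int; 0 outside breast, 1..n inside
    seed_points: np.ndarray  # (n, 2) row/col coordinates
    breast_mask: np.ndarray
    dropout_ids: tuple[int, ...] = ()
    dropout_factor: float = 1.0

    def __post_init__(self) -> None:
        n = len(self.seed_points)
        if not set(self.dropout_ids) <= set(range(1, n + 1)):
            raise ValueError("dropout_ids must be a subset of 1..n_territories")
        if not 0.0 <= self.dropout_factor <= 1.0:
            raise ValueError("dropout_factor must lie in [0, 1]")

    @property
    def n_territories(self) -> int:
        return len(self.seed_points)

    def dropout_mask(self) -> np.ndarray:
        """Union of dropout territories (the ground-truth hypoperfusion)."""
        return np.isin(self.labels, list(self.dropout_ids))

    def plateau_scale(self) -> np.ndarray:
        """Per-pixel multiplier: dropout_factor inside dropout, 1 elsewhere."""
        scale = np.where(self.breast_mask, 1.0, 0.0)
        scale[self.dropout_mask()] = self.dropout_factor
        return scale


@dataclass
class SyntheticCase:
    """A generated recording plus masks and ground truth for recovery tests."""

    frames: FrameSequence
    breast_mask: np.ndarray
    nipple_mask: np.ndarray
    truth_hypo_mask: np.ndarray
    truth_area_fraction: float
    rng_seed: int
    profile: KineticProfile = field(default_factory=KineticProfile)


def make_breast_domain(
    height: int,
    width: int,
    nipple_center: tuple[int, int] | None = None,
    nipple_radius: float = 10.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Build an elliptical breast mask and a disc-shaped nipple mask.

    The breast is a centred ellipse with semi-axes 45% of the image height
    and width (the operator-drawn ROI of the clinical workflow).  The nipple
    disc must lie entirely inside the breast; a radius of 0 yields an empty
    nipple mask, which is valid (skin-sparing mastectomy).

    Returns
    -------
    (breast_mask, nipple_mask)
        Boolean ``(height, width)`` arrays with ``nipple ⊆ breast``.
    """
    if height < 4 or width < 4:
        raise ValueError("domain too small for an elliptical breast mask")
    rows, cols = np.ogrid[:height, :width]
    cy, cx = (height - 1) / 2.0, (width - 1) / 2.0
    a, b = 0.45 * height, 0.45 * width
    breast = ((rows - cy) / a) ** 2 + ((cols - cx) / b) ** 2 <= 1.0

    if nipple_center is None:
        nipple_center = (int(round(cy)), int(round(cx)))
    ny, nx = nipple_center
    if nipple_radius > 0:
        nipple = (rows - ny) ** 2 + (cols - nx) ** 2 <= nipple_radius**2
    else:
        nipple = np.zeros_like(breast)
    if nipple_radius > 0 and not breast[ny, nx]:
        raise ValueError("nipple_center lies outside the breast mask")
    if np.any(nipple & ~breast):
        raise ValueError("nipple disc does not fit inside the breast mask")
    return breast, nipple


def make_territories(
    breast_mask: np.ndarray,
    n_territories: int,
    seed: int,
    dropout_ids: tuple[int, ...] = (),
    dropout_factor: float = 1.0,
) -> TerritoryModel:
    """Partition the breast ROI into ``n_territories`` Voronoi territories.

    Seed points are drawn uniformly without replacement among breast pixels
    from ``numpy.random.default_rng(seed)``; every breast pixel is labelled
    by its nearest seed point (Euclidean, ties resolved by cKDTree's lowest
    index), so the labelling is deterministic given the seed.
    """
    breast_mask = np.asarray(breast_mask, dtype=bool)
    pix = np.argwhere(breast_mask)
    if n_territories < 1:
        raise ValueError("n_territories must be >= 1")
    if n_territories > len(pix):
        raise ValueError("more territories than breast pixels")
    rng = np.random.default_rng(seed)
    seeds = pix[rng.choice(len(pix), size=n_territories, replace=False)]
    _, nearest = cKDTree(seeds).query(pix)
    labels = np.zeros(breast_mask.shape, dtype=np.int32)
    labels[breast_mask] = nearest + 1
    labels = _merge_stray_fragments(labels, breast_mask)
    return TerritoryModel(
        labels=labels,
        seed_points=seeds,
        breast_mask=breast_mask,
        dropout_ids=tuple(int(i) for i in dropout_ids),
        dropout_factor=float(dropout_factor),
    )


def _merge_stray_fragments(labels: np.ndarray, breast_mask: np.ndarray) -> np.ndarray:
    """Make every territory 8-connected on the discrete grid.

    Voronoi cells are connected in continuous space, but their pixelation
    restricted to the elliptical breast can shed tiny disconnected slivers
    along the boundary.  A perforator territory is a contiguous patch of
    skin, so minor fragments are absorbed into the adjacent territory they
    touch most (the main component of each label is kept).
    """
    structure = np.ones((3, 3), dtype=int)
    for _ in range(10):
        changed = False
        for lab in range(1, int(labels.max()) + 1):
            comp, n = ndimage.label(labels == lab, structure)
            if n <= 1:
                continue
            sizes = np.bincount(comp.ravel())
            sizes[0] = 0
            main = int(sizes.argmax())
            for frag in range(1, n + 1):
                if frag == main:
                    continue
                frag_mask = comp == frag
                ring = (ndimage.binary_dilation(frag_mask, structure)
                        & breast_mask & ~frag_mask)
                neighbours = labels[ring]
                neighbours = neighbours[(neighbours > 0) & (neighbours != lab)]
                if neighbours.size:
                    labels[frag_mask] = int(np.bincount(neighbours).argmax())
                    changed = True
        if not changed:
            break
    return labels


def simulate_recording(
    territories: TerritoryModel,
    nipple_mask: np.ndarray,
    profile: KineticProfile | None = None,
    frame_times: np.ndarray | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> SyntheticCase:
    """Render a full synthetic ICG-A recording for one breast.

    Per-pixel intensity is the kinetic curve scaled by the territory dropout
    factor; outside the breast a constant background of 1% of the plateau
    level keeps the ROI necessary for correct normalization.  Zero-mean
    Gaussian sensor noise of standard deviation ``noise_sd`` is added and
    the result truncated at 0 (intensities are non-negative counts).

    The ground-truth hypoperfused mask is the union of dropout territories;
    the ground-truth area fraction excludes the nipple from the numerator
    and divides by the full breast area, matching the downstream ratio
    convention.
    """
    if profile is None:
        profile = KineticProfile()
    if frame_times is None:
        frame_times = np.arange(0.0, 180.0 + 1e-9, 2.0)
    frame_times = np.asarray(frame_times, dtype=float)
    if frame_times.size == 0:
        raise ValueError("frame_times must be nonempty")
    if frame_times.size > 1 and not np.all(np.diff(frame_times) > 0):
        raise ValueError("frame_times must be strictly increasing")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    nipple_mask = np.asarray(nipple_mask, dtype=bool)
    breast = territories.breast_mask
    if nipple_mask.shape != breast.shape:
        raise ValueError("nipple_mask shape differs from breast_mask")

    scale = territories.plateau_scale()
    background = BACKGROUND_FRACTION * profile.plateau_level
    curve = profile.curve(frame_times)
    # signal: curve(t) * territory scale inside breast, flat background outside
    frames = curve[:, None, None] * scale[None, :, :]
    frames[:, ~breast] = background

    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        frames = np.maximum(frames + rng.normal(0.0, noise_sd, frames.shape), 0.0)

    truth = territories.dropout_mask()
    n_breast = int(breast.sum())
    truth_fraction = 100.0 * int((truth & ~nipple_mask).sum()) / n_breast
    seq = FrameSequence(
        frames=frames,
        times=frame_times,
        metadata={
            "icg_dose": "4 mL at 2.5 mg/mL + 10 mL saline flush",
            "recording_s": float(frame_times[-1]),
        },
    )
    return SyntheticCase(
        frames=seq,
        breast_mask=breast,
        nipple_mask=nipple_mask,
        truth_hypo_mask=truth,
        truth_area_fraction=truth_fraction,
        rng_seed=int(seed),
        profile=profile,
    )


def simulate_case(
    height: int = 160,
    width: int = 192,
    n_territories: int = 12,
    target_dropout_fraction: float = 0.0,
    dropout_factor: float = 0.15,
    nipple_radius: float = 8.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    profile: KineticProfile | None = None,
    frame_times: np.ndarray | None = None,
) -> SyntheticCase:
    """Convenience wrapper: domain + territories + recording in one call.

    Dropout territories are chosen greedily (in shuffled order) until their
    cumulative breast-pixel share reaches ``target_dropout_fraction``
    percent; the achieved ground truth is recorded exactly in
    ``truth_area_fraction``, so recovery tests compare against realized, not
    requested, geometry.
    """
    breast, nipple = make_breast_domain(height, width, nipple_radius=nipple_radius)
    rng = np.random.default_rng(seed)
    terr = make_territories(breast, n_territories, seed=int(rng.integers(2**31)))
    dropout_ids: list[int] = []
    if target_dropout_fraction > 0:
        n_breast = breast.sum()
        sizes = {i: int((terr.labels == i).sum()) for i in range(1, n_territories + 1)}
        order = rng.permutation(np.arange(1, n_territories + 1))
        acc = 0
        for tid in order:
            if 100.0 * acc / n_breast >= target_dropout_fraction:
                break
            dropout_ids.append(int(tid))
            acc += sizes[int(tid)]
    terr = TerritoryModel(
        labels=terr.labels,
        seed_points=terr.seed_points,
        breast_mask=terr.breast_mask,
        dropout_ids=tuple(dropout_ids),
        dropout_factor=dropout_factor,
    )
    return simulate_recording(
        terr,
        nipple,
        profile=profile,
        frame_times=frame_times,
        noise_sd=noise_sd,
        seed=int(rng.integers(2**31)),
    )


def simulate_cohort(
    n: int,
    prevalence: float,
    sens: float,
    spec: float,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw a synthetic patient cohort with known operating characteristics.

    Necrosis ~ Bernoulli(prevalence); the binary predictor ("hypoperfused
    flap") is positive with probability ``sens`` given necrosis and negative
    with probability ``spec`` given no necrosis.  Covariates (age, BMI,
    mastectomy and reconstruction type, area percent ratio) are plausible
    fillers keyed to outcome status so that cohort reports have structure.
    """
    if n <= 0:
        raise ValueError("cohort size n must be positive")
    for name, p in [("prevalence", prevalence), ("sens", sens), ("spec", spec)]:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    necrosis = rng.random(n) < prevalence
    predictor = np.where(
        necrosis, rng.random(n) < sens, rng.random(n) >= spec
    )
    age = np.round(rng.normal(np.where(necrosis, 50.4, 45.2), 8.0), 1)
    bmi = np.round(rng.normal(23.1, 3.8, n), 1)
    mastectomy = rng.choice(["SSM", "NSM"], size=n, p=[0.64, 0.36])
    reconstruction = rng.choice(["TE", "DTI"], size=n, p=[0.43, 0.57])
    ratio = np.round(
        np.where(
            predictor,
            rng.gamma(2.0, 5.0, n),  # hypoperfused flaps: spread of ratios
            rng.gamma(1.1, 0.4, n),  # well-perfused: near zero
        ),
        2,
    )
    return pd.DataFrame(
        {
            "case_id": [f"case_{i:04d}" for i in range(n)],
            "predictor_positive": predictor,
            "necrosis": necrosis,
            "age": np.clip(age, 19, None),
            "bmi": np.clip(bmi, 15, None),
            "mastectomy_type": mastectomy,
            "reconstruction_type": reconstruction,
            "area_percent_ratio": np.clip(ratio, 0.0, 100.0),
        },
        columns=COHORT_COLUMNS,
    )
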
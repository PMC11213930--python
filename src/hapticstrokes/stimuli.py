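"""Grating stimuli and quality-graded visual prior displays.

The haptic stimuli are disc-shaped sinusoidal gratings: ridges of amplitude
A and period P, presented at one of six axial orientations.  The visual
prior shown before each trial is a field of short line segments on a disc;
its quality q is the fraction of segments aligned with the upcoming
grating's ridge orientation, the rest being uniformly random.  ``prior_readout``
summarises a prior's orientation signal with axial statistics, which is the
package's sanity check that the quality manipulation behaves as intended.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import circstats

__all__ = [
    "GratingSpec",
    "PriorStimulus",
    "STUDY_ORIENTATIONS_DEG",
    "EXP1_PERIODS_MM",
    "EXP1_PAIRS_MM",
    "EXP2_LOW_DEMAND_PAIRS_MM",
    "EXP2_HIGH_DEMAND_PAIRS_MM",
    "TEXTURE_DIAMETER_MM",
    "grating_height",
    "make_prior",
    "prior_readout",
    "prior_to_frame",
]

#: Axial grating orientations used in all study designs (degrees).
STUDY_ORIENTATIONS_DEG: tuple[float, ...] = (15.0, 45.0, 75.0, 105.0, 135.0, 165.0)

#: Grating periods (mm); adjacent periods form the three comparison pairs.
EXP1_PERIODS_MM: tuple[float, ...] = (1.524, 2.032, 2.540, 3.048)
EXP1_PAIRS_MM: tuple[tuple[float, float], ...] = (
    (1.524, 2.032), (2.032, 2.540), (2.540, 3.048))

#: Discrimination pairs with ~2 vs ~1 Weber fractions of period difference.
EXP2_LOW_DEMAND_PAIRS_MM: tuple[tuple[float, float], ...] = (
    (1.524, 2.032), (2.540, 3.048))
EXP2_HIGH_DEMAND_PAIRS_MM: tuple[tuple[float, float], ...] = (
    (1.92, 2.16), (2.40, 2.64))

TEXTURE_DIAMETER_MM: float = 90.7


@dataclass(frozen=True)
class GratingSpec:
    """Physical description of one sinusoidal grating disc."""

    period_mm: float
    amplitude_mm: float = 0.3
    texture_diameter_mm: float = TEXTURE_DIAMETER_MM
    orientation_deg: float = 0.0

    def __post_init__(self) -> None:
        if self.period_mm <= 0:
            raise ValueError("period_mm must be positive")
        if self.amplitude_mm <= 0:
            raise ValueError("amplitude_mm must be positive")
        if self.texture_diameter_mm <= 0:
            raise ValueError("texture_diameter_mm must be positive")
        object.__setattr__(self, "orientation_deg", self.orientation_deg % 180.0)


def grating_height(x, spec: GratingSpec, offset: float = 0.5):
    """Surface height profile z(x) = (A/2) sin(2 pi x / P) + offset.

    ``x`` runs along the axis orthogonal to the ridges; the profile is
    periodic with period P and bounded by offset +/- A/2.  The additive
    offset only shifts the baseline and never enters any analysis quantity.
    """
    x = np.asarray(x, dtype=float)
    return 0.5 * spec.amplitude_mm * np.sin(2.0 * np.pi * x / spec.period_mm) + offset


# --------------------------------------------------------------------------
# visual priors
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PriorStimulus:
    """A quality-graded visual prior: oriented line segments on a disc."""

    orientation_deg: float
    quality_fraction: float
    centers_mm: np.ndarray          # (n, 2) segment centres
    segment_orientations_deg: np.ndarray  # (n,) axial angles
    aligned: np.ndarray             # (n,) bool, True for quality-aligned segments

    @property
    def n_segments(self) -> int:
        return int(self.segment_orientations_deg.size)

    @property
    def n_aligned(self) -> int:
        return int(np.count_nonzero(self.aligned))


def _round_half_up(x: float) -> int:
    # reproducible tie-break for q*n ties such as 0.5*25
    return int(math.floor(x + 0.5))


def _sample_disc_centers(n: int, radius: float, min_spacing: float,
                         rng: np.random.Generator,
                         max_attempts: int = 200_000) -> np.ndarray:
    """Rejection-sample n points in a disc with a minimum pairwise spacing."""
    pts: list[np.ndarray] = []
    attempts = 0
    while len(pts) < n:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"could not place {n} segments with spacing {min_spacing} mm "
                f"inside a disc of radius {radius} mm")
        r = radius * math.sqrt(rng.random())
        phi = rng.uniform(0.0, 2.0 * math.pi)
        p = np.array([r * math.cos(phi), r * math.sin(phi)])
        if pts:
            arr = np.asarray(pts)
            if np.min(np.hypot(arr[:, 0] - p[0], arr[:, 1] - p[1])) < min_spacing:
                continue
        pts.append(p)
    return np.asarray(pts)


def make_prior(orientation_deg: float, quality_fraction: float,
               n_segments: int = 100,
               rng_seed: int | np.random.Generator | None = None,
               texture_diameter_mm: float = TEXTURE_DIAMETER_MM,
               min_spacing_mm: float = 4.0) -> PriorStimulus:
    """Construct a visual prior with exactly round(q * n) aligned segments.

    Segment centres are rejection-sampled inside the texture disc with a
    minimum centre spacing (default 4 mm) so the 8 x 1 mm segments do not
    visually overlap.  Deterministic given the seed.
    """
    if not 0.0 <= quality_fraction <= 1.0:
        raise ValueError("quality_fraction must lie in [0, 1]")
    if n_segments < 1:
        raise ValueError("n_segments must be at least 1")
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    orientation_deg = orientation_deg % 180.0
    n_aligned = _round_half_up(quality_fraction * n_segments)
    centers = _sample_disc_centers(n_segments, texture_diameter_mm / 2.0,
                                   min_spacing_mm, rng)
    orient = rng.uniform(0.0, 180.0, size=n_segments)
    aligned = np.zeros(n_segments, dtype=bool)
    idx = rng.permutation(n_segments)[:n_aligned]
    aligned[idx] = True
    orient[aligned] = orientation_deg
    return PriorStimulus(orientation_deg, quality_fraction, centers, orient, aligned)


def prior_readout(prior: PriorStimulus) -> tuple[float, float]:
    """Axial mean orientation and resultant length of a prior's segments.

    The resultant length rises with quality, so this read-out verifies that
    the quality manipulation actually modulates the orientation signal.
    """
    if prior.n_segments < 2:
        raise ValueError("prior_readout requires at least 2 segments")
    res = circstats.axial_mean(prior.segment_orientations_deg)
    return res.mean_direction_deg, res.resultant_length


def prior_to_frame(prior: PriorStimulus) -> pd.DataFrame:
    """Serialize a prior to one row per segment (CSV-friendly)."""
    return pd.DataFrame({
        "cx_mm": prior.centers_mm[:, 0],
        "cz_mm": prior.centers_mm[:, 1],
        "orientation_deg": prior.segment_orientations_deg,
        "aligned_flag": prior.aligned.astype(int),
    })
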
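"""Stroke segmentation of raw finger trajectories.

A stroke is one unidirectional lateral movement across a texture.  The
extraction follows the study's rule set:

1.  Contact episodes are maximal runs where the normal force is at least
    0.1 N *and* the finger is over a stimulus disc, kept only if they last
    longer than 200 ms.
2.  Within a contact, stroke boundaries are zero crossings of the smoothed
    first derivative of the x- or z-position (movement turns), plus
    crossings of the texture border.  Because a derivative hovering around
    zero in noisy data produces spurious crossings, a sign change only
    counts once the derivative has exceeded a small speed deadband on the
    other side (``min_turn_speed_mm_s``); a genuine turn always does.
3.  Boundaries closer together than a merge window collapse (keeping the
    first), and segments whose net displacement is below a minimum are
    merged into their successor.
4.  Each surviving segment becomes a stroke whose direction is the axial
    orientation (0-180 deg) of the line connecting its start and end point
    in the horizontal x-z plane.

Roles: the first stroke of a trial is *initial*, the final one *last*, and
the *middle* stroke is the chronologically later candidate when the stroke
count is even.  A single stroke is both initial and last, with the middle
undefined.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import Trajectory, middle_stroke_index

__all__ = [
    "SegmentationConfig",
    "Stroke",
    "ContactInterval",
    "SegmentedTrial",
    "detect_contacts",
    "split_strokes",
    "stroke_direction",
    "assign_roles",
    "trial_summary",
    "segment_trial",
    "strokes_to_frame",
]


@dataclass(frozen=True)
class SegmentationConfig:
    force_threshold_n: float = 0.1
    min_contact_ms: float = 200.0
    smoothing_window_ms: float = 25.0
    min_stroke_displacement_mm: float = 5.0
    boundary_merge_ms: float = 50.0
    texture_radius_mm: float = 45.35
    stimulus_centers_mm: tuple[tuple[float, float], tuple[float, float]] = (
        (-65.0, 0.0), (65.0, 0.0))
    min_turn_speed_mm_s: float = 25.0     # derivative deadband for turn detection
    boundary_mode: str = "either"         # "either" axis or "dominant" axis only
    negative_force_tolerance_n: float = 0.02

    def __post_init__(self) -> None:
        for name in ("force_threshold_n", "min_contact_ms", "smoothing_window_ms",
                     "min_stroke_displacement_mm", "boundary_merge_ms",
                     "texture_radius_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.min_contact_ms < self.smoothing_window_ms:
            raise ValueError("min_contact_ms must be at least smoothing_window_ms")
        if self.boundary_mode not in ("either", "dominant"):
            raise ValueError("boundary_mode must be 'either' or 'dominant'")


@dataclass(frozen=True)
class ContactInterval:
    start_index: int   # half-open [start, end)
    end_index: int
    stimulus_side: str

    def duration_s(self, fs: float) -> float:
        return (self.end_index - self.start_index) / fs


@dataclass(frozen=True)
class Stroke:
    start_index: int   # half-open [start, end) in trajectory samples
    end_index: int
    start_point: tuple[float, float]
    end_point: tuple[float, float]
    direction_deg: float
    duration_s: float
    stimulus_side: str
    roles: frozenset[str] = frozenset()
    ordinal: int = 0   # 1-based chronological position within the trial

    @property
    def role(self) -> str:
        """Primary role label (initial > middle > last > other)."""
        for r in ("initial", "middle", "last"):
            if r in self.roles:
                return r
        return "other"


def stroke_direction(start_point, end_point) -> float:
    """Axial direction (degrees in [0, 180)) of the start-to-end line."""
    dx = float(end_point[0]) - float(start_point[0])
    dz = float(end_point[1]) - float(start_point[1])
    if dx == 0.0 and dz == 0.0:
        raise ValueError("coincident start and end point: direction undefined")
    return math.degrees(math.atan2(dz, dx)) % 180.0


# --------------------------------------------------------------------------
# contact detection
# --------------------------------------------------------------------------

def _nearest_side(x: float, z: float, cfg: SegmentationConfig) -> str:
    (lx, lz), (rx, rz) = cfg.stimulus_centers_mm
    dl = math.hypot(x - lx, z - lz)
    dr = math.hypot(x - rx, z - rz)
    return "left" if dl <= dr else "right"


def detect_contacts(traj: Trajectory, cfg: SegmentationConfig) -> list[ContactInterval]:
    """Maximal supra-threshold, on-stimulus runs longer than the contact gate."""
    if traj.time_s.size == 0:
        raise ValueError("empty trajectory")
    force = traj.force_n
    if np.any(force < -cfg.negative_force_tolerance_n):
        warnings.warn("negative forces beyond noise tolerance; clipping to 0",
                      stacklevel=2)
    force = np.maximum(force, 0.0)
    on_disc = np.zeros(force.size, dtype=bool)
    for cx, cz in cfg.stimulus_centers_mm:
        on_disc |= (np.hypot(traj.x_mm - cx, traj.z_mm - cz)
                    <= cfg.texture_radius_mm)
    active = (force >= cfg.force_threshold_n) & on_disc
    padded = np.concatenate(([False], active, [False]))
    d = np.diff(padded.astype(np.int8))
    run_starts = np.flatnonzero(d == 1)
    run_ends = np.flatnonzero(d == -1)
    fs = traj.sampling_rate_hz
    out: list[ContactInterval] = []
    for s, e in zip(run_starts, run_ends):
        if (e - s) / fs * 1000.0 > cfg.min_contact_ms:
            mx = float(np.mean(traj.x_mm[s:e]))
            mz = float(np.mean(traj.z_mm[s:e]))
            out.append(ContactInterval(int(s), int(e), _nearest_side(mx, mz, cfg)))
    return out


# --------------------------------------------------------------------------
# stroke splitting
# --------------------------------------------------------------------------

def _moving_average(series: np.ndarray, window: int) -> np.ndarray:
    if window <= 1 or series.size < 3:
        return series.astype(float)
    window = min(window, series.size if series.size % 2 == 1 else series.size - 1)
    pad = window // 2
    padded = np.pad(series.astype(float), pad, mode="reflect")
    kernel = np.ones(window) / window
    return np.convolve(padded, kernel, mode="valid")


def _deadband_sign_changes(v: np.ndarray, deadband: float) -> list[int]:
    """Indices where the series crosses from beyond +deadband to beyond
    -deadband or vice versa (hysteresis suppresses noise flicker at zero)."""
    s = np.where(v > deadband, 1, np.where(v < -deadband, -1, 0))
    changes: list[int] = []
    state = 0
    for i, si in enumerate(s):
        if si == 0:
            continue
        if state != 0 and si != state:
            changes.append(i)
        state = si
    return changes


def split_strokes(traj: Trajectory, contact: ContactInterval,
                  cfg: SegmentationConfig) -> list[Stroke]:
    """Split one contact episode into strokes at turns and border crossings."""
    s0, e0 = contact.start_index, contact.end_index
    n = e0 - s0
    if n < 2:
        warnings.warn("contact interval shorter than 2 samples; skipped",
                      stacklevel=2)
        return []
    fs = traj.sampling_rate_hz
    window = max(1, int(round(cfg.smoothing_window_ms / 1000.0 * fs)))
    if window % 2 == 0:
        window += 1
    x = traj.x_mm[s0:e0]
    z = traj.z_mm[s0:e0]
    xs = _moving_average(x, window)
    zs = _moving_average(z, window)
    vx = _moving_average(np.gradient(xs) * fs, window)
    vz = _moving_average(np.gradient(zs) * fs, window)

    if cfg.boundary_mode == "dominant":
        dominant = vx if float(np.mean(np.abs(vx))) >= float(np.mean(np.abs(vz))) \
            else vz
        turn_idx = _deadband_sign_changes(dominant, cfg.min_turn_speed_mm_s)
    else:
        turn_idx = (_deadband_sign_changes(vx, cfg.min_turn_speed_mm_s)
                    + _deadband_sign_changes(vz, cfg.min_turn_speed_mm_s))

    # texture border entries/exits within the contact
    cx, cz = (cfg.stimulus_centers_mm[0] if contact.stimulus_side == "left"
              else cfg.stimulus_centers_mm[1])
    dist = np.hypot(xs - cx, zs - cz)
    inside = dist <= cfg.texture_radius_mm
    border_idx = list(np.flatnonzero(np.diff(inside.astype(np.int8))) + 1)

    boundaries = sorted(set(int(i) for i in turn_idx + border_idx))
    merge = max(1, int(round(cfg.boundary_merge_ms / 1000.0 * fs)))
    kept: list[int] = []
    for b in boundaries:
        if b < merge or b > n - merge:
            continue  # too close to the contact edges
        if kept and b - kept[-1] < merge:
            continue  # keep the first of a cluster
        kept.append(b)

    cuts = [0] + kept + [n]
    segments = [(cuts[i], cuts[i + 1]) for i in range(len(cuts) - 1)]

    def displacement(seg: tuple[int, int]) -> float:
        a, b = seg
        return math.hypot(x[b - 1] - x[a], z[b - 1] - z[a])

    # merge under-displaced segments into their successor (predecessor if last)
    changed = True
    while changed and len(segments) > 1:
        changed = False
        for i, seg in enumerate(segments):
            if displacement(seg) < cfg.min_stroke_displacement_mm:
                if i + 1 < len(segments):
                    segments[i:i + 2] = [(seg[0], segments[i + 1][1])]
                else:
                    segments[i - 1:i + 1] = [(segments[i - 1][0], seg[1])]
                changed = True
                break

    strokes: list[Stroke] = []
    for a, b in segments:
        p0 = (float(x[a]), float(z[a]))
        p1 = (float(x[b - 1]), float(z[b - 1]))
        if p0 == p1:
            continue  # zero net displacement; nothing to orient
        strokes.append(Stroke(
            start_index=s0 + a, end_index=s0 + b, start_point=p0, end_point=p1,
            direction_deg=stroke_direction(p0, p1),
            duration_s=(b - a) / fs, stimulus_side=contact.stimulus_side))
    return strokes


# --------------------------------------------------------------------------
# roles and summaries
# --------------------------------------------------------------------------

def assign_roles(strokes: list[Stroke]) -> list[Stroke]:
    """Label initial / middle / last / other roles chronologically.

    For even stroke counts the later of the two central strokes is the
    middle one; a single stroke is both initial and last and the trial
    contributes nothing to middle-stroke analyses.
    """
    n = len(strokes)
    if n == 0:
        raise ValueError("cannot assign roles to an empty stroke list")
    roles: list[set[str]] = [set() for _ in range(n)]
    roles[0].add("initial")
    roles[-1].add("last")
    mid = middle_stroke_index(n)
    if mid is not None:
        roles[mid].add("middle")
    out = []
    for i, s in enumerate(strokes):
        r = roles[i] if roles[i] else {"other"}
        out.append(Stroke(start_index=s.start_index, end_index=s.end_index,
                          start_point=s.start_point, end_point=s.end_point,
                          direction_deg=s.direction_deg, duration_s=s.duration_s,
                          stimulus_side=s.stimulus_side,
                          roles=frozenset(r), ordinal=i + 1))
    return out


@dataclass(frozen=True)
class TrialSummary:
    n_strokes: int
    n_switches: int
    time_on_stimuli_s: float


def trial_summary(strokes: list[Stroke], contacts: list[ContactInterval],
                  fs: float) -> TrialSummary:
    """Per-trial movement summary: stroke count, side switches, contact time."""
    switches = sum(1 for a, b in zip(strokes, strokes[1:])
                   if a.stimulus_side != b.stimulus_side)
    on = sum(c.duration_s(fs) for c in contacts)
    return TrialSummary(len(strokes), switches, on)


@dataclass
class SegmentedTrial:
    strokes: list[Stroke]
    contacts: list[ContactInterval]
    summary: TrialSummary


def segment_trial(traj: Trajectory, cfg: SegmentationConfig | None = None
                  ) -> SegmentedTrial:
    """Run the full segmentation of one trial: contacts, strokes, roles."""
    cfg = cfg or SegmentationConfig()
    contacts = detect_contacts(traj, cfg)
    strokes: list[Stroke] = []
    for c in contacts:
        strokes.extend(split_strokes(traj, c, cfg))
    if strokes:
        strokes = assign_roles(strokes)
    return SegmentedTrial(strokes=strokes, contacts=contacts,
                          summary=trial_summary(strokes, contacts,
                                                traj.sampling_rate_hz))


def strokes_to_frame(segmented: SegmentedTrial, traj: Trajectory,
                     participant: int | None = None) -> pd.DataFrame:
    """One row per stroke, with trial/design metadata when available."""
    fs = traj.sampling_rate_hz
    rows = []
    for s in segmented.strokes:
        row = {
            "ordinal": s.ordinal,
            "role": s.role,
            "is_initial": "initial" in s.roles,
            "is_middle": "middle" in s.roles,
            "is_last": "last" in s.roles,
            "start_s": s.start_index / fs,
            "end_s": s.end_index / fs,
            "x0": s.start_point[0], "z0": s.start_point[1],
            "x1": s.end_point[0], "z1": s.end_point[1],
            "direction_deg": s.direction_deg,
            "side": s.stimulus_side,
        }
        if traj.trial is not None:
            row["trial_index"] = traj.trial.trial_index
            row["quality_fraction"] = traj.trial.quality_fraction
            row["orientation_deg"] = traj.trial.orientation_deg
            row["demand"] = traj.trial.demand
        if participant is not None:
            row["participant"] = participant
        rows.append(row)
    return pd.DataFrame(rows)
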
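"""Factorial trial designs and synthetic exploration trajectories.

Two jobs live here.  First, the exact factorial trial lists of the three
experiments: 360 trials (5 qualities x 6 orientations x 3 pairs x 2
stimulus locations x 2 start locations) for experiment 1, and 288 trials
(144 per task-demand condition, presented in 4 alternating blocks of 72)
for experiments 2 and 3.  Second, a generative stand-in for the recorded
finger trajectories: multi-stroke explorations over two disc textures in
which the initial stroke direction is drawn from a quality-weighted mixture
of an axial von Mises component centred orthogonal to the texture
orientation and an axial uniform component, later strokes are more
concentrated, and the normal force drops to near zero between strokes.
Every synthetic trial carries ground-truth stroke annotations so the
segmentation stage can be validated by round-trip.

The mixture weight w(q) and the concentrations are generative stand-ins:
the study implies that prior usage grows with prior quality but does not
formalise a movement model, so the defaults here only claim qualitative
realism (documented in the methods note).
"""
from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable

import numpy as np
import pandas as pd

from . import stimuli
from .circstats import sample_axial_vonmises

__all__ = [
    "TrialDesign",
    "SimParams",
    "Trajectory",
    "StrokeTruth",
    "ParticipantData",
    "Dataset",
    "QUALITY_LEVELS",
    "EXPERIMENT_N_TRIALS",
    "default_prior_weight",
    "build_trial_list",
    "design_to_frame",
    "sample_stroke_direction",
    "simulate_trial",
    "simulate_participant",
    "simulate_experiment",
    "middle_stroke_index",
]

#: Visual prior quality levels (fraction of aligned segments) per experiment.
QUALITY_LEVELS: dict[int, tuple[float, ...]] = {
    1: (0.0, 0.15, 0.25, 0.35, 0.50),
    2: (0.0, 0.25, 0.50),
    3: (0.0, 0.15, 0.50),
}

EXPERIMENT_N_TRIALS: dict[int, int] = {1: 360, 2: 288, 3: 288}

#: Participants per experiment in the study design.
EXPERIMENT_N_PARTICIPANTS: dict[int, int] = {1: 16, 2: 18, 3: 14}

_EXP1_BLOCK = 60   # break every 60 trials
_EXP23_BLOCK = 72  # break after every demand block of 72 trials


@dataclass(frozen=True)
class TrialDesign:
    """One cell of the factorial design, placed at a chronological position."""

    experiment_id: int
    quality_fraction: float
    orientation_deg: float
    pair_id: str
    period_left_mm: float
    period_right_mm: float
    stimulus_location: str   # "left-right" or "right-left" assignment of the pair
    start_location: str      # "left" or "right"
    demand: str              # "low", "high", or "none" (experiment 1)
    block_index: int         # 1-based
    trial_index: int         # 1-based, chronological

    @property
    def high_frequency_side(self) -> str:
        """Side carrying the smaller period, i.e. the higher spatial frequency."""
        return "left" if self.period_left_mm < self.period_right_mm else "right"


def _exp1_cells() -> list[tuple]:
    return list(itertools.product(
        QUALITY_LEVELS[1], stimuli.STUDY_ORIENTATIONS_DEG,
        stimuli.EXP1_PAIRS_MM, ("left-right", "right-left"), ("left", "right")))


def _exp23_cells(experiment_id: int, demand: str) -> list[tuple]:
    pairs = (stimuli.EXP2_LOW_DEMAND_PAIRS_MM if demand == "low"
             else stimuli.EXP2_HIGH_DEMAND_PAIRS_MM)
    return list(itertools.product(
        QUALITY_LEVELS[experiment_id], stimuli.STUDY_ORIENTATIONS_DEG,
        pairs, ("left-right", "right-left"), ("left", "right")))


def _cell_to_trial(cell: tuple, experiment_id: int, demand: str,
                   block_index: int, trial_index: int) -> TrialDesign:
    quality, orientation, pair, stim_loc, start_loc = cell
    a, b = pair
    left, right = (a, b) if stim_loc == "left-right" else (b, a)
    return TrialDesign(
        experiment_id=experiment_id, quality_fraction=quality,
        orientation_deg=orientation, pair_id=f"{a:g}x{b:g}",
        period_left_mm=left, period_right_mm=right,
        stimulus_location=stim_loc, start_location=start_loc,
        demand=demand, block_index=block_index, trial_index=trial_index)


def build_trial_list(experiment_id: int, rng_seed: int | np.random.Generator = 0,
                     order: str = "low-first") -> list[TrialDesign]:
    """Build the randomized factorial trial list of one session.

    Experiment 1 presents every one of its 360 cells once in fully random
    order.  Experiments 2 and 3 block trials by task demand: each demand's
    144 cells are split at random into two blocks of 72, and the four
    blocks alternate (ABAB), with ``order`` deciding which demand starts.
    """
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    if experiment_id == 1:
        cells = _exp1_cells()
        rng.shuffle(cells)
        return [_cell_to_trial(c, 1, "none", i // _EXP1_BLOCK + 1, i + 1)
                for i, c in enumerate(cells)]
    if experiment_id in (2, 3):
        if order not in ("low-first", "high-first"):
            raise ValueError("order must be 'low-first' or 'high-first'")
        first = "low" if order == "low-first" else "high"
        second = "high" if first == "low" else "low"
        halves: dict[str, list[list[tuple]]] = {}
        for demand in ("low", "high"):
            cells = _exp23_cells(experiment_id, demand)
            rng.shuffle(cells)
            halves[demand] = [cells[:_EXP23_BLOCK], cells[_EXP23_BLOCK:]]
        sequence = [halves[first][0], halves[second][0],
                    halves[first][1], halves[second][1]]
        demands = [first, second, first, second]
        trials: list[TrialDesign] = []
        idx = 1
        for block_i, (block, demand) in enumerate(zip(sequence, demands), start=1):
            for cell in block:
                trials.append(_cell_to_trial(cell, experiment_id, demand,
                                             block_i, idx))
                idx += 1
        return trials
    raise ValueError(f"unknown experiment_id {experiment_id!r}")


def design_to_frame(trials: Iterable[TrialDesign],
                    participant: int | None = None,
                    order: str | None = None) -> pd.DataFrame:
    df = pd.DataFrame([vars(t) for t in trials])
    if participant is not None:
        df.insert(0, "participant", participant)
    if order is not None:
        df["order"] = order
    return df


# --------------------------------------------------------------------------
# generative model of one exploration
# --------------------------------------------------------------------------

def default_prior_weight(quality_fraction: float) -> float:
    """Default mixture weight w(q) = min(1, 0.2 + 0.9 q).

    Chosen so simulated orthogonal-initial proportions rise from somewhat
    above chance at q = 0 to roughly 35-45% at q = 0.5; a qualitative
    stand-in, not a fitted quantity.
    """
    return min(1.0, 0.2 + 0.9 * quality_fraction)


@dataclass(frozen=True)
class SimParams:
    """Generative parameters of the synthetic-trajectory model.

    ``weight_fn`` maps prior quality q to the probability that the initial
    stroke is drawn from the orthogonal von Mises component rather than the
    uniform one; ``time_weight_fn``, if given, replaces it with a
    session-progress-dependent weight w(q, progress) to emulate gradual
    learning.  Concentrations are on the doubled-angle scale.
    """

    weight_fn: Callable[[float], float] = default_prior_weight
    time_weight_fn: Callable[[float, float], float] | None = None
    kappa_initial: float = 2.0
    kappa_late: float = 8.0
    late_weight: float = 0.9
    strokes_per_trial_mean: float = 6.6
    switches_per_trial_mean: float = 1.7
    stroke_speed_mm_s: float = 100.0
    sampling_rate_hz: float = 500.0
    force_peak_n: float = 1.0
    force_noise_sd_n: float = 0.01
    position_noise_sd_mm: float = 0.05
    response_accuracy: float = 0.911
    texture_radius_mm: float = stimuli.TEXTURE_DIAMETER_MM / 2.0
    stimulus_centers_mm: tuple[tuple[float, float], tuple[float, float]] = (
        (-65.0, 0.0), (65.0, 0.0))
    min_stroke_length_mm: float = 30.0
    border_margin_mm: float = 1.5

    def __post_init__(self) -> None:
        if self.kappa_initial < 0 or self.kappa_late < 0:
            raise ValueError("concentrations must be nonnegative")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        if self.stroke_speed_mm_s <= 0:
            raise ValueError("stroke_speed_mm_s must be positive")
        if self.force_peak_n <= 0.1:
            warnings.warn("force_peak_n at or below the 0.1 N contact gate: "
                          "simulated strokes will not register as contacts",
                          stacklevel=2)

    def initial_weight(self, quality_fraction: float,
                       progress: float = 0.0) -> float:
        if self.time_weight_fn is not None:
            w = self.time_weight_fn(quality_fraction, progress)
        else:
            w = self.weight_fn(quality_fraction)
        if not 0.0 <= w <= 1.0:
            raise ValueError(f"mixture weight {w} outside [0, 1]")
        return w


@dataclass(frozen=True)
class StrokeTruth:
    """Ground-truth annotation of one simulated stroke."""

    start_index: int      # half-open [start, end) span in the sample arrays
    end_index: int
    direction_deg: float  # axial, lab frame
    relative_direction_deg: float  # axial, texture-aligned
    side: str
    role: str             # initial / middle / last / other


@dataclass
class Trajectory:
    """One trial's uniformly sampled (time, x, z, force) series."""

    time_s: np.ndarray
    x_mm: np.ndarray
    z_mm: np.ndarray
    force_n: np.ndarray
    sampling_rate_hz: float
    trial: TrialDesign | None = None
    ground_truth: list[StrokeTruth] | None = None

    def __post_init__(self) -> None:
        n = self.time_s.size
        if not (self.x_mm.size == self.z_mm.size == self.force_n.size == n):
            raise ValueError("all trajectory series must have equal length")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.time_s, "x_mm": self.x_mm,
                             "z_mm": self.z_mm, "force_n": self.force_n})


def middle_stroke_index(n_strokes: int) -> int | None:
    """0-based index of the middle stroke; the later candidate for even counts.

    Returns None for a single stroke (middle undefined).
    """
    if n_strokes < 1:
        raise ValueError("need at least one stroke")
    if n_strokes == 1:
        return None
    if n_strokes % 2 == 1:
        return (n_strokes + 1) // 2 - 1   # 1-based ceil(n/2)
    return n_strokes // 2                 # 1-based n/2 + 1


def _role_labels(n_strokes: int) -> list[str]:
    roles = ["other"] * n_strokes
    mid = middle_stroke_index(n_strokes)
    if mid is not None:
        roles[mid] = "middle"
    roles[n_strokes - 1] = "last"
    roles[0] = "initial"  # for n == 1 the single stroke counts as initial (and last)
    return roles


def sample_stroke_direction(role: str, trial: TrialDesign, params: SimParams,
                            rng: np.random.Generator,
                            progress: float = 0.0) -> float:
    """Draw one stroke direction relative to the texture, in [0, 180) deg.

    With probability w (quality-dependent for the initial stroke, a fixed
    high weight for later ones) the direction comes from an axial von Mises
    centred at 90 deg; otherwise it is uniform on the axis.
    """
    if role == "initial":
        w = params.initial_weight(trial.quality_fraction, progress)
        kappa = params.kappa_initial
    elif role in ("middle", "last", "other"):
        w = params.late_weight
        kappa = params.kappa_late
    else:
        raise ValueError(f"unknown stroke role {role!r}")
    if rng.random() < w:
        return float(sample_axial_vonmises(1, 90.0, kappa, rng)[0])
    return float(rng.uniform(0.0, 180.0))


def _chord_extents(midpoint: np.ndarray, center: np.ndarray, unit: np.ndarray,
                   radius: float) -> tuple[float, float]:
    """Distances from midpoint to the circle border along +unit and -unit."""
    rel = midpoint - center
    b = float(rel @ unit)
    c = float(rel @ rel) - radius**2
    disc = b * b - c
    if disc <= 0:
        return 0.0, 0.0
    root = math.sqrt(disc)
    return root - b, root + b  # t_plus, t_minus (both positive for interior points)


def _axial_direction_deg(start: np.ndarray, end: np.ndarray) -> float:
    return math.degrees(math.atan2(end[1] - start[1], end[0] - start[0])) % 180.0


def simulate_trial(trial: TrialDesign, params: SimParams,
                   rng: np.random.Generator, n_strokes: int | None = None,
                   progress: float = 0.0) -> Trajectory:
    """Simulate one trial's trajectory with ground-truth stroke annotations.

    Strokes are straight constant-speed chords inside the touched disc,
    clipped to the border; the normal force sits at ``force_peak_n`` during
    a stroke and near zero for at least 0.3 s between strokes, so each
    stroke forms one supra-threshold contact episode.
    """
    fs = params.sampling_rate_hz
    centers = {side: np.asarray(c, dtype=float)
               for side, c in zip(("left", "right"), params.stimulus_centers_mm)}
    r_eff = params.texture_radius_mm - params.border_margin_mm

    if n_strokes is None:
        n_strokes = max(2, 1 + int(rng.poisson(max(params.strokes_per_trial_mean - 1.0,
                                                   0.0))))
    n_switches = int(min(rng.poisson(params.switches_per_trial_mean), n_strokes - 1))
    sides = [trial.start_location]
    switch_at = set(rng.choice(n_strokes - 1, size=n_switches, replace=False).tolist()) \
        if n_strokes > 1 and n_switches > 0 else set()
    for i in range(1, n_strokes):
        prev = sides[-1]
        if (i - 1) in switch_at:
            sides.append("right" if prev == "left" else "left")
        else:
            sides.append(prev)

    roles = _role_labels(n_strokes)
    x_parts: list[np.ndarray] = []
    z_parts: list[np.ndarray] = []
    f_parts: list[np.ndarray] = []
    truth: list[StrokeTruth] = []

    lead_n = int(round(0.3 * fs))
    pos = centers[sides[0]] + np.array([0.0, -(params.texture_radius_mm + 15.0)])
    cursor = 0

    def _append_transit(target: np.ndarray, duration_s: float) -> None:
        nonlocal pos, cursor
        n = max(int(round(duration_s * fs)), 2)
        frac = np.linspace(0.0, 1.0, n, endpoint=False)
        seg = pos[None, :] + frac[:, None] * (target - pos)[None, :]
        x_parts.append(seg[:, 0])
        z_parts.append(seg[:, 1])
        f_parts.append(np.zeros(n))
        pos = target.copy()
        cursor += n

    first_planned = True
    for i in range(n_strokes):
        side = sides[i]
        center = centers[side]
        rel_dir = sample_stroke_direction(roles[i], trial, params, rng, progress)
        lab_dir = (rel_dir + trial.orientation_deg) % 180.0
        sign = 1.0 if rng.random() < 0.5 else -1.0
        theta = math.radians(lab_dir)
        unit = sign * np.array([math.cos(theta), math.sin(theta)])

        # midpoint near the disc centre; fall back to the full chord when the
        # sampled length cannot fit (never an error, the path is truncated)
        rho = 0.3 * params.texture_radius_mm * math.sqrt(rng.random())
        phi = rng.uniform(0.0, 2.0 * math.pi)
        mid = center + rho * np.array([math.cos(phi), math.sin(phi)])
        t_plus, t_minus = _chord_extents(mid, center, unit, r_eff)
        half = 0.5 * rng.uniform(0.9, 1.7) * params.texture_radius_mm
        a, b = min(half, t_plus), min(half, t_minus)
        if a + b < params.min_stroke_length_mm:
            a, b = t_plus, t_minus
        start = mid - b * unit
        end = mid + a * unit
        length = float(np.hypot(*(end - start)))

        # reach the stroke start with the force off
        if first_planned:
            _append_transit(start, lead_n / fs)
            first_planned = False
        else:
            gap = rng.uniform(0.35, 0.6)
            _append_transit(start, gap)

        n_samp = max(int(round(length / params.stroke_speed_mm_s * fs)), 4)
        frac = np.linspace(0.0, 1.0, n_samp)
        seg = start[None, :] + frac[:, None] * (end - start)[None, :]
        x_parts.append(seg[:, 0])
        z_parts.append(seg[:, 1])
        f_parts.append(np.full(n_samp, params.force_peak_n))
        truth.append(StrokeTruth(
            start_index=cursor, end_index=cursor + n_samp,
            direction_deg=_axial_direction_deg(start, end),
            relative_direction_deg=(_axial_direction_deg(start, end)
                                    - trial.orientation_deg) % 180.0,
            side=side, role=roles[i]))
        pos = end.copy()
        cursor += n_samp

    # short stationary tail with the finger lifted
    tail = max(int(round(0.2 * fs)), 2)
    x_parts.append(np.full(tail, pos[0]))
    z_parts.append(np.full(tail, pos[1]))
    f_parts.append(np.zeros(tail))

    x = np.concatenate(x_parts)
    z = np.concatenate(z_parts)
    f = np.concatenate(f_parts)
    if params.position_noise_sd_mm > 0:
        x = x + rng.normal(0.0, params.position_noise_sd_mm, x.size)
        z = z + rng.normal(0.0, params.position_noise_sd_mm, z.size)
    if params.force_noise_sd_n > 0:
        f = f + rng.normal(0.0, params.force_noise_sd_n, f.size)
    f = np.maximum(f, 0.0)
    t = np.arange(x.size) / fs
    return Trajectory(time_s=t, x_mm=x, z_mm=z, force_n=f,
                      sampling_rate_hz=fs, trial=trial, ground_truth=truth)


# --------------------------------------------------------------------------
# whole-session / whole-experiment simulation
# --------------------------------------------------------------------------

@dataclass
class ParticipantData:
    participant: int
    order: str
    trials: list[TrialDesign]
    trajectories: dict[int, Trajectory]          # keyed by trial_index
    responses: pd.DataFrame


@dataclass
class Dataset:
    experiment_id: int
    design: pd.DataFrame
    responses: pd.DataFrame
    trajectories: dict[tuple[int, int], Trajectory]  # (participant, trial_index)
    ground_truth: pd.DataFrame | None = None


_PARTICIPANT_SEED_STRIDE = 7919  # fixed offset between per-participant streams


def participant_order(participant: int) -> str:
    """Counterbalanced demand order: odd participants start with low demand."""
    return "low-first" if participant % 2 == 1 else "high-first"


def simulate_participant(experiment_id: int, participant: int, params: SimParams,
                         master_seed: int, order: str | None = None) -> ParticipantData:
    """Simulate one participant's full session from an independent RNG stream."""
    seed = int(master_seed) + _PARTICIPANT_SEED_STRIDE * int(participant)
    rng = np.random.default_rng(seed)
    if order is None:
        order = participant_order(participant) if experiment_id != 1 else "low-first"
    trials = build_trial_list(experiment_id, rng, order=order)
    n_total = len(trials)
    trajectories: dict[int, Trajectory] = {}
    records = []
    for trial in trials:
        progress = (trial.trial_index - 1) / max(n_total - 1, 1)
        trajectories[trial.trial_index] = simulate_trial(trial, params, rng,
                                                         progress=progress)
        correct = bool(rng.random() < params.response_accuracy)
        high = trial.high_frequency_side
        chosen = high if correct else ("left" if high == "right" else "right")
        records.append({"participant": participant,
                        "trial_index": trial.trial_index,
                        "chosen_side": chosen, "correct": correct,
                        "response_time_s": float(rng.uniform(0.5, 2.0))})
    return ParticipantData(participant=participant, order=order, trials=trials,
                           trajectories=trajectories,
                           responses=pd.DataFrame(records))


def ground_truth_to_frame(participant: int, trajectories: dict[int, Trajectory]
                          ) -> pd.DataFrame:
    rows = []
    for trial_index, traj in trajectories.items():
        for k, s in enumerate(traj.ground_truth or []):
            rows.append({"participant": participant, "trial_index": trial_index,
                         "ordinal": k + 1, "start_index": s.start_index,
                         "end_index": s.end_index,
                         "direction_deg": s.direction_deg,
                         "relative_direction_deg": s.relative_direction_deg,
                         "side": s.side, "role": s.role})
    return pd.DataFrame(rows)


def simulate_experiment(experiment_id: int, n_participants: int,
                        params: SimParams | None = None,
                        seed: int = 0) -> Dataset:
    """Simulate a full multi-participant experiment as an in-memory dataset.

    Per-participant RNG streams are derived from the master seed by a fixed
    offset, so any participant can be re-simulated independently.
    """
    if n_participants < 1:
        raise ValueError("n_participants must be at least 1")
    params = params or SimParams()
    designs, responses, truths = [], [], []
    trajectories: dict[tuple[int, int], Trajectory] = {}
    for pid in range(1, n_participants + 1):
        pdata = simulate_participant(experiment_id, pid, params, seed)
        designs.append(design_to_frame(pdata.trials, participant=pid,
                                       order=pdata.order))
        responses.append(pdata.responses)
        truths.append(ground_truth_to_frame(pid, pdata.trajectories))
        for idx, traj in pdata.trajectories.items():
            trajectories[(pid, idx)] = traj
    return Dataset(experiment_id=experiment_id,
                   design=pd.concat(designs, ignore_index=True),
                   responses=pd.concat(responses, ignore_index=True),
                   trajectories=trajectories,
                   ground_truth=pd.concat(truths, ignore_index=True))
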
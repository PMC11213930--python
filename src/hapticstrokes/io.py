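"""Dataset serialization, configuration, and provenance.

On-disk layout of one dataset (all CSV, UTF-8, header row, '.' decimals):

    <root>/design.csv                 one row per participant x trial
    <root>/responses.csv              one row per trial
    <root>/ground_truth.csv           synthetic datasets only
    <root>/trajectories/p<participant>/trial_<index>.csv
                                      time_s, x_mm, z_mm, force_n

Every file written here starts with provenance comment lines (tool version,
config hash, seed) so a run is reproducible from its artifacts alone; the
readers skip lines starting with '#'.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .segmentation import SegmentationConfig
from .simulate import Dataset, SimParams, TrialDesign, Trajectory

__all__ = [
    "PipelineConfig",
    "write_dataset",
    "read_dataset",
    "resample_to_position_clock",
    "load_config",
    "save_config",
    "config_hash",
    "get_logger",
]

log = logging.getLogger("hapticstrokes")


def get_logger(level: str = "INFO") -> logging.Logger:
    if not log.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(logging.Formatter(
            "%(asctime)s %(name)s %(levelname)s %(message)s"))
        log.addHandler(handler)
    log.setLevel(level.upper())
    return log


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Everything a pipeline run needs, materialized to YAML next to outputs."""

    experiment_id: int = 1
    dataset_root: str = "dataset"
    output_root: str = "results"
    master_seed: int = 0
    window_halfwidth_deg: float = 15.0
    axial_mode: str = "double"
    n_quarters: int = 4
    log_level: str = "INFO"
    segmentation: dict = field(default_factory=dict)   # SegmentationConfig overrides
    simulation: dict = field(default_factory=dict)     # SimParams overrides

    def __post_init__(self) -> None:
        if self.master_seed < 0:
            raise ValueError("master_seed must be nonnegative")

    def segmentation_config(self) -> SegmentationConfig:
        return SegmentationConfig(**{
            k: tuple(tuple(c) for c in v) if k == "stimulus_centers_mm" else v
            for k, v in self.segmentation.items()})

    def sim_params(self) -> SimParams:
        return SimParams(**{
            k: tuple(tuple(c) for c in v) if k == "stimulus_centers_mm" else v
            for k, v in self.simulation.items()})


def config_hash(config: PipelineConfig) -> str:
    canon = yaml.safe_dump(dataclasses.asdict(config), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


def load_config(path: str | Path) -> PipelineConfig:
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    return PipelineConfig(**raw)


def save_config(config: PipelineConfig, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=True)


# --------------------------------------------------------------------------
# provenance-stamped CSV
# --------------------------------------------------------------------------

def _provenance_lines(seed: int | None, cfg_hash: str | None) -> str:
    parts = [f"# hapticstrokes {__version__}"]
    if cfg_hash is not None:
        parts.append(f"# config_hash: {cfg_hash}")
    if seed is not None:
        parts.append(f"# seed: {seed}")
    return "\n".join(parts) + "\n"


def write_csv(df: pd.DataFrame, path: Path, seed: int | None = None,
              cfg_hash: str | None = None) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(_provenance_lines(seed, cfg_hash))
        df.to_csv(fh, index=False, float_format="%.6f", lineterminator="\n")


def read_csv(path: Path) -> pd.DataFrame:
    _check_dialect(path)
    try:
        return pd.read_csv(path, comment="#")
    except (pd.errors.ParserError, ValueError) as err:
        raise ValueError(f"could not parse {path}: {err}. If the file uses "
                         "decimal commas, convert it to '.'-decimal CSV") from err


def _check_dialect(path: Path) -> None:
    """Reject decimal-comma files, which silently mis-parse as extra columns."""
    header = data = None
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            if header is None:
                header = line
            else:
                data = line
                break
    if header is not None and data is not None:
        if data.count(",") > header.count(","):
            raise ValueError(
                f"{path} has more fields in its data rows than in the header; "
                "this usually means decimal commas were used. Convert the file "
                "to '.'-decimal CSV")


# --------------------------------------------------------------------------
# dataset round-trip
# --------------------------------------------------------------------------

def _trajectory_path(root: Path, participant: int, trial_index: int) -> Path:
    return root / "trajectories" / f"p{participant:03d}" / f"trial_{trial_index:04d}.csv"


def write_dataset(dataset: Dataset, root: str | Path,
                  seed: int | None = None, cfg_hash: str | None = None) -> Path:
    root = Path(root)
    write_csv(dataset.design, root / "design.csv", seed, cfg_hash)
    write_csv(dataset.responses, root / "responses.csv", seed, cfg_hash)
    if dataset.ground_truth is not None and not dataset.ground_truth.empty:
        write_csv(dataset.ground_truth, root / "ground_truth.csv", seed, cfg_hash)
    for (pid, idx), traj in dataset.trajectories.items():
        write_csv(traj.to_frame(), _trajectory_path(root, pid, idx))
    (root / "experiment.json").write_text(
        json.dumps({"experiment_id": dataset.experiment_id,
                    "version": __version__}) + "\n", encoding="utf-8")
    return root


_DESIGN_COLUMNS = [f.name for f in dataclasses.fields(TrialDesign)]


def read_dataset(root: str | Path, load_trajectories: bool = True) -> Dataset:
    """Read a dataset directory, validating layout and time monotonicity."""
    root = Path(root)
    design_path = root / "design.csv"
    if not design_path.exists():
        raise FileNotFoundError(f"no design.csv under {root}")
    design = read_csv(design_path)
    responses_path = root / "responses.csv"
    responses = read_csv(responses_path) if responses_path.exists() \
        else pd.DataFrame(columns=["participant", "trial_index", "chosen_side",
                                   "correct"])
    gt_path = root / "ground_truth.csv"
    ground_truth = read_csv(gt_path) if gt_path.exists() else None
    meta_path = root / "experiment.json"
    exp_id = int(json.loads(meta_path.read_text())["experiment_id"]) \
        if meta_path.exists() else int(design["experiment_id"].iloc[0])

    trajectories: dict[tuple[int, int], Trajectory] = {}
    if load_trajectories:
        missing: list[tuple[int, int]] = []
        for _, row in design.iterrows():
            pid, idx = int(row["participant"]), int(row["trial_index"])
            path = _trajectory_path(root, pid, idx)
            if not path.exists():
                missing.append((pid, idx))
                continue
            tdf = read_csv(path)
            needed = {"time_s", "x_mm", "z_mm", "force_n"}
            if not needed.issubset(tdf.columns) or tdf.empty:
                raise ValueError(f"truncated or malformed trajectory file {path}")
            t = tdf["time_s"].to_numpy(float)
            if np.any(np.diff(t) <= 0):
                raise ValueError(f"non-monotone time in {path}")
            fs = 1.0 / float(np.median(np.diff(t)))
            trial = _row_to_trial(row)
            trajectories[(pid, idx)] = Trajectory(
                time_s=t, x_mm=tdf["x_mm"].to_numpy(float),
                z_mm=tdf["z_mm"].to_numpy(float),
                force_n=tdf["force_n"].to_numpy(float),
                sampling_rate_hz=fs, trial=trial)
        if missing:
            raise FileNotFoundError(
                f"{len(missing)} trajectories referenced by design.csv are "
                f"missing, e.g. {missing[:5]}")
    return Dataset(experiment_id=exp_id, design=design, responses=responses,
                   trajectories=trajectories, ground_truth=ground_truth)


def _row_to_trial(row: pd.Series) -> TrialDesign:
    kwargs = {}
    for name in _DESIGN_COLUMNS:
        val = row[name]
        if name in ("experiment_id", "block_index", "trial_index"):
            val = int(val)
        elif name in ("quality_fraction", "orientation_deg",
                      "period_left_mm", "period_right_mm"):
            val = float(val)
        else:
            val = str(val)
        kwargs[name] = val
    return TrialDesign(**kwargs)


def resample_to_position_clock(force_time_s: np.ndarray, force_n: np.ndarray,
                               position_time_s: np.ndarray) -> np.ndarray:
    """Linearly interpolate a force series onto the position sample clock.

    Real recordings sample force and position at different rates; the
    segmentation expects a single common clock.
    """
    return np.interp(position_time_s, force_time_s, force_n)
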
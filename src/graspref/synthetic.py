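"""Synthetic pattern datasets, trial schedules, and BOLD time series.

Every generator has a known ground truth so downstream stages (decoding,
evidence combination, searchlight, group inference) can be validated by
parameter recovery. Voxel tuning prototypes are i.i.d. standard Gaussian
per coded level; per-run noise is spherical Gaussian with unit SD, and the
prototype contribution is scaled by ``snr`` (signal SD / noise SD), so
``snr = 0`` yields label-independent data.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .design_space import CONFIG_LABELS, make_configurations

__all__ = [
    "CODING_SCHEMES",
    "MODALITY_MODELS",
    "MODALITIES",
    "SimulationSpec",
    "PatternDataset",
    "simulate_patterns",
    "simulate_schedule",
    "schedule_to_bids",
    "simulate_bold",
    "simulate_volume",
]

CODING_SCHEMES = ("gaze_centered", "body_centered", "gaze_direction", "mixed", "null")
MODALITY_MODELS = ("shared", "independent", "switching")
MODALITIES = ("visual", "somaesthetic")


@dataclass(frozen=True)
class SimulationSpec:
    """Ground-truth recipe for one simulated dataset pair.

    ``mix_weight`` is the gaze-centered share under the ``mixed`` scheme.
    ``run_jitter_sd`` adds an independent Gaussian perturbation of the
    prototype per run (between-run pattern variability), also scaled by snr.
    """

    coding_scheme: str = "null"
    n_voxels: int = 50
    n_runs_per_modality: int = 8
    snr: float = 0.0
    seed: int = 0
    mix_weight: float = 0.5
    modality_model: str = "shared"
    run_jitter_sd: float = 0.0

    def __post_init__(self):
        if self.coding_scheme not in CODING_SCHEMES:
            raise ValueError(f"unknown coding_scheme {self.coding_scheme!r}")
        if self.modality_model not in MODALITY_MODELS:
            raise ValueError(f"unknown modality_model {self.modality_model!r}")
        if self.n_voxels <= 0:
            raise ValueError("n_voxels must be positive")
        if self.n_runs_per_modality <= 0:
            raise ValueError("n_runs_per_modality must be positive")
        if self.snr < 0:
            raise ValueError("snr must be nonnegative")
        if not 0.0 <= self.mix_weight <= 1.0:
            raise ValueError("mix_weight must lie in [0, 1]")
        if self.run_jitter_sd < 0:
            raise ValueError("run_jitter_sd must be nonnegative")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class PatternDataset:
    """Per-run, per-configuration voxel patterns for one modality.

    ``values`` has shape ``(n_runs, n_configurations, n_voxels)`` and holds
    t-value-like reals — exactly one pattern per configuration per run.
    Volumetric datasets additionally carry ``affine`` and a 3D boolean
    ``mask``; the voxel axis then follows C-order over the in-mask voxels.
    """

    values: np.ndarray
    modality: str
    run_ids: Sequence = None
    config_labels: Sequence[str] = CONFIG_LABELS
    affine: Optional[np.ndarray] = None
    mask: Optional[np.ndarray] = None
    flagged_voxels: Optional[np.ndarray] = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be (runs, configurations, voxels)")
        if self.values.shape[1] != len(self.config_labels):
            raise ValueError("values second axis must match config_labels")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("patterns contain non-finite values")
        if self.run_ids is None:
            self.run_ids = list(range(self.values.shape[0]))
        if len(self.run_ids) != self.values.shape[0]:
            raise ValueError("run_ids length must match number of runs")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if int(self.mask.sum()) != self.n_voxels:
                raise ValueError("mask voxel count does not match values")

    @property
    def n_runs(self) -> int:
        return self.values.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.values.shape[2]

    def config_index(self, label: str) -> int:
        try:
            return list(self.config_labels).index(label)
        except ValueError:
            raise KeyError(f"unknown configuration label {label!r}") from None

    def select_voxels(self, voxel_idx: np.ndarray) -> "PatternDataset":
        """Restrict to a voxel subset (e.g. one searchlight sphere)."""
        return PatternDataset(
            values=self.values[:, :, voxel_idx],
            modality=self.modality,
            run_ids=list(self.run_ids),
            config_labels=self.config_labels,
        )

    def mean_pattern(self, label: str) -> np.ndarray:
        """Across-run mean pattern for one configuration."""
        return self.values[:, self.config_index(label), :].mean(axis=0)


def _config_levels() -> dict:
    """Coded-level index per configuration for each elementary scheme."""
    configs = make_configurations()
    side = {"left": 0, "right": 1}
    gaze = {"left": 0, "center": 1, "right": 2}
    return {
        "gaze_centered": {c.label: side[c.target_side_gaze] for c in configs},
        "body_centered": {c.label: side[c.target_side_body] for c in configs},
        "gaze_direction": {c.label: gaze[c.gaze_position] for c in configs},
    }


_LEVELS = _config_levels()


def _signal_matrix(scheme: str, mix_weight: float, n_voxels: int, rng) -> np.ndarray:
    """Noise-free signal per configuration, shape (4, n_voxels).

    Prototypes are drawn per coded level even for the null scheme (and then
    discarded) so that datasets with different schemes but the same seed
    consume the generator stream identically.
    """
    gc = rng.standard_normal((2, n_voxels))
    bc = rng.standard_normal((2, n_voxels))
    gd = rng.standard_normal((3, n_voxels))
    if scheme == "null":
        return np.zeros((len(CONFIG_LABELS), n_voxels))
    rows = []
    for label in CONFIG_LABELS:
        if scheme == "gaze_centered":
            rows.append(gc[_LEVELS["gaze_centered"][label]])
        elif scheme == "body_centered":
            rows.append(bc[_LEVELS["body_centered"][label]])
        elif scheme == "gaze_direction":
            rows.append(gd[_LEVELS["gaze_direction"][label]])
        elif scheme == "mixed":
            rows.append(
                mix_weight * gc[_LEVELS["gaze_centered"][label]]
                + (1.0 - mix_weight) * bc[_LEVELS["body_centered"][label]]
            )
        else:  # pragma: no cover
            raise ValueError(scheme)
    return np.stack(rows)


def simulate_patterns(spec: SimulationSpec) -> tuple[PatternDataset, PatternDataset]:
    """Simulate one pattern dataset per modality under ``spec``.

    Returns
    -------
    (visual, somaesthetic) : tuple of PatternDataset
        Under ``modality_model="shared"`` the two modalities reuse identical
        prototypes; ``"independent"`` draws fresh prototypes; ``"switching"``
        makes the visual dataset gaze-centered and the somaesthetic dataset
        body-centered (with independent prototypes).
    """
    rng = np.random.default_rng(spec.seed)
    proto_rng = np.random.default_rng(rng.integers(2**63))
    noise_rng = np.random.default_rng(rng.integers(2**63))

    if spec.modality_model == "switching":
        schemes = {"visual": "gaze_centered", "somaesthetic": "body_centered"}
    else:
        schemes = {m: spec.coding_scheme for m in MODALITIES}

    signals = {}
    shared = None
    for m in MODALITIES:
        if spec.modality_model == "shared":
            if shared is None:
                shared = _signal_matrix(schemes[m], spec.mix_weight, spec.n_voxels, proto_rng)
            signals[m] = shared
        else:
            signals[m] = _signal_matrix(schemes[m], spec.mix_weight, spec.n_voxels, proto_rng)

    out = []
    for m in MODALITIES:
        sig = signals[m]
        vals = np.empty((spec.n_runs_per_modality, len(CONFIG_LABELS), spec.n_voxels))
        for r in range(spec.n_runs_per_modality):
            run_sig = sig
            if spec.run_jitter_sd > 0:
                run_sig = sig + spec.run_jitter_sd * noise_rng.standard_normal(sig.shape)
            vals[r] = spec.snr * run_sig + noise_rng.standard_normal(sig.shape)
        out.append(PatternDataset(values=vals, modality=m))
    return tuple(out)


# ---------------------------------------------------------------------------
# Trial schedules


def simulate_schedule(
    n_runs: int,
    trials_per_run: int,
    delay_range_s: tuple[float, float] = (3.0, 6.0),
    seed: int = 0,
    start_fixation_s: float = 20.0,
    end_fixation_s: float = 10.0,
    movement_s: float = 3.0,
    inter_trial_s: float = 1.5,
) -> pd.DataFrame:
    """Simulate an event schedule balanced over the four configurations.

    Each run begins with ``start_fixation_s`` and ends with
    ``end_fixation_s`` of fixation. Trial counts per configuration are split
    as evenly as possible within a run, with the remainder rotated across
    runs so that totals balance exactly over the whole session (16 runs of
    22 trials give 88 trials per configuration). Within each run the trial
    order greedily equalizes first-order configuration transitions. Delays
    are uniform on ``delay_range_s``.

    Returns a DataFrame with one row per trial: run, trial, configuration,
    cue_onset, delay, go_onset, movement_end, saccade_onset, run_end.
    """
    lo, hi = delay_range_s
    if hi < lo:
        raise ValueError("delay range inverted")
    if n_runs <= 0 or trials_per_run <= 0:
        raise ValueError("n_runs and trials_per_run must be positive")
    rng = np.random.default_rng(seed)
    n_cfg = len(CONFIG_LABELS)

    base, rem = divmod(trials_per_run, n_cfg)
    transition_counts = np.zeros((n_cfg, n_cfg), dtype=int)
    rows = []
    extra_cursor = 0
    for run in range(n_runs):
        counts = np.full(n_cfg, base, dtype=int)
        for _ in range(rem):
            counts[extra_cursor % n_cfg] += 1
            extra_cursor += 1
        # greedy first-order counterbalancing of configuration transitions
        order = []
        prev = None
        remaining = counts.copy()
        while remaining.sum() > 0:
            avail = np.flatnonzero(remaining > 0)
            if prev is None:
                choice = rng.choice(avail)
            else:
                costs = transition_counts[prev, avail]
                best = avail[costs == costs.min()]
                choice = rng.choice(best)
                transition_counts[prev, choice] += 1
            order.append(int(choice))
            remaining[choice] -= 1
            prev = int(choice)

        t = start_fixation_s
        for i, cfg in enumerate(order):
            delay = float(rng.uniform(lo, hi))
            cue, go = t, t + delay
            move_end = go + movement_s
            rows.append(
                {
                    "run": run,
                    "trial": i,
                    "configuration": CONFIG_LABELS[cfg],
                    "cue_onset": cue,
                    "delay": delay,
                    "go_onset": go,
                    "movement_end": move_end,
                    "saccade_onset": go + 2.0,
                }
            )
            t = move_end + inter_trial_s
        run_end = t - inter_trial_s + end_fixation_s
        for r in rows:
            if r["run"] == run and "run_end" not in r:
                r["run_end"] = run_end
    return pd.DataFrame(rows)


def schedule_to_bids(schedule: pd.DataFrame) -> pd.DataFrame:
    """Flatten a schedule to BIDS-style events (onset, duration, trial_type, run)."""
    rows = []
    for _, tr in schedule.iterrows():
        rows.append(
            {
                "onset": tr.cue_onset,
                "duration": tr.delay,
                "trial_type": f"plan_{tr.configuration}",
                "run": int(tr.run),
            }
        )
        rows.append(
            {
                "onset": tr.go_onset,
                "duration": tr.movement_end - tr.go_onset,
                "trial_type": f"move_{tr.configuration}",
                "run": int(tr.run),
            }
        )
    return pd.DataFrame(rows).sort_values(["run", "onset"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# BOLD simulation


def simulate_bold(
    schedule_run: pd.DataFrame,
    true_betas: np.ndarray,
    noise_sd: float,
    tr_s: float = 1.63,
    seed: int = 0,
    drift_amplitude: float = 0.0,
    n_scans: Optional[int] = None,
) -> np.ndarray:
    """Simulate a (scans, voxels) run from delay-period responses.

    Delay-period boxcars per configuration are convolved with the canonical
    HRF, scaled by ``true_betas`` (shape ``(4, n_voxels)``), plus i.i.d.
    Gaussian noise and an optional slow cosine drift.
    """
    from .glm import hrf_boxcar_regressor

    true_betas = np.asarray(true_betas, dtype=float)
    if true_betas.ndim != 2 or true_betas.shape[0] != len(CONFIG_LABELS):
        raise ValueError("true_betas must have shape (4, n_voxels)")
    if tr_s <= 0:
        raise ValueError("tr_s must be positive")
    if n_scans is None:
        n_scans = int(np.ceil(float(schedule_run["run_end"].iloc[0]) / tr_s))
    rng = np.random.default_rng(seed)

    P = np.zeros((n_scans, len(CONFIG_LABELS)))
    for j, label in enumerate(CONFIG_LABELS):
        trials = schedule_run[schedule_run.configuration == label]
        if len(trials):
            P[:, j] = hrf_boxcar_regressor(
                trials.cue_onset.to_numpy(), trials.delay.to_numpy(), n_scans, tr_s
            )
    y = P @ true_betas
    if drift_amplitude:
        t = np.arange(n_scans) * tr_s
        drift = drift_amplitude * np.cos(2 * np.pi * t / (2 * n_scans * tr_s))
        y = y + drift[:, None]
    if noise_sd:
        y = y + noise_sd * rng.standard_normal(y.shape)
    return y


# ---------------------------------------------------------------------------
# Volumetric fixtures


def simulate_volume(
    grid_shape: tuple[int, int, int],
    region_specs: Sequence[tuple[tuple, SimulationSpec]],
    voxel_size_mm: float = 3.5,
    n_runs_per_modality: int = 8,
    background_seed: int = 0,
) -> tuple[PatternDataset, PatternDataset]:
    """Simulate a volumetric dataset pair with region-wise coding schemes.

    ``region_specs`` is a list of ``(bbox, SimulationSpec)`` where ``bbox``
    is ``((x0, x1), (y0, y1), (z0, z1))`` in voxel indices (half-open).
    Voxels inside each region follow its scheme; background voxels are pure
    noise. Regions must not overlap. The affine is diagonal with
    ``voxel_size_mm`` spacing and the mask covers the whole grid.
    """
    grid_shape = tuple(int(s) for s in grid_shape)
    mask = np.ones(grid_shape, dtype=bool)
    claimed = np.zeros(grid_shape, dtype=bool)
    affine = np.diag([voxel_size_mm] * 3 + [1.0])
    n_vox = int(np.prod(grid_shape))
    n_cfg = len(CONFIG_LABELS)

    vals = {
        m: np.random.default_rng([background_seed, mi]).standard_normal(
            (n_runs_per_modality, n_cfg, n_vox)
        )
        for mi, m in enumerate(MODALITIES)
    }

    flat_index = np.arange(n_vox).reshape(grid_shape)
    for bbox, spec in region_specs:
        (x0, x1), (y0, y1), (z0, z1) = bbox
        if not (0 <= x0 < x1 <= grid_shape[0] and 0 <= y0 < y1 <= grid_shape[1]
                and 0 <= z0 < z1 <= grid_shape[2]):
            raise ValueError(f"region {bbox} outside grid {grid_shape}")
        box = np.s_[x0:x1, y0:y1, z0:z1]
        if claimed[box].any():
            raise ValueError(f"region {bbox} overlaps a previous region")
        claimed[box] = True
        region_idx = flat_index[box].ravel()
        rspec = dataclasses.replace(
            spec, n_voxels=len(region_idx), n_runs_per_modality=n_runs_per_modality
        )
        if rspec.n_runs_per_modality != n_runs_per_modality:
            raise ValueError("region run count must match volume run count")
        vis, som = simulate_patterns(rspec)
        vals["visual"][:, :, region_idx] = vis.values
        vals["somaesthetic"][:, :, region_idx] = som.values

    return tuple(
        PatternDataset(values=vals[m], modality=m, affine=affine, mask=mask)
        for m in MODALITIES
    )
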
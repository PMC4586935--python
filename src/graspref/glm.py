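"""First-level GLM: design construction, high-pass filtering, OLS fitting.

The per-run design follows a fixed recipe: four delay-period (planning)
boxcars and four movement-period boxcars — one per trial configuration —
three event spikes (stimulus, saccade cue, run onset), twelve motion
parameters, and five compartment-intensity regressors: 28 columns in all.
All hemodynamic columns share the same canonical (double-gamma) HRF.
The per-configuration planning-vs-baseline t-values are the patterns
consumed by the decoding stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .design_space import CONFIG_LABELS
from .synthetic import PatternDataset

__all__ = [
    "DesignMatrix",
    "GlmFit",
    "canonical_hrf",
    "hrf_boxcar_regressor",
    "build_design",
    "highpass",
    "dct_drift_basis",
    "fit_glm",
    "planning_contrasts",
    "patterns_from_bold",
]

DEFAULT_TR_S = 1.63
N_MOTION = 12
N_COMPARTMENT = 5


def canonical_hrf(tr_s: float, duration_s: float = 32.0) -> np.ndarray:
    """Canonical double-gamma HRF sampled at the scan rate.

    Response peak at 6 s, undershoot peaking at 16 s with 1/6 amplitude;
    normalized to unit sum so convolution preserves boxcar area.
    """
    t = np.arange(0, duration_s, tr_s)
    peak = scipy.stats.gamma.pdf(t, 6.0)
    under = scipy.stats.gamma.pdf(t, 16.0)
    h = peak - under / 6.0
    return h / h.sum()


def _boxcar(onsets, durations, n_scans: int, tr_s: float) -> np.ndarray:
    """Scan-sampled boxcar by exact fractional overlap with scan intervals.

    The integral (sum of samples) equals total duration / tr_s exactly.
    """
    x = np.zeros(n_scans)
    for onset, dur in zip(np.atleast_1d(onsets), np.atleast_1d(durations)):
        if dur < 0:
            raise ValueError("negative event duration")
        end = onset + dur
        for i in range(int(np.floor(onset / tr_s)), min(n_scans, int(np.ceil(end / tr_s)))):
            lo, hi = i * tr_s, (i + 1) * tr_s
            x[i] += max(0.0, min(hi, end) - max(lo, onset)) / tr_s
    return x


def _spike(onsets, n_scans: int, tr_s: float) -> np.ndarray:
    x = np.zeros(n_scans)
    for onset in np.atleast_1d(onsets):
        i = int(round(onset / tr_s))
        if 0 <= i < n_scans:
            x[i] += 1.0
    return x


def hrf_boxcar_regressor(onsets, durations, n_scans: int, tr_s: float) -> np.ndarray:
    """HRF-convolved boxcar regressor, truncated to the run length."""
    box = _boxcar(onsets, durations, n_scans, tr_s)
    return np.convolve(box, canonical_hrf(tr_s))[:n_scans]


@dataclass
class DesignMatrix:
    """Per-run design. ``matrix`` is (scans, regressors)."""

    matrix: np.ndarray
    names: list[str]
    tr_s: float
    empty_columns: list[str] = field(default_factory=list)

    @property
    def n_scans(self) -> int:
        return self.matrix.shape[0]

    def column(self, name: str) -> np.ndarray:
        return self.matrix[:, self.names.index(name)]


@dataclass
class GlmFit:
    betas: np.ndarray  # (regressor, voxel)
    t_map: np.ndarray  # (contrast, voxel)
    dof: int
    residual_var: np.ndarray = None


def _simulated_nuisance(n_scans: int, n_cols: int, rng, rho: float = 0.8,
                        amplitude: float = 0.05) -> np.ndarray:
    """Small-amplitude AR(1) series standing in for motion/compartment traces."""
    x = np.zeros((n_scans, n_cols))
    innov = rng.standard_normal((n_scans, n_cols))
    for i in range(1, n_scans):
        x[i] = rho * x[i - 1] + innov[i]
    return amplitude * x


def build_design(
    events: pd.DataFrame,
    n_scans: int,
    tr_s: float = DEFAULT_TR_S,
    include_nuisance: bool = True,
    nuisance: Optional[np.ndarray] = None,
    seed: int = 0,
) -> DesignMatrix:
    """Assemble the 28-regressor single-run design matrix.

    Parameters
    ----------
    events : DataFrame
        One run of a schedule (columns configuration, cue_onset, delay,
        go_onset, movement_end, saccade_onset).
    nuisance : optional (scans, 17) array
        Measured motion (12) + compartment (5) traces; simulated AR(1)
        series are used when omitted. Ignored if ``include_nuisance`` is
        False, leaving an 11-column task-only design.

    Planning boxcars span cue onset to Go (the delay period); movement
    boxcars span Go to hand return. Spikes mark stimulus (cue) onsets,
    saccade cues, and the run onset. Configurations with no trials yield a
    zero column recorded in ``empty_columns``.
    """
    if tr_s <= 0:
        raise ValueError("tr_s must be positive")
    run_len = n_scans * tr_s
    if len(events) and (events.cue_onset.min() < 0 or events.movement_end.max() > run_len):
        raise ValueError("events fall outside the run")
    unknown = set(events.configuration) - set(CONFIG_LABELS)
    if unknown:
        raise ValueError(f"unknown configuration labels {sorted(unknown)}")

    cols, names, empty = [], [], []
    for label in CONFIG_LABELS:
        tr = events[events.configuration == label]
        name = f"plan_{label}"
        if len(tr) == 0:
            cols.append(np.zeros(n_scans))
            empty.append(name)
        else:
            cols.append(
                hrf_boxcar_regressor(tr.cue_onset.to_numpy(), tr.delay.to_numpy(), n_scans, tr_s)
            )
        names.append(name)
    for label in CONFIG_LABELS:
        tr = events[events.configuration == label]
        name = f"move_{label}"
        if len(tr) == 0:
            cols.append(np.zeros(n_scans))
            empty.append(name)
        else:
            cols.append(
                hrf_boxcar_regressor(
                    tr.go_onset.to_numpy(),
                    (tr.movement_end - tr.go_onset).to_numpy(),
                    n_scans,
                    tr_s,
                )
            )
        names.append(name)

    hrf = canonical_hrf(tr_s)
    for name, onsets in [
        ("spike_stimulus", events.cue_onset.to_numpy()),
        ("spike_saccade", events.saccade_onset.to_numpy()),
        ("spike_run_onset", np.array([0.0])),
    ]:
        cols.append(np.convolve(_spike(onsets, n_scans, tr_s), hrf)[:n_scans])
        names.append(name)

    if include_nuisance:
        if nuisance is None:
            nuisance = _simulated_nuisance(
                n_scans, N_MOTION + N_COMPARTMENT, np.random.default_rng(seed)
            )
        nuisance = np.asarray(nuisance, dtype=float)
        if nuisance.shape != (n_scans, N_MOTION + N_COMPARTMENT):
            raise ValueError(
                f"nuisance must have shape ({n_scans}, {N_MOTION + N_COMPARTMENT})"
            )
        for i in range(N_MOTION):
            cols.append(nuisance[:, i])
            names.append(f"motion_{i + 1}")
        for i in range(N_COMPARTMENT):
            cols.append(nuisance[:, N_MOTION + i])
            names.append(f"compartment_{i + 1}")

    return DesignMatrix(np.column_stack(cols), names, tr_s, empty)


def dct_drift_basis(n_scans: int, tr_s: float, cutoff_s: float) -> np.ndarray:
    """Discrete-cosine drift basis (excluding the constant term).

    Includes cosines with period >= ``cutoff_s``; columns are orthonormal.
    """
    total = n_scans * tr_s
    k_max = int(np.floor(2.0 * total / cutoff_s))
    n = np.arange(n_scans)
    cols = [
        np.sqrt(2.0 / n_scans) * np.cos(np.pi * k * (2 * n + 1) / (2 * n_scans))
        for k in range(1, k_max + 1)
    ]
    return np.column_stack(cols) if cols else np.zeros((n_scans, 0))


def highpass(timeseries: np.ndarray, tr_s: float, cutoff_s: float = 128.0) -> np.ndarray:
    """Remove slow drifts by regressing out the DCT basis below the cutoff.

    The constant (mean) component is retained as baseline. If the run is
    shorter than half the cutoff period there is nothing to remove; the
    input is returned unchanged with a warning.
    """
    y = np.asarray(timeseries, dtype=float)
    squeeze = y.ndim == 1
    if squeeze:
        y = y[:, None]
    if cutoff_s <= 2 * tr_s:
        raise ValueError("cutoff_s must exceed twice the TR")
    basis = dct_drift_basis(y.shape[0], tr_s, cutoff_s)
    if basis.shape[1] == 0:
        warnings.warn("high-pass cutoff longer than run; filter is the identity")
        return timeseries if not squeeze else np.asarray(timeseries, dtype=float)
    mean = y.mean(axis=0, keepdims=True)
    resid = (y - mean) - basis @ (basis.T @ (y - mean)) + mean
    return resid[:, 0] if squeeze else resid


def fit_glm(
    timeseries: np.ndarray,
    design: DesignMatrix,
    contrasts: Optional[np.ndarray] = None,
) -> GlmFit:
    """Ordinary least squares with t-statistics for the given contrasts.

    ``t = c'b / sqrt(sigma2 * c'(X'X)^- c)`` with ``sigma2 = RSS / dof`` and
    ``dof = scans - rank(X)``. For a rank-deficient design, contrasts
    outside the estimable space raise a ValueError.
    """
    Y = np.asarray(timeseries, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    X = design.matrix
    if Y.shape[0] != X.shape[0]:
        raise ValueError("time series and design length differ")
    rank = np.linalg.matrix_rank(X)
    dof = X.shape[0] - rank
    if dof < 1:
        raise ValueError("not enough scans for the design rank")
    pinv = np.linalg.pinv(X)
    betas = pinv @ Y
    resid = Y - X @ betas
    sigma2 = (resid**2).sum(axis=0) / dof
    xtx_pinv = np.linalg.pinv(X.T @ X)

    t_map = None
    if contrasts is not None:
        C = np.atleast_2d(np.asarray(contrasts, dtype=float))
        if C.shape[1] != X.shape[1]:
            raise ValueError("contrast length does not match design columns")
        if rank < X.shape[1]:
            xtx = X.T @ X
            for c in C:
                if not np.allclose(c @ xtx_pinv @ xtx, c, atol=1e-8):
                    raise ValueError("contrast not estimable under rank-deficient design")
        t_rows = []
        for c in C:
            var_c = float(c @ xtx_pinv @ c)
            denom = np.sqrt(sigma2 * var_c)
            with np.errstate(divide="ignore", invalid="ignore"):
                t_rows.append(np.where(denom > 0, (c @ betas) / denom, np.nan))
        t_map = np.vstack(t_rows)
    return GlmFit(betas=betas, t_map=t_map, dof=dof, residual_var=sigma2)


def planning_contrasts(design: DesignMatrix) -> np.ndarray:
    """The four planning-vs-baseline contrast vectors (one per configuration)."""
    C = np.zeros((len(CONFIG_LABELS), len(design.names)))
    for i, label in enumerate(CONFIG_LABELS):
        C[i, design.names.index(f"plan_{label}")] = 1.0
    return C


def patterns_from_bold(
    runs: Sequence[tuple[np.ndarray, pd.DataFrame]],
    modality: str,
    tr_s: float = DEFAULT_TR_S,
    cutoff_s: float = 128.0,
    include_nuisance: bool = True,
    seed: int = 0,
) -> PatternDataset:
    """Fit per-run GLMs and assemble planning t-patterns into a dataset.

    ``runs`` is a sequence of ``(timeseries, events)`` pairs; runs are
    modeled separately. High-pass filtering is applied to both data and
    hemodynamic regressors (equivalent to adding the drift basis to the
    model).
    """
    pats = []
    for r, (Y, events) in enumerate(runs):
        Y = np.asarray(Y, dtype=float)
        design = build_design(
            events, Y.shape[0], tr_s, include_nuisance=include_nuisance, seed=seed + r
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            Yf = highpass(Y, tr_s, cutoff_s)
            Xf = highpass(design.matrix, tr_s, cutoff_s)
        fit = fit_glm(Yf, DesignMatrix(Xf, design.names, tr_s), planning_contrasts(design))
        pats.append(fit.t_map)
    return PatternDataset(values=np.stack(pats), modality=modality)
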
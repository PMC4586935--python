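"""Group-level GLM on evidence maps, cluster thresholding, ROI definition.

The group design is the full crossing of subjects x modalities x pairs x
tests (classification / cross-classification), modeled with one intercept
per subject plus one regressor per modality-pair-test cell. The subject
intercepts and the condition set are jointly collinear, so the rank is one
less than the column count (e.g. 432 observations, 42 regressors, rank 41,
391 error degrees of freedom).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.ndimage
import scipy.stats

__all__ = [
    "GroupDesign",
    "RoiSpec",
    "make_group_design",
    "group_glm",
    "condition_contrast",
    "cluster_threshold",
    "local_maxima",
    "define_roi",
    "roi_sphere_mask",
    "roi_stats",
]

TESTS = ("classification", "cross_classification")


@dataclass
class GroupDesign:
    matrix: np.ndarray  # (observations, regressors)
    names: list
    labels: pd.DataFrame

    @property
    def rank(self) -> int:
        return int(np.linalg.matrix_rank(self.matrix))

    @property
    def dof(self) -> int:
        return self.matrix.shape[0] - self.rank


@dataclass
class RoiSpec:
    name: str
    reference_mm: tuple
    chosen_peak_mm: tuple
    chosen_peak_ijk: tuple
    radius_mm: float = 7.0


def make_group_design(labels: pd.DataFrame) -> GroupDesign:
    """Design matrix from observation labels.

    ``labels`` needs columns subject, modality, pair, test and must contain
    the full crossing exactly once. Columns are subject intercepts followed
    by one indicator per (modality, pair, test) cell.
    """
    required = {"subject", "modality", "pair", "test"}
    if not required.issubset(labels.columns):
        raise ValueError(f"labels need columns {sorted(required)}")
    subjects = sorted(labels.subject.unique())
    cells = sorted(
        {(m, p, t) for m, p, t in zip(labels.modality, labels.pair, labels.test)}
    )
    expected = len(subjects) * len(cells)
    if len(labels) != expected:
        raise ValueError(
            f"expected full crossing of {len(subjects)} subjects x {len(cells)} cells "
            f"= {expected} observations, got {len(labels)}"
        )
    counts = labels.groupby(["subject", "modality", "pair", "test"]).size()
    if (counts != 1).any():
        raise ValueError("missing or duplicated cells in the crossing")

    n = len(labels)
    cols, names = [], []
    # deviation-coded subject effects (columns sum to zero), so the grand
    # mean is carried by the condition cells and cell contrasts against
    # chance remain estimable
    for s in subjects:
        cols.append((labels.subject == s).to_numpy(float) - 1.0 / len(subjects))
        names.append(f"subject_{s}")
    for m, p, t in cells:
        cols.append(
            ((labels.modality == m) & (labels.pair == p) & (labels.test == t)).to_numpy(float)
        )
        names.append(f"{m}|{p}|{t}")
    return GroupDesign(np.column_stack(cols), names, labels.reset_index(drop=True))


def condition_contrast(design: GroupDesign, modality=None, pair=None, test=None,
                       weight: float = 1.0) -> np.ndarray:
    """Contrast averaging the condition cells matching the given selectors."""
    c = np.zeros(len(design.names))
    hits = []
    for i, name in enumerate(design.names):
        if "|" not in name:
            continue
        m, p, t = name.split("|")
        if (modality is None or m == modality) and (pair is None or p == pair) and (
            test is None or t == test
        ):
            hits.append(i)
    if not hits:
        raise ValueError("no condition regressor matches the selectors")
    c[hits] = weight / len(hits)
    return c


def group_glm(
    evidence: np.ndarray,
    design: GroupDesign,
    contrasts: dict,
    center: float = 0.0,
) -> tuple[dict, int, np.ndarray]:
    """Per-voxel OLS over subjects with t-maps for named contrasts.

    ``evidence`` is (observations, voxels); ``center`` (e.g. chance level
    0.5) is subtracted before fitting so condition contrasts test
    chance-exceedance. Voxels with zero residual variance get NaN t and are
    flagged.

    Returns ``(t_maps, dof, flagged)``.
    """
    Y = np.asarray(evidence, dtype=float) - center
    X = design.matrix
    if Y.shape[0] != X.shape[0]:
        raise ValueError("evidence rows must match design observations")
    dof = design.dof
    if dof < 1:
        raise ValueError("no error degrees of freedom")
    pinv = np.linalg.pinv(X)
    betas = pinv @ Y
    resid = Y - X @ betas
    sigma2 = (resid**2).sum(axis=0) / dof
    flagged = sigma2 == 0
    xtx_pinv = np.linalg.pinv(X.T @ X)
    xtx = X.T @ X
    t_maps = {}
    for name, c in contrasts.items():
        c = np.asarray(c, dtype=float)
        if not np.allclose(c @ xtx_pinv @ xtx, c, atol=1e-8):
            raise ValueError(f"contrast {name!r} not estimable")
        var_c = float(c @ xtx_pinv @ c)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (c @ betas) / np.sqrt(sigma2 * var_c)
        t[flagged] = np.nan
        t_maps[name] = t
    return t_maps, dof, flagged


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 26:
        return np.ones((3, 3, 3), dtype=bool)
    if connectivity == 6:
        return scipy.ndimage.generate_binary_structure(3, 1)
    if connectivity == 18:
        return scipy.ndimage.generate_binary_structure(3, 2)
    raise ValueError("connectivity must be 6, 18 or 26")


def cluster_threshold(
    t_map: np.ndarray,
    dof: int,
    alpha: float = 0.05,
    min_cluster_voxels: int = 250,
    connectivity: int = 26,
    affine: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Threshold a 3D t-map at p < alpha and keep clusters strictly larger
    than ``min_cluster_voxels``.

    One-tailed (positive) p-values from the t distribution with ``dof``.
    Returns the binary surviving map and a cluster table (size, peak t,
    peak voxel and — when an affine is given — peak mm coordinates).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    t_map = np.asarray(t_map, dtype=float)
    if t_map.ndim != 3:
        raise ValueError("t_map must be 3D")
    t_crit = scipy.stats.t.isf(alpha, dof)
    supra = np.nan_to_num(t_map, nan=-np.inf) > t_crit
    labeled, n = scipy.ndimage.label(supra, structure=_structure(connectivity))
    keep = np.zeros_like(supra)
    rows = []
    for lab in range(1, n + 1):
        comp = labeled == lab
        size = int(comp.sum())
        if size <= min_cluster_voxels:
            continue
        keep |= comp
        masked = np.where(comp, t_map, -np.inf)
        peak = np.unravel_index(np.argmax(masked), t_map.shape)
        row = {"n_voxels": size, "peak_t": float(t_map[peak]),
               "peak_i": peak[0], "peak_j": peak[1], "peak_k": peak[2]}
        if affine is not None:
            mm = np.asarray(affine) @ np.array([*peak, 1.0])
            row.update({"peak_x_mm": mm[0], "peak_y_mm": mm[1], "peak_z_mm": mm[2]})
        rows.append(row)
    table = pd.DataFrame(rows, columns=["n_voxels", "peak_t", "peak_i", "peak_j", "peak_k"]
                         + (["peak_x_mm", "peak_y_mm", "peak_z_mm"] if affine is not None else []))
    if len(table):
        table = table.sort_values("n_voxels", ascending=False).reset_index(drop=True)
    return keep, table


def local_maxima(volume: np.ndarray, mask: Optional[np.ndarray] = None,
                 connectivity: int = 26) -> np.ndarray:
    """Voxel coordinates of in-mask strict local maxima.

    A voxel counts as a peak when it exceeds every neighbor in the
    connectivity neighborhood (plateaus are not peaks).
    """
    vol = np.asarray(volume, dtype=float)
    if mask is None:
        mask = np.isfinite(vol)
    else:
        mask = np.asarray(mask, dtype=bool) & np.isfinite(vol)
    filled = np.where(mask, vol, -np.inf)
    footprint = _structure(connectivity).copy()
    footprint[1, 1, 1] = False  # compare against neighbors only
    neighbor_max = scipy.ndimage.maximum_filter(filled, footprint=footprint,
                                                mode="constant", cval=-np.inf)
    peaks = (filled > neighbor_max) & mask
    return np.argwhere(peaks)


def define_roi(
    independent_t_map: np.ndarray,
    reference_mm: Sequence[float],
    affine: np.ndarray,
    mask: Optional[np.ndarray] = None,
    radius_mm: float = 7.0,
    name: str = "",
) -> RoiSpec:
    """7-mm sphere at the in-mask local maximum nearest a reference point.

    The t-map must derive only from the independent pairs (center/outer
    sides) so the ROI placement stays independent of the frame evidence.
    Equidistant peaks break ties lexicographically on voxel coordinates.
    """
    peaks = local_maxima(independent_t_map, mask)
    if len(peaks) == 0:
        raise ValueError("no local maximum inside the mask")
    affine = np.asarray(affine, dtype=float)
    ref = np.asarray(reference_mm, dtype=float)
    hom = np.c_[peaks, np.ones(len(peaks))]
    mm = (affine @ hom.T).T[:, :3]
    d = np.linalg.norm(mm - ref, axis=1)
    order = np.lexsort((peaks[:, 2], peaks[:, 1], peaks[:, 0], d))
    best = order[0]
    return RoiSpec(
        name=name,
        reference_mm=tuple(ref),
        chosen_peak_mm=tuple(mm[best]),
        chosen_peak_ijk=tuple(int(v) for v in peaks[best]),
        radius_mm=float(radius_mm),
    )


def roi_sphere_mask(shape: tuple, affine: np.ndarray, center_mm: Sequence[float],
                    radius_mm: float = 7.0) -> np.ndarray:
    """Boolean mask of voxels whose centers lie within the ROI sphere."""
    idx = np.indices(shape).reshape(3, -1).T
    hom = np.c_[idx, np.ones(len(idx))]
    mm = (np.asarray(affine) @ hom.T).T[:, :3]
    d = np.linalg.norm(mm - np.asarray(center_mm, dtype=float), axis=1)
    return (d <= radius_mm + 1e-9).reshape(shape)


def _paired_t(x: np.ndarray, y: np.ndarray, alternative: str = "two-sided"):
    res = scipy.stats.ttest_rel(x, y, alternative=alternative)
    return float(res.statistic), float(res.pvalue)


def roi_stats(df: pd.DataFrame, chance: float = 0.5) -> pd.DataFrame:
    """ROI-level tests on per-subject frame aggregates.

    ``df`` needs columns subject, modality, aggregate_gc, aggregate_bc with
    one row per subject per modality. Reports, per modality, one-tailed
    one-sample tests of each aggregate against chance and a paired GC-vs-BC
    test; across modalities, paired visual-vs-somaesthetic tests per
    aggregate and the (GC - BC) x modality interaction (paired two-tailed).
    """
    required = {"subject", "modality", "aggregate_gc", "aggregate_bc"}
    if not required.issubset(df.columns):
        raise ValueError(f"need columns {sorted(required)}")
    if df.subject.nunique() < 3:
        raise ValueError("roi_stats requires at least 3 subjects")
    wide = df.pivot_table(index="subject", columns="modality",
                          values=["aggregate_gc", "aggregate_bc"])
    rows = []
    for modality in df.modality.unique():
        gc = wide[("aggregate_gc", modality)].to_numpy()
        bc = wide[("aggregate_bc", modality)].to_numpy()
        for label, v in (("gc_vs_chance", gc), ("bc_vs_chance", bc)):
            res = scipy.stats.ttest_1samp(v, chance, alternative="greater")
            rows.append({"test": label, "modality": modality, "mean": float(v.mean()),
                         "t": float(res.statistic), "p": float(res.pvalue),
                         "df": len(v) - 1})
        t, p = _paired_t(gc, bc)
        rows.append({"test": "gc_vs_bc", "modality": modality,
                     "mean": float((gc - bc).mean()), "t": t, "p": p, "df": len(gc) - 1})
    modalities = list(df.modality.unique())
    if len(modalities) == 2:
        m1, m2 = modalities
        for label in ("aggregate_gc", "aggregate_bc"):
            x, y = wide[(label, m1)].to_numpy(), wide[(label, m2)].to_numpy()
            t, p = _paired_t(x, y)
            rows.append({"test": f"{label}_{m1}_vs_{m2}", "modality": "both",
                         "mean": float((x - y).mean()), "t": t, "p": p, "df": len(x) - 1})
        d1 = wide[("aggregate_gc", m1)] - wide[("aggregate_bc", m1)]
        d2 = wide[("aggregate_gc", m2)] - wide[("aggregate_bc", m2)]
        t, p = _paired_t(d1.to_numpy(), d2.to_numpy())
        rows.append({"test": "interaction_gcbc_x_modality", "modality": "both",
                     "mean": float((d1 - d2).mean()), "t": t, "p": p, "df": len(d1) - 1})
    return pd.DataFrame(rows)
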
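"""Searchlight mapping: local spheres, per-sphere scoring, voxel averaging.

A sphere is centered at every in-mask voxel and contains the in-mask voxels
within the radius (world mm via the affine; inclusive boundary). A score
computed per sphere is then written back not to the center voxel but as the
mean over all spheres containing each voxel, which smooths the map and
reflects each voxel's contribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Union

import numpy as np

from .synthetic import PatternDataset

__all__ = [
    "SphereIndex",
    "EvidenceMap",
    "build_spheres",
    "sphere_volume_mm3",
    "run_searchlight",
    "voxelwise_average",
    "frame_evidence_scorer",
]


@dataclass
class SphereIndex:
    """Sphere membership for every in-mask center.

    ``membership[i]`` lists, as indices into the C-order in-mask voxel
    sequence, the voxels of the sphere centered at in-mask voxel ``i``.
    Membership is symmetric: v is in the sphere at c iff c is in the sphere
    at v.
    """

    mask: np.ndarray
    affine: np.ndarray
    radius_mm: float
    centers: np.ndarray  # (n, 3) voxel coordinates of in-mask voxels
    membership: list

    @property
    def n_centers(self) -> int:
        return len(self.membership)

    def sphere_sizes(self) -> np.ndarray:
        return np.array([len(m) for m in self.membership])


def _voxel_sizes(affine: np.ndarray) -> np.ndarray:
    return np.linalg.norm(np.asarray(affine)[:3, :3], axis=0)


def sphere_volume_mm3(n_voxels: int, affine: np.ndarray) -> float:
    """Volume of a sphere of ``n_voxels`` voxels, in cubic millimetres."""
    return float(n_voxels * abs(np.linalg.det(np.asarray(affine)[:3, :3])))


def build_spheres(
    mask: np.ndarray,
    radius_mm: float,
    affine: Optional[np.ndarray] = None,
    voxel_size_mm: Optional[float] = None,
) -> SphereIndex:
    """Index the searchlight spheres over an in-mask grid.

    Distances are center-to-center in world mm (inclusive boundary), so
    anisotropic voxels are handled through the affine. Spheres are
    restricted to the mask; boundary spheres are simply smaller. Every
    in-mask voxel is a center.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 3:
        raise ValueError("mask must be 3D")
    if not mask.any():
        raise ValueError("mask is empty")
    if affine is None:
        affine = np.diag([voxel_size_mm or 1.0] * 3 + [1.0])
    affine = np.asarray(affine, dtype=float)
    vsz = _voxel_sizes(affine)
    if radius_mm < vsz.min():
        raise ValueError("radius must be at least one voxel")

    reach = np.floor(radius_mm / vsz).astype(int)
    offs = []
    for dx in range(-reach[0], reach[0] + 1):
        for dy in range(-reach[1], reach[1] + 1):
            for dz in range(-reach[2], reach[2] + 1):
                d = affine[:3, :3] @ np.array([dx, dy, dz], dtype=float)
                if np.dot(d, d) <= radius_mm**2 + 1e-9:
                    offs.append((dx, dy, dz))
    offsets = np.array(offs)

    flat = -np.ones(mask.shape, dtype=int)
    centers = np.argwhere(mask)
    flat[mask] = np.arange(len(centers))
    shape = np.array(mask.shape)

    membership = []
    for c in centers:
        pos = c + offsets
        ok = np.all((pos >= 0) & (pos < shape), axis=1)
        idx = flat[tuple(pos[ok].T)]
        membership.append(np.sort(idx[idx >= 0]))
    return SphereIndex(mask, affine, float(radius_mm), centers, membership)


@dataclass
class EvidenceMap:
    """Volumetric per-voxel evidence with provenance.

    ``values`` is a 3D grid, NaN outside the mask.
    """

    values: np.ndarray
    affine: np.ndarray
    measure: str = ""
    params: dict = field(default_factory=dict)


def run_searchlight(
    datasets: Union[PatternDataset, Sequence[PatternDataset]],
    index: SphereIndex,
    scoring: Callable,
) -> dict:
    """Apply a scoring operation within every sphere.

    ``scoring`` receives the dataset(s) restricted to one sphere's voxels
    and returns either a float or a dict of named floats. Centers are
    independent, so results do not depend on processing order.

    Returns a dict mapping measure name to a (n_centers,) array (a single
    float score is stored under ``"score"``).
    """
    single = isinstance(datasets, PatternDataset)
    ds_list = [datasets] if single else list(datasets)
    for ds in ds_list:
        if ds.mask is None or ds.mask.shape != index.mask.shape or not np.array_equal(ds.mask, index.mask):
            raise ValueError("dataset grid/mask does not match the sphere index")
    out = None
    for i, members in enumerate(index.membership):
        subs = [ds.select_voxels(members) for ds in ds_list]
        res = scoring(subs[0]) if single else scoring(*subs)
        if not isinstance(res, dict):
            res = {"score": float(res)}
        if out is None:
            out = {k: np.empty(index.n_centers) for k in res}
        for k, v in res.items():
            out[k][i] = float(v)
    return out


def voxelwise_average(scores: np.ndarray, index: SphereIndex) -> EvidenceMap:
    """Average per-sphere scores onto voxels.

    The value at voxel v is the mean of the scores of all spheres whose
    membership includes v (not center-voxel attribution). Because every
    in-mask voxel is a center with an inclusive-boundary sphere, every
    in-mask voxel is covered by at least its own sphere.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.shape != (index.n_centers,):
        raise ValueError("need exactly one score per center")
    total = np.zeros(index.n_centers)
    count = np.zeros(index.n_centers, dtype=int)
    for i, members in enumerate(index.membership):
        total[members] += scores[i]
        count[members] += 1
    assert (count > 0).all(), "every in-mask voxel must lie in at least one sphere"
    vol = np.full(index.mask.shape, np.nan)
    vol[index.mask] = total / count
    return EvidenceMap(vol, index.affine, measure="voxelwise_average",
                       params={"radius_mm": index.radius_mm})


def frame_evidence_scorer(zscore_scope: str = "all_patterns", xmode: str = "pair") -> Callable:
    """Scorer computing frame aggregates and their contrast per sphere.

    Returns a callable mapping one PatternDataset (a sphere's patterns) to
    ``{"aggregate_gc", "aggregate_bc", "contrast"}``.
    """
    from .decoding import compute_evidence_table
    from .evidence import aggregate

    def score(dataset: PatternDataset) -> dict:
        ev = aggregate(compute_evidence_table(dataset, zscore_scope, xmode))
        return {
            "aggregate_gc": ev.aggregate_gc,
            "aggregate_bc": ev.aggregate_bc,
            "contrast": ev.contrast,
        }

    return score
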
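"""Combining classification and cross-classification into frame evidence.

Each reference frame predicts which pairs are *distinct* (scored by
classification, a) and which are *common* (scored by cross-classification,
o). The aggregate per frame is the mean of two a's and two o's — the same
count on both sides, so any imbalance between the two score types, and any
gaze-direction contribution, cancels in the gaze-minus-body contrast. The
conjunction rule instead requires significant evidence on both sides.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import scipy.stats

from .decoding import EvidenceTable
from .design_space import MAIN_PAIRS

__all__ = [
    "FrameEvidence",
    "GC_AGGREGATE_TERMS",
    "BC_AGGREGATE_TERMS",
    "aggregate",
    "conjunction",
    "gaze_direction_test",
    "significance_flags",
    "group_significance_flags",
    "combine",
]

#: (pair, score type) terms entering each frame's aggregate.
GC_AGGREGATE_TERMS = (
    ("left_wrt_gaze", "o"),
    ("right_wrt_gaze", "o"),
    ("left_wrt_body", "a"),
    ("right_wrt_body", "a"),
)
BC_AGGREGATE_TERMS = (
    ("left_wrt_gaze", "a"),
    ("right_wrt_gaze", "a"),
    ("left_wrt_body", "o"),
    ("right_wrt_body", "o"),
)


@dataclass
class FrameEvidence:
    """Aggregates, contrast, and (optionally) boolean conjunction outcomes."""

    aggregate_gc: float
    aggregate_bc: float
    contrast: float
    conj_gc: Optional[bool] = None
    conj_bc: Optional[bool] = None
    gazedir: Optional[bool] = None

    def conjunction_code(self) -> int:
        """0 = none, 1 = BC, 2 = GC, 3 = both (for uint8 maps)."""
        return int(bool(self.conj_bc)) + 2 * int(bool(self.conj_gc))


def _terms(table: EvidenceTable, terms) -> list[float]:
    out = []
    for pair, kind in terms:
        d = table.a if kind == "a" else table.o
        if pair not in d:
            raise KeyError(f"missing pair {pair!r}")
        out.append(d[pair])
    return out


def aggregate(table: EvidenceTable) -> FrameEvidence:
    """Frame aggregates and their contrast.

    aggregate_gc = mean(o(left/right w.r.t. gaze), a(left/right w.r.t. body));
    aggregate_bc mirrors the roles; contrast = aggregate_gc - aggregate_bc.
    """
    agg_gc = float(np.mean(_terms(table, GC_AGGREGATE_TERMS)))
    agg_bc = float(np.mean(_terms(table, BC_AGGREGATE_TERMS)))
    return FrameEvidence(agg_gc, agg_bc, agg_gc - agg_bc)


def _require_flags(flags: dict, keys) -> None:
    missing = [k for k in keys if k not in flags]
    if missing:
        raise KeyError(f"missing significance flags: {missing}")


def conjunction(flags: dict) -> tuple[bool, bool]:
    """Two-sided conjunction per frame from per-(pair, test) significance.

    ``flags`` maps ``(pair_name, "a" | "o")`` to booleans. Gaze-centered
    conjunction requires a significant gaze-pair cross-classification AND a
    significant body-pair classification; body-centered is the mirror. Both
    may hold simultaneously.
    """
    keys = [(p, k) for p in MAIN_PAIRS for k in ("a", "o")]
    _require_flags(flags, keys)
    conj_gc = (flags[("left_wrt_gaze", "o")] or flags[("right_wrt_gaze", "o")]) and (
        flags[("left_wrt_body", "a")] or flags[("right_wrt_body", "a")]
    )
    conj_bc = (flags[("left_wrt_body", "o")] or flags[("right_wrt_body", "o")]) and (
        flags[("left_wrt_gaze", "a")] or flags[("right_wrt_gaze", "a")]
    )
    return bool(conj_gc), bool(conj_bc)


def gaze_direction_test(flags: dict) -> bool:
    """True iff all four main-pair classifications AND the center-sides
    cross-classification are significant — the signature of coding driven by
    gaze position alone."""
    keys = [(p, "a") for p in MAIN_PAIRS] + [("center_sides", "o")]
    _require_flags(flags, keys)
    return bool(all(flags[k] for k in keys))


def _onesided_p(scores: np.ndarray, chance: float = 0.5) -> float:
    """One-tailed one-sample t-test p-value against chance.

    Degenerate zero-variance samples resolve by the sign of the mean.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.std(ddof=1 if len(scores) > 1 else 0) == 0 or len(scores) < 2:
        return 0.0 if scores.mean() > chance else 1.0
    return float(scipy.stats.ttest_1samp(scores, chance, alternative="greater").pvalue)


def _corrected_fold_p(fold_scores: np.ndarray, chance: float = 0.5) -> float:
    """One-tailed p-value for cross-validated fold scores against chance.

    Uses the variance-corrected resampled t-test: fold scores from
    leave-one-run-out folds overlap in their training sets and are
    positively correlated, so the naive t-test is anti-conservative. The
    corrected statistic inflates the variance of the mean from ``s²/J`` to
    ``s²(1/J + r)`` with ``r`` the test/train size ratio (1/(J-1) for
    leave-one-out folds). Zero-variance fold sets resolve by the sign of
    the mean.
    """
    scores = np.asarray(fold_scores, dtype=float)
    J = len(scores)
    m = scores.mean() - chance
    if J < 2 or scores.std(ddof=1) == 0:
        return 0.0 if m > 0 else 1.0
    rho = 1.0 / (J - 1)
    t = m / np.sqrt(scores.var(ddof=1) * (1.0 / J + rho))
    return float(scipy.stats.t.sf(t, J - 1))


def significance_flags(table: EvidenceTable, alpha: float = 0.05) -> dict:
    """Single-dataset flags from corrected across-fold tests vs chance (0.5).

    One-tailed, per (pair, test). Group-level inference is the principled
    route; these single-dataset flags exist for standalone use and testing.
    """
    flags = {}
    for pair in table.a_folds:
        flags[(pair, "a")] = _corrected_fold_p(table.a_folds[pair]) < alpha
        flags[(pair, "o")] = _corrected_fold_p(table.o_folds[pair]) < alpha
    return flags


def group_significance_flags(tables: Sequence[EvidenceTable], alpha: float = 0.05) -> dict:
    """Flags from across-dataset (subject-level) t-tests against chance."""
    if len(tables) < 2:
        raise ValueError("group flags require at least two datasets")
    pairs = tables[0].a.keys()
    flags = {}
    for pair in pairs:
        flags[(pair, "a")] = _onesided_p(np.array([t.a[pair] for t in tables])) < alpha
        flags[(pair, "o")] = _onesided_p(np.array([t.o[pair] for t in tables])) < alpha
    return flags


def combine(table: EvidenceTable, flags: Optional[dict] = None, alpha: float = 0.05) -> FrameEvidence:
    """Aggregate plus conjunction and gaze-direction outcomes in one record."""
    ev = aggregate(table)
    if flags is None:
        flags = significance_flags(table, alpha)
    ev.conj_gc, ev.conj_bc = conjunction(flags)
    ev.gazedir = gaze_direction_test(flags)
    return ev
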
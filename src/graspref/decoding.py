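"""Pairwise classification and replacement-routed cross-classification.

For each of the six condition pairs, a binary linear max-margin classifier
is trained under leave-one-run-out cross-validation; its held-out accuracy
is the *classification score* ``a`` (evidence that the two configurations
are distinct). Each trained classifier is additionally tested with one of
its two configurations replaced by a non-trained one; that score is routed
to the *receiving pair* {replaced, replacement} and averaged into the
*cross-classification score* ``o`` (evidence that replaced and replacement
share a representation). Every trained pair feeds exactly four receiving
pairs, and every receiving pair aggregates exactly four routed scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .design_space import CONFIG_LABELS, PAIR_NAMES, ConditionPair, enumerate_pairs, make_configurations
from .synthetic import PatternDataset

__all__ = [
    "EvidenceTable",
    "zscore_patterns",
    "FoldClassifiers",
    "train_fold_classifiers",
    "classify_pair",
    "cross_classify",
    "evidence_from_classifiers",
    "compute_evidence_table",
    "cross_modal_scores",
    "default_pairs",
]

ZSCORE_SCOPES = ("all_patterns", "train_only")
XMODES = ("pair", "replacement_only")


def default_pairs() -> list[ConditionPair]:
    return enumerate_pairs(make_configurations())


@dataclass
class EvidenceTable:
    """Per-pair classification (a) and cross-classification (o) scores.

    ``a_folds`` / ``o_folds`` retain the per-fold scores for inference
    (for cross-modal tables the two "folds" are the two transfer
    directions).
    """

    a: dict
    o: dict
    a_folds: dict
    o_folds: dict
    n_folds: int
    modality_context: str
    #: distinct held-out decisions per fold behind each score (for exact
    #: binomial inference): 2 test patterns for a; 4 routed scores of 1
    #: (replacement_only) or 2 (pair mode) decisions each for o
    a_decisions_per_fold: int = 2
    o_decisions_per_fold: int = 8

    def __post_init__(self):
        for name in PAIR_NAMES:
            if name not in self.a or name not in self.o:
                raise ValueError(f"pair {name!r} missing a or o score")
        for d in (self.a, self.o):
            for name, v in d.items():
                if not 0.0 <= v <= 1.0:
                    raise ValueError(f"score for {name!r} outside [0, 1]: {v}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "pair": list(PAIR_NAMES),
                "a": [self.a[p] for p in PAIR_NAMES],
                "o": [self.o[p] for p in PAIR_NAMES],
                "n_folds": self.n_folds,
                "modality_context": self.modality_context,
            }
        )

    def fold_frame(self) -> pd.DataFrame:
        """Long-format per-fold scores."""
        rows = []
        for pair in PAIR_NAMES:
            for test, folds in (("classification", self.a_folds), ("cross_classification", self.o_folds)):
                for k, s in enumerate(folds[pair]):
                    rows.append(
                        {
                            "pair": pair,
                            "test": test,
                            "fold": k,
                            "score": s,
                            "modality_context": self.modality_context,
                        }
                    )
        return pd.DataFrame(rows)


def zscore_patterns(
    dataset: PatternDataset,
    scope: str = "all_patterns",
    train_runs: Optional[Sequence[int]] = None,
) -> PatternDataset:
    """Z-score t-values per voxel across patterns.

    With ``scope="all_patterns"`` moments are taken over every pattern in
    the dataset (runs x configurations). With ``scope="train_only"`` the
    moments come from ``train_runs`` only and are applied to all patterns,
    so held-out runs never contribute statistics. Zero-variance voxels get
    SD 1 (output zeros) and are recorded in ``flagged_voxels``.
    """
    if scope not in ZSCORE_SCOPES:
        raise ValueError(f"unknown z-scoring scope {scope!r}")
    vals = dataset.values
    if vals.shape[0] * vals.shape[1] < 2:
        raise ValueError("need at least two patterns per voxel to z-score")
    if scope == "train_only":
        if train_runs is None:
            raise ValueError("train_only scope requires train_runs")
        ref = vals[np.asarray(train_runs, dtype=int)]
    else:
        ref = vals
    flat = ref.reshape(-1, vals.shape[2])
    mean = flat.mean(axis=0)
    sd = flat.std(axis=0, ddof=0)
    flagged = np.flatnonzero(sd == 0)
    sd = np.where(sd == 0, 1.0, sd)
    return PatternDataset(
        values=(vals - mean) / sd,
        modality=dataset.modality,
        run_ids=list(dataset.run_ids),
        config_labels=dataset.config_labels,
        affine=dataset.affine,
        mask=dataset.mask,
        flagged_voxels=flagged,
    )


def _fit_svm(X: np.ndarray, y: np.ndarray) -> SVC:
    clf = SVC(kernel="linear", C=1.0)
    clf.fit(X, y)
    return clf


def _score(clf: SVC, x: np.ndarray, correct: int) -> float:
    """1/0 by decision sign; a pattern exactly on the boundary scores 0.5."""
    d = float(clf.decision_function(x[None, :])[0])
    if d == 0.0:
        return 0.5
    predicted = clf.classes_[1] if d > 0 else clf.classes_[0]
    return 1.0 if predicted == correct else 0.0


@dataclass
class FoldClassifiers:
    """All six pair classifiers for every leave-one-run-out fold.

    ``classifiers[fold][pair_name]`` is a fitted binary classifier;
    ``test_values[fold]`` holds the (configurations, voxels) patterns of
    the held-out run, z-scored consistently with the training data.
    """

    classifiers: list
    test_values: list
    pairs: list
    dataset: PatternDataset
    zscore_scope: str
    n_train_patterns: int = 0

    @property
    def n_folds(self) -> int:
        return len(self.classifiers)


def train_fold_classifiers(
    dataset: PatternDataset,
    pairs: Optional[Sequence[ConditionPair]] = None,
    zscore_scope: str = "all_patterns",
) -> FoldClassifiers:
    """Train every pair's classifier for every leave-one-run-out fold.

    Class labels are configuration indices. Training patterns for pair
    {A, B} in fold r are the A and B patterns of all runs except r
    (2 x (R - 1) patterns); the held-out run supplies the test patterns.
    """
    if pairs is None:
        pairs = default_pairs()
    R = dataset.n_runs
    if R < 2:
        raise ValueError("leave-one-run-out requires at least two runs")
    if zscore_scope == "all_patterns":
        z = zscore_patterns(dataset, "all_patterns")
    classifiers, test_values = [], []
    n_train = 0
    for r in range(R):
        train_runs = [i for i in range(R) if i != r]
        if zscore_scope == "train_only":
            z = zscore_patterns(dataset, "train_only", train_runs=train_runs)
        per_pair = {}
        for pair in pairs:
            ia, ib = (dataset.config_index(lbl) for lbl in pair.member_labels())
            X = np.concatenate([z.values[train_runs][:, ia, :], z.values[train_runs][:, ib, :]])
            y = np.array([ia] * len(train_runs) + [ib] * len(train_runs))
            n_train = X.shape[0]
            per_pair[pair.name] = _fit_svm(X, y)
        classifiers.append(per_pair)
        test_values.append(z.values[r])
    return FoldClassifiers(classifiers, test_values, list(pairs), dataset, zscore_scope, n_train)


def classify_pair(
    fold_classifiers: FoldClassifiers, pair: ConditionPair
) -> tuple[np.ndarray, float]:
    """Leave-one-run-out accuracies and their mean ``a`` for one pair."""
    ds = fold_classifiers.dataset
    ia, ib = (ds.config_index(lbl) for lbl in pair.member_labels())
    accs = []
    for fold in range(fold_classifiers.n_folds):
        clf = fold_classifiers.classifiers[fold][pair.name]
        test = fold_classifiers.test_values[fold]
        accs.append((_score(clf, test[ia], ia) + _score(clf, test[ib], ib)) / 2.0)
    accs = np.array(accs)
    return accs, float(accs.mean())


def _replacement_routes(pairs: Sequence[ConditionPair]):
    """Enumerate (trained pair, replaced, replacement, receiving pair) routes.

    For a classifier trained on {A, B} with non-trained configurations C, D
    the four replacements are A->C, A->D, B->C, B->D; the receiving pair is
    {replaced, replacement}.
    """
    by_members = {frozenset(p.member_labels()): p.name for p in pairs}
    routes = []
    for pair in pairs:
        a, b = pair.member_labels()
        others = [lbl for lbl in CONFIG_LABELS if lbl not in (a, b)]
        for replaced, retained in ((a, b), (b, a)):
            for replacement in others:
                receiving = by_members[frozenset((replaced, replacement))]
                routes.append((pair.name, replaced, retained, replacement, receiving))
    return routes


def cross_classify(
    fold_classifiers: FoldClassifiers, scoring_mode: str = "pair"
) -> tuple[dict, dict]:
    """Cross-classification scores ``o`` per receiving pair.

    Per fold, each trained classifier is tested with one trained
    configuration replaced by a non-trained one; test patterns come only
    from the held-out run. The replacement pattern is scored correct when
    assigned the replaced configuration's class. In ``"pair"`` mode the
    retained configuration's held-out pattern is also scored (correct =
    its own class) and the two are averaged; ``"replacement_only"`` keeps
    just the replacement score. Every receiving pair averages exactly four
    routed scores per fold.

    Returns ``(o, o_folds)`` mapping pair name to the mean score and the
    per-fold scores.
    """
    if scoring_mode not in XMODES:
        raise ValueError(f"unknown scoring mode {scoring_mode!r}")
    ds = fold_classifiers.dataset
    routes = _replacement_routes(fold_classifiers.pairs)
    per_fold = {name: [] for name in PAIR_NAMES}
    for fold in range(fold_classifiers.n_folds):
        test = fold_classifiers.test_values[fold]
        routed = {name: [] for name in PAIR_NAMES}
        for trained, replaced, retained, replacement, receiving in routes:
            clf = fold_classifiers.classifiers[fold][trained]
            i_replaced = ds.config_index(replaced)
            s = _score(clf, test[ds.config_index(replacement)], i_replaced)
            if scoring_mode == "pair":
                i_retained = ds.config_index(retained)
                s = (s + _score(clf, test[i_retained], i_retained)) / 2.0
            routed[receiving].append(s)
        for name, scores in routed.items():
            assert len(scores) == 4, "each receiving pair aggregates exactly 4 scores"
            per_fold[name].append(float(np.mean(scores)))
    o_folds = {name: np.array(v) for name, v in per_fold.items()}
    o = {name: float(v.mean()) for name, v in o_folds.items()}
    return o, o_folds


def evidence_from_classifiers(fold_classifiers: FoldClassifiers,
                              xmode: str = "pair") -> EvidenceTable:
    """Assemble an evidence table from already-trained fold classifiers."""
    a, a_folds = {}, {}
    for pair in fold_classifiers.pairs:
        folds, mean_a = classify_pair(fold_classifiers, pair)
        a[pair.name], a_folds[pair.name] = mean_a, folds
    o, o_folds = cross_classify(fold_classifiers, xmode)
    return EvidenceTable(a, o, a_folds, o_folds, fold_classifiers.n_folds,
                         fold_classifiers.dataset.modality,
                         a_decisions_per_fold=2,
                         o_decisions_per_fold=8 if xmode == "pair" else 4)


def compute_evidence_table(
    dataset: PatternDataset,
    zscore_scope: str = "all_patterns",
    xmode: str = "pair",
    pairs: Optional[Sequence[ConditionPair]] = None,
) -> EvidenceTable:
    """Full within-modality evidence table (a and o for all six pairs)."""
    fc = train_fold_classifiers(dataset, pairs, zscore_scope)
    return evidence_from_classifiers(fc, xmode)


def cross_modal_scores(
    dataset_vis: PatternDataset,
    dataset_som: PatternDataset,
    xmode: str = "pair",
    pairs: Optional[Sequence[ConditionPair]] = None,
) -> EvidenceTable:
    """Across-modality evidence: train on one modality, test on the other.

    Each modality is z-scored separately (all patterns) before transfer.
    Classifiers are trained on all runs of the source modality and tested
    on all runs of the target; scores are averaged over the two transfer
    directions, which are retained as the two "folds".
    """
    if dataset_vis.n_voxels != dataset_som.n_voxels:
        raise ValueError("voxel count mismatch between modalities")
    if pairs is None:
        pairs = default_pairs()
    routes = _replacement_routes(pairs)
    z = {
        "visual": zscore_patterns(dataset_vis, "all_patterns"),
        "somaesthetic": zscore_patterns(dataset_som, "all_patterns"),
    }
    ds = dataset_vis
    a_dir = {p.name: [] for p in pairs}
    o_dir = {name: [] for name in PAIR_NAMES}
    for source, target in (("visual", "somaesthetic"), ("somaesthetic", "visual")):
        src, tgt = z[source].values, z[target].values
        clfs = {}
        for pair in pairs:
            ia, ib = (ds.config_index(lbl) for lbl in pair.member_labels())
            X = np.concatenate([src[:, ia, :], src[:, ib, :]])
            y = np.array([ia] * src.shape[0] + [ib] * src.shape[0])
            clfs[pair.name] = _fit_svm(X, y)
        for pair in pairs:
            ia, ib = (ds.config_index(lbl) for lbl in pair.member_labels())
            scores = [
                _score(clfs[pair.name], tgt[r, i], i)
                for r in range(tgt.shape[0])
                for i in (ia, ib)
            ]
            a_dir[pair.name].append(float(np.mean(scores)))
        routed = {name: [] for name in PAIR_NAMES}
        for trained, replaced, retained, replacement, receiving in routes:
            clf = clfs[trained]
            i_replaced = ds.config_index(replaced)
            i_replacement = ds.config_index(replacement)
            scores = []
            for r in range(tgt.shape[0]):
                s = _score(clf, tgt[r, i_replacement], i_replaced)
                if xmode == "pair":
                    i_retained = ds.config_index(retained)
                    s = (s + _score(clf, tgt[r, i_retained], i_retained)) / 2.0
                scores.append(s)
            routed[receiving].append(float(np.mean(scores)))
        for name, scores in routed.items():
            o_dir[name].append(float(np.mean(scores)))
    a_folds = {name: np.array(v) for name, v in a_dir.items()}
    o_folds = {name: np.array(v) for name, v in o_dir.items()}
    n_runs = dataset_vis.n_runs
    return EvidenceTable(
        a={n: float(v.mean()) for n, v in a_folds.items()},
        o={n: float(v.mean()) for n, v in o_folds.items()},
        a_folds=a_folds,
        o_folds=o_folds,
        n_folds=2,
        modality_context="cross_modal",
        a_decisions_per_fold=2 * n_runs,
        o_decisions_per_fold=(8 if xmode == "pair" else 4) * n_runs,
    )
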
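"""Trial-configuration geometry and condition-pair predictions.

Four gaze/target configurations are tested (gaze left-target left, gaze
center-target left, gaze center-target right, gaze right-target right).
Every unordered pair of configurations is either *common* or *distinct*
under each candidate coding hypothesis (gaze-centered, body-centered,
gaze-direction), and those predictions drive which score — classification
or cross-classification — counts as evidence for which hypothesis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

__all__ = [
    "ConfigurationError",
    "TrialConfiguration",
    "ConditionPair",
    "CONFIG_LABELS",
    "PAIR_NAMES",
    "MAIN_PAIRS",
    "INDEPENDENT_PAIRS",
    "make_configurations",
    "enumerate_pairs",
    "pairs_as_table",
]

#: Canonical configuration labels, in fixed order.
CONFIG_LABELS = ("GL-TL", "GC-TL", "GC-TR", "GR-TR")

#: Canonical pair names, in fixed order.
PAIR_NAMES = (
    "left_wrt_gaze",
    "right_wrt_gaze",
    "left_wrt_body",
    "right_wrt_body",
    "outer_sides",
    "center_sides",
)

#: The four pairs carrying reference-frame predictions.
MAIN_PAIRS = PAIR_NAMES[:4]

#: The two pairs distinct in both frames (ROI definition / gaze-direction control).
INDEPENDENT_PAIRS = PAIR_NAMES[4:]


class ConfigurationError(ValueError):
    """Raised when the gaze/target geometry is degenerate or invalid."""


@dataclass(frozen=True)
class TrialConfiguration:
    """One tested gaze x target combination.

    Parameters
    ----------
    label : str
        Canonical identifier, e.g. ``"GL-TL"``.
    gaze_position : str
        ``"left"``, ``"center"`` or ``"right"``.
    gaze_angle_deg, target_angle_deg : float
        Positions in degrees of visual angle from the mid-sagittal plane.

    The frame-specific sides are derived from the angles, never stored.
    """

    label: str
    gaze_position: str
    gaze_angle_deg: float
    target_angle_deg: float

    @property
    def target_side_body(self) -> str:
        """Side of the target w.r.t. the body midline (sign of its angle)."""
        return "left" if self.target_angle_deg < 0 else "right"

    @property
    def target_side_gaze(self) -> str:
        """Side of the target w.r.t. the gaze line (sign of target - gaze)."""
        delta = self.target_angle_deg - self.gaze_angle_deg
        if delta == 0:
            raise ConfigurationError(
                f"{self.label}: target collinear with gaze; gaze-frame side undefined"
            )
        return "left" if delta < 0 else "right"


@dataclass(frozen=True)
class ConditionPair:
    """Unordered pair of trial configurations with per-hypothesis predictions.

    ``prediction_gc`` / ``prediction_bc`` are ``"common"`` or ``"distinct"``
    for the four main pairs, and ``"unused"`` for the two independent pairs
    (outer/center sides — geometrically distinct in both frames, but not
    entering frame evidence). ``prediction_gazedir`` is ``"common"`` only for
    the center-sides pair, where gaze position is identical.
    """

    name: str
    members: frozenset
    prediction_gc: str
    prediction_bc: str
    prediction_gazedir: str

    @property
    def is_main(self) -> bool:
        return self.name in MAIN_PAIRS

    def member_labels(self):
        """Member labels in canonical configuration order."""
        return tuple(
            c.label for c in sorted(self.members, key=lambda c: CONFIG_LABELS.index(c.label))
        )


_GAZE_NAMES = ("left", "center", "right")


def make_configurations(
    gaze_angles_deg: Sequence[float] = (-11.0, 0.0, 11.0),
    target_offsets_deg: Sequence[float] = (-5.0, 5.0),
) -> list[TrialConfiguration]:
    """Build the four tested trial configurations.

    Of the six raw gaze x target combinations sharing a gaze position with a
    target, only the four where the target is adjacent to the gaze line are
    tested; gaze-left/target-right and gaze-right/target-left are excluded.

    Parameters
    ----------
    gaze_angles_deg : three fixation angles, strictly ordered left < center < right.
    target_offsets_deg : one negative and one positive target angle.

    Raises
    ------
    ConfigurationError
        On unordered gaze angles, same-sign targets, or a target collinear
        with any gaze angle (gaze-frame side undefined).
    """
    if len(gaze_angles_deg) != 3:
        raise ConfigurationError("exactly three gaze angles required")
    gl, gc, gr = (float(a) for a in gaze_angles_deg)
    if not gl < gc < gr:
        raise ConfigurationError("gaze angles must be strictly ordered left < center < right")
    if len(target_offsets_deg) != 2:
        raise ConfigurationError("exactly two target offsets required")
    tl, tr = sorted(float(t) for t in target_offsets_deg)
    if not (tl < 0 < tr):
        raise ConfigurationError("target offsets must be one negative, one positive")
    for t in (tl, tr):
        if t in (gl, gc, gr):
            raise ConfigurationError(f"target at {t} deg collinear with a gaze angle")

    configs = [
        TrialConfiguration("GL-TL", "left", gl, tl),
        TrialConfiguration("GC-TL", "center", gc, tl),
        TrialConfiguration("GC-TR", "center", gc, tr),
        TrialConfiguration("GR-TR", "right", gr, tr),
    ]
    # Force evaluation so degenerate geometry fails eagerly.
    for c in configs:
        c.target_side_gaze
    return configs


def enumerate_pairs(configs: Sequence[TrialConfiguration]) -> list[ConditionPair]:
    """Enumerate the six unordered condition pairs with their predictions.

    The six pairs partition all C(4,2) combinations of the four
    configurations. A pair is *common* under a hypothesis when its two
    members agree on the quantity that hypothesis codes (gaze-frame side,
    body-frame side, or gaze position), and *distinct* otherwise.
    """
    if len(configs) != 4:
        raise ConfigurationError("exactly four configurations required")
    by_label = {c.label: c for c in configs}
    if set(by_label) != set(CONFIG_LABELS):
        raise ConfigurationError(
            f"expected configurations {CONFIG_LABELS}, got {sorted(by_label)}"
        )

    def pick(side_attr: str, value: str) -> frozenset:
        return frozenset(c for c in configs if getattr(c, side_attr) == value)

    pairs = []
    for name, members in [
        ("left_wrt_gaze", pick("target_side_gaze", "left")),
        ("right_wrt_gaze", pick("target_side_gaze", "right")),
        ("left_wrt_body", pick("target_side_body", "left")),
        ("right_wrt_body", pick("target_side_body", "right")),
        ("outer_sides", frozenset((by_label["GL-TL"], by_label["GR-TR"]))),
        ("center_sides", frozenset((by_label["GC-TL"], by_label["GC-TR"]))),
    ]:
        if len(members) != 2:
            raise ConfigurationError(f"pair {name} does not have exactly two members")
        a, b = sorted(members, key=lambda c: CONFIG_LABELS.index(c.label))
        if name in MAIN_PAIRS:
            pred_gc = "common" if a.target_side_gaze == b.target_side_gaze else "distinct"
            pred_bc = "common" if a.target_side_body == b.target_side_body else "distinct"
        else:
            pred_gc = pred_bc = "unused"
        pred_gd = "common" if a.gaze_position == b.gaze_position else "distinct"
        pairs.append(ConditionPair(name, members, pred_gc, pred_bc, pred_gd))

    all_members = [p.members for p in pairs]
    if len(set(all_members)) != 6:
        raise ConfigurationError("pairs do not partition the C(4,2) combinations")
    return pairs


def pairs_as_table(pairs: Sequence[ConditionPair]):
    """Pair table as a pandas DataFrame (exportable as TSV)."""
    import pandas as pd

    rows = []
    for p in pairs:
        m1, m2 = p.member_labels()
        rows.append(
            {
                "pair": p.name,
                "member_1": m1,
                "member_2": m2,
                "pred_gc": p.prediction_gc,
                "pred_bc": p.prediction_bc,
                "pred_gazedir": p.prediction_gazedir,
            }
        )
    return pd.DataFrame(rows)
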
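"""Stepwise rule-based placement assignment for 2-5 device sessions.

The decision order mirrors how informative each feature is:

1. orientation changes single out wrist devices (arms rotate far more);
2. walking gyroscope energy separates shanks (high) from the waist (low);
3. the sign of the gated x-y gyroscope product splits left from right
   wrist (positive left, negative right under dorsal mounting);
4. the extension/flexion z-gyroscope difference splits left from right
   shank (higher on the left).

Two- and three-device layouts cannot determine side, so they emit the
side-agnostic labels ``H?`` (wrist) and ``L?`` (shank).

Every degenerate situation — ties, undefined gated means, zero
orientation-change counts on a wrist, agreeing Cxy signs — is resolved
deterministically (first in input order wins) and surfaces as a named
diagnostic, never as silent randomness: the diagnostics are exactly the
failure signatures seen in the field (e.g. severe rigidity suppressing
arm orientation changes, or ventrally mounted wrist devices flipping the
Cxy sign).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

from .features import FeatureVector, extract_features
from .signal_model import AlgorithmParams, SessionBundle, validate_session

__all__ = [
    "BD", "LL", "RL", "LH", "RH", "WRIST", "SHANK",
    "ConfigurationError",
    "Diagnostic",
    "PlacementAssignment",
    "detect_configuration",
    "classify_two",
    "classify_three",
    "classify_four",
    "classify_five",
    "identify_placements",
]

BD = "BD"   # body (waist)
LL = "LL"   # left leg (shank)
RL = "RL"   # right leg (shank)
LH = "LH"   # left hand (wrist)
RH = "RH"   # right hand (wrist)
WRIST = "H?"  # wrist, side undetermined (2- and 3-device layouts)
SHANK = "L?"  # shank, side undetermined

_CONFIG_BY_COUNT = {2: "two", 3: "three", 4: "four", 5: "five"}


class ConfigurationError(ValueError):
    """The session's device count has no supported placement layout."""


@dataclass(frozen=True)
class Diagnostic:
    """A named degeneracy observed while applying a decision rule."""

    code: str
    devices: tuple[str, ...] = ()

    def __str__(self) -> str:
        if self.devices:
            return f"{self.code}({', '.join(self.devices)})"
        return self.code


@dataclass(frozen=True)
class PlacementAssignment:
    """Device-to-position mapping plus per-decision diagnostics."""

    configuration: str
    mapping: dict[str, str]
    diagnostics: tuple[Diagnostic, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        labels = list(self.mapping.values())
        if len(set(labels)) != len(labels):
            raise ValueError(f"labels must be distinct: {labels}")

    @property
    def diagnostic_codes(self) -> set[str]:
        return {d.code for d in self.diagnostics}

    def to_json(self) -> str:
        return json.dumps(
            {
                "configuration": self.configuration,
                "assignments": [
                    {"device_id": d, "label": l} for d, l in self.mapping.items()
                ],
                "diagnostics": [
                    {"code": d.code, "devices": list(d.devices)}
                    for d in self.diagnostics
                ],
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "PlacementAssignment":
        obj = json.loads(text)
        return cls(
            configuration=obj["configuration"],
            mapping={a["device_id"]: a["label"] for a in obj["assignments"]},
            diagnostics=tuple(
                Diagnostic(d["code"], tuple(d["devices"]))
                for d in obj["diagnostics"]
            ),
        )


def detect_configuration(bundle: SessionBundle) -> str:
    """Map the recording count to the supported layout name."""
    n = len(bundle.recordings)
    if n not in _CONFIG_BY_COUNT:
        raise ConfigurationError(
            f"{n} devices unsupported: at least two and at most five "
            "sensing devices must be used"
        )
    return _CONFIG_BY_COUNT[n]


# ---------------------------------------------------------------------------
# ranking helpers — stable on input order so ties resolve deterministically
# ---------------------------------------------------------------------------


def _rank_desc(
    fvs: Sequence[FeatureVector], key
) -> tuple[list[FeatureVector], bool, bool]:
    """Sort descending by ``key`` (None ranks last), input order stable.

    Returns (sorted, any_tie_between_adjacent, any_undefined).
    """
    keyed = [(key(fv), i, fv) for i, fv in enumerate(fvs)]
    any_undefined = any(k is None for k, _, _ in keyed)
    as_num = [(-float("inf") if k is None else k, i, fv) for k, i, fv in keyed]
    as_num.sort(key=lambda t: (-t[0], t[1]))
    any_tie = any(a[0] == b[0] for a, b in zip(as_num, as_num[1:]))
    return [fv for _, _, fv in as_num], any_tie, any_undefined


def _split_top(
    fvs: Sequence[FeatureVector], k: int, key
) -> tuple[list[FeatureVector], list[FeatureVector], bool]:
    """Split into the top-k and the rest; flag a tie at the boundary."""
    ranked, _, _ = _rank_desc(fvs, key)
    boundary_tie = False
    if len(ranked) > k:
        top_val = key(ranked[k - 1])
        next_val = key(ranked[k])
        boundary_tie = top_val == next_val
    top_ids = {fv.device_id for fv in ranked[:k]}
    # preserve input order within each group
    top = [fv for fv in fvs if fv.device_id in top_ids]
    rest = [fv for fv in fvs if fv.device_id not in top_ids]
    return top, rest, boundary_tie


def _wrist_selection_diags(wrists, boundary_tie) -> list[Diagnostic]:
    diags = []
    zero = [fv.device_id for fv in wrists if fv.orientation_changes == 0]
    if zero:
        diags.append(Diagnostic("zero_orientation_changes", tuple(zero)))
    if boundary_tie:
        diags.append(
            Diagnostic(
                "tie_broken_by_input_order",
                tuple(fv.device_id for fv in wrists),
            )
        )
    return diags


def _assign_wrist_sides(
    wrists: Sequence[FeatureVector],
) -> tuple[dict[str, str], list[Diagnostic]]:
    """Left/right wrist by the sign of Cxy; ordering fallback when degenerate."""
    a, b = wrists
    diags: list[Diagnostic] = []
    signs_disagree = (
        a.cxy is not None
        and b.cxy is not None
        and ((a.cxy > 0 > b.cxy) or (b.cxy > 0 > a.cxy))
    )
    if signs_disagree:
        left, right = (a, b) if a.cxy > 0 else (b, a)
        return {left.device_id: LH, right.device_id: RH}, diags
    if a.cxy is None or b.cxy is None:
        diags.append(
            Diagnostic(
                "cxy_undefined",
                tuple(fv.device_id for fv in wrists if fv.cxy is None),
            )
        )
    else:
        diags.append(Diagnostic("cxy_signs_agree", (a.device_id, b.device_id)))
        if a.cxy < 0 and b.cxy < 0:
            diags.append(
                Diagnostic("both_cxy_negative", (a.device_id, b.device_id))
            )
    ranked, tie, _ = _rank_desc(wrists, lambda fv: fv.cxy)
    if tie:
        diags.append(
            Diagnostic("tie_broken_by_input_order", tuple(fv.device_id for fv in wrists))
        )
    return {ranked[0].device_id: LH, ranked[1].device_id: RH}, diags


def _assign_shank_sides(
    shanks: Sequence[FeatureVector],
) -> tuple[dict[str, str], list[Diagnostic]]:
    """Higher extension/flexion difference is the left shank."""
    diags: list[Diagnostic] = []
    undefined = [fv.device_id for fv in shanks if fv.gdiff is None]
    if undefined:
        diags.append(Diagnostic("gdiff_undefined", tuple(undefined)))
    ranked, tie, _ = _rank_desc(shanks, lambda fv: fv.gdiff)
    if tie:
        diags.append(
            Diagnostic("tie_broken_by_input_order", tuple(fv.device_id for fv in shanks))
        )
    return {ranked[0].device_id: LL, ranked[1].device_id: RL}, diags


# ---------------------------------------------------------------------------
# configuration-specific procedures
# ---------------------------------------------------------------------------


def classify_two(fvs: Sequence[FeatureVector]) -> PlacementAssignment:
    """Wrist vs shank by orientation changes (side undeterminable)."""
    if len(fvs) != 2:
        raise ValueError("classify_two requires exactly 2 feature vectors")
    ranked, tie, _ = _rank_desc(fvs, lambda fv: fv.orientation_changes)
    diags = _wrist_selection_diags(ranked[:1], tie)
    return PlacementAssignment(
        configuration="two",
        mapping={ranked[0].device_id: WRIST, ranked[1].device_id: SHANK},
        diagnostics=tuple(diags),
    )


def classify_three(fvs: Sequence[FeatureVector]) -> PlacementAssignment:
    """Wrist by orientation changes, then shank vs waist by walking energy."""
    if len(fvs) != 3:
        raise ValueError("classify_three requires exactly 3 feature vectors")
    wrists, rest, boundary_tie = _split_top(fvs, 1, lambda fv: fv.orientation_changes)
    diags = _wrist_selection_diags(wrists, boundary_tie)
    ranked, tie, undef = _rank_desc(rest, lambda fv: fv.gen)
    if undef:
        diags.append(
            Diagnostic(
                "gen_undefined",
                tuple(fv.device_id for fv in rest if fv.gen is None),
            )
        )
    if tie:
        diags.append(
            Diagnostic("tie_broken_by_input_order", tuple(fv.device_id for fv in rest))
        )
    return PlacementAssignment(
        configuration="three",
        mapping={
            wrists[0].device_id: WRIST,
            ranked[0].device_id: SHANK,
            ranked[1].device_id: BD,
        },
        diagnostics=tuple(diags),
    )


def classify_four(fvs: Sequence[FeatureVector]) -> PlacementAssignment:
    """Wrist pair by orientation changes; sides by Cxy sign and GDiff order."""
    if len(fvs) != 4:
        raise ValueError("classify_four requires exactly 4 feature vectors")
    wrists, shanks, boundary_tie = _split_top(fvs, 2, lambda fv: fv.orientation_changes)
    diags = _wrist_selection_diags(wrists, boundary_tie)
    wrist_map, wd = _assign_wrist_sides(wrists)
    shank_map, sd = _assign_shank_sides(shanks)
    mapping = {fv.device_id: (wrist_map | shank_map)[fv.device_id] for fv in fvs}
    return PlacementAssignment(
        configuration="four", mapping=mapping, diagnostics=tuple(diags + wd + sd)
    )


def classify_five(fvs: Sequence[FeatureVector]) -> PlacementAssignment:
    """Full layout: wrists, then waist as the lowest-energy non-wrist device."""
    if len(fvs) != 5:
        raise ValueError("classify_five requires exactly 5 feature vectors")
    wrists, rest, boundary_tie = _split_top(fvs, 2, lambda fv: fv.orientation_changes)
    diags = _wrist_selection_diags(wrists, boundary_tie)
    ranked, tie, undef = _rank_desc(rest, lambda fv: fv.gen)
    waist = ranked[-1]
    shanks = [fv for fv in rest if fv.device_id != waist.device_id]
    if undef:
        diags.append(
            Diagnostic(
                "gen_undefined",
                tuple(fv.device_id for fv in rest if fv.gen is None),
            )
        )
    if ranked[-2].gen == waist.gen or (ranked[-2].gen is None and waist.gen is None):
        diags.append(
            Diagnostic(
                "tie_broken_by_input_order",
                (ranked[-2].device_id, waist.device_id),
            )
        )
    wrist_map, wd = _assign_wrist_sides(wrists)
    shank_map, sd = _assign_shank_sides(shanks)
    side_map = wrist_map | shank_map | {waist.device_id: BD}
    mapping = {fv.device_id: side_map[fv.device_id] for fv in fvs}
    return PlacementAssignment(
        configuration="five", mapping=mapping, diagnostics=tuple(diags + wd + sd)
    )


_CLASSIFIERS = {
    "two": classify_two,
    "three": classify_three,
    "four": classify_four,
    "five": classify_five,
}


def identify_placements(
    bundle: SessionBundle, params: AlgorithmParams | None = None
) -> PlacementAssignment:
    """Extract features for every device and apply the layout's procedure.

    Deterministic given its inputs; raises :class:`ConfigurationError`
    for unsupported device counts and :class:`ValueError` when the
    duration gate (if enforced) fails.
    """
    params = params or AlgorithmParams()
    issues = validate_session(bundle, params)
    config = detect_configuration(bundle)  # raises on bad count
    duration_issues = [i for i in issues if i.startswith("below_min_duration")]
    if duration_issues:
        raise ValueError(
            "session below minimum duration "
            f"({params.min_duration} s): {duration_issues}"
        )
    fvs = [extract_features(rec, params) for rec in bundle.recordings]
    return _CLASSIFIERS[config](fvs)
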
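"""Cuff-size parsing, selection and miss-cuffing classification.

A cuff is suitable only for the arm-circumference range printed on it;
measuring with a cuff that is too small for the arm biases pressures upward
and one that is too large biases them downward, so "miss-cuffing" — the
fraction of subjects measured with a non-covering cuff — is a standard
survey quality indicator.  Bladder adequacy applies the conventional rule
that the bladder should span at least 40% (width) and 80% (length) of the
arm circumference.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Optional, Sequence

from .survey_data import CuffSpec, SurveyDataset

__all__ = [
    "CuffParseError",
    "CuffAssignment",
    "MisscuffReport",
    "parse_cuff_range",
    "format_cuff_range",
    "split_cuff_list",
    "classify_cuffing",
    "select_cuff",
    "misscuff_report",
    "bladder_adequacy",
]


class CuffParseError(ValueError):
    """A printed cuff label did not match any recognised range pattern."""


# printed labels use an en-dash; plain hyphens are accepted too
_RANGE_RE = re.compile(r"^(\d+(?:\.\d+)?)\s*[–-]\s*(\d+(?:\.\d+)?)$")
_BOUND_RE = re.compile(r"^(≤|≥|<=|>=|<|>)\s*(\d+(?:\.\d+)?)$")


def parse_cuff_range(label: str) -> CuffSpec:
    """Parse a printed recommended-circumference label into a :class:`CuffSpec`.

    Handles closed ranges ("22–32 cm", inclusive at both ends), and
    one-sided bounds ("≤34 cm", "≥ 32 cm", "> 42 cm", "< 22 cm").  The
    "cm" unit suffix is optional.
    """
    if not label or not label.strip():
        raise CuffParseError("empty cuff label")
    text = label.strip()
    core = re.sub(r"\s*cm\.?\s*$", "", text, flags=re.IGNORECASE).strip()
    m = _RANGE_RE.match(core)
    if m:
        lo, hi = float(m.group(1)), float(m.group(2))
        return CuffSpec(label=text, min_circ_cm=lo, max_circ_cm=hi)
    m = _BOUND_RE.match(core)
    if m:
        op, value = m.group(1), float(m.group(2))
        if op in ("≤", "<="):
            return CuffSpec(label=text, max_circ_cm=value, upper_inclusive=True)
        if op == "<":
            return CuffSpec(label=text, max_circ_cm=value, upper_inclusive=False)
        if op in ("≥", ">="):
            return CuffSpec(label=text, min_circ_cm=value, lower_inclusive=True)
        return CuffSpec(label=text, min_circ_cm=value, lower_inclusive=False)
    raise CuffParseError(f"unrecognised cuff label {label!r}")


def format_cuff_range(cuff: CuffSpec) -> str:
    """Render bounds back to a canonical printed label (re-parses to the
    same bounds)."""
    lo_fin = math.isfinite(cuff.min_circ_cm)
    hi_fin = math.isfinite(cuff.max_circ_cm)

    def num(x: float) -> str:
        return f"{x:g}"

    if lo_fin and hi_fin:
        return f"{num(cuff.min_circ_cm)}–{num(cuff.max_circ_cm)} cm"
    if hi_fin:
        op = "≤" if cuff.upper_inclusive else "<"
        return f"{op}{num(cuff.max_circ_cm)} cm"
    if lo_fin:
        op = "≥" if cuff.lower_inclusive else ">"
        return f"{op}{num(cuff.min_circ_cm)} cm"
    raise ValueError("cuff with no finite bound cannot be formatted")


def split_cuff_list(text: str) -> list[str]:
    """Split a printed cuff inventory ("22–32 cm and 33–41 cm",
    "17–26 cm, 24–32 cm, 32–48 cm") into individual labels."""
    parts = re.split(r",|\band\b", text)
    return [p.strip() for p in parts if p.strip()]


@dataclass(frozen=True)
class CuffAssignment:
    participant_id: str
    circumference_cm: Optional[float]
    cuff_used: Optional[CuffSpec]
    status: str  # correct | too_small_cuff | too_large_cuff | unknown


@dataclass(frozen=True)
class MisscuffReport:
    n_classified: int
    n_miscuffed: int
    n_too_small: int
    n_too_large: int
    n_unknown: int
    assignments: tuple[CuffAssignment, ...] = ()

    @property
    def proportion(self) -> Optional[float]:
        if self.n_classified == 0:
            return None
        return self.n_miscuffed / self.n_classified


def classify_cuffing(circumference_cm: Optional[float], cuff: Optional[CuffSpec]) -> str:
    """Classify one measurement as correct / too_small_cuff / too_large_cuff.

    A cuff is *too small* when the arm circumference lies above its printed
    range, *too large* when below.  Missing inputs give ``unknown``.
    """
    if circumference_cm is None or cuff is None:
        return "unknown"
    if circumference_cm <= 0:
        raise ValueError("arm circumference must be positive")
    if cuff.covers(circumference_cm):
        return "correct"
    above = circumference_cm > cuff.max_circ_cm or (
        circumference_cm == cuff.max_circ_cm and not cuff.upper_inclusive
    )
    return "too_small_cuff" if above else "too_large_cuff"


def select_cuff(
    circumference_cm: float, inventory: Sequence[CuffSpec]
) -> tuple[CuffSpec, bool]:
    """Pick the appropriate cuff from an inventory.

    Returns ``(cuff, covered)``.  Among covering cuffs the one with the
    smaller upper bound wins (adjacent printed ranges overlap at their
    shared boundary; the smaller cuff biases less at such circumferences).
    If no cuff covers the arm, the nearest range is returned with
    ``covered=False`` — a forced miss-cuff.
    """
    if not inventory:
        raise ValueError("empty cuff inventory")
    if circumference_cm <= 0:
        raise ValueError("arm circumference must be positive")
    covering = [c for c in inventory if c.covers(circumference_cm)]
    if covering:
        chosen = min(covering, key=lambda c: (c.max_circ_cm, c.min_circ_cm))
        return chosen, True

    def distance(c: CuffSpec) -> float:
        if circumference_cm < c.min_circ_cm:
            return c.min_circ_cm - circumference_cm
        return circumference_cm - c.max_circ_cm

    return min(inventory, key=distance), False


def _match_cuff(label: str, inventory: Sequence[CuffSpec]) -> Optional[CuffSpec]:
    """Resolve a participant's recorded cuff label against the inventory,
    tolerating hyphen/en-dash and unit-spacing differences."""

    def norm(s: str) -> str:
        return re.sub(r"\s+", "", s.replace("-", "–").lower())

    target = norm(label)
    for c in inventory:
        if norm(c.label) == target:
            return c
    try:
        return parse_cuff_range(label)
    except CuffParseError:
        return None


def misscuff_report(ds: SurveyDataset, keep_assignments: bool = False) -> MisscuffReport:
    """Classify every participant's cuff use and summarise miss-cuffing.

    Participants with a missing arm circumference or an unresolvable cuff
    label are ``unknown`` and excluded from the denominator, mirroring the
    published tables' "not possible to calculate" entries.
    """
    inventory = ds.protocol.cuff_inventory
    assignments: list[CuffAssignment] = []
    n_small = n_large = n_correct = n_unknown = 0
    for p in ds.participants:
        cuff = (
            _match_cuff(p.cuff_label, inventory) if p.cuff_label is not None else None
        )
        status = classify_cuffing(p.arm_circumference_cm, cuff)
        if status == "too_small_cuff":
            n_small += 1
        elif status == "too_large_cuff":
            n_large += 1
        elif status == "correct":
            n_correct += 1
        else:
            n_unknown += 1
        if keep_assignments:
            assignments.append(
                CuffAssignment(p.participant_id, p.arm_circumference_cm, cuff, status)
            )
    return MisscuffReport(
        n_classified=n_correct + n_small + n_large,
        n_miscuffed=n_small + n_large,
        n_too_small=n_small,
        n_too_large=n_large,
        n_unknown=n_unknown,
        assignments=tuple(assignments),
    )


def bladder_adequacy(
    circumference_cm: float, cuff: CuffSpec
) -> dict[str, Optional[bool]]:
    """Check the 40%-width / 80%-length bladder rule (boundary inclusive).

    Missing bladder dimensions give ``None`` for the corresponding check.
    """
    if circumference_cm <= 0:
        raise ValueError("arm circumference must be positive")
    width_ok = (
        None
        if cuff.bladder_width_cm is None
        else cuff.bladder_width_cm >= 0.4 * circumference_cm
    )
    length_ok = (
        None
        if cuff.bladder_length_cm is None
        else cuff.bladder_length_cm >= 0.8 * circumference_cm
    )
    return {"width_ok": width_ok, "length_ok": length_ok}
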
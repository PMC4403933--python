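"""Reference measurement protocol and survey-protocol comparison.

The reference procedure encoded here is the standardized European health
examination survey protocol: three sequential measurements one minute
apart, right arm, sitting posture after five minutes of quiet rest, cuff
chosen from at least three sizes, and — when a mercury column is
auscultated — the bell of the stethoscope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .survey_data import SurveyProtocol

__all__ = [
    "ReferenceProtocol",
    "Deviation",
    "ComplianceReport",
    "ehes_reference",
    "compare_protocol",
    "census",
    "manufacturer",
]


@dataclass(frozen=True)
class ReferenceProtocol:
    n_measurements: int = 3
    interval_minutes: float = 1.0
    arm: str = "right"
    posture: str = "sitting"
    rest_minutes: float = 5.0
    stethoscope_side: str = "bell"  # applies to auscultatory devices only
    min_cuff_count: int = 3


@dataclass(frozen=True)
class Deviation:
    field: str
    expected: object
    observed: object
    severity: str  # "deviation" | "note"


@dataclass
class ComplianceReport:
    survey_id: str
    deviations: list[Deviation] = field(default_factory=list)

    @property
    def is_compliant(self) -> bool:
        return not any(d.severity == "deviation" for d in self.deviations)


def ehes_reference() -> ReferenceProtocol:
    """The constant reference protocol."""
    return ReferenceProtocol()


def compare_protocol(p: SurveyProtocol) -> ComplianceReport:
    """Report a survey protocol's deviations from the reference.

    One entry per mismatched field.  Fewer than three cuff sizes is a
    deviation; using the diaphragm with an auscultatory device is a
    deviation.  The device type itself is a national choice, so a
    non-mercury device is recorded as a note, not a deviation.  Fields the
    survey did not declare (``None``) are skipped.
    """
    ref = ehes_reference()
    devs: list[Deviation] = []

    def check(fieldname: str, expected, observed) -> None:
        if observed is not None and observed != expected:
            devs.append(Deviation(fieldname, expected, observed, "deviation"))

    check("n_measurements", ref.n_measurements, p.n_measurements)
    check("interval_minutes", ref.interval_minutes, p.interval_minutes)
    check("rest_minutes", ref.rest_minutes, p.rest_minutes)
    check("arm", ref.arm, p.arm)
    check("posture", ref.posture, p.posture)
    if len(p.cuff_inventory) < ref.min_cuff_count:
        devs.append(
            Deviation(
                "cuff_count", f">={ref.min_cuff_count}", len(p.cuff_inventory), "deviation"
            )
        )
    if p.device_type != "oscillometric":
        if p.stethoscope_side != ref.stethoscope_side:
            devs.append(
                Deviation(
                    "stethoscope_side", ref.stethoscope_side, p.stethoscope_side, "deviation"
                )
            )
    if p.device_type != "mercury":
        devs.append(Deviation("device_type", "mercury", p.device_type, "note"))
    return ComplianceReport(survey_id=p.survey_id, deviations=devs)


def manufacturer(device_model: str, overrides: Optional[dict[str, str]] = None) -> str:
    """Manufacturer of a device model: the first whitespace-delimited token
    ("Omron M6" -> "Omron"), overridable via an explicit map."""
    if overrides and device_model in overrides:
        return overrides[device_model]
    return device_model.split()[0] if device_model.split() else ""


def census(
    protocols: Sequence[SurveyProtocol],
    manufacturer_overrides: Optional[dict[str, str]] = None,
) -> dict[str, int]:
    """Cross-survey protocol counts.

    Device model and manufacturer counts are scoped to oscillometric
    devices (mercury columns are a single generic instrument class).
    ``n_multi_cuff`` counts surveys with more than one cuff size available;
    ``n_temp_recorded`` counts surveys that routinely recorded room
    temperature.
    """
    if not protocols:
        raise ValueError("census requires a non-empty protocol list")
    oscillometric = [p for p in protocols if p.device_type == "oscillometric"]
    models = {p.device_model for p in oscillometric}
    manufacturers = {
        manufacturer(p.device_model, manufacturer_overrides) for p in oscillometric
    }
    return {
        "n_surveys": len(protocols),
        "n_mercury": sum(1 for p in protocols if p.device_type == "mercury"),
        "n_oscillometric": len(oscillometric),
        "n_aneroid": sum(1 for p in protocols if p.device_type == "aneroid"),
        "n_models_oscillometric": len(models),
        "n_manufacturers_oscillometric": len(manufacturers),
        "n_multi_cuff": sum(1 for p in protocols if len(p.cuff_inventory) > 1),
        "n_temp_recorded": sum(1 for p in protocols if p.temp_recorded),
    }
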
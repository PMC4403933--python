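"""Seeded generator of synthetic BP survey datasets.

The generator emulates the statistical structure the QC battery is designed
to detect: a Normal true-pressure distribution; additive offsets for
protocol deviations (talking, crossed legs, unsupported arm, wrong cuff,
...) taken from the published effect-magnitude ranges; observer behaviour
(systematic offset, terminal-digit-zero preference, copying of a previous
reading); and device rounding — a mercury column is read to the nearest
2 mmHg (even terminal digits), an oscillometric display to 1 mmHg.

Random draws are consumed in a fixed order independent of parameter values,
so two configurations differing only in an effect size or a prevalence are
driven by common random numbers when given the same seed — paired designs
(e.g. talking vs. silent, offset vs. no offset) difference out the sampling
noise.
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np

from . import cuff_matching
from .survey_data import (
    ALL_FLAGS,
    DURING_FLAGS,
    PRE_EXAM_FLAGS,
    CuffSpec,
    LoadLog,
    ParticipantRecord,
    Reading,
    SurveyDataset,
    SurveyProtocol,
)

__all__ = [
    "FactorEffect",
    "EffectModel",
    "ObserverModel",
    "SimulationConfig",
    "ConfigError",
    "default_effect_model",
    "default_cuff_inventory",
    "simulate_survey",
    "inject_misscuffing",
]


class ConfigError(ValueError):
    """A simulation configuration violates its constraints."""


@dataclass(frozen=True)
class FactorEffect:
    """Additive offset range (mmHg) a factor imposes on the observed
    pressure; the sign encodes direction."""

    sbp_low: float
    sbp_high: float
    dbp_low: float
    dbp_high: float

    def __post_init__(self) -> None:
        if self.sbp_low > self.sbp_high or self.dbp_low > self.dbp_high:
            raise ConfigError("effect range must satisfy low <= high")

    def draw(self, which: str, mode: str, u: float) -> float:
        lo, hi = (
            (self.sbp_low, self.sbp_high) if which == "sbp" else (self.dbp_low, self.dbp_high)
        )
        if mode == "midpoint":
            return (lo + hi) / 2.0
        return lo + u * (hi - lo)


EffectModel = Mapping[str, FactorEffect]


def default_effect_model() -> dict[str, FactorEffect]:
    """Published effect magnitudes of measurement-condition factors.

    One entry per reported factor; ranges are reproduced as published and
    the two "extreme" magnitudes (uncomfortably distended bladder; too-small
    cuff on an obese arm) are exposed under separate ``*_extreme`` names so
    the moderate ranges stay the defaults.  ``cuff_over_clothing`` has no
    reported diastolic effect — transcribed as 0.
    """
    return {
        "cold_room": FactorEffect(14, 14, 15, 15),
        "full_bladder": FactorEffect(10, 15, 10, 10),
        "full_bladder_extreme": FactorEffect(40, 40, 50, 50),
        "heavy_exercise": FactorEffect(-20, -18, -9, -7),
        "heavy_meal": FactorEffect(-20, -20, -20, -20),
        "smoking": FactorEffect(10, 10, 8, 8),
        "no_rest": FactorEffect(10, 20, 14, 14),
        "left_arm": FactorEffect(-3, -1, 1, 1),
        "supine": FactorEffect(3, 10, 1, 5),
        "back_unsupported": FactorEffect(5, 15, 6, 6),
        "arm_unsupported": FactorEffect(1, 7, 5, 11),
        "legs_crossed": FactorEffect(5, 8, 3, 5),
        "talking": FactorEffect(17, 17, 13, 13),
        "arm_below_heart": FactorEffect(10, 10, 10, 10),
        "cuff_over_clothing": FactorEffect(5, 5, 0, 0),
        "cuff_too_large": FactorEffect(-30, -10, -30, -10),
        "cuff_too_small": FactorEffect(3, 12, 2, 8),
        "cuff_too_small_extreme": FactorEffect(30, 30, 30, 30),
    }


def default_cuff_inventory() -> list[CuffSpec]:
    """A common three-cuff inventory (small/standard/large)."""
    return [
        cuff_matching.parse_cuff_range(s)
        for s in ("17–22 cm", "22–32 cm", "32–42 cm")
    ]


@dataclass(frozen=True)
class ObserverModel:
    """Observer-behaviour parameters.

    ``zero_preference_prob`` — probability a reading is pulled to a
    terminal digit of 0 (rounded to the nearest 10 mmHg);
    ``identical_copy_prob`` — probability a reading is copied verbatim from
    the previous one instead of being measured;
    ``systematic_offset_mmHg`` — constant offset added to every reading
    (e.g. mishearing Korotkoff sounds, calibration error).
    """

    zero_preference_prob: float = 0.0
    identical_copy_prob: float = 0.0
    systematic_offset_mmHg: float = 0.0

    def __post_init__(self) -> None:
        for name in ("zero_preference_prob", "identical_copy_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")


@dataclass
class SimulationConfig:
    n_participants: int = 500
    true_sbp_mean: float = 130.0
    true_sbp_sd: float = 17.0
    true_dbp_mean: float = 80.0
    true_dbp_sd: float = 10.0
    within_person_sd: float = 4.0
    device_type: str = "oscillometric"
    device_model: str = "Omron M6"
    cuff_inventory: list[CuffSpec] = field(default_factory=default_cuff_inventory)
    arm_circ_mean: float = 30.5
    arm_circ_sd: float = 4.5
    factor_prevalence: dict[str, float] = field(default_factory=dict)
    effect_model: dict[str, FactorEffect] = field(default_factory=default_effect_model)
    observer: ObserverModel = field(default_factory=ObserverModel)
    effect_draw: str = "midpoint"  # or "uniform_in_range"
    room_temp_mean: float = 22.5
    room_temp_sd: float = 0.5
    temp_recorded: bool = True
    survey_id: str = "SIM"
    seed: int = 0


def _validate_config(cfg: SimulationConfig) -> None:
    if cfg.n_participants <= 0:
        raise ConfigError("n_participants must be positive")
    for name in ("true_sbp_sd", "true_dbp_sd", "within_person_sd", "arm_circ_sd", "room_temp_sd"):
        if getattr(cfg, name) < 0:
            raise ConfigError(f"{name} must be nonnegative")
    if cfg.device_type not in ("mercury", "oscillometric", "aneroid"):
        raise ConfigError(f"unknown device_type {cfg.device_type!r}")
    if cfg.effect_draw not in ("midpoint", "uniform_in_range"):
        raise ConfigError(f"unknown effect_draw {cfg.effect_draw!r}")
    for flag, prob in cfg.factor_prevalence.items():
        if flag not in ALL_FLAGS:
            raise ConfigError(f"unknown factor {flag!r} in prevalence map")
        if not 0.0 <= prob <= 1.0:
            raise ConfigError(f"prevalence of {flag!r} must lie in [0, 1]")


def _device_round(values: np.ndarray, device_type: str) -> np.ndarray:
    """Device rounding: mercury to the nearest 2 mmHg (ties to the higher
    even value), otherwise to the nearest integer (ties up)."""
    if device_type == "mercury":
        return np.floor(values / 2.0 + 0.5) * 2.0
    return np.floor(values + 0.5)


def _round_to_ten(values: np.ndarray) -> np.ndarray:
    return np.floor(values / 10.0 + 0.5) * 10.0


def simulate_survey(cfg: SimulationConfig) -> SurveyDataset:
    """Generate a full synthetic survey dataset, deterministic in ``cfg.seed``.

    Per participant: true pressures are drawn from the configured Normal
    distributions; condition flags switch on independently with their
    configured prevalences and add their effect offsets (range midpoint by
    default, or uniform within the range); each of the three readings adds
    independent within-person noise and the observer's systematic offset;
    readings are rounded on the device grid unless pulled to a terminal 0;
    finally, with the configured copy probability, a reading is replaced by
    a verbatim copy of the previous one.  A participant whose assigned cuff
    cannot cover the arm (inventory gap) also receives the too-small/too-
    large cuff effect.
    """
    _validate_config(cfg)
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_participants

    # Fixed draw order (common random numbers across configurations).
    true_sbp = rng.normal(cfg.true_sbp_mean, cfg.true_sbp_sd, n)
    true_dbp = rng.normal(cfg.true_dbp_mean, cfg.true_dbp_sd, n)
    flag_u = rng.random((n, len(ALL_FLAGS)))
    effect_u = rng.random((n, len(ALL_FLAGS) + 2))  # +2: cuff too small/large
    circ = rng.normal(cfg.arm_circ_mean, cfg.arm_circ_sd, n)
    noise_sbp = rng.normal(0.0, cfg.within_person_sd, (n, 3))
    noise_dbp = rng.normal(0.0, cfg.within_person_sd, (n, 3))
    zero_u = rng.random((n, 3))
    copy_u = rng.random((n, 2))
    temps = rng.normal(cfg.room_temp_mean, cfg.room_temp_sd, n)

    circ = np.clip(np.round(circ, 1), 16.0, 60.0)
    flags_on = flag_u < np.array(
        [cfg.factor_prevalence.get(f, 0.0) for f in ALL_FLAGS]
    )

    participants: list[ParticipantRecord] = []
    log = LoadLog()
    obs = cfg.observer
    for i in range(n):
        eff_sbp = eff_dbp = 0.0
        active = [f for j, f in enumerate(ALL_FLAGS) if flags_on[i, j]]
        for j, f in enumerate(ALL_FLAGS):
            if flags_on[i, j] and f in cfg.effect_model:
                e = cfg.effect_model[f]
                eff_sbp += e.draw("sbp", cfg.effect_draw, effect_u[i, j])
                eff_dbp += e.draw("dbp", cfg.effect_draw, effect_u[i, j])

        cuff_label = None
        if cfg.cuff_inventory:
            cuff, covered = cuff_matching.select_cuff(circ[i], cfg.cuff_inventory)
            cuff_label = cuff.label
            if not covered:
                factor = (
                    "cuff_too_small" if circ[i] > cuff.max_circ_cm else "cuff_too_large"
                )
                if factor in cfg.effect_model:
                    e = cfg.effect_model[factor]
                    k = len(ALL_FLAGS) + (0 if factor == "cuff_too_small" else 1)
                    eff_sbp += e.draw("sbp", cfg.effect_draw, effect_u[i, k])
                    eff_dbp += e.draw("dbp", cfg.effect_draw, effect_u[i, k])

        sbp_raw = true_sbp[i] + eff_sbp + obs.systematic_offset_mmHg + noise_sbp[i]
        dbp_raw = true_dbp[i] + eff_dbp + obs.systematic_offset_mmHg + noise_dbp[i]
        pulled = zero_u[i] < obs.zero_preference_prob
        sbp = np.where(
            pulled, _round_to_ten(sbp_raw), _device_round(sbp_raw, cfg.device_type)
        )
        dbp = np.where(
            pulled, _round_to_ten(dbp_raw), _device_round(dbp_raw, cfg.device_type)
        )
        for t in (1, 2):
            if copy_u[i, t - 1] < obs.identical_copy_prob:
                sbp[t] = sbp[t - 1]
                dbp[t] = dbp[t - 1]
        sbp = np.clip(sbp, 40, 300).astype(int)
        dbp = np.clip(dbp, 40, 300).astype(int)
        # keep the physiological ordering; a 2-mmHg gap stays on the mercury grid
        dbp = np.minimum(dbp, sbp - 2)

        participants.append(
            ParticipantRecord(
                participant_id=f"{cfg.survey_id}-{i + 1:05d}",
                survey_id=cfg.survey_id,
                readings=tuple(
                    Reading(t + 1, int(sbp[t]), int(dbp[t])) for t in range(3)
                ),
                arm_circumference_cm=float(circ[i]),
                cuff_label=cuff_label,
                room_temp_c=float(np.round(temps[i], 1)) if cfg.temp_recorded else None,
                pre_exam_flags=frozenset(f for f in active if f in PRE_EXAM_FLAGS),
                during_flags=frozenset(f for f in active if f in DURING_FLAGS),
            )
        )

    recorded = cfg.temp_recorded
    protocol = SurveyProtocol(
        survey_id=cfg.survey_id,
        n_participants=n,
        device_type=cfg.device_type,
        device_model=cfg.device_model,
        cuff_inventory=list(cfg.cuff_inventory),
        arm="right",
        posture="sitting",
        n_measurements=3,
        rest_minutes=5.0,
        interval_minutes=1.0,
        stethoscope_side="not_relevant" if cfg.device_type == "oscillometric" else "bell",
        temp_recorded=recorded,
        mean_temp_c=float(np.round(temps.mean(), 1)) if recorded else None,
        min_temp_c=float(np.round(temps.min(), 1)) if recorded else None,
        max_temp_c=float(np.round(temps.max(), 1)) if recorded else None,
    )
    return SurveyDataset(protocol=protocol, participants=participants, log=log)


def inject_misscuffing(
    ds: SurveyDataset,
    fraction: float,
    direction: str = "too_small",
    seed: int = 0,
    effect_model: Optional[EffectModel] = None,
    effect_draw: str = "midpoint",
) -> SurveyDataset:
    """Return a copy of the dataset with a random fraction of participants
    re-assigned to a non-covering cuff.

    ``direction='too_small'`` re-assigns to a cuff whose range lies below
    the arm circumference (and applies the too-small-cuff pressure effect),
    ``'too_large'`` the converse.  Participants without a usable
    circumference, or for whom the inventory holds no cuff in the requested
    direction, are skipped and listed in the returned dataset's log.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ConfigError("fraction must lie in [0, 1]")
    if direction not in ("too_small", "too_large"):
        raise ConfigError("direction must be 'too_small' or 'too_large'")
    effect_model = effect_model if effect_model is not None else default_effect_model()
    factor = "cuff_too_small" if direction == "too_small" else "cuff_too_large"
    effect = effect_model[factor]
    inventory = ds.protocol.cuff_inventory
    rng = np.random.default_rng(seed)
    device = ds.protocol.device_type

    new_participants: list[ParticipantRecord] = []
    log = LoadLog(warnings=list(ds.log.warnings), excluded=list(ds.log.excluded))
    for p in ds.participants:
        u, eu = rng.random(), rng.random()  # always drawn: keeps pairing stable
        if u >= fraction or p.arm_circumference_cm is None:
            new_participants.append(_copy.deepcopy(p))
            continue
        circ = p.arm_circumference_cm
        if direction == "too_small":
            candidates = [c for c in inventory if circ > c.max_circ_cm]
            wrong = max(candidates, key=lambda c: c.max_circ_cm) if candidates else None
        else:
            candidates = [c for c in inventory if circ < c.min_circ_cm]
            wrong = min(candidates, key=lambda c: c.min_circ_cm) if candidates else None
        if wrong is None:
            log.warnings.append(
                f"{p.participant_id}: no {direction} cuff available for "
                f"circumference {circ} cm; skipped"
            )
            new_participants.append(_copy.deepcopy(p))
            continue
        d_sbp = effect.draw("sbp", effect_draw, eu)
        d_dbp = effect.draw("dbp", effect_draw, eu)
        readings = []
        for r in p.readings:
            sbp = r.sbp
            dbp = r.dbp
            if sbp is not None:
                sbp = int(np.clip(_device_round(np.array([sbp + d_sbp]), device)[0], 40, 300))
            if dbp is not None:
                dbp = int(np.clip(_device_round(np.array([dbp + d_dbp]), device)[0], 40, 300))
            if sbp is not None and dbp is not None:
                dbp = min(dbp, sbp - 2)
            readings.append(Reading(r.sequence_index, sbp, dbp))
        new_participants.append(replace(_copy.deepcopy(p), readings=tuple(readings), cuff_label=wrong.label))
    return SurveyDataset(
        protocol=_copy.deepcopy(ds.protocol), participants=new_participants, log=log
    )
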
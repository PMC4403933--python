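"""Propagation of systematic BP measurement offsets into hypertension
prevalence.

Population prevalence is the tail fraction of the blood-pressure
distribution beyond a classification threshold (conventionally
SBP >= 140 or DBP >= 90 mmHg), so even a small systematic measurement
offset shifts the whole distribution and moves a disproportionate mass
across the threshold.  ``analytic_shift`` quantifies the mechanism in a
Normal-threshold model; ``empirical_shift`` measures it on paired
simulated surveys driven by common random numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

from scipy import stats

from .survey_data import SurveyDataset

__all__ = [
    "PrevalenceShift",
    "prevalence",
    "analytic_shift",
    "empirical_shift",
]

#: Conventional clinical classification thresholds, mmHg.
DEFAULT_SBP_THRESHOLD = 140.0
DEFAULT_DBP_THRESHOLD = 90.0


@dataclass(frozen=True)
class PrevalenceShift:
    threshold_mmHg: float
    offset_mmHg: float
    baseline_prevalence: float
    shifted_prevalence: float
    method: str  # "analytic_normal" | "empirical"
    mc_se: Optional[float] = None  # Monte-Carlo SE of relative_change

    @property
    def relative_change(self) -> float:
        return (self.shifted_prevalence - self.baseline_prevalence) / self.baseline_prevalence


def _participant_bp(p, summary: str) -> tuple[Optional[float], Optional[float]]:
    if summary == "mean23":
        pairs = [(p.reading(2), p.reading(3))]
        r2, r3 = pairs[0]
        if r2.sbp is None or r3.sbp is None or r2.dbp is None or r3.dbp is None:
            return None, None
        return (r2.sbp + r3.sbp) / 2.0, (r2.dbp + r3.dbp) / 2.0
    if summary == "mean3":
        sbps = [r.sbp for r in p.readings]
        dbps = [r.dbp for r in p.readings]
        if any(v is None for v in sbps + dbps):
            return None, None
        return sum(sbps) / 3.0, sum(dbps) / 3.0
    if summary == "last":
        r = p.reading(3)
        if r.sbp is None or r.dbp is None:
            return None, None
        return float(r.sbp), float(r.dbp)
    raise ValueError(f"unknown summary {summary!r}")


def prevalence(
    ds: SurveyDataset,
    threshold_sbp: float = DEFAULT_SBP_THRESHOLD,
    threshold_dbp: Optional[float] = DEFAULT_DBP_THRESHOLD,
    summary: str = "mean23",
) -> float:
    """Fraction of participants classified hypertensive.

    The participant-level blood pressure is the mean of the 2nd and 3rd
    readings by default (the first reading is typically elevated), with
    ``summary='mean3'`` and ``'last'`` as alternatives.  A participant is
    hypertensive when SBP >= ``threshold_sbp`` or DBP >= ``threshold_dbp``;
    pass ``threshold_dbp=None`` for a systolic-only classification.
    """
    n = hyper = 0
    for p in ds.participants:
        sbp, dbp = _participant_bp(p, summary)
        if sbp is None:
            continue
        n += 1
        if sbp >= threshold_sbp or (threshold_dbp is not None and dbp >= threshold_dbp):
            hyper += 1
    if n == 0:
        raise ValueError("no participant with the required readings present")
    return hyper / n


def analytic_shift(
    mu: float, sigma: float, delta: float, threshold: float = DEFAULT_SBP_THRESHOLD
) -> PrevalenceShift:
    """Prevalence shift under a Normal(mu, sigma) pressure distribution.

    Baseline prevalence is the upper-tail probability at the threshold; a
    systematic offset ``delta`` shifts the mean.  The relative change is
    asymmetric in the sign of ``delta`` because the Normal tail is convex.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    baseline = float(stats.norm.sf(threshold, loc=mu, scale=sigma))
    shifted = float(stats.norm.sf(threshold, loc=mu + delta, scale=sigma))
    return PrevalenceShift(
        threshold_mmHg=threshold,
        offset_mmHg=delta,
        baseline_prevalence=baseline,
        shifted_prevalence=shifted,
        method="analytic_normal",
    )


def empirical_shift(
    cfg, delta: float, threshold: float = DEFAULT_SBP_THRESHOLD, summary: str = "mean23"
) -> PrevalenceShift:
    """Measure the prevalence shift on paired simulated surveys.

    Simulates the survey twice from the same seed — once as configured and
    once with the observer's systematic offset increased by ``delta`` — so
    the two datasets share every random draw and the shift is estimated
    with common random numbers.  Classification is systolic-only, matching
    the univariate analytic model.  ``mc_se`` is a delta-method standard
    error of the relative change.
    """
    from .synthetic_data import simulate_survey  # deferred: avoid cycle at import

    base_ds = simulate_survey(cfg)
    shifted_cfg = replace(
        cfg,
        observer=replace(
            cfg.observer,
            systematic_offset_mmHg=cfg.observer.systematic_offset_mmHg + delta,
        ),
    )
    shifted_ds = simulate_survey(shifted_cfg)

    p0 = prevalence(base_ds, threshold_sbp=threshold, threshold_dbp=None, summary=summary)
    p1 = prevalence(shifted_ds, threshold_sbp=threshold, threshold_dbp=None, summary=summary)
    if p0 == 0:
        raise ValueError("baseline prevalence is zero; relative change undefined")

    # Delta-method SE of (p1-p0)/p0 for paired indicators: with a common-
    # random-number pairing and a monotone offset the two classifications
    # are nested, so q = |p1 - p0| is itself a sample proportion.
    n = cfg.n_participants
    q = abs(p1 - p0)
    var_q = q * (1 - q) / n
    var_p0 = p0 * (1 - p0) / n
    cov = -q * p0 / n  # disjoint-category multinomial covariance
    rel = (p1 - p0) / p0
    var_rel = (var_q + rel**2 * var_p0 - 2 * rel * cov) / p0**2 if q > 0 else var_q / p0**2
    return PrevalenceShift(
        threshold_mmHg=threshold,
        offset_mmHg=delta,
        baseline_prevalence=p0,
        shifted_prevalence=p1,
        method="empirical",
        mc_se=float(var_rel**0.5),
    )
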
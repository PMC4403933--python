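"""Retrospective data-quality statistics for triplicate BP measurements.

The battery covers the classic observer-error diagnostics for blood-pressure
surveys:

* **terminal-digit preference** — under careful measurement, terminal digits
  of readings are uniform over the device's digit support: {0,2,4,6,8} for a
  mercury column read to the nearest 2 mmHg, {0,...,9} for oscillometric
  displays.  Departures (typically an excess of 0) are tested with a
  chi-square goodness-of-fit test against the uniform null;
* **identical sequential readings** — an observer copying a previous value
  rather than measuring produces exactly equal consecutive readings far more
  often than chance;
* **missingness** per data item.

``flag_quality`` turns these statistics into survey-level warning flags.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
from scipy import stats

from .survey_data import ALL_FLAGS, SurveyDataset

__all__ = [
    "MERCURY_DIGITS",
    "ALL_DIGITS",
    "DigitSupport",
    "DigitTestResult",
    "IdenticalPairStats",
    "MissingnessReport",
    "QCThresholds",
    "terminal_digit_counts",
    "digit_chisq_test",
    "counts_from_percentages",
    "identical_pairs",
    "missingness",
    "zero_digit_excess",
    "estimate_zero_preference",
    "flag_quality",
]

MERCURY_DIGITS = (0, 2, 4, 6, 8)
ALL_DIGITS = tuple(range(10))


@dataclass(frozen=True)
class DigitSupport:
    digits: tuple[int, ...]

    @property
    def expected_proportion(self) -> float:
        return 1.0 / len(self.digits)


@dataclass(frozen=True)
class DigitTestResult:
    """Chi-square goodness-of-fit of terminal digits against uniformity."""

    observed_counts: tuple[int, ...]  # indexed by digit 0..9
    n_readings: int
    support: DigitSupport
    expected_counts: tuple[float, ...]  # over the support, in digit order
    chi2: float
    df: int
    p_value: float
    off_support_proportion: float


@dataclass(frozen=True)
class PairStat:
    proportion: Optional[float]
    denominator: int


@dataclass(frozen=True)
class IdenticalPairStats:
    """Identical-consecutive-reading proportions, keyed by pressure type
    ("SBP"/"DBP") and pair ("1-2"/"2-3")."""

    stats: Mapping[tuple[str, str], PairStat]

    def proportion(self, pressure: str, pair: str) -> Optional[float]:
        return self.stats[(pressure, pair)].proportion

    def proportions(self) -> list[float]:
        return [s.proportion for s in self.stats.values() if s.proportion is not None]


@dataclass(frozen=True)
class MissingnessReport:
    proportions: Mapping[str, float]  # data item -> missing fraction


@dataclass(frozen=True)
class QCThresholds:
    """Flagging thresholds.

    ``alpha`` — digit-test significance level; ``zero_excess`` — excess of
    terminal digit 0 over its expected share that triggers the digit flag
    on its own; ``identical`` — identical-reading proportion at or above
    which the copying flag raises (the published criterion is 28%).
    """

    alpha: float = 0.001
    zero_excess: float = 0.10
    identical: float = 0.28


def terminal_digit_counts(ds: SurveyDataset, pressure: str) -> np.ndarray:
    """Pool terminal digits (value mod 10) of all non-missing readings of
    one pressure type over all three sequences.

    Returns a length-10 integer array ``O[d]``; ``O.sum()`` is the number
    of pooled readings.
    """
    if pressure not in ("SBP", "DBP"):
        raise ValueError("pressure must be 'SBP' or 'DBP'")
    attr = "sbp" if pressure == "SBP" else "dbp"
    counts = np.zeros(10, dtype=np.int64)
    for p in ds.participants:
        for r in p.readings:
            value = getattr(r, attr)
            if value is not None:
                counts[value % 10] += 1
    if counts.sum() == 0:
        raise ValueError(f"no non-missing {pressure} readings to pool")
    return counts


def digit_chisq_test(
    counts: Union[np.ndarray, Sequence[int]], device_type: str
) -> DigitTestResult:
    """Chi-square goodness-of-fit of digit counts against the device's
    uniform digit support.

    For a mercury device the support is the even digits; if odd digits
    nevertheless occur (readings taken to 1 mmHg against protocol), the
    test falls back to the full 0–9 support so every expected count stays
    positive, and ``off_support_proportion`` reports the odd-digit share.
    """
    O = np.asarray(counts, dtype=np.int64)
    if O.shape != (10,):
        raise ValueError("counts must be a length-10 vector indexed by digit")
    if (O < 0).any():
        raise ValueError("digit counts must be nonnegative")
    n = int(O.sum())
    if n == 0:
        raise ValueError("empty digit counts")

    support_digits = MERCURY_DIGITS if device_type == "mercury" else ALL_DIGITS
    off = [d for d in ALL_DIGITS if d not in support_digits]
    off_count = int(O[off].sum()) if off else 0
    if off_count > 0:
        support_digits = ALL_DIGITS
    support = DigitSupport(tuple(support_digits))

    k = len(support.digits)
    observed = O[list(support.digits)].astype(float)
    expected = np.full(k, n / k)
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    df = k - 1
    p = float(stats.chi2.sf(chi2, df))
    return DigitTestResult(
        observed_counts=tuple(int(x) for x in O),
        n_readings=n,
        support=support,
        expected_counts=tuple(expected),
        chi2=chi2,
        df=df,
        p_value=p,
        off_support_proportion=off_count / n,
    )


def counts_from_percentages(
    pcts: Sequence[float], n_readings: int
) -> np.ndarray:
    """Reconstruct integer digit counts from printed percentages by
    largest-remainder apportionment, so the counts sum to ``n_readings``
    exactly.
    """
    p = np.asarray(pcts, dtype=float)
    if p.ndim != 1 or len(p) != 10:
        raise ValueError("expected 10 digit percentages")
    if (p < 0).any():
        raise ValueError("percentages must be nonnegative")
    total = p.sum()
    if not 95.0 <= total <= 105.0:
        raise ValueError(f"percentages sum to {total:g}, outside [95, 105]")
    if n_readings < 0:
        raise ValueError("n_readings must be nonnegative")
    quota = p / total * n_readings
    base = np.floor(quota).astype(np.int64)
    remainder = int(n_readings - base.sum())
    # ties broken by digit order for determinism
    order = np.lexsort((np.arange(10), -(quota - base)))
    base[order[:remainder]] += 1
    return base


def identical_pairs(ds: SurveyDataset) -> IdenticalPairStats:
    """Proportion of exactly equal consecutive readings per pressure type.

    The denominator for each pair is the number of participants with both
    readings present (only comparable pairs can be identical); a zero
    denominator leaves the proportion undefined (``None``).
    """
    out: dict[tuple[str, str], PairStat] = {}
    for pressure, attr in (("SBP", "sbp"), ("DBP", "dbp")):
        for pair, (i, j) in (("1-2", (1, 2)), ("2-3", (2, 3))):
            denom = equal = 0
            for p in ds.participants:
                a = getattr(p.reading(i), attr)
                b = getattr(p.reading(j), attr)
                if a is not None and b is not None:
                    denom += 1
                    if a == b:
                        equal += 1
            out[(pressure, pair)] = PairStat(
                proportion=equal / denom if denom else None, denominator=denom
            )
    return IdenticalPairStats(stats=out)


#: Data items scored for missingness.
MISSINGNESS_ITEMS = (
    "sbp1",
    "dbp1",
    "sbp2",
    "dbp2",
    "sbp3",
    "dbp3",
    "arm_circumference_cm",
    "cuff_label",
    "room_temp_c",
)


def missingness(ds: SurveyDataset) -> MissingnessReport:
    """Per-item missing fraction over all participants."""
    n = len(ds.participants)
    if n == 0:
        return MissingnessReport(proportions={item: 0.0 for item in MISSINGNESS_ITEMS})
    miss = dict.fromkeys(MISSINGNESS_ITEMS, 0)
    for p in ds.participants:
        for r in p.readings:
            if r.sbp is None:
                miss[f"sbp{r.sequence_index}"] += 1
            if r.dbp is None:
                miss[f"dbp{r.sequence_index}"] += 1
        if p.arm_circumference_cm is None:
            miss["arm_circumference_cm"] += 1
        if p.cuff_label is None:
            miss["cuff_label"] += 1
        if p.room_temp_c is None:
            miss["room_temp_c"] += 1
    return MissingnessReport(proportions={k: v / n for k, v in miss.items()})


def zero_digit_excess(result: DigitTestResult) -> float:
    """Observed share of terminal digit 0 minus its expected share under
    uniformity on the support used."""
    return result.observed_counts[0] / result.n_readings - result.support.expected_proportion


def estimate_zero_preference(result: DigitTestResult) -> float:
    """Estimate the probability that a reading was pulled to a terminal 0.

    Under a mixture in which each reading is forced to 0 with probability z
    and otherwise lands uniformly on the support, the digit-0 share is
    z + (1-z)/k, so z = excess / (1 - 1/k).  Unbiased for z; may be
    slightly negative by sampling noise.
    """
    k = len(result.support.digits)
    return zero_digit_excess(result) / (1.0 - 1.0 / k)


def flag_quality(
    digit_results: Union[DigitTestResult, Iterable[DigitTestResult]],
    identical: IdenticalPairStats,
    thresholds: Optional[QCThresholds] = None,
) -> set[str]:
    """Turn battery statistics into survey-level warning flags.

    ``digit_preference`` raises when any digit test is significant at
    ``thresholds.alpha`` or shows a zero-digit excess above
    ``thresholds.zero_excess``; ``identical_readings`` raises when any
    consecutive-pair proportion reaches ``thresholds.identical``.
    """
    thresholds = thresholds or QCThresholds()
    if isinstance(digit_results, DigitTestResult):
        digit_results = [digit_results]
    flags: set[str] = set()
    for r in digit_results:
        if r.p_value < thresholds.alpha or zero_digit_excess(r) > thresholds.zero_excess:
            flags.add("digit_preference")
    if any(p >= thresholds.identical for p in identical.proportions()):
        flags.add("identical_readings")
    return flags
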
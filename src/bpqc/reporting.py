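"""End-to-end QC pipeline: load -> validate -> compliance -> battery ->
cuff matching -> report files.

Emitted artefacts mirror the shape of the published per-survey summary
tables: a cuff/identical-readings table, and one terminal-digit percentage
table per pressure type with the chi-square p-value printed as "<0.0001"
below that floor.  All file content is a pure function of the inputs, so
repeated runs are byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional, Union

import pandas as pd

from . import cuff_matching, protocol_compliance, qc_battery, survey_data

__all__ = ["PipelineError", "QCReport", "run_pipeline", "format_p"]

P_FLOOR = 1e-4


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class QCReport:
    survey_id: str
    compliance: protocol_compliance.ComplianceReport
    validation: survey_data.ValidationReport
    missingness: qc_battery.MissingnessReport
    identical: qc_battery.IdenticalPairStats
    digit_sbp: qc_battery.DigitTestResult
    digit_dbp: qc_battery.DigitTestResult
    misscuff: cuff_matching.MisscuffReport
    temperature: survey_data.TemperatureSummary
    flags: set[str]


def format_p(p: float, floor: float = P_FLOOR) -> str:
    """Display a p-value the way the summary tables print it: four decimals,
    floored at "<0.0001"."""
    if p < floor:
        return f"<{floor:.4f}".rstrip("0").rstrip(".") if floor != 1e-4 else "<0.0001"
    return f"{p:.4f}"


def _pct(x: Optional[float]) -> str:
    return "#" if x is None else str(round(100 * x))


def _report_json(report: QCReport) -> dict:
    return {
        "survey_id": report.survey_id,
        "compliance": {
            "is_compliant": report.compliance.is_compliant,
            "deviations": [asdict(d) for d in report.compliance.deviations],
        },
        "validation": {
            "n_violations": report.validation.n_violations,
            "issues": [asdict(i) for i in report.validation.issues],
        },
        "missingness": dict(report.missingness.proportions),
        "identical_readings": {
            f"{pressure.lower()}_{pair.replace('-', '')}": {
                "proportion": s.proportion,
                "denominator": s.denominator,
            }
            for (pressure, pair), s in report.identical.stats.items()
        },
        "digit_tests": {
            name: {
                "observed_counts": list(r.observed_counts),
                "n_readings": r.n_readings,
                "support": list(r.support.digits),
                "chi2": r.chi2,
                "df": r.df,
                "p_value": r.p_value,
                "p_display": format_p(r.p_value),
                "off_support_proportion": r.off_support_proportion,
            }
            for name, r in (("SBP", report.digit_sbp), ("DBP", report.digit_dbp))
        },
        "misscuffing": {
            "n_classified": report.misscuff.n_classified,
            "n_miscuffed": report.misscuff.n_miscuffed,
            "n_too_small": report.misscuff.n_too_small,
            "n_too_large": report.misscuff.n_too_large,
            "n_unknown": report.misscuff.n_unknown,
            "proportion": report.misscuff.proportion,
        },
        "temperature": asdict(report.temperature),
        "flags": sorted(report.flags),
    }


def _digit_row(survey_id: str, device_model: str, r: qc_battery.DigitTestResult) -> dict:
    row = {"survey_id": survey_id, "device": device_model}
    for d in range(10):
        row[f"pct_digit_{d}"] = round(100 * r.observed_counts[d] / r.n_readings)
    row["p_text"] = format_p(r.p_value)
    return row


def run_pipeline(
    inputs: Union[survey_data.SurveyDataset, tuple],
    out_dir: Optional[Union[str, Path]] = None,
    thresholds: Optional[qc_battery.QCThresholds] = None,
) -> QCReport:
    """Run the full QC battery on one survey.

    ``inputs`` is either an in-memory :class:`SurveyDataset` or a
    ``(participants_csv, protocol_yaml)`` path pair.  When ``out_dir`` is
    given, writes ``report.json`` plus table-shaped CSVs with integer
    percentages.  A failing stage raises :class:`PipelineError` naming the
    stage; partially written outputs are removed.
    """
    if isinstance(inputs, survey_data.SurveyDataset):
        ds = inputs
    else:
        try:
            participants_path, protocol_path = inputs
            protocol = survey_data.load_protocol(protocol_path)
            ds = survey_data.load_participants(participants_path, protocol)
        except Exception as exc:  # noqa: BLE001 - rewrapped with stage context
            raise PipelineError("load", exc) from exc

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(name, exc) from exc

    validation = stage("validate", survey_data.validate_dataset, ds)
    compliance = stage("compliance", protocol_compliance.compare_protocol, ds.protocol)
    miss = stage("missingness", qc_battery.missingness, ds)
    identical = stage("identical_pairs", qc_battery.identical_pairs, ds)
    counts_sbp = stage("digit_counts", qc_battery.terminal_digit_counts, ds, "SBP")
    counts_dbp = stage("digit_counts", qc_battery.terminal_digit_counts, ds, "DBP")
    digit_sbp = stage(
        "digit_test", qc_battery.digit_chisq_test, counts_sbp, ds.protocol.device_type
    )
    digit_dbp = stage(
        "digit_test", qc_battery.digit_chisq_test, counts_dbp, ds.protocol.device_type
    )
    misscuff = stage("cuff_matching", cuff_matching.misscuff_report, ds)
    temperature = stage("temperature", survey_data.temperature_summary, [ds.protocol])
    flags = stage(
        "flags", qc_battery.flag_quality, [digit_sbp, digit_dbp], identical, thresholds
    )

    report = QCReport(
        survey_id=ds.protocol.survey_id,
        compliance=compliance,
        validation=validation,
        missingness=miss,
        identical=identical,
        digit_sbp=digit_sbp,
        digit_dbp=digit_dbp,
        misscuff=misscuff,
        temperature=temperature,
        flags=flags,
    )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        written: list[Path] = []
        try:
            path = out / "report.json"
            path.write_text(
                json.dumps(_report_json(report), indent=2, sort_keys=True) + "\n",
                encoding="utf-8",
            )
            written.append(path)

            s = identical.stats
            cuff_row = {
                "survey_id": report.survey_id,
                "pct_misscuffed": _pct(misscuff.proportion),
                "pct_identical_sbp_12": _pct(s[("SBP", "1-2")].proportion),
                "pct_identical_dbp_12": _pct(s[("DBP", "1-2")].proportion),
                "pct_identical_sbp_23": _pct(s[("SBP", "2-3")].proportion),
                "pct_identical_dbp_23": _pct(s[("DBP", "2-3")].proportion),
            }
            path = out / "cuff_identical.csv"
            pd.DataFrame([cuff_row]).to_csv(path, index=False)
            written.append(path)

            for name, result in (("sbp", digit_sbp), ("dbp", digit_dbp)):
                path = out / f"digits_{name}.csv"
                pd.DataFrame(
                    [_digit_row(report.survey_id, ds.protocol.device_model, result)]
                ).to_csv(path, index=False)
                written.append(path)
        except Exception as exc:  # noqa: BLE001
            for p in written:
                p.unlink(missing_ok=True)
            raise PipelineError("report", exc) from exc
    return report
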
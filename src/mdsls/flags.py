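"""Blood-smear flagging: conventional CBC thresholds and the MDS-LS flag.

The conventional rules mirror the analyzer's pre-configured review
thresholds (e.g. haemoglobin < 80 g/L, platelets < 100 G/L).  All
comparisons are strict: a value exactly at a threshold does not flag, which
is what leaves moderately cytopenic MDS patients — including transfused
ones — without a smear under the standard strategy.  The MDS-LS flag fires
whenever the likelihood score is negative.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .score import ScoreResult


@dataclass(frozen=True)
class FlagRule:
    parameter_name: str
    comparator: str  # "<" or ">"
    threshold: float
    flag_label: str

    def __post_init__(self) -> None:
        if self.comparator not in ("<", ">"):
            raise ValueError("comparator must be '<' or '>'")

    def triggered(self, value: float) -> bool:
        # strict comparison: boundary values never flag
        if self.comparator == "<":
            return value < self.threshold
        return value > self.threshold


@dataclass
class FlagReport:
    subject_id: str
    conventional_flags: list[str]
    mds_flag: bool | None

    @property
    def smear_triggered_conventional(self) -> bool:
        return bool(self.conventional_flags)

    @property
    def smear_triggered_mdsls(self) -> bool:
        return bool(self.mds_flag) or self.smear_triggered_conventional


_DEFAULT_RULES: list[tuple[str, str, float]] = [
    ("Hb", "<", 80.0),
    ("MCV", ">", 105.0),
    ("MCHC", ">", 36.0),
    ("RDW", ">", 22.0),
    ("Plt", "<", 100.0),
    ("MPV", "<", 7.0),
    ("% MO", ">", 20.0),
    ("Abs NE", "<", 1.5),
    ("Abs LY", ">", 4.0),
    ("Abs MO", ">", 1.5),
    ("Abs EO", ">", 1.5),
    ("Abs BA", ">", 0.3),
    ("% NRBC", ">", 2.0),
]


def default_flag_rules() -> list[FlagRule]:
    """The 13 pre-configured CBC review thresholds."""
    return [FlagRule(name, cmp_, thr, f"{name}{cmp_}{thr:g}")
            for name, cmp_, thr in _DEFAULT_RULES]


def apply_flags(record: pd.Series | dict, rules: list[FlagRule],
                score: "ScoreResult | float | None" = None) -> FlagReport:
    """Evaluate every rule on one record; the MDS-LS flag uses ``score``
    when supplied (negative score, or exactly zero, flags)."""
    if isinstance(record, dict):
        record = pd.Series(record)
    triggered = []
    for rule in rules:
        if rule.parameter_name not in record.index or pd.isna(
                record[rule.parameter_name]):
            raise ValueError(f"missing flagged parameter "
                             f"{rule.parameter_name!r}")
        if rule.triggered(float(record[rule.parameter_name])):
            triggered.append(rule.flag_label)
    mds_flag: bool | None = None
    if score is not None:
        value = score.mds_ls if isinstance(score, ScoreResult) else float(score)
        mds_flag = value <= 0
    return FlagReport(subject_id=str(record.get("subject_id", "")),
                      conventional_flags=triggered, mds_flag=mds_flag)


def cohort_flag_summary(reports: list[FlagReport]) -> dict[str, int]:
    """Tallies of subjects each flagging system would send to smear."""
    conventional = sum(r.smear_triggered_conventional for r in reports)
    mdsls = sum(bool(r.mds_flag) for r in reports)
    only_mdsls = sum(bool(r.mds_flag) and not r.smear_triggered_conventional
                     for r in reports)
    either = sum(r.smear_triggered_mdsls for r in reports)
    return {
        "n": len(reports),
        "conventional_triggered": conventional,
        "mdsls_triggered": mdsls,
        "mdsls_only": only_mdsls,
        "either_triggered": either,
    }


def reports_to_frame(reports: list[FlagReport]) -> pd.DataFrame:
    return pd.DataFrame({
        "subject_id": [r.subject_id for r in reports],
        "conventional_flags": [";".join(r.conventional_flags)
                               for r in reports],
        "smear_conventional": [r.smear_triggered_conventional
                               for r in reports],
        "mds_flag": [r.mds_flag for r in reports],
        "smear_mdsls": [r.smear_triggered_mdsls for r in reports],
    })


def load_undetected_patients() -> pd.DataFrame:
    """The 11 published MDS patients whose CBC raised no conventional flag.

    One row per patient: the conventional CBC panel plus the published
    MDS-LS value (all negative).
    """
    with resources.files("mdsls.data").joinpath(
            "table1_undetected_patients.csv").open() as fh:
        return pd.read_csv(fh)
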
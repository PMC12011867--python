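"""Shared object factories for the test suite."""

from __future__ import annotations

from typing import Optional, Sequence

from pvsignal.cohort import CaseReport
from pvsignal.faers_io import DemoRecord, DrugRecord, ParsedDate, parse_date


def make_demo(primaryid: int,
              caseid: Optional[int] = None,
              fda: str = "20230310",
              event: str = "",
              age: Optional[float] = None,
              age_unit: str = "YR",
              weight: Optional[float] = None,
              weight_unit: str = "KG",
              sex: str = "F",
              country: str = "US",
              occupation: str = "MD") -> DemoRecord:
    return DemoRecord(
        primaryid=primaryid,
        caseid=caseid if caseid is not None else primaryid,
        fda_dt=parse_date(fda),
        event_dt=parse_date(event),
        age_value=age,
        age_unit=age_unit,
        weight_value=weight,
        weight_unit=weight_unit,
        sex=sex,
        country=country,
        occupation=occupation,
    )


def make_report(primaryid: int,
                pts: Sequence[str],
                drugs: Sequence[tuple[str, str, Optional[str]]] = (
                    ("pembrolizumab", "PS", "cervix carcinoma"),),
                therapy_start: str = "",
                **demo_kw) -> CaseReport:
    """A CaseReport with normalized, unique reactions.

    ``drugs`` entries are (name, role, indication_pt).
    """
    drug_records = [
        DrugRecord(primaryid=primaryid, drug_seq=i + 1, drugname=name,
                   role_cod=role, indication_pt=indication)
        for i, (name, role, indication) in enumerate(drugs)
    ]
    therapy: dict[int, ParsedDate] = {}
    if therapy_start:
        therapy[1] = parse_date(therapy_start)
    report = CaseReport(
        primaryid=primaryid,
        demographics=make_demo(primaryid, **demo_kw),
        drugs=drug_records,
        reactions=sorted(set(pts)),
        therapy_starts=therapy,
    )
    report.off_label_flag = "product use in unapproved indication" in report.reactions
    return report
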
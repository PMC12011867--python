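"""Cohort selection and MedDRA PT/SOC normalization.

A *cohort* report carries the target drug in a qualifying reporter role
(default: primary suspect only) together with a qualifying indication PT;
everything else in the cleaned database forms the comparator background.
Event terms are normalized to current MedDRA preferred terms via a
user-supplied mapping; the package bundles a small synthetic dictionary
(the real MedDRA dictionary is licensed and cannot be redistributed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Optional, Sequence

from .dedup import DedupResult
from .faers_io import (
    DemoRecord,
    DrugRecord,
    ParsedDate,
    ParseWarnings,
    RawQuarter,
    demo_records,
    drug_records,
    outc_records,
    reac_records,
    ther_records,
)

DEFAULT_DRUG_NAMES = ("pembrolizumab",)
DEFAULT_INDICATION_PTS = ("cervix carcinoma", "cervical cancer",
                          "cervix carcinoma recurrent")
OFF_LABEL_PT = "product use in unapproved indication"


@dataclass(frozen=True)
class CohortSpec:
    """Declarative definition of the analysis cohort.

    ``drug_names`` match case-insensitively; exact token match by default,
    substring match when ``substring_match`` is set (FAERS drugname free text
    is noisy, exact matching keeps the cohort auditable).  An empty
    ``indication_pts`` disables indication filtering.
    """

    drug_names: tuple[str, ...] = DEFAULT_DRUG_NAMES
    role_codes: frozenset[str] = frozenset({"PS"})
    indication_pts: tuple[str, ...] = DEFAULT_INDICATION_PTS
    substring_match: bool = False

    def __post_init__(self) -> None:
        if not self.role_codes:
            raise ValueError("role_codes must be non-empty")

    def drug_matches(self, drugname: str) -> bool:
        name = " ".join(drugname.casefold().split())
        for pattern in self.drug_names:
            pattern = pattern.casefold()
            if (pattern in name) if self.substring_match else (pattern == name):
                return True
        return False


class MeddraMap:
    """PT normalization (synonym -> canonical PT) and PT -> SOC lookup."""

    def __init__(self, pt_to_soc: dict[str, str],
                 pt_normalization: Optional[dict[str, str]] = None,
                 version_label: str = "unversioned") -> None:
        self.pt_to_soc = {k.casefold(): v for k, v in pt_to_soc.items()}
        self.pt_normalization = {
            k.casefold(): v.casefold()
            for k, v in (pt_normalization or {}).items()
        }
        self.version_label = version_label
        missing = [v for v in self.pt_normalization.values()
                   if v not in self.pt_to_soc]
        if missing:
            raise ValueError(
                f"synonym targets missing from PT->SOC map: {sorted(set(missing))}")

    def soc_of(self, pt: str) -> Optional[str]:
        return self.pt_to_soc.get(pt.casefold())

    @classmethod
    def from_files(cls, pt_soc_path: str,
                   synonyms_path: Optional[str] = None,
                   version_label: str = "user") -> "MeddraMap":
        pt_to_soc = _read_two_column(pt_soc_path)
        synonyms = _read_two_column(synonyms_path) if synonyms_path else {}
        return cls(pt_to_soc, synonyms, version_label)

    @classmethod
    def bundled(cls) -> "MeddraMap":
        """The synthetic mini-dictionary shipped with the package."""
        base = resources.files("pvsignal") / "data"
        pt_to_soc = _parse_two_column(
            (base / "meddra_synthetic.tsv").read_text(encoding="utf-8"))
        synonyms = _parse_two_column(
            (base / "pt_synonyms.tsv").read_text(encoding="utf-8"))
        return cls(pt_to_soc, synonyms, version_label="synthetic-mini")


def _parse_two_column(text: str) -> dict[str, str]:
    out: dict[str, str] = {}
    lines = [ln for ln in text.splitlines() if ln.strip()]
    for line in lines[1:]:  # first line is the header
        left, _, right = line.partition("\t")
        out[left.strip()] = right.strip()
    return out


def _read_two_column(path: str) -> dict[str, str]:
    with open(path, encoding="utf-8") as fh:
        return _parse_two_column(fh.read())


def normalize_pt(raw_pt: str, meddra: MeddraMap,
                 warnings: Optional[ParseWarnings] = None) -> str:
    """Case-fold, collapse whitespace, and map synonyms to the current PT.

    Terms absent from the dictionary pass through unchanged (with a counted
    warning) rather than being dropped: unmapped verbatim terms still count
    toward disproportionality.
    """
    pt = " ".join(raw_pt.casefold().split())
    pt = meddra.pt_normalization.get(pt, pt)
    if pt not in meddra.pt_to_soc and warnings is not None:
        warnings.add("unmapped_pt")
    return pt


@dataclass
class CaseReport:
    """One deduplicated safety report with normalized reactions."""

    primaryid: int
    demographics: DemoRecord
    drugs: list[DrugRecord] = field(default_factory=list)
    reactions: list[str] = field(default_factory=list)  # unique, sorted
    outcomes: list[str] = field(default_factory=list)
    therapy_starts: dict[int, ParsedDate] = field(default_factory=dict)
    in_cohort: bool = False
    off_label_flag: bool = False

    @property
    def caseid(self) -> int:
        return self.demographics.caseid


def assemble_reports(quarters: Iterable[RawQuarter],
                     dedup: DedupResult,
                     meddra: MeddraMap,
                     warnings: Optional[ParseWarnings] = None) -> list[CaseReport]:
    """Join DEMO/DRUG/REAC/OUTC/THER rows into CaseReports for kept reports.

    Reactions are normalized and de-duplicated within each report (the
    counting unit downstream is the report, not the PT occurrence).
    """
    quarters = list(quarters)
    warnings = warnings if warnings is not None else ParseWarnings()
    kept = set(dedup.kept)
    demo_by_id = {r.primaryid: r for r in demo_records(quarters, warnings)}

    reports: dict[int, CaseReport] = {}
    for pid in dedup.kept:
        demo = demo_by_id.get(pid)
        if demo is None:
            warnings.add("kept_without_demo")
            continue
        reports[pid] = CaseReport(primaryid=pid, demographics=demo)

    for drug in drug_records(quarters, warnings):
        if drug.primaryid in reports:
            reports[drug.primaryid].drugs.append(drug)
    reaction_sets: dict[int, set[str]] = {pid: set() for pid in reports}
    for reac in reac_records(quarters, warnings):
        if reac.primaryid in kept and reac.primaryid in reports:
            reaction_sets[reac.primaryid].add(normalize_pt(reac.pt, meddra, warnings))
    for pid, pts in reaction_sets.items():
        reports[pid].reactions = sorted(pts)
    for outc in outc_records(quarters, warnings):
        if outc.primaryid in reports:
            reports[outc.primaryid].outcomes.append(outc.outcome_code)
    for ther in ther_records(quarters, warnings):
        if ther.primaryid in reports:
            existing = reports[ther.primaryid].therapy_starts.get(ther.drug_seq)
            if existing is None or (
                ther.start_dt.is_full
                and (not existing.is_full or ther.start_dt.value < existing.value)
            ):
                reports[ther.primaryid].therapy_starts[ther.drug_seq] = ther.start_dt
    for report in reports.values():
        report.off_label_flag = flag_off_label(report)
    return [reports[pid] for pid in sorted(reports)]


def _matches_spec(report: CaseReport, spec: CohortSpec, meddra: MeddraMap) -> bool:
    name_role = any(
        spec.drug_matches(d.drugname) and d.role_cod in spec.role_codes
        for d in report.drugs
    )
    if not name_role:
        return False
    if not spec.indication_pts:
        return True
    wanted = {normalize_pt(pt, meddra) for pt in spec.indication_pts}
    # the indication filter is applied at report level: any drug row's
    # indication PT qualifies the whole report
    return any(
        d.indication_pt and normalize_pt(d.indication_pt, meddra) in wanted
        for d in report.drugs
    )


def select_cohort(reports: Sequence[CaseReport], spec: CohortSpec,
                  meddra: Optional[MeddraMap] = None
                  ) -> tuple[list[CaseReport], list[CaseReport]]:
    """Partition deduplicated reports into (cohort, background)."""
    meddra = meddra or MeddraMap.bundled()
    cohort: list[CaseReport] = []
    background: list[CaseReport] = []
    for report in reports:
        if _matches_spec(report, spec, meddra):
            report.in_cohort = True
            cohort.append(report)
        else:
            report.in_cohort = False
            background.append(report)
    return cohort, background


def flag_off_label(report: CaseReport) -> bool:
    """Off-label use, operationalized as the dedicated reaction PT.

    Spontaneous reports carry no structured off-label field; the MedDRA term
    'product use in unapproved indication' is the only derivable marker.
    """
    return OFF_LABEL_PT in report.reactions
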
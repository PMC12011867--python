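"""FDA two-step case deduplication.

FAERS case reports are versioned: successive submissions of the same case
share a CASEID but carry distinct PRIMARYIDs.  Step one keeps, within each
CASEID, the version with the latest FDA receipt date (ties broken by the
largest PRIMARYID).  Step two removes cases named on the quarterly deletion
lists, pooled across all loaded quarters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .faers_io import DemoRecord


class IntegrityError(ValueError):
    """The report key (primaryid) is not unique across DEMO rows."""


@dataclass
class DedupResult:
    kept: list[int]
    dropped_duplicates: int
    dropped_deleted: int
    input_count: int
    # per caseid: (kept primaryid, [dropped primaryids])
    audit: dict[int, tuple[int, list[int]]] = field(default_factory=dict)
    _caseid_of: dict[int, int] = field(default_factory=dict, repr=False)
    _fda_dt_of: dict[int, int] = field(default_factory=dict, repr=False)

    def check_conservation(self) -> bool:
        return self.dropped_duplicates + self.dropped_deleted + len(self.kept) \
            == self.input_count

    def audit_table(self) -> pd.DataFrame:
        """Audit trail with one row per input report: Keep or Delete."""
        rows = []
        kept_set = set(self.kept)
        for caseid, (keeper, dropped) in sorted(self.audit.items()):
            for pid in sorted(dropped + [keeper]):
                op = "Keep" if pid == keeper and pid in kept_set else "Delete"
                rows.append({
                    "Primaryid": pid,
                    "Caseid": caseid,
                    "FDA_DT": self._fda_dt_of.get(pid, ""),
                    "Operation": op,
                })
        return pd.DataFrame(rows, columns=["Primaryid", "Caseid", "FDA_DT", "Operation"])


def deduplicate(demo: Sequence[DemoRecord]) -> DedupResult:
    """Keep one report per CASEID: max FDA_DT, ties by max PRIMARYID."""
    seen: set[int] = set()
    for rec in demo:
        if rec.primaryid in seen:
            raise IntegrityError(f"duplicate primaryid {rec.primaryid} in DEMO")
        seen.add(rec.primaryid)

    groups: dict[int, list[DemoRecord]] = {}
    for rec in demo:
        groups.setdefault(rec.caseid, []).append(rec)

    kept: list[int] = []
    audit: dict[int, tuple[int, list[int]]] = {}
    caseid_of: dict[int, int] = {}
    fda_dt_of: dict[int, int] = {}
    dropped = 0
    for caseid, members in groups.items():
        keeper = max(members, key=lambda r: (r.fda_dt.value, r.primaryid))
        kept.append(keeper.primaryid)
        losers = [r.primaryid for r in members if r.primaryid != keeper.primaryid]
        dropped += len(losers)
        audit[caseid] = (keeper.primaryid, losers)
        for r in members:
            caseid_of[r.primaryid] = caseid
            fda_dt_of[r.primaryid] = int(r.fda_dt.raw or 0)
    kept.sort()
    return DedupResult(
        kept=kept,
        dropped_duplicates=dropped,
        dropped_deleted=0,
        input_count=len(demo),
        audit=audit,
        _caseid_of=caseid_of,
        _fda_dt_of=fda_dt_of,
    )


def apply_deletion_lists(result: DedupResult,
                         deleted_caseids: Iterable[int]) -> DedupResult:
    """Drop kept reports whose CASEID appears on any quarterly deletion list.

    Unknown caseids (never seen, or already gone as duplicates) are no-ops.
    """
    deleted = set(deleted_caseids)
    kept: list[int] = []
    n_deleted = result.dropped_deleted
    for pid in result.kept:
        if result._caseid_of.get(pid) in deleted:
            n_deleted += 1
        else:
            kept.append(pid)
    return DedupResult(
        kept=kept,
        dropped_duplicates=result.dropped_duplicates,
        dropped_deleted=n_deleted,
        input_count=result.input_count,
        audit=result.audit,
        _caseid_of=result._caseid_of,
        _fda_dt_of=result._fda_dt_of,
    )
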
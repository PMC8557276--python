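"""7-day mortality association: contingency rows and relative risk.

For each phrase group, the number of unique matched inpatients and the
number whose recorded death date falls within 7 days after one of
their *matched* documents; the percentage and the relative risk against
the no-phrase control cohort are derived from the unrounded absolute
counts.  Small death counts can be display-suppressed ("<10") without
touching the underlying numerics.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from datetime import date

from .cohort import CorpusIndex, MatchResult
from .synth import PatientRecord

__all__ = [
    "ContingencyRow",
    "AssociationTable",
    "died_within_window",
    "mortality_counts",
    "percentage",
    "relative_risk",
    "suppress_small_counts",
    "build_association_table",
    "table_from_counts",
    "write_association_csv",
    "write_association_markdown",
]

DEFAULT_WINDOW_DAYS = 7


def died_within_window(doc_date: date, death_date: date | None,
                       window_days: int = DEFAULT_WINDOW_DAYS) -> bool:
    """True iff ``0 <= death_date - doc_date <= window_days`` whole days.

    Inclusive on both ends: death on the document day counts, death
    ``window_days`` after counts, death before the document never does.
    Absent death date is False.
    """
    if death_date is None:
        return False
    delta = (death_date - doc_date).days
    return 0 <= delta <= window_days


def mortality_counts(match: MatchResult, patients: list[PatientRecord],
                     index: CorpusIndex,
                     window_days: int = DEFAULT_WINDOW_DAYS) -> tuple[int, int]:
    """``(n_patients, n_deaths)`` for one matched group.

    A matched patient counts as a 7-day death iff at least one of their
    *matched* documents precedes the death by at most the window; an
    in-window death relative to an unmatched document does not count.
    """
    death_of = {p.patient_id: p.death_date for p in patients}
    deaths = 0
    docs_of_patient: dict[str, list[date]] = {}
    for doc_id in match.matched_doc_ids:
        d = index.doc_by_id[doc_id]
        docs_of_patient.setdefault(d.patient_id, []).append(d.doc_date)
    for pid in match.matched_patient_ids:
        dd = death_of.get(pid)
        if dd is None:
            continue
        if any(died_within_window(doc_date, dd, window_days)
               for doc_date in docs_of_patient.get(pid, [])):
            deaths += 1
    return len(match.matched_patient_ids), deaths


def percentage(d: int, n: int) -> float:
    """100 * d / n (raw; display is rounded to 1 dp)."""
    if n <= 0:
        raise ValueError("percentage undefined for n = 0")
    return 100.0 * d / n


def relative_risk(d_g: int, n_g: int, d_c: int, n_c: int) -> float:
    """(d_g/n_g) / (d_c/n_c) computed on unrounded rates.

    Display is rounded to 2 dp.  Undefined (raises) when the control
    has zero deaths.
    """
    if n_g <= 0 or n_c <= 0:
        raise ValueError("relative risk undefined for an empty group or control")
    if d_c <= 0:
        raise ValueError("relative risk undefined when the control has zero deaths")
    return (d_g / n_g) / (d_c / n_c)


@dataclass
class ContingencyRow:
    group_label: str
    n_patients: int
    n_deaths_7d: int | None            # None when unknown (suppressed source)
    pct_mortality: float | None = None
    relative_risk: float | None = None
    suppressed: bool = False
    undefined: bool = False            # empty group: no % or RR

    def display(self, floor: int = 10) -> dict[str, str]:
        """Render with small-count suppression; numerics untouched."""
        d = self.n_deaths_7d
        if d is None:
            deaths = f"<{floor}"
        elif 0 < d < floor and self.suppressed:
            deaths = f"<{floor}"
        else:
            deaths = str(d)
        return {
            "group": self.group_label,
            "n_patients": str(self.n_patients),
            "n_deaths_7d": deaths,
            "pct_mortality": ("" if self.pct_mortality is None
                              else f"{self.pct_mortality:.1f}"),
            "relative_risk": ("" if self.relative_risk is None
                              else f"{self.relative_risk:.2f}"),
        }


def suppress_small_counts(row: ContingencyRow, floor: int = 10) -> ContingencyRow:
    """Flag counts in (0, floor) for '<floor' display."""
    if floor < 1:
        raise ValueError("floor must be >= 1")
    d = row.n_deaths_7d
    row.suppressed = d is not None and 0 < d < floor
    return row


@dataclass
class AssociationTable:
    rows: list[ContingencyRow]
    control: ContingencyRow

    def all_rows(self) -> list[ContingencyRow]:
        return self.rows + [self.control]


def _make_row(label: str, n: int, d: int | None, d_c: int, n_c: int) -> ContingencyRow:
    if n == 0 or d is None:
        return ContingencyRow(label, n, d, undefined=(n == 0))
    return ContingencyRow(
        label, n, d,
        pct_mortality=percentage(d, n),
        relative_risk=relative_risk(d, n, d_c, n_c),
    )


def build_association_table(matches: list[MatchResult], control_ids: set[str],
                            patients: list[PatientRecord], index: CorpusIndex,
                            window_days: int = DEFAULT_WINDOW_DAYS,
                            date_start: date | None = None,
                            date_end: date | None = None) -> AssociationTable:
    """One contingency row per group plus the control row (RR = 1).

    Control deaths are counted symmetrically to the groups: a control
    patient is a 7-day death if any of their in-range documents
    precedes the death by at most the window (none of their documents
    matched, so all are eligible).  Overlapping groups both count their
    shared patients; no exclusivity is imposed.
    """
    if not control_ids:
        raise ValueError("control cohort is empty")
    death_of = {p.patient_id: p.death_date for p in patients}
    control_deaths = 0
    docs_of: dict[str, list[date]] = {}
    for doc in index.documents:
        if date_start is not None and not (date_start <= doc.doc_date <= date_end):
            continue
        if doc.patient_id in control_ids:
            docs_of.setdefault(doc.patient_id, []).append(doc.doc_date)
    for pid in control_ids:
        dd = death_of.get(pid)
        if dd is not None and any(
            died_within_window(dt, dd, window_days) for dt in docs_of.get(pid, [])
        ):
            control_deaths += 1
    n_c, d_c = len(control_ids), control_deaths

    rows = []
    for m in matches:
        n_g, d_g = mortality_counts(m, patients, index, window_days)
        if n_g == 0:
            rows.append(ContingencyRow(m.group_label, 0, 0, undefined=True))
        elif d_c == 0:
            rows.append(ContingencyRow(m.group_label, n_g, d_g,
                                       pct_mortality=percentage(d_g, n_g)))
        else:
            rows.append(_make_row(m.group_label, n_g, d_g, d_c, n_c))
    control = ContingencyRow("control", n_c, d_c,
                             pct_mortality=percentage(d_c, n_c) if n_c else None,
                             relative_risk=1.0 if d_c else None)
    return AssociationTable(rows, control)


def table_from_counts(counts: list[tuple[str, int, int | None]],
                      control: tuple[str, int, int]) -> AssociationTable:
    """Association table directly from (label, n, deaths) counts.

    ``deaths=None`` marks a source-suppressed cell: the row is carried
    with its n but no % or RR is derived.  This is the table-only path:
    published aggregate counts reproduce their printed percentages and
    relative risks without any corpus.
    """
    c_label, n_c, d_c = control
    rows = [_make_row(label, n, d, d_c, n_c) for label, n, d in counts]
    ctrl = ContingencyRow(c_label, n_c, d_c,
                          pct_mortality=percentage(d_c, n_c),
                          relative_risk=1.0)
    return AssociationTable(rows, ctrl)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

_COLUMNS = ["group", "n_patients", "n_deaths_7d", "pct_mortality", "relative_risk"]


def write_association_csv(table: AssociationTable, path: str, floor: int = 10) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=_COLUMNS)
        w.writeheader()
        for row in table.all_rows():
            w.writerow(suppress_small_counts(row, floor).display(floor))


def write_association_markdown(table: AssociationTable, path: str,
                               floor: int = 10) -> None:
    header = ("| Phrase group | Inpatients with phrase | Deaths within 7 days "
              "| % | Relative risk vs control |")
    lines = [header, "|---|---|---|---|---|"]
    for row in table.all_rows():
        disp = suppress_small_counts(row, floor).display(floor)
        lines.append("| " + " | ".join(disp[c] for c in _COLUMNS) + " |")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
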
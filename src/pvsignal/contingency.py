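"""2x2 contingency tables per adverse event for the target drug vs all others.

The counting unit is the distinct (report, event) pair: a report listing
the same Preferred Term twice contributes one unit, and at System Organ
Class level a report counts once per distinct SOC.  For each event e the
table is

    a = units with e among cohort reports        b = cohort units - a
    c = units with e among non-cohort reports    d = non-cohort units - c

so N = a+b+c+d equals the corpus-wide unit total for every event at a
given level.  A report-based comparator (b, d counted over reports
rather than units) is available via ``unit="reports"`` for sensitivity
analysis.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

from pvsignal.faers_io import MedDRAMap, QuarterBundle

logger = logging.getLogger(__name__)

UNMAPPED = "UNMAPPED"


@dataclass(frozen=True)
class ContingencyTable:
    """Cell counts for one drug-event pair."""

    event_label: str
    level: str  # "PT" or "SOC"
    a: int
    b: int
    c: int
    d: int

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def swapped(self) -> "ContingencyTable":
        """Exchange cohort and comparator rows."""
        return ContingencyTable(self.event_label, self.level, self.c, self.d, self.a, self.b)


@dataclass
class EventUnits:
    """Distinct (report, event) pairs plus per-report unit counts."""

    level: str
    pairs: set[tuple[str, str]]
    display: dict[str, str]  # normalized event -> display label

    def units_per_report(self) -> Counter:
        out: Counter = Counter()
        for pid, _ in self.pairs:
            out[pid] += 1
        return out


def _normalize(label: str) -> str:
    return " ".join(label.split()).casefold()


def build_event_units(
    bundle: QuarterBundle,
    level: str = "PT",
    meddra_map: MedDRAMap | None = None,
) -> EventUnits:
    """Collect distinct (report, event) pairs at PT or SOC level.

    At SOC level every PT is resolved through ``meddra_map``; PTs absent
    from the map fall into an explicit ``UNMAPPED`` bucket (counted and
    logged) rather than being dropped silently.
    """
    level = level.upper()
    if level not in ("PT", "SOC"):
        raise ValueError(f"level must be PT or SOC, got {level!r}")
    if level == "SOC" and meddra_map is None:
        raise ValueError("SOC level requires a MedDRA map")

    pairs: set[tuple[str, str]] = set()
    display: dict[str, str] = {}
    unmapped: Counter = Counter()
    for rec in bundle.reac:
        pt = rec.pt.strip()
        if not pt:
            continue
        if level == "PT":
            key = _normalize(pt)
            display.setdefault(key, pt)
        else:
            soc = meddra_map.soc_of(pt)  # type: ignore[union-attr]
            if soc is None:
                unmapped[pt] += 1
                soc = UNMAPPED
            key = _normalize(soc)
            display.setdefault(key, soc)
        pairs.add((rec.primaryid, key))
    if unmapped:
        logger.warning(
            "%d REAC rows over %d PTs had no SOC mapping; bucketed as %s",
            sum(unmapped.values()), len(unmapped), UNMAPPED,
        )
    return EventUnits(level=level, pairs=pairs, display=display)


def build_tables(
    units: EventUnits,
    cohort_ids: set[str],
    all_report_ids: set[str] | None = None,
    unit: str = "pairs",
) -> list[ContingencyTable]:
    """One 2x2 table per distinct event.

    ``unit="pairs"`` (default): margins b, d are unit totals, keeping N
    constant across events.  ``unit="reports"``: b, d count reports
    without the event, giving the report-level odds ratio.  Events never
    seen in the cohort (a = 0) are retained and flagged downstream as
    non-computable rather than dropped.
    """
    if unit not in ("pairs", "reports"):
        raise ValueError(f"unit must be 'pairs' or 'reports', got {unit!r}")

    a_counts: Counter = Counter()
    c_counts: Counter = Counter()
    for pid, event in units.pairs:
        if pid in cohort_ids:
            a_counts[event] += 1
        else:
            c_counts[event] += 1

    if unit == "pairs":
        total_cohort = sum(a_counts.values())
        total_other = sum(c_counts.values())
    else:
        if all_report_ids is None:
            all_report_ids = {pid for pid, _ in units.pairs} | cohort_ids
        total_cohort = len(cohort_ids & all_report_ids)
        total_other = len(all_report_ids - cohort_ids)

    events = sorted(set(a_counts) | set(c_counts))
    tables = []
    for event in events:
        a = a_counts[event]
        c = c_counts[event]
        tables.append(
            ContingencyTable(
                event_label=units.display.get(event, event),
                level=units.level,
                a=a,
                b=total_cohort - a,
                c=c,
                d=total_other - c,
            )
        )
    return tables


def tables_to_rows(tables: list[ContingencyTable]) -> list[tuple[str, str, int, int, int, int]]:
    """Flatten tables for TSV output: (event_label, level, a, b, c, d)."""
    return [(t.event_label, t.level, t.a, t.b, t.c, t.d) for t in tables]


__all__ = [
    "UNMAPPED",
    "ContingencyTable",
    "EventUnits",
    "build_event_units",
    "build_tables",
    "tables_to_rows",
]
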
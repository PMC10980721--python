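"""Target-drug cohort selection and descriptive constituent-ratio summaries.

A report enters the cohort when at least one of its drug rows has a
qualifying role (by default the primary suspect, PS) and a drug name or
active ingredient containing the target keyword (case-insensitive
substring).  The descriptive summary tabulates, per category, the number
of cohort reports and the constituent ratio — count over cohort size,
in percent, rounded half-up to two decimals.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

from pvsignal.faers_io import (
    OUTCOME_DISPLAY,
    REPORTER_DISPLAY,
    DemoRecord,
    DrugRecord,
    QuarterBundle,
    TherRecord,
)

logger = logging.getLogger(__name__)

UNKNOWN = "Unknown"

#: Age bins in years, left-closed right-open; the final bin is unbounded.
AGE_BINS: list[tuple[float, float, str]] = [
    (0.0, 18.0, "<18"),
    (18.0, 45.0, "18-45"),
    (45.0, 65.0, "45-65"),
    (65.0, 75.0, "65-75"),
    (75.0, float("inf"), ">=75"),
]

#: Time-to-onset bins in days (inclusive bounds; final bin unbounded).
TTO_BINS: list[tuple[int, int, str]] = [
    (0, 30, "0-30"),
    (31, 60, "31-60"),
    (61, 90, "61-90"),
    (91, 120, "91-120"),
    (121, 150, "121-150"),
    (151, 180, "151-180"),
    (181, 360, "181-360"),
    (361, 10**9, ">360"),
]

SEX_DISPLAY = {"F": "Female", "M": "Male"}


def constituent_ratio(count: int, denominator: int) -> float:
    """Percentage ``100*count/denominator`` rounded half-up to 2 decimals."""
    if denominator == 0:
        return 0.0
    pct = Decimal(100) * Decimal(count) / Decimal(denominator)
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class CohortSpec:
    """How to recognise the target drug on a report."""

    drug_keyword: str = "alprazolam"
    match_fields: frozenset[str] = frozenset({"drugname", "prod_ai"})
    roles: frozenset[str] = frozenset({"PS"})

    def __post_init__(self) -> None:
        if not self.match_fields:
            raise ValueError("at least one match field required")
        if not self.roles:
            raise ValueError("at least one role required")
        bad = self.match_fields - {"drugname", "prod_ai"}
        if bad:
            raise ValueError(f"unknown match fields: {sorted(bad)}")

    def matches(self, drug: DrugRecord) -> bool:
        if drug.role_cod not in self.roles:
            return False
        key = self.drug_keyword.strip().casefold()
        for fname in self.match_fields:
            value = drug.drugname if fname == "drugname" else drug.prod_ai
            if value is not None and key in value.strip().casefold():
                return True
        return False


def select_cohort(bundle: QuarterBundle, spec: CohortSpec | None = None) -> set[str]:
    """Primaryids of reports with >= 1 drug row matching the cohort spec."""
    spec = spec or CohortSpec()
    cohort = {d.primaryid for d in bundle.drug if spec.matches(d)}
    demo_ids = {r.primaryid for r in bundle.demo}
    cohort &= demo_ids
    if not cohort:
        logger.warning("cohort for keyword %r is empty", spec.drug_keyword)
    return cohort


def age_bin(age_years: float | None) -> str:
    """Map an age in years to its bin label; missing or negative -> Unknown."""
    if age_years is None:
        return UNKNOWN
    if age_years < 0:
        logger.warning("negative age %.6g binned as Unknown", age_years)
        return UNKNOWN
    for lo, hi, label in AGE_BINS:
        if lo <= age_years < hi:
            return label
    return UNKNOWN  # pragma: no cover - bins cover [0, inf)


def tto_bin(days: int) -> str:
    """Map a non-negative day count to its time-to-onset bin label."""
    for lo, hi, label in TTO_BINS:
        if lo <= days <= hi:
            return label
    raise ValueError(f"day count {days} outside supported range")


def time_to_onset_days(
    demo: DemoRecord,
    drugs: list[DrugRecord],
    thers: list[TherRecord],
    spec: CohortSpec | None = None,
) -> int | None:
    """Days from the earliest matched-drug therapy start to event onset.

    Both dates must be full ``YYYYMMDD`` values; partial or missing dates
    yield ``None``, as does a negative difference (therapy starting after
    the event), which is logged.
    """
    spec = spec or CohortSpec()
    event = demo.event_dt
    if event is None:
        return None
    matched_seqs = {d.drug_seq for d in drugs if d.primaryid == demo.primaryid and spec.matches(d)}
    starts = [
        t.start_dt
        for t in thers
        if t.primaryid == demo.primaryid and t.dsg_drug_seq in matched_seqs and t.start_dt is not None
    ]
    if not starts:
        return None
    delta = (event - min(starts)).days
    if delta < 0:
        logger.warning("report %s: therapy start after event onset; onset time dropped", demo.primaryid)
        return None
    return delta


@dataclass
class DescriptiveSummary:
    """Category counts and constituent ratios for one cohort.

    Every category dict maps label -> count; ``ratio`` converts to the
    percentage of the cohort denominator.  Outcome categories count
    reports with multiplicity across codes, so they need not sum to the
    denominator; gender and year partitions do.
    """

    denominator: int
    gender: dict[str, int] = field(default_factory=dict)
    age: dict[str, int] = field(default_factory=dict)
    reporter: dict[str, int] = field(default_factory=dict)
    country: dict[str, int] = field(default_factory=dict)
    year: dict[str, int] = field(default_factory=dict)
    outcomes: dict[str, int] = field(default_factory=dict)
    time_to_onset: dict[str, int] = field(default_factory=dict)

    def ratio(self, count: int) -> float:
        return constituent_ratio(count, self.denominator)

    def sections(self) -> list[tuple[str, dict[str, int]]]:
        return [
            ("Gender", self.gender),
            ("Age", self.age),
            ("Reporter", self.reporter),
            ("Reported countries", self.country),
            ("Report year", self.year),
            ("Serious outcomes", self.outcomes),
            ("Time to onset (days)", self.time_to_onset),
        ]

    def to_rows(self) -> list[tuple[str, str, int, float]]:
        """Flatten to (section, label, count, percent) rows."""
        rows = []
        for section, counts in self.sections():
            for label, count in counts.items():
                rows.append((section, label, count, self.ratio(count)))
        return rows


def _order(counts: Counter, preferred: list[str]) -> dict[str, int]:
    """Order categories: preferred labels first, then by count desc, Unknown last."""
    ordered: dict[str, int] = {}
    for label in preferred:
        if label in counts:
            ordered[label] = counts[label]
    rest = sorted(
        (lbl for lbl in counts if lbl not in ordered and lbl != UNKNOWN),
        key=lambda lbl: (-counts[lbl], lbl),
    )
    for lbl in rest:
        ordered[lbl] = counts[lbl]
    if UNKNOWN in counts:
        ordered[UNKNOWN] = counts[UNKNOWN]
    return ordered


def summarize_cohort(
    bundle: QuarterBundle,
    cohort_ids: set[str],
    spec: CohortSpec | None = None,
) -> DescriptiveSummary:
    """Tabulate cohort demographics, outcomes and onset times.

    Each report contributes once per category dimension (outcomes with
    multiplicity across distinct codes).  Report year comes from the FDA
    receive date of the kept report version; onset times with partial or
    missing dates are excluded, and the excluded fraction is logged.
    """
    spec = spec or CohortSpec()
    demo = [r for r in bundle.demo if r.primaryid in cohort_ids]
    denom = len(demo)

    gender: Counter = Counter()
    age: Counter = Counter()
    reporter: Counter = Counter()
    country: Counter = Counter()
    year: Counter = Counter()
    for rec in demo:
        gender[SEX_DISPLAY.get((rec.sex or "").upper(), UNKNOWN)] += 1
        age[age_bin(rec.age_years())] += 1
        reporter[REPORTER_DISPLAY.get((rec.occp_cod or "").upper(), UNKNOWN)] += 1
        country[rec.occr_country or UNKNOWN] += 1
        fda = rec.fda_dt_raw
        year[fda[:4] if fda and len(fda) >= 4 else UNKNOWN] += 1

    outcomes: Counter = Counter()
    seen_outc: set[tuple[str, str]] = set()
    for rec in bundle.outc:
        if rec.primaryid in cohort_ids and (rec.primaryid, rec.outc_cod) not in seen_outc:
            seen_outc.add((rec.primaryid, rec.outc_cod))
            outcomes[OUTCOME_DISPLAY.get(rec.outc_cod, rec.outc_cod)] += 1

    drugs_by_id: dict[str, list[DrugRecord]] = defaultdict(list)
    for d in bundle.drug:
        if d.primaryid in cohort_ids:
            drugs_by_id[d.primaryid].append(d)
    thers_by_id: dict[str, list[TherRecord]] = defaultdict(list)
    for t in bundle.ther:
        if t.primaryid in cohort_ids:
            thers_by_id[t.primaryid].append(t)

    tto: Counter = Counter()
    n_onset = 0
    for rec in demo:
        days = time_to_onset_days(rec, drugs_by_id.get(rec.primaryid, []), thers_by_id.get(rec.primaryid, []), spec)
        if days is not None:
            tto[tto_bin(days)] += 1
            n_onset += 1
    if denom:
        logger.info(
            "time-to-onset computable for %d/%d cohort reports (%.1f%%)",
            n_onset, denom, 100.0 * n_onset / denom,
        )

    return DescriptiveSummary(
        denominator=denom,
        gender=_order(gender, ["Female", "Male"]),
        age=_order(age, [lbl for _, _, lbl in AGE_BINS]),
        reporter=_order(reporter, list(REPORTER_DISPLAY.values())),
        country=_order(country, []),
        year=dict(sorted(((y, c) for y, c in year.items()), key=lambda kv: (kv[0] == UNKNOWN, kv[0]))),
        outcomes=_order(outcomes, [OUTCOME_DISPLAY[c] for c in ("DE", "DS", "HO", "LT")]),
        time_to_onset={lbl: tto[lbl] for _, _, lbl in TTO_BINS if lbl in tto},
    )


__all__ = [
    "AGE_BINS",
    "TTO_BINS",
    "UNKNOWN",
    "CohortSpec",
    "DescriptiveSummary",
    "age_bin",
    "constituent_ratio",
    "select_cohort",
    "summarize_cohort",
    "time_to_onset_days",
    "tto_bin",
]
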
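"""Reading and writing FAERS-format quarterly ASCII tables.

FAERS quarterly data packages ship one ``$``-delimited ASCII file per
table (DEMO, DRUG, REAC, OUTC, THER) with a header row and no quoting.
This module parses those files into typed records, writes them back in
the same dialect, and loads the two-column PT -> SOC terminology map
(MedDRA itself is licensed and never bundled; the map file is supplied
by the user or generated synthetically).

Dates in FAERS are 8-digit ``YYYYMMDD`` strings but are frequently
partial (``YYYY`` or ``YYYYMM``) or absent.  Records keep the raw digit
string alongside a parsed :class:`datetime.date` that is set only when
the raw value is a valid full calendar date; deduplication orders raw
values numerically so partial dates still compare deterministically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)

DELIMITER = "$"

#: Conversion factors from FAERS age units to years.
AGE_UNIT_YEARS = {
    "YR": 1.0,
    "DEC": 10.0,
    "MON": 1.0 / 12.0,
    "WK": 1.0 / 52.1775,
    "DY": 1.0 / 365.25,
    "HR": 1.0 / 8766.0,
}

ROLE_CODES = frozenset({"PS", "SS", "C", "I"})
OUTCOME_CODES = frozenset({"DE", "LT", "HO", "DS", "CA", "RI", "OT"})

#: Display names for reporter occupation codes (mirrors FAERS documentation).
REPORTER_DISPLAY = {
    "CN": "Consumer",
    "PH": "Pharmacist",
    "MD": "Physician",
    "HP": "Other health professional",
    "LW": "Lawyer",
    "OT": "Other",
}

#: Display names for serious-outcome codes.
OUTCOME_DISPLAY = {
    "DE": "Death",
    "LT": "Life-Threatening",
    "HO": "Hospitalization-initial or prolonged",
    "DS": "Disability",
    "CA": "Congenital Anomaly",
    "RI": "Required Intervention",
    "OT": "Other",
}


class FormatError(ValueError):
    """A required column is missing or a file violates the expected dialect."""


def parse_date(raw: str | None) -> date | None:
    """Parse an 8-digit ``YYYYMMDD`` string into a date, else ``None``.

    Partial (4/6-digit) and malformed values yield ``None``; the raw
    string is preserved on the record so nothing is lost.
    """
    if raw is None:
        return None
    raw = raw.strip()
    if len(raw) != 8 or not raw.isdigit():
        return None
    try:
        return date(int(raw[:4]), int(raw[4:6]), int(raw[6:8]))
    except ValueError:
        return None


def _clean(value: str | None) -> str | None:
    if value is None:
        return None
    value = value.strip()
    return value or None


def _clean_date_raw(value: str | None, *, context: str = "") -> str | None:
    """Keep only well-formed raw date strings (4, 6 or 8 digits)."""
    value = _clean(value)
    if value is None:
        return None
    if value.isdigit() and len(value) in (4, 6, 8):
        return value
    logger.warning("unparseable date %r%s treated as missing", value, context)
    return None


@dataclass(frozen=True)
class DemoRecord:
    """One row of the DEMO table: report identity plus demographics."""

    primaryid: str
    caseid: str | None = None
    fda_dt_raw: str | None = None
    event_dt_raw: str | None = None
    sex: str | None = None
    age: float | None = None
    age_cod: str | None = None
    occp_cod: str | None = None
    occr_country: str | None = None
    quarter: str | None = None

    @property
    def fda_dt(self) -> date | None:
        return parse_date(self.fda_dt_raw)

    @property
    def event_dt(self) -> date | None:
        return parse_date(self.event_dt_raw)

    def age_years(self) -> float | None:
        """Age converted to years; missing unit treated as years with a warning."""
        if self.age is None:
            return None
        if self.age_cod is None:
            logger.warning(
                "report %s: age %.6g has no unit code; assuming years", self.primaryid, self.age
            )
            return self.age
        factor = AGE_UNIT_YEARS.get(self.age_cod.upper())
        if factor is None:
            logger.warning(
                "report %s: unknown age unit %r; assuming years", self.primaryid, self.age_cod
            )
            return self.age
        return self.age * factor


@dataclass(frozen=True)
class DrugRecord:
    """One row of the DRUG table: a drug mentioned on a report."""

    primaryid: str
    drug_seq: int
    role_cod: str | None = None
    drugname: str | None = None
    prod_ai: str | None = None


@dataclass(frozen=True)
class ReacRecord:
    """One row of the REAC table: a MedDRA Preferred Term on a report."""

    primaryid: str
    pt: str


@dataclass(frozen=True)
class OutcRecord:
    """One row of the OUTC table: a report outcome code."""

    primaryid: str
    outc_cod: str


@dataclass(frozen=True)
class TherRecord:
    """One row of the THER table: therapy dates for one drug on a report."""

    primaryid: str
    dsg_drug_seq: int
    start_dt_raw: str | None = None

    @property
    def start_dt(self) -> date | None:
        return parse_date(self.start_dt_raw)


@dataclass
class MedDRAMap:
    """Case-insensitive PT -> primary SOC lookup."""

    pt_to_soc: dict[str, tuple[str, str | None]] = field(default_factory=dict)

    @staticmethod
    def normalize(pt: str) -> str:
        return " ".join(pt.split()).casefold()

    def lookup(self, pt: str) -> tuple[str, str | None] | None:
        return self.pt_to_soc.get(self.normalize(pt))

    def soc_of(self, pt: str) -> str | None:
        hit = self.lookup(pt)
        return hit[0] if hit else None

    def __len__(self) -> int:
        return len(self.pt_to_soc)


@dataclass
class QuarterBundle:
    """All records of one (or several merged) FAERS quarters."""

    demo: list[DemoRecord] = field(default_factory=list)
    drug: list[DrugRecord] = field(default_factory=list)
    reac: list[ReacRecord] = field(default_factory=list)
    outc: list[OutcRecord] = field(default_factory=list)
    ther: list[TherRecord] = field(default_factory=list)
    deleted_caseids: set[str] = field(default_factory=set)

    def merge(self, other: "QuarterBundle") -> "QuarterBundle":
        """Concatenate two bundles (e.g. successive quarters)."""
        return QuarterBundle(
            demo=self.demo + other.demo,
            drug=self.drug + other.drug,
            reac=self.reac + other.reac,
            outc=self.outc + other.outc,
            ther=self.ther + other.ther,
            deleted_caseids=self.deleted_caseids | other.deleted_caseids,
        )


# --- parsing -----------------------------------------------------------

_TABLE_COLUMNS = {
    "demo": ["primaryid", "caseid", "fda_dt", "event_dt", "sex", "age", "age_cod", "occp_cod", "occr_country"],
    "drug": ["primaryid", "drug_seq", "role_cod", "drugname", "prod_ai"],
    "reac": ["primaryid", "pt"],
    "outc": ["primaryid", "outc_cod"],
    "ther": ["primaryid", "dsg_drug_seq", "start_dt"],
}

_REQUIRED_COLUMNS = {
    "demo": ["primaryid"],
    "drug": ["primaryid", "drug_seq"],
    "reac": ["primaryid", "pt"],
    "outc": ["primaryid", "outc_cod"],
    "ther": ["primaryid", "dsg_drug_seq"],
}


def _read_table(path: Path, table: str) -> list[dict[str, str | None]]:
    """Read one ``$``-delimited file into row dicts keyed by lower-cased header."""
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines:
        logger.warning("%s: empty file, no records", path)
        return []
    header = [h.strip().lower() for h in lines[0].split(DELIMITER)]
    for col in _REQUIRED_COLUMNS[table]:
        if col not in header:
            raise FormatError(f"{path}: required column {col!r} missing from header {header}")
    rows: list[dict[str, str | None]] = []
    rejected = 0
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split(DELIMITER)
        if len(parts) != len(header):
            rejected += 1
            logger.warning("%s:%d: %d fields, expected %d; row rejected", path, lineno, len(parts), len(header))
            continue
        rows.append({col: _clean(val) for col, val in zip(header, parts)})
    logger.info("%s: %d rows read, %d rejected", path, len(rows), rejected)
    return rows


def _parse_float(value: str | None, context: str) -> float | None:
    if value is None:
        return None
    try:
        return float(value)
    except ValueError:
        logger.warning("non-numeric value %r%s treated as missing", value, context)
        return None


def _parse_int(value: str | None, default: int = 0) -> int:
    if value is None:
        return default
    try:
        return int(float(value))
    except ValueError:
        return default


def read_quarter(paths: Mapping[str, str | Path], quarter_label: str | None = None) -> QuarterBundle:
    """Read one quarter's tables into a :class:`QuarterBundle`.

    Parameters
    ----------
    paths
        Mapping with keys among ``demo, drug, reac, outc, ther, deleted``;
        ``demo`` is required, the rest optional.  ``deleted`` points to a
        plain-text file with one CASEID per line.
    quarter_label
        Stamped onto every DemoRecord (e.g. ``"2019Q1"``).
    """
    if "demo" not in paths:
        raise FormatError("paths must include a 'demo' table")
    bundle = QuarterBundle()
    for row in _read_table(Path(paths["demo"]), "demo"):
        pid = row.get("primaryid")
        if pid is None:
            logger.warning("DEMO row without primaryid skipped")
            continue
        bundle.demo.append(
            DemoRecord(
                primaryid=pid,
                caseid=row.get("caseid"),
                fda_dt_raw=_clean_date_raw(row.get("fda_dt"), context=f" (fda_dt, report {pid})"),
                event_dt_raw=_clean_date_raw(row.get("event_dt"), context=f" (event_dt, report {pid})"),
                sex=row.get("sex"),
                age=_parse_float(row.get("age"), f" (age, report {pid})"),
                age_cod=row.get("age_cod"),
                occp_cod=row.get("occp_cod"),
                occr_country=row.get("occr_country"),
                quarter=quarter_label,
            )
        )
    if "drug" in paths:
        for row in _read_table(Path(paths["drug"]), "drug"):
            role = row.get("role_cod")
            if role is not None and role.upper() not in ROLE_CODES:
                logger.warning("report %s: unknown role code %r kept verbatim", row.get("primaryid"), role)
            bundle.drug.append(
                DrugRecord(
                    primaryid=row["primaryid"],
                    drug_seq=_parse_int(row.get("drug_seq")),
                    role_cod=role.upper() if role else None,
                    drugname=row.get("drugname"),
                    prod_ai=row.get("prod_ai"),
                )
            )
    if "reac" in paths:
        for row in _read_table(Path(paths["reac"]), "reac"):
            pt = row.get("pt")
            if pt is None:
                logger.warning("report %s: empty PT skipped", row.get("primaryid"))
                continue
            bundle.reac.append(ReacRecord(primaryid=row["primaryid"], pt=pt))
    if "outc" in paths:
        for row in _read_table(Path(paths["outc"]), "outc"):
            cod = (row.get("outc_cod") or "").upper()
            if cod not in OUTCOME_CODES:
                logger.warning("report %s: unknown outcome code %r skipped", row.get("primaryid"), cod)
                continue
            bundle.outc.append(OutcRecord(primaryid=row["primaryid"], outc_cod=cod))
    if "ther" in paths:
        for row in _read_table(Path(paths["ther"]), "ther"):
            bundle.ther.append(
                TherRecord(
                    primaryid=row["primaryid"],
                    dsg_drug_seq=_parse_int(row.get("dsg_drug_seq")),
                    start_dt_raw=_clean_date_raw(row.get("start_dt"), context=f" (start_dt, report {row.get('primaryid')})"),
                )
            )
    if "deleted" in paths:
        bundle.deleted_caseids = read_deleted_list(Path(paths["deleted"]))
    return bundle


def read_deleted_list(path: str | Path) -> set[str]:
    """Read a deleted-case list: one CASEID per line, blanks ignored."""
    out: set[str] = set()
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            cid = line.strip()
            if cid:
                out.add(cid)
    return out


# --- writing -----------------------------------------------------------

def _fmt(value: object | None) -> str:
    if value is None:
        return ""
    if isinstance(value, float):
        return f"{value:g}"
    return str(value)


def write_quarter(bundle: QuarterBundle, out_dir: str | Path) -> dict[str, Path]:
    """Write a bundle back as ``$``-delimited tables; inverse of :func:`read_quarter`."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    specs: list[tuple[str, Sequence[str], Iterable[Sequence[object | None]]]] = [
        (
            "demo",
            _TABLE_COLUMNS["demo"],
            (
                (r.primaryid, r.caseid, r.fda_dt_raw, r.event_dt_raw, r.sex, r.age, r.age_cod, r.occp_cod, r.occr_country)
                for r in bundle.demo
            ),
        ),
        (
            "drug",
            _TABLE_COLUMNS["drug"],
            ((r.primaryid, r.drug_seq, r.role_cod, r.drugname, r.prod_ai) for r in bundle.drug),
        ),
        ("reac", _TABLE_COLUMNS["reac"], ((r.primaryid, r.pt) for r in bundle.reac)),
        ("outc", _TABLE_COLUMNS["outc"], ((r.primaryid, r.outc_cod) for r in bundle.outc)),
        ("ther", _TABLE_COLUMNS["ther"], ((r.primaryid, r.dsg_drug_seq, r.start_dt_raw) for r in bundle.ther)),
    ]
    for table, columns, rows in specs:
        path = out / f"{table.upper()}.txt"
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(DELIMITER.join(columns) + "\n")
            for row in rows:
                fh.write(DELIMITER.join(_fmt(v) for v in row) + "\n")
        paths[table] = path

    deleted_path = out / "DELETED.txt"
    with open(deleted_path, "w", encoding="utf-8") as fh:
        for cid in sorted(bundle.deleted_caseids):
            fh.write(cid + "\n")
    paths["deleted"] = deleted_path
    return paths


# --- terminology map ---------------------------------------------------

def load_meddra_map(path: str | Path) -> MedDRAMap:
    """Load a PT -> SOC mapping from a 2- or 3-column TSV.

    Columns: PT, SOC name, optional SOC code.  Lookup is whitespace- and
    case-insensitive.  Duplicate rows are tolerated when consistent;
    a PT mapped to two different SOCs raises ``ValueError`` (each PT has
    exactly one primary SOC).
    """
    mapping: dict[str, tuple[str, str | None]] = {}
    conflicts: list[str] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: expected at least 2 tab-separated columns")
            pt_raw, soc_name = parts[0].strip(), parts[1].strip()
            soc_code = parts[2].strip() if len(parts) > 2 and parts[2].strip() else None
            if lineno == 1 and pt_raw.lower() in ("pt", "preferred term", "preferred_term"):
                continue  # optional header
            key = MedDRAMap.normalize(pt_raw)
            if key in mapping and mapping[key][0] != soc_name:
                conflicts.append(pt_raw)
                continue
            mapping[key] = (soc_name, soc_code)
    if conflicts:
        raise ValueError(f"{path}: PT(s) mapped to conflicting SOCs: {sorted(set(conflicts))}")
    return MedDRAMap(pt_to_soc=mapping)


def write_meddra_map(mapping: MedDRAMap, path: str | Path, display_names: Mapping[str, str] | None = None) -> Path:
    """Write a PT -> SOC map as TSV (inverse of :func:`load_meddra_map`).

    ``display_names`` optionally restores original PT casing keyed by
    the normalized PT.
    """
    path = Path(path)
    display_names = display_names or {}
    with open(path, "w", encoding="utf-8") as fh:
        for key in sorted(mapping.pt_to_soc):
            soc_name, soc_code = mapping.pt_to_soc[key]
            pt = display_names.get(key, key)
            cols = [pt, soc_name] + ([soc_code] if soc_code else [])
            fh.write("\t".join(cols) + "\n")
    return path


__all__ = [
    "AGE_UNIT_YEARS",
    "DELIMITER",
    "DemoRecord",
    "DrugRecord",
    "FormatError",
    "MedDRAMap",
    "OUTCOME_CODES",
    "OUTCOME_DISPLAY",
    "OutcRecord",
    "QuarterBundle",
    "REPORTER_DISPLAY",
    "ROLE_CODES",
    "ReacRecord",
    "TherRecord",
    "load_meddra_map",
    "parse_date",
    "read_deleted_list",
    "read_quarter",
    "write_meddra_map",
    "write_quarter",
]
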
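"""Synthetic FAERS-like corpus generator with known injected signals.

Reports are simulated case by case: one primary-suspect (PS) drug drawn
from a Zipf-weighted catalogue, extra concomitant/secondary drugs, and a
set of Preferred Terms where each PT enters a report independently with
a small background probability.  A signal spec (drug, PT, lambda)
multiplies the *odds* of that PT on reports whose PS drug matches, so
the report-level odds ratio between the drug's cohort and all other
reports equals lambda exactly — the ground truth that recovery tests
compare against.

Structural FAERS artefacts are reproduced: duplicate report versions
(same CASEID, later FDA_DT and fresh PRIMARYID, identical clinical
fields), a deleted-case list, and partial or missing event dates.  Every
draw flows through one seeded generator, so a config and seed map to a
byte-identical corpus.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from datetime import date, timedelta
from pathlib import Path

import numpy as np

from pvsignal.faers_io import (
    DemoRecord,
    DrugRecord,
    MedDRAMap,
    OutcRecord,
    QuarterBundle,
    ReacRecord,
    TherRecord,
    write_meddra_map,
    write_quarter,
)

#: The 27 MedDRA System Organ Classes (name, code) used by the fixture map.
SOC_CATALOGUE: list[tuple[str, str]] = [
    ("Psychiatric disorders", "10037175"),
    ("General disorders and administration site conditions", "10018065"),
    ("Nervous system disorders", "10029205"),
    ("Injury, poisoning and procedural complications", "10022117"),
    ("Gastrointestinal disorders", "10017947"),
    ("Respiratory, thoracic and mediastinal disorders", "10038738"),
    ("Cardiac disorders", "10007541"),
    ("Investigations", "10022891"),
    ("Musculoskeletal and connective tissue disorders", "10028395"),
    ("Skin and subcutaneous tissue disorders", "10040785"),
    ("Vascular disorders", "10047065"),
    ("Eye disorders", "10015919"),
    ("Product issues", "10077536"),
    ("Metabolism and nutrition disorders", "10027433"),
    ("Infections and infestations", "10021881"),
    ("Social circumstances", "10041244"),
    ("Immune system disorders", "10021428"),
    ("Renal and urinary disorders", "10038359"),
    ("Hepatobiliary disorders", "10019805"),
    ("Ear and labyrinth disorders", "10013993"),
    ("Blood and lymphatic system disorders", "10005329"),
    ("Neoplasms benign, malignant and unspecified (incl cysts and polyps)", "10029104"),
    ("Surgical and medical procedures", "10042613"),
    ("Congenital, familial and genetic disorders", "10010331"),
    ("Pregnancy, puerperium and perinatal conditions", "10036585"),
    ("Reproductive system and breast disorders", "10038604"),
    ("Endocrine disorders", "10014698"),
]


@dataclass(frozen=True)
class SignalSpec:
    """Inject a multiplicative reporting-rate signal for one (drug, PT) pair."""

    drug: int  # PS-drug index in the catalogue
    pt: int  # PT index in the catalogue
    lam: float  # odds multiplier; 1 = null

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError("lambda must be positive")


@dataclass
class SimConfig:
    """Conditions of one simulated spontaneous-report corpus.

    Demographic mixtures default to the composition typical of a large
    psychotropic-drug cohort in FAERS: female-majority reporting, ages
    centred in mid-adulthood with ~28% missing, consumers as the
    dominant reporter group, US-majority origin, and report volume
    ramping upward over 2004-2023.  Duplicate (10%) and deletion (2%)
    rates reflect the magnitude of versioned cases and deleted-case
    lists in real quarterly packages.
    """

    n_reports: int = 5000  # unique cases before duplication
    n_drugs: int = 50
    n_pts: int = 150
    drug_zipf_exponent: float = 1.0
    pt_zipf_exponent: float = 1.0
    mean_pts_per_report: float = 2.0  # truncated-geometric-like; >= 1 enforced
    mean_extra_drugs: float = 1.0  # Poisson; plus the single PS drug
    signal_specs: list[SignalSpec] = field(default_factory=list)
    duplicate_rate: float = 0.10
    deletion_rate: float = 0.02
    missing_date_rate: float = 0.02
    partial_date_rate: float = 0.05
    age_missing_rate: float = 0.28
    year_range: tuple[int, int] = (2004, 2023)
    seed: int = 0

    # categorical mixtures (label -> probability; None label = missing field)
    sex_probs: dict[str | None, float] = field(
        default_factory=lambda: {"F": 0.565, "M": 0.358, None: 0.077}
    )
    reporter_probs: dict[str | None, float] = field(
        default_factory=lambda: {"CN": 0.36, "MD": 0.30, "PH": 0.20, "HP": 0.12, "LW": 0.003, None: 0.017}
    )
    country_probs: dict[str | None, float] = field(
        default_factory=lambda: {"US": 0.545, "FR": 0.186, "IT": 0.100, "BR": 0.032, "JP": 0.019, "DE": 0.050, "GB": 0.040, None: 0.028}
    )
    outcome_probs: dict[str, float] = field(
        default_factory=lambda: {"DE": 0.10, "HO": 0.18, "LT": 0.04, "DS": 0.02, "OT": 0.12, "CA": 0.004, "RI": 0.004}
    )

    def validate(self) -> None:
        if self.n_reports <= 0 or self.n_drugs <= 0 or self.n_pts <= 0:
            raise ValueError("n_reports, n_drugs, n_pts must be positive")
        for name in ("duplicate_rate", "deletion_rate", "missing_date_rate", "partial_date_rate", "age_missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.mean_pts_per_report > self.n_pts:
            raise ValueError("mean_pts_per_report cannot exceed n_pts")
        if self.mean_pts_per_report <= 0:
            raise ValueError("mean_pts_per_report must be positive")
        for spec in self.signal_specs:
            if not 0 <= spec.drug < self.n_drugs:
                raise ValueError(f"signal drug index {spec.drug} out of range")
            if not 0 <= spec.pt < self.n_pts:
                raise ValueError(f"signal pt index {spec.pt} out of range")

    def drug_name(self, i: int) -> str:
        return f"DRUG{i:03d}"

    def pt_name(self, i: int) -> str:
        return f"Synthetic reaction {i:04d}"

    def pt_background_probs(self) -> np.ndarray:
        """Per-PT background inclusion probabilities (Zipf weights, capped)."""
        w = (np.arange(1, self.n_pts + 1, dtype=float)) ** (-self.pt_zipf_exponent)
        w /= w.sum()
        return np.minimum(self.mean_pts_per_report * w, 0.5)

    def drug_weights(self) -> np.ndarray:
        w = (np.arange(1, self.n_drugs + 1, dtype=float)) ** (-self.drug_zipf_exponent)
        return w / w.sum()


@dataclass
class SyntheticTruth:
    """Ground truth of a generated corpus, for recovery testing."""

    seed: int
    n_cases: int
    signals: list[dict]  # drug/pt indices, names, lambda, realized count
    deleted_caseids: list[str]
    n_duplicates: int

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(asdict(self), indent=2, sort_keys=True) + "\n", encoding="utf-8")
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        return cls(**json.loads(Path(path).read_text(encoding="utf-8")))


def _draw_categorical(rng: np.random.Generator, probs: dict, size: int) -> list:
    labels = list(probs.keys())
    p = np.asarray([probs[k] for k in labels], dtype=float)
    p = p / p.sum()
    idx = rng.choice(len(labels), size=size, p=p)
    return [labels[i] for i in idx]


def _fmt_date(d: date) -> str:
    return f"{d.year:04d}{d.month:02d}{d.day:02d}"


def generate_corpus(cfg: SimConfig) -> tuple[QuarterBundle, SyntheticTruth]:
    """Generate one corpus: records (with duplicates) plus ground truth."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_reports

    # --- PS drugs and the PT inclusion matrix -------------------------
    ps_drug = rng.choice(cfg.n_drugs, size=n, p=cfg.drug_weights())
    base = cfg.pt_background_probs()
    probs = np.tile(base, (n, 1))
    for spec in cfg.signal_specs:
        pi = base[spec.pt]
        boosted = spec.lam * pi / (1.0 - pi + spec.lam * pi)  # odds multiplied by lambda
        probs[ps_drug == spec.drug, spec.pt] = boosted
    include = rng.random((n, cfg.n_pts)) < probs
    # every report must list at least one reaction: redraw empty rows
    empty = np.flatnonzero(~include.any(axis=1))
    while empty.size:
        include[empty] = rng.random((empty.size, cfg.n_pts)) < probs[empty]
        empty = empty[~include[empty].any(axis=1)]

    # --- demographics --------------------------------------------------
    sexes = _draw_categorical(rng, cfg.sex_probs, n)
    reporters = _draw_categorical(rng, cfg.reporter_probs, n)
    countries = _draw_categorical(rng, cfg.country_probs, n)
    ages = np.clip(rng.normal(46.0, 20.0, size=n), 0.25, 100.0)
    age_missing = rng.random(n) < cfg.age_missing_rate

    y0, y1 = cfg.year_range
    year_labels = np.arange(y0, y1 + 1)
    year_w = np.linspace(1.0, 4.0, num=year_labels.size)  # volume ramps upward
    years = rng.choice(year_labels, size=n, p=year_w / year_w.sum())
    start_month = rng.integers(1, 13, size=n)
    start_day = rng.integers(1, 29, size=n)
    # onset delay: mostly within a month, occasional long-latency tail
    delay = rng.geometric(1.0 / 10.0, size=n) - 1
    long_tail = rng.random(n) < 0.06
    delay = np.where(long_tail, rng.integers(31, 800, size=n), delay)
    report_lag = rng.integers(2, 90, size=n)
    date_fate = rng.random(n)  # < missing -> drop event date; next band -> partial
    partial_kind = rng.integers(0, 2, size=n)  # 0: YYYYMM, 1: YYYY

    n_extra = np.minimum(rng.poisson(cfg.mean_extra_drugs, size=n), cfg.n_drugs - 1)
    name_style = rng.integers(0, 3, size=n)  # exercise casing/punctuation variants
    has_prod_ai = rng.random(n) < 0.7
    outc_draws = rng.random((n, len(cfg.outcome_probs)))
    outc_codes = list(cfg.outcome_probs.keys())
    outc_p = np.asarray([cfg.outcome_probs[c] for c in outc_codes])
    ther_missing = rng.random(n) < 0.05

    bundle = QuarterBundle()
    signal_counts = {(s.drug, s.pt): 0 for s in cfg.signal_specs}

    for i in range(n):
        caseid = str(7_000_000 + i)
        primaryid = caseid + "1"
        start = date(int(years[i]), int(start_month[i]), int(start_day[i]))
        event = start + timedelta(days=int(delay[i]))
        fda = event + timedelta(days=int(report_lag[i]))

        event_raw: str | None = _fmt_date(event)
        if date_fate[i] < cfg.missing_date_rate:
            event_raw = None
        elif date_fate[i] < cfg.missing_date_rate + cfg.partial_date_rate:
            event_raw = event_raw[:6] if partial_kind[i] == 0 else event_raw[:4]

        quarter = f"{fda.year}Q{(fda.month - 1) // 3 + 1}"
        bundle.demo.append(
            DemoRecord(
                primaryid=primaryid,
                caseid=caseid,
                fda_dt_raw=_fmt_date(fda),
                event_dt_raw=event_raw,
                sex=sexes[i],
                age=None if age_missing[i] else round(float(ages[i]), 1),
                age_cod=None if age_missing[i] else "YR",
                occp_cod=reporters[i],
                occr_country=countries[i],
                quarter=quarter,
            )
        )

        # drugs: one PS, then extras with SS/C roles
        drug_ids = [int(ps_drug[i])]
        others = [d for d in range(cfg.n_drugs) if d != drug_ids[0]]
        if n_extra[i] > 0:
            extra = rng.choice(len(others), size=int(n_extra[i]), replace=False)
            drug_ids.extend(others[j] for j in sorted(extra))
        for seq, did in enumerate(drug_ids, start=1):
            base_name = cfg.drug_name(did)
            style = (name_style[i] + seq) % 3
            drugname = [base_name, base_name.lower(), base_name + "."][style]
            role = "PS" if seq == 1 else ("SS" if seq % 2 == 0 else "C")
            bundle.drug.append(
                DrugRecord(
                    primaryid=primaryid,
                    drug_seq=seq,
                    role_cod=role,
                    drugname=drugname,
                    prod_ai=base_name if has_prod_ai[i] else None,
                )
            )
        bundle.ther.append(
            TherRecord(
                primaryid=primaryid,
                dsg_drug_seq=1,
                start_dt_raw=None if ther_missing[i] else _fmt_date(start),
            )
        )

        pts = np.flatnonzero(include[i])
        for p in pts:
            bundle.reac.append(ReacRecord(primaryid=primaryid, pt=cfg.pt_name(int(p))))
            key = (int(ps_drug[i]), int(p))
            if key in signal_counts:
                signal_counts[key] += 1

        for j, code in enumerate(outc_codes):
            if outc_draws[i, j] < outc_p[j]:
                bundle.outc.append(OutcRecord(primaryid=primaryid, outc_cod=code))

    # --- duplicate report versions -------------------------------------
    n_dup = int(round(cfg.duplicate_rate * n))
    dup_idx = rng.choice(n, size=n_dup, replace=False) if n_dup else np.array([], dtype=int)
    same_fda = rng.random(n_dup) < 0.3  # exercise the primaryid tie-break
    fda_shift = rng.integers(1, 31, size=n_dup)
    demo_by_idx = {int(ix): bundle.demo[int(ix)] for ix in dup_idx}
    child_rows: dict[str, list] = {}
    for table in ("drug", "reac", "outc", "ther"):
        for rec in getattr(bundle, table):
            child_rows.setdefault(rec.primaryid, []).append(rec)
    for k, ix in enumerate(sorted(int(v) for v in dup_idx)):
        orig = bundle.demo[ix]
        new_pid = orig.caseid + "2"  # numerically larger than version ...1
        if same_fda[k]:
            new_fda_raw = orig.fda_dt_raw
        else:
            new_fda_raw = _fmt_date(orig.fda_dt + timedelta(days=int(fda_shift[k])))
        bundle.demo.append(
            DemoRecord(
                primaryid=new_pid,
                caseid=orig.caseid,
                fda_dt_raw=new_fda_raw,
                event_dt_raw=orig.event_dt_raw,
                sex=orig.sex,
                age=orig.age,
                age_cod=orig.age_cod,
                occp_cod=orig.occp_cod,
                occr_country=orig.occr_country,
                quarter=orig.quarter,
            )
        )
        for rec in child_rows.get(orig.primaryid, []):
            cls = type(rec)
            kwargs = {f: getattr(rec, f) for f in cls.__dataclass_fields__}
            kwargs["primaryid"] = new_pid
            getattr(bundle, {"DrugRecord": "drug", "ReacRecord": "reac", "OutcRecord": "outc", "TherRecord": "ther"}[cls.__name__]).append(cls(**kwargs))

    # --- deleted-case list ---------------------------------------------
    n_del = int(round(cfg.deletion_rate * n))
    del_idx = rng.choice(n, size=n_del, replace=False) if n_del else np.array([], dtype=int)
    deleted = sorted(str(7_000_000 + int(ix)) for ix in del_idx)
    bundle.deleted_caseids = set(deleted)

    # realized counts exclude deleted cases (they never survive the pipeline)
    deleted_set = set(deleted)
    final_counts = {key: 0 for key in signal_counts}
    if cfg.signal_specs:
        pt_index = {cfg.pt_name(s.pt): s.pt for s in cfg.signal_specs}
        for i in range(n):
            caseid = str(7_000_000 + i)
            if caseid in deleted_set:
                continue
            for p in np.flatnonzero(include[i]):
                key = (int(ps_drug[i]), int(p))
                if key in final_counts:
                    final_counts[key] += 1
        del pt_index

    truth = SyntheticTruth(
        seed=cfg.seed,
        n_cases=n,
        signals=[
            {
                "drug": s.drug,
                "drug_name": cfg.drug_name(s.drug),
                "pt": s.pt,
                "pt_name": cfg.pt_name(s.pt),
                "lambda": s.lam,
                "count_with_dups": signal_counts[(s.drug, s.pt)],
                "count": final_counts.get((s.drug, s.pt), signal_counts[(s.drug, s.pt)]),
            }
            for s in cfg.signal_specs
        ],
        deleted_caseids=deleted,
        n_duplicates=n_dup,
    )
    return bundle, truth


def generate_meddra_fixture(cfg: SimConfig) -> tuple[MedDRAMap, dict[str, str]]:
    """Deterministic PT -> SOC assignment over the 27-SOC catalogue.

    Returns the map plus a display-name dict (normalized PT -> original
    casing) for TSV round-tripping.
    """
    mapping: dict[str, tuple[str, str | None]] = {}
    display: dict[str, str] = {}
    for i in range(cfg.n_pts):
        pt = cfg.pt_name(i)
        soc_name, soc_code = SOC_CATALOGUE[i % len(SOC_CATALOGUE)]
        key = MedDRAMap.normalize(pt)
        mapping[key] = (soc_name, soc_code)
        display[key] = pt
    return MedDRAMap(pt_to_soc=mapping), display


def write_corpus(cfg: SimConfig, out_dir: str | Path) -> dict[str, Path]:
    """Generate and write a full corpus: tables, deleted list, map, truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle, truth = generate_corpus(cfg)
    paths = write_quarter(bundle, out)
    meddra, display = generate_meddra_fixture(cfg)
    paths["meddra"] = write_meddra_map(meddra, out / "meddra_pt_soc.tsv", display_names=display)
    paths["truth"] = truth.to_json(out / "truth.json")
    return paths


__all__ = [
    "SOC_CATALOGUE",
    "SignalSpec",
    "SimConfig",
    "SyntheticTruth",
    "generate_corpus",
    "generate_meddra_fixture",
    "write_corpus",
]
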
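"""End-to-end pipeline: ingest -> dedup -> cohort -> contingency -> signals.

One configured run reads (or simulates) a corpus, removes duplicate and
deleted reports, selects the target-drug primary-suspect cohort, builds
PT- and SOC-level contingency tables, computes the four
disproportionality statistics, and writes the descriptive summary,
per-level signal tables, ranked top-N tables, and a JSON manifest with
per-stage row accounting.  Outputs are byte-stable for a fixed config
and seed.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from pvsignal.cohort import CohortSpec, DescriptiveSummary, summarize_cohort, select_cohort
from pvsignal.contingency import build_event_units, build_tables
from pvsignal.dedup import dedup_bundle
from pvsignal.faers_io import MedDRAMap, QuarterBundle, load_meddra_map, read_quarter
from pvsignal.signal_stats import (
    BcpnnPriors,
    SignalStats,
    compute_signal_stats,
    rank_results,
)
from pvsignal.synthetic import SimConfig, SignalSpec, generate_corpus, generate_meddra_fixture

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything one pipeline run needs; serializable for provenance."""

    input_dir: str | None = None  # corpus directory (DEMO.txt, ...); None -> simulate
    meddra_path: str | None = None  # PT->SOC TSV; None + simulate -> fixture map
    simulate: SimConfig | None = None
    drug_keyword: str = "alprazolam"
    roles: tuple[str, ...] = ("PS",)
    match_fields: tuple[str, ...] = ("drugname", "prod_ai")
    levels: tuple[str, ...] = ("PT", "SOC")
    unit: str = "pairs"
    chi2_variant: str = "yates"
    priors: BcpnnPriors = field(default_factory=BcpnnPriors)
    policy: str = "all"
    top_n: int = 30
    out_dir: str = "pvsignal_out"
    seed: int = 0

    def cohort_spec(self) -> CohortSpec:
        return CohortSpec(
            drug_keyword=self.drug_keyword,
            match_fields=frozenset(self.match_fields),
            roles=frozenset(self.roles),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        if "simulate" in raw and raw["simulate"] is not None:
            sim = dict(raw["simulate"])
            sim["signal_specs"] = [SignalSpec(**s) for s in sim.get("signal_specs", [])]
            if "year_range" in sim:
                sim["year_range"] = tuple(sim["year_range"])
            raw["simulate"] = SimConfig(**sim)
        if "simulate" in raw and raw["simulate"] is not None:
            for attr in ("sex_probs", "reporter_probs", "country_probs"):
                probs = getattr(raw["simulate"], attr)
                if "" in probs:  # empty string stands for a missing field
                    probs[None] = probs.pop("")
        if "priors" in raw and raw["priors"] is not None:
            raw["priors"] = BcpnnPriors(**raw["priors"])
        for key in ("roles", "match_fields", "levels"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        def sanitize(obj):
            if isinstance(obj, dict):
                return {("" if k is None else k): sanitize(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [sanitize(v) for v in obj]
            return obj

        return sanitize(asdict(self))


def _fmt_stat(x: float) -> str:
    return "NA" if (isinstance(x, float) and math.isnan(x)) else f"{x:.2f}"


SIGNAL_COLUMNS = [
    "soc", "event", "level", "case_reports", "a", "b", "c", "d",
    "ror", "ror_lo", "ror_hi", "prr", "prr_lo", "prr_hi", "chi2",
    "ic", "e_ic", "ic025", "ebgm", "ebgm05", "ebgm95",
    "ror_flag", "prr_flag", "bcpnn_flag", "ebgm_flag", "signal",
]


def write_signal_tsv(results: list[SignalStats], path: Path, meddra: MedDRAMap | None = None) -> None:
    """Signal table mirroring the published layout: one row per event.

    Statistics print at 2 decimals; non-computable values print NA.  At
    PT level the event's primary SOC is included when a map is given.
    """
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(SIGNAL_COLUMNS) + "\n")
        for s in results:
            soc = ""
            if s.level == "SOC":
                soc = s.event_label
            elif meddra is not None:
                soc = meddra.soc_of(s.event_label) or ""
            row = [
                soc, s.event_label, s.level, str(s.a), str(s.a), str(s.b), str(s.c), str(s.d),
                _fmt_stat(s.ror), _fmt_stat(s.ror_lo), _fmt_stat(s.ror_hi),
                _fmt_stat(s.prr), _fmt_stat(s.prr_lo), _fmt_stat(s.prr_hi), _fmt_stat(s.chi2),
                _fmt_stat(s.ic), _fmt_stat(s.e_ic), _fmt_stat(s.ic025),
                _fmt_stat(s.ebgm), _fmt_stat(s.ebgm05), _fmt_stat(s.ebgm95),
                str(int(s.ror_flag)), str(int(s.prr_flag)), str(int(s.bcpnn_flag)),
                str(int(s.ebgm_flag)), str(int(s.combined_flag)),
            ]
            fh.write("\t".join(row) + "\n")


def write_summary_tsv(summary: DescriptiveSummary, path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("section\tcategory\tcount\tpercent\n")
        for section, label, count, pct in summary.to_rows():
            fh.write(f"{section}\t{label}\t{count}\t{pct:.2f}\n")


def analyze_bundle(
    bundle: QuarterBundle,
    spec: CohortSpec,
    level: str = "PT",
    meddra: MedDRAMap | None = None,
    unit: str = "pairs",
    priors: BcpnnPriors | None = None,
    chi2_variant: str = "yates",
    policy: str = "all",
) -> list[SignalStats]:
    """Library shortcut: dedup a bundle and compute signal statistics.

    Runs the same stages as :func:`run_pipeline` (dedup, deletions,
    cohort selection, event units, 2x2 tables, statistics) without
    touching the filesystem; results come back ranked by case reports.
    """
    bundle, _ = dedup_bundle(bundle)
    cohort = select_cohort(bundle, spec)
    units = build_event_units(bundle, level=level, meddra_map=meddra)
    all_ids = {r.primaryid for r in bundle.demo}
    tables = build_tables(units, cohort, all_report_ids=all_ids, unit=unit)
    results = [
        compute_signal_stats(t, priors=priors, chi2_variant=chi2_variant, policy=policy)
        for t in tables
    ]
    return rank_results(results, by="case_reports")


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full analysis; returns the run manifest dict."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    from pvsignal import __version__

    manifest: dict = {"version": __version__, "config": cfg.to_dict(), "stages": {}}

    # --- ingest --------------------------------------------------------
    meddra: MedDRAMap | None = None
    if cfg.simulate is not None:
        sim = cfg.simulate
        bundle, truth = generate_corpus(sim)
        meddra, _ = generate_meddra_fixture(sim)
        manifest["stages"]["simulate"] = {"cases": truth.n_cases, "duplicates": truth.n_duplicates,
                                          "deleted": len(truth.deleted_caseids)}
    elif cfg.input_dir is not None:
        root = Path(cfg.input_dir)
        paths = {}
        for table in ("demo", "drug", "reac", "outc", "ther"):
            p = root / f"{table.upper()}.txt"
            if p.exists():
                paths[table] = p
        deleted = root / "DELETED.txt"
        if deleted.exists():
            paths["deleted"] = deleted
        bundle = read_quarter(paths)
    else:
        raise ValueError("RunConfig needs input_dir or simulate")
    if cfg.meddra_path is not None:
        meddra = load_meddra_map(cfg.meddra_path)
    manifest["stages"]["ingest"] = {
        "demo_rows": len(bundle.demo), "drug_rows": len(bundle.drug),
        "reac_rows": len(bundle.reac), "outc_rows": len(bundle.outc),
        "ther_rows": len(bundle.ther), "deleted_caseids": len(bundle.deleted_caseids),
    }

    # --- dedup ---------------------------------------------------------
    bundle, dedup_result = dedup_bundle(bundle)
    manifest["stages"]["dedup"] = {
        "kept": len(dedup_result.kept_primaryids),
        "removed_as_duplicate": dedup_result.removed_as_duplicate,
        "removed_as_deleted": dedup_result.removed_as_deleted,
    }

    # --- cohort --------------------------------------------------------
    spec = cfg.cohort_spec()
    cohort = select_cohort(bundle, spec)
    manifest["stages"]["cohort"] = {"keyword": cfg.drug_keyword, "reports": len(cohort)}
    summary = summarize_cohort(bundle, cohort, spec)
    write_summary_tsv(summary, out / "descriptive_summary.tsv")

    # --- contingency + signals ----------------------------------------
    all_ids = {r.primaryid for r in bundle.demo}
    priors = cfg.priors
    for level in cfg.levels:
        if level.upper() == "SOC" and meddra is None:
            logger.warning("no MedDRA map available; SOC level skipped")
            continue
        units = build_event_units(bundle, level=level, meddra_map=meddra)
        tables = build_tables(units, cohort, all_report_ids=all_ids, unit=cfg.unit)
        results = [
            compute_signal_stats(t, priors=priors, chi2_variant=cfg.chi2_variant, policy=cfg.policy)
            for t in tables
        ]
        results = rank_results(results, by="case_reports")
        write_signal_tsv(results, out / f"signals_{level.upper()}.tsv", meddra)
        manifest["stages"][f"signals_{level.upper()}"] = {
            "units": len(units.pairs),
            "events": len(tables),
            "flagged": sum(r.combined_flag for r in results),
        }
        if level.upper() == "PT":
            top_cases = rank_results(results, by="case_reports", top_n=cfg.top_n)
            top_ebgm = rank_results([r for r in results if r.a > 0], by="ebgm", top_n=cfg.top_n)
            write_signal_tsv(top_cases, out / "top_by_case_reports.tsv", meddra)
            write_signal_tsv(top_ebgm, out / "top_by_ebgm.tsv", meddra)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8")
    (out / "config.yaml").write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True), encoding="utf-8")
    return manifest


__all__ = ["RunConfig", "analyze_bundle", "run_pipeline", "write_signal_tsv", "write_summary_tsv"]
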
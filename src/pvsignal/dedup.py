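"""FDA-style duplicate-report removal and deleted-case handling.

A FAERS case (CASEID) accumulates report versions (PRIMARYID) as
follow-up information arrives.  The FDA-recommended rule keeps, for each
case, the version with the largest FDA receive date (FDA_DT), breaking
ties by the largest PRIMARYID — the most recent version is presumed the
most complete.  Quarterly packages additionally ship a list of deleted
cases, removed after deduplication.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from pvsignal.faers_io import DemoRecord, QuarterBundle

logger = logging.getLogger(__name__)


def _sort_key(rec: DemoRecord) -> tuple[int, int]:
    """(fda_dt, primaryid) as integers; missing/partial fda_dt sorts lowest.

    Raw date strings compare by integer value so a partial ``202001``
    still orders deterministically below any full date in that month.
    """
    fda = int(rec.fda_dt_raw) if rec.fda_dt_raw else -1
    try:
        pid = int(rec.primaryid)
    except ValueError:
        pid = -1
    return (fda, pid)


@dataclass
class DedupResult:
    """Outcome of deduplication: which report versions survive."""

    kept_primaryids: list[str] = field(default_factory=list)
    kept_records: list[DemoRecord] = field(default_factory=list)
    removed_as_duplicate: int = 0
    removed_as_deleted: int = 0

    @property
    def kept_set(self) -> set[str]:
        return set(self.kept_primaryids)


def deduplicate(demo: list[DemoRecord]) -> DedupResult:
    """Keep one report version per case: max by (FDA_DT, then PRIMARYID).

    Records with a missing CASEID cannot be grouped and are kept
    unconditionally.  The result is deterministic regardless of input
    order; kept records are returned sorted by primaryid (numeric where
    possible) for stable downstream output.
    """
    best: dict[str, DemoRecord] = {}
    no_case: list[DemoRecord] = []
    duplicates = 0
    for rec in demo:
        if rec.caseid is None:
            no_case.append(rec)
            continue
        incumbent = best.get(rec.caseid)
        if incumbent is None:
            best[rec.caseid] = rec
        else:
            duplicates += 1
            if _sort_key(rec) > _sort_key(incumbent):
                best[rec.caseid] = rec
    if no_case:
        logger.info("%d records without caseid kept unconditionally", len(no_case))
    kept = list(best.values()) + no_case
    kept.sort(key=lambda r: (len(r.primaryid), r.primaryid))
    logger.info("dedup: %d rows in, %d kept, %d removed as duplicates", len(demo), len(kept), duplicates)
    return DedupResult(
        kept_primaryids=[r.primaryid for r in kept],
        kept_records=kept,
        removed_as_duplicate=duplicates,
    )


def apply_deletions(result: DedupResult, deleted_caseids: set[str]) -> DedupResult:
    """Drop kept reports whose CASEID appears on the deleted-case list."""
    if not deleted_caseids:
        return result
    seen = {r.caseid for r in result.kept_records if r.caseid is not None}
    unseen = deleted_caseids - seen
    if unseen:
        logger.debug("%d deleted caseids not present in corpus ignored", len(unseen))
    kept = [r for r in result.kept_records if r.caseid not in deleted_caseids]
    n_deleted = len(result.kept_records) - len(kept)
    logger.info("deletions: %d reports removed via deleted-case list", n_deleted)
    return DedupResult(
        kept_primaryids=[r.primaryid for r in kept],
        kept_records=kept,
        removed_as_duplicate=result.removed_as_duplicate,
        removed_as_deleted=result.removed_as_deleted + n_deleted,
    )


def filter_bundle(bundle: QuarterBundle, kept_primaryids: set[str]) -> QuarterBundle:
    """Restrict all tables to the surviving report versions."""
    return QuarterBundle(
        demo=[r for r in bundle.demo if r.primaryid in kept_primaryids],
        drug=[r for r in bundle.drug if r.primaryid in kept_primaryids],
        reac=[r for r in bundle.reac if r.primaryid in kept_primaryids],
        outc=[r for r in bundle.outc if r.primaryid in kept_primaryids],
        ther=[r for r in bundle.ther if r.primaryid in kept_primaryids],
        deleted_caseids=set(bundle.deleted_caseids),
    )


def dedup_bundle(bundle: QuarterBundle) -> tuple[QuarterBundle, DedupResult]:
    """Deduplicate, apply the deleted-case list, and filter child tables."""
    result = deduplicate(bundle.demo)
    result = apply_deletions(result, bundle.deleted_caseids)
    return filter_bundle(bundle, result.kept_set), result


__all__ = ["DedupResult", "deduplicate", "apply_deletions", "filter_bundle", "dedup_bundle"]
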
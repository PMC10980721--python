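import sys
from pathlib import Path

import pytest
from hypothesis import settings

sys.path.insert(0, str(Path(__file__).parent))  # make oracle.py importable

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from pvsignal.faers_io import (
    DemoRecord,
    DrugRecord,
    OutcRecord,
    QuarterBundle,
    ReacRecord,
    TherRecord,
)


def make_report(
    primaryid: str,
    caseid: str | None = None,
    fda_dt: str | None = "20200115",
    event_dt: str | None = "20200110",
    sex: str | None = "F",
    age: float | None = 40.0,
    drugs: list[tuple[str, str]] | None = None,  # (role, name)
    pts: list[str] | None = None,
    outcomes: list[str] | None = None,
    start_dt: str | None = "20200101",
) -> QuarterBundle:
    """One-report bundle; merge several for multi-report corpora."""
    b = QuarterBundle()
    b.demo.append(
        DemoRecord(
            primaryid=primaryid,
            caseid=caseid or primaryid,
            fda_dt_raw=fda_dt,
            event_dt_raw=event_dt,
            sex=sex,
            age=age,
            age_cod="YR" if age is not None else None,
            occp_cod="MD",
            occr_country="US",
        )
    )
    for seq, (role, name) in enumerate(drugs or [("PS", "ALPRAZOLAM")], start=1):
        b.drug.append(DrugRecord(primaryid=primaryid, drug_seq=seq, role_cod=role, drugname=name))
    for pt in pts or ["Somnolence"]:
        b.reac.append(ReacRecord(primaryid=primaryid, pt=pt))
    for cod in outcomes or []:
        b.outc.append(OutcRecord(primaryid=primaryid, outc_cod=cod))
    if start_dt is not None:
        b.ther.append(TherRecord(primaryid=primaryid, dsg_drug_seq=1, start_dt_raw=start_dt))
    return b


def merge_all(bundles) -> QuarterBundle:
    out = QuarterBundle()
    for b in bundles:
        out = out.merge(b)
    return out


@pytest.fixture
def report_factory():
    return make_report


@pytest.fixture
def bundle_factory():
    def build(reports):
        return merge_all(reports)

    return build
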
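"""Shared fixtures: everything is generated at test time (synthetic DICOM,
in-memory stores, virtual clocks); no binary fixtures on disk."""

from __future__ import annotations

import datetime as dt

import pytest

from pacsbroker import (
    AccessWindow,
    AERegistry,
    Broker,
    GovernancePolicy,
    MockPacs,
    PacsEndpoint,
    Project,
    SyntheticStudySpec,
    SystemConfig,
    VirtualClock,
)

ALL_DAYS = ("Mon", "Tue", "Wed", "Thu", "Fri", "Sat", "Sun")
OPEN_ALL_WEEK = AccessWindow(
    days=ALL_DAYS, start=0, end=1440, rate_count=10_000, rate_period="minute"
)

UTC = dt.timezone.utc


def make_config(
    tmp_path,
    *,
    projects=None,
    windows=(OPEN_ALL_WEEK,),
    max_concurrent=1_000_000,
    max_studies_per_patient=None,
    quota=1 << 30,
    n_projects=1,
    allowlists=None,
) -> SystemConfig:
    """One endpoint E1/PACS1 plus n lexicographically ordered projects."""
    if projects is None:
        projects = []
        for i in range(1, n_projects + 1):
            allow = (
                allowlists[i - 1]
                if allowlists is not None
                else {f"MRN{i}{j:03d}" for j in range(50)}
            )
            projects.append(
                Project(
                    id=f"P{i}",
                    irb_id=f"IRB-{i}",
                    members=frozenset({f"user{i}"}),
                    allowlist=frozenset(allow),
                    cache_quota_bytes=quota,
                )
            )
    return SystemConfig(
        endpoints=(
            PacsEndpoint(
                id="E1", institution="Test Hospital", aet="PACS1",
                host="localhost", port=11112,
            ),
        ),
        policies={
            "E1": GovernancePolicy(
                windows=tuple(windows),
                max_concurrent=max_concurrent,
                max_studies_per_patient=max_studies_per_patient,
            )
        },
        projects=tuple(projects),
        cache_root=str(tmp_path / "cache"),
        audit_store=str(tmp_path / "audit.db"),
    )


def make_spec(seed: int, mrn: str, accession: str, **kw) -> SyntheticStudySpec:
    kw.setdefault("study_date", "2012-03-04")
    return SyntheticStudySpec(
        seed=seed, canonical_mrn=mrn, accession_number=accession, **kw
    )


@pytest.fixture
def clock() -> VirtualClock:
    # Monday 2014-06-02 00:00 UTC
    return VirtualClock()


@pytest.fixture
def registry() -> AERegistry:
    return AERegistry()


@pytest.fixture
def pacs(registry, clock) -> MockPacs:
    return MockPacs("PACS1", registry, clock=clock)


@pytest.fixture
def broker_env(tmp_path, registry, clock, pacs):
    """(config, broker, pacs) with one project P1/user1 and three studies
    for allowlisted patients."""
    config = make_config(tmp_path)
    specs = [
        make_spec(11, "MRN1000", "AN1", n_series=2, instances_per_series=3),
        make_spec(12, "MRN1001", "AN2", modality="CT", study_date="2011-02-02"),
        make_spec(13, "MRN1002", "AN3", modality="US", study_date="2009-05-01"),
    ]
    for s in specs:
        pacs.add_spec(s)
    broker = Broker(config, registry, clock=clock, tz=UTC)
    return config, broker, pacs, specs
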
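"""Synthetic DICOM fixtures and a configurable mock PACS.

Everything the broker is tested against is generated here: standards-valid
Part-10 secondary-capture instances with deterministic, seed-derived UIDs
and tiny pseudo-random pixel data, served by an in-process archive that
answers patient/study C-FIND, executes C-MOVE by storing instances to the
registered destination AE, and injects configurable failure behaviour
(association refusal, probabilistic move failure, off-line-archive latency)
from a seeded random source.

Study size realism is simulated with an optional padding attribute so quota
accounting can be exercised at hundred-megabyte scale without
hundred-megabyte files.

The mock records every query and association it sees; access-control tests
use this log as the ground truth for "what did the archive observe".
"""

from __future__ import annotations

import hashlib
import io
import random
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, SecondaryCaptureImageStorage

from .clock import Clock, VirtualClock
from .config import Project
from .dimse import (
    STATUS_FAILURE,
    STATUS_MOVE_DESTINATION_UNKNOWN,
    STATUS_SUCCESS,
    AERegistry,
    MoveOutcome,
)
from .errors import EndpointUnreachableError, NotFoundError

_UID_ROOT = "2.25."
_IMPLEMENTATION_UID = "2.25.3141592653589793238462643383279"


def _det_uid(*parts) -> str:
    """Deterministic DICOM UID from arbitrary parts (≤ 64 chars)."""
    digest = hashlib.sha256("/".join(str(p) for p in parts).encode()).hexdigest()
    return _UID_ROOT + str(int(digest, 16) % 10**38)


@dataclass(frozen=True)
class SyntheticStudySpec:
    """Recipe for one reproducible synthetic study."""

    seed: int
    canonical_mrn: str
    accession_number: str
    study_date: str  # ISO YYYY-MM-DD
    n_series: int = 1
    instances_per_series: int = 1
    modality: str = "MR"
    pixel_dims: tuple[int, int] = (32, 32)
    patient_name: str = "SYNTHETIC^PATIENT"
    birth_date: Optional[str] = None  # ISO
    institution: str = "Test Hospital"
    study_description: str = "SYNTHETIC STUDY"
    padding_bytes: int = 0

    def __post_init__(self):
        if self.n_series < 1 or self.instances_per_series < 1:
            raise ValueError("n_series and instances_per_series must be >= 1")

    @property
    def study_instance_uid(self) -> str:
        return _det_uid("study", self.seed, self.canonical_mrn, self.accession_number)


def generate_datasets(spec: SyntheticStudySpec) -> list[pydicom.FileDataset]:
    """Generate the study's instances as in-memory datasets.

    Deterministic: identical specs yield byte-identical serializations.
    """
    rng = np.random.RandomState(spec.seed % (2**31))
    rows, cols = spec.pixel_dims
    out = []
    for s in range(1, spec.n_series + 1):
        series_uid = _det_uid("series", spec.seed, spec.study_instance_uid, s)
        for i in range(1, spec.instances_per_series + 1):
            sop_uid = _det_uid("sop", spec.seed, series_uid, i)
            meta = FileMetaDataset()
            meta.MediaStorageSOPClassUID = SecondaryCaptureImageStorage
            meta.MediaStorageSOPInstanceUID = sop_uid
            meta.TransferSyntaxUID = ExplicitVRLittleEndian
            meta.ImplementationClassUID = _IMPLEMENTATION_UID
            meta.ImplementationVersionName = "PACSBROKER"

            ds = pydicom.FileDataset(None, {}, file_meta=meta, preamble=b"\0" * 128)
            ds.SOPClassUID = SecondaryCaptureImageStorage
            ds.SOPInstanceUID = sop_uid
            ds.PatientID = spec.canonical_mrn
            ds.PatientName = spec.patient_name
            if spec.birth_date:
                ds.PatientBirthDate = spec.birth_date.replace("-", "")
            ds.AccessionNumber = spec.accession_number
            ds.StudyInstanceUID = spec.study_instance_uid
            ds.SeriesInstanceUID = series_uid
            ds.StudyDate = spec.study_date.replace("-", "")
            ds.SeriesDate = ds.StudyDate
            ds.StudyDescription = spec.study_description
            ds.InstitutionName = spec.institution
            ds.Modality = spec.modality
            ds.SeriesNumber = s
            ds.InstanceNumber = i
            ds.ConversionType = "SYN"
            ds.SamplesPerPixel = 1
            ds.PhotometricInterpretation = "MONOCHROME2"
            ds.Rows = rows
            ds.Columns = cols
            ds.BitsAllocated = 8
            ds.BitsStored = 8
            ds.HighBit = 7
            ds.PixelRepresentation = 0
            ds.PixelData = rng.randint(0, 256, size=rows * cols, dtype=np.uint8).tobytes()
            if spec.padding_bytes:
                # private size-padding element: simulates large studies
                block = ds.private_block(0x0009, "PACSBROKER", create=True)
                pad = spec.padding_bytes + (spec.padding_bytes % 2)
                block.add_new(0x01, "OB", b"\0" * pad)
            out.append(ds)
    return out


def dataset_bytes(ds: pydicom.FileDataset) -> bytes:
    buf = io.BytesIO()
    ds.save_as(buf, enforce_file_format=True)
    return buf.getvalue()


def generate_study(spec: SyntheticStudySpec, out_dir: str | Path) -> list[Path]:
    """Write the study's instances as Part-10 files; returns paths in
    (SeriesNumber, InstanceNumber) order."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for ds in generate_datasets(spec):
        p = out_dir / f"{ds.SeriesNumber:03d}_{ds.InstanceNumber:04d}_{ds.SOPInstanceUID}.dcm"
        p.write_bytes(dataset_bytes(ds))
        paths.append(p)
    return paths


@dataclass(frozen=True)
class MockBehavior:
    """Failure/latency envelope of the mock archive (seeded, reproducible)."""

    association_latency: float = 0.0  # seconds, applied per association
    move_failure_probability: float = 0.0
    offline_fraction: float = 0.0  # fraction of studies on 'off-line' media
    offline_delay: float = 600.0  # seconds before an off-line study moves
    refuse_associations: bool = False
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.move_failure_probability <= 1.0):
            raise ValueError("move_failure_probability must be in [0, 1]")
        if not (0.0 <= self.offline_fraction <= 1.0):
            raise ValueError("offline_fraction must be in [0, 1]")


class MockPacs:
    """In-process Q/R archive over generated studies.

    Records every query (``query_log``) and every association
    (``associations``) for test assertions.
    """

    def __init__(
        self,
        aet: str,
        registry: AERegistry,
        behavior: MockBehavior = MockBehavior(),
        clock: Optional[Clock] = None,
    ):
        self.aet = aet
        self.registry = registry
        self.behavior = behavior
        self.clock = clock
        self._rng = random.Random(behavior.seed)
        self._studies: dict[str, list[pydicom.FileDataset]] = {}
        self._offline: set[str] = set()
        self.query_log: list[tuple[str, dict]] = []
        self.associations: list[dict] = []
        registry.register(aet, self)

    # -- dataset management -------------------------------------------

    def add_study(self, datasets: list[pydicom.FileDataset]) -> str:
        if not datasets:
            raise ValueError("cannot add an empty study")
        uid = datasets[0].StudyInstanceUID
        self._studies.setdefault(uid, []).extend(datasets)
        if self._rng.random() < self.behavior.offline_fraction:
            self._offline.add(uid)
        return uid

    def add_spec(self, spec: SyntheticStudySpec) -> str:
        return self.add_study(generate_datasets(spec))

    @property
    def study_uids(self) -> list[str]:
        return list(self._studies)

    def instance_count(self, study_uid: str) -> int:
        return len(self._studies.get(study_uid, []))

    # -- service primitives -------------------------------------------

    def _associate(self, calling_aet: str, op: str) -> None:
        if self.behavior.refuse_associations:
            raise EndpointUnreachableError(f"{self.aet}: association rejected")
        if self.behavior.association_latency and isinstance(self.clock, VirtualClock):
            self.clock.advance(self.behavior.association_latency)
        self.associations.append({"calling_aet": calling_aet, "op": op})

    def c_echo(self, calling_aet: str) -> bool:
        self._associate(calling_aet, "C-ECHO")
        return True

    def c_find(self, calling_aet: str, level: str, identifier: dict) -> list[dict]:
        self._associate(calling_aet, "C-FIND")
        self.query_log.append((level, dict(identifier)))
        if level == "PATIENT":
            return self._find_patients(identifier)
        if level == "STUDY":
            return self._find_studies(identifier)
        raise ValueError(f"unsupported query level {level!r}")

    def _find_patients(self, identifier: dict) -> list[dict]:
        pid = identifier.get("PatientID", "")
        seen, out = set(), []
        for insts in self._studies.values():
            ds = insts[0]
            if pid and ds.PatientID != pid:
                continue
            if ds.PatientID in seen:
                continue
            seen.add(ds.PatientID)
            out.append(
                {
                    "PatientID": ds.PatientID,
                    "PatientName": str(ds.PatientName),
                    "PatientBirthDate": getattr(ds, "PatientBirthDate", ""),
                }
            )
        return out

    def _find_studies(self, identifier: dict) -> list[dict]:
        pid = identifier.get("PatientID", "")
        accession = identifier.get("AccessionNumber", "")
        out = []
        for uid, insts in self._studies.items():
            ds = insts[0]
            if pid and ds.PatientID != pid:
                continue
            if accession and ds.AccessionNumber != accession:
                continue
            out.append(
                {
                    "PatientID": ds.PatientID,
                    "AccessionNumber": ds.AccessionNumber,
                    "StudyInstanceUID": uid,
                    "StudyDate": getattr(ds, "StudyDate", ""),
                    "ModalitiesInStudy": sorted({d.Modality for d in insts}),
                    "StudyDescription": getattr(ds, "StudyDescription", ""),
                    "InstitutionName": getattr(ds, "InstitutionName", ""),
                }
            )
        return out

    def c_move(self, calling_aet: str, identifier: dict, destination_aet: str) -> MoveOutcome:
        self._associate(calling_aet, "C-MOVE")
        self.query_log.append(("MOVE", dict(identifier)))
        uid = identifier.get("StudyInstanceUID", "")
        insts = self._studies.get(uid)
        if insts is None:
            return MoveOutcome(0, 0, STATUS_FAILURE)
        try:
            dest = self.registry.resolve(destination_aet)
        except NotFoundError:
            return MoveOutcome(0, 0, STATUS_MOVE_DESTINATION_UNKNOWN)
        if uid in self._offline and isinstance(self.clock, VirtualClock):
            self.clock.advance(self.behavior.offline_delay)
        if self._rng.random() < self.behavior.move_failure_probability:
            return MoveOutcome(0, len(insts), STATUS_FAILURE)
        completed = failed = 0
        for ds in insts:
            status = dest.c_store(self.aet, dataset_bytes(ds))
            if status == STATUS_SUCCESS:
                completed += 1
            else:
                failed += 1
        return MoveOutcome(completed, failed, STATUS_SUCCESS)

    def c_store(self, calling_aet: str, part10_bytes: bytes) -> str:
        self._associate(calling_aet, "C-STORE")
        ds = pydicom.dcmread(io.BytesIO(part10_bytes))
        self._studies.setdefault(ds.StudyInstanceUID, []).append(ds)
        return STATUS_SUCCESS


class MockStorage:
    """Bare C-STORE endpoint (stands in for XNAT/workstation targets).

    Keeps the exact bytes received so forwarding tests can assert
    byte-identity.
    """

    def __init__(self, aet: str, registry: AERegistry, accept: bool = True):
        self.aet = aet
        self.accept = accept
        self.received: list[bytes] = []
        registry.register(aet, self)

    def c_echo(self, calling_aet: str) -> bool:
        if not self.accept:
            raise EndpointUnreachableError(f"{self.aet}: association rejected")
        return True

    def c_find(self, calling_aet: str, level: str, identifier: dict) -> list[dict]:
        raise NotImplementedError("storage endpoint is not a Q/R provider")

    def c_move(self, calling_aet: str, identifier: dict, destination_aet: str) -> MoveOutcome:
        raise NotImplementedError("storage endpoint is not a Q/R provider")

    def c_store(self, calling_aet: str, part10_bytes: bytes) -> str:
        if not self.accept:
            raise EndpointUnreachableError(f"{self.aet}: association rejected")
        self.received.append(part10_bytes)
        return STATUS_SUCCESS


# ---------------------------------------------------------------------------
# Scripted workloads
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Workload:
    """Reproducible multi-project scenario for end-to-end tests."""

    projects: tuple[Project, ...]
    specs: dict[str, tuple[SyntheticStudySpec, ...]]  # project_id -> studies
    submission_order: tuple[tuple[str, int], ...]  # (project_id, spec index)
    users: dict[str, str]  # project_id -> submitting member


def generate_workload(
    n_projects: int, n_requests_per_project: int, seed: int
) -> Workload:
    """Deterministic scenario: projects, allowlists, study specs and an
    interleaved submission schedule."""
    if n_projects < 1 or n_requests_per_project < 1:
        raise ValueError("workload sizes must be >= 1")
    rng = random.Random(seed)
    projects, specs, users = [], {}, {}
    for p in range(1, n_projects + 1):
        pid = f"P{p:02d}"
        user = f"user{p:02d}"
        study_specs = []
        mrns = []
        for q in range(n_requests_per_project):
            mrn = f"{seed % 97:02d}{p:02d}{q:04d}"
            mrns.append(mrn)
            study_specs.append(
                SyntheticStudySpec(
                    seed=seed * 10_000 + p * 100 + q,
                    canonical_mrn=mrn,
                    accession_number=f"AN{p:02d}{q:04d}",
                    study_date=f"201{rng.randint(0, 3)}-{rng.randint(1, 12):02d}-{rng.randint(1, 28):02d}",
                    n_series=rng.randint(1, 2),
                    instances_per_series=rng.randint(1, 3),
                    modality=rng.choice(["MR", "CT", "US"]),
                )
            )
        projects.append(
            Project(
                id=pid,
                irb_id=f"IRB-{seed}-{p}",
                members=frozenset({user}),
                allowlist=frozenset(mrns),
                cache_quota_bytes=1 << 30,
            )
        )
        specs[pid] = tuple(study_specs)
        users[pid] = user
    order = [
        (f"P{p:02d}", q)
        for q in range(n_requests_per_project)
        for p in range(1, n_projects + 1)
    ]
    return Workload(tuple(projects), specs, tuple(order), users)
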
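"""DICOM query/retrieve gateway.

The broker's service-class-user face: patient- and study-level C-FIND
(one exact-match query per identifier, no wildcards — access is always by
a predefined list), study-root C-MOVE addressed to the broker's own
storage AE, and C-STORE forwarding of cached studies to other DICOM
entities. The companion :class:`StorageReceiver` is the broker's
service-class-provider face: it accepts the instances a PACS moves toward
the broker and stages them, rejecting anything that does not match an
active retrieval.

Query keys are fixed: PatientID / PatientName / PatientBirthDate at
patient level; PatientID, AccessionNumber, StudyInstanceUID, StudyDate,
ModalitiesInStudy, StudyDescription, InstitutionName at study level.
Dates travel in DICOM DA form (YYYYMMDD) and surface as ISO-8601.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Optional

import pydicom

from .config import GovernancePolicy, PacsEndpoint
from .dimse import STATUS_OUT_OF_RESOURCES, STATUS_SUCCESS, AERegistry, MoveOutcome
from .errors import AuthorizationError, EndpointUnreachableError
from .facets import FacetFilter, apply_facets


def _date_key(iso: Optional[str]) -> int:
    if not iso:
        return 0
    digits = iso.replace("-", "")
    return int(digits) if digits.isdigit() else 0


def _iso_date(da: str) -> Optional[str]:
    da = (da or "").strip()
    if len(da) == 8 and da.isdigit():
        return f"{da[:4]}-{da[4:6]}-{da[6:]}"
    return da or None


@dataclass(frozen=True)
class PatientResult:
    canonical_mrn: str
    patient_name: str
    birth_date: Optional[str]
    source_endpoint_id: str


@dataclass(frozen=True)
class StudyResult:
    canonical_mrn: str
    accession_number: str
    study_instance_uid: str
    study_date: Optional[str]
    modalities: frozenset[str]
    study_description: str
    institution: str
    source_endpoint_id: str
    truncated_flag: bool = False


class DicomGateway:
    """SCU operations against configured PACS endpoints."""

    def __init__(self, registry: AERegistry, broker_aet: str = "PACSBROKER"):
        self.registry = registry
        self.broker_aet = broker_aet

    def _node(self, endpoint: PacsEndpoint):
        return self.registry.resolve(endpoint.aet)

    def echo(self, endpoint: PacsEndpoint) -> bool:
        return self._node(endpoint).c_echo(self.broker_aet)

    def find_patients(
        self,
        endpoint: PacsEndpoint,
        mrns: Iterable[str],
        facets: Optional[FacetFilter] = None,
    ) -> list[PatientResult]:
        """Patient-level C-FIND, one exact query per authorized MRN."""
        node = self._node(endpoint)
        results: list[PatientResult] = []
        for mrn in mrns:
            identifier = {
                "QueryRetrieveLevel": "PATIENT",
                "PatientID": mrn,
                "PatientName": "",
                "PatientBirthDate": "",
            }
            for match in node.c_find(self.broker_aet, "PATIENT", identifier):
                results.append(
                    PatientResult(
                        canonical_mrn=match["PatientID"],
                        patient_name=match.get("PatientName", ""),
                        birth_date=_iso_date(match.get("PatientBirthDate", "")),
                        source_endpoint_id=endpoint.id,
                    )
                )
        return apply_facets(results, facets)

    def find_studies(
        self,
        endpoint: PacsEndpoint,
        policy: GovernancePolicy,
        mrns: Optional[Iterable[str]] = None,
        accessions: Optional[Iterable[str]] = None,
        facets: Optional[FacetFilter] = None,
        authorized_mrns: Optional[frozenset[str]] = None,
    ) -> list[StudyResult]:
        """Study-level C-FIND keyed by MRN list or accession-number list.

        Accession-keyed results are released only after their patient passes
        the allowlist (``authorized_mrns``); per patient, at most the
        policy's ``max_studies_per_patient`` newest studies are returned
        with ``truncated_flag`` set when clipped.
        """
        if (mrns is None) == (accessions is None):
            raise ValueError("provide exactly one of mrns or accessions")
        node = self._node(endpoint)
        raw: list[dict] = []
        keys = list(mrns) if mrns is not None else list(accessions)
        for key in keys:
            identifier = {
                "QueryRetrieveLevel": "STUDY",
                "PatientID": key if mrns is not None else "",
                "AccessionNumber": key if accessions is not None else "",
                "StudyInstanceUID": "",
                "StudyDate": "",
                "ModalitiesInStudy": "",
                "StudyDescription": "",
                "InstitutionName": "",
            }
            raw.extend(node.c_find(self.broker_aet, "STUDY", identifier))

        if accessions is not None and authorized_mrns is not None:
            off_list = sorted({m["PatientID"] for m in raw} - set(authorized_mrns))
            if off_list:
                raise AuthorizationError(
                    "accession lookup resolved to off-allowlist patient(s): "
                    + ", ".join(off_list)
                )

        results = [
            StudyResult(
                canonical_mrn=m["PatientID"],
                accession_number=m.get("AccessionNumber", ""),
                study_instance_uid=m["StudyInstanceUID"],
                study_date=_iso_date(m.get("StudyDate", "")),
                modalities=frozenset(m.get("ModalitiesInStudy", ()) or ()),
                study_description=m.get("StudyDescription", ""),
                institution=m.get("InstitutionName", ""),
                source_endpoint_id=endpoint.id,
            )
            for m in raw
        ]
        results = self._truncate_per_patient(results, policy.max_studies_per_patient)
        return apply_facets(results, facets)

    @staticmethod
    def _truncate_per_patient(
        results: list[StudyResult], limit: Optional[int]
    ) -> list[StudyResult]:
        """Keep the newest ``limit`` studies per patient (StudyDate
        descending, ties by StudyInstanceUID ascending)."""
        if limit is None:
            return results
        by_patient: dict[str, list[StudyResult]] = {}
        for r in results:
            by_patient.setdefault(r.canonical_mrn, []).append(r)
        out: list[StudyResult] = []
        for mrn, rows in by_patient.items():
            rows.sort(key=lambda r: (-(_date_key(r.study_date)), r.study_instance_uid))
            clipped = len(rows) > limit
            for r in rows[:limit]:
                out.append(
                    StudyResult(**{**r.__dict__, "truncated_flag": clipped})
                    if clipped
                    else r
                )
        return out

    def retrieve_study(self, endpoint: PacsEndpoint, study_instance_uid: str) -> MoveOutcome:
        """Study-root C-MOVE toward the broker's own storage AE."""
        identifier = {
            "QueryRetrieveLevel": "STUDY",
            "StudyInstanceUID": study_instance_uid,
        }
        return self._node(endpoint).c_move(self.broker_aet, identifier, self.broker_aet)

    def forward_study(
        self, instance_paths: Iterable[Path], destination_aet: str
    ) -> dict:
        """Send every instance of a cached study via C-STORE.

        Returns per-instance status; raises EndpointUnreachableError with
        the cache untouched when the destination is down.
        """
        node = self.registry.resolve(destination_aet)
        statuses = []
        for p in instance_paths:
            status = node.c_store(self.broker_aet, Path(p).read_bytes())
            statuses.append({"file": Path(p).name, "status": status})
        stored = sum(1 for s in statuses if s["status"] == STATUS_SUCCESS)
        return {"destination": destination_aet, "stored": stored, "instances": statuses}


class StorageReceiver:
    """The broker's C-STORE SCP: stages incoming instances for admission.

    Only instances matching an active (PROCESSING) retrieval are accepted;
    anything unsolicited is rejected out-of-band and reported through
    ``on_reject`` so it can be audited.
    """

    def __init__(
        self,
        aet: str,
        registry: AERegistry,
        staging_for_study: Callable[[str], Optional[Path]],
        on_reject: Optional[Callable[[str], None]] = None,
    ):
        self.aet = aet
        self.staging_for_study = staging_for_study
        self.on_reject = on_reject
        self.rejected: list[str] = []
        registry.register(aet, self)

    def c_echo(self, calling_aet: str) -> bool:
        return True

    def c_find(self, calling_aet: str, level: str, identifier: dict) -> list[dict]:
        raise NotImplementedError("the broker storage AE is not a Q/R provider")

    def c_move(self, calling_aet: str, identifier: dict, destination_aet: str) -> MoveOutcome:
        raise NotImplementedError("the broker storage AE is not a Q/R provider")

    def c_store(self, calling_aet: str, part10_bytes: bytes) -> str:
        ds = pydicom.dcmread(io.BytesIO(part10_bytes), stop_before_pixels=True)
        study_uid = str(ds.StudyInstanceUID)
        staging = self.staging_for_study(study_uid)
        if staging is None:
            self.rejected.append(study_uid)
            if self.on_reject is not None:
                self.on_reject(study_uid)
            return STATUS_OUT_OF_RESOURCES
        staging.mkdir(parents=True, exist_ok=True)
        # keyed by SOPInstanceUID: duplicate delivery overwrites idempotently
        (staging / f"{ds.SOPInstanceUID}.dcm").write_bytes(part10_bytes)
        return STATUS_SUCCESS
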
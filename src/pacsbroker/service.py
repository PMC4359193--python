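"""Broker service: wires access control, gateway, scheduler, cache and audit
into the governed end-to-end workflow (search patients -> search studies ->
request -> dispatch/retrieve -> repository -> download/forward/delete).

Ordering contracts enforced here:

* authorization precedes any PACS traffic; denials are audited as
  ACCESS_DENIED (one event per denial) and denied identifiers never reach
  an outbound query;
* the audit write for an action is durably appended *before* the action
  touches the PACS or the filesystem (write-ahead); if the audit store is
  down the action fails closed;
* retrieval quota gating happens at dispatch (inside the scheduler), and
  every dispatched move ends in a single COMPLETED or FAILED transition
  with its own audit event.
"""

from __future__ import annotations

import datetime as _dt
import shutil
from pathlib import Path
from typing import Optional

from . import access
from .audit import Action, AuditLog
from .cache import CacheEntry, CacheRepository, CacheUsage
from .clock import Clock, VirtualClock
from .config import SystemConfig, normalize_mrn
from .dimse import AERegistry
from .errors import AuthorizationError, EndpointUnreachableError, NotFoundError
from .facets import FacetFilter
from .gateway import DicomGateway, PatientResult, StorageReceiver, StudyResult
from .scheduler import RequestState, RetrievalRequest, Scheduler, StudyRef
from .store import StateStore

BROKER_AET = "PACSBROKER"


class Broker:
    def __init__(
        self,
        config: SystemConfig,
        registry: AERegistry,
        clock: Optional[Clock] = None,
        tz: Optional[_dt.tzinfo] = None,
        broker_aet: str = BROKER_AET,
        state_store: Optional[StateStore] = None,
    ):
        self.config = config
        self.registry = registry
        self.clock = clock or Clock()
        self.tz = tz
        cache_root = Path(config.cache_root)
        cache_root.mkdir(parents=True, exist_ok=True)
        self.store = state_store or StateStore(cache_root / "state.db")
        self.audit = AuditLog(config.audit_store)
        self.cache = CacheRepository(cache_root, self.store, self.clock)
        self.scheduler = Scheduler(
            config,
            self.clock,
            self.store,
            usage_fn=lambda pid: self.cache.usage_tuple(config.project(pid)),
            tz=tz,
            audit=self.audit,
        )
        self.gateway = DicomGateway(registry, broker_aet)
        self._in_flight: dict[str, RetrievalRequest] = {}  # study_uid -> request
        self.receiver = StorageReceiver(
            broker_aet,
            registry,
            staging_for_study=self._staging_for_study,
            on_reject=self._audit_unsolicited,
        )

    # -- helpers -------------------------------------------------------

    def _staging_for_study(self, study_uid: str) -> Optional[Path]:
        req = self._in_flight.get(study_uid)
        if req is None or req.state is not RequestState.PROCESSING:
            return None
        return self.cache.staging_dir(req.id)

    def _audit_unsolicited(self, study_uid: str) -> None:
        self.audit.record(
            timestamp=self.clock.now(), user="<storage-scp>", project_id="<none>",
            action=Action.ACCESS_DENIED,
            detail=f"unsolicited instance rejected study={study_uid}",
        )

    def _project(self, project_id: str):
        try:
            return self.config.project(project_id)
        except KeyError:
            raise NotFoundError(f"unknown project {project_id!r}") from None

    def _endpoint(self, endpoint_id: str):
        try:
            return self.config.endpoint(endpoint_id)
        except KeyError:
            raise NotFoundError(f"unknown endpoint {endpoint_id!r}") from None

    def _audit_denial(self, user, project_id, endpoint_id, decision, what: str) -> None:
        # a partial denial (query proceeds for the on-list subset) is
        # reported as OFF_ALLOWLIST rather than the decision's OK reason
        reason = decision.reason.value if not decision.allowed else "OFF_ALLOWLIST"
        self.audit.record(
            timestamp=self.clock.now(), user=user, project_id=project_id,
            endpoint_id=endpoint_id, action=Action.ACCESS_DENIED,
            detail=f"{what} reason={reason} "
                   f"denied={','.join(decision.denied_mrns) or '-'}",
        )

    def _require_member(self, user: str, project, what: str) -> None:
        now = self.clock.now()
        if not access.project_is_active(project, now, self.tz):
            self.audit.record(
                timestamp=now, user=user, project_id=project.id,
                action=Action.ACCESS_DENIED, detail=f"{what} reason=PROJECT_EXPIRED denied=-",
            )
            raise AuthorizationError(f"project {project.id} has expired")
        if user not in project.members:
            self.audit.record(
                timestamp=now, user=user, project_id=project.id,
                action=Action.ACCESS_DENIED, detail=f"{what} reason=NOT_MEMBER denied=-",
            )
            raise AuthorizationError(f"{user} is not a member of project {project.id}")

    # -- search --------------------------------------------------------

    def search_patients(
        self,
        user: str,
        project_id: str,
        endpoint_id: str,
        raw_mrns: list[str],
        facets: Optional[FacetFilter] = None,
    ) -> tuple[access.AccessDecision, list[PatientResult]]:
        """Authorized patient search; returns the access decision (with any
        denied MRNs) alongside the results."""
        project = self._project(project_id)
        endpoint = self._endpoint(endpoint_id)
        canonical = [normalize_mrn(m, endpoint.mrn_rule) for m in raw_mrns]
        now = self.clock.now()
        decision = access.authorize_patient_query(user, project, canonical, now, self.tz)
        if decision.denied_mrns or not decision.allowed:
            self._audit_denial(user, project_id, endpoint_id, decision, "patient query")
        if not decision.allowed:
            return decision, []
        self.audit.record(  # write-ahead: before any PACS traffic
            timestamp=now, user=user, project_id=project_id, endpoint_id=endpoint_id,
            action=Action.PATIENT_QUERY,
            detail=f"mrns={','.join(decision.filtered_mrns)}",
        )
        results = self.gateway.find_patients(endpoint, decision.filtered_mrns, facets)
        return decision, results

    def search_studies(
        self,
        user: str,
        project_id: str,
        endpoint_id: str,
        raw_mrns: Optional[list[str]] = None,
        accessions: Optional[list[str]] = None,
        facets: Optional[FacetFilter] = None,
    ) -> tuple[access.AccessDecision, list[StudyResult]]:
        """Authorized study search by MRN list or accession-number list."""
        project = self._project(project_id)
        endpoint = self._endpoint(endpoint_id)
        policy = self.config.policy(endpoint_id)
        now = self.clock.now()

        if raw_mrns is not None:
            canonical = [normalize_mrn(m, endpoint.mrn_rule) for m in raw_mrns]
            decision = access.authorize_patient_query(user, project, canonical, now, self.tz)
            if decision.denied_mrns or not decision.allowed:
                self._audit_denial(user, project_id, endpoint_id, decision, "study query")
            if not decision.allowed:
                return decision, []
            self.audit.record(
                timestamp=now, user=user, project_id=project_id, endpoint_id=endpoint_id,
                action=Action.STUDY_QUERY,
                detail=f"mrns={','.join(decision.filtered_mrns)}",
            )
            results = self.gateway.find_studies(
                endpoint, policy, mrns=decision.filtered_mrns, facets=facets
            )
            return decision, results

        if accessions is None:
            raise ValueError("provide raw_mrns or accessions")
        self._require_member(user, project, "accession study query")
        self.audit.record(
            timestamp=now, user=user, project_id=project_id, endpoint_id=endpoint_id,
            action=Action.STUDY_QUERY, detail=f"accessions={','.join(accessions)}",
        )
        try:
            results = self.gateway.find_studies(
                endpoint, policy, accessions=accessions, facets=facets,
                authorized_mrns=project.allowlist,
            )
        except AuthorizationError as exc:
            self.audit.record(
                timestamp=self.clock.now(), user=user, project_id=project_id,
                endpoint_id=endpoint_id, action=Action.ACCESS_DENIED,
                detail=f"accession study query denied: {exc}",
            )
            raise
        decision = access.AccessDecision(
            True, tuple(sorted({r.canonical_mrn for r in results})), (), access.DenialReason.OK
        ) if results else access.AccessDecision(
            False, (), (), access.DenialReason.EMPTY_AFTER_FILTER
        )
        return decision, results

    # -- retrieval -----------------------------------------------------

    def request_study(self, user: str, project_id: str, study: StudyResult) -> RetrievalRequest:
        """Submit one study retrieval; it is queued, governed, and fetched
        on a later dispatch."""
        project = self._project(project_id)
        endpoint = self._endpoint(study.source_endpoint_id)
        now = self.clock.now()
        decision = access.authorize_study_retrieval(
            user, project, study.canonical_mrn, now, self.tz
        )
        if not decision.allowed:
            self._audit_denial(user, project_id, endpoint.id, decision, "retrieval request")
            raise AuthorizationError(
                f"retrieval denied for MRN {study.canonical_mrn}: {decision.reason.value}"
            )
        ref = StudyRef(study.study_instance_uid, study.accession_number, study.canonical_mrn)
        return self.scheduler.submit_request(project, user, endpoint, ref)

    def process_one(self) -> Optional[RetrievalRequest]:
        """Dispatch and execute at most one governed retrieval."""
        req = self.scheduler.next_dispatch()
        if req is None:
            return None
        endpoint = self._endpoint(req.endpoint_id)
        project = self._project(req.project_id)
        uid = req.study_ref.study_instance_uid
        self._in_flight[uid] = req
        staging = self.cache.staging_dir(req.id)
        try:
            outcome = self.gateway.retrieve_study(endpoint, uid)
            if outcome.ok:
                self.cache.admit_study(project, staging)
                self.scheduler.transition(req, RequestState.COMPLETED)
            else:
                reason = (
                    f"move failed: status={outcome.status} "
                    f"completed={outcome.completed} failed={outcome.failed}"
                    if outcome.completed or outcome.failed or outcome.status != "SUCCESS"
                    else "empty study: zero instances received"
                )
                self.scheduler.transition(req, RequestState.FAILED, failure_reason=reason)
        except EndpointUnreachableError as exc:
            self.scheduler.transition(req, RequestState.FAILED, failure_reason=str(exc))
        except Exception as exc:
            self.scheduler.transition(
                req, RequestState.FAILED, failure_reason=f"{type(exc).__name__}: {exc}"
            )
        finally:
            self._in_flight.pop(uid, None)
            if staging.exists():
                shutil.rmtree(staging, ignore_errors=True)
        return req

    def drain(self, max_virtual_seconds: float = 7 * 24 * 3600, step: float = 30.0) -> int:
        """Process the queue to exhaustion, advancing a virtual clock across
        closed windows/rate gaps. Returns the number of dispatches."""
        done = 0
        waited = 0.0
        while self.scheduler.pending() > 0:
            if self.process_one() is not None:
                done += 1
                waited = 0.0
                continue
            if not isinstance(self.clock, VirtualClock) or waited >= max_virtual_seconds:
                break
            self.clock.advance(step)
            waited += step
        return done

    # -- repository ----------------------------------------------------

    def list_cache(self, project_id: str, facets: Optional[FacetFilter] = None) -> list[CacheEntry]:
        return self.cache.list_entries(self._project(project_id), facets)

    def cache_usage(self, project_id: str) -> CacheUsage:
        return self.cache.usage(self._project(project_id))

    def download_study(
        self,
        user: str,
        project_id: str,
        study_uid: str,
        destination: str | Path,
        *,
        encrypt: bool = False,
        passphrase: Optional[str] = None,
        rng=None,
        kdf_iterations: Optional[int] = None,
    ) -> dict:
        if encrypt and not passphrase:
            from .errors import UsageError

            raise UsageError("encrypted download requires a passphrase")
        project = self._project(project_id)
        self._require_member(user, project, "download")
        self.cache.get_entry(project_id, study_uid)  # not-found before audit
        self.audit.record(  # write-ahead: the download attempt is on record
            timestamp=self.clock.now(), user=user, project_id=project_id,
            action=Action.CACHE_DOWNLOAD,
            detail=f"study={study_uid} encrypted={encrypt}",
        )
        kwargs = dict(encrypt=encrypt, passphrase=passphrase, rng=rng)
        if kdf_iterations is not None:
            kwargs["kdf_iterations"] = kdf_iterations
        return self.cache.export_study(project, study_uid, user, destination, **kwargs)

    def delete_study(self, user: str, project_id: str, study_uid: str) -> CacheUsage:
        project = self._project(project_id)
        self._require_member(user, project, "delete")
        self.cache.get_entry(project_id, study_uid)  # not-found before audit
        self.audit.record(
            timestamp=self.clock.now(), user=user, project_id=project_id,
            action=Action.CACHE_DELETE, detail=f"study={study_uid}",
        )
        return self.cache.delete_study(project, study_uid, user)

    def forward_study(
        self, user: str, project_id: str, study_uid: str, destination_aet: str
    ) -> dict:
        project = self._project(project_id)
        self._require_member(user, project, "forward")
        entry = self.cache.get_entry(project_id, study_uid)
        self.audit.record(
            timestamp=self.clock.now(), user=user, project_id=project_id,
            action=Action.CACHE_FORWARD,
            detail=f"study={study_uid} destination={destination_aet}",
        )
        return self.gateway.forward_study(self.cache.instance_paths(entry), destination_aet)

    # -- logs ----------------------------------------------------------

    def request_log(self, **filters) -> list[RetrievalRequest]:
        return self.scheduler.request_log(**filters)

    def audit_events(self, **criteria):
        return self.audit.query_events(**criteria)
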
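"""Fair, rate-governed retrieval scheduling.

Each project owns a FIFO queue of retrieval tickets (one ticket = one
radiological study). Dispatch walks the projects round-robin from a
persistent cursor so every project is served fairly, subject to the
governance negotiated per archive endpoint:

* **time-of-day windows** — retrieval only inside a configured weekly
  window; a window with ``rate_count == 0`` is an explicit block (peak
  clinical hours), and outside all windows nothing moves;
* **transfer rate** — at most ``rate_count`` dispatches in any sliding
  interval of one ``rate_period``. The limiter is a sliding-log bucket:
  each dispatch consumes a token that regenerates exactly one period after
  it was consumed, which enforces the sliding bound strictly (a classic
  refill bucket admits up to twice the rate across a window boundary).
  Token state resets when the active window changes;
* **concurrency cap** — at most ``max_concurrent`` moves in flight per
  endpoint; ``0`` disables retrieval entirely;
* **cache quota gate** — a project at or over its cache quota is skipped
  (its requests stay queued) until the user frees space;
* **re-authorization** — the allowlist/expiration check is re-run at
  dispatch time, so a project expiring while requests sit in the queue
  generates no further PACS traffic; such heads are skipped, not failed.

All timing flows through the injected clock, so window and rate behaviour
is testable deterministically under virtual time.
"""

from __future__ import annotations

import datetime as _dt
import enum
from collections import deque
from dataclasses import dataclass
from typing import Callable, Optional

from . import access
from .audit import Action, AuditLog
from .clock import Clock
from .config import AccessWindow, GovernancePolicy, SystemConfig
from .errors import AuthorizationError, DuplicateRequestError, StateTransitionError
from .store import StateStore


class RequestState(enum.Enum):
    SCHEDULED = "SCHEDULED"
    PROCESSING = "PROCESSING"
    COMPLETED = "COMPLETED"
    FAILED = "FAILED"


_LEGAL = {
    (RequestState.SCHEDULED, RequestState.PROCESSING),
    (RequestState.PROCESSING, RequestState.COMPLETED),
    (RequestState.PROCESSING, RequestState.FAILED),
}


@dataclass(frozen=True)
class StudyRef:
    study_instance_uid: str
    accession_number: str
    canonical_mrn: str


@dataclass
class RetrievalRequest:
    id: str
    project_id: str
    user: str
    endpoint_id: str
    study_ref: StudyRef
    state: RequestState = RequestState.SCHEDULED
    submitted_at: Optional[str] = None
    started_at: Optional[str] = None
    finished_at: Optional[str] = None
    failure_reason: Optional[str] = None

    def to_row(self) -> dict:
        return {
            "id": self.id,
            "project_id": self.project_id,
            "user": self.user,
            "endpoint_id": self.endpoint_id,
            "study_instance_uid": self.study_ref.study_instance_uid,
            "accession_number": self.study_ref.accession_number,
            "canonical_mrn": self.study_ref.canonical_mrn,
            "state": self.state.value,
            "submitted_at": self.submitted_at,
            "started_at": self.started_at,
            "finished_at": self.finished_at,
            "failure_reason": self.failure_reason,
        }

    @classmethod
    def from_row(cls, row: dict) -> "RetrievalRequest":
        return cls(
            id=row["id"],
            project_id=row["project_id"],
            user=row["user"],
            endpoint_id=row["endpoint_id"],
            study_ref=StudyRef(
                row["study_instance_uid"], row["accession_number"], row["canonical_mrn"]
            ),
            state=RequestState(row["state"]),
            submitted_at=row["submitted_at"],
            started_at=row["started_at"],
            finished_at=row["finished_at"],
            failure_reason=row["failure_reason"],
        )


def current_rate(
    policy: GovernancePolicy, now: _dt.datetime, tz: Optional[_dt.tzinfo] = None
) -> Optional[tuple[int, str]]:
    """The (rate_count, rate_period) governing ``now``, or None if blocked
    (no window contains the instant). Windows are start-inclusive,
    end-exclusive."""
    w = _window_at(policy, now, tz)
    return (w.rate_count, w.rate_period) if w is not None else None


def _window_at(
    policy: GovernancePolicy, now: _dt.datetime, tz: Optional[_dt.tzinfo]
) -> Optional[AccessWindow]:
    local = now.astimezone(tz) if tz is not None else now
    return policy.window_at(local.weekday(), local.hour * 60 + local.minute + local.second / 60.0)


class Scheduler:
    """Round-robin governed dispatcher over per-project queues."""

    def __init__(
        self,
        config: SystemConfig,
        clock: Clock,
        store: Optional[StateStore] = None,
        usage_fn: Optional[Callable[[str], tuple[int, int]]] = None,
        tz: Optional[_dt.tzinfo] = None,
        audit: Optional[AuditLog] = None,
    ):
        self.config = config
        self.clock = clock
        self.store = store or StateStore(":memory:")
        self.usage_fn = usage_fn
        self.tz = tz
        self.audit = audit
        self._order = sorted(p.id for p in config.projects)
        self._queues: dict[str, deque[RetrievalRequest]] = {p: deque() for p in self._order}
        self._requests: dict[str, RetrievalRequest] = {}
        self.active: dict[str, int] = {e.id: 0 for e in config.endpoints}
        # sliding-log token state per endpoint
        self._dispatch_log: dict[str, deque[_dt.datetime]] = {e.id: deque() for e in config.endpoints}
        self._last_window: dict[str, Optional[tuple]] = {e.id: None for e in config.endpoints}
        self._restore()

    # -- persistence ---------------------------------------------------

    def _restore(self) -> None:
        for row in self.store.list_requests(states=["SCHEDULED", "PROCESSING"]):
            req = RetrievalRequest.from_row(row)
            self._requests[req.id] = req
            if req.state is RequestState.SCHEDULED:
                if req.project_id in self._queues:
                    self._queues[req.project_id].append(req)
            else:
                self.active[req.endpoint_id] = self.active.get(req.endpoint_id, 0) + 1
        cursor_pid = self.store.get_kv("rr_cursor")
        self._cursor = self._order.index(cursor_pid) if cursor_pid in self._order else 0

    # -- submission ----------------------------------------------------

    def submit_request(self, project, user: str, endpoint, study_ref: StudyRef) -> RetrievalRequest:
        """Queue one study for retrieval.

        Rejects duplicates (same project + study already queued or in
        flight, naming the existing ticket) and unauthorized submissions.
        """
        now = self.clock.now()
        decision = access.authorize_study_retrieval(
            user, project, study_ref.canonical_mrn, now, self.tz
        )
        if not decision.allowed:
            raise AuthorizationError(
                f"retrieval of {study_ref.study_instance_uid} denied: {decision.reason.value}"
            )
        existing = self.store.list_requests(
            project_id=project.id,
            study_instance_uid=study_ref.study_instance_uid,
            states=["SCHEDULED", "PROCESSING"],
        )
        if existing:
            raise DuplicateRequestError(
                f"study {study_ref.study_instance_uid} already requested "
                f"(ticket {existing[0]['id']})",
                existing_ticket=existing[0]["id"],
            )
        req = RetrievalRequest(
            id=self.store.next_ticket(),
            project_id=project.id,
            user=user,
            endpoint_id=endpoint.id,
            study_ref=study_ref,
            submitted_at=now.astimezone(_dt.timezone.utc).isoformat(),
        )
        # write-ahead: the audit record lands before the ticket exists
        if self.audit is not None:
            self.audit.record(
                timestamp=now, user=user, project_id=project.id,
                endpoint_id=endpoint.id, action=Action.RETRIEVE_REQUEST,
                detail=f"ticket={req.id} study={study_ref.study_instance_uid} "
                       f"accession={study_ref.accession_number} mrn={study_ref.canonical_mrn}",
            )
        self.store.insert_request(req.to_row())
        self._requests[req.id] = req
        self._queues.setdefault(project.id, deque()).append(req)
        return req

    # -- dispatch ------------------------------------------------------

    def _tokens_available(self, endpoint_id: str, window: AccessWindow, now: _dt.datetime) -> bool:
        log = self._dispatch_log[endpoint_id]
        ident = (window.days, window.start, window.end, window.rate_count, window.rate_period)
        if self._last_window[endpoint_id] != ident:
            log.clear()
            self._last_window[endpoint_id] = ident
        horizon = now - _dt.timedelta(seconds=window.period_seconds)
        while log and log[0] <= horizon:
            log.popleft()
        return len(log) < window.rate_count

    def _head_eligible(self, req: RetrievalRequest, now: _dt.datetime) -> bool:
        try:
            project = self.config.project(req.project_id)
        except KeyError:
            return False
        if not access.authorize_study_retrieval(
            req.user, project, req.study_ref.canonical_mrn, now, self.tz
        ).allowed:
            return False
        if self.usage_fn is not None:
            used, quota = self.usage_fn(req.project_id)
            if used >= quota:
                return False
        policy = self.config.policy(req.endpoint_id)
        if policy.max_concurrent == 0:
            return False
        if self.active.get(req.endpoint_id, 0) >= policy.max_concurrent:
            return False
        window = _window_at(policy, now, self.tz)
        if window is None or window.rate_count == 0:
            return False
        return self._tokens_available(req.endpoint_id, window, now)

    def next_dispatch(self, now: Optional[_dt.datetime] = None) -> Optional[RetrievalRequest]:
        """Pop and start the next eligible request, or None when nothing can
        move (closed window, empty bucket, concurrency cap, quota-full or
        unauthorized heads, or empty queues)."""
        now = now or self.clock.now()
        n = len(self._order)
        for step in range(n):
            idx = (self._cursor + step) % n
            pid = self._order[idx]
            queue = self._queues.get(pid)
            if not queue:
                continue
            req = queue[0]
            if not self._head_eligible(req, now):
                continue
            queue.popleft()
            req.state = RequestState.PROCESSING
            req.started_at = now.astimezone(_dt.timezone.utc).isoformat()
            self.store.update_request(req.id, state="PROCESSING", started_at=req.started_at)
            self.active[req.endpoint_id] = self.active.get(req.endpoint_id, 0) + 1
            policy = self.config.policy(req.endpoint_id)
            window = _window_at(policy, now, self.tz)
            self._dispatch_log[req.endpoint_id].append(now)
            self._cursor = (idx + 1) % n
            self.store.set_kv("rr_cursor", self._order[self._cursor])
            return req
        return None

    def transition(
        self,
        request: RetrievalRequest,
        outcome: RequestState,
        now: Optional[_dt.datetime] = None,
        failure_reason: Optional[str] = None,
    ) -> RetrievalRequest:
        """Finish an in-flight request (COMPLETED or FAILED with reason)."""
        if outcome not in (RequestState.COMPLETED, RequestState.FAILED):
            raise StateTransitionError(f"outcome must be terminal, got {outcome}")
        if (request.state, outcome) not in _LEGAL:
            raise StateTransitionError(
                f"illegal transition {request.state.value} -> {outcome.value}"
            )
        if outcome is RequestState.FAILED and not failure_reason:
            raise StateTransitionError("FAILED transitions require a failure_reason")
        now = now or self.clock.now()
        request.state = outcome
        request.finished_at = now.astimezone(_dt.timezone.utc).isoformat()
        request.failure_reason = failure_reason
        self.store.update_request(
            request.id,
            state=outcome.value,
            finished_at=request.finished_at,
            failure_reason=failure_reason,
        )
        self.active[request.endpoint_id] = max(0, self.active.get(request.endpoint_id, 0) - 1)
        if self.audit is not None:
            action = (
                Action.RETRIEVE_COMPLETE if outcome is RequestState.COMPLETED else Action.RETRIEVE_FAIL
            )
            detail = f"ticket={request.id} study={request.study_ref.study_instance_uid}"
            if failure_reason:
                detail += f" reason={failure_reason}"
            self.audit.record(
                timestamp=now, user=request.user, project_id=request.project_id,
                endpoint_id=request.endpoint_id, action=action, detail=detail,
            )
        return request

    # -- introspection -------------------------------------------------

    def queue_length(self, project_id: str) -> int:
        return len(self._queues.get(project_id, ()))

    def pending(self) -> int:
        return sum(len(q) for q in self._queues.values())

    def request_log(self, **filters) -> list[RetrievalRequest]:
        return [RetrievalRequest.from_row(r) for r in self.store.list_requests(**filters)]
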
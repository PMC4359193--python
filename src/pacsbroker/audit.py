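"""Append-only audit trail.

Every access-relevant action — patient/study queries, retrieval lifecycle,
cache downloads, deletions, forwards, and denials — produces exactly one
immutable :class:`AuditEvent`, durably written *before* the triggering
operation proceeds (write-ahead). If the audit store cannot accept the
write, the operation itself fails: an action that cannot be logged must not
happen (fail-closed). This is what makes ex post IRB/HIPAA-style review
trustworthy.

Backed by a single SQLite table; ``seq`` is the rowid, so it is strictly
increasing and gap-free for a given store.
"""

from __future__ import annotations

import datetime as _dt
import enum
import sqlite3
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

from .errors import AuditUnavailableError


class Action(enum.Enum):
    PATIENT_QUERY = "PATIENT_QUERY"
    STUDY_QUERY = "STUDY_QUERY"
    RETRIEVE_REQUEST = "RETRIEVE_REQUEST"
    RETRIEVE_COMPLETE = "RETRIEVE_COMPLETE"
    RETRIEVE_FAIL = "RETRIEVE_FAIL"
    CACHE_DOWNLOAD = "CACHE_DOWNLOAD"
    CACHE_DELETE = "CACHE_DELETE"
    CACHE_FORWARD = "CACHE_FORWARD"
    ACCESS_DENIED = "ACCESS_DENIED"


@dataclass(frozen=True)
class AuditEvent:
    seq: int
    timestamp: str  # UTC ISO-8601
    user: str
    project_id: str
    endpoint_id: Optional[str]
    action: Action
    detail: str


_SCHEMA = """
CREATE TABLE IF NOT EXISTS audit_events (
    seq INTEGER PRIMARY KEY AUTOINCREMENT,
    timestamp TEXT NOT NULL,
    user TEXT NOT NULL,
    project_id TEXT NOT NULL,
    endpoint_id TEXT,
    action TEXT NOT NULL,
    detail TEXT NOT NULL
);
"""


class AuditLog:
    """SQLite-backed append-only audit store.

    ``locator`` is a filesystem path or ``":memory:"``.
    """

    def __init__(self, locator: str | Path):
        self._locator = str(locator)
        try:
            self._conn = sqlite3.connect(self._locator)
            self._conn.execute(_SCHEMA)
            self._conn.commit()
        except sqlite3.Error as exc:
            raise AuditUnavailableError(f"audit store unavailable: {exc}") from exc

    def record(
        self,
        *,
        timestamp: _dt.datetime,
        user: str,
        project_id: str,
        action: Action,
        detail: str,
        endpoint_id: Optional[str] = None,
    ) -> AuditEvent:
        """Durably append one event; raises AuditUnavailableError on any
        storage failure so callers can fail closed."""
        if not user or not project_id:
            raise ValueError("audit events require user and project")
        ts = timestamp.astimezone(_dt.timezone.utc).isoformat()
        try:
            cur = self._conn.execute(
                "INSERT INTO audit_events (timestamp, user, project_id, endpoint_id, action, detail)"
                " VALUES (?, ?, ?, ?, ?, ?)",
                (ts, user, project_id, endpoint_id, action.value, detail),
            )
            self._conn.commit()
        except sqlite3.Error as exc:
            raise AuditUnavailableError(f"audit write failed: {exc}") from exc
        return AuditEvent(cur.lastrowid, ts, user, project_id, endpoint_id, action, detail)

    def query_events(
        self,
        *,
        project_id: Optional[str] = None,
        user: Optional[str] = None,
        action: Optional[Action] = None,
        start: Optional[_dt.datetime] = None,
        end: Optional[_dt.datetime] = None,
    ) -> list[AuditEvent]:
        """All and only the matching events, in seq order."""
        clauses, params = [], []
        if project_id is not None:
            clauses.append("project_id = ?"); params.append(project_id)
        if user is not None:
            clauses.append("user = ?"); params.append(user)
        if action is not None:
            clauses.append("action = ?"); params.append(action.value)
        if start is not None:
            clauses.append("timestamp >= ?")
            params.append(start.astimezone(_dt.timezone.utc).isoformat())
        if end is not None:
            clauses.append("timestamp <= ?")
            params.append(end.astimezone(_dt.timezone.utc).isoformat())
        sql = "SELECT seq, timestamp, user, project_id, endpoint_id, action, detail FROM audit_events"
        if clauses:
            sql += " WHERE " + " AND ".join(clauses)
        sql += " ORDER BY seq"
        rows = self._conn.execute(sql, params).fetchall()
        return [
            AuditEvent(r[0], r[1], r[2], r[3], r[4], Action(r[5]), r[6]) for r in rows
        ]

    def close(self) -> None:
        self._conn.close()
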
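"""Persistent state shared by the scheduler and the cache repository.

One SQLite database holds the request log (every retrieval ticket and its
lifecycle), the cache entry index, and a small key/value table (round-robin
cursor, ticket counter) so that a service restart resumes where it left
off. Rows are plain dicts; the owning modules (:mod:`pacsbroker.scheduler`,
:mod:`pacsbroker.cache`) convert to their dataclasses.
"""

from __future__ import annotations

import json
import sqlite3
from pathlib import Path
from typing import Any, Iterable, Optional

_SCHEMA = """
CREATE TABLE IF NOT EXISTS requests (
    id TEXT PRIMARY KEY,
    project_id TEXT NOT NULL,
    user TEXT NOT NULL,
    endpoint_id TEXT NOT NULL,
    study_instance_uid TEXT NOT NULL,
    accession_number TEXT NOT NULL,
    canonical_mrn TEXT NOT NULL,
    state TEXT NOT NULL,
    submitted_at TEXT NOT NULL,
    started_at TEXT,
    finished_at TEXT,
    failure_reason TEXT
);
CREATE TABLE IF NOT EXISTS cache_entries (
    project_id TEXT NOT NULL,
    study_instance_uid TEXT NOT NULL,
    accession_number TEXT NOT NULL,
    canonical_mrn TEXT NOT NULL,
    instance_count INTEGER NOT NULL,
    total_bytes INTEGER NOT NULL,
    admitted_at TEXT NOT NULL,
    modalities TEXT NOT NULL,
    study_date TEXT,
    file_layout TEXT NOT NULL,
    PRIMARY KEY (project_id, study_instance_uid)
);
CREATE TABLE IF NOT EXISTS kv (
    key TEXT PRIMARY KEY,
    value TEXT NOT NULL
);
"""

_REQ_COLS = (
    "id", "project_id", "user", "endpoint_id", "study_instance_uid",
    "accession_number", "canonical_mrn", "state", "submitted_at",
    "started_at", "finished_at", "failure_reason",
)
_CACHE_COLS = (
    "project_id", "study_instance_uid", "accession_number", "canonical_mrn",
    "instance_count", "total_bytes", "admitted_at", "modalities",
    "study_date", "file_layout",
)


class StateStore:
    def __init__(self, locator: str | Path = ":memory:"):
        self._conn = sqlite3.connect(str(locator))
        self._conn.executescript(_SCHEMA)
        self._conn.commit()

    # -- key/value -----------------------------------------------------

    def get_kv(self, key: str, default: Optional[str] = None) -> Optional[str]:
        row = self._conn.execute("SELECT value FROM kv WHERE key = ?", (key,)).fetchone()
        return row[0] if row else default

    def set_kv(self, key: str, value: str) -> None:
        self._conn.execute(
            "INSERT INTO kv (key, value) VALUES (?, ?)"
            " ON CONFLICT(key) DO UPDATE SET value = excluded.value",
            (key, value),
        )
        self._conn.commit()

    def next_ticket(self) -> str:
        n = int(self.get_kv("ticket_counter", "0")) + 1
        self.set_kv("ticket_counter", str(n))
        return f"R{n:06d}"

    # -- request log ---------------------------------------------------

    def insert_request(self, row: dict[str, Any]) -> None:
        self._conn.execute(
            f"INSERT INTO requests ({', '.join(_REQ_COLS)}) VALUES ({', '.join('?' * len(_REQ_COLS))})",
            tuple(row.get(c) for c in _REQ_COLS),
        )
        self._conn.commit()

    def update_request(self, request_id: str, **fields: Any) -> None:
        cols = ", ".join(f"{k} = ?" for k in fields)
        self._conn.execute(
            f"UPDATE requests SET {cols} WHERE id = ?", (*fields.values(), request_id)
        )
        self._conn.commit()

    def get_request(self, request_id: str) -> Optional[dict[str, Any]]:
        row = self._conn.execute(
            f"SELECT {', '.join(_REQ_COLS)} FROM requests WHERE id = ?", (request_id,)
        ).fetchone()
        return dict(zip(_REQ_COLS, row)) if row else None

    def list_requests(
        self,
        *,
        project_id: Optional[str] = None,
        user: Optional[str] = None,
        states: Optional[Iterable[str]] = None,
        study_instance_uid: Optional[str] = None,
    ) -> list[dict[str, Any]]:
        clauses, params = [], []
        if project_id is not None:
            clauses.append("project_id = ?"); params.append(project_id)
        if user is not None:
            clauses.append("user = ?"); params.append(user)
        if study_instance_uid is not None:
            clauses.append("study_instance_uid = ?"); params.append(study_instance_uid)
        if states is not None:
            states = list(states)
            clauses.append(f"state IN ({', '.join('?' * len(states))})")
            params.extend(states)
        sql = f"SELECT {', '.join(_REQ_COLS)} FROM requests"
        if clauses:
            sql += " WHERE " + " AND ".join(clauses)
        sql += " ORDER BY submitted_at, id"
        return [dict(zip(_REQ_COLS, r)) for r in self._conn.execute(sql, params)]

    # -- cache entry index ---------------------------------------------

    def insert_cache_entry(self, row: dict[str, Any]) -> None:
        row = dict(row)
        row["file_layout"] = json.dumps(row["file_layout"])
        row["modalities"] = json.dumps(sorted(row["modalities"]))
        self._conn.execute(
            f"INSERT INTO cache_entries ({', '.join(_CACHE_COLS)}) VALUES ({', '.join('?' * len(_CACHE_COLS))})",
            tuple(row.get(c) for c in _CACHE_COLS),
        )
        self._conn.commit()

    def delete_cache_entry(self, project_id: str, study_instance_uid: str) -> int:
        cur = self._conn.execute(
            "DELETE FROM cache_entries WHERE project_id = ? AND study_instance_uid = ?",
            (project_id, study_instance_uid),
        )
        self._conn.commit()
        return cur.rowcount

    def get_cache_entry(self, project_id: str, study_instance_uid: str) -> Optional[dict[str, Any]]:
        row = self._conn.execute(
            f"SELECT {', '.join(_CACHE_COLS)} FROM cache_entries"
            " WHERE project_id = ? AND study_instance_uid = ?",
            (project_id, study_instance_uid),
        ).fetchone()
        return self._decode_cache(row) if row else None

    def list_cache_entries(self, project_id: str) -> list[dict[str, Any]]:
        rows = self._conn.execute(
            f"SELECT {', '.join(_CACHE_COLS)} FROM cache_entries WHERE project_id = ?"
            " ORDER BY admitted_at DESC, study_instance_uid",
            (project_id,),
        ).fetchall()
        return [self._decode_cache(r) for r in rows]

    @staticmethod
    def _decode_cache(row) -> dict[str, Any]:
        d = dict(zip(_CACHE_COLS, row))
        d["file_layout"] = json.loads(d["file_layout"])
        d["modalities"] = set(json.loads(d["modalities"]))
        return d

    def close(self) -> None:
        self._conn.close()
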
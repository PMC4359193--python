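"""Per-project quota-limited image repository.

Retrieved studies land in a staging area (written by the storage receiver)
and are *admitted* atomically into the owning project's cache directory.
Usage accounting is truthful: a study whose size was unknown before
transfer may push a project over quota, the overflow is reported as-is, and
the scheduler's quota gate then blocks further dispatch until the user
deletes studies. Deletion, listing, download (plaintext or encrypted) and
forwarding all live here.

On-disk layout: ``<cache_root>/<project_id>/<study_instance_uid>/<files>``;
plaintext exports use ``<mrn>/<study_uid>/<series>/<instance>.dcm``.
"""

from __future__ import annotations

import datetime as _dt
import shutil
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import pydicom

from . import crypto
from .config import Project
from .errors import (
    AuthorizationError,
    EmptyStudyError,
    NotFoundError,
    StagingCorruptionError,
    UsageError,
)
from .facets import FacetFilter, apply_facets
from .store import StateStore


@dataclass(frozen=True)
class CacheEntry:
    """One retrieved study resident in a project's cache."""

    project_id: str
    study_instance_uid: str
    accession_number: str
    canonical_mrn: str
    instance_count: int
    total_bytes: int
    admitted_at: str
    modalities: frozenset[str]
    study_date: Optional[str]
    file_layout: tuple[dict, ...]  # (SeriesNumber, InstanceNumber, SOPInstanceUID) ascending

    @classmethod
    def from_row(cls, row: dict) -> "CacheEntry":
        return cls(
            project_id=row["project_id"],
            study_instance_uid=row["study_instance_uid"],
            accession_number=row["accession_number"],
            canonical_mrn=row["canonical_mrn"],
            instance_count=row["instance_count"],
            total_bytes=row["total_bytes"],
            admitted_at=row["admitted_at"],
            modalities=frozenset(row["modalities"]),
            study_date=row.get("study_date"),
            file_layout=tuple(row["file_layout"]),
        )


@dataclass(frozen=True)
class CacheUsage:
    project_id: str
    used_bytes: int
    quota_bytes: int
    entries: int


class CacheRepository:
    def __init__(self, cache_root: str | Path, store: StateStore, clock=None):
        self.root = Path(cache_root)
        self.root.mkdir(parents=True, exist_ok=True)
        self.store = store
        self.clock = clock

    # -- paths ---------------------------------------------------------

    def project_dir(self, project_id: str) -> Path:
        return self.root / project_id

    def study_dir(self, project_id: str, study_uid: str) -> Path:
        return self.project_dir(project_id) / study_uid

    def staging_dir(self, request_id: str) -> Path:
        return self.root / "staging" / request_id

    def instance_paths(self, entry: CacheEntry) -> list[Path]:
        base = self.study_dir(entry.project_id, entry.study_instance_uid)
        return [base / item["filename"] for item in entry.file_layout]

    # -- admission -----------------------------------------------------

    def admit_study(self, project: Project, staging: str | Path) -> CacheEntry:
        """Atomically move one staged study into the project cache.

        Admission proceeds even when it overflows the quota (the size of a
        study is unknown before transfer); the scheduler gate handles the
        consequence. Mixed studies in one staging area are corruption.
        """
        staging = Path(staging)
        files = sorted(p for p in staging.glob("*.dcm") if p.is_file())
        if not files:
            raise EmptyStudyError(f"staging {staging} holds no instances")
        layout, uids, modalities, study_dates = [], set(), set(), set()
        accession = mrn = ""
        total = 0
        for p in files:
            ds = pydicom.dcmread(p, stop_before_pixels=True)
            uids.add(ds.StudyInstanceUID)
            modalities.add(str(getattr(ds, "Modality", "")))
            study_dates.add(str(getattr(ds, "StudyDate", "")))
            accession = str(getattr(ds, "AccessionNumber", accession))
            mrn = str(getattr(ds, "PatientID", mrn))
            size = p.stat().st_size
            total += size
            layout.append(
                {
                    "filename": p.name,
                    "sop_instance_uid": str(ds.SOPInstanceUID),
                    "series_number": int(getattr(ds, "SeriesNumber", 0) or 0),
                    "instance_number": int(getattr(ds, "InstanceNumber", 0) or 0),
                    "bytes": size,
                }
            )
        if len(uids) != 1:
            raise StagingCorruptionError(
                f"staging {staging} mixes study UIDs: {sorted(uids)}"
            )
        study_uid = uids.pop()
        layout.sort(
            key=lambda d: (d["series_number"], d["instance_number"], d["sop_instance_uid"])
        )
        dest = self.study_dir(project.id, study_uid)
        if dest.exists():
            shutil.rmtree(dest)
        dest.parent.mkdir(parents=True, exist_ok=True)
        shutil.move(str(staging), str(dest))

        admitted_at = (
            self.clock.now() if self.clock else _dt.datetime.now(_dt.timezone.utc)
        ).astimezone(_dt.timezone.utc).isoformat()
        date = max(d for d in study_dates) if study_dates else None
        row = {
            "project_id": project.id,
            "study_instance_uid": study_uid,
            "accession_number": accession,
            "canonical_mrn": mrn,
            "instance_count": len(layout),
            "total_bytes": total,
            "admitted_at": admitted_at,
            "modalities": {m for m in modalities if m},
            "study_date": date,
            "file_layout": layout,
        }
        self.store.delete_cache_entry(project.id, study_uid)  # re-admission replaces
        self.store.insert_cache_entry(row)
        return CacheEntry.from_row(self.store.get_cache_entry(project.id, study_uid))

    # -- accounting ----------------------------------------------------

    def usage(self, project: Project) -> CacheUsage:
        rows = self.store.list_cache_entries(project.id)
        return CacheUsage(
            project_id=project.id,
            used_bytes=sum(r["total_bytes"] for r in rows),
            quota_bytes=project.cache_quota_bytes,
            entries=len(rows),
        )

    def usage_tuple(self, project: Project) -> tuple[int, int]:
        u = self.usage(project)
        return u.used_bytes, u.quota_bytes

    # -- listing / deletion --------------------------------------------

    def get_entry(self, project_id: str, study_uid: str) -> CacheEntry:
        row = self.store.get_cache_entry(project_id, study_uid)
        if row is None:
            raise NotFoundError(f"no cached study {study_uid} for project {project_id}")
        return CacheEntry.from_row(row)

    def list_entries(
        self, project: Project, facets: Optional[FacetFilter] = None
    ) -> list[CacheEntry]:
        """Project entries, newest admission first, facet-filtered with the
        same semantics as query-result filtering."""
        entries = [CacheEntry.from_row(r) for r in self.store.list_cache_entries(project.id)]
        if facets is not None:
            entries = apply_facets(entries, facets)
        return entries

    def delete_study(self, project: Project, study_uid: str, user: str) -> CacheUsage:
        if user not in project.members:
            raise AuthorizationError(f"{user} is not a member of project {project.id}")
        entry = self.get_entry(project.id, study_uid)  # raises NotFoundError
        shutil.rmtree(self.study_dir(project.id, study_uid), ignore_errors=True)
        self.store.delete_cache_entry(project.id, study_uid)
        return self.usage(project)

    # -- export --------------------------------------------------------

    def export_study(
        self,
        project: Project,
        study_uid: str,
        user: str,
        destination: str | Path,
        *,
        encrypt: bool = False,
        passphrase: Optional[str] = None,
        kdf_iterations: int = crypto.DEFAULT_ITERATIONS,
        rng=None,
        opener=open,
    ) -> dict:
        """Download a cached study to ``destination``.

        Plaintext mode copies Part-10 files byte-identically under
        ``mrn/study/series/instance.dcm``; encrypted mode writes only
        ciphertext with obfuscated order-preserving names.
        Returns an export manifest (mode, files written).
        """
        if user not in project.members:
            raise AuthorizationError(f"{user} is not a member of project {project.id}")
        if encrypt and not passphrase:
            raise UsageError("encrypted export requires a passphrase")
        entry = self.get_entry(project.id, study_uid)
        destination = Path(destination)
        written: list[str] = []
        if encrypt:
            manifest = crypto.encrypt_study_export(
                entry,
                self.instance_paths(entry),
                destination,
                passphrase,
                iterations=kdf_iterations,
                rng=rng,
                opener=opener,
            )
            written = [crypto.MANIFEST_NAME, *manifest.names]
        else:
            for item, src in zip(entry.file_layout, self.instance_paths(entry)):
                rel = (
                    Path(entry.canonical_mrn)
                    / entry.study_instance_uid
                    / str(item["series_number"])
                    / f"{item['instance_number']}.dcm"
                )
                target = destination / rel
                target.parent.mkdir(parents=True, exist_ok=True)
                shutil.copyfile(src, target)
                written.append(str(rel))
        return {
            "mode": "encrypted" if encrypt else "plaintext",
            "study_instance_uid": study_uid,
            "files": written,
        }
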
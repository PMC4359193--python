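"""IRB access enforcement.

Every patient query and every study retrieval is checked against the
requesting project's allowlist, membership and expiration *before* any PACS
traffic is generated. Denial is a value (an :class:`AccessDecision`), not an
exception, so that the audit trail can record exactly what was refused and
why.

Expiration is inclusive of the stated date: access stops at the first
instant of the following day in the service time zone, matching the usual
IRB approval-period convention.
"""

from __future__ import annotations

import datetime as _dt
import enum
from dataclasses import dataclass
from typing import Iterable, Optional

from .config import Project


class DenialReason(enum.Enum):
    OK = "OK"
    PROJECT_EXPIRED = "PROJECT_EXPIRED"
    NOT_MEMBER = "NOT_MEMBER"
    EMPTY_AFTER_FILTER = "EMPTY_AFTER_FILTER"


@dataclass(frozen=True)
class AccessDecision:
    allowed: bool
    filtered_mrns: tuple[str, ...]
    denied_mrns: tuple[str, ...]
    reason: DenialReason = DenialReason.OK

    def __post_init__(self):
        assert self.allowed == (self.reason is DenialReason.OK and bool(self.filtered_mrns))
        assert not set(self.filtered_mrns) & set(self.denied_mrns)


def project_is_active(
    project: Project,
    now: _dt.datetime,
    tz: Optional[_dt.tzinfo] = None,
) -> bool:
    """True while the project's IRB approval has not lapsed.

    A project with no expiration never lapses; one with an expiration is
    active through the whole of that calendar date (service time zone).
    """
    if project.expiration is None:
        return True
    local = now.astimezone(tz) if tz is not None else now
    return local.date() <= project.expiration


def authorize_patient_query(
    user: str,
    project: Project,
    mrns: Iterable[str],
    now: _dt.datetime,
    tz: Optional[_dt.tzinfo] = None,
) -> AccessDecision:
    """Filter a patient-level query against the project allowlist.

    Partial filtering: on-list MRNs proceed, off-list MRNs are denied (and
    later audited); membership or expiration failures deny everything.
    """
    mrns = tuple(dict.fromkeys(mrns))  # dedupe, keep order
    if not project_is_active(project, now, tz):
        return AccessDecision(False, (), mrns, DenialReason.PROJECT_EXPIRED)
    if user not in project.members:
        return AccessDecision(False, (), mrns, DenialReason.NOT_MEMBER)
    allowed = tuple(m for m in mrns if m in project.allowlist)
    denied = tuple(m for m in mrns if m not in project.allowlist)
    if not allowed:
        return AccessDecision(False, (), denied, DenialReason.EMPTY_AFTER_FILTER)
    return AccessDecision(True, allowed, denied, DenialReason.OK)


def authorize_study_retrieval(
    user: str,
    project: Project,
    canonical_mrn: str,
    now: _dt.datetime,
    tz: Optional[_dt.tzinfo] = None,
) -> AccessDecision:
    """Authorize retrieval of one study by its patient's canonical MRN.

    Closes the loophole of retrieving a study whose patient is off-list:
    the same allowlist gate applies at study granularity, and it is re-run
    at dispatch time so a project expiring while requests sit in the queue
    stops them.
    """
    return authorize_patient_query(user, project, (canonical_mrn,), now, tz)
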
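"""System data model and configuration loading.

The broker is driven by one structured YAML file that encodes the PACS
endpoints it may talk to, the governance policy negotiated with each
endpoint's radiology department (time-of-day access windows, transfer rates,
concurrency caps, per-patient study limits), and the research projects
(IRB-scoped tenants) allowed to use it. Loading validates every invariant up
front so that a running service never discovers a malformed policy mid-
dispatch.

Medical record numbers (MRNs) arrive in site-specific formats (dashes,
case, zero-padding, site prefixes). Each endpoint carries an
:class:`MrnFormatRule`; comparisons anywhere in the broker happen on the
canonical form only. Project allowlists are canonicalized once at load time
with the endpoint-independent default rule.
"""

from __future__ import annotations

import datetime as _dt
from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, field_validator, model_validator

from .errors import ConfigSyntaxError, ConfigValidationError, InvalidMrnError

DAY_NAMES = ("Mon", "Tue", "Wed", "Thu", "Fri", "Sat", "Sun")

_PRINTABLE = set(chr(c) for c in range(0x20, 0x7F)) - {"\\"}


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)


class MrnFormatRule(_Model):
    """Normalization recipe turning a site-format MRN into canonical form.

    Applied as: drop an already-present ``prefix``, remove ``strip_chars``,
    uppercase, left zero-pad to ``pad_width``, prepend ``prefix``. Dropping
    an existing prefix first makes the transform idempotent.
    """

    strip_chars: str = ""
    uppercase: bool = False
    pad_width: Optional[int] = Field(default=None, ge=1)
    prefix: Optional[str] = None


#: Rule applied to project allowlists at configuration load time. User input
#: is normalized per-endpoint at query time; allowlists need one site-neutral
#: canonical form so a single project can span endpoints.
DEFAULT_MRN_RULE = MrnFormatRule(strip_chars="- ", uppercase=True)


def normalize_mrn(raw: str, rule: MrnFormatRule = DEFAULT_MRN_RULE) -> str:
    """Return the canonical form of ``raw`` under ``rule``.

    Deterministic and idempotent; raises :class:`InvalidMrnError` when
    nothing remains after stripping.
    """
    s = raw
    if rule.prefix and s.startswith(rule.prefix):
        s = s[len(rule.prefix):]
    for ch in rule.strip_chars:
        s = s.replace(ch, "")
    s = s.strip()
    if rule.uppercase:
        s = s.upper()
    if not s:
        raise InvalidMrnError(f"MRN {raw!r} is empty after stripping")
    if rule.pad_width is not None:
        s = s.rjust(rule.pad_width, "0")
    if rule.prefix:
        s = rule.prefix + s
    return s


class PacsEndpoint(_Model):
    """One reachable archive: network identity plus display labels."""

    id: str = Field(min_length=1)
    institution: str = Field(min_length=1)
    department: Optional[str] = None
    aet: str
    host: str = Field(min_length=1)
    port: int = Field(ge=1, le=65535)
    mrn_rule: MrnFormatRule = Field(default_factory=MrnFormatRule)

    @field_validator("aet")
    @classmethod
    def _aet_valid(cls, v: str) -> str:
        if not (1 <= len(v) <= 16) or not set(v) <= _PRINTABLE:
            raise ValueError(
                "aet: application-entity title must be 1-16 printable characters"
            )
        return v


class AccessWindow(_Model):
    """One recurring weekly slot during which retrievals may run.

    ``start``/``end`` are minutes of day; containment is half-open
    ``[start, end)``. ``rate_count == 0`` marks a window where retrieval is
    explicitly blocked (e.g. peak clinical hours).
    """

    days: tuple[str, ...]
    start: int = Field(ge=0, lt=1440)
    end: int = Field(gt=0, le=1440)
    rate_count: int = Field(ge=0)
    rate_period: str

    @field_validator("days")
    @classmethod
    def _days_valid(cls, v: tuple[str, ...]) -> tuple[str, ...]:
        bad = [d for d in v if d not in DAY_NAMES]
        if bad or not v:
            raise ValueError(f"days: must be a non-empty subset of {DAY_NAMES}, got {bad or v}")
        return v

    @field_validator("rate_period")
    @classmethod
    def _period_valid(cls, v: str) -> str:
        if v not in ("minute", "hour"):
            raise ValueError("rate_period: must be 'minute' or 'hour'")
        return v

    @model_validator(mode="after")
    def _start_before_end(self) -> "AccessWindow":
        if not self.start < self.end:
            raise ValueError(
                f"start: window start ({self.start}) must be < end ({self.end})"
            )
        return self

    @property
    def period_seconds(self) -> int:
        return 60 if self.rate_period == "minute" else 3600

    def intervals(self):
        """Expand to (day-index, start-minute, end-minute) triples."""
        for d in self.days:
            yield DAY_NAMES.index(d), self.start, self.end

    def contains(self, day_index: int, minute: float) -> bool:
        return any(
            d == day_index and s <= minute < e for d, s, e in self.intervals()
        )


class GovernancePolicy(_Model):
    """Per-endpoint governance negotiated with the archive's operators."""

    windows: tuple[AccessWindow, ...] = ()
    max_concurrent: int = Field(ge=0)
    max_studies_per_patient: Optional[int] = Field(default=None, ge=1)

    @model_validator(mode="after")
    def _windows_disjoint(self) -> "GovernancePolicy":
        seen: list[tuple[int, int, int]] = []
        for w in self.windows:
            for day, s, e in w.intervals():
                for day2, s2, e2 in seen:
                    if day == day2 and s < e2 and s2 < e:
                        raise ValueError(
                            f"windows: overlapping windows on {DAY_NAMES[day]} "
                            f"({s}-{e} vs {s2}-{e2})"
                        )
                seen.append((day, s, e))
        return self

    def window_at(self, day_index: int, minute: float) -> Optional[AccessWindow]:
        for w in self.windows:
            if w.contains(day_index, minute):
                return w
        return None


class Project(_Model):
    """An IRB-scoped tenant: who may act, which patients, until when."""

    id: str = Field(min_length=1)
    irb_id: str
    members: frozenset[str] = Field(min_length=1)
    allowlist: frozenset[str] = Field(min_length=1)
    expiration: Optional[_dt.date] = None
    cache_quota_bytes: int = Field(gt=0)


class SystemConfig(_Model):
    endpoints: tuple[PacsEndpoint, ...]
    policies: dict[str, GovernancePolicy]
    projects: tuple[Project, ...]
    cache_root: str
    audit_store: str

    @model_validator(mode="after")
    def _cross_checks(self) -> "SystemConfig":
        ids = [e.id for e in self.endpoints]
        if len(set(ids)) != len(ids):
            raise ValueError("endpoints: duplicate endpoint id")
        for key in self.policies:
            if key not in ids:
                raise ValueError(f"policies: policy references unknown endpoint id {key!r}")
        for e in self.endpoints:
            if e.id not in self.policies:
                raise ValueError(f"policies: endpoint {e.id!r} has no policy")
        pids = [p.id for p in self.projects]
        if len(set(pids)) != len(pids):
            raise ValueError("projects: duplicate project id")
        return self

    def endpoint(self, endpoint_id: str) -> PacsEndpoint:
        for e in self.endpoints:
            if e.id == endpoint_id:
                return e
        raise KeyError(endpoint_id)

    def project(self, project_id: str) -> Project:
        for p in self.projects:
            if p.id == project_id:
                return p
        raise KeyError(project_id)

    def policy(self, endpoint_id: str) -> GovernancePolicy:
        return self.policies[endpoint_id]


def _windows_from_raw(raw) -> list[dict]:
    out = []
    for w in raw or []:
        w = dict(w)
        for key in ("start", "end"):
            v = w.get(key)
            if isinstance(v, str) and ":" in v:
                h, m = v.split(":")
                w[key] = int(h) * 60 + int(m)
        out.append(w)
    return out


def load_config(source: str | Path) -> SystemConfig:
    """Load and validate a configuration file (YAML text or path).

    Allowlist entries are canonicalized through :data:`DEFAULT_MRN_RULE`.
    Raises :class:`ConfigSyntaxError` (naming the line) on parse failure and
    :class:`ConfigValidationError` (naming field and rule) on any invariant
    violation.
    """
    if isinstance(source, Path) or (
        isinstance(source, str) and "\n" not in source and source.endswith((".yaml", ".yml"))
    ):
        text = Path(source).read_text()
    else:
        text = str(source)
    try:
        raw = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        line = mark.line + 1 if mark is not None else "?"
        raise ConfigSyntaxError(f"configuration syntax error at line {line}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigSyntaxError("configuration syntax error: document is not a mapping")

    raw = dict(raw)
    for pol in (raw.get("policies") or {}).values():
        if isinstance(pol, dict):
            pol["windows"] = _windows_from_raw(pol.get("windows"))
    for proj in raw.get("projects") or []:
        if isinstance(proj, dict) and isinstance(proj.get("allowlist"), list):
            try:
                proj["allowlist"] = [normalize_mrn(m, DEFAULT_MRN_RULE) for m in proj["allowlist"]]
            except InvalidMrnError as exc:
                raise ConfigValidationError(f"allowlist: {exc}") from exc
        if isinstance(proj, dict) and isinstance(proj.get("expiration"), str):
            proj["expiration"] = _dt.date.fromisoformat(proj["expiration"])

    try:
        return SystemConfig.model_validate(raw)
    except ValidationError as exc:
        first = exc.errors()[0]
        loc = ".".join(str(p) for p in first["loc"])
        raise ConfigValidationError(
            f"invalid configuration: {loc}: {first['msg']}"
        ) from exc


def serialize(config: SystemConfig) -> str:
    """Render ``config`` back to the configuration dialect.

    ``load_config(serialize(load_config(x)))`` is a fixed point.
    """
    def _win(w: AccessWindow) -> dict:
        return {
            "days": list(w.days), "start": w.start, "end": w.end,
            "rate_count": w.rate_count, "rate_period": w.rate_period,
        }

    doc = {
        "endpoints": [
            {
                "id": e.id, "institution": e.institution, "department": e.department,
                "aet": e.aet, "host": e.host, "port": e.port,
                "mrn_rule": {
                    "strip_chars": e.mrn_rule.strip_chars,
                    "uppercase": e.mrn_rule.uppercase,
                    "pad_width": e.mrn_rule.pad_width,
                    "prefix": e.mrn_rule.prefix,
                },
            }
            for e in config.endpoints
        ],
        "policies": {
            eid: {
                "max_concurrent": p.max_concurrent,
                "max_studies_per_patient": p.max_studies_per_patient,
                "windows": [_win(w) for w in p.windows],
            }
            for eid, p in config.policies.items()
        },
        "projects": [
            {
                "id": p.id, "irb_id": p.irb_id,
                "members": sorted(p.members),
                "allowlist": sorted(p.allowlist),
                "expiration": p.expiration.isoformat() if p.expiration else None,
                "cache_quota_bytes": p.cache_quota_bytes,
            }
            for p in config.projects
        ],
        "cache_root": config.cache_root,
        "audit_store": config.audit_store,
    }
    return yaml.safe_dump(doc, sort_keys=False)
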
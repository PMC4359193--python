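"""Injectable clocks.

All scheduling, expiration and audit timestamps flow through a ``Clock`` so
that governance behaviour (time-of-day windows, rates, expirations) is
testable deterministically under virtual time. Clocks produce timezone-aware
UTC datetimes; window containment converts to the service time zone at the
point of evaluation.
"""

from __future__ import annotations

import datetime as _dt


class Clock:
    """Wall clock (UTC)."""

    def now(self) -> _dt.datetime:
        return _dt.datetime.now(_dt.timezone.utc)


class VirtualClock(Clock):
    """Deterministic clock for tests and simulations.

    Starts at ``start`` (aware datetime; naive input is taken as UTC) and
    only moves when :meth:`advance` or :meth:`set` is called.
    """

    def __init__(self, start: _dt.datetime | None = None):
        if start is None:
            # A Monday, 00:00 UTC — convenient anchor for day-of-week windows.
            start = _dt.datetime(2014, 6, 2, 0, 0, tzinfo=_dt.timezone.utc)
        if start.tzinfo is None:
            start = start.replace(tzinfo=_dt.timezone.utc)
        self._now = start

    def now(self) -> _dt.datetime:
        return self._now

    def advance(self, seconds: float) -> _dt.datetime:
        if seconds < 0:
            raise ValueError("clock cannot move backwards")
        self._now = self._now + _dt.timedelta(seconds=seconds)
        return self._now

    def set(self, when: _dt.datetime) -> _dt.datetime:
        if when.tzinfo is None:
            when = when.replace(tzinfo=_dt.timezone.utc)
        if when < self._now:
            raise ValueError("clock cannot move backwards")
        self._now = when
        return self._now
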
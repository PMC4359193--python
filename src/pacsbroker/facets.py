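"""Faceted result filtering.

Search-result tables (patients, studies, cache entries, request log) can be
narrowed column by column: ordered columns (dates, numbers) take a range,
categorical columns (modality, institution) take a value set with checkbox
semantics. A row survives only if it passes *every* filtered column
(conjunction across columns), and passes a value-set column if its value —
or, for set-valued fields like a study's modalities, *any* of its values —
is in the set (disjunction within a column).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping, Optional, Sequence


@dataclass(frozen=True)
class FacetFilter:
    """Per-column predicates, ANDed across columns.

    ``ranges`` maps column name -> (low, high), inclusive on both ends;
    either bound may be None for open-ended. ``value_sets`` maps column
    name -> allowed values.
    """

    ranges: Mapping[str, tuple[Optional[Any], Optional[Any]]] = field(default_factory=dict)
    value_sets: Mapping[str, frozenset] = field(default_factory=dict)

    @classmethod
    def empty(cls) -> "FacetFilter":
        return cls()

    def matches(self, row: Any) -> bool:
        for col, (lo, hi) in self.ranges.items():
            value = _get(row, col)
            if value is None:
                return False
            if lo is not None and value < lo:
                return False
            if hi is not None and value > hi:
                return False
        for col, allowed in self.value_sets.items():
            value = _get(row, col)
            if isinstance(value, (set, frozenset, list, tuple)):
                if not any(v in allowed for v in value):
                    return False
            elif value not in allowed:
                return False
        return True


def _get(row: Any, col: str) -> Any:
    if isinstance(row, Mapping):
        return row.get(col)
    return getattr(row, col, None)


def apply_facets(rows: Sequence[Any], facets: Optional[FacetFilter]) -> list[Any]:
    """Filter ``rows``, preserving order; an empty filter is the identity."""
    if facets is None:
        return list(rows)
    return [r for r in rows if facets.matches(r)]


def parse_filter_args(args: Iterable[str]) -> FacetFilter:
    """Build a filter from CLI ``COLUMN=LO..HI`` / ``COLUMN=a,b,c`` strings."""
    ranges: dict[str, tuple[Optional[str], Optional[str]]] = {}
    sets: dict[str, frozenset] = {}
    for raw in args:
        if "=" not in raw:
            raise ValueError(f"bad filter {raw!r}: expected COLUMN=RANGE or COLUMN=SET")
        col, _, rhs = raw.partition("=")
        if ".." in rhs:
            lo, _, hi = rhs.partition("..")
            ranges[col] = (lo or None, hi or None)
        else:
            sets[col] = frozenset(v for v in rhs.split(",") if v)
    return FacetFilter(ranges=ranges, value_sets=sets)
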
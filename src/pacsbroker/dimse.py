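"""In-process DICOM service layer.

The broker, the storage receiver and the mock PACS exchange the standard
DICOM service primitives (C-ECHO, C-FIND, C-MOVE, C-STORE) through an
application-entity registry that routes each primitive to the node
registered under the destination AE title — the same topology as a DICOM
network (a C-MOVE names a *destination AE*, and the archive opens a store
association to it), with the TCP upper layer abstracted away. Query
identifiers and responses are attribute-keyed mappings using standard DICOM
keyword names; stored instances travel as serialized Part-10 bytes, so
byte-identity at the receiver is a real end-to-end property.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Protocol

from .errors import NotFoundError

# C-STORE / C-MOVE status summaries
STATUS_SUCCESS = "SUCCESS"
STATUS_FAILURE = "FAILURE"
STATUS_MOVE_DESTINATION_UNKNOWN = "MOVE_DESTINATION_UNKNOWN"
STATUS_OUT_OF_RESOURCES = "OUT_OF_RESOURCES"


@dataclass(frozen=True)
class MoveOutcome:
    """Final C-MOVE response: sub-operation accounting."""

    completed: int
    failed: int
    status: str = STATUS_SUCCESS

    @property
    def ok(self) -> bool:
        return self.status == STATUS_SUCCESS and self.failed == 0 and self.completed >= 1


class DicomNode(Protocol):
    """Service-class-provider surface of one network node."""

    def c_echo(self, calling_aet: str) -> bool: ...

    def c_find(self, calling_aet: str, level: str, identifier: dict) -> list[dict]: ...

    def c_move(self, calling_aet: str, identifier: dict, destination_aet: str) -> MoveOutcome: ...

    def c_store(self, calling_aet: str, part10_bytes: bytes) -> str: ...


@dataclass
class AERegistry:
    """Maps AE titles to reachable nodes (the 'network')."""

    nodes: dict[str, DicomNode] = field(default_factory=dict)

    def register(self, aet: str, node: DicomNode) -> None:
        self.nodes[aet] = node

    def resolve(self, aet: str) -> DicomNode:
        try:
            return self.nodes[aet]
        except KeyError:
            raise NotFoundError(f"no application entity registered as {aet!r}") from None
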
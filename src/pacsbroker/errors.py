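"""Exception hierarchy for the broker.

Every error class maps to a distinct CLI exit code (see :mod:`pacsbroker.cli`)
so that scripted callers can branch on failure class.
"""


class BrokerError(Exception):
    """Base class for all broker errors."""


class ConfigSyntaxError(BrokerError):
    """The configuration file does not parse; message names the line."""


class ConfigValidationError(BrokerError):
    """The configuration parses but violates an invariant; message names
    the offending field and the rule it breaks."""


class InvalidMrnError(BrokerError):
    """An MRN is empty after normalization stripping."""


class AuthorizationError(BrokerError):
    """An operation was attempted by a non-member, for an expired project,
    or against an off-allowlist patient."""


class DuplicateRequestError(BrokerError):
    """A retrieval request for the same (project, study) is already queued
    or in flight; message names the existing ticket."""

    def __init__(self, message: str, existing_ticket: str):
        super().__init__(message)
        self.existing_ticket = existing_ticket


class StateTransitionError(BrokerError):
    """An illegal request-lifecycle transition was attempted."""


class EndpointUnreachableError(BrokerError):
    """The PACS refused the association or timed out."""


class MoveFailedError(BrokerError):
    """A C-MOVE retrieval failed (rejection, timeout, zero instances)."""


class StagingCorruptionError(BrokerError):
    """Staged instances for one request span multiple studies."""


class EmptyStudyError(BrokerError):
    """A retrieval or admission produced zero instances."""


class NotFoundError(BrokerError):
    """A cache entry, request ticket or endpoint id does not exist."""


class AuditUnavailableError(BrokerError):
    """The audit store rejected a write; the triggering operation must
    fail closed (no PACS traffic, no state change)."""


class CryptoError(BrokerError):
    """Base for encryption-layer failures."""


class AuthenticationFailure(CryptoError):
    """Ciphertext authentication failed: wrong key or tampering."""


class UsageError(BrokerError):
    """Caller misuse: missing passphrase, empty passphrase, bad flag
    combination."""
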
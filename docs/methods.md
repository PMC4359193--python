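# Methods

This note documents the model behind `pacsbroker`, the choices made where
the design was genuinely open, and what the test suite does and does not
demonstrate about behaviour against real clinical archives.

## System model

The broker mediates between research projects and one or more clinical
archives speaking DICOM query/retrieve. A *project* is an IRB-scoped
tenant: a set of member usernames, an allowlist of canonical medical
record numbers (MRNs), an optional expiration date, and a cache quota in
bytes. An *endpoint* is one archive (AE title, host, port) with a
*governance policy* negotiated with its operators: weekly access windows,
a transfer rate, a concurrency cap, and an optional per-patient study
limit. All of this lives in one validated YAML configuration; every
invariant (window overlap, dangling policy references, AE-title syntax,
empty allowlists) is rejected at load time so a running service never
discovers a malformed policy mid-dispatch.

### MRN canonicalization

Sites format MRNs differently (dashes, case, zero-padding, prefixes).
Each endpoint carries a normalization rule applied to user input at query
time; allowlists are canonicalized once at configuration load with a
site-neutral default rule (strip `-` and spaces, uppercase). All
comparisons happen on canonical form. The transform drops an
already-present prefix before re-applying strip/uppercase/pad/prefix,
which makes it idempotent — without that step a configured prefix would
stack on repeated normalization. Idempotence is property-tested over
random inputs.

### Access control

Authorization runs **before any PACS traffic** and returns a decision
value rather than raising, so denials can be audited with full detail. A
query mixing on-list and off-list MRNs proceeds for the on-list subset
and audits the denied subset (partial filtering maximizes utility while
keeping the trail complete; all-or-nothing would be the conservative
alternative and is a one-line change). Accession-number lookups resolve
to a patient first and are released only if that patient is on-list.
Expiration is inclusive of the stated date — access stops at the first
instant of the following day in the service time zone — matching the
usual reading of an IRB approval period. The time zone is a service
constructor argument (default: host zone) because clinical "nights and
weekends" are local notions; stored timestamps are UTC.

Authorization is re-checked at dispatch time, not only at submission, so
a project that expires while requests sit in the queue generates no
further archive traffic. Such queue heads are *skipped*, not failed: the
request state machine deliberately has no SCHEDULED→FAILED edge, and a
skipped head simply never dispatches.

### Scheduling and governance

Each project owns a FIFO queue of retrieval tickets (one ticket = one
radiological study). Dispatch walks projects in lexicographic id order
from a cursor that persists across restarts; the cursor advances past the
chosen project, and heads that are blocked (closed window, empty bucket,
quota-full project, revoked authorization) are skipped so one stuck
project cannot stall the rotation. With equal queues and no limits this
yields the classic round-robin guarantee — per-project dispatch counts
never differ by more than one at any prefix — which the suite checks
exhaustively for small cases and over randomized interleavings.

The transfer rate ("N studies per minute/hour") is enforced as a
**sliding-log bucket**: each dispatch consumes a token that regenerates
exactly one rate period after it was consumed, and dispatch is allowed
only when fewer than `rate_count` dispatches fall inside the trailing
period. This is deliberately stricter than a refill token bucket
(capacity + continuous refill), which admits up to twice the nominal rate
across a window boundary; the sliding log makes "at most N per period"
true for *every* sliding interval, which is the promise an archive
operator actually cares about, and reproduces the intuitive behaviour
that after a burst of N the next slot opens exactly one period later.
Token state resets when the active window changes. Windows are half-open
`[start, end)` and start-inclusive so boundary instants are unambiguous;
a window with `rate_count = 0` is an explicit block (peak clinical
hours), and outside all windows nothing moves. The concurrency cap is
per endpoint; `max_concurrent = 0` disables retrieval entirely. Failed
requests are not retried automatically — failure is surfaced in the
request log and users resubmit — because silent retry would blur the
audit trail and the operational failure modes (off-line media, archive
load) are not generally transient at machine timescales.

All timing flows through an injectable clock; the governance suites run
under virtual time, so a week of window behaviour is simulated in
milliseconds, deterministically.

### Cache and quota

Study size is unknown before transfer (DICOM offers no reliable pre-move
size), so the quota is enforced as a **dispatch gate with truthful
overflow accounting**: an in-flight admission may push a project over
quota, the overflow is reported as-is, and no further dispatches happen
for that project until deletion brings it under quota. Cache keying is
(project, StudyInstanceUID); two projects caching the same study store it
twice — per-IRB isolation outweighs deduplication. Admission is an atomic
directory move from staging; accounting is checked against a recursive
directory walk after randomized operation interleavings. There is no
eviction or TTL: deletion is always user-initiated.

### Audit

One SQLite table, append-only, `seq` gap-free. The contract is
write-ahead with fail-closed semantics: the audit record for an action is
durably committed before the action touches the archive or the
filesystem, and an audit-store failure aborts the action. A compliance
log that actions can escape is not a compliance log. Denials are audited
as first-class events (one `ACCESS_DENIED` per denial decision, listing
the denied canonical MRNs), which is a conservative superset of logging
only successful queries.

### Encrypted export

The export path guarantees no plaintext on the destination disk:

* AES-128 in CTR mode. The block cipher is implemented in the package
  (numpy-vectorized over blocks) and validated against the published
  FIPS-197 known-answer vector; CTR keystream counters are 128-bit
  big-endian with a random per-file 16-byte nonce.
* Encrypt-then-MAC: each ciphertext chunk (64 KiB) carries an
  HMAC-SHA256 tag bound to the nonce and chunk index, and a final tag
  binds the chunk count and total length, so bit-flips, truncation and
  reordering all fail authentication rather than yielding a corrupted
  image. Encryption and MAC keys are derived separately from the master
  key. Decryption verifies every tag before releasing plaintext and
  creates no files.
* Keys come from PBKDF2-HMAC-SHA256 over the user passphrase with a
  random 16-byte salt per export, stored in the file header
  (`magic | salt | iterations | nonce`, then length-prefixed chunks).
  The default iteration count (200 000) targets ~100 ms of stretching on
  a desktop; tests use a reduced count since stretching strength is
  orthogonal to every property they check.
* Filenames are obfuscated as zero-padded sequence numbers
  (`000001.bin` …) assigned in (SeriesNumber, InstanceNumber,
  SOPInstanceUID) order, so lexicographic order equals acquisition order;
  the mapping back to instance identities is itself encrypted as
  `000000.bin`. Nothing about the patient or study is inferable from the
  directory listing.

The no-plaintext property is tested with a write-intercepting file opener
that records every byte string ever passed to `write()`; the plaintext's
first KiB (and the `DICM` magic) must never appear in that stream.

## The synthetic archive

The mock PACS serves studies produced by a deterministic generator:
secondary-capture instances with 32×32 8-bit pseudo-random pixels, UIDs
derived by hashing the seed (so identical specs are byte-identical), and
the attribute set the broker queries (patient identity, accession,
study/series/instance hierarchy, dates, modality, institution). An
optional padding attribute inflates file size so quota behaviour can be
exercised at megabyte scale without megabyte fixtures. Failure behaviour
— association refusal, per-move failure probability, off-line-archive
latency — flows from one seeded RNG per archive instance.

DICOM *networking* is modeled at the service-primitive level: an
in-process AE registry routes C-ECHO/C-FIND/C-MOVE/C-STORE between the
gateway, the broker's storage receiver and mock endpoints, with stored
instances travelling as serialized Part-10 bytes (so byte-identity at a
forwarding destination is a real end-to-end property). What passing tests
therefore demonstrate is the broker's *behaviour* — governance,
containment, accounting, auditing, encryption — not interoperability of
a TCP DICOM upper layer with vendor archives; deploying against a real
PACS would swap the registry for a network transport behind the same
four-primitive interface. Generated files, however, are real DICOM: an
independent reader (SimpleITK) must accept 100 % of them, which guards
the generator against self-consistent nonsense. The mock archive also
records every query and association it observes; access-control tests
treat that log as ground truth for "what did the archive see".

Problem sizes in the tests and the acceptance script (up to 5 projects,
500 requests, 150-ticket rate traces, week-long window sweeps at 30-min
resolution) were chosen so the full suite completes in seconds while
every property is exercised well past its boundary conditions; the
stochastic end-to-end check uses a 3 σ binomial band around the
configured 3 % move-failure rate at n = 500.

## Known limitations

* No TCP DICOM transport in-tree (see above); no series/instance-level
  C-FIND, wildcard matching, MPPS or storage commitment.
* Quota is strictly per project; cache space is shared by a project's
  members but never pooled across projects, even under one IRB.
* The per-endpoint concurrency cap and rate are not pooled globally
  across endpoints.
* No de-identification: the design places that responsibility on the
  IRB-approved users, and the audit/encryption machinery exists precisely
  because exports remain identifiable.
* The audit log is append-only but not tamper-evident (no hash
  chaining).
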
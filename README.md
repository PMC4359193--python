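# pacsbroker

A governed DICOM query/retrieve broker that gives credentialed research
projects access to imaging studies held in clinical PACS archives —
without handing researchers the keys to the archive.

Clinical PACS are built for radiology workflow, not for research: they
cannot enforce that an investigator touches only the patients their IRB
protocol covers, they keep no research-grade audit trail, and uncontrolled
bulk retrieval can degrade clinical operations. `pacsbroker` sits between
researchers and the archive and adds exactly that missing governance
layer:

* **IRB scoping** — every project is a tenant with an MRN allowlist, a
  member list, an expiration date and a cache quota. Off-list identifiers
  never reach the archive; an expired project generates zero PACS traffic.
* **Governed retrieval** — study retrievals (one C-MOVE per study) are
  queued per project and dispatched **round-robin** so all projects are
  served fairly, under per-archive limits: weekly time-of-day windows
  (e.g. nights and weekends only), a studies-per-minute/hour transfer
  rate enforced as a strict sliding-window bound, and a concurrency cap.
* **Audit trail** — every patient query, study query, retrieval, download,
  delete, forward and *denial* is an immutable, gap-free audit record,
  written **before** the action executes; if the audit store is down the
  action fails closed.
* **Quota-limited cache** — retrieved studies land in a per-project cache
  with truthful byte accounting; a project at quota is dispatch-blocked
  until its users delete studies.
* **Encrypted export** — downloads can be AES-128 encrypted (CTR mode
  with per-chunk HMAC-SHA256 authentication, PBKDF2-stretched passphrase)
  streamed so that *no plaintext DICOM bytes ever exist on the destination
  disk*, with order-preserving obfuscated filenames and an encrypted
  manifest. Decryption is to memory only.

Everything is testable offline: the package ships a synthetic DICOM
generator (deterministic, standards-valid secondary-capture studies) and a
mock PACS that answers C-FIND/C-MOVE with configurable failure behaviour.
DICOM networking is modeled at the service-primitive level through an
in-process application-entity registry; Part-10 file I/O is real
(pydicom), and generated fixtures are validated with an independent
reader (SimpleITK).

## Worked example

A configuration file declares archives, governance and projects
(`config.yaml`):

```yaml
endpoints:
  - id: mgh
    institution: General Hospital
    aet: PACS1
    host: pacs.example.org
    port: 11112
    mrn_rule: {strip_chars: "-", uppercase: true}
policies:
  mgh:
    max_concurrent: 3
    max_studies_per_patient: 3
    windows:
      - {days: [Mon,Tue,Wed,Thu,Fri], start: "22:00", end: "24:00", rate_count: 60, rate_period: hour}
      - {days: [Sat,Sun], start: 0, end: 1440, rate_count: 120, rate_period: hour}
projects:
  - id: stroke-atlas
    irb_id: IRB-2013-0042
    members: [alice]
    allowlist: ["12-345", "67-890"]
    expiration: "2015-06-30"
    cache_quota_bytes: 104857600
cache_root: ./cache
audit_store: ./audit.db
```

With a synthetic fixture archive (`--fixtures fixtures.yaml`) the full
workflow runs from the shell:

```
$ pacsbroker ... find-studies --project stroke-atlas --endpoint mgh --mrn-file mrns.txt
mrn     accession  study_uid                                   date        modalities  ...
12345   ACC001     2.25.67336345697932422599434990455183304412 2012-03-04  MR
67890   ACC002     2.25.87578317775933233604095249247431977777 2013-07-01  CT

$ pacsbroker ... request --project stroke-atlas --endpoint mgh --accession ACC001
R000001 SCHEDULED

$ pacsbroker ... serve
dispatched      1

$ pacsbroker ... log --project stroke-atlas
ticket   state      study_uid              submitted                  finished
R000001  COMPLETED  2.25.6733634569793...  2014-06-02T00:00:00+00:00  2014-06-02T22:00:00+00:00
```

The MRN `99-999` in `mrns.txt` was off the allowlist: it never reached the
archive and produced one `ACCESS_DENIED` audit record. The retrieval
submitted at 00:00 Monday *finished at 22:00*: the weekday window opens at
22:00, so the scheduler held the request until governance allowed it.

An encrypted download writes only ciphertext with obfuscated,
order-preserving names (`000000.bin` is the encrypted manifest):

```
$ pacsbroker ... repo download --project stroke-atlas \
      --study 2.25.67336345697932422599434990455183304412 \
      --dest ./download --encrypt --passphrase "correct horse"
000000.bin
000001.bin
...
000006.bin
```

The same operations are available as a library (`pacsbroker.Broker`); the
CLI is a thin shell over it.

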
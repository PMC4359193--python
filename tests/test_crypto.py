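"""Authenticated encryption, key derivation and filename obfuscation."""

import itertools
import os
import random
from types import SimpleNamespace

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pacsbroker import crypto
from pacsbroker.errors import AuthenticationFailure, UsageError

SALT = b"\x01" * 16
FAST_ITERS = 500  # key-stretching strength is irrelevant to these properties


def km(passphrase="correct horse", salt=SALT):
    return crypto.derive_key(passphrase, salt=salt, iterations=FAST_ITERS)


class RecordingOpener:
    """File opener that captures every byte string ever passed to write(),
    emulating a disk-snapshot harness at write granularity."""

    def __init__(self):
        self.writes: list[bytes] = []

    def __call__(self, path, mode):
        outer = self
        real = open(path, mode)

        class Wrapper:
            def write(self, data):
                outer.writes.append(bytes(data))
                return real.write(data)

            def __enter__(self):
                return self

            def __exit__(self, *exc):
                real.close()
                return False

        return Wrapper()


def test_aes_known_answer_fips197():
    """The AES core matches the published FIPS-197 example vector."""
    key = bytes(range(16))
    pt = bytes.fromhex("00112233445566778899aabbccddeeff")
    assert crypto.aes128_encrypt_block(key, pt).hex() == "69c4e0d86a7b0430d8cdb78070b4c55a"


class TestDeriveKey:
    def test_deterministic(self):
        assert km().key == km().key

    def test_distinct_salts_distinct_keys(self):
        rng = random.Random(0)
        salts = {bytes(rng.randrange(256) for _ in range(16)) for _ in range(1000)}
        keys = {crypto.derive_key("pw", salt=s, iterations=1).key for s in salts}
        assert len(keys) == len(salts)

    def test_empty_passphrase_rejected(self):
        with pytest.raises(UsageError):
            crypto.derive_key("")

    def test_key_is_128_bits(self):
        assert len(km().key) == 16


class TestRoundTrip:
    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(data=st.binary(min_size=0, max_size=300_000))
    def test_decrypt_encrypt_identity(self, data, tmp_path_factory):
        path = tmp_path_factory.mktemp("rt") / "x.bin"
        key = km()
        crypto.encrypt_instance_stream(data, key, path, nonce=b"\x02" * 16)
        assert crypto.decrypt_to_memory(path, key=key) == data

    def test_fifty_random_streams(self, tmp_path):
        rng = random.Random(42)
        key = km()
        for i in range(50):
            data = bytes(rng.randrange(256) for _ in range(rng.randrange(0, 4096)))
            p = tmp_path / f"{i}.bin"
            crypto.encrypt_instance_stream(data, key, p, nonce=bytes(rng.randrange(256) for _ in range(16)))
            assert crypto.decrypt_to_memory(p, "correct horse") == data

    def test_wrong_passphrase_is_auth_failure_not_garbage(self, tmp_path):
        p = tmp_path / "x.bin"
        crypto.encrypt_instance_stream(b"secret" * 100, km(), p)
        with pytest.raises(AuthenticationFailure):
            crypto.decrypt_to_memory(p, "wrong horse")

    @pytest.mark.parametrize("offset_frac", [0.1, 0.5, 0.95])
    def test_single_byte_tamper_detected(self, tmp_path, offset_frac):
        p = tmp_path / "x.bin"
        crypto.encrypt_instance_stream(os.urandom(10_000), km(), p)
        blob = bytearray(p.read_bytes())
        blob[int(len(blob) * offset_frac)] ^= 0x01
        p.write_bytes(bytes(blob))
        with pytest.raises(AuthenticationFailure):
            crypto.decrypt_to_memory(p, "correct horse")

    def test_truncation_detected(self, tmp_path):
        p = tmp_path / "x.bin"
        crypto.encrypt_instance_stream(os.urandom(200_000), km(), p)  # > 1 chunk
        blob = p.read_bytes()
        p.write_bytes(blob[: len(blob) // 2])
        with pytest.raises(AuthenticationFailure):
            crypto.decrypt_to_memory(p, "correct horse")

    def test_decrypt_creates_no_files(self, tmp_path):
        p = tmp_path / "x.bin"
        crypto.encrypt_instance_stream(os.urandom(5000), km(), p)
        before = sorted(os.listdir(tmp_path))
        crypto.decrypt_to_memory(p, "correct horse")
        assert sorted(os.listdir(tmp_path)) == before


class TestNoPlaintextOnDisk:
    def test_no_write_ever_contains_plaintext_prefix(self, tmp_path):
        """Under a write-intercepting harness, the concatenation of all
        bytes written never contains the plaintext's first KiB."""
        plaintext = b"\x00" * 128 + b"DICM" + os.urandom(130_000)
        opener = RecordingOpener()
        crypto.encrypt_instance_stream(plaintext, km(), tmp_path / "x.bin", opener=opener)
        everything = b"".join(opener.writes)
        assert plaintext[:1024] not in everything
        assert b"DICM" not in everything

    def test_output_is_not_parseable_dicom(self, tmp_path):
        import io

        import pydicom

        from conftest import make_spec
        from pacsbroker.mockpacs import dataset_bytes, generate_datasets

        ds = generate_datasets(make_spec(3, "M1", "A1"))[0]
        raw = dataset_bytes(ds)
        out = tmp_path / "x.bin"
        crypto.encrypt_instance_stream(raw, km(), out)
        blob = out.read_bytes()
        assert blob[128:132] != b"DICM"
        with pytest.raises(Exception):
            pydicom.dcmread(io.BytesIO(blob))

    def test_key_separation_across_salts(self, tmp_path):
        """Ciphertexts of the same plaintext under different salts share no
        16-byte block with each other or with the plaintext."""
        plaintext = os.urandom(8192)

        def blocks(b):
            return {b[i:i + 16] for i in range(0, len(b) - 15, 16)}

        cts = []
        for i in range(4):
            key = crypto.derive_key("pw", salt=bytes([i]) * 16, iterations=FAST_ITERS)
            p = tmp_path / f"{i}.bin"
            crypto.encrypt_instance_stream(plaintext, key, p, nonce=bytes([i + 100]) * 16)
            cts.append(p.read_bytes()[44:])  # past the shared-format header
        for a, b in itertools.combinations(cts, 2):
            assert not (blocks(a) & blocks(b))
        for c in cts:
            assert not (blocks(c) & blocks(plaintext))


def entry_with_layout(layout):
    return SimpleNamespace(
        file_layout=layout,
        study_instance_uid="2.25.1",
        accession_number="AN1",
        canonical_mrn="M1",
    )


class TestObfuscation:
    def test_six_instances_named_sequentially(self):
        layout = [
            {"sop_instance_uid": f"2.25.{i}", "series_number": 1 + i // 3,
             "instance_number": 1 + i % 3, "filename": f"f{i}.dcm"}
            for i in range(6)
        ]
        m = crypto.build_obfuscation_manifest(entry_with_layout(layout))
        assert list(m.names) == [f"{i:06d}.bin" for i in range(1, 7)]
        assert sorted(m.names) == list(m.names)

    @pytest.mark.parametrize("n", range(1, 9))
    def test_lexicographic_sort_reproduces_order_exhaustively(self, n):
        """For every instance count up to 8 the obfuscated names sort back
        into the entry's (series, instance) order."""
        layout = [
            {"sop_instance_uid": f"2.25.{i}", "series_number": (i // 3) + 1,
             "instance_number": (i % 3) + 1, "filename": f"f{i}.dcm"}
            for i in range(n)
        ]
        m = crypto.build_obfuscation_manifest(entry_with_layout(layout))
        order_by_name = [m.identities[m.names.index(nm)] for nm in sorted(m.names)]
        assert order_by_name == list(m.identities)

    def test_manifest_round_trips_and_is_encrypted(self, tmp_path):
        layout = [
            {"sop_instance_uid": "2.25.7", "series_number": 1,
             "instance_number": 1, "filename": "f.dcm"}
        ]
        entry = entry_with_layout(layout)
        src = tmp_path / "f.dcm"
        src.write_bytes(os.urandom(512))
        manifest = crypto.encrypt_study_export(
            entry, [src], tmp_path / "out", "pw",
            iterations=FAST_ITERS, salt=SALT,
        )
        blob = (tmp_path / "out" / crypto.MANIFEST_NAME).read_bytes()
        assert b"2.25.7" not in blob and b"M1" not in blob
        decoded = crypto.ObfuscationManifest.from_json(
            crypto.decrypt_to_memory(tmp_path / "out" / crypto.MANIFEST_NAME, "pw")
        )
        assert decoded == manifest
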
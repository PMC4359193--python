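"""Cache repository: admission, accounting conservation, quota gating,
deletion and export."""

import os
import random

import pydicom
import pytest

from pacsbroker import (
    CacheRepository,
    FacetFilter,
    StateStore,
    VirtualClock,
    crypto,
    generate_study,
)
from pacsbroker.errors import (
    AuthorizationError,
    EmptyStudyError,
    NotFoundError,
    StagingCorruptionError,
    UsageError,
)

from conftest import make_config, make_spec


@pytest.fixture
def repo(tmp_path):
    return CacheRepository(tmp_path / "cache", StateStore(), VirtualClock())


@pytest.fixture
def project(tmp_path):
    return make_config(tmp_path, quota=1 << 20).projects[0]


def stage(repo, spec, name="s1"):
    d = repo.root / "staging" / name
    generate_study(spec, d)
    return d


class TestAdmission:
    def test_accounting_identity(self, repo, project):
        spec = make_spec(1, "M1", "A1", n_series=2, instances_per_series=3)
        staging = stage(repo, spec)
        sizes = sum(p.stat().st_size for p in staging.glob("*.dcm"))
        entry = repo.admit_study(project, staging)
        assert entry.instance_count == 6
        assert entry.total_bytes == sizes
        assert not staging.exists()  # atomic move
        # layout ordered by (series, instance, sop)
        keys = [(i["series_number"], i["instance_number"]) for i in entry.file_layout]
        assert keys == sorted(keys)

    def test_mixed_study_uids_rejected(self, repo, project):
        d = repo.root / "staging" / "bad"
        generate_study(make_spec(1, "M1", "A1"), d)
        generate_study(make_spec(2, "M2", "A2"), d)
        with pytest.raises(StagingCorruptionError):
            repo.admit_study(project, d)

    def test_empty_staging_rejected(self, repo, project, tmp_path):
        empty = tmp_path / "nothing"
        empty.mkdir()
        with pytest.raises(EmptyStudyError):
            repo.admit_study(project, empty)

    def test_admission_may_overflow_quota(self, repo, tmp_path):
        project = make_config(tmp_path / "c2", quota=10_000).projects[0]
        spec = make_spec(3, "M1", "A1", padding_bytes=20_000)
        entry = repo.admit_study(project, stage(repo, spec))
        usage = repo.usage(project)
        assert usage.used_bytes == entry.total_bytes > usage.quota_bytes


class TestConservation:
    def test_used_bytes_equals_directory_walk_after_random_ops(self, repo, project):
        """After arbitrary admit/delete interleavings the index equals
        on-disk truth."""
        rng = random.Random(5)
        live = {}
        for i in range(12):
            if live and rng.random() < 0.4:
                uid = rng.choice(sorted(live))
                repo.delete_study(project, uid, "user1")
                live.pop(uid)
            else:
                spec = make_spec(100 + i, f"M{i}", f"A{i}",
                                 instances_per_series=rng.randint(1, 3))
                entry = repo.admit_study(project, stage(repo, spec, f"s{i}"))
                live[entry.study_instance_uid] = entry
            disk = sum(
                p.stat().st_size
                for p in (repo.root / project.id).rglob("*")
                if p.is_file()
            ) if (repo.root / project.id).exists() else 0
            assert repo.usage(project).used_bytes == disk


class TestDeletionAndListing:
    def test_delete_frees_space(self, repo, project):
        entry = repo.admit_study(project, stage(repo, make_spec(1, "M1", "A1")))
        usage = repo.delete_study(project, entry.study_instance_uid, "user1")
        assert usage.used_bytes == 0 and usage.entries == 0
        assert not repo.study_dir(project.id, entry.study_instance_uid).exists()

    def test_delete_unknown_entry(self, repo, project):
        with pytest.raises(NotFoundError):
            repo.delete_study(project, "2.25.404", "user1")

    def test_delete_requires_membership(self, repo, project):
        entry = repo.admit_study(project, stage(repo, make_spec(1, "M1", "A1")))
        with pytest.raises(AuthorizationError):
            repo.delete_study(project, entry.study_instance_uid, "mallory")

    def test_listing_newest_first_with_facets(self, repo, project):
        clock = repo.clock
        for i, mod in enumerate(["MR", "CT", "US"]):
            repo.admit_study(
                project, stage(repo, make_spec(10 + i, f"M{i}", f"A{i}", modality=mod), f"s{i}")
            )
            clock.advance(60)
        out = repo.list_entries(project)
        assert [sorted(e.modalities)[0] for e in out] == ["US", "CT", "MR"]
        only_ct = repo.list_entries(
            project, FacetFilter(value_sets={"modalities": frozenset({"CT"})})
        )
        assert len(only_ct) == 1 and "CT" in only_ct[0].modalities

    def test_empty_cache_lists_empty(self, repo, project):
        assert repo.list_entries(project) == []


class TestExport:
    def test_plaintext_byte_identical_layout(self, repo, project, tmp_path):
        spec = make_spec(1, "M1", "A1", n_series=2, instances_per_series=3)
        entry = repo.admit_study(project, stage(repo, spec))
        out = repo.export_study(project, entry.study_instance_uid, "user1", tmp_path / "dl")
        assert out["mode"] == "plaintext" and len(out["files"]) == 6
        for rel, src in zip(out["files"], repo.instance_paths(entry)):
            dst = tmp_path / "dl" / rel
            assert dst.read_bytes() == src.read_bytes()
            # layout mrn/study/series/instance.dcm
            parts = dst.relative_to(tmp_path / "dl").parts
            assert parts[0] == "M1" and parts[1] == entry.study_instance_uid

    def test_encrypted_export_has_no_parseable_dicom(self, repo, project, tmp_path):
        import io

        spec = make_spec(1, "M1", "A1", n_series=2, instances_per_series=3)
        entry = repo.admit_study(project, stage(repo, spec))
        out = repo.export_study(
            project, entry.study_instance_uid, "user1", tmp_path / "enc",
            encrypt=True, passphrase="pw", kdf_iterations=500,
        )
        files = sorted((tmp_path / "enc").iterdir())
        assert [p.name for p in files] == sorted(out["files"])
        for p in files:
            blob = p.read_bytes()
            assert b"DICM" not in blob[:1024]
            with pytest.raises(Exception):
                pydicom.dcmread(io.BytesIO(blob))

    def test_encrypt_decrypt_round_trip_matches_plaintext_export(
        self, repo, project, tmp_path
    ):
        spec = make_spec(4, "M1", "A1", n_series=2, instances_per_series=2)
        entry = repo.admit_study(project, stage(repo, spec))
        repo.export_study(project, entry.study_instance_uid, "user1", tmp_path / "enc",
                          encrypt=True, passphrase="pw", kdf_iterations=500)
        manifest = crypto.ObfuscationManifest.from_json(
            crypto.decrypt_to_memory(tmp_path / "enc" / crypto.MANIFEST_NAME, "pw")
        )
        for name, src in zip(manifest.names, repo.instance_paths(entry)):
            assert crypto.decrypt_to_memory(tmp_path / "enc" / name, "pw") == src.read_bytes()

    def test_encrypt_without_passphrase(self, repo, project, tmp_path):
        entry = repo.admit_study(project, stage(repo, make_spec(1, "M1", "A1")))
        with pytest.raises(UsageError):
            repo.export_study(project, entry.study_instance_uid, "user1",
                              tmp_path / "x", encrypt=True)

    def test_export_requires_membership(self, repo, project, tmp_path):
        entry = repo.admit_study(project, stage(repo, make_spec(1, "M1", "A1")))
        with pytest.raises(AuthorizationError):
            repo.export_study(project, entry.study_instance_uid, "mallory", tmp_path / "x")
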
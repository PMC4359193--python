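"""Round-robin fairness, window/rate governance, concurrency caps and the
request lifecycle."""

import datetime as dt
import itertools
import random

import pytest

from pacsbroker import (
    AccessWindow,
    RequestState,
    Scheduler,
    StudyRef,
    VirtualClock,
    current_rate,
)
from pacsbroker.errors import (
    AuthorizationError,
    DuplicateRequestError,
    StateTransitionError,
)

from conftest import ALL_DAYS, OPEN_ALL_WEEK, UTC, make_config

MONDAY = dt.datetime(2014, 6, 2, 0, 0, tzinfo=UTC)


def make_scheduler(tmp_path, *, n_projects=1, windows=(OPEN_ALL_WEEK,),
                   max_concurrent=1_000_000, usage_fn=None, clock=None, config=None):
    cfg = config or make_config(
        tmp_path, n_projects=n_projects, windows=windows, max_concurrent=max_concurrent
    )
    clock = clock or VirtualClock(MONDAY)
    return cfg, clock, Scheduler(cfg, clock, usage_fn=usage_fn, tz=UTC)


def submit(sched, cfg, project_idx: int, label: str):
    project = cfg.projects[project_idx]
    user = sorted(project.members)[0]
    mrn = sorted(project.allowlist)[0]
    ref = StudyRef(f"2.25.{project_idx}{label}", f"AN{label}", mrn)
    return sched.submit_request(project, user, cfg.endpoints[0], ref)


class TestRoundRobin:
    def test_hand_stepped_rotation(self, tmp_path):
        """Queues [A1,A2],[B1],[C1,C2] drain as A1,B1,C1,A2,C2."""
        cfg, clock, sched = make_scheduler(tmp_path, n_projects=3)
        a1 = submit(sched, cfg, 0, "1"); a2 = submit(sched, cfg, 0, "2")
        b1 = submit(sched, cfg, 1, "1")
        c1 = submit(sched, cfg, 2, "1"); c2 = submit(sched, cfg, 2, "2")
        order = [sched.next_dispatch().id for _ in range(5)]
        assert order == [a1.id, b1.id, c1.id, a2.id, c2.id]
        assert sched.next_dispatch() is None

    @pytest.mark.parametrize("k", [2, 3, 5])
    def test_fairness_equal_queues(self, tmp_path, k):
        """Per-project dispatch counts never differ by more than 1 at any
        prefix, for equal queues and no limits."""
        cfg, clock, sched = make_scheduler(tmp_path, n_projects=k)
        per = 6
        for j in range(per):
            for i in range(k):
                submit(sched, cfg, i, str(j))
        counts = {p.id: 0 for p in cfg.projects}
        for _ in range(k * per):
            req = sched.next_dispatch()
            assert req is not None
            counts[req.project_id] += 1
            assert max(counts.values()) - min(counts.values()) <= 1

    def test_fairness_randomized_uneven_arrivals(self, tmp_path):
        rng = random.Random(7)
        cfg, clock, sched = make_scheduler(tmp_path, n_projects=4)
        remaining = {i: 5 for i in range(4)}
        label = itertools.count()
        # interleave submissions and dispatches randomly
        dispatched = {p.id: 0 for p in cfg.projects}
        pending_total = 0
        while sum(remaining.values()) or sched.pending():
            if sum(remaining.values()) and (rng.random() < 0.6 or not sched.pending()):
                i = rng.choice([i for i in remaining if remaining[i]])
                submit(sched, cfg, i, str(next(label)))
                remaining[i] -= 1
            else:
                req = sched.next_dispatch()
                if req is not None:
                    dispatched[req.project_id] += 1
        assert sum(dispatched.values()) == 20


class TestWindowsAndRates:
    def test_token_bucket_two_per_minute(self, tmp_path):
        window = AccessWindow(days=ALL_DAYS, start=0, end=1440, rate_count=2, rate_period="minute")
        cfg, clock, sched = make_scheduler(tmp_path, windows=(window,))
        for j in range(3):
            submit(sched, cfg, 0, str(j))
        assert sched.next_dispatch() is not None
        assert sched.next_dispatch() is not None
        assert sched.next_dispatch() is None  # bucket empty at t=0
        clock.advance(59)
        assert sched.next_dispatch() is None  # still inside the minute
        clock.advance(1)  # t = +60 s
        assert sched.next_dispatch() is not None

    def test_blocked_window_rate_zero(self, tmp_path):
        window = AccessWindow(days=("Mon",), start=540, end=1020, rate_count=0, rate_period="hour")
        cfg, clock, sched = make_scheduler(tmp_path, windows=(window,))
        submit(sched, cfg, 0, "1")
        clock.set(MONDAY.replace(hour=10))  # Monday 10:00, inside the blocked window
        assert sched.next_dispatch() is None

    def test_outside_all_windows_nothing_moves(self, tmp_path):
        weekend = AccessWindow(days=("Sat", "Sun"), start=0, end=1440, rate_count=60, rate_period="hour")
        cfg, clock, sched = make_scheduler(tmp_path, windows=(weekend,))
        submit(sched, cfg, 0, "1")
        assert sched.next_dispatch() is None  # Monday
        clock.set(MONDAY + dt.timedelta(days=5))  # Saturday
        assert sched.next_dispatch() is not None

    def test_sliding_window_rate_bound_holds(self, tmp_path):
        """No 60-second interval ever contains more than rate_count
        dispatches, across a long irregular trace."""
        window = AccessWindow(days=ALL_DAYS, start=0, end=1440, rate_count=3, rate_period="minute")
        cfg, clock, sched = make_scheduler(tmp_path, windows=(window,))
        for j in range(40):
            submit(sched, cfg, 0, str(j))
        rng = random.Random(3)
        times = []
        while sched.pending():
            req = sched.next_dispatch()
            if req is not None:
                times.append(clock.now())
            clock.advance(rng.choice([1, 5, 13, 31]))
        for i, t in enumerate(times):
            in_window = [u for u in times if t < u <= t + dt.timedelta(seconds=60)]
            assert len(in_window) <= 3

    def test_current_rate_examples(self):
        from pacsbroker import GovernancePolicy

        weekend = GovernancePolicy(
            windows=(AccessWindow(days=("Sat", "Sun"), start=0, end=1440,
                                  rate_count=60, rate_period="hour"),),
            max_concurrent=5,
        )
        saturday_3am = dt.datetime(2014, 6, 7, 3, 0, tzinfo=UTC)
        assert current_rate(weekend, saturday_3am, UTC) == (60, "hour")
        wednesday_noon = dt.datetime(2014, 6, 4, 12, 0, tzinfo=UTC)
        assert current_rate(weekend, wednesday_noon, UTC) is None

    def test_window_start_inclusive_end_exclusive(self):
        from pacsbroker import GovernancePolicy

        pol = GovernancePolicy(
            windows=(AccessWindow(days=("Mon",), start=1320, end=1440,
                                  rate_count=5, rate_period="minute"),),
            max_concurrent=1,
        )
        at_start = dt.datetime(2014, 6, 2, 22, 0, tzinfo=UTC)
        assert current_rate(pol, at_start, UTC) == (5, "minute")
        just_before = dt.datetime(2014, 6, 2, 21, 59, tzinfo=UTC)
        assert current_rate(pol, just_before, UTC) is None


class TestConcurrency:
    def test_cap_enforced_until_transition(self, tmp_path):
        cfg, clock, sched = make_scheduler(tmp_path, max_concurrent=2)
        for j in range(3):
            submit(sched, cfg, 0, str(j))
        r1 = sched.next_dispatch(); r2 = sched.next_dispatch()
        assert r1 and r2
        assert sched.next_dispatch() is None  # cap reached
        sched.transition(r1, RequestState.COMPLETED)
        assert sched.next_dispatch() is not None

    def test_zero_concurrency_disables_retrieval(self, tmp_path):
        cfg, clock, sched = make_scheduler(tmp_path, max_concurrent=0)
        submit(sched, cfg, 0, "1")
        assert sched.next_dispatch() is None


class TestLifecycle:
    def test_completed_path(self, tmp_path):
        cfg, clock, sched = make_scheduler(tmp_path)
        req = submit(sched, cfg, 0, "1")
        assert req.state is RequestState.SCHEDULED
        sched.next_dispatch()
        assert req.state is RequestState.PROCESSING
        sched.transition(req, RequestState.COMPLETED)
        assert req.state is RequestState.COMPLETED
        assert req.submitted_at <= req.started_at <= req.finished_at

    def test_failed_requires_reason(self, tmp_path):
        cfg, clock, sched = make_scheduler(tmp_path)
        req = submit(sched, cfg, 0, "1")
        sched.next_dispatch()
        with pytest.raises(StateTransitionError):
            sched.transition(req, RequestState.FAILED)
        sched.transition(req, RequestState.FAILED, failure_reason="move timeout")
        assert req.failure_reason == "move timeout"

    def test_scheduled_to_completed_is_illegal(self, tmp_path):
        cfg, clock, sched = make_scheduler(tmp_path)
        req = submit(sched, cfg, 0, "1")
        with pytest.raises(StateTransitionError):
            sched.transition(req, RequestState.COMPLETED)

    def test_duplicate_names_existing_ticket(self, tmp_path):
        cfg, clock, sched = make_scheduler(tmp_path)
        first = submit(sched, cfg, 0, "1")
        with pytest.raises(DuplicateRequestError) as err:
            submit(sched, cfg, 0, "1")
        assert err.value.existing_ticket == first.id

    def test_resubmission_allowed_after_failure(self, tmp_path):
        cfg, clock, sched = make_scheduler(tmp_path)
        req = submit(sched, cfg, 0, "1")
        sched.next_dispatch()
        sched.transition(req, RequestState.FAILED, failure_reason="x")
        again = submit(sched, cfg, 0, "1")
        assert again.id != req.id

    def test_expired_project_submission_rejected(self, tmp_path):
        from pacsbroker import Project

        expired = Project(
            id="P1", irb_id="i", members=frozenset({"user1"}),
            allowlist=frozenset({"M"}), expiration=dt.date(2013, 1, 1),
            cache_quota_bytes=1 << 20,
        )
        cfg = make_config(tmp_path, projects=[expired])
        sched = Scheduler(cfg, VirtualClock(MONDAY), tz=UTC)
        with pytest.raises(AuthorizationError):
            sched.submit_request(
                expired, "user1", cfg.endpoints[0], StudyRef("2.25.9", "AN", "M")
            )


class TestGates:
    def test_quota_gate_blocks_and_resumes(self, tmp_path):
        usage = {"used": 150, "quota": 100}
        cfg, clock, sched = make_scheduler(
            tmp_path, usage_fn=lambda pid: (usage["used"], usage["quota"])
        )
        submit(sched, cfg, 0, "1")
        assert sched.next_dispatch() is None  # over quota: head skipped
        usage["used"] = 50  # user deleted studies
        assert sched.next_dispatch() is not None

    def test_expiry_while_queued_stops_dispatch(self, tmp_path):
        from pacsbroker import Project

        proj = Project(
            id="P1", irb_id="i", members=frozenset({"user1"}),
            allowlist=frozenset({"M"}), expiration=dt.date(2014, 6, 2),
            cache_quota_bytes=1 << 20,
        )
        cfg = make_config(tmp_path, projects=[proj])
        clock = VirtualClock(MONDAY)
        sched = Scheduler(cfg, clock, tz=UTC)
        sched.submit_request(proj, "user1", cfg.endpoints[0], StudyRef("2.25.9", "AN", "M"))
        clock.set(MONDAY + dt.timedelta(days=1))  # past the inclusive end date
        assert sched.next_dispatch() is None

    def test_liveness_when_everything_is_open(self, tmp_path):
        cfg, clock, sched = make_scheduler(tmp_path, n_projects=2)
        submit(sched, cfg, 1, "1")
        assert sched.next_dispatch() is not None


class TestPersistence:
    def test_restart_resumes_queue_and_cursor(self, tmp_path):
        from pacsbroker import StateStore

        store = StateStore(tmp_path / "state.db")
        cfg = make_config(tmp_path, n_projects=2)
        clock = VirtualClock(MONDAY)
        sched = Scheduler(cfg, clock, store=store, tz=UTC)
        submit(sched, cfg, 0, "1"); submit(sched, cfg, 0, "2")
        submit(sched, cfg, 1, "1")
        first = sched.next_dispatch()
        assert first.project_id == "P1"
        # service restart: rebuild from the same store
        sched2 = Scheduler(cfg, clock, store=store, tz=UTC)
        nxt = sched2.next_dispatch()
        assert nxt.project_id == "P2"  # cursor survived the restart
        assert sched2.pending() == 1
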
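import pytest

from ddxbench import (
    RaterOutput,
    failure_table,
    gold_ranked_list,
    regime_all,
    regime_intersection,
    regime_succeeded,
)
from ddxbench.benchmark import CHECKER_FAILURES, SUITE_SIZE
from ddxbench.regimes import EmptyIntersectionError, read_outputs, write_outputs
from ddxbench.simulate import RaterSkillProfile, SimulationConfig, generate_suite, simulate_rater


def outputs_with_statuses(statuses, rater_id="r", ddx=("something",)):
    return [
        RaterOutput(
            rater_id=rater_id,
            vignette_id=f"v{i:04d}",
            status=s,
            ddx=list(ddx) if s == "ok" else [],
        )
        for i, s in enumerate(statuses)
    ]


def statuses_from_counts(counts, total):
    statuses = []
    for cat in ("search_limit", "age_limit", "crash", "no_ddx"):
        statuses += [cat] * counts.get(cat, 0)
    statuses += ["ok"] * (total - len(statuses))
    return statuses


class TestFailureTable:
    @pytest.mark.parametrize(
        "rater, expected_ok", [("K Health", 345), ("Buoy", 316), ("Babylon", 34), ("Ada", 400)]
    )
    def test_success_counts_from_failure_counts(self, rater, expected_ok):
        outs = outputs_with_statuses(
            statuses_from_counts(CHECKER_FAILURES[rater], SUITE_SIZE), rater_id=rater
        )
        table = failure_table(outs, SUITE_SIZE)
        assert table.ok == expected_ok
        assert table.suite_size == SUITE_SIZE

    def test_zero_failures(self):
        table = failure_table(outputs_with_statuses(["ok"] * 10), 10)
        assert table.ok == 10 and table.no_ddx == 0

    def test_duplicate_vignette_rejected(self):
        outs = outputs_with_statuses(["ok", "ok"])
        outs[1] = outs[1].model_copy(update={"vignette_id": outs[0].vignette_id})
        with pytest.raises(ValueError, match="duplicate"):
            failure_table(outs, 2)

    def test_wrong_count_rejected(self):
        with pytest.raises(ValueError, match="expected"):
            failure_table(outputs_with_statuses(["ok"] * 3), 4)

    def test_question_stats_skip_crashes(self):
        outs = [
            RaterOutput(rater_id="r", vignette_id="a", status="ok", ddx=["x"], questions_asked=10),
            RaterOutput(rater_id="r", vignette_id="b", status="ok", ddx=["x"], questions_asked=20),
            RaterOutput(rater_id="r", vignette_id="c", status="crash", questions_asked=999),
        ]
        table = failure_table(outs, 3)
        assert table.questions_mean == pytest.approx(15.0)
        assert table.questions_sd == pytest.approx(50**0.5)


class TestStatusValidation:
    def test_ok_requires_differential(self):
        with pytest.raises(ValueError, match="non-empty"):
            RaterOutput(rater_id="r", vignette_id="v", status="ok", ddx=[])

    def test_failure_forbids_differential(self):
        with pytest.raises(ValueError, match="empty"):
            RaterOutput(rater_id="r", vignette_id="v", status="crash", ddx=["x"])


def two_vignette_fixture(make_vignette):
    v1 = make_vignette("a")
    v2 = make_vignette("b")
    perfect = list(gold_ranked_list(v1))
    return [v1, v2], perfect


class TestRegimes:
    def test_all_penalizes_crash(self, make_vignette):
        suite, perfect = two_vignette_fixture(make_vignette)
        outs = [
            RaterOutput(rater_id="r", vignette_id="a", status="ok", ddx=perfect),
            RaterOutput(rater_id="r", vignette_id="b", status="crash"),
        ]
        s = regime_all(outs, suite)
        assert s.m1_pct == 50.0 and s.n_vignettes == 2

    def test_all_perfect_is_100(self, make_vignette):
        suite, perfect = two_vignette_fixture(make_vignette)
        outs = [
            RaterOutput(rater_id="r", vignette_id=v.id, status="ok", ddx=list(gold_ranked_list(v)))
            for v in suite
        ]
        s = regime_all(outs, suite)
        assert all(getattr(s, m) == 100.0 for m in s.METRICS)

    def test_succeeded_excludes_crash(self, make_vignette):
        suite, perfect = two_vignette_fixture(make_vignette)
        outs = [
            RaterOutput(rater_id="r", vignette_id="a", status="ok", ddx=perfect),
            RaterOutput(rater_id="r", vignette_id="b", status="crash"),
        ]
        s = regime_succeeded(outs, suite)
        assert s.m1_pct == 100.0 and s.n_vignettes == 1

    def test_succeeded_penalizes_no_ddx(self, make_vignette):
        suite, perfect = two_vignette_fixture(make_vignette)
        outs = [
            RaterOutput(rater_id="r", vignette_id="a", status="ok", ddx=perfect),
            RaterOutput(rater_id="r", vignette_id="b", status="no_ddx"),
        ]
        s = regime_succeeded(outs, suite)
        assert s.m1_pct == 50.0 and s.n_vignettes == 2

    def test_succeeded_denominator_matches_hard_failures(self):
        # a rater blocked on 15 searches with 351 empty sessions and 34 ok ones
        # keeps 400 - 15 = 385 vignettes in the succeeded-only denominator
        suite, _ = generate_suite(SimulationConfig(n_vignettes=SUITE_SIZE, seed=4))
        statuses = statuses_from_counts(CHECKER_FAILURES["Babylon"], SUITE_SIZE)
        outs = [
            RaterOutput(
                rater_id="r",
                vignette_id=v.id,
                status=s,
                ddx=[v.gold_main] if s == "ok" else [],
            )
            for v, s in zip(suite, statuses)
        ]
        assert regime_succeeded(outs, suite).n_vignettes == 385

    def test_all_equals_succeeded_without_hard_failures(self):
        suite, lex = generate_suite(SimulationConfig(n_vignettes=60, seed=5))
        profile = RaterSkillProfile(failure_rates={"no_ddx": 0.2})
        outs = simulate_rater(suite, lex, profile, 3, rater_id="soft")
        a = regime_all(outs, suite, lex)
        b = regime_succeeded(outs, suite, lex)
        assert a == b

    def test_succeeded_dominates_all(self):
        suite, lex = generate_suite(SimulationConfig(n_vignettes=80, seed=6))
        profile = RaterSkillProfile(
            failure_rates={"search_limit": 0.05, "age_limit": 0.05, "crash": 0.05, "no_ddx": 0.1}
        )
        outs = simulate_rater(suite, lex, profile, 8, rater_id="flaky")
        a = regime_all(outs, suite, lex)
        b = regime_succeeded(outs, suite, lex)
        for m in a.METRICS:
            assert getattr(b, m) >= getattr(a, m) - 1e-12

    def test_coverage_gap_rejected(self, make_vignette):
        suite, perfect = two_vignette_fixture(make_vignette)
        outs = [RaterOutput(rater_id="r", vignette_id="a", status="ok", ddx=perfect)]
        with pytest.raises(ValueError, match="missing"):
            regime_all(outs, suite)


class TestIntersection:
    def test_shared_ok_set(self, make_vignette):
        suite, perfect = two_vignette_fixture(make_vignette)
        by_rater = {
            "r1": [
                RaterOutput(rater_id="r1", vignette_id="a", status="ok", ddx=perfect),
                RaterOutput(rater_id="r1", vignette_id="b", status="ok", ddx=["x"]),
            ],
            "r2": [
                RaterOutput(rater_id="r2", vignette_id="a", status="ok", ddx=perfect),
                RaterOutput(rater_id="r2", vignette_id="b", status="crash"),
            ],
        }
        result = regime_intersection(by_rater, suite)
        assert result["r1"].n_vignettes == result["r2"].n_vignettes == 1
        assert result["r1"].m1_pct == 100.0

    def test_single_rater_equals_own_ok_set(self):
        suite, lex = generate_suite(SimulationConfig(n_vignettes=50, seed=7))
        profile = RaterSkillProfile(failure_rates={"crash": 0.1, "no_ddx": 0.1})
        outs = simulate_rater(suite, lex, profile, 9, rater_id="solo")
        only = regime_intersection({"solo": outs}, suite, lex)["solo"]
        ok_ids = {o.vignette_id for o in outs if o.status == "ok"}
        assert only.n_vignettes == len(ok_ids)

    def test_removing_flaky_rater_grows_set(self):
        suite, lex = generate_suite(SimulationConfig(n_vignettes=60, seed=8))
        good = simulate_rater(suite, lex, RaterSkillProfile(), 1, rater_id="good")
        flaky = simulate_rater(
            suite,
            lex,
            RaterSkillProfile(failure_rates={"no_ddx": 0.5}),
            1,
            rater_id="flaky",
        )
        by_rater = {"good": good, "flaky": flaky}
        with_flaky = regime_intersection(by_rater, suite, lex)["good"].n_vignettes
        without = regime_intersection(by_rater, suite, lex, include=["good"])["good"].n_vignettes
        assert without >= with_flaky

    def test_empty_intersection_reported(self, make_vignette):
        suite, perfect = two_vignette_fixture(make_vignette)
        by_rater = {
            "r1": [
                RaterOutput(rater_id="r1", vignette_id="a", status="ok", ddx=perfect),
                RaterOutput(rater_id="r1", vignette_id="b", status="crash"),
            ],
            "r2": [
                RaterOutput(rater_id="r2", vignette_id="a", status="no_ddx"),
                RaterOutput(rater_id="r2", vignette_id="b", status="ok", ddx=["x"]),
            ],
        }
        with pytest.raises(EmptyIntersectionError):
            regime_intersection(by_rater, suite)


class TestOutputIO:
    @pytest.mark.parametrize("ext", ["csv", "jsonl"])
    def test_round_trip(self, tmp_path, ext):
        outs = outputs_with_statuses(["ok", "no_ddx", "crash"], ddx=("a", "b"))
        outs[0] = outs[0].model_copy(update={"questions_asked": 12})
        path = tmp_path / f"outs.{ext}"
        write_outputs(outs, path)
        assert read_outputs(path) == outs
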
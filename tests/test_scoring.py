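"""The seven indicator scoring rules and their invariants."""

import itertools

import pytest

from hopforecast.scoring import (
    INDICATORS,
    LEVEL_SETS,
    SessionLog,
    read_logs,
    score_indicator,
    score_session,
)


def log(**kwargs) -> SessionLog:
    return SessionLog(**kwargs)


@pytest.mark.parametrize(
    "kwargs, indicator, expected",
    [
        # strength: both quotas -> 10, one -> 5, neither -> 0; quotas are minimums
        (dict(moderate_strength_bouts=6, high_strength_bouts=3), "STT", 10),
        (dict(moderate_strength_bouts=8, high_strength_bouts=5), "STT", 10),
        (dict(moderate_strength_bouts=6, high_strength_bouts=0), "STT", 5),
        (dict(moderate_strength_bouts=0, high_strength_bouts=3), "STT", 5),
        (dict(moderate_strength_bouts=5, high_strength_bouts=2), "STT", 0),
        # speed: pass/fail
        (dict(sprint_within_time=True), "SPT", 10),
        (dict(sprint_within_time=False), "SPT", 0),
        # endurance: all three -> 10, exactly two -> 5, else 0
        (dict(endurance_types_completed={"aerobic", "anaerobic", "hybrid"}), "ENT", 10),
        (dict(endurance_types_completed={"aerobic", "anaerobic"}), "ENT", 5),
        (dict(endurance_types_completed={"hybrid"}), "ENT", 0),
        (dict(endurance_types_completed=set()), "ENT", 0),
        # regional: both conditions -> 10, one -> 5
        (dict(regional_completed={"barrier_free", "obstacle"}), "RET", 10),
        (dict(regional_completed={"obstacle"}), "RET", 5),
        (dict(regional_completed=set()), "RET", 0),
        # stress test: pass/fail
        (dict(stress_test_passed=True), "RST", 10),
        (dict(stress_test_passed=False), "RST", 0),
        # recovery: strictly slower than the group mean -> 5, else 10
        (dict(recovery_time=31.0, group_mean_recovery_time=30.0), "RCT", 5),
        (dict(recovery_time=30.0, group_mean_recovery_time=30.0), "RCT", 10),
        (dict(recovery_time=25.0, group_mean_recovery_time=30.0), "RCT", 10),
        # basic skill: pass/fail
        (dict(basic_skills_standard=True), "BST", 10),
        (dict(basic_skills_standard=False), "BST", 0),
    ],
)
def test_scoring_rules(kwargs, indicator, expected):
    assert score_indicator(log(**kwargs), indicator) == expected


def test_unknown_indicator_key():
    with pytest.raises(ValueError, match="unknown indicator"):
        score_indicator(log(), "XYZ")


def test_score_session_all_max():
    entry = log(
        moderate_strength_bouts=6,
        high_strength_bouts=3,
        sprint_within_time=True,
        endurance_types_completed={"aerobic", "anaerobic", "hybrid"},
        regional_completed={"barrier_free", "obstacle"},
        stress_test_passed=True,
        recovery_time=20.0,
        group_mean_recovery_time=30.0,
        basic_skills_standard=True,
    )
    assert tuple(score_session(entry)) == (10, 10, 10, 10, 10, 10, 10)


def test_score_session_all_min_has_recovery_floor():
    # Recovery training has no 0 level: even a slow recovery earns 5 points.
    entry = log(recovery_time=40.0, group_mean_recovery_time=30.0)
    assert tuple(score_session(entry)) == (0, 0, 0, 0, 0, 5, 0)


def test_mixed_session():
    entry = log(moderate_strength_bouts=6, high_strength_bouts=0, sprint_within_time=True)
    scores = score_session(entry)
    assert scores["STT"] == 5
    assert scores["SPT"] == 10


def _log_grid():
    """A grid covering every scoring-rule condition combination."""
    for moderate, high, sprint, endurance, regional, stress, rec, skills in itertools.product(
        (0, 5, 6),
        (0, 2, 3),
        (False, True),
        [frozenset(s) for r in range(4)
         for s in itertools.combinations(("aerobic", "anaerobic", "hybrid"), r)],
        [frozenset(s) for r in range(3)
         for s in itertools.combinations(("barrier_free", "obstacle"), r)],
        (False, True),
        (25.0, 30.0, 35.0),
        (False, True),
    ):
        yield SessionLog(
            moderate_strength_bouts=moderate,
            high_strength_bouts=high,
            sprint_within_time=sprint,
            endurance_types_completed=endurance,
            regional_completed=regional,
            stress_test_passed=stress,
            recovery_time=rec,
            group_mean_recovery_time=30.0,
            basic_skills_standard=skills,
        )


def test_mapping_is_total_and_respects_level_sets():
    for entry in _log_grid():
        scores = score_session(entry)
        for key, value in scores.as_dict().items():
            assert value in LEVEL_SETS[key]


def test_adding_completed_activity_never_decreases_scores():
    base = SessionLog(
        moderate_strength_bouts=5,
        high_strength_bouts=2,
        endurance_types_completed={"aerobic"},
        regional_completed=frozenset(),
        recovery_time=35.0,
    )
    upgrades = [
        dict(moderate_strength_bouts=6),
        dict(high_strength_bouts=3),
        dict(sprint_within_time=True),
        dict(endurance_types_completed={"aerobic", "anaerobic"}),
        dict(regional_completed={"obstacle"}),
        dict(stress_test_passed=True),
        dict(recovery_time=25.0),
        dict(basic_skills_standard=True),
    ]
    base_scores = score_session(base).scores
    for upgrade in upgrades:
        upgraded = SessionLog(**{**base.__dict__, **upgrade})
        for before, after in zip(base_scores, score_session(upgraded).scores):
            assert after >= before


@pytest.mark.parametrize(
    "kwargs",
    [
        dict(moderate_strength_bouts=-1),
        dict(recovery_time=0.0),
        dict(endurance_types_completed={"swimming"}),
        dict(regional_completed={"uphill"}),
    ],
)
def test_invalid_logs_rejected(kwargs):
    with pytest.raises(ValueError):
        SessionLog(**kwargs)


def test_read_logs_csv(tmp_path):
    path = tmp_path / "logs.csv"
    path.write_text(
        "moderate_strength_bouts,high_strength_bouts,sprint_within_time,"
        "endurance_types_completed,regional_completed,stress_test_passed,"
        "recovery_time,group_mean_recovery_time,basic_skills_standard\n"
        "6,3,true,aerobic|anaerobic|hybrid,barrier_free;obstacle,yes,20,30,1\n"
        "0,0,false,,,no,35,30,0\n"
    )
    logs = read_logs(path)
    assert tuple(score_session(logs[0])) == (10, 10, 10, 10, 10, 10, 10)
    assert tuple(score_session(logs[1])) == (0, 0, 0, 0, 0, 5, 0)
    assert list(score_session(logs[0]).as_dict()) == list(INDICATORS)
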
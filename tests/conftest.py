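import dataclasses

import numpy as np
import pytest

from tapsurv import (
    AssessmentType,
    GameRecord,
    SimulationConfig,
    assemble_games,
    simulate_study,
)
from tapsurv.simulate import fig2_fixture


@pytest.fixture
def fig2():
    """(reference, assessment_B, assessment_C) worked-example games."""
    return fig2_fixture()


@pytest.fixture
def small_study():
    """A small but complete synthetic study (events, streams, truth)."""
    cfg = SimulationConfig(seed=7, n_control=4, n_patient=4, weeks=4)
    return cfg, simulate_study(cfg)


def make_game(taps, level=None, *, game_id="g", subject_id="s",
              atype=AssessmentType.JEWELS_A, n_mistakes=0):
    taps = tuple(float(t) for t in taps)
    return GameRecord(
        subject_id=subject_id,
        game_id=game_id,
        assessment_type=atype,
        level=level if level is not None else len(taps),
        tap_times=taps,
        n_mistakes=n_mistakes,
        completed=level is None or level == len(taps),
    )


def random_game_pair(rng, max_level=4):
    """A random (assessment, reference-like) pair of completed games."""
    la = int(rng.integers(1, max_level + 1))
    lr = int(rng.integers(1, max_level + 1))
    a = make_game(np.sort(rng.uniform(0.1, 10.0, size=la)), game_id="a")
    r = make_game(np.sort(rng.uniform(0.1, 10.0, size=lr)), game_id="r")
    return a, r


@pytest.fixture
def rename_cohort():
    """Re-label a simulated cohort's subjects/games so cohorts can be merged."""

    def _rename(games, prefix):
        return [
            dataclasses.replace(g, subject_id=prefix + g.subject_id[1:],
                                game_id=prefix + g.game_id)
            for g in games
        ]

    return _rename


def simulate_cohort(seed, level_dist, prefix, *, n=12, rate=2.0, rename=None, **kw):
    """Control-only cohort playing Jewels A at the given rate."""
    cfg = SimulationConfig(
        seed=seed, n_control=n, n_patient=0, level_dist=level_dist,
        subject_sd=kw.pop("subject_sd", 0.0), mistake_prob=kw.pop("mistake_prob", 0.0),
        include_streams=False,
        games_per_week={
            ("control", "JEWELS_A"): rate, ("control", "JEWELS_B"): 0.0,
            ("patient", "JEWELS_A"): 0.0, ("patient", "JEWELS_B"): 0.0,
        },
        **kw,
    )
    evs, _, _ = simulate_study(cfg)
    games = assemble_games(evs)
    if rename:
        games = [
            dataclasses.replace(g, subject_id=rename + g.subject_id[1:],
                                game_id=rename + g.game_id)
            for g in games
        ]
    return games
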
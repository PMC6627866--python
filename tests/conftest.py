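import pytest

from sugarsteps import SynthConfig, generate_food_db


def small_participants(n_per_stratum: int = 25) -> dict:
    return {
        (year, sex): n_per_stratum
        for year in (5, 8, 11)
        for sex in ("girl", "boy")
    }


@pytest.fixture(scope="session")
def small_world():
    """A 90-item synthetic database with planted truth and matching config."""
    cfg = SynthConfig(
        n_single=60,
        n_composite=30,
        seed=7,
        participant_counts=small_participants(),
    )
    db, truth, proc = generate_food_db(cfg)
    return cfg, db, truth, proc
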
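import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True,
                          deadline=None, max_examples=25)
settings.load_profile("deterministic")

from peersway.design import DesignConfig, assign_schedule_feedback, generate_schedule
from peersway.epochs import EpochSet, default_times, load_montage


def make_rated_schedule(config, seed=0, rating_mean=4.2, rating_sd=1.2,
                        participant="s01"):
    """Schedule with random ratings assigned and conditions drawn."""
    rng = np.random.default_rng(seed)
    sched = generate_schedule(config, rng, participant=participant)
    faces = sched.loc[sched["phase"] == "test", "face_id"]
    ratings = {
        f: int(np.clip(round(rng.normal(rating_mean, rating_sd)), 1, 8))
        for f in faces
    }
    return assign_schedule_feedback(sched, ratings, config, rng)


@pytest.fixture(scope="session")
def montage():
    return load_montage()


@pytest.fixture(scope="session")
def online_schedule():
    return make_rated_schedule(DesignConfig.online(), seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_epochs(n_trials=40, n_channels=8, sfreq=100.0, seed=0,
                labels=None, noise_sd=1.0):
    """Small random EpochSet with a toy circular montage."""
    rng = np.random.default_rng(seed)
    times = default_times(sfreq)
    theta = np.linspace(0, 2 * np.pi, n_channels, endpoint=False)
    pos = np.c_[np.cos(theta), np.sin(theta), np.zeros(n_channels)] * 0.09
    data = rng.normal(0, noise_sd, (n_trials, n_channels, times.size))
    return EpochSet(
        data=data, times=times,
        ch_names=[f"ch{i}" for i in range(n_channels)],
        ch_pos=pos, labels=labels, sfreq=sfreq,
    )


def make_trial_frame(rows):
    """Trial table from (participant, phase, face, condition, test, fictive, post)."""
    recs = []
    for participant, phase, face, cond, test, fict, post in rows:
        recs.append({
            "participant": participant, "phase": phase, "face_id": face,
            "condition": cond, "test_rating": test,
            "fictive_rating": fict, "post_rating": post,
        })
    return pd.DataFrame(recs)
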
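"""Shared fixtures: a small synthetic image set, its reduced statistics, and
a simulated two-photon session, reused across test modules (session-scoped —
these are the expensive objects)."""

import numpy as np
import pytest

from texgeom import twophoton as tp
from texgeom.psstats import GROUPS, compute_ps_statistics, reduce_statistics
from texgeom.synth import (
    TwoPhotonTruth,
    make_full_image_set,
    make_trial_schedule,
    simulate_twophoton_session,
)

GROUP_BLOCKS = {g: slice(2 * i, 2 * i + 2) for i, g in enumerate(GROUPS)}


@pytest.fixture(scope="session")
def image_set():
    """4 families x 8 exemplars x {texture, scramble} x {0, 90} at 64 px."""
    return make_full_image_set(n_exemplars=8, rng_seed=11, size=64)


@pytest.fixture(scope="session")
def ps_stats(image_set):
    return [compute_ps_statistics(im) for im in image_set]


@pytest.fixture(scope="session")
def reduced(ps_stats):
    with pytest.warns(UserWarning):  # constant |lowpass| mean column dropped
        return reduce_statistics(ps_stats)


@pytest.fixture(scope="session")
def tp_bundle(image_set, reduced):
    """Simulated two-photon session plus its processed response table."""
    X = reduced.features(2)
    stim_index = image_set.manifest()
    schedule = make_trial_schedule(
        "twophoton", rng_seed=3, n_exemplars=8, n_repeats=4, n_blanks=40
    )
    truth = TwoPhotonTruth(n_cells=60, rate_hz=10.0)
    session = simulate_twophoton_session(
        X, stim_index, schedule, truth, rng_seed=5, keep_true_soma=True
    )
    traces = tp.preprocess_traces(
        session.soma, session.neuropil, session.rate_hz, r=truth.neuropil_r
    )
    trials = tp.frame_zero_tensor(traces, schedule)
    table = tp.response_table(trials)
    X_aligned = tp.align_features(table, X, stim_index)
    return dict(
        session=session,
        schedule=schedule,
        traces=traces,
        trials=trials,
        table=table,
        features=X_aligned,
        truth=truth,
    )
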
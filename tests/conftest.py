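import numpy as np
import pytest

import seqtime as st


@pytest.fixture(scope="session")
def cfg():
    return st.TaskConfig()


@pytest.fixture(scope="session")
def small_cfg():
    # 3 blocks of 8 trials, short ITI: keeps generated sessions cheap
    return st.TaskConfig(n_blocks=3, trials_per_block=8, reverse_fraction=0.25)


@pytest.fixture(scope="session")
def small_params():
    return st.GeneratorParams(
        n_cells_per_odor=6, n_noise_cells=8, n_odor2_cells=2,
        iti=2.0, pre_roll=3.0,
    )


@pytest.fixture(scope="session")
def small_session(small_cfg, small_params):
    rec, cells = st.generate_session(small_cfg, small_params, seed=11)
    return rec, cells


@pytest.fixture(scope="session")
def default_session(cfg):
    params = st.GeneratorParams(
        n_cells_per_odor=20, n_noise_cells=30, n_odor2_cells=6,
        anticipation_weight=1.0,
    )
    rec, cells = st.generate_session(cfg, params, seed=7)
    return rec, cells


@pytest.fixture(scope="session")
def default_aligned(default_session):
    rec, _ = default_session
    return st.condition_and_align(rec)


@pytest.fixture(scope="session")
def default_stats(default_aligned, cfg):
    return st.detect_sequence_cells(
        default_aligned, cfg, st.DetectionParams(n_shuffles=500), seed=5)


def make_aligned(tensor, cfg, trials=None, bin_size=None, window_start=-2.0,
                 bin_frames=5):
    """Wrap a raw tensor as AlignedActivity with a synthetic trial table."""
    tensor = np.asarray(tensor, dtype=float)
    n_neurons, n_trials, n_bins = tensor.shape
    if bin_size is None:
        bin_size = bin_frames / cfg.frame_rate
    if trials is None:
        built = []
        t = 5.0
        for i in range(n_trials):
            delay = cfg.short_delay
            built.append(st.Trial(
                index=i, odor1=cfg.odor_labels[0], odor2=cfg.odor_labels[1],
                delay=delay, is_reverse=False, odor1_onset=t,
                odor2_onset=t + cfg.odor_duration + delay,
            ))
            t += 20.0
        trials = st.TrialTable(built, cfg)
    time_axis = window_start + (np.arange(n_bins) + 0.5) * bin_size
    return st.AlignedActivity(
        tensor=tensor, bin_frames=bin_frames, bin_size=bin_size,
        time_axis=time_axis, trial_index_map=np.arange(n_trials),
        trials=trials,
    )
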
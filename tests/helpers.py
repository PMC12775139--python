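"""Shared test helpers."""

import numpy as np


def make_windowset(
    n_trials=12,
    windows_per_trial=3,
    n_channels=2,
    n_samples=300,
    rate=250.0,
    labeler=None,
    seed=0,
):
    """Random-noise WindowSet with per-trial labels for CV/guard tests."""
    from frustmi import WindowSet

    gen = np.random.default_rng(seed)
    n = n_trials * windows_per_trial
    trial_ids = np.repeat([f"t{i:03d}" for i in range(n_trials)], windows_per_trial)
    if labeler is None:
        labeler = lambda i: "left" if i % 2 == 0 else "right"
    trial_labels = {f"t{i:03d}": labeler(i) for i in range(n_trials)}
    mi = np.array([trial_labels[t] for t in trial_ids], dtype=object)
    windows = gen.normal(0, 1, size=(n, n_channels, n_samples))
    return WindowSet(
        windows=windows,
        mi_label=mi,
        state_label=np.full(n, "none", dtype=object),
        subject_id=np.full(n, "S01", dtype=object),
        trial_id=trial_ids.astype(object),
        window_len=n_samples,
        step=n_samples,
        rate=rate,
        channel_names=[f"ch{i}" for i in range(n_channels)],
    )
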
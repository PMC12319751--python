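import numpy as np
import pytest

from miclean import (
    ChannelInfo,
    ChannelKind,
    EventTable,
    Recording,
    generate_dataset,
    select_artefacts,
)
import pandas as pd


def make_grad_recording(
    n_pairs: int = 3, n_samples: int = 500, sfreq: float = 200.0, seed: int = 0
) -> Recording:
    """Small gradiometer recording with paired channels on a line layout."""
    rng = np.random.default_rng(seed)
    channels = []
    for p in range(n_pairs):
        for suffix in ("a", "b"):
            channels.append(
                ChannelInfo(
                    f"G{p}{suffix}", ChannelKind.grad, pair_id=p, position=(float(p), 0.0)
                )
            )
    return Recording(
        sfreq=sfreq, channels=channels, data=rng.standard_normal((2 * n_pairs, n_samples))
    )


def make_events(onsets, sfreq=200.0, task="vocal", label="picture", run=0) -> EventTable:
    rows = [
        {"onset_sample": int(o), "label": label, "task": task, "run": run, "block": 0}
        for o in onsets
    ]
    return EventTable(pd.DataFrame(rows))


@pytest.fixture(scope="session")
def gn_dataset():
    """One default gesture+naming synthetic session, shared across tests."""
    return generate_dataset("GN", seed=7)


@pytest.fixture(scope="session")
def gn_outcome(gn_dataset):
    """Selection outcome of the GN variant on the shared session."""
    return select_artefacts(gn_dataset, "GN")
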
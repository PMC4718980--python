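"""Shared fixtures: the strong-effect synthetic corpus and its feature table.

The corpus geometry (10 speakers per class, 3 s sustained phonations at
25 kHz) matches the conditions the package's planted-effect checks are
defined for; it is built once per session and shared.
"""

import numpy as np
import pandas as pd
import pytest

import modspec as m

STRONG_SEED = 1


@pytest.fixture(scope="session")
def strong_corpus():
    spec = m.CorpusSpec(n_speakers_per_class=10, duration_s=3.0, effect="strong", seed=STRONG_SEED)
    return m.make_corpus(spec)


@pytest.fixture(scope="session")
def strong_table(strong_corpus):
    return m.corpus_metrics_table(strong_corpus.recordings)


@pytest.fixture(scope="session")
def strong_plan(strong_table):
    return m.assign_speaker_folds(strong_table[["speaker_id", "label"]], k=7, seed=STRONG_SEED)


@pytest.fixture(scope="session")
def strong_single_metric_cv(strong_table, strong_plan):
    """Mean CV efficiency of each metric's EER detector on the strong corpus."""
    out = {}
    for name in m.METRIC_NAMES:
        scores = strong_table.rename(columns={name: "score"})[
            ["recording_id", "speaker_id", "label", "frame_index", "score"]
        ]
        out[name] = m.cv_single_metric_efficiency(scores, strong_plan).mean_efficiency
    return out


def metric_scores(table: pd.DataFrame, name: str) -> pd.DataFrame:
    return table.rename(columns={name: "score"})[
        ["recording_id", "speaker_id", "label", "frame_index", "score"]
    ]


@pytest.fixture(scope="session")
def tone_spectrum():
    """MS of one 180 ms frame of a 1 kHz tone at 25 kHz."""
    rec = m.pure_tone(1000.0, 1.0, 25_000.0)
    frame = m.frame_signal(rec, 180.0).frames[0]
    return m.compute_modspec(frame, rec.fs)
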
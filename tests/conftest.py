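"""Shared fixtures.

The expensive end-to-end runs (train on sequence 01, segment and track
sequence 02) are session-scoped and computed once; individual tests assert
different properties of the same run.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

from stiptrack import metrics, pipeline
from stiptrack.io_ctc import SequenceHandle
from stiptrack.synthetic import default_fixture
from stiptrack.tracking import count_divisions


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def fixture_noisy():
    return default_fixture(noisy=True)


@pytest.fixture(scope="session")
def fixture_noisefree():
    return default_fixture(noisy=False)


@dataclass
class EndToEndRun:
    f1: float
    seg: float
    det: float
    tra: float
    divisions: int
    planted_divisions: int
    pred_counts: list[int]
    true_counts: list[int]
    labelmaps: list[np.ndarray]
    tracked_masks: list[np.ndarray]
    records: list


def _run_end_to_end(fix) -> EndToEndRun:
    s01, s02 = fix["01"], fix["02"]
    seq01 = SequenceHandle(frames=s01.frames)
    seq02 = SequenceHandle(frames=s02.frames)
    an01, f01 = pipeline.analyze_sequence(seq01)
    model = pipeline.train_on_sequence(seq01, s01.masks, analyses=an01,
                                       fields=f01)
    an02, f02 = pipeline.analyze_sequence(seq02)
    labelmaps = pipeline.segment_sequence(seq02, model, analyses=an02,
                                          fields=f02)
    masks, records, tracks, _ = pipeline.track_segmented(labelmaps, f02)
    report = metrics.evaluate_sequences(masks, records, s02.masks, s02.lineage)
    return EndToEndRun(
        f1=pipeline.foreground_f1(labelmaps, s02.masks),
        seg=report.seg, det=report.det, tra=report.tra,
        divisions=count_divisions(tracks),
        planted_divisions=len(s02.config.divisions),
        pred_counts=[int(len(np.unique(m)) - 1) for m in labelmaps],
        true_counts=[int(len(np.unique(m)) - 1) for m in s02.masks],
        labelmaps=labelmaps, tracked_masks=masks, records=records,
    )


@pytest.fixture(scope="session")
def e2e_noisy(fixture_noisy):
    return _run_end_to_end(fixture_noisy)


@pytest.fixture(scope="session")
def e2e_noisefree(fixture_noisefree):
    return _run_end_to_end(fixture_noisefree)
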
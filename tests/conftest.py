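import numpy as np
import pytest

from tracemem import (
    StimulusEvent,
    TraceParams,
    TrialLog,
    TrialResult,
    TrialSpec,
)


@pytest.fixture
def default_params() -> TraceParams:
    return TraceParams()


@pytest.fixture
def noiseless_params() -> TraceParams:
    return TraceParams(noise_sd=0.0, lapse=0.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_log(correct_flags, sessions=None, subject="fix") -> TrialLog:
    """Hand-built sequence-task log with prescribed correct/incorrect trials."""
    results = []
    for i, correct in enumerate(correct_flags):
        tt = "AB" if correct else "AA"
        first = "A"
        second = "B" if tt == "AB" else "A"
        spec = TrialSpec(
            phase="sequence_disc",
            trial_index=i + 1,
            block_index=i // 18 + 1,
            trial_type=tt,
            sample_events=(
                StimulusEvent(first, 0.0, 1.0),
                StimulusEvent(second, 1.3, 2.3),
            ),
            delay=0.0,
            options=("left", "right"),
            option_positions=("left", "right"),
            rewarded_option="left" if tt == "AB" else "right",
        )
        response = spec.rewarded_option if correct else (
            "right" if spec.rewarded_option == "left" else "left")
        session = 1 if sessions is None else sessions[i]
        results.append(TrialResult(spec=spec, response=response,
                                   correct=bool(correct),
                                   rewarded=bool(correct), session=session))
    return TrialLog(subject_id=subject, results=results, metadata={"seed": 0})
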
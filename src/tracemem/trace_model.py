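"""Memory-trace representation of stimulus sequences.

A presented stimulus leaves a *memory trace*: a scalar intensity that grows
with exposure duration and decays exponentially with elapsed time.  A
two-stimulus sequence is represented only as the unordered pair of trace
intensities at decision time — order information survives solely through
differential decay (the earlier stimulus has faded more).  Choices among
on-screen options are read out from the traces through a softmax with
temperature ``beta``, a uniform lapse ``epsilon``, or a noisy
winner-take-all with Gaussian intensity noise ``sigma``.

Closed-form predictions derived here:

* :func:`retention_curve` — exponential forgetting of a single sample in
  delayed matching-to-sample, ``c + (1 - c) * a * exp(-lambda_r * delay)``.
* :func:`probe_prediction` — the probability of choosing the *first* of the
  two sample stimuli on a sequence probe trial, as a function of the two
  exposure durations and the decay rate.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "StimulusEvent",
    "TraceParams",
    "TraceState",
    "RetentionParams",
    "encode_intensity",
    "trace_state",
    "choice_probabilities",
    "probe_prediction",
    "retention_curve",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StimulusEvent:
    """One timed presentation of an identified stimulus.

    Times are in seconds from trial onset; ``offset`` must exceed ``onset``.
    """

    stimulus_id: str
    onset: float
    offset: float

    def __post_init__(self) -> None:
        if self.onset < 0:
            raise ValueError(f"onset must be >= 0, got {self.onset}")
        if not self.offset > self.onset:
            raise ValueError(
                f"offset must exceed onset, got [{self.onset}, {self.offset}]"
            )

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass(frozen=True)
class TraceParams:
    """Parameters of the trace model.

    gain
        Per-second encoding rate ``g`` (> 0): how fast exposure builds trace
        intensity.  With the default saturating law, intensity after a
        presentation of duration ``d`` is ``1 - exp(-g * d)``.
    decay
        Per-second decay rate ``lambda`` (>= 0) of intensity after offset.
    noise_sd
        S.d. ``sigma`` (>= 0) of Gaussian intensity noise at decision time
        (used by the noisy winner-take-all readout and by simulated agents).
    temperature
        Softmax inverse temperature ``beta`` (>= 0).
    lapse
        Probability ``epsilon`` in [0, 1] of a uniform random response,
        mixed in after the softmax.
    encoding
        ``"saturating"`` (default) or ``"linear"`` (intensity ``g * d``).
    noise_model
        ``"additive"`` (default) or ``"weber"`` (s.d. proportional to
        intensity, ``sigma * intensity``).
    """

    gain: float = 1.0
    decay: float = 0.5
    noise_sd: float = 0.3
    temperature: float = 3.0
    lapse: float = 0.02
    encoding: str = "saturating"
    noise_model: str = "additive"

    def __post_init__(self) -> None:
        if not self.gain > 0:
            raise ValueError(f"gain must be > 0, got {self.gain}")
        if self.decay < 0:
            raise ValueError(f"decay must be >= 0, got {self.decay}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.temperature < 0:
            raise ValueError(f"temperature must be >= 0, got {self.temperature}")
        if not 0.0 <= self.lapse <= 1.0:
            raise ValueError(f"lapse must be in [0, 1], got {self.lapse}")
        if self.encoding not in ("saturating", "linear"):
            raise ValueError(f"unknown encoding law {self.encoding!r}")
        if self.noise_model not in ("additive", "weber"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")

    # flat JSON round-trip -------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "TraceParams":
        return cls(**json.loads(text))


@dataclass(frozen=True)
class TraceState:
    """Trace intensities for every presented stimulus at ``query_time``.

    Stimuli never presented are absent from the map and read as 0.
    """

    intensities: Mapping[str, float]
    query_time: float

    def __post_init__(self) -> None:
        for sid, x in self.intensities.items():
            if x < 0:
                raise ValueError(f"negative intensity {x} for {sid!r}")

    def intensity(self, stimulus_id: str) -> float:
        return self.intensities.get(stimulus_id, 0.0)


@dataclass(frozen=True)
class RetentionParams:
    """Exponential retention curve for delayed matching-to-sample.

    Predicted proportion correct is ``c + (1 - c) * a * exp(-lambda_r * d)``
    for delay ``d``: at zero delay ``c + (1 - c) * a``, falling to the chance
    level ``c`` as the delay grows.
    """

    asymptote: float
    decay_rate: float
    chance: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.asymptote <= 1.0:
            raise ValueError(f"asymptote must be in [0, 1], got {self.asymptote}")
        if self.decay_rate < 0:
            raise ValueError(f"decay_rate must be >= 0, got {self.decay_rate}")
        if not 0.0 < self.chance < 1.0:
            raise ValueError(f"chance must be in (0, 1), got {self.chance}")

    def to_json(self) -> str:
        return json.dumps(
            {"asymptote": self.asymptote, "decay_rate": self.decay_rate,
             "chance": self.chance}
        )

    @classmethod
    def from_json(cls, text: str) -> "RetentionParams":
        return cls(**json.loads(text))


# ---------------------------------------------------------------------------
# Encoding and decay
# ---------------------------------------------------------------------------

def encode_intensity(duration: float, params: TraceParams) -> float:
    """Trace intensity laid down by a single presentation of ``duration`` s.

    Saturating law (default): ``1 - exp(-g * duration)`` — strictly
    increasing in duration and bounded by 1, so very long exposures do not
    dominate without limit.  The linear law ``g * duration`` is available via
    ``params.encoding``.
    """
    if not duration > 0:
        raise ValueError(f"duration must be > 0, got {duration}")
    if params.encoding == "linear":
        return params.gain * duration
    return -math.expm1(-params.gain * duration)


def trace_state(
    events: Iterable[StimulusEvent], t: float, params: TraceParams
) -> TraceState:
    """Trace intensities at time ``t`` for a set of presentations.

    Each event contributes ``encode_intensity(duration) * exp(-lambda * (t -
    offset))``; repeated presentations of the same stimulus add.  ``t`` must
    not precede the last offset (traces are queried after the sequence ends).
    """
    events = list(events)
    if events:
        last = max(e.offset for e in events)
        if t < last:
            raise ValueError(
                f"query time {t} precedes the last stimulus offset {last}"
            )
    intensities: dict[str, float] = {}
    for e in events:
        contrib = encode_intensity(e.duration, params) * math.exp(
            -params.decay * (t - e.offset)
        )
        intensities[e.stimulus_id] = intensities.get(e.stimulus_id, 0.0) + contrib
    return TraceState(intensities=intensities, query_time=t)


# ---------------------------------------------------------------------------
# Choice readout
# ---------------------------------------------------------------------------

def _softmax_lapse(intensities: np.ndarray, beta: float, lapse: float) -> np.ndarray:
    z = beta * intensities
    z = z - z.max()
    w = np.exp(z)
    p = w / w.sum()
    k = len(p)
    return (1.0 - lapse) * p + lapse / k


def choice_probabilities(
    state: TraceState,
    options: Sequence[str],
    params: TraceParams,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Probability of choosing each on-screen option from its trace.

    Without ``rng``: softmax over ``beta * intensity``, mixed with the lapse
    rate toward uniform.  With ``rng``: intensities are perturbed once by
    zero-mean Gaussian noise of s.d. ``sigma`` (or ``sigma * intensity``
    under the Weber model) and all mass goes to the noisy maximum, again
    lapse-mixed; this is the single-trial readout simulated agents use.
    """
    if len(options) == 0:
        raise ValueError("options must be non-empty")
    if len(set(options)) != len(options):
        raise ValueError("options must be unique")
    x = np.array([state.intensity(o) for o in options], dtype=float)
    k = len(x)
    if rng is None:
        return _softmax_lapse(x, params.temperature, params.lapse)
    if params.noise_model == "weber":
        noisy = x + rng.normal(0.0, params.noise_sd * np.abs(x))
    else:
        noisy = x + rng.normal(0.0, params.noise_sd, size=k)
    p = np.zeros(k)
    p[int(np.argmax(noisy))] = 1.0
    return (1.0 - params.lapse) * p + params.lapse / k


# ---------------------------------------------------------------------------
# Closed-form task predictions
# ---------------------------------------------------------------------------

def probe_prediction(
    d_first: float,
    isi: float,
    d_second: float,
    retention_gap: float,
    params: TraceParams,
) -> float:
    """P(choose the first-sample stimulus | a sample stimulus is chosen).

    Builds the two-event probe sequence (first stimulus for ``d_first`` s,
    blank inter-stimulus interval, second stimulus for ``d_second`` s),
    evaluates the traces at options onset (``retention_gap`` s after the
    second offset), places the two samples among four options with the two
    non-matching foils at intensity 0, and returns the softmax+lapse choice
    probability of the first sample conditional on either sample being
    chosen.

    With equal durations and any positive decay this is < 0.5 (recency); it
    increases with ``d_first`` and decreases with ``d_second``.
    """
    if not (d_first > 0 and d_second > 0):
        raise ValueError("stimulus durations must be > 0")
    if isi < 0 or retention_gap < 0:
        raise ValueError("isi and retention_gap must be >= 0")
    events = [
        StimulusEvent("first", 0.0, d_first),
        StimulusEvent("second", d_first + isi, d_first + isi + d_second),
    ]
    t = events[-1].offset + retention_gap
    state = trace_state(events, t, params)
    p = choice_probabilities(state, ["first", "second", "foil1", "foil2"], params)
    return float(p[0] / (p[0] + p[1]))


def retention_curve(delay, rp: RetentionParams):
    """Predicted proportion correct at ``delay`` s in two-option DMTS.

    ``c + (1 - c) * a * exp(-lambda_r * delay)``; accepts a scalar or array
    delay and never leaves ``[c, 1]``.
    """
    delay = np.asarray(delay, dtype=float)
    if np.any(delay < 0):
        raise ValueError("delay must be >= 0")
    out = rp.chance + (1.0 - rp.chance) * rp.asymptote * np.exp(
        -rp.decay_rate * delay
    )
    return float(out) if out.ndim == 0 else out
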
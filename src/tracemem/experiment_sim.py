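"""Simulators of the three behavioural paradigms and the agents that run them.

Three touchscreen tasks are scheduled exactly as administered:

* **Matching-to-sample (MTS)** — a sample colour, then (after an optional
  delay) the two colours side by side; choosing the match is rewarded.
  Sample colour and correct side are balanced 5/5 within every 10-trial
  window.  The delayed variant alternates 0-s delay trials with
  pseudo-random draws from the non-zero delays {2, 5, 10} s.
* **Two-choice sequence discrimination** — two 1-s colour screens separated
  by a 0.3-s gap, then a left and a right response button.  AB rewards
  left; AA, BA and BB reward right.  Blocks of 18 trials contain 9 AB and
  3 of each other type, shuffled.  Errors trigger correction trials: the
  same sequence repeats until answered correctly.
* **Probe phase** — 4-alternative MTS over a 20-item picture pool, with one
  unrewarded two-stimulus sequence probe hidden at a random position in
  every 10-trial block; probe options contain both sample stimuli plus two
  foils, and the six probe duration conditions cross a 1-s standard with
  {0.5, 1.5, 4.5} s comparisons.

Agents implement ``act(spec, rng) -> response`` and ``learn(result)``:

* :class:`TraceAgent` perceives only noisy trace intensities (never the
  ordered sequence) and learns side values by the delta rule.
* :class:`FaithfulAgent` perceives the ordered sequence as a lossless key —
  the human-like learner — with tabular delta-rule values.
* :class:`RandomAgent` is the chance baseline.

All randomness flows from explicit ``numpy.random.Generator`` objects; the
same (seed, config) always yields byte-identical schedules and logs.
"""

from __future__ import annotations

import math
import warnings
from abc import ABC, abstractmethod
from collections import deque
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .trace_model import StimulusEvent, TraceParams, trace_state

__all__ = [
    "PHASES",
    "DMTS_DELAYS",
    "PROBE_CONDITIONS",
    "SEQUENCE_ISI",
    "TrialSpec",
    "TrialResult",
    "TrialLog",
    "Agent",
    "RandomAgent",
    "TraceAgent",
    "FaithfulAgent",
    "AgentContractError",
    "schedule_mts",
    "schedule_delayed_mts",
    "schedule_sequence_task",
    "schedule_probe_phase",
    "run_task",
]

PHASES = (
    "simultaneous_mts",
    "zero_delay_mts",
    "delayed_mts",
    "sequence_disc",
    "probe_mts",
)

#: delays (s) used in the delayed matching-to-sample test
DMTS_DELAYS = (0.0, 2.0, 5.0, 10.0)

#: (first duration, second duration) in seconds for the six probe conditions
PROBE_CONDITIONS = (
    (0.5, 1.0),
    (1.5, 1.0),
    (4.5, 1.0),
    (1.0, 0.5),
    (1.0, 1.5),
    (1.0, 4.5),
)

#: gap between the two stimuli of a sequence (s)
SEQUENCE_ISI = 0.3
#: sample exposure in MTS pre-training / delayed MTS (s)
MTS_SAMPLE_DURATION = 2.0
#: sample exposure on baseline trials of the probe phase (s)
BASELINE_SAMPLE_DURATION = 1.0
#: sequence-task stimulus exposure (s)
SEQUENCE_STIM_DURATION = 1.0


class AgentContractError(RuntimeError):
    """An agent returned a response that was not among the on-screen options."""


# ---------------------------------------------------------------------------
# Trial records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrialSpec:
    """One scheduled trial: what is shown, when, and what pays off."""

    phase: str
    trial_index: int
    block_index: int
    trial_type: str
    sample_events: tuple[StimulusEvent, ...]
    delay: float
    options: tuple[str, ...]
    option_positions: tuple[str, ...]
    rewarded_option: str | None
    is_probe: bool = False
    is_correction: bool = False

    def __post_init__(self) -> None:
        if self.phase not in PHASES:
            raise ValueError(f"unknown phase {self.phase!r}")
        if self.is_probe and self.rewarded_option is not None:
            raise ValueError("probe trials are never rewarded")
        if len(self.options) != len(set(self.options)):
            raise ValueError("options must be unique")
        if self.phase == "sequence_disc" and not self.is_probe:
            if len(self.sample_events) != 2:
                raise ValueError("sequence trials show exactly 2 sample stimuli")

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(e.stimulus_id for e in self.sample_events)

    @property
    def decision_time(self) -> float:
        """Options onset: last sample offset plus the retention delay."""
        last = max(e.offset for e in self.sample_events)
        return last + self.delay


@dataclass(frozen=True)
class TrialResult:
    spec: TrialSpec
    response: str
    correct: bool
    rewarded: bool
    session: int = 1

    def __post_init__(self) -> None:
        if self.spec.is_probe and self.rewarded:
            raise ValueError("probe trials are never rewarded")
        if self.correct and not self.spec.is_probe and not self.rewarded:
            raise ValueError("correct non-probe responses are rewarded")


#: column order of the on-disk trial log
LOG_COLUMNS = [
    "subject_id", "phase", "session", "block", "trial", "trial_type",
    "delay_s", "dur_first_s", "dur_second_s", "isi_s", "sample_ids",
    "is_probe", "is_correction", "option_ids", "response",
    "rewarded_option", "correct", "rewarded", "seed",
]


@dataclass
class TrialLog:
    """Ordered trial results for one subject and phase; the unit all
    analyses consume.  Serializes to a one-row-per-trial UTF-8 CSV."""

    subject_id: str
    results: list[TrialResult]
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.results)

    def __iter__(self):
        return iter(self.results)

    def to_frame(self) -> pd.DataFrame:
        seed = self.metadata.get("seed", -1)
        rows = []
        for r in self.results:
            s = r.spec
            ev = s.sample_events
            d1 = ev[0].duration if len(ev) >= 1 else np.nan
            d2 = ev[1].duration if len(ev) >= 2 else np.nan
            isi = ev[1].onset - ev[0].offset if len(ev) >= 2 else np.nan
            rows.append({
                "subject_id": self.subject_id,
                "phase": s.phase,
                "session": r.session,
                "block": s.block_index,
                "trial": s.trial_index,
                "trial_type": s.trial_type,
                "delay_s": s.delay,
                "dur_first_s": d1,
                "dur_second_s": d2,
                "isi_s": isi,
                "sample_ids": "|".join(s.sample_ids),
                "is_probe": s.is_probe,
                "is_correction": s.is_correction,
                "option_ids": "|".join(s.options),
                "response": r.response,
                "rewarded_option": s.rewarded_option if s.rewarded_option else np.nan,
                "correct": r.correct,
                "rewarded": r.rewarded,
                "seed": seed,
            })
        return pd.DataFrame(rows, columns=LOG_COLUMNS)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, encoding="utf-8")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "TrialLog":
        results: list[TrialResult] = []
        for row in frame.itertuples(index=False):
            samples = str(row.sample_ids).split("|") if row.sample_ids else []
            events = []
            if samples:
                d1 = float(row.dur_first_s)
                events.append(StimulusEvent(samples[0], 0.0, d1))
                if len(samples) > 1 and not pd.isna(row.dur_second_s):
                    isi = float(row.isi_s)
                    d2 = float(row.dur_second_s)
                    events.append(StimulusEvent(samples[1], d1 + isi, d1 + isi + d2))
            rewarded_option = (
                None if pd.isna(row.rewarded_option) else str(row.rewarded_option)
            )
            spec = TrialSpec(
                phase=str(row.phase),
                trial_index=int(row.trial),
                block_index=int(row.block),
                trial_type=str(row.trial_type),
                sample_events=tuple(events),
                delay=float(row.delay_s),
                options=tuple(str(row.option_ids).split("|")),
                option_positions=tuple(
                    f"p{i + 1}" for i in range(len(str(row.option_ids).split("|")))
                ),
                rewarded_option=rewarded_option,
                is_probe=bool(row.is_probe),
                is_correction=bool(row.is_correction),
            )
            results.append(TrialResult(
                spec=spec,
                response=str(row.response),
                correct=bool(row.correct),
                rewarded=bool(row.rewarded),
                session=int(row.session),
            ))
        subject = str(frame["subject_id"].iloc[0]) if len(frame) else "unknown"
        seed = int(frame["seed"].iloc[0]) if len(frame) else -1
        return cls(subject_id=subject, results=results, metadata={"seed": seed})

    @classmethod
    def from_csv(cls, path) -> "TrialLog":
        return cls.from_frame(pd.read_csv(path, encoding="utf-8"))


# ---------------------------------------------------------------------------
# Schedulers
# ---------------------------------------------------------------------------

def _balanced_pairs(n: int, rng: np.random.Generator,
                    stimuli: tuple[str, str]) -> list[tuple[str, str]]:
    """(sample colour, correct side) pairs balanced 5/5 per 10-trial window."""
    pairs: list[tuple[str, str]] = []
    full, rem = divmod(n, 10)
    for _ in range(full):
        colours = [stimuli[0]] * 5 + [stimuli[1]] * 5
        sides = ["left"] * 5 + ["right"] * 5
        rng.shuffle(colours)
        rng.shuffle(sides)
        pairs.extend(zip(colours, sides))
    if rem:
        warnings.warn(
            f"{n} trials is not a multiple of 10; the final {rem}-trial "
            "window is drawn without the 5/5 balance guarantee",
            stacklevel=3,
        )
        colours = [stimuli[int(b)] for b in rng.integers(0, 2, size=rem)]
        sides = [("left", "right")[int(b)] for b in rng.integers(0, 2, size=rem)]
        pairs.extend(zip(colours, sides))
    return pairs


def _mts_spec(phase: str, idx: int, colour: str, side: str, delay: float,
              stimuli: tuple[str, str], trial_type: str) -> TrialSpec:
    other = stimuli[1] if colour == stimuli[0] else stimuli[0]
    options = (colour, other) if side == "left" else (other, colour)
    return TrialSpec(
        phase=phase,
        trial_index=idx,
        block_index=(idx - 1) // 10 + 1,
        trial_type=trial_type,
        sample_events=(StimulusEvent(colour, 0.0, MTS_SAMPLE_DURATION),),
        delay=delay,
        options=options,
        option_positions=("left", "right"),
        rewarded_option=colour,
    )


def schedule_mts(
    phase: str,
    n_trials: int,
    seed: int,
    stimuli: tuple[str, str] = ("A", "B"),
) -> list[TrialSpec]:
    """Simultaneous or zero-delay MTS pre-training schedule.

    Sample colour and correct side are each represented 5 times, in random
    order, within every 10-trial window aligned to block starts.
    """
    if phase not in ("simultaneous_mts", "zero_delay_mts"):
        raise ValueError(f"phase must be a pre-training MTS phase, got {phase!r}")
    if n_trials <= 0:
        raise ValueError("n_trials must be > 0")
    rng = np.random.default_rng(seed)
    pairs = _balanced_pairs(n_trials, rng, stimuli)
    return [
        _mts_spec(phase, i + 1, colour, side, 0.0, stimuli, "delay_0")
        for i, (colour, side) in enumerate(pairs)
    ]


def schedule_delayed_mts(
    n_trials: int,
    delays: Sequence[float] = DMTS_DELAYS,
    seed: int = 0,
    stimuli: tuple[str, str] = ("A", "B"),
) -> list[TrialSpec]:
    """Delayed-MTS schedule: every second trial (1st, 3rd, ...) has a 0-s
    delay to keep reward rates high; the remaining slots draw from the
    non-zero delays in shuffled balanced blocks (each non-zero delay equally
    often over the long run)."""
    if n_trials <= 0:
        raise ValueError("n_trials must be > 0")
    delays = sorted(set(float(d) for d in delays))
    if not delays:
        raise ValueError("delay set must be non-empty")
    if 0.0 not in delays:
        raise ValueError("delay set must contain 0")
    nonzero = [d for d in delays if d > 0]
    rng = np.random.default_rng(seed)
    pairs = _balanced_pairs(n_trials, rng, stimuli)

    n_slots = n_trials // 2
    draw: list[float] = []
    while len(draw) < n_slots:
        block = list(nonzero) if nonzero else [0.0]
        rng.shuffle(block)
        draw.extend(block)
    draw = draw[:n_slots]

    specs = []
    j = 0
    for i, (colour, side) in enumerate(pairs):
        if i % 2 == 0:
            d = 0.0
        else:
            d = draw[j]
            j += 1
        label = f"delay_{d:g}"
        specs.append(_mts_spec("delayed_mts", i + 1, colour, side, d,
                               stimuli, label))
    return specs


def _sequence_events(trial_type: str, stimuli: tuple[str, str]) -> tuple[StimulusEvent, StimulusEvent]:
    ids = {"A": stimuli[0], "B": stimuli[1]}
    first, second = ids[trial_type[0]], ids[trial_type[1]]
    t1 = SEQUENCE_STIM_DURATION
    t2 = t1 + SEQUENCE_ISI
    return (
        StimulusEvent(first, 0.0, t1),
        StimulusEvent(second, t2, t2 + SEQUENCE_STIM_DURATION),
    )


def schedule_sequence_task(
    n_blocks: int,
    seed: int = 0,
    assignment: Mapping[str, str] | None = None,
) -> list[TrialSpec]:
    """Two-choice sequence-discrimination schedule.

    Each 18-trial block holds 9 AB and 3 each of AA, BA, BB, shuffled.  AB
    rewards the left button; everything else rewards the right button.
    ``assignment`` optionally relabels the abstract stimuli A and B to
    counterbalanced colour tokens; the reward structure is unchanged (agents
    are colour-blind to the names).
    """
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    if assignment is not None:
        if set(assignment) != {"A", "B"}:
            raise ValueError("assignment must map exactly the keys A and B")
        stimuli = (assignment["A"], assignment["B"])
    else:
        stimuli = ("A", "B")
    rng = np.random.default_rng(seed)
    specs = []
    idx = 0
    for b in range(n_blocks):
        types = ["AB"] * 9 + ["AA", "BA", "BB"] * 3
        rng.shuffle(types)
        for tt in types:
            idx += 1
            specs.append(TrialSpec(
                phase="sequence_disc",
                trial_index=idx,
                block_index=b + 1,
                trial_type=tt,
                sample_events=_sequence_events(tt, stimuli),
                delay=0.0,
                options=("left", "right"),
                option_positions=("left", "right"),
                rewarded_option="left" if tt == "AB" else "right",
            ))
    return specs


def schedule_probe_phase(
    conditions: Sequence[tuple[float, float]] | None = None,
    reps_per_condition: int = 20,
    block_len: int = 10,
    pool_size: int = 20,
    seed: int = 0,
    isi: float = SEQUENCE_ISI,
) -> list[TrialSpec]:
    """Probe-phase schedule: 4-alternative matching with hidden sequence probes.

    One probe per ``block_len``-trial block at a uniformly random position.
    Probe samples are two distinct stimuli drawn from the pool; the options
    are both samples plus two non-matching foils, and no probe response is
    rewarded.  Baseline trials show a 1-s sample and four options (sample +
    three foils).  At the defaults this yields ``20 x 6 = 120`` probes in
    1200 trials.
    """
    if conditions is None:
        conditions = PROBE_CONDITIONS
    if pool_size < 4:
        raise ValueError("pool_size must be >= 4 to form four options")
    if reps_per_condition < 1 or block_len < 1:
        raise ValueError("reps_per_condition and block_len must be >= 1")
    rng = np.random.default_rng(seed)
    pool = [f"s{i + 1:02d}" for i in range(pool_size)]

    order: list[tuple[float, float]] = []
    for _ in range(reps_per_condition):
        idx = rng.permutation(len(conditions))
        order.extend(conditions[i] for i in idx)

    specs = []
    t_idx = 0
    for b, (d1, d2) in enumerate(order):
        probe_pos = int(rng.integers(block_len))
        for pos in range(block_len):
            t_idx += 1
            if pos == probe_pos:
                pair = rng.choice(len(pool), size=2, replace=False)
                first, second = pool[pair[0]], pool[pair[1]]
                foils = [s for s in pool if s not in (first, second)]
                foil_idx = rng.choice(len(foils), size=2, replace=False)
                opts = [first, second, foils[foil_idx[0]], foils[foil_idx[1]]]
                perm = rng.permutation(4)
                options = tuple(opts[i] for i in perm)
                events = (
                    StimulusEvent(first, 0.0, d1),
                    StimulusEvent(second, d1 + isi, d1 + isi + d2),
                )
                specs.append(TrialSpec(
                    phase="probe_mts", trial_index=t_idx, block_index=b + 1,
                    trial_type="probe", sample_events=events, delay=0.0,
                    options=options,
                    option_positions=("p1", "p2", "p3", "p4"),
                    rewarded_option=None, is_probe=True,
                ))
            else:
                sample = pool[int(rng.integers(pool_size))]
                foils = [s for s in pool if s != sample]
                foil_idx = rng.choice(len(foils), size=3, replace=False)
                opts = [sample] + [foils[i] for i in foil_idx]
                perm = rng.permutation(4)
                options = tuple(opts[i] for i in perm)
                specs.append(TrialSpec(
                    phase="probe_mts", trial_index=t_idx, block_index=b + 1,
                    trial_type="baseline",
                    sample_events=(StimulusEvent(
                        sample, 0.0, BASELINE_SAMPLE_DURATION),),
                    delay=0.0,
                    options=options,
                    option_positions=("p1", "p2", "p3", "p4"),
                    rewarded_option=sample,
                ))
    return specs


# ---------------------------------------------------------------------------
# Agents
# ---------------------------------------------------------------------------

class Agent(ABC):
    """Behaviour contract: a response policy plus an update rule.

    ``act`` must be a pure function of internal state, the trial spec and
    the supplied generator; all learning happens in ``learn``.
    """

    @abstractmethod
    def act(self, spec: TrialSpec, rng: np.random.Generator) -> str:
        ...

    def learn(self, result: TrialResult) -> None:  # noqa: B027 - optional hook
        pass


class RandomAgent(Agent):
    """Uniform random choice among the on-screen options."""

    def act(self, spec: TrialSpec, rng: np.random.Generator) -> str:
        return spec.options[int(rng.integers(len(spec.options)))]


class TraceAgent(Agent):
    """Responds from noisy memory-trace intensities only.

    On matching trials the agent picks the option with the largest noisy
    trace (lapsing to a random option with probability ``lapse``).  On
    sequence trials it perceives the unordered pair of noisy intensities
    (m_first_colour, m_second_colour) at decision time — never the ordered
    sequence — and chooses a side by softmax over linear action values
    ``w . (m_A, m_B, 1)``, updated by the delta rule on reward.
    """

    def __init__(self, params: TraceParams, stimuli: tuple[str, str] = ("A", "B"),
                 alpha: float = 0.1):
        if not 0 < alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        self.params = params
        self.stimuli = tuple(stimuli)
        self.alpha = alpha
        self.weights = np.zeros((2, 3))  # rows: left, right
        self._seq_cache: dict[str, tuple[float, float]] = {}
        self._last_features: np.ndarray | None = None

    # -- perception --------------------------------------------------------
    def _sequence_intensities(self, spec: TrialSpec) -> tuple[float, float]:
        key = spec.trial_type
        cached = self._seq_cache.get(key)
        if cached is None:
            state = trace_state(spec.sample_events, spec.decision_time,
                                self.params)
            cached = (state.intensity(self.stimuli[0]),
                      state.intensity(self.stimuli[1]))
            self._seq_cache[key] = cached
        return cached

    def act(self, spec: TrialSpec, rng: np.random.Generator) -> str:
        p = self.params
        if spec.phase == "sequence_disc":
            m = self._sequence_intensities(spec)
            noise = rng.normal(0.0, p.noise_sd, size=2) if p.noise_sd > 0 else (0.0, 0.0)
            x = np.array([m[0] + noise[0], m[1] + noise[1], 1.0])
            self._last_features = x
            z = self.weights @ x
            d = float(z[0] - z[1])
            # numerically stable logistic
            p_left = 1.0 / (1.0 + math.exp(-d)) if d >= 0 else (
                math.exp(d) / (1.0 + math.exp(d)))
            return "left" if rng.random() < p_left else "right"
        # matching phases: noisy winner-take-all over option traces
        if p.lapse > 0 and rng.random() < p.lapse:
            return spec.options[int(rng.integers(len(spec.options)))]
        state = trace_state(spec.sample_events, spec.decision_time, p)
        vals = np.array([state.intensity(o) for o in spec.options])
        if p.noise_sd > 0:
            if p.noise_model == "weber":
                vals = vals + rng.normal(0.0, p.noise_sd * np.abs(vals))
            else:
                vals = vals + rng.normal(0.0, p.noise_sd, size=len(vals))
        return spec.options[int(np.argmax(vals))]

    def learn(self, result: TrialResult) -> None:
        if result.spec.phase != "sequence_disc" or self._last_features is None:
            return
        j = 0 if result.response == "left" else 1
        x = self._last_features
        r = 1.0 if result.rewarded else 0.0
        v = float(self.weights[j] @ x)
        # normalized step keeps the delta rule stable for any feature scale
        step = self.alpha / max(1.0, float(x @ x))
        self.weights[j] += step * (r - v) * x
        self._last_features = None


class FaithfulAgent(Agent):
    """Perceives the ordered stimulus sequence as a lossless key.

    Tabular action values per (ordered sequence key, response), delta-rule
    update, epsilon-greedy policy.  Values start optimistic (``q_init``
    above the 0 reward of an error) so a single unrewarded mistake rules an
    option out; with learning rate 1 and deterministic reward this gives at
    most one error per key after its first exposure (up to exploration).
    """

    def __init__(self, alpha: float = 1.0, epsilon: float = 0.1,
                 q_init: float = 0.5):
        if not 0 < alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        if not 0 <= epsilon < 1:
            raise ValueError("epsilon must be in [0, 1)")
        self.alpha = alpha
        self.epsilon = epsilon
        self.q_init = q_init
        self.q: dict[tuple[tuple[str, ...], str], float] = {}
        self._last_key: tuple[str, ...] | None = None

    def act(self, spec: TrialSpec, rng: np.random.Generator) -> str:
        key = spec.sample_ids  # ordered: AB and BA are distinct keys
        self._last_key = key
        if self.epsilon > 0 and rng.random() < self.epsilon:
            return spec.options[int(rng.integers(len(spec.options)))]
        vals = np.array([self.q.get((key, o), self.q_init)
                         for o in spec.options])
        best = np.flatnonzero(vals == vals.max())
        return spec.options[int(best[int(rng.integers(len(best)))])]

    def learn(self, result: TrialResult) -> None:
        key = self._last_key if self._last_key is not None else result.spec.sample_ids
        pair = (key, result.response)
        v = self.q.get(pair, self.q_init)
        r = 1.0 if result.rewarded else 0.0
        self.q[pair] = v + self.alpha * (r - v)
        self._last_key = None


# ---------------------------------------------------------------------------
# Task execution
# ---------------------------------------------------------------------------

def run_task(
    agent: Agent,
    schedule: Sequence[TrialSpec],
    correction: bool = False,
    seed: int = 0,
    subject_id: str = "sim",
    session_cap: int | None = None,
    metadata: Mapping | None = None,
) -> TrialLog:
    """Execute a schedule with an agent and return the full trial log.

    With ``correction`` on (sequence task), an incorrect non-probe response
    re-inserts the same trial flagged as a correction, repeating until the
    response is correct; correction trials count toward the log.  Probe
    responses are recorded but never rewarded.  ``session_cap`` splits the
    log into daily sessions of at most that many trials.
    """
    if len(schedule) == 0:
        raise ValueError("schedule must be non-empty")
    rng = np.random.default_rng(seed)
    pending: deque[TrialSpec] = deque(schedule)
    results: list[TrialResult] = []
    idx = 0
    while pending:
        spec = pending.popleft()
        idx += 1
        spec = replace(spec, trial_index=idx)
        response = agent.act(spec, rng)
        if response not in spec.options:
            raise AgentContractError(
                f"agent responded {response!r}; options were {spec.options}"
            )
        correct = (spec.rewarded_option is not None
                   and response == spec.rewarded_option)
        rewarded = correct and not spec.is_probe
        session = 1 if session_cap is None else idx // session_cap + (idx % session_cap > 0)
        result = TrialResult(spec=spec, response=response, correct=correct,
                             rewarded=rewarded, session=session)
        agent.learn(result)
        results.append(result)
        if (correction and not correct and not spec.is_probe
                and spec.phase == "sequence_disc"):
            pending.appendleft(replace(spec, is_correction=True))
    meta = {"seed": seed}
    if metadata:
        meta.update(metadata)
    return TrialLog(subject_id=subject_id, results=results, metadata=meta)
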
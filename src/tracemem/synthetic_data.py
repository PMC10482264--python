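"""Study-shaped synthetic datasets with known ground truth.

Generates complete per-subject trial logs for the three paradigms — delayed
matching-to-sample, two-choice sequence discrimination, and the probe phase
— for a cohort of trace-limited ("bonobo-like") subjects and a cohort of
order-faithful ("human-like") subjects, plus a ground-truth JSON recording
every generating parameter and seed.  Regeneration with the same master
seed is byte-identical, and each log round-trips through the CSV reader.

Also transcribes the in-study probe-count tables for the two tested
subjects into fixtures: contingency tables and *synthetic* probe trial logs
whose per-condition counts match the published ones (the within-condition
response order is invented and non-informative).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .trace_model import RetentionParams, StimulusEvent, TraceParams, retention_curve
from .experiment_sim import (
    PROBE_CONDITIONS,
    FaithfulAgent,
    TraceAgent,
    TrialLog,
    TrialResult,
    TrialSpec,
    run_task,
    schedule_delayed_mts,
    schedule_probe_phase,
    schedule_sequence_task,
)

__all__ = [
    "StudyConfig",
    "generate_study",
    "write_study",
    "transcribe_paper_tables",
    "KANZI_PROBE_COUNTS",
    "TECO_PROBE_COUNTS",
]

# Published probe-count tables: one row per (first duration, second
# duration) condition, columns = responses to the first / second sample.
KANZI_PROBE_COUNTS = ((6, 14), (5, 15), (8, 11), (6, 13), (1, 18), (3, 16))
TECO_PROBE_COUNTS = ((4, 13), (4, 12), (4, 11), (7, 7), (3, 12), (3, 14))


@dataclass(frozen=True)
class StudyConfig:
    """Sizes and generating parameters of a synthetic study.

    Defaults mirror the study design: 4 trace-limited subjects each doing at
    least 2,300 sequence-discrimination trials (128 blocks of 18 = 2,304
    first presentations), a delayed-MTS phase with delays {0, 2, 5, 10} s,
    and a probe phase of 20 repetitions of the six duration conditions; and
    5 order-faithful subjects doing the sequence task.  Subjects are
    parameter-heterogeneous: trace and retention parameters are jittered
    around the cohort means to emulate between-subject spread.
    """

    n_trace_subjects: int = 4
    n_faithful_subjects: int = 5
    master_seed: int = 0
    # cohort-mean trace parameters for bonobo-like simulated subjects
    trace_gain: float = 1.0
    trace_decay: float = 0.5
    trace_noise_sd: float = 0.3
    trace_temperature: float = 3.0
    trace_lapse: float = 0.02
    trace_alpha: float = 0.1
    # cohort-mean retention curve (chosen to sit on the observed DMTS
    # pattern: ~86% at 0 s falling toward chance past 5 s)
    retention_asymptote: float = 0.72
    retention_decay_rate: float = 0.35
    # multiplicative jitter s.d. applied to the means per subject
    subject_jitter: float = 0.1
    # paradigm sizes
    dmts_trials: int = 1200
    dmts_delays: tuple[float, ...] = (0.0, 2.0, 5.0, 10.0)
    sequence_blocks: int = 128
    probe_reps: int = 20
    probe_block_len: int = 10
    probe_pool_size: int = 20
    # faithful-agent policy
    faithful_alpha: float = 1.0
    faithful_epsilon: float = 0.1
    faithful_blocks: int = 8

    def __post_init__(self) -> None:
        if self.n_trace_subjects < 1 or self.n_faithful_subjects < 1:
            raise ValueError("need at least one subject per cohort")
        for name in ("dmts_trials", "sequence_blocks", "probe_reps",
                     "probe_block_len", "faithful_blocks"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.subject_jitter < 0:
            raise ValueError("subject_jitter must be >= 0")

    @classmethod
    def from_json(cls, text: str) -> "StudyConfig":
        data = json.loads(text)
        if "dmts_delays" in data:
            data["dmts_delays"] = tuple(data["dmts_delays"])
        return cls(**data)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def _jitter(rng: np.random.Generator, value: float, sd: float,
            lo: float = 1e-6, hi: float | None = None) -> float:
    out = value * float(np.exp(rng.normal(0.0, sd)))
    if hi is not None:
        out = min(out, hi)
    return max(out, lo)


def _dmts_log(subject: str, rp: RetentionParams, config: StudyConfig,
              seed: int) -> TrialLog:
    """Delayed-MTS log whose per-delay accuracy follows the retention curve."""
    schedule = schedule_delayed_mts(config.dmts_trials, config.dmts_delays,
                                    seed=seed)
    rng = np.random.default_rng(seed + 1)
    results = []
    for spec in schedule:
        p = retention_curve(spec.delay, rp)
        correct = bool(rng.random() < p)
        other = next(o for o in spec.options if o != spec.rewarded_option)
        response = spec.rewarded_option if correct else other
        results.append(TrialResult(spec=spec, response=response,
                                   correct=correct, rewarded=correct))
    return TrialLog(subject_id=subject, results=results,
                    metadata={"seed": seed, "phase": "delayed_mts"})


def generate_study(config: StudyConfig) -> dict:
    """Generate the full synthetic study.

    Returns ``{"logs": {subject_id: {paradigm: TrialLog}}, "ground_truth":
    {...}}``.  Trace-like subjects contribute ``dmts``, ``seqdisc`` and
    ``probe`` logs; faithful-like subjects contribute ``seqdisc`` logs.
    """
    root = np.random.default_rng(config.master_seed)
    # pre-draw independent seeds/jitters so cohort sizes are independent
    logs: dict[str, dict[str, TrialLog]] = {}
    truth: dict = {"master_seed": config.master_seed,
                   "config": asdict(config), "subjects": {}}

    for i in range(config.n_trace_subjects):
        sid = f"trace{i + 1:02d}"
        jrng = np.random.default_rng(root.integers(2**31))
        params = TraceParams(
            gain=_jitter(jrng, config.trace_gain, config.subject_jitter),
            decay=_jitter(jrng, config.trace_decay, config.subject_jitter),
            noise_sd=_jitter(jrng, config.trace_noise_sd, config.subject_jitter),
            temperature=_jitter(jrng, config.trace_temperature,
                                config.subject_jitter),
            lapse=min(config.trace_lapse, 1.0),
        )
        rp = RetentionParams(
            asymptote=_jitter(jrng, config.retention_asymptote,
                              config.subject_jitter, hi=1.0),
            decay_rate=_jitter(jrng, config.retention_decay_rate,
                               config.subject_jitter),
        )
        seed_dmts = int(root.integers(2**31))
        seed_seq = int(root.integers(2**31))
        seed_probe = int(root.integers(2**31))

        dmts = _dmts_log(sid, rp, config, seed_dmts)

        agent = TraceAgent(params, alpha=config.trace_alpha)
        seq = run_task(
            agent,
            schedule_sequence_task(config.sequence_blocks, seed=seed_seq),
            correction=True, seed=seed_seq + 1, subject_id=sid,
        )

        probe_agent = TraceAgent(params, alpha=config.trace_alpha)
        probe = run_task(
            probe_agent,
            schedule_probe_phase(
                PROBE_CONDITIONS, config.probe_reps, config.probe_block_len,
                config.probe_pool_size, seed=seed_probe,
            ),
            seed=seed_probe + 1, subject_id=sid,
        )
        logs[sid] = {"dmts": dmts, "seqdisc": seq, "probe": probe}
        truth["subjects"][sid] = {
            "kind": "trace",
            "trace_params": asdict(params),
            "retention_params": {"asymptote": rp.asymptote,
                                 "decay_rate": rp.decay_rate,
                                 "chance": rp.chance},
            "seeds": {"dmts": seed_dmts, "seqdisc": seed_seq,
                      "probe": seed_probe},
        }

    for i in range(config.n_faithful_subjects):
        sid = f"faithful{i + 1:02d}"
        seed_seq = int(root.integers(2**31))
        agent = FaithfulAgent(alpha=config.faithful_alpha,
                              epsilon=config.faithful_epsilon)
        seq = run_task(
            agent,
            schedule_sequence_task(config.faithful_blocks, seed=seed_seq),
            correction=True, seed=seed_seq + 1, subject_id=sid,
        )
        logs[sid] = {"seqdisc": seq}
        truth["subjects"][sid] = {
            "kind": "faithful",
            "agent_params": {"alpha": config.faithful_alpha,
                             "epsilon": config.faithful_epsilon},
            "seeds": {"seqdisc": seed_seq},
        }

    return {"logs": logs, "ground_truth": truth}


def write_study(bundle: dict, out_dir) -> list[Path]:
    """Write one CSV per subject/paradigm plus ground_truth.json and a
    readme describing the bundle.  Returns the written paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for sid, by_paradigm in bundle["logs"].items():
        for paradigm, log in by_paradigm.items():
            path = out / f"{sid}_{paradigm}.csv"
            log.to_csv(path)
            written.append(path)
    gt = out / "ground_truth.json"
    gt.write_text(json.dumps(bundle["ground_truth"], indent=2),
                  encoding="utf-8")
    written.append(gt)
    readme = out / "README.txt"
    readme.write_text(
        "Synthetic study bundle.\n"
        "One CSV trial log per subject and paradigm "
        "(dmts = delayed matching-to-sample, seqdisc = two-choice sequence\n"
        "discrimination with correction trials, probe = 4-alternative "
        "matching with sequence probe trials).\n"
        "ground_truth.json records every generating parameter and seed.\n",
        encoding="utf-8",
    )
    written.append(readme)
    return written


# ---------------------------------------------------------------------------
# Published-table fixtures
# ---------------------------------------------------------------------------

def _probe_log_from_counts(subject: str, counts) -> TrialLog:
    """Synthetic probe log whose per-condition choice counts match a
    published table.  Within-condition response order (and the identity of
    the foil chosen on no-sample trials) is invented and non-informative."""
    reps = 20
    results = []
    idx = 0
    for cond_i, ((d1, d2), (k_first, k_second)) in enumerate(
            zip(PROBE_CONDITIONS, counts)):
        for j in range(reps):
            idx += 1
            first, second, f1, f2 = (f"c{cond_i}t{j}_{s}"
                                     for s in ("a", "b", "x", "y"))
            events = (
                StimulusEvent(first, 0.0, d1),
                StimulusEvent(second, d1 + 0.3, d1 + 0.3 + d2),
            )
            spec = TrialSpec(
                phase="probe_mts", trial_index=idx, block_index=cond_i * reps + j + 1,
                trial_type="probe", sample_events=events, delay=0.0,
                options=(first, second, f1, f2),
                option_positions=("p1", "p2", "p3", "p4"),
                rewarded_option=None, is_probe=True,
            )
            if j < k_first:
                response = first
            elif j < k_first + k_second:
                response = second
            else:
                response = f1
            results.append(TrialResult(spec=spec, response=response,
                                       correct=False, rewarded=False))
    return TrialLog(subject_id=subject, results=results,
                    metadata={"seed": -1, "source": "published_counts",
                              "synthetic": True})


def transcribe_paper_tables() -> dict:
    """Fixtures built from the published probe-count tables.

    Returns per subject a 6x2 :class:`ContingencyTable` of (chose first,
    chose second) counts across the six probe duration conditions and a
    synthetic probe :class:`TrialLog` consistent with those counts.
    """
    from .stats_analysis import ContingencyTable

    labels = tuple(f"first={c[0]:g}s,second={c[1]:g}s"
                   for c in PROBE_CONDITIONS)
    out: dict = {}
    for subject, counts in (("Kanzi", KANZI_PROBE_COUNTS),
                            ("Teco", TECO_PROBE_COUNTS)):
        table = ContingencyTable(
            row_labels=labels,
            col_labels=("chose_first", "chose_second"),
            counts=np.asarray(counts, dtype=int),
        )
        out[subject] = {
            "table": table,
            "log": _probe_log_from_counts(subject, counts),
        }
    return out
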
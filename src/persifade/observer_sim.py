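"""Synthetic judgment-of-synchrony observers and experiment design builders.

The measurement logic: a transient (or proxy) stimulus event at t_T triggers a
percept after an unknown latency e_T; a reference stimulus presented at
t_T + Δt is perceived after its own latency e_R.  The observer adjusts Δt
across repetitions of the sequence until the reference percept appears
synchronous with the onset (on-trials) or the offset (off-trials) of the
fading percept.  Because both latencies shift the onset and offset settings
equally, the persistence estimate VP = D - E is latency-free; that invariance
is the point of the method and is exercised directly in the test suite.

The observer's decision rule is a stand-in for whatever humans actually do:
on each repetition it perceives the asynchrony A = (t_T + Δt + e_R) -
perceived_event_time plus Gaussian judgment noise, then either confirms or
applies the adjustment that most reduces |A| (greedy over the four key steps,
or a direct knob correction Δt <- Δt - A).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .decay_model import DecayParams, calibrate_offset, persistence_duration

__all__ = [
    "ObserverProfile",
    "AdjustmentControls",
    "SessionState",
    "build_design",
    "perceived_event_time",
    "simulate_trial",
    "simulate_experiment",
    "default_profiles",
    "default_controls",
]

EXP1_SIZES_PX = (100, 200)
EXP1_THICKNESSES_PX = (25, 75)
EXP1_MODALITIES = ("auditory", "visual")
EXP2_DURATIONS_MS = (200, 400, 600, 800, 1000, 1200)
EXP3_DIAMETERS_DEG = (1.5, 3.0, 4.5, 6.0)
EXP3_ECCENTRICITIES_DEG = (3.0, 4.5, 6.0, 7.5)
TASKS = ("onset", "offset")

#: condition fields that vary trial-to-trial and do not define a condition cell
_NON_CELL_FIELDS = frozenset({"direction_rad"})


@dataclass
class ObserverProfile:
    """Latent parameters of one synthetic subject.

    Latencies are in ms.  ``offset_criterion`` is the normalized trace level
    below which the percept counts as gone.  The internal persistence trace
    drives the offset percept of transient shapes; ``base_persistence_ms``,
    when set, replaces the trace-derived duration so condition means can be
    specified directly, with ``persistence_effects`` adding per-condition
    shifts (field name -> {level: shift in ms}).  ``persistence_jitter_sd_ms``
    perturbs the effective persistence once per off-trial, emulating
    trial-to-trial wobble of the offset criterion.
    """

    e_t_ms: float = 60.0
    e_r_auditory_ms: float = 40.0
    e_r_visual_ms: float = 40.0
    offset_criterion: float = 0.01
    judgment_noise_sd_ms: float = 30.0
    confirm_jnd_ms: float = 20.0
    trace: Optional[DecayParams] = None
    base_persistence_ms: Optional[float] = None
    persistence_effects: Mapping[str, Mapping] = field(default_factory=dict)
    persistence_jitter_sd_ms: float = 0.0
    subject: str = "s01"

    def __post_init__(self) -> None:
        if not (0 < self.offset_criterion <= 1):
            raise ValueError("offset_criterion must be in (0, 1]")
        if self.confirm_jnd_ms < 0 or self.judgment_noise_sd_ms < 0:
            raise ValueError("noise/JND parameters must be non-negative")
        if not (math.isfinite(self.e_t_ms) and math.isfinite(self.e_r_auditory_ms)
                and math.isfinite(self.e_r_visual_ms)):
            raise ValueError("latencies must be finite")

    def e_r_ms(self, condition: Optional[Mapping] = None) -> float:
        modality = (condition or {}).get("modality", "auditory")
        return self.e_r_visual_ms if modality == "visual" else self.e_r_auditory_ms

    def persistence_ms(self, condition: Optional[Mapping] = None) -> float:
        """True persistence duration (ms) for a condition of this subject."""
        if self.base_persistence_ms is not None:
            base = self.base_persistence_ms
        else:
            trace = self.trace if self.trace is not None else _default_trace()
            base = 1000.0 * persistence_duration(trace, self.offset_criterion)
        shift = 0.0
        for fieldname, table in self.persistence_effects.items():
            if condition is not None and fieldname in condition:
                shift += table[condition[fieldname]]
        return base + shift


_TRACE_CACHE: Dict[Tuple[float, float, float, float], DecayParams] = {}


def _default_trace() -> DecayParams:
    return _calibrated_trace(50.0, 0.6, 0.01, 1.2)


def _calibrated_trace(a: float, t_off: float, thr: float, ratio: float) -> DecayParams:
    key = (a, t_off, thr, ratio)
    if key not in _TRACE_CACHE:
        _TRACE_CACHE[key] = calibrate_offset(a, t_off, thr, ratio)
    return _TRACE_CACHE[key]


@dataclass(frozen=True)
class AdjustmentControls:
    """Response-device model: key steps or a continuous knob.

    KEYS: the four steps change Δt by -100/-10/+10/+100 ms; the display frame
    (10 ms) bounds the smallest step.  KNOB: Δt is adjusted continuously
    (about 1000 ms per 90 degrees of rotation) and rounded to the frame at
    presentation, while the continuous setting is retained.

    ``init_policy`` "semi_adaptive": the first encounter of a (condition,
    task) starts at a random jitter from ``init_jitter_set_ms``; later trials
    start at the running mean of prior estimates plus jitter.  "uniform":
    starts at the physical anchor plus a uniform draw from
    ``init_uniform_range_ms``.
    """

    mode: str = "keys"  # "keys" | "knob"
    key_steps_ms: Tuple[float, ...] = (-100.0, -10.0, 10.0, 100.0)
    knob_gain_ms_per_deg: float = 1000.0 / 90.0
    init_policy: str = "semi_adaptive"  # "semi_adaptive" | "uniform"
    init_jitter_set_ms: Tuple[float, ...] = (-30, -20, -10, 0, 10, 20, 30)
    init_uniform_range_ms: Tuple[float, float] = (-200.0, 200.0)
    frame_ms: float = 10.0
    max_repetitions: int = 200

    def __post_init__(self) -> None:
        if self.mode not in ("keys", "knob"):
            raise ValueError(f"mode must be 'keys' or 'knob', got {self.mode!r}")
        if self.init_policy not in ("semi_adaptive", "uniform"):
            raise ValueError(f"unknown init_policy {self.init_policy!r}")
        if self.mode == "keys" and min(abs(s) for s in self.key_steps_ms) < self.frame_ms:
            raise ValueError("smallest key step must be at least one display frame")
        if self.max_repetitions < 2:
            raise ValueError("max_repetitions must allow the minimum two repetitions")

    @property
    def min_step_ms(self) -> float:
        if self.mode == "keys":
            return min(abs(s) for s in self.key_steps_ms)
        return self.frame_ms


class SessionState:
    """Running means of prior estimates, keyed by (task, condition cell)."""

    def __init__(self) -> None:
        self._sums: Dict[tuple, Tuple[float, int]] = {}

    @staticmethod
    def _key(task: str, condition: Mapping) -> tuple:
        cell = tuple(sorted((k, v) for k, v in condition.items()
                            if k not in _NON_CELL_FIELDS))
        return (task, cell)

    def mean(self, task: str, condition: Mapping) -> Optional[float]:
        entry = self._sums.get(self._key(task, condition))
        if entry is None:
            return None
        total, n = entry
        return total / n

    def update(self, task: str, condition: Mapping, estimate: float) -> None:
        key = self._key(task, condition)
        total, n = self._sums.get(key, (0.0, 0))
        self._sums[key] = (total + estimate, n + 1)


def build_design(experiment: int, reps: int, seed) -> List[Tuple[dict, str]]:
    """Ordered list of (condition, task) pairs for one subject's session.

    Experiment 1: 2 sizes x 2 thicknesses x 2 reference modalities, tasks
    alternating in blocks of 10 with onset first, conditions shuffled within
    each task stream.  Experiment 2: 6 decay durations x 2 tasks, fully
    randomized.  Experiment 3: 4 disk sizes x 4 eccentricities, task blocks of
    10 with onset first, a fresh random displacement direction every trial.
    """
    if reps <= 0:
        raise ValueError("reps must be positive")
    rng = np.random.default_rng(seed)
    if experiment == 1:
        cells = [
            {"size_px": s, "thickness_px": t, "modality": m}
            for s in EXP1_SIZES_PX for t in EXP1_THICKNESSES_PX
            for m in EXP1_MODALITIES
        ]
        return _blocked_design(cells, reps, rng)
    if experiment == 2:
        trials = [({"duration_ms": d}, task)
                  for d in EXP2_DURATIONS_MS for task in TASKS
                  for _ in range(reps)]
        order = rng.permutation(len(trials))
        return [trials[i] for i in order]
    if experiment == 3:
        cells = [
            {"diameter_deg": d, "eccentricity_deg": e}
            for d in EXP3_DIAMETERS_DEG for e in EXP3_ECCENTRICITIES_DEG
        ]
        design = _blocked_design(cells, reps, rng)
        return [({**cond, "direction_rad": float(rng.uniform(0, 2 * math.pi))}, task)
                for cond, task in design]
    raise ValueError(f"experiment must be 1, 2, or 3, got {experiment!r}")


def _blocked_design(cells: List[dict], reps: int,
                    rng: np.random.Generator) -> List[Tuple[dict, str]]:
    """Interleave per-task shuffled streams in alternating blocks of 10,
    starting with an onset block."""
    streams = {}
    for task in TASKS:
        stream = [dict(c) for c in cells for _ in range(reps)]
        order = rng.permutation(len(stream))
        streams[task] = [stream[i] for i in order]
    out: List[Tuple[dict, str]] = []
    block, i = 10, {t: 0 for t in TASKS}
    while any(i[t] < len(streams[t]) for t in TASKS):
        for task in TASKS:  # onset block first
            take = streams[task][i[task]: i[task] + block]
            out.extend((cond, task) for cond in take)
            i[task] += len(take)
    return out


def perceived_event_time(
    task: str,
    t_t_ms: float,
    profile: ObserverProfile,
    condition: Optional[Mapping] = None,
    *,
    stimulus_trace: Optional[DecayParams] = None,
    persistence_jitter_ms: float = 0.0,
) -> float:
    """Time (ms) at which the judged percept event occurs.

    Onset task: t_T + e_T.  Offset task: t_T + e_T plus the persistence
    duration -- read from the physical stimulus trace when one exists (the
    contrast-decay proxy), otherwise from the observer's internal trace or
    specified condition means.
    """
    if task not in TASKS:
        raise ValueError(f"task must be one of {TASKS}, got {task!r}")
    t = t_t_ms + profile.e_t_ms
    if task == "offset":
        if stimulus_trace is not None:
            dur = 1000.0 * persistence_duration(stimulus_trace,
                                                profile.offset_criterion)
        else:
            dur = profile.persistence_ms(condition)
        t += max(dur + persistence_jitter_ms, 0.0)
    return t


def simulate_trial(
    condition: Mapping,
    task: str,
    profile: ObserverProfile,
    controls: AdjustmentControls,
    session: SessionState,
    rng: np.random.Generator,
    *,
    stimulus_trace: Optional[DecayParams] = None,
) -> dict:
    """Run one trial's adjustment loop and return the trial record fields.

    The transition is taken as t_T = 0, so the recorded Δt is directly the
    reference-onset delay.  The loop confirms when the perceived asynchrony is
    below the confirmation JND and no available adjustment would noticeably
    improve it; otherwise it steps (KEYS: the key that most reduces |A|;
    KNOB: Δt <- Δt - A, presented rounded to the frame).  Trials exceeding
    ``max_repetitions`` are kept but flagged non-converged.
    """
    e_r = profile.e_r_ms(condition)
    jitter = 0.0
    if task == "offset" and profile.persistence_jitter_sd_ms > 0:
        jitter = float(rng.normal(0.0, profile.persistence_jitter_sd_ms))
    target = perceived_event_time(task, 0.0, profile, condition,
                                  stimulus_trace=stimulus_trace,
                                  persistence_jitter_ms=jitter)

    # initial Δt
    if controls.init_policy == "uniform":
        anchor = 0.0
        if task == "offset" and stimulus_trace is not None and stimulus_trace.t_off_s:
            anchor = 1000.0 * stimulus_trace.t_off_s
        delta_t = anchor + float(rng.uniform(*controls.init_uniform_range_ms))
    else:
        eps = float(rng.choice(controls.init_jitter_set_ms))
        prior = session.mean(task, condition)
        delta_t = eps if prior is None else prior + eps

    frame = controls.frame_ms
    noise_sd = profile.judgment_noise_sd_ms
    converged = False
    reps = 0
    for reps in range(1, controls.max_repetitions + 1):
        presented = round(delta_t / frame) * frame
        noise = float(rng.normal(0.0, noise_sd)) if noise_sd > 0 else 0.0
        a = presented + e_r - target + noise  # perceived asynchrony
        if controls.mode == "keys":
            step = min(controls.key_steps_ms, key=lambda s: (abs(a + s), abs(s)))
            if abs(a) < profile.confirm_jnd_ms and abs(a + step) >= abs(a):
                converged = True
                break
            delta_t += step
        else:  # knob: continuous correction, confirm once within resolution
            if abs(a) < min(profile.confirm_jnd_ms, frame):
                converged = True
                break
            delta_t -= a
    n_reps = max(reps, 2)  # a trial always comprises at least two repetitions

    final = delta_t if controls.mode == "knob" else round(delta_t / frame) * frame
    session.update(task, condition, final)
    record = {k: v for k, v in condition.items()}
    record.update(task=task, delta_t_ms=float(final), n_reps=int(n_reps),
                  converged=bool(converged))
    return record


_DEFAULT_REPS = {1: 20, 2: 10, 3: 10}


def default_controls(experiment: int) -> AdjustmentControls:
    """Response device per experiment: keys (Exp 1) or knob (Exp 2 and 3);
    Exp 2 used uniform random initial delays around the physical event."""
    if experiment == 1:
        return AdjustmentControls(mode="keys")
    if experiment == 2:
        return AdjustmentControls(mode="knob", init_policy="uniform")
    if experiment == 3:
        return AdjustmentControls(mode="knob")
    raise ValueError(f"experiment must be 1, 2, or 3, got {experiment!r}")


def simulate_experiment(
    experiment: int,
    profiles: Sequence[ObserverProfile],
    controls: Optional[AdjustmentControls] = None,
    *,
    reps: Optional[int] = None,
    seed=0,
) -> pd.DataFrame:
    """Simulate the full design once per profile; deterministic under
    (seed, profiles).  Returns one row per trial."""
    if len(profiles) == 0:
        raise ValueError("need at least one observer profile")
    if controls is None:
        controls = default_controls(experiment)
    if reps is None:
        reps = _DEFAULT_REPS[experiment]
    root = np.random.SeedSequence(seed)
    rows = []
    for profile, child in zip(profiles, root.spawn(len(profiles))):
        design_seed, loop_seed = child.spawn(2)
        design = build_design(experiment, reps, design_seed)
        rng = np.random.default_rng(loop_seed)
        session = SessionState()
        for trial_index, (condition, task) in enumerate(design):
            trace = None
            if experiment == 2:
                t_off = condition["duration_ms"] / 1000.0
                trace = _calibrated_trace(50.0, t_off, 0.01, 1.2)
            rec = simulate_trial(condition, task, profile, controls, session,
                                 rng, stimulus_trace=trace)
            rec.update(subject=profile.subject, experiment=experiment,
                       trial_index=trial_index, seed=seed)
            rows.append(rec)
    df = pd.DataFrame(rows)
    front = ["subject", "experiment", "trial_index", "task"]
    return df[front + [c for c in df.columns if c not in front]]


def default_profiles(experiment: int, n_subjects: Optional[int] = None,
                     seed=0) -> List[ObserverProfile]:
    """Observer panels emulating each experiment's study population.

    Condition means follow the reported marginal effects (Exp 1: thick-thin
    +69.0 ms, small-large +55.6 ms, auditory-visual +102.2 ms around a
    489.7 ms grand mean; Exp 3: cell means on the line 67.78 ms per degree of
    diameter above 1007.95 ms).  Exp 2 observers judge the physical decay with
    the 0.01 calibration criterion.  Between-subject spread and judgment noise
    are broad-brush choices documented in the methods note.
    """
    if n_subjects is None:
        n_subjects = 4 if experiment == 2 else 9
    rng = np.random.default_rng(seed)
    profiles = []
    for i in range(n_subjects):
        common = dict(
            e_t_ms=float(rng.normal(60.0, 15.0)),
            e_r_auditory_ms=float(rng.normal(40.0, 15.0)),
            e_r_visual_ms=float(rng.normal(50.0, 15.0)),
            subject=f"s{i + 1:02d}",
        )
        if experiment == 1:
            profiles.append(ObserverProfile(
                **common,
                base_persistence_ms=float(np.clip(rng.normal(489.7, 150.0),
                                                  150.0, 1200.0)),
                persistence_effects={
                    "thickness_px": {25: -34.5, 75: +34.5},
                    "size_px": {100: +27.8, 200: -27.8},
                    "modality": {"auditory": +51.1, "visual": -51.1},
                },
                judgment_noise_sd_ms=30.0,
                persistence_jitter_sd_ms=35.0,
            ))
        elif experiment == 2:
            profiles.append(ObserverProfile(
                **common,
                offset_criterion=0.01,
                judgment_noise_sd_ms=70.0,
                persistence_jitter_sd_ms=60.0,
            ))
        elif experiment == 3:
            profiles.append(ObserverProfile(
                **common,
                base_persistence_ms=float(np.clip(rng.normal(1007.95, 250.0),
                                                  300.0, 2200.0)),
                persistence_effects={
                    "diameter_deg": {d: 67.78 * d for d in EXP3_DIAMETERS_DEG},
                },
                judgment_noise_sd_ms=80.0,
                persistence_jitter_sd_ms=200.0,
            ))
        else:
            raise ValueError(f"experiment must be 1, 2, or 3, got {experiment!r}")
    return profiles
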
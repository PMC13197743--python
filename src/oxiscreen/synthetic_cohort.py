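"""Synthetic 1 Hz SpO2 signals and labeled cohorts.

Signals are a stable per-subject baseline with superimposed, non-overlapping
desaturation dips (raised-cosine by default, triangular for exact-area
oracles), additive Gaussian noise, and values clipped to [40, 100]. Every
generated signal is accompanied by a log of the inserted events so that
downstream detectors can be checked against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from oxiscreen.errors import ConfigurationError, GenerationError
from oxiscreen.oximetry_summary import OximetryFeatures
from oxiscreen.spo2_io import Spo2Signal, write_signal

#: ODI qualifying-depth threshold used for ground-truth event rates and labels.
QUALIFYING_DEPTH = 4.0

#: Event rate (events/h) at or above which a subject is labeled OSA.
OSA_RATE_THRESHOLD = 5.0

#: Guard gap (s) enforced between inserted events so recovery flanks stay clean.
EVENT_GUARD_GAP_S = 10


@dataclass
class SignalProfile:
    """Generative parameters for one subject class."""

    baseline_mean: float = 96.0
    baseline_sd: float = 0.5
    event_rate_per_h: float = 0.0
    depth_mean: float = 8.0
    depth_sd: float = 2.0
    depth_min: float = 0.0  # truncation floor for sampled depths
    duration_mean: float = 30.0
    duration_sd: float = 5.0
    noise_sd: float = 0.3
    duration_h: float = 8.0
    event_shape: str = "raised-cosine"  # or "triangular"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 80.0 < self.baseline_mean <= 100.0:
            raise ConfigurationError("baseline_mean must lie in (80, 100]")
        if self.event_rate_per_h < 0 or self.depth_mean < 0:
            raise ConfigurationError("event rate and depth must be non-negative")
        if self.duration_mean <= 0 or self.duration_h <= 0:
            raise ConfigurationError("durations must be positive")
        if self.event_shape not in ("raised-cosine", "triangular"):
            raise ConfigurationError(f"unknown event shape {self.event_shape!r}")


@dataclass
class InsertedEvent:
    onset_s: int
    duration_s: int
    depth: float


@dataclass
class GenerationLog:
    baseline: float
    events: list[InsertedEvent] = field(default_factory=list)
    duration_h: float = 0.0

    def qualifying_rate_per_h(self, depth_threshold: float = QUALIFYING_DEPTH) -> float:
        n = sum(1 for e in self.events if e.depth >= depth_threshold)
        return n / self.duration_h if self.duration_h > 0 else 0.0


@dataclass
class Demographics:
    male_fraction: float = 0.75
    age_mean: float = 45.0
    age_sd: float = 12.0
    age_min: int = 18
    age_max: int = 90


@dataclass
class SubjectRecord:
    subject_id: str
    label: int
    sex: str
    age_years: int
    cohort: str
    true_event_rate: float
    tst_seconds: float
    features: OximetryFeatures | None = None


def _dip_shape(duration: int, depth: float, shape: str) -> np.ndarray:
    t = np.arange(duration + 1, dtype=np.float64)
    if shape == "raised-cosine":
        return depth * 0.5 * (1.0 - np.cos(2.0 * np.pi * t / duration))
    # triangular: linear fall to the midpoint, linear recovery
    half = duration / 2.0
    return depth * (1.0 - np.abs(t - half) / half)


def _place_events(rng: np.random.Generator, n_events: int, n_samples: int,
                  profile: SignalProfile) -> list[InsertedEvent]:
    """Place non-overlapping events by distributing the free time as random
    inter-event gaps; raises if the events cannot physically fit."""
    durations = [int(np.clip(round(rng.normal(profile.duration_mean, profile.duration_sd)),
                             4, n_samples - 2)) for _ in range(n_events)]
    depths = [float(max(profile.depth_min,
                        max(0.0, rng.normal(profile.depth_mean, profile.depth_sd))))
              for _ in range(n_events)]
    occupied = sum(d + EVENT_GUARD_GAP_S for d in durations) + EVENT_GUARD_GAP_S
    free = n_samples - occupied
    if free < 0:
        raise GenerationError(
            f"cannot fit {n_events} events of ~{profile.duration_mean:.0f} s "
            f"(plus {EVENT_GUARD_GAP_S} s guard gaps) in {n_samples} s")
    weights = rng.random(n_events + 1)
    gaps = np.floor(weights / weights.sum() * free).astype(int)
    events: list[InsertedEvent] = []
    pos = EVENT_GUARD_GAP_S
    for duration, depth, gap in zip(durations, depths, gaps):
        pos += int(gap)
        events.append(InsertedEvent(pos, duration, depth))
        pos += duration + EVENT_GUARD_GAP_S
    return events


def generate_signal(profile: SignalProfile,
                    subject_id: str = "synthetic") -> tuple[Spo2Signal, GenerationLog]:
    """Generate one 1 Hz signal plus the log of inserted events.

    Deterministic in ``profile.seed``: the same profile always yields a
    bit-identical signal and log.
    """
    rng = np.random.default_rng(profile.seed)
    n = int(round(profile.duration_h * 3600))
    baseline = float(min(100.0, rng.normal(profile.baseline_mean, profile.baseline_sd)))
    values = np.full(n, baseline, dtype=np.float64)

    n_events = int(rng.poisson(profile.event_rate_per_h * profile.duration_h))
    events = _place_events(rng, n_events, n, profile) if n_events else []
    for ev in events:
        dip = _dip_shape(ev.duration_s, ev.depth, profile.event_shape)
        stop = min(n, ev.onset_s + ev.duration_s + 1)
        values[ev.onset_s:stop] -= dip[: stop - ev.onset_s]

    if profile.noise_sd > 0:
        values = values + rng.normal(0.0, profile.noise_sd, size=n)
    values = np.clip(values, 40.0, 100.0)

    signal = Spo2Signal(values=values, rate_hz=1.0,
                        valid_mask=np.ones(n, dtype=bool), subject_id=subject_id)
    log = GenerationLog(baseline=baseline, events=events, duration_h=profile.duration_h)
    return signal, log


def generate_cohort(
    n: int,
    prevalence: float,
    profiles: dict[int, SignalProfile],
    demographics: Demographics | None = None,
    seed: int = 0,
    cohort: str = "internal",
    max_retries: int = 20,
) -> list[tuple[SubjectRecord, Spo2Signal, GenerationLog]]:
    """Generate a labeled cohort of subjects with signals and ground truth.

    Exactly ``round(n * prevalence)`` subjects are OSA; every subject's
    realized qualifying-event rate is consistent with its label under the
    ≥ 5 events/h rule (events are redrawn, bounded, until it is).
    """
    if not 0.0 < prevalence < 1.0:
        raise ConfigurationError("prevalence must lie strictly between 0 and 1")
    if set(profiles) != {0, 1}:
        raise ConfigurationError("profiles must map labels 0 and 1 to SignalProfile")
    if profiles[1].event_rate_per_h < OSA_RATE_THRESHOLD:
        raise ConfigurationError("OSA-class profile must have event rate ≥ 5/h")
    if profiles[0].event_rate_per_h >= OSA_RATE_THRESHOLD:
        raise ConfigurationError("non-OSA-class profile must have event rate < 5/h")
    demographics = demographics or Demographics()

    master = np.random.SeedSequence(seed)
    label_rng = np.random.default_rng(master.spawn(1)[0])
    n_osa = int(round(n * prevalence))
    labels = np.array([1] * n_osa + [0] * (n - n_osa))
    label_rng.shuffle(labels)

    subject_seeds = master.spawn(n)
    out: list[tuple[SubjectRecord, Spo2Signal, GenerationLog]] = []
    for i, (label, sseq) in enumerate(zip(labels, subject_seeds)):
        sid = f"{cohort[:3]}{i + 1:04d}"
        demo_rng = np.random.default_rng(sseq.spawn(1)[0])
        sex = "male" if demo_rng.random() < demographics.male_fraction else "female"
        age = int(np.clip(round(demo_rng.normal(demographics.age_mean, demographics.age_sd)),
                          demographics.age_min, demographics.age_max))

        profile = profiles[int(label)]
        signal = log = None
        for attempt_seq in sseq.spawn(max_retries):
            trial = replace(profile, seed=int(attempt_seq.generate_state(1)[0]))
            trial_signal, trial_log = generate_signal(trial, subject_id=sid)
            rate = trial_log.qualifying_rate_per_h()
            consistent = rate >= OSA_RATE_THRESHOLD if label == 1 else rate < OSA_RATE_THRESHOLD
            if consistent:
                signal, log = trial_signal, trial_log
                break
        if signal is None:
            raise GenerationError(
                f"subject {sid}: could not realize a label-consistent event rate "
                f"in {max_retries} draws")
        record = SubjectRecord(
            subject_id=sid,
            label=int(label),
            sex=sex,
            age_years=age,
            cohort=cohort,
            true_event_rate=log.qualifying_rate_per_h(),
            tst_seconds=signal.trt_seconds,
        )
        out.append((record, signal, log))
    return out


def cohort_manifest(records: list[SubjectRecord]) -> pd.DataFrame:
    columns = ["subject_id", "label", "sex", "age_years", "cohort", "true_event_rate"]
    return pd.DataFrame(
        [{c: getattr(r, c) for c in columns} for r in records], columns=columns)


def save_cohort(directory, generated, signals_subdir: str = "signals") -> Path:
    """Write the cohort manifest and per-subject canonical signal files."""
    directory = Path(directory)
    sig_dir = directory / signals_subdir
    sig_dir.mkdir(parents=True, exist_ok=True)
    records = [rec for rec, _, _ in generated]
    manifest_path = directory / "cohort.csv"
    cohort_manifest(records).to_csv(manifest_path, index=False)
    for rec, signal, _ in generated:
        write_signal(sig_dir / f"{rec.subject_id}.csv", signal)
    return manifest_path
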
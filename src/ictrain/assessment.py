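"""Auditory Go/Nogo assessment tasks and their behavioral scoring.

Two task variants measure general inhibitory control: tones at 1100 and
2000 Hz, 200 ms long, presented at a fixed interstimulus interval of either
2500 ms ("longer" reaction-time deadline) or 1250 ms ("shorter").  One tone
is the frequent Go stimulus (70% of 100 trials, realized as exact counts),
the other the infrequent Nogo stimulus; tone assignment and task order are
counterbalanced across participants and sessions.

The generated sequence doubles as the event-marker stream consumed by the
ERP pipeline, so scored trials and epochs correspond one-to-one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .agents import Agent
from .engine import GO, HEALTHY, NOGO, UNHEALTHY, Trial

LONGER = "longer"
SHORTER = "shorter"
ISI_BY_VARIANT = {LONGER: 2500.0, SHORTER: 1250.0}


@dataclass(frozen=True)
class AssessmentSpec:
    n_trials: int = 100
    p_go: float = 0.70
    tone_hz_pair: tuple[int, int] = (1100, 2000)
    tone_duration_ms: float = 200.0
    isi_ms: float = 2500.0
    go_tone_hz: int = 1100
    n_practice: int = 10

    def __post_init__(self) -> None:
        n_go = self.p_go * self.n_trials
        if abs(n_go - round(n_go)) > 1e-9:
            raise ValueError(
                f"p_go={self.p_go} does not yield an integral Go count for "
                f"{self.n_trials} trials"
            )
        if self.isi_ms not in ISI_BY_VARIANT.values():
            raise ValueError("isi_ms must be 2500 (longer RTD) or 1250 (shorter RTD)")
        if self.go_tone_hz not in self.tone_hz_pair:
            raise ValueError("go tone must be one of the task's tone pair")

    @classmethod
    def for_variant(cls, variant: str, **kwargs) -> "AssessmentSpec":
        return cls(isi_ms=ISI_BY_VARIANT[variant], **kwargs)

    @property
    def variant(self) -> str:
        return LONGER if self.isi_ms == ISI_BY_VARIANT[LONGER] else SHORTER

    @property
    def n_go(self) -> int:
        return round(self.p_go * self.n_trials)

    @property
    def nogo_tone_hz(self) -> int:
        a, b = self.tone_hz_pair
        return b if self.go_tone_hz == a else a


@dataclass(frozen=True)
class TrialSequence:
    """Ordered trial labels with onset times (ms from task start)."""

    labels: tuple[str, ...]
    onsets_ms: tuple[float, ...]
    isi_ms: float
    variant: str

    def __len__(self) -> int:
        return len(self.labels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"onset_ms": self.onsets_ms, "label": self.labels, "task": self.variant}
        )


@dataclass(frozen=True)
class BehaviorScore:
    n_correct_go: int
    mean_go_rt_ms: float
    n_nogo_errors: int
    n_omissions: int


def generate_sequence(spec: AssessmentSpec, rng: np.random.Generator) -> TrialSequence:
    """Randomly ordered exact-count sequence: onsets at k * isi_ms.

    Exact-count (not Bernoulli): every default sequence carries exactly 70
    Go and 30 Nogo labels, only the ordering varies with the seed.
    """
    labels = np.array([GO] * spec.n_go + [NOGO] * (spec.n_trials - spec.n_go))
    labels = labels[rng.permutation(spec.n_trials)]
    onsets = np.arange(spec.n_trials) * spec.isi_ms
    return TrialSequence(
        labels=tuple(labels.tolist()),
        onsets_ms=tuple(onsets.tolist()),
        isi_ms=spec.isi_ms,
        variant=spec.variant,
    )


def generate_practice(spec: AssessmentSpec, rng: np.random.Generator) -> TrialSequence:
    """Short instructional block; generated but never scored or epoched."""
    n_go = round(spec.p_go * spec.n_practice)
    labels = np.array([GO] * n_go + [NOGO] * (spec.n_practice - n_go))
    labels = labels[rng.permutation(spec.n_practice)]
    onsets = np.arange(spec.n_practice) * spec.isi_ms
    return TrialSequence(
        labels=tuple(labels.tolist()),
        onsets_ms=tuple(onsets.tolist()),
        isi_ms=spec.isi_ms,
        variant=spec.variant,
    )


ORDERS = ("longer_first", "shorter_first")


def counterbalance(
    n_participants: int,
    n_sessions: int = 2,
    tone_hz_pair: tuple[int, int] = (1100, 2000),
) -> pd.DataFrame:
    """Balanced assignment of Go tone and task order per participant x session.

    The four (go tone x order) cells are cycled across participants with a
    per-session rotation, so each cell is used equally often (within one)
    across any roster and no participant keeps the same cell in both
    sessions.
    """
    if n_participants < 1:
        raise ValueError("need at least one participant")
    cells = [(tone, order) for tone in tone_hz_pair for order in ORDERS]
    rows = []
    for p in range(n_participants):
        for s in range(n_sessions):
            tone, order = cells[(p + s) % len(cells)]
            rows.append(
                {
                    "participant": p,
                    "session": s + 1,
                    "go_tone_hz": tone,
                    "task_order": order,
                }
            )
    return pd.DataFrame(rows)


def score_behavior(
    seq: TrialSequence,
    press_times_ms,
    response_window_ms: float | None = None,
) -> BehaviorScore:
    """Score a stream of button presses against the trial sequence.

    Each press is attributed to the most recent tone onset if it falls in
    ``(onset, onset + window]``; the window defaults to the ISI, which is
    the de facto deadline of the task.  Only the first press per trial
    counts.  Presses are a set, so permuting the input leaves the score
    unchanged.
    """
    window = seq.isi_ms if response_window_ms is None else response_window_ms
    if window <= 0 or window > seq.isi_ms:
        raise ValueError("response window must lie in (0, isi]")
    onsets = np.asarray(seq.onsets_ms)
    duration = onsets[-1] + seq.isi_ms
    first_press: dict[int, float] = {}
    for t in sorted(float(t) for t in press_times_ms):
        if not 0.0 < t <= duration:
            raise ValueError(f"press at {t} ms outside the task duration")
        i = int(np.searchsorted(onsets, t, side="right")) - 1
        if i < 0:
            continue
        dt = t - onsets[i]
        if 0.0 < dt <= window and i not in first_press:
            first_press[i] = dt
    go_idx = [i for i, lab in enumerate(seq.labels) if lab == GO]
    go_rts = [first_press[i] for i in go_idx if i in first_press]
    n_nogo_errors = sum(
        1 for i, lab in enumerate(seq.labels) if lab == NOGO and i in first_press
    )
    return BehaviorScore(
        n_correct_go=len(go_rts),
        mean_go_rt_ms=float(np.mean(go_rts)) if go_rts else float("nan"),
        n_nogo_errors=n_nogo_errors,
        n_omissions=len(go_idx) - len(go_rts),
    )


def simulate_responses(
    seq: TrialSequence, agent: Agent, rng: np.random.Generator
) -> list[float]:
    """Press times produced by an agent playing the assessment task.

    Each tone is presented to the agent as a go/nogo trial whose deadline is
    the ISI (the next tone ends the response window).
    """
    presses = []
    for onset, label in zip(seq.onsets_ms, seq.labels):
        trial = Trial(
            index=0,
            kind=label,
            category=HEALTHY if label == GO else UNHEALTHY,
            rtd_ms=seq.isi_ms,
        )
        responded, rt = agent.respond(trial, rng)
        if responded and rt is not None and rt <= seq.isi_ms:
            presses.append(onset + rt)
    return presses
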
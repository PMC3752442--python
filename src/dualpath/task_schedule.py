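"""Trial construction for the four training tasks.

Trials are event-indexed: inputs clamp a layer at specific time events
(1-based), targets supervise a layer at specific events, and events carrying
no target are free-running.  Development-phase tasks: standard repetition
(hear events 1-3, reproduce 4-6), comprehension (hear 1-3, semantic target
1-3) and speaking (semantic clamp 1-3, mora target 1-3).  The recovery phase
adds the conduite d'approche trial (hear 1-3, reproduce a *second* time at
7-9, events 4-6 unsupervised) and extends the comprehension target to events
1-9 so the meaning is maintained for the full nine-tick trial.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from dualpath.lexigen import Corpus, LexiconItem, Mora

__all__ = [
    "TrialSpec",
    "make_repetition",
    "make_cda",
    "make_comprehension",
    "make_speaking",
    "build_epoch",
    "DEV_TASK_FREQ",
    "RECOVERY_TASK_FREQ",
]

AUDITORY = "Auditory"
SPEECH_MOTOR = "SpeechMotor"
VATL = "vATL"

#: per-word task frequencies within one epoch
DEV_TASK_FREQ = {"repetition": 1, "comprehension": 3, "speaking": 2}
RECOVERY_TASK_FREQ = {"repetition": 1, "cda": 1, "comprehension": 3,
                      "speaking": 2}


@dataclass
class TrialSpec:
    """One task instance: event-indexed input clamps and target patterns."""

    task: str
    n_events: int
    inputs: dict[str, dict[int, np.ndarray]]
    targets: dict[str, dict[int, np.ndarray]]
    item_ref: tuple[int, int, int]

    def __post_init__(self):
        for name, layer in (("input", self.inputs), ("target", self.targets)):
            for events in layer.values():
                for t in events:
                    if not 1 <= t <= self.n_events:
                        raise ValueError(
                            f"{name} event {t} outside 1..{self.n_events}")

    def to_dict(self) -> dict:
        """JSON-friendly representation for debugging."""
        return {
            "task": self.task,
            "n_events": self.n_events,
            "item_ref": list(self.item_ref),
            "inputs": {l: {t: v.tolist() for t, v in ev.items()}
                       for l, ev in self.inputs.items()},
            "targets": {l: {t: v.tolist() for t, v in ev.items()}
                        for l, ev in self.targets.items()},
        }


def _mora_vectors(item: LexiconItem, inventory: list[Mora]) -> list[np.ndarray]:
    if len(item.morae) != 3:
        raise ValueError("items must have exactly 3 morae")
    by_id = {m.id: m.features for m in inventory}
    return [by_id[m] for m in item.morae]


def make_repetition(item: LexiconItem, inventory: list[Mora]) -> TrialSpec:
    """Hear the three morae at events 1-3; reproduce them at events 4-6."""
    vecs = _mora_vectors(item, inventory)
    return TrialSpec(
        task="repetition",
        n_events=6,
        inputs={AUDITORY: {t + 1: vecs[t] for t in range(3)}},
        targets={SPEECH_MOTOR: {t + 4: vecs[t] for t in range(3)}},
        item_ref=item.morae,
    )


def make_cda(item: LexiconItem, inventory: list[Mora]) -> TrialSpec:
    """Hear at events 1-3; the target is a *second* repetition at events 7-9.

    Events 4-6 carry no target on any layer: because the network is also
    trained on standard repetition, it spontaneously produces a first
    (unsupervised) attempt there, so the trial trains it to repeat twice.
    """
    vecs = _mora_vectors(item, inventory)
    return TrialSpec(
        task="cda",
        n_events=9,
        inputs={AUDITORY: {t + 1: vecs[t] for t in range(3)}},
        targets={SPEECH_MOTOR: {t + 7: vecs[t] for t in range(3)}},
        item_ref=item.morae,
    )


def make_comprehension(item: LexiconItem, inventory: list[Mora],
                       phase: str = "development") -> TrialSpec:
    """Hear at events 1-3; the semantic pattern is the vATL target.

    In development the trial lasts 3 events with the target at every one of
    them (compute the meaning as fast as possible).  In recovery the trial is
    stretched to 9 events with the target applied throughout, so the meaning
    is maintained for the duration of a conduite d'approche trial.
    """
    if not item.is_word:
        raise ValueError("comprehension needs a word (nonwords have no semantics)")
    if phase not in ("development", "recovery"):
        raise ValueError(f"unknown phase {phase!r}")
    vecs = _mora_vectors(item, inventory)
    n_events = 3 if phase == "development" else 9
    return TrialSpec(
        task="comprehension",
        n_events=n_events,
        inputs={AUDITORY: {t + 1: vecs[t] for t in range(3)}},
        targets={VATL: {t: item.semantics for t in range(1, n_events + 1)}},
        item_ref=item.morae,
    )


def make_speaking(item: LexiconItem, inventory: list[Mora]) -> TrialSpec:
    """Clamp the semantic pattern onto vATL at events 1-3; produce the three
    morae at events 1-3.  Identical in both phases."""
    if not item.is_word:
        raise ValueError("speaking needs a word (nonwords have no semantics)")
    vecs = _mora_vectors(item, inventory)
    return TrialSpec(
        task="speaking",
        n_events=3,
        inputs={VATL: {t: item.semantics for t in range(1, 4)}},
        targets={SPEECH_MOTOR: {t + 1: vecs[t] for t in range(3)}},
        item_ref=item.morae,
    )


def make_trial(task: str, item: LexiconItem, inventory: list[Mora],
               phase: str = "development") -> TrialSpec:
    if task == "repetition":
        return make_repetition(item, inventory)
    if task == "cda":
        return make_cda(item, inventory)
    if task == "comprehension":
        return make_comprehension(item, inventory, phase)
    if task == "speaking":
        return make_speaking(item, inventory)
    raise ValueError(f"unknown task {task!r}")


def build_epoch(corpus: Corpus, phase: str, seed: int) -> list[TrialSpec]:
    """Build one epoch's trials in seeded random order.

    Per word: development = 1 repetition + 3 comprehension + 2 speaking;
    recovery = 1 repetition + 1 conduite d'approche + 3 comprehension +
    2 speaking.  The trial multiset is fixed; only the order depends on the
    seed.  Nonwords never appear in training epochs.
    """
    if not corpus.train_words:
        raise ValueError("corpus has no training words")
    if phase == "development":
        freq = DEV_TASK_FREQ
    elif phase == "recovery":
        freq = RECOVERY_TASK_FREQ
    else:
        raise ValueError(f"unknown phase {phase!r}")
    trials: list[TrialSpec] = []
    for item in corpus.train_words:
        for task, n in freq.items():
            for _ in range(n):
                trials.append(make_trial(task, item, corpus.mora_inventory,
                                         phase))
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(trials))
    return [trials[i] for i in order]
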
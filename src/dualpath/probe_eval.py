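"""Decoding, scoring, the conduite d'approche statistic, and the
repeated-measures statistics run across replicate networks.

A double-repetition probe presents an item's three morae at events 1-3 and
lets the network free-run to event 9.  Events 4-6 are the first repetition
attempt and events 7-9 the second.  Each motor output event is decoded to
the nearest inventory mora (Euclidean distance, ties to the lowest id); an
attempt is correct only if all three decoded morae match the target in
order.  The conduite d'approche rate is the number of items correct on the
second attempt among those incorrect on the first — the rate of successful
self-correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats

from dualpath.lexigen import LexiconItem, Mora
from dualpath.srn_core import NetworkState, forward_trial
from dualpath.task_schedule import TrialSpec, make_cda

__all__ = [
    "ProbeRecord",
    "CdAResult",
    "StatsResult",
    "decode_event",
    "decode_window",
    "probe_double_repetition",
    "cda_rate",
    "repeated_measures_2level",
    "interaction_2x2",
]


@dataclass(frozen=True)
class ProbeRecord:
    """Scoring of one double-repetition probe of one item."""

    item_ref: tuple[int, int, int]
    is_word: bool
    probe_index: int
    decoded1: tuple[int, int, int]
    decoded2: tuple[int, int, int]

    @property
    def attempt1_correct(self) -> bool:
        return self.decoded1 == self.item_ref

    @property
    def attempt2_correct(self) -> bool:
        return self.decoded2 == self.item_ref


@dataclass(frozen=True)
class CdAResult:
    """Self-correction statistic: second-attempt successes conditioned on
    first-attempt errors.  ``rate`` is None when no first-attempt error
    occurred (the statistic is undefined, never 0/0)."""

    n_first_errors: int
    n_self_corrected: int

    @property
    def rate(self) -> float | None:
        if self.n_first_errors == 0:
            return None
        return self.n_self_corrected / self.n_first_errors

    @property
    def defined(self) -> bool:
        return self.n_first_errors > 0


def decode_event(activation: np.ndarray, inventory: list[Mora]) -> int:
    """Nearest-neighbor decode of one motor output vector to a mora id.

    Ties break deterministically to the lowest mora id.
    """
    codes = np.stack([m.features for m in inventory])
    d2 = np.sum((codes - activation[None, :]) ** 2, axis=1)
    ids = np.array([m.id for m in inventory])
    best = d2.min()
    return int(ids[np.isclose(d2, best)].min())


def decode_window(acts: np.ndarray, events: range,
                  inventory: list[Mora]) -> tuple[int, ...]:
    """Decode a run of motor output events (1-based) to mora ids."""
    return tuple(decode_event(acts[ev - 1], inventory) for ev in events)


def probe_double_repetition(net: NetworkState, items: list[LexiconItem],
                            inventory: list[Mora], n_noise_probes: int = 5,
                            seed: int = 0) -> list[ProbeRecord]:
    """Probe every item ``n_noise_probes`` times with fresh noise draws.

    Each probe runs a 9-event double-repetition trial (auditory input events
    1-3, free run to event 9) and scores events 4-6 and 7-9 separately.
    Deterministic given the seed; with an entirely noise-free network all
    probes of an item are identical.
    """
    rng = np.random.default_rng(seed)
    noisy = any(sd > 0 for sd in net.noise_sd.values())
    records: list[ProbeRecord] = []
    for item in items:
        trial = make_cda(item, inventory)
        for k in range(n_noise_probes):
            acts = forward_trial(net, trial, rng if noisy else None)
            motor = acts["SpeechMotor"]
            records.append(ProbeRecord(
                item_ref=item.morae,
                is_word=item.is_word,
                probe_index=k,
                decoded1=decode_window(motor, range(4, 7), inventory),
                decoded2=decode_window(motor, range(7, 10), inventory),
            ))
    return records


def cda_rate(records: list[ProbeRecord]) -> CdAResult:
    """Conduite d'approche statistic over a set of probe records."""
    if not records:
        raise ValueError("no probe records")
    firsts = [r for r in records if not r.attempt1_correct]
    corrected = [r for r in firsts if r.attempt2_correct]
    return CdAResult(n_first_errors=len(firsts),
                     n_self_corrected=len(corrected))


@dataclass(frozen=True)
class StatsResult:
    """Two-level repeated-measures F (the square of the paired t), its
    p-value on F(1, n-1), and Cohen's d on the paired differences."""

    F: float
    df: tuple[int, int]
    p: float
    cohen_d: float

    @property
    def infinite(self) -> bool:
        return math.isinf(self.F)


def _paired_f(diff: np.ndarray) -> StatsResult:
    n = diff.size
    if n < 2:
        raise ValueError("need at least 2 paired observations")
    mean = float(np.mean(diff))
    sd = float(np.std(diff, ddof=1))
    if sd == 0.0:
        if mean == 0.0:
            return StatsResult(0.0, (1, n - 1), 1.0, 0.0)
        return StatsResult(math.inf, (1, n - 1), 0.0, math.inf)
    t = mean / (sd / math.sqrt(n))
    F = t * t
    p = float(sstats.f.sf(F, 1, n - 1))
    return StatsResult(F, (1, n - 1), p, mean / sd)


def repeated_measures_2level(cond_a, cond_b) -> StatsResult:
    """Paired two-condition repeated-measures test across networks.

    F equals the square of the paired t statistic on a-b; p is drawn from
    F(1, n-1); Cohen's d is the paired-differences d (mean/sd of a-b).
    Zero-variance differences with a nonzero mean yield an infinite-F flag
    with p = 0.
    """
    a = np.asarray(cond_a, dtype=float)
    b = np.asarray(cond_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("conditions must be equal-length 1-d paired samples")
    return _paired_f(a - b)


def interaction_2x2(word_pre, word_post, nonword_pre, nonword_post
                    ) -> StatsResult:
    """2x2 repeated-measures interaction (lexicality x damage): the paired
    t-squared on the per-network double difference
    (word_pre - word_post) - (nonword_pre - nonword_post)."""
    arrs = [np.asarray(x, dtype=float)
            for x in (word_pre, word_post, nonword_pre, nonword_post)]
    if len({a.shape for a in arrs}) != 1 or arrs[0].ndim != 1:
        raise ValueError("need four equal-length paired samples")
    dd = (arrs[0] - arrs[1]) - (arrs[2] - arrs[3])
    return _paired_f(dd)
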
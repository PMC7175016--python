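"""Probabilistic selection task: design constants and trial schedules.

The task presents pairs of face stimuli (labelled A-F). During learning,
three fixed pairs (AB, CD, EF) are reinforced probabilistically: choosing
the optimal member (A, C, E) yields "correct" feedback with probability
0.80, 0.70 and 0.60 respectively, and choosing the suboptimal member with
the complementary probability. A subsequent transfer phase presents all 15
pairwise combinations of the six stimuli (12 of them novel) without
feedback, probing the value beliefs established during learning.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

STIMULI = ("A", "B", "C", "D", "E", "F")

#: P(feedback == "correct") when each stimulus is chosen, implied by the
#: pair-level schedules 80:20 (AB), 70:30 (CD) and 60:40 (EF).
STIM_REINFORCEMENT = {
    "A": 0.80, "B": 0.20,
    "C": 0.70, "D": 0.30,
    "E": 0.60, "F": 0.40,
}

LEARNING_PAIRS = ("AB", "CD", "EF")
ALL_PAIRS = tuple("".join(p) for p in combinations(STIMULI, 2))
NOVEL_PAIRS = tuple(p for p in ALL_PAIRS if p not in LEARNING_PAIRS)

POSITIVE_STIMULI = frozenset("ACE")

TRIAL_COLUMNS = [
    "subject_id", "phase", "block", "trial_index", "pair", "optimal_side",
    "choice", "reward", "onset_s", "feedback_onset_s", "trial_sign",
]


def trial_sign(pair: str) -> str:
    """Classify a pair by the valence of its members during learning.

    ``+/+`` — both members were predominantly rewarded (A, C, E);
    ``-/-`` — both predominantly unrewarded (B, D, F); ``+/-`` otherwise.
    """
    a, b = pair[0], pair[1]
    if a in POSITIVE_STIMULI and b in POSITIVE_STIMULI:
        return "+/+"
    if a not in POSITIVE_STIMULI and b not in POSITIVE_STIMULI:
        return "-/-"
    return "+/-"


def optimal_member(pair: str) -> str:
    """The member with the higher scheduled reinforcement probability."""
    a, b = pair[0], pair[1]
    for s in (a, b):
        if s not in STIM_REINFORCEMENT:
            raise ValueError(f"unknown stimulus {s!r} in pair {pair!r}")
    return a if STIM_REINFORCEMENT[a] > STIM_REINFORCEMENT[b] else b


@dataclass
class TaskConfig:
    """Design constants of the selection task.

    Parameters mirror the experiment: 300 learning trials split equally
    over the pairs in ``pair_probs``, 360 transfer trials (24 per pair over
    all 15 combinations), onset jitters of 0-1500 ms in 500-ms steps, and
    20% randomly interspersed null (fixation-only) trials.
    """

    pair_probs: dict = field(
        default_factory=lambda: {"AB": 0.80, "CD": 0.70, "EF": 0.60})
    n_learning_trials: int = 300
    n_transfer_trials: int = 360
    jitter_set_ms: tuple = (0, 500, 1000, 1500)
    null_fraction: float = 0.20
    trial_duration_ms: int = 4000

    def __post_init__(self):
        for pair, p in self.pair_probs.items():
            if not (0.5 < p <= 1.0):
                raise ValueError(
                    f"pair {pair}: reinforcement probability {p} must be in (0.5, 1]")
        if self.n_learning_trials < 0 or self.n_transfer_trials < 0:
            raise ValueError("trial counts must be non-negative")
        if not (0.0 <= self.null_fraction < 1.0):
            raise ValueError("null_fraction must be in [0, 1)")

    @property
    def trial_duration_s(self) -> float:
        return self.trial_duration_ms / 1000.0

    def stim_reinforcement(self) -> dict:
        """Per-stimulus P(correct | chosen), derived from ``pair_probs``."""
        probs = {}
        for pair, p in self.pair_probs.items():
            opt = pair[0] if STIM_REINFORCEMENT.get(pair[0], 1) >= STIM_REINFORCEMENT.get(pair[1], 0) else pair[1]
            sub = pair[1] if opt == pair[0] else pair[0]
            probs[opt] = p
            probs[sub] = 1.0 - p
        return probs


def _interleave_nulls(n_trials: int, null_fraction: float, rng) -> np.ndarray:
    """Boolean mask over the padded sequence: True where a null trial sits."""
    n_null = int(round(null_fraction * n_trials))
    mask = np.zeros(n_trials + n_null, dtype=bool)
    if n_null:
        mask[rng.choice(n_trials + n_null, size=n_null, replace=False)] = True
    return mask


def _balanced_sides(n: int, rng) -> np.ndarray:
    """Sequence of 'left'/'right' with counts as equal as possible, shuffled."""
    sides = np.array(["left"] * (n // 2) + ["right"] * (n - n // 2), dtype=object)
    rng.shuffle(sides)
    return sides


def _assemble(pairs, sides, config: TaskConfig, phase: str, rng,
              subject_id: str = "sim") -> pd.DataFrame:
    n = len(pairs)
    order = rng.permutation(n)
    pairs = np.asarray(pairs, dtype=object)[order]
    sides = np.asarray(sides, dtype=object)[order]

    null_mask = _interleave_nulls(n, config.null_fraction, rng)
    jitters_s = rng.choice(np.asarray(config.jitter_set_ms) / 1000.0, size=n)

    onsets = np.empty(n)
    t = 0.0
    j = 0
    for slot_is_null in null_mask:
        if slot_is_null:
            t += config.trial_duration_s
        else:
            t += jitters_s[j]          # fixation jitter precedes stimulus onset
            onsets[j] = t
            t += config.trial_duration_s
            j += 1

    if phase == "learning":
        # nominal feedback latency; overwritten with RT-locked onsets when
        # an agent with response-time modelling completes the schedule
        feedback = onsets + 1.75
    else:
        feedback = np.full(n, np.nan)

    n_blocks = 2 if phase == "learning" else 3
    block = 1 + (np.arange(n) * n_blocks) // max(n, 1)

    return pd.DataFrame({
        "subject_id": subject_id,
        "phase": phase,
        "block": block,
        "trial_index": np.arange(n),
        "pair": pairs,
        "optimal_side": sides,
        "choice": pd.array([None] * n, dtype="string"),
        "reward": np.full(n, np.nan),
        "onset_s": onsets,
        "feedback_onset_s": feedback,
        "trial_sign": [trial_sign(p) for p in pairs],
    })


def build_learning_schedule(config: TaskConfig, seed: int,
                            subject_id: str = "sim") -> pd.DataFrame:
    """Randomised learning-phase schedule: equal pair counts, balanced sides.

    Returns a trial table (one row per stimulus trial; null trials appear
    only as gaps in the onset sequence). Raises ``ValueError`` if the trial
    count does not divide evenly over the configured pairs.
    """
    rng = np.random.default_rng(seed)
    pairs = list(config.pair_probs)
    n = config.n_learning_trials
    if n % len(pairs):
        raise ValueError(
            f"{n} learning trials not divisible by {len(pairs)} pairs")
    per_pair = n // len(pairs)
    pair_seq, side_seq = [], []
    for pair in pairs:
        pair_seq += [pair] * per_pair
        side_seq += list(_balanced_sides(per_pair, rng))
    return _assemble(pair_seq, side_seq, config, "learning", rng, subject_id)


def build_transfer_schedule(config: TaskConfig, seed: int,
                            subject_id: str = "sim") -> pd.DataFrame:
    """Transfer-phase schedule over all 15 pairs, side-balanced, no feedback."""
    rng = np.random.default_rng(seed)
    n = config.n_transfer_trials
    if n % len(ALL_PAIRS):
        raise ValueError(
            f"{n} transfer trials not divisible by {len(ALL_PAIRS)} pairs")
    per_pair = n // len(ALL_PAIRS)
    pair_seq, side_seq = [], []
    for pair in ALL_PAIRS:
        pair_seq += [pair] * per_pair
        side_seq += list(_balanced_sides(per_pair, rng))
    return _assemble(pair_seq, side_seq, config, "transfer", rng, subject_id)
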
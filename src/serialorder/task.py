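"""Combinatorial and temporal structure of the transitive-inference (TI) task.

A session presents pairs of images drawn from an implicitly ordered list of
``n_items`` pictures (ranks 1..n, labelled A, B, C, ...).  The subject is
rewarded for choosing the lower-ranked item.  Each pair carries two derived
quantities that organise every downstream analysis:

* **symbolic distance** (SD): the difference of the two ranks, ``B − A``;
* **joint rank** (JR): the sum of the two ranks, ``A + B``.

The two are numerically uncorrelated over the balanced pair set but jointly
determine the pair, since ``B = (JR + SD) / 2`` and ``A = (JR − SD) / 2``.

This module also encodes the session block structure (a single-stimulus phase
followed by all-pairs blocks with positional counterbalancing), the trial
timing distributions, and the named peri-event analysis windows (epochs).
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "StimulusList",
    "StimPair",
    "TrialTiming",
    "EpochWindow",
    "EpochScheme",
    "VAC_EPOCHS",
    "OUTCOME_EPOCHS",
    "IDENTITY_WINDOW",
    "ScheduledTrial",
    "SessionSchedule",
    "InvalidListError",
    "InvalidPairError",
    "NoSuchPairError",
    "enumerate_pairs",
    "symbolic_distance",
    "joint_rank",
    "decompose_ranks",
    "build_session_schedule",
]


class InvalidListError(ValueError):
    """Raised for stimulus lists with fewer than two items."""


class InvalidPairError(ValueError):
    """Raised for pairs that do not consist of two distinct in-range ranks."""


class NoSuchPairError(ValueError):
    """Raised when a (joint rank, symbolic distance) combination maps to no pair."""


@dataclass(frozen=True)
class StimulusList:
    """An ordered list of stimuli; rank 1 is the first letter ('A')."""

    n_items: int = 7
    item_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.n_items < 2:
            raise InvalidListError(f"a list needs at least 2 items, got {self.n_items}")
        if not self.item_ids:
            letters = string.ascii_uppercase
            if self.n_items <= len(letters):
                ids = tuple(letters[: self.n_items])
            else:
                ids = tuple(f"S{i}" for i in range(1, self.n_items + 1))
            object.__setattr__(self, "item_ids", ids)
        if len(self.item_ids) != self.n_items:
            raise InvalidListError("item_ids length must equal n_items")
        if len(set(self.item_ids)) != self.n_items:
            raise InvalidListError("item_ids must be unique")

    def label(self, rank: int) -> str:
        return self.item_ids[rank - 1]


@dataclass(frozen=True)
class StimPair:
    """An unordered pair of distinct ranks; carries SD and JR."""

    rank_low: int
    rank_high: int

    def __post_init__(self) -> None:
        if self.rank_low == self.rank_high:
            raise InvalidPairError("pair ranks must be distinct")
        if self.rank_low > self.rank_high:
            raise InvalidPairError("rank_low must be the smaller rank")
        if self.rank_low < 1:
            raise InvalidPairError("ranks are 1-based")

    @property
    def symbolic_distance(self) -> int:
        return self.rank_high - self.rank_low

    @property
    def joint_rank(self) -> int:
        return self.rank_low + self.rank_high

    def contains_terminal(self, n_items: int) -> bool:
        """True if the pair includes the first or last list item."""
        return self.rank_low == 1 or self.rank_high == n_items

    def label(self, stim_list: StimulusList) -> str:
        return stim_list.label(self.rank_low) + stim_list.label(self.rank_high)


def enumerate_pairs(stim_list: StimulusList) -> list[StimPair]:
    """All unordered pairs of distinct ranks, n(n−1)/2 of them (21 for n=7)."""
    n = stim_list.n_items
    return [StimPair(i, j) for i in range(1, n) for j in range(i + 1, n + 1)]


def symbolic_distance(pair: StimPair) -> int:
    """Difference of the two ranks (BC → 1, AG → 6 for a 7-item list)."""
    return pair.symbolic_distance


def joint_rank(pair: StimPair) -> int:
    """Sum of the two ranks (BC → 5, AG → 8); range [3, 2n−1]."""
    return pair.joint_rank


def decompose_ranks(jr: int, sd: int, n_items: int = 7) -> tuple[int, int]:
    """Invert (JR, SD) back to the pair of ranks.

    rank_high = (JR + SD) / 2 and rank_low = (JR − SD) / 2; valid only when
    JR and SD have equal parity and the result lies inside the list.
    """
    if (jr + sd) % 2 != 0:
        raise NoSuchPairError(f"JR={jr} and SD={sd} have mismatched parity")
    hi = (jr + sd) // 2
    lo = (jr - sd) // 2
    if not (1 <= lo < hi <= n_items):
        raise NoSuchPairError(f"(JR={jr}, SD={sd}) is outside a {n_items}-item list")
    return lo, hi


# ---------------------------------------------------------------------------
# Trial timing
# ---------------------------------------------------------------------------

def _solve_fix_delay_rate(lo: float, hi: float, mean: float) -> float:
    """Rate of the truncated shifted exponential on [lo, hi] with given mean."""
    span = hi - lo

    def excess(lam: float) -> float:
        return 1.0 / lam - span / np.expm1(span * lam) - (mean - lo)

    return brentq(excess, 1e-3, 200.0)


@dataclass(frozen=True)
class TrialTiming:
    """Trial interval distributions.

    The fixation delay is positively skewed on [0.4, 1.2] s with mean 0.5 s,
    modelled as a truncated shifted exponential (rate solved once numerically).
    Hold and reward intervals are uniform; the response deadline is 1.5 s.
    """

    fix_delay_lo: float = 0.4
    fix_delay_hi: float = 1.2
    fix_delay_mean: float = 0.5
    response_deadline: float = 1.5
    hold_lo: float = 0.4
    hold_hi: float = 0.6
    reward_lo: float = 0.35
    reward_hi: float = 0.65
    _rate: float = field(init=False, repr=False, default=0.0)

    def __post_init__(self) -> None:
        rate = _solve_fix_delay_rate(self.fix_delay_lo, self.fix_delay_hi, self.fix_delay_mean)
        object.__setattr__(self, "_rate", rate)

    def sample_fix_delay(self, rng: np.random.Generator, size=None) -> np.ndarray | float:
        # inverse CDF of the truncated shifted exponential
        span = self.fix_delay_hi - self.fix_delay_lo
        u = rng.uniform(size=size)
        return self.fix_delay_lo - np.log1p(-u * (-np.expm1(-self._rate * span))) / self._rate

    def sample_hold(self, rng: np.random.Generator, size=None):
        return rng.uniform(self.hold_lo, self.hold_hi, size=size)

    def sample_reward_interval(self, rng: np.random.Generator, size=None):
        return rng.uniform(self.reward_lo, self.reward_hi, size=size)


# ---------------------------------------------------------------------------
# Epochs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EpochWindow:
    """A half-open analysis window [start_ms, end_ms) relative to an event.

    ``align`` is 'stimulus' or 'saccade'.  ``end_align`` may name a different
    event to support variable-length windows (e.g. stimulus onset → saccade).
    """

    align: str
    start_ms: float
    end_ms: float | None = None
    end_align: str | None = None

    def __post_init__(self) -> None:
        if self.align not in ("stimulus", "saccade"):
            raise ValueError(f"unknown alignment event {self.align!r}")
        if self.end_align is None and self.end_ms is None:
            raise ValueError("window needs end_ms or end_align")
        if self.end_align is None and self.end_ms is not None and not self.start_ms < self.end_ms:
            raise ValueError("window start must precede end")


EpochScheme = dict[str, EpochWindow]

#: Epochs used for variance partitioning (baseline-subtracted VAC).
VAC_EPOCHS: EpochScheme = {
    "baseline": EpochWindow("stimulus", -250.0, 0.0),
    "visual": EpochWindow("stimulus", 5.0, 150.0),
    "presaccadic": EpochWindow("saccade", -100.0, 0.0),
    "postsaccadic": EpochWindow("saccade", 0.0, 500.0),
}

#: Epochs used for correct-vs-incorrect outcome tests.
OUTCOME_EPOCHS: EpochScheme = {
    "background": EpochWindow("stimulus", -200.0, 0.0),
    "visual": EpochWindow("stimulus", 40.0, 150.0),
    "presaccadic": EpochWindow("saccade", -150.0, 0.0),
}

#: Visual window used for stimulus identity / rank coding analyses.
IDENTITY_WINDOW = EpochWindow("stimulus", 40.0, 150.0)


# ---------------------------------------------------------------------------
# Session schedule
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScheduledTrial:
    """One scheduled trial before behavior is simulated.

    ``phase`` is 1 (single stimulus) or 2 (choice pair).  For phase-1 trials
    ``single_rank`` holds the presented item and ``in_rf`` whether it is in
    the recorded neuron's receptive field.  For phase-2 trials ``pair`` holds
    the two ranks and ``in_rf_item`` the rank placed inside the RF (the other
    item sits diametrically opposite).
    """

    phase: int
    single_rank: int | None = None
    in_rf: bool | None = None
    pair: StimPair | None = None
    in_rf_item: int | None = None
    block: int = 0


@dataclass
class SessionSchedule:
    stim_list: StimulusList
    trials: list[ScheduledTrial]
    n_pair_blocks: int
    seed: int

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def phase1_trials(self) -> list[ScheduledTrial]:
        return [t for t in self.trials if t.phase == 1]

    def phase2_trials(self) -> list[ScheduledTrial]:
        return [t for t in self.trials if t.phase == 2]


def build_session_schedule(
    stim_list: StimulusList,
    n_pair_blocks: int = 20,
    rng_seed: int = 0,
    n_phase1_blocks: int = 5,
) -> SessionSchedule:
    """Build the two-phase session schedule.

    Phase 1: ``n_phase1_blocks`` blocks of 2·n single-stimulus trials (every
    item once in and once out of the RF per block, order shuffled).  Phase 2:
    ``n_pair_blocks`` blocks, each containing every pair exactly twice — once
    per positional arrangement (which item is in the RF) — shuffled within
    block.  Deterministic given the seed.
    """
    if not 1 <= n_pair_blocks <= 20:
        raise ValueError("n_pair_blocks must be between 1 and 20")
    rng = np.random.default_rng(rng_seed)
    n = stim_list.n_items
    trials: list[ScheduledTrial] = []

    for b in range(n_phase1_blocks):
        block = [
            ScheduledTrial(phase=1, single_rank=r, in_rf=in_rf, block=b)
            for r in range(1, n + 1)
            for in_rf in (True, False)
        ]
        order = rng.permutation(len(block))
        trials.extend(block[i] for i in order)

    pairs = enumerate_pairs(stim_list)
    for b in range(n_pair_blocks):
        block = [
            ScheduledTrial(phase=2, pair=p, in_rf_item=item, block=b)
            for p in pairs
            for item in (p.rank_low, p.rank_high)
        ]
        order = rng.permutation(len(block))
        trials.extend(block[i] for i in order)

    return SessionSchedule(stim_list, trials, n_pair_blocks, rng_seed)
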
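"""The Iowa gambling task environment.

Four decks A-D are served card by card.  Decks A and B pay 100 points
per draw but lose 1250 points per block of 10 cards (A: five losses of
250, B: one loss of 1250), for a net of -250 per block.  Decks C and D
pay 50 points per draw and lose 250 per block (C: five losses of 50,
D: one loss of 250), for a net of +250 per block.  Loss positions
within each block of 10 are not constrained by the payoff scheme; they
are either shuffled (seeded) or placed at a fixed documented layout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rand import u01

DECKS = ("A", "B", "C", "D")
DECK_INDEX = {d: i for i, d in enumerate(DECKS)}

#: reward per draw, loss magnitude per losing draw, losses per 10 cards
REWARD_PER_TRIAL = np.array([100.0, 100.0, 50.0, 50.0])
LOSS_MAGNITUDE = np.array([250.0, 1250.0, 50.0, 250.0])
LOSSES_PER_BLOCK = np.array([5, 1, 5, 1])

#: fixed_canonical layout: 0-based loss positions within each block of 10.
#: Frequent-loss decks (A, C) lose on the odd positions; infrequent-loss
#: decks (B, D) lose on the middle card.  Any layout satisfies the
#: per-block aggregates; this one is shipped for bit-reproducible tests.
CANONICAL_LOSS_POSITIONS = {
    "A": (1, 3, 5, 7, 9),
    "B": (4,),
    "C": (1, 3, 5, 7, 9),
    "D": (4,),
}


class DeckExhaustedError(RuntimeError):
    """Raised when a deck's card sequence has been fully consumed."""


@dataclass(frozen=True)
class Outcome:
    """One card draw: a gain and a loss magnitude, both non-negative."""

    gain: float
    loss: float

    @property
    def net(self) -> float:
        return self.gain - self.loss


@dataclass
class TaskSchedule:
    """Per-deck outcome sequences plus independent draw cursors.

    ``gains``/``losses`` have shape (4, length); each deck's sequence is
    consumed independently so that an agent may draw every card from a
    single deck.
    """

    gains: np.ndarray
    losses: np.ndarray
    n_trials: int
    seed: int
    loss_policy: str
    cursors: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.cursors is None:
            self.cursors = np.zeros(4, dtype=int)

    @property
    def length(self) -> int:
        return self.gains.shape[1]

    def copy(self) -> "TaskSchedule":
        return TaskSchedule(
            self.gains.copy(), self.losses.copy(), self.n_trials,
            self.seed, self.loss_policy, self.cursors.copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        """Long-format audit table with columns deck, index, gain, loss."""
        rows = []
        for i, d in enumerate(DECKS):
            for j in range(self.length):
                rows.append((d, j, self.gains[i, j], self.losses[i, j]))
        return pd.DataFrame(rows, columns=["deck", "index", "gain", "loss"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, n_trials: int | None = None) -> "TaskSchedule":
        df = pd.read_csv(path)
        missing = {"deck", "index", "gain", "loss"} - set(df.columns)
        if missing:
            raise ValueError(f"schedule CSV missing columns: {sorted(missing)}")
        length = df["index"].max() + 1
        gains = np.zeros((4, length))
        losses = np.zeros((4, length))
        for _, row in df.iterrows():
            i = DECK_INDEX[str(row["deck"])]
            gains[i, int(row["index"])] = row["gain"]
            losses[i, int(row["index"])] = row["loss"]
        return cls(gains, losses, n_trials or length, seed=-1,
                   loss_policy="imported")


def _loss_indicators(n_blocks: int, seed: int, policy: str) -> np.ndarray:
    """(4, n_blocks*10) boolean array marking losing positions."""
    ind = np.zeros((4, n_blocks, 10), dtype=bool)
    if policy == "fixed_canonical":
        for i, d in enumerate(DECKS):
            ind[i, :, list(CANONICAL_LOSS_POSITIONS[d])] = True
    elif policy == "shuffled_block":
        # rank of each slot's uniform within its block; losses on the
        # lowest-ranked slots.
        u = u01(seed, np.arange(4)[:, None, None],
                np.arange(n_blocks)[None, :, None],
                np.arange(10)[None, None, :])
        rank = u.argsort(axis=-1).argsort(axis=-1)
        ind = rank < LOSSES_PER_BLOCK[:, None, None]
    else:
        raise ValueError(
            f"unknown loss_policy {policy!r}; "
            "expected 'shuffled_block' or 'fixed_canonical'"
        )
    return ind.reshape(4, n_blocks * 10)


def build_standard_schedule(
    n_trials: int = 100,
    seed: int = 0,
    loss_policy: str = "shuffled_block",
) -> TaskSchedule:
    """Build the standard payoff schedule.

    Each deck's sequence is long enough (next multiple of 10 at or above
    ``n_trials``) that any deck can serve every trial.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    n_blocks = -(-n_trials // 10)
    ind = _loss_indicators(n_blocks, seed, loss_policy)
    length = n_blocks * 10
    gains = np.repeat(REWARD_PER_TRIAL[:, None], length, axis=1)
    losses = np.where(ind, LOSS_MAGNITUDE[:, None], 0.0)
    return TaskSchedule(gains, losses, n_trials, seed, loss_policy)


def draw(schedule: TaskSchedule, deck: str) -> Outcome:
    """Serve the next card of ``deck``, advancing only that deck's cursor."""
    if deck not in DECK_INDEX:
        raise ValueError(f"unknown deck {deck!r}")
    i = DECK_INDEX[deck]
    c = schedule.cursors[i]
    if c >= schedule.length:
        raise DeckExhaustedError(f"deck {deck} exhausted after {c} draws")
    schedule.cursors[i] = c + 1
    return Outcome(float(schedule.gains[i, c]), float(schedule.losses[i, c]))


def batch_schedules(
    n_agents: int,
    n_trials: int,
    seed: int,
    loss_policy: str = "shuffled_block",
    agent_offset: int = 0,
    agent_ids: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Schedules for many agents at once: (gains, losses) of shape
    (n_agents, 4, length).  Agent ``i`` receives the same cards it would
    receive from any other partitioning with the same id
    (``agent_offset + i``, or ``agent_ids[i]`` when given).
    """
    n_blocks = -(-n_trials // 10)
    length = n_blocks * 10
    ids = (np.asarray(agent_ids, dtype=np.int64) if agent_ids is not None
           else agent_offset + np.arange(n_agents))
    if loss_policy == "fixed_canonical":
        ind = np.zeros((1, 4, n_blocks, 10), dtype=bool)
        for i, d in enumerate(DECKS):
            ind[0, i, :, list(CANONICAL_LOSS_POSITIONS[d])] = True
        ind = np.broadcast_to(ind, (n_agents, 4, n_blocks, 10))
    elif loss_policy == "shuffled_block":
        u = u01(seed, ids[:, None, None, None],
                np.arange(4)[None, :, None, None],
                np.arange(n_blocks)[None, None, :, None],
                np.arange(10)[None, None, None, :])
        rank = u.argsort(axis=-1).argsort(axis=-1)
        ind = rank < LOSSES_PER_BLOCK[None, :, None, None]
    else:
        raise ValueError(f"unknown loss_policy {loss_policy!r}")
    ind = ind.reshape(n_agents, 4, length)
    gains = np.broadcast_to(
        REWARD_PER_TRIAL[None, :, None], (n_agents, 4, length)
    ).copy()
    losses = np.where(ind, LOSS_MAGNITUDE[None, :, None], 0.0)
    return gains, losses
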
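"""Choice-pattern classification and sequential-exploration indices.

A subject's 100 deck choices are summarized by two contrasts:

* value contrast ``d_value = (nC + nD) - (nA + nB)`` — good minus bad
  decks;
* frequency contrast ``d_freq = (nB + nD) - (nA + nC)`` — infrequent-
  minus frequent-loss decks.

The *broad* classification assigns the label of the dominant contrast:
Infrequent-Over-Frequent (IOF) or Frequent-Over-Infrequent (FOI) when
``|d_freq| >= |d_value|`` and the frequency contrast is nonzero, else
Good-Over-Bad (GOB) or Bad-Over-Good (BOG); "Remaining" only when both
contrasts vanish.  Giving the frequency dimension priority on exact
magnitude ties is the package default (a value-priority variant is
available via ``rule=``): the labels stay exclusive either way, and the
frequency-priority split matches the reported ORL parameter-space
profile, where IOF exceeds BOG.  The *restricted* classification additionally
requires the dominant pair to reach 65 of 100 choices (C+D >= 65 for
GOB, A+B >= 65 for BOG, B+D >= 65 for IOF); FOI has no restricted
category.

Sequential-exploration (SeqE) indices count runs of distinct decks:
DE3 and DE4 slide a window of 3 or 4 over the sequence and count
windows whose decks are all distinct; DE4F partitions the sequence into
floor(n/4) fixed chunks of 4 and counts fully distinct chunks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .task import DECK_INDEX
from .models import TrialSequence

BROAD_LABELS = ("GOB", "BOG", "IOF", "FOI", "Remaining")
RESTRICTED_LABELS = ("GOB", "BOG", "IOF")


@dataclass(frozen=True)
class PatternCounts:
    na: int
    nb: int
    nc: int
    nd: int

    @property
    def n_trials(self) -> int:
        return self.na + self.nb + self.nc + self.nd

    @property
    def d_value(self) -> int:
        return (self.nc + self.nd) - (self.na + self.nb)

    @property
    def d_freq(self) -> int:
        return (self.nb + self.nd) - (self.na + self.nc)


@dataclass(frozen=True)
class SeqEIndex:
    de3: int
    de4: int
    de4f: int


def _as_choice_array(seq) -> np.ndarray:
    if isinstance(seq, TrialSequence):
        return seq.choices
    arr = np.asarray(list(seq) if isinstance(seq, str) else seq)
    if arr.dtype.kind in "US":
        try:
            arr = np.array([DECK_INDEX[str(s)] for s in arr])
        except KeyError as e:
            raise ValueError(f"unknown deck symbol {e.args[0]!r}") from None
    arr = arr.astype(int)
    if arr.size and (arr.min() < 0 or arr.max() > 3):
        raise ValueError("deck indices must lie in 0..3")
    return arr


def count_choices(seq) -> PatternCounts:
    """Tally per-deck choice counts from a sequence or TrialSequence."""
    arr = _as_choice_array(seq)
    if arr.size == 0:
        raise ValueError("empty choice sequence")
    n = np.bincount(arr, minlength=4)
    return PatternCounts(int(n[0]), int(n[1]), int(n[2]), int(n[3]))


def classify_broad(counts: PatternCounts, rule: str = "freq_priority") -> str:
    """Dominant-contrast broad label.

    ``rule`` resolves exact magnitude ties between the two contrasts:
    the default gives the frequency dimension priority;
    ``"value_priority"`` gives the value dimension priority.
    """
    dv, df = counts.d_value, counts.d_freq
    if rule == "freq_priority":
        if abs(df) >= abs(dv) and df != 0:
            return "IOF" if df > 0 else "FOI"
        if dv != 0:
            return "GOB" if dv > 0 else "BOG"
    elif rule == "value_priority":
        if abs(dv) >= abs(df) and dv != 0:
            return "GOB" if dv > 0 else "BOG"
        if df != 0:
            return "IOF" if df > 0 else "FOI"
    else:
        raise ValueError(f"unknown classification rule {rule!r}")
    return "Remaining"


def classify_restricted(
    counts: PatternCounts,
    threshold: int = 65,
    n_trials_required: int | None = 100,
) -> str | None:
    """Restricted label (GOB/BOG/IOF) or None.

    The 65-of-100 pair-sum criterion is defined on 100-trial sessions;
    pass ``n_trials_required=None`` to override.
    """
    if n_trials_required is not None and counts.n_trials != n_trials_required:
        raise ValueError(
            f"restricted classification is defined on {n_trials_required} "
            f"trials (got {counts.n_trials}); pass n_trials_required=None "
            "to override"
        )
    broad = classify_broad(counts)
    if broad == "GOB" and counts.nc + counts.nd >= threshold:
        return "GOB"
    if broad == "BOG" and counts.na + counts.nb >= threshold:
        return "BOG"
    if broad == "IOF" and counts.nb + counts.nd >= threshold:
        return "IOF"
    return None


def classify_counts_batch(counts: np.ndarray, threshold: int = 65,
                          rule: str = "freq_priority"):
    """Vectorized broad + restricted labels for an (N, 4) count matrix.

    Returns (broad, restricted) integer arrays: broad indexes
    BROAD_LABELS; restricted indexes RESTRICTED_LABELS with -1 = none.
    """
    counts = np.asarray(counts)
    dv = (counts[:, 2] + counts[:, 3]) - (counts[:, 0] + counts[:, 1])
    df = (counts[:, 1] + counts[:, 3]) - (counts[:, 0] + counts[:, 2])
    broad = np.full(len(counts), 4, dtype=np.int8)  # Remaining
    if rule == "freq_priority":
        freq_dom = (np.abs(df) >= np.abs(dv)) & (df != 0)
        value_dom = ~freq_dom & (dv != 0)
    elif rule == "value_priority":
        value_dom = (np.abs(dv) >= np.abs(df)) & (dv != 0)
        freq_dom = ~value_dom & (df != 0)
    else:
        raise ValueError(f"unknown classification rule {rule!r}")
    broad[value_dom & (dv > 0)] = 0
    broad[value_dom & (dv < 0)] = 1
    broad[freq_dom & (df > 0)] = 2
    broad[freq_dom & (df < 0)] = 3
    restricted = np.full(len(counts), -1, dtype=np.int8)
    restricted[(broad == 0) & (counts[:, 2] + counts[:, 3] >= threshold)] = 0
    restricted[(broad == 1) & (counts[:, 0] + counts[:, 1] >= threshold)] = 1
    restricted[(broad == 2) & (counts[:, 1] + counts[:, 3] >= threshold)] = 2
    return broad, restricted


def seqe_indices(seq) -> SeqEIndex:
    """DE3/DE4 sliding-window and DE4F fixed-chunk exploration counts."""
    arr = _as_choice_array(seq)
    n = len(arr)
    if n < 4:
        raise ValueError("SeqE indices require at least 4 trials")
    w3 = np.lib.stride_tricks.sliding_window_view(arr, 3)
    de3 = int(((w3[:, 0] != w3[:, 1]) & (w3[:, 0] != w3[:, 2])
               & (w3[:, 1] != w3[:, 2])).sum())
    w4 = np.lib.stride_tricks.sliding_window_view(arr, 4)
    de4 = int(_all_distinct4(w4).sum())
    nchunk = n // 4
    chunks = arr[: nchunk * 4].reshape(nchunk, 4)
    de4f = int(_all_distinct4(chunks).sum())
    return SeqEIndex(de3, de4, de4f)


def _all_distinct4(w: np.ndarray) -> np.ndarray:
    # four deck ids are distinct iff their one-hot union covers all decks
    masks = np.left_shift(1, w).astype(np.int16)
    return (masks[:, 0] | masks[:, 1] | masks[:, 2] | masks[:, 3]) == 0b1111


def summarize_subject(seq: TrialSequence) -> dict:
    """Per-subject pattern row: counts, labels, SeqE indices."""
    counts = count_choices(seq)
    restricted = (
        classify_restricted(counts) if counts.n_trials == 100 else None
    )
    idx = seqe_indices(seq) if seq.n_trials >= 4 else SeqEIndex(0, 0, 0)
    return {
        "subjID": seq.subject_id,
        "nA": counts.na,
        "nB": counts.nb,
        "nC": counts.nc,
        "nD": counts.nd,
        "broad": classify_broad(counts),
        "restricted": restricted if restricted is not None else "none",
        "DE3": idx.de3,
        "DE4": idx.de4,
        "DE4F": idx.de4f,
    }


def cohort_pattern_table(subjects) -> pd.DataFrame:
    return pd.DataFrame([summarize_subject(s) for s in subjects])


def pattern_proportions(table: pd.DataFrame) -> pd.DataFrame:
    """Cohort-level broad/restricted pattern proportions (bar-chart data)."""
    rows = []
    n = len(table)
    for label in BROAD_LABELS:
        rows.append(("broad", label, (table["broad"] == label).sum() / n))
    qualifying = table["restricted"].isin(RESTRICTED_LABELS).sum()
    for label in RESTRICTED_LABELS:
        k = (table["restricted"] == label).sum()
        rows.append(("restricted_raw", label, k / n))
        rows.append(
            ("restricted_renorm", label, k / qualifying if qualifying else np.nan)
        )
    return pd.DataFrame(rows, columns=["definition", "label", "proportion"])
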
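"""Classic IGT reinforcement-learning models: EV, PVL, EV-PU, PVL-Delta.

These are the comparison baselines from the earlier modeling
literature, implemented from their canonical formulations:

* **EV** (expectancy valence): attention-weighted utility
  ``u = (1-w)*W - w*L``, delta-rule expectancy learning on the chosen
  deck, and a trial-dependent sensitivity ``theta(t) = (t/10)**c``.
* **PVL** (prospect valence learning): prospect utility
  ``u = x**A`` for net gains and ``-w*|x|**A`` for net losses, decay-RL
  learning (all expectancies decay by ``d``; the chosen deck adds
  ``u``), and trait sensitivity ``theta = 3**c - 1``.
* **EV-PU**: PVL's prospect utility with EV's delta rule and
  trial-dependent sensitivity.
* **PVL-Delta**: PVL's utility and trait sensitivity with delta-rule
  learning on the chosen deck only.

All four use the softmax choice rule ``p ~ exp(theta * Ev)`` on a single
per-deck expectancy vector.  Outcomes are rescaled by ``outcome_scale``
before the utility, as for ORL/VSE.
"""

from __future__ import annotations

import numpy as np

from ._rand import u01
from .models import DEFAULT_OUTCOME_SCALE, _softmax
from .task import batch_schedules

LEGACY_MODELS = ("EV", "PVL", "EV-PU", "PVL-DELTA")

#: parameter grid bounds per model, in order
LEGACY_GRID_BOUNDS = {
    "EV": {"w": (0.0, 1.0), "a": (0.0, 1.0), "c": (-5.0, 5.0)},
    "PVL": {"A": (0.0, 1.0), "w": (0.0, 5.0), "a": (0.0, 1.0), "c": (0.0, 5.0)},
    "EV-PU": {"A": (0.0, 1.0), "w": (0.0, 5.0), "a": (0.0, 1.0), "c": (-5.0, 5.0)},
    "PVL-DELTA": {"A": (0.0, 1.0), "w": (0.0, 5.0), "a": (0.0, 1.0), "c": (0.0, 5.0)},
}


def _norm_id(model_id: str) -> str:
    mid = model_id.upper().replace("_", "-")
    if mid == "PVLDELTA":
        mid = "PVL-DELTA"
    if mid == "EVPU":
        mid = "EV-PU"
    if mid not in LEGACY_MODELS:
        raise ValueError(f"unsupported legacy model {model_id!r}")
    return mid


def _utility(mid: str, params: np.ndarray, gain, loss):
    """Batched utility; gain/loss already on the model scale."""
    if mid == "EV":
        w = params[:, 0]
        return (1.0 - w) * gain - w * loss
    A, w = params[:, 0], params[:, 1]
    x = gain - loss
    return np.where(x >= 0, np.abs(x) ** A, -w * np.abs(x) ** A)


def _sensitivity(mid: str, params: np.ndarray, trial_index: int):
    """Softmax sensitivity at 0-based ``trial_index``."""
    c = params[:, -1]
    if mid in ("EV", "EV-PU"):
        return ((trial_index + 1) / 10.0) ** c
    return 3.0 ** c - 1.0


def legacy_update(
    model_id: str,
    params,
    state: np.ndarray,
    chosen: int,
    outcome,
    outcome_scale: float = DEFAULT_OUTCOME_SCALE,
) -> np.ndarray:
    """One expectancy update; ``state`` is the 4-vector of expectancies."""
    mid = _norm_id(model_id)
    p = np.atleast_2d(np.asarray(params, dtype=float))
    ev = np.asarray(state, dtype=float).copy()
    u = float(
        _utility(mid, p, outcome.gain * outcome_scale,
                 outcome.loss * outcome_scale)[0]
    )
    a = float(p[0, -2])  # recency / updating rate
    if mid in ("EV", "EV-PU", "PVL-DELTA"):
        ev[chosen] += a * (u - ev[chosen])  # delta rule, chosen deck only
    else:
        ev *= a  # decay-RL: all decks decay, chosen adds utility
        ev[chosen] += u
    return ev


def legacy_choice_probs(
    model_id: str, params, state: np.ndarray, trial_index: int
) -> np.ndarray:
    """Softmax with the model's (possibly trial-dependent) sensitivity."""
    mid = _norm_id(model_id)
    p = np.atleast_2d(np.asarray(params, dtype=float))
    theta = float(_sensitivity(mid, p, trial_index)[0])
    return _softmax(np.asarray(state, dtype=float) * theta)


def simulate_batch_legacy(
    model_id: str,
    params: np.ndarray,
    n_trials: int,
    seed: int,
    loss_policy: str = "shuffled_block",
    outcome_scale: float = DEFAULT_OUTCOME_SCALE,
    agent_offset: int = 0,
    agent_ids: np.ndarray | None = None,
):
    """Batched generative simulation mirroring models.simulate_batch."""
    mid = _norm_id(model_id)
    params = np.asarray(params, dtype=float)
    B = params.shape[0]
    ids = (np.asarray(agent_ids, dtype=np.int64) if agent_ids is not None
           else agent_offset + np.arange(B))
    sched_gains, sched_losses = batch_schedules(
        B, n_trials, seed, loss_policy, agent_offset, agent_ids
    )
    cursors = np.zeros((B, 4), dtype=int)
    rows = np.arange(B)
    ev = np.zeros((B, 4))
    decay = mid == "PVL"
    a = params[:, -2]
    choices = np.zeros((B, n_trials), dtype=np.int8)
    gains = np.zeros((B, n_trials))
    losses = np.zeros((B, n_trials))
    with np.errstate(over="ignore"):
        for t in range(n_trials):
            theta = np.minimum(_sensitivity(mid, params, t), 1e8)
            probs = _softmax(ev * theta[:, None])
            u = u01(seed ^ 0x5EED, ids, np.full(B, t))
            cum = np.cumsum(probs, axis=1)
            chosen = (u[:, None] > cum).sum(axis=1).clip(0, 3)
            g = sched_gains[rows, chosen, cursors[rows, chosen]]
            l = sched_losses[rows, chosen, cursors[rows, chosen]]
            cursors[rows, chosen] += 1
            choices[:, t] = chosen
            gains[:, t] = g
            losses[:, t] = l
            util = _utility(mid, params, g * outcome_scale, l * outcome_scale)
            if decay:
                ev *= a[:, None]
                ev[rows, chosen] += util
            else:
                ev[rows, chosen] += a * (util - ev[rows, chosen])
    return choices, gains, losses
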
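"""ORL and VSE reinforcement-learning models of the Iowa gambling task.

Both models maintain deck-level latent values that are updated trial by
trial and mapped to choice probabilities through a softmax.

**ORL** (outcome-representation learning) tracks three signals per deck:
an expected value ``EV`` updated by a delta rule with separate reward
(``A_rew``) and punishment (``A_pun``) learning rates, an expected win
frequency ``EF`` updated toward ``sgn(net)`` for the chosen deck and
``-sgn(net)/3`` for each unchosen deck, and a perseverance trace ``PS``
that is reset to ``1/(1+K)`` on the chosen deck and divided by ``1+K``
elsewhere, with ``K = 3**K' - 1``.  The integrated signal is
``V = EV + EF*beta_F + PS*beta_P`` and choice probabilities are
``softmax(V)`` (sensitivity fixed at 1).

**VSE** (value plus sequential exploration) splits value into an
exploitation weight, decayed by ``delta`` and incremented by the utility
``v = gain**theta - loss**theta`` on the chosen deck, and an exploration
weight that is zeroed on the chosen deck and moves toward the
exploration bonus ``phi`` at rate ``alpha`` on unchosen decks.  Choice
probabilities are ``softmax((explore + exploit) * c)`` with consistency
``c = 3**beta - 1``.

Outcomes are rescaled by ``outcome_scale`` (default 1/100) before they
enter either model, so a 100-point gain contributes +1; unscaled
payoffs of +/-1250 would saturate the softmax for most parameter
values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._rand import u01
from .task import DECKS, DECK_INDEX, TaskSchedule, batch_schedules, draw

#: default rescaling applied to raw point outcomes before model updates
DEFAULT_OUTCOME_SCALE = 0.01


# ---------------------------------------------------------------------------
# parameters and state


@dataclass(frozen=True)
class ORLParams:
    """ORL parameters on their natural scales (Table-range convention)."""

    a_rew: float  # reward learning rate, (0, 1)
    a_pun: float  # punishment learning rate, (0, 1)
    k_prime: float  # decay exponent, [0, 5]
    beta_f: float  # outcome-frequency weight, unbounded
    beta_p: float  # perseverance weight, unbounded

    def __post_init__(self):
        if not (0.0 <= self.a_rew <= 1.0 and 0.0 <= self.a_pun <= 1.0):
            raise ValueError("learning rates must lie in [0, 1]")
        if not 0.0 <= self.k_prime <= 5.0:
            raise ValueError("k_prime must lie in [0, 5]")

    @property
    def K(self) -> float:
        """Perseverance decay ``K = 3**K' - 1``, in [0, 242]."""
        return 3.0 ** self.k_prime - 1.0

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.a_rew, self.a_pun, self.k_prime, self.beta_f, self.beta_p]
        )


@dataclass(frozen=True)
class VSEParams:
    theta: float  # utility sensitivity, [0, 1]
    delta: float  # exploitation decay, [0, 1]
    alpha: float  # exploration learning rate, [0, 1]
    phi: float  # exploration bonus, unbounded
    beta: float  # inverse temperature, [0, 5]

    def __post_init__(self):
        for name in ("theta", "delta", "alpha"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 0.0 <= self.beta <= 5.0:
            raise ValueError("beta must lie in [0, 5]")

    @property
    def c(self) -> float:
        """Choice consistency ``c = 3**beta - 1``, in [0, 242]."""
        return 3.0 ** self.beta - 1.0

    def as_array(self) -> np.ndarray:
        return np.array([self.theta, self.delta, self.alpha, self.phi, self.beta])


@dataclass
class ORLState:
    ev: np.ndarray = field(default_factory=lambda: np.zeros(4))
    ef: np.ndarray = field(default_factory=lambda: np.zeros(4))
    ps: np.ndarray = field(default_factory=lambda: np.zeros(4))

    def value_signal(self, params: ORLParams) -> np.ndarray:
        """Integrated value V = EV + EF*beta_F + PS*beta_P."""
        return self.ev + self.ef * params.beta_f + self.ps * params.beta_p

    def copy(self) -> "ORLState":
        return ORLState(self.ev.copy(), self.ef.copy(), self.ps.copy())


@dataclass
class VSEState:
    exploit: np.ndarray = field(default_factory=lambda: np.zeros(4))
    explore: np.ndarray = field(default_factory=lambda: np.zeros(4))

    def copy(self) -> "VSEState":
        return VSEState(self.exploit.copy(), self.explore.copy())


@dataclass
class TrialSequence:
    """One subject's ordered choices with realized raw-point outcomes."""

    choices: np.ndarray  # deck indices 0..3
    gains: np.ndarray
    losses: np.ndarray  # loss magnitudes (non-negative)
    subject_id: str = "subj"

    def __post_init__(self):
        self.choices = np.asarray(self.choices, dtype=int)
        self.gains = np.asarray(self.gains, dtype=float)
        self.losses = np.asarray(self.losses, dtype=float)
        if not (len(self.choices) == len(self.gains) == len(self.losses)):
            raise ValueError("choices, gains and losses must share length")

    @property
    def n_trials(self) -> int:
        return len(self.choices)

    @property
    def deck_letters(self) -> list[str]:
        return [DECKS[c] for c in self.choices]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subjID": self.subject_id,
                "trial": np.arange(1, self.n_trials + 1),
                "deck": self.deck_letters,
                "gain": self.gains,
                "loss": self.losses,
            }
        )


# ---------------------------------------------------------------------------
# single-step updates (reference implementations; the batched engine below
# mirrors them exactly)


def _check_finite(*arrays) -> None:
    for a in arrays:
        if not np.all(np.isfinite(a)):
            raise FloatingPointError("non-finite model state or outcome")


def orl_update(
    state: ORLState,
    params: ORLParams,
    chosen: str | int,
    outcome,
    outcome_scale: float = DEFAULT_OUTCOME_SCALE,
) -> ORLState:
    """One ORL trial update given the chosen deck's outcome.

    The learning rate is selected by the sign of the net outcome
    (``A_rew`` for net >= 0, ``A_pun`` otherwise) for both the EV update
    of the chosen deck and the EF updates of all decks.
    """
    j = DECK_INDEX[chosen] if isinstance(chosen, str) else int(chosen)
    net = (outcome.gain - outcome.loss) * outcome_scale
    _check_finite(state.ev, state.ef, state.ps, [net])
    new = state.copy()
    rate = params.a_rew if net >= 0 else params.a_pun
    s = np.sign(net)
    new.ev[j] += rate * (net - new.ev[j])
    for d in range(4):
        target = s if d == j else -s / 3.0
        new.ef[d] += rate * (target - new.ef[d])
    K = params.K
    new.ps /= 1.0 + K
    new.ps[j] = 1.0 / (1.0 + K)
    return new


def _softmax(x: np.ndarray) -> np.ndarray:
    z = np.exp(x - np.max(x, axis=-1, keepdims=True))
    return z / z.sum(axis=-1, keepdims=True)


def orl_choice_probs(state: ORLState, params: ORLParams) -> np.ndarray:
    """Softmax over the integrated value signal, sensitivity fixed at 1."""
    v = state.value_signal(params)
    _check_finite(v)
    return _softmax(v)


def vse_utility(gain: float, loss: float, theta: float) -> float:
    """Prospect-style utility ``gain**theta - loss**theta``.

    ``loss`` is a magnitude; there is no loss-aversion weight.
    """
    if gain < 0 or loss < 0:
        raise ValueError("gain and loss magnitudes must be non-negative")
    return float(gain) ** theta - float(loss) ** theta


def vse_update(
    state: VSEState,
    params: VSEParams,
    chosen: str | int,
    outcome,
    outcome_scale: float = DEFAULT_OUTCOME_SCALE,
) -> VSEState:
    j = DECK_INDEX[chosen] if isinstance(chosen, str) else int(chosen)
    _check_finite(state.exploit, state.explore)
    v = vse_utility(outcome.gain * outcome_scale, outcome.loss * outcome_scale,
                    params.theta)
    new = state.copy()
    new.exploit *= params.delta
    new.exploit[j] += v
    new.explore += params.alpha * (params.phi - new.explore)
    new.explore[j] = 0.0
    return new


def vse_choice_probs(state: VSEState, params: VSEParams) -> np.ndarray:
    w = (state.explore + state.exploit) * params.c
    _check_finite(w)
    return _softmax(w)


# ---------------------------------------------------------------------------
# batched trial engine (vectorized over agents)


def _orl_step_batch(ev, ef, ps, V, p, chosen, net):
    """In-place batched ORL update; p = (a_rew, a_pun, k', b_f, b_p)."""
    B = ev.shape[0]
    rows = np.arange(B)
    rate = np.where(net >= 0, p[:, 0], p[:, 1])
    s = np.sign(net)
    ev[rows, chosen] += rate * (net - ev[rows, chosen])
    target = np.repeat((-s / 3.0)[:, None], 4, axis=1)
    target[rows, chosen] = s
    ef += rate[:, None] * (target - ef)
    K1 = 3.0 ** p[:, 2]  # 1 + K
    ps /= K1[:, None]
    ps[rows, chosen] = 1.0 / K1
    V[:] = ev + ef * p[:, 3:4] + ps * p[:, 4:5]


def _vse_step_batch(exploit, explore, W, p, chosen, gain, loss):
    """In-place batched VSE update; p = (theta, delta, alpha, phi, beta)."""
    B = exploit.shape[0]
    rows = np.arange(B)
    v = gain ** p[:, 0] - loss ** p[:, 0]
    exploit *= p[:, 1:2]
    exploit[rows, chosen] += v
    explore += p[:, 2:3] * (p[:, 3:4] - explore)
    explore[rows, chosen] = 0.0
    c = 3.0 ** p[:, 4] - 1.0
    W[:] = (explore + exploit) * c[:, None]


def simulate_batch(
    model: str,
    params: np.ndarray,
    n_trials: int,
    seed: int,
    loss_policy: str = "shuffled_block",
    outcome_scale: float = DEFAULT_OUTCOME_SCALE,
    agent_offset: int = 0,
    agent_ids: np.ndarray | None = None,
    sched_gains: np.ndarray | None = None,
    sched_losses: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Simulate many agents at once.

    params: (B, 5) on natural scales.  Returns (choices, gains, losses)
    of shape (B, n_trials); gains/losses are raw points.  Agent ``i``'s
    trajectory depends only on ``(seed, its agent id, params[i])``, so
    any chunking of a large batch reproduces identical results.
    """
    model = model.upper()
    if model not in ("ORL", "VSE"):
        raise ValueError(f"unknown model {model!r}")
    params = np.asarray(params, dtype=float)
    B = params.shape[0]
    ids = (np.asarray(agent_ids, dtype=np.int64) if agent_ids is not None
           else agent_offset + np.arange(B))
    if sched_gains is None:
        sched_gains, sched_losses = batch_schedules(
            B, n_trials, seed, loss_policy, agent_offset, agent_ids
        )
    cursors = np.zeros((B, 4), dtype=int)
    rows = np.arange(B)

    state1 = np.zeros((B, 4))
    state2 = np.zeros((B, 4))
    state3 = np.zeros((B, 4))
    W = np.zeros((B, 4))  # softmax input

    choices = np.zeros((B, n_trials), dtype=np.int8)
    gains = np.zeros((B, n_trials))
    losses = np.zeros((B, n_trials))

    for t in range(n_trials):
        probs = _softmax(W)
        u = u01(seed ^ 0x5EED, ids, np.full(B, t))
        cum = np.cumsum(probs, axis=1)
        chosen = (u[:, None] > cum).sum(axis=1).clip(0, 3)
        g = sched_gains[rows, chosen, cursors[rows, chosen]]
        l = sched_losses[rows, chosen, cursors[rows, chosen]]
        cursors[rows, chosen] += 1
        choices[:, t] = chosen
        gains[:, t] = g
        losses[:, t] = l
        if model == "ORL":
            net = (g - l) * outcome_scale
            _orl_step_batch(state1, state2, state3, W, params, chosen, net)
        else:
            _vse_step_batch(state1, state2, W, params, chosen,
                            g * outcome_scale, l * outcome_scale)
    return choices, gains, losses


def simulate_agent(
    model: str,
    params,
    schedule: TaskSchedule,
    seed: int = 0,
    outcome_scale: float = DEFAULT_OUTCOME_SCALE,
    subject_id: str = "sim",
) -> TrialSequence:
    """Simulate a single subject on an explicit :class:`TaskSchedule`.

    State starts at zero, so first-trial probabilities are uniform.
    Deterministic given (model, params, schedule, seed).
    """
    p = params.as_array() if hasattr(params, "as_array") else np.asarray(params)
    model = model.upper()
    if model not in ("ORL", "VSE"):
        raise ValueError(f"unknown model {model!r}")
    sched = schedule.copy()
    n = sched.n_trials
    orl = model == "ORL"
    state = ORLState() if orl else VSEState()
    pobj = ORLParams(*p) if orl else VSEParams(*p)
    choices = np.zeros(n, dtype=int)
    gains = np.zeros(n)
    losses = np.zeros(n)
    for t in range(n):
        probs = (
            orl_choice_probs(state, pobj) if orl else vse_choice_probs(state, pobj)
        )
        u = float(u01(seed ^ 0x5EED, np.array([0]), np.array([t]))[0])
        chosen = int(np.searchsorted(np.cumsum(probs), u, side="right").clip(0, 3))
        out = draw(sched, DECKS[chosen])
        choices[t] = chosen
        gains[t] = out.gain
        losses[t] = out.loss
        if orl:
            state = orl_update(state, pobj, chosen, out, outcome_scale)
        else:
            state = vse_update(state, pobj, chosen, out, outcome_scale)
    return TrialSequence(choices, gains, losses, subject_id)


# ---------------------------------------------------------------------------
# likelihood


def log_likelihood(
    model: str,
    params,
    data: TrialSequence,
    outcome_scale: float = DEFAULT_OUTCOME_SCALE,
    pointwise: bool = False,
):
    """Teacher-forced log-likelihood of a subject's observed choices.

    State is evolved with the observed choices and outcomes; trial ``t``'s
    probability uses the state after trial ``t-1``'s update.  Returns the
    total log-likelihood, or the per-trial vector when ``pointwise``.
    """
    from ._core import pointwise_loglik

    p = params.as_array() if hasattr(params, "as_array") else np.asarray(params)
    ll = pointwise_loglik(
        model.upper(),
        p[None, :],
        data.choices[None, :].astype(np.int64),
        (data.gains * outcome_scale)[None, :],
        (data.losses * outcome_scale)[None, :],
    )[0]
    return ll if pointwise else float(ll.sum())
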
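"""The 27 -> 100 ReLU -> 1 sigmoid categorisation network.

A single-hidden-layer MLP maps a stimulus image plus a 2-unit task signal to
an accept probability f(x, theta) through a sigmoidal output unit.  Training
minimises the reward loss J(theta) = -f(x, theta) * R by online stochastic
gradient descent (one trial per update), which pushes the network to accept
rewarding (R > 0) and reject punished (R < 0) stimuli.

The last two columns of the input-to-hidden weight matrix connect the task
units to the hidden layer ("task weights"); they are the substrate of the
context-gating analyses and of the Hebbian update in
:mod:`hebbgate.learning_motifs`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit

from .task_environment import N_INPUTS, N_PIXELS, Trial, network_input, one_hot_signal

VARIANTS = ("vanilla", "manual_gating", "hebbian", "sluggish", "sluggish_hebbian")


@dataclass
class NetworkParams:
    """All weights and biases of the network.

    ``W_in`` has shape (n_hidden, 27); its last two columns are the task
    weights, addressable as a view via :attr:`task_weights`.
    """

    W_in: np.ndarray
    b_hidden: np.ndarray
    w_out: np.ndarray
    b_out: float

    @property
    def n_hidden(self) -> int:
        return self.W_in.shape[0]

    @property
    def task_weights(self) -> np.ndarray:
        """(n_hidden, 2) view onto the task-unit columns of W_in."""
        return self.W_in[:, N_PIXELS:]

    def copy(self) -> "NetworkParams":
        return NetworkParams(self.W_in.copy(), self.b_hidden.copy(),
                             self.w_out.copy(), float(self.b_out))


@dataclass(frozen=True)
class ForwardTrace:
    """Intermediate quantities of one forward pass."""

    pre: np.ndarray       # hidden pre-activations y_j
    post: np.ndarray      # ReLU outputs
    logit: float
    p_accept: float


@dataclass
class TrainConfig:
    """Hyperparameters of one training run.

    epsilon            SGD learning rate (full-scale default 0.2, interleaved).
    eta                Hebbian (Oja) learning rate; 0 disables the Hebbian step.
    alpha              sluggishness of the task signal, EMA carry-over in [0,1).
    variant            vanilla | manual_gating | hebbian | sluggish | sluggish_hebbian.
    centring_scheme    'second_task_only' uses a one-hot cue for task 1 and a
                       mean-centred cue for task 2 during Hebbian training;
                       'symmetric' mean-centres both tasks' cues.
    init_scale_hidden  std of the input->hidden weight initialisation.
    eval_every         evaluate on the 50-condition test grid every k trials.
    """

    epsilon: float = 0.2
    eta: float = 0.0
    alpha: float = 0.0
    n_per_task: int = 5000
    curriculum: str = "interleaved"
    variant: str = "vanilla"
    seed: int = 0
    init_scale_hidden: float = 0.1
    n_hidden: int = 100
    sigma: float = 1.0
    centring_scheme: str = "second_task_only"
    eval_every: int = 100

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        if self.eta < 0:
            raise ValueError("eta must be >= 0")
        if not 0.0 <= self.alpha < 1.0:
            raise ValueError("alpha must be in [0, 1)")
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        if self.centring_scheme not in ("second_task_only", "symmetric"):
            raise ValueError("centring_scheme must be 'second_task_only' or 'symmetric'")


def init_network(config: TrainConfig,
                 rng: np.random.Generator | None = None) -> NetworkParams:
    """Draw initial parameters.

    Input-to-hidden weights are zero-mean Gaussian with the configured std
    (default 0.1, i.e. variance 0.01 — the small-weight "rich" regime);
    readout weights are zero-mean Gaussian with variance 1/n_hidden; all
    biases start at zero.  Deterministic given the config seed.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    h = config.n_hidden
    W_in = rng.normal(0.0, config.init_scale_hidden, size=(h, N_INPUTS))
    w_out = rng.normal(0.0, 1.0 / np.sqrt(h), size=h)
    return NetworkParams(W_in=W_in, b_hidden=np.zeros(h), w_out=w_out, b_out=0.0)


def forward(params: NetworkParams, x: np.ndarray) -> ForwardTrace:
    """One forward pass; returns pre/post activations and accept probability."""
    x = np.asarray(x, dtype=float)
    if x.shape != (params.W_in.shape[1],):
        raise ValueError(f"input must have shape ({params.W_in.shape[1]},), got {x.shape}")
    pre = params.W_in @ x + params.b_hidden
    post = np.maximum(pre, 0.0)
    logit = float(params.w_out @ post + params.b_out)
    return ForwardTrace(pre=pre, post=post, logit=logit, p_accept=float(expit(logit)))


def forward_batch(params: NetworkParams, X: np.ndarray) -> dict[str, np.ndarray]:
    """Vectorised forward pass over rows of X (n, n_inputs)."""
    pre = X @ params.W_in.T + params.b_hidden
    post = np.maximum(pre, 0.0)
    logits = post @ params.w_out + params.b_out
    return {"pre": pre, "post": post, "logit": logits, "p_accept": expit(logits)}


def loss_gradients(params: NetworkParams, x: np.ndarray, reward: float,
                   trace: ForwardTrace | None = None):
    """Backpropagated gradients of J = -f(x, theta) * R.

    Returns (dW_in, db_hidden, dw_out, db_out).  dJ/dlogit = -R p (1-p);
    the ReLU passes gradient only where the pre-activation is positive.
    """
    if trace is None:
        trace = forward(params, x)
    p = trace.p_accept
    dlogit = -reward * p * (1.0 - p)
    dw_out = dlogit * trace.post
    db_out = dlogit
    dpre = dlogit * params.w_out * (trace.pre > 0.0)
    dW_in = np.outer(dpre, x)
    db_hidden = dpre
    return dW_in, db_hidden, dw_out, db_out


def sgd_step(params: NetworkParams, trial: Trial, x: np.ndarray, epsilon: float,
             trace: ForwardTrace | None = None,
             freeze_task_weights: bool = False) -> NetworkParams:
    """One online SGD update on the reward loss; mutates and returns params.

    With ``freeze_task_weights`` the task-unit columns of W_in are left
    untouched (used by the manual-gating variant, whose gating pattern is
    fixed by hand).
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    dW_in, db_hidden, dw_out, db_out = loss_gradients(params, x, trial.reward, trace)
    if freeze_task_weights:
        dW_in[:, N_PIXELS:] = 0.0
    params.W_in -= epsilon * dW_in
    params.b_hidden -= epsilon * db_hidden
    params.w_out -= epsilon * dw_out
    params.b_out -= epsilon * db_out
    return params


def decisions_correct(p_accept: np.ndarray, rewards: np.ndarray) -> np.ndarray:
    """Elementwise correctness of decoded decisions.

    Accept is decoded as p > 0.5, reject as p < 0.5; a tie at exactly 0.5
    carries no decision and counts as incorrect.  Only meaningful for
    non-boundary trials (R != 0).
    """
    p = np.asarray(p_accept, dtype=float)
    r = np.asarray(rewards, dtype=float)
    return ((p > 0.5) & (r > 0)) | ((p < 0.5) & (r < 0))


def accuracy(params: NetworkParams, trials: list[Trial],
             task_signal_policy=None, sigma: float = 1.0) -> float:
    """Mean decision accuracy over the non-boundary trials in ``trials``.

    Boundary trials (reward 0) are excluded: their decisions are arbitrary.
    ``task_signal_policy`` maps a trial to its 2-entry task signal
    (default: veridical one-hot cue).
    """
    if task_signal_policy is None:
        task_signal_policy = lambda t: one_hot_signal(t.task)
    scored = [t for t in trials if t.reward != 0]
    if not scored:
        raise ValueError("accuracy is undefined on an all-boundary trial set")
    X = np.stack([network_input(t, task_signal_policy(t), sigma=sigma) for t in scored])
    p = forward_batch(params, X)["p_accept"]
    rewards = np.array([t.reward for t in scored], dtype=float)
    return float(np.mean(decisions_correct(p, rewards)))
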
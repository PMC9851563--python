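"""The two algorithmic motifs: sluggish (EMA) task signals and Oja-rule gating.

Sluggishness models the carry-over of contextual information from previous
trials: the task signal fed to the network is an exponentially moving average
of the raw cues, with carry-over weight alpha.  Under interleaved curricula
consecutive trials often belong to different tasks, so a sluggish cue is a
mixture of both contexts and creates a switch cost; under blocked curricula
the cue is constant within a block and the EMA converges to the veridical cue.

The Hebbian motif alternates each supervised SGD update with an Oja-rule step
restricted to the task-weight block (the 2 columns of W_in that connect the
task units to the hidden layer).  Oja's rule,

    dw_j = eta * y_j * (x - w_j * y_j),

drives each unit's task weights towards the leading principal component of
the (mean-centred) task signal, i.e. the contrast between the two contexts,
so per-unit task weights with opposing signs emerge.  Passed through the
ReLU, these anti-correlated weights gate disjoint subsets of hidden units on
per context, protecting the first task's subnetwork from being overwritten
while the second is learned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from . import task_environment as te
from .network_core import (ForwardTrace, NetworkParams, TrainConfig, forward_batch,
                           decisions_correct, init_network)
from .task_environment import N_PIXELS, Trial, make_curriculum, one_hot_signal


@dataclass
class EMAState:
    """State of the exponentially-moving-average task signal.

    On the first trial the smoothed signal equals the raw signal; afterwards
    smoothed <- (1 - alpha) * x_t + alpha * smoothed_prev.  Entries always
    stay inside the convex hull of the observed raw signals.
    """

    alpha: float
    smoothed: np.ndarray | None = None
    t: int = 0


def ema_update(state: EMAState, x_t: np.ndarray) -> EMAState:
    if not 0.0 <= state.alpha < 1.0:
        raise ValueError("alpha must be in [0, 1)")
    x_t = np.asarray(x_t, dtype=float)
    if state.t == 0 or state.smoothed is None:
        smoothed = x_t.copy()
    else:
        smoothed = (1.0 - state.alpha) * x_t + state.alpha * state.smoothed
    return EMAState(alpha=state.alpha, smoothed=smoothed, t=state.t + 1)


def apply_manual_gating(params: NetworkParams) -> NetworkParams:
    """Hand-craft the anti-correlated gating pattern on the task weights.

    Hidden units 1, 3, 5, ... (1-based) get task weights [+1, -1], units
    2, 4, 6, ... get [-1, +1], so each unit receives an additive bias of
    opposite sign in the two contexts.  The caller is expected to freeze this
    block during subsequent SGD (train() does so for the manual variant).
    """
    tw = params.task_weights
    tw[0::2, 0], tw[0::2, 1] = 1.0, -1.0   # 0-based even rows = 1-based odd units
    tw[1::2, 0], tw[1::2, 1] = -1.0, 1.0
    return params


def oja_step(task_weights: np.ndarray, task_signal: np.ndarray,
             pre: np.ndarray, eta: float) -> np.ndarray:
    """In-place Oja update of the task-weight block.

    Per hidden unit j:  w_j <- w_j + eta * y_j * (x - w_j * y_j), with y_j the
    unit's full pre-activation (image plus task contribution) and x the
    2-entry task signal of the current trial.  Only the task-weight block is
    touched.
    """
    if eta < 0:
        raise ValueError("eta must be >= 0")
    if eta == 0.0:
        return task_weights
    y = np.asarray(pre, dtype=float)
    x = np.asarray(task_signal, dtype=float)
    task_weights += eta * (np.outer(y, x) - (y * y)[:, None] * task_weights)
    return task_weights


def raw_task_signal(task: int, variant: str, centring_scheme: str = "second_task_only") -> np.ndarray:
    """Pre-EMA task signal for a trial of the given task under a variant.

    Non-Hebbian variants use the veridical one-hot cue.  Hebbian variants use
    a leakage-avoiding mean-centring scheme: a one-hot cue [1, 0] while
    training the first task, and for the second task the mean-centred task
    contrast [-1, 1] ("do task 2 while suppressing task 1"), so no
    information about the yet-unseen task leaks into the first block.  The
    'symmetric' scheme uses the contrast code for both tasks ([1, -1] and
    [-1, 1]).  Both codes sum to zero, the property Oja's rule needs.
    """
    if variant in ("hebbian", "sluggish_hebbian"):
        if centring_scheme == "symmetric":
            return np.array([1.0, -1.0]) if task == 1 else np.array([-1.0, 1.0])
        return np.array([1.0, 0.0]) if task == 1 else np.array([-1.0, 1.0])
    return one_hot_signal(task)


def task_signal_for_trial(trial: Trial, variant: str, ema_state: EMAState,
                          centring_scheme: str = "second_task_only"
                          ) -> tuple[np.ndarray, EMAState]:
    """Task signal fed to the network on this trial, plus updated EMA state.

    Sluggish variants smooth the raw signal with the EMA; for alpha = 0 the
    EMA is the identity and every variant reduces to its non-sluggish twin.
    """
    raw = raw_task_signal(trial.task, variant, centring_scheme)
    if variant in ("sluggish", "sluggish_hebbian"):
        ema_state = ema_update(ema_state, raw)
        return ema_state.smoothed, ema_state
    return raw, ema_state


@dataclass
class RunRecord:
    """Everything recorded from one seeded training run.

    curve               (n_evals, 2) per-task test accuracy at each snapshot.
    eval_steps          trial indices of the snapshots (1-based, monotone).
    taskweight_corr     Pearson r between the two task-weight columns.
    test_traces         batch forward pass of the final network on the
                        canonical 50-condition grid with veridical cues:
                        keys 'pre', 'post' (50, n_hidden), 'logit',
                        'p_accept' (50,).
    """

    config: TrainConfig
    eval_steps: np.ndarray
    curve: np.ndarray
    taskweight_corr: np.ndarray
    final_params: NetworkParams
    test_traces: dict[str, np.ndarray]


class DivergenceError(RuntimeError):
    pass


def _taskweight_corr(task_weights: np.ndarray) -> float:
    a, b = task_weights[:, 0], task_weights[:, 1]
    sa, sb = a.std(), b.std()
    if sa == 0.0 or sb == 0.0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def evaluate(params: NetworkParams, sigma: float = 1.0
             ) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Per-task accuracy on the 50-condition grid with veridical cues.

    Returns ((acc_task1, acc_task2), traces).  Boundary conditions are
    excluded from accuracy; ties at p = 0.5 count as incorrect.
    """
    X = te.test_inputs(sigma=sigma)
    traces = forward_batch(params, X)
    rewards = te.test_rewards()
    correct = decisions_correct(traces["p_accept"], rewards)
    accs = np.empty(2)
    for k in range(2):
        sl = slice(25 * k, 25 * (k + 1))
        scored = rewards[sl] != 0
        accs[k] = correct[sl][scored].mean()
    return accs, traces


def train(config: TrainConfig) -> RunRecord:
    """Run one seeded training run and record its learning trajectory.

    Per trial: (1) compute the (possibly sluggish) task signal, (2) forward
    pass, (3) online SGD step on J = -f R, (4) for Hebbian variants, an Oja
    step on the task-weight block.  Every ``eval_every`` trials the network is
    evaluated on the full 50-condition grid with veridical cues.
    """
    ss = np.random.SeedSequence(config.seed)
    ss_init, ss_curr = ss.spawn(2)
    params = init_network(config, rng=np.random.default_rng(ss_init))
    curriculum = make_curriculum(config.curriculum, config.n_per_task,
                                 seed=int(ss_curr.generate_state(1)[0] % (2**31)))

    manual = config.variant == "manual_gating"
    hebbian = config.variant in ("hebbian", "sluggish_hebbian")
    if manual:
        apply_manual_gating(params)

    W_in, b_h, w_out = params.W_in, params.b_hidden, params.w_out
    b_out = params.b_out
    eps, eta = config.epsilon, config.eta
    ema = EMAState(alpha=config.alpha)

    # pre-rendered blob pixels per feature combination
    pix = {(x, y): te._blob_pixels(x, y, float(config.sigma))
           for x in te.LEVELS for y in te.LEVELS}

    x_vec = np.empty(te.N_INPUTS)
    eval_steps, curve, tw_corr = [], [], []

    for i, trial in enumerate(curriculum.trials, start=1):
        signal, ema = task_signal_for_trial(trial, config.variant, ema,
                                            config.centring_scheme)
        x_vec[:N_PIXELS] = pix[(trial.x, trial.y)]
        x_vec[N_PIXELS:] = signal

        pre = W_in @ x_vec + b_h
        post = np.maximum(pre, 0.0)
        logit = w_out @ post + b_out
        p = expit(logit)

        # backprop on J = -f R
        dlogit = -trial.reward * p * (1.0 - p)
        dpre = dlogit * w_out * (pre > 0.0)
        if manual:
            dpre_in = dpre[:, None] * x_vec[None, :N_PIXELS]
            W_in[:, :N_PIXELS] -= eps * dpre_in
        else:
            W_in -= eps * np.outer(dpre, x_vec)
        b_h -= eps * dpre
        w_out -= eps * dlogit * post
        b_out -= eps * dlogit

        if hebbian and eta > 0.0:
            tw = W_in[:, N_PIXELS:]
            tw += eta * (np.outer(pre, signal) - (pre * pre)[:, None] * tw)

        if i % config.eval_every == 0 or i == len(curriculum.trials):
            if not np.isfinite(logit):
                raise DivergenceError(
                    f"non-finite network output at trial {i} "
                    f"(variant={config.variant}, eps={eps}, eta={eta})")
            params.b_out = float(b_out)
            accs, _ = evaluate(params, sigma=config.sigma)
            eval_steps.append(i)
            curve.append(accs)
            tw_corr.append(_taskweight_corr(W_in[:, N_PIXELS:]))

    params.b_out = float(b_out)
    _, traces = evaluate(params, sigma=config.sigma)
    return RunRecord(config=config,
                     eval_steps=np.asarray(eval_steps),
                     curve=np.asarray(curve),
                     taskweight_corr=np.asarray(tw_corr),
                     final_params=params,
                     test_traces=traces)
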
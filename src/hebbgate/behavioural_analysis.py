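"""Choice-level analyses: choice matrices, congruency, psychometric fits.

All analyses operate on a *choice matrix*: a (2, 5, 5) array of accept
probabilities indexed [task, x, y] over the canonical 50-condition test grid
(x and y levels in ascending order -2..2).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit, minimize
from scipy.spatial.distance import pdist, squareform
from scipy.special import expit

from . import task_environment as te
from .network_core import decisions_correct
from .learning_motifs import RunRecord

_LEVELS = np.array(te.LEVELS, dtype=float)


@dataclass(frozen=True)
class SigmoidFit:
    """Lapse-bounded logistic psychometric fit: L + (1-2L) / (1+exp(-k(x-x0)))."""

    lapse: float
    slope: float
    offset: float
    degenerate: bool = False


@dataclass(frozen=True)
class PsychophysicalFit:
    """Five-parameter boundary model fit.

    theta_a / theta_b are the orientations (degrees) of the normals to the
    fitted category boundaries of the two tasks; the ground-truth normals are
    0 deg (task 1, x-rule) and 90 deg (task 2, y-rule).  angular_bias is the
    mean absolute deviation of the fitted angles from those normals, folded
    to [0, 90] deg (an angle and its 180-deg flip describe the same boundary).
    """

    theta_a: float
    theta_b: float
    lapse: float
    slope: float
    offset: float
    loss: float
    angular_bias: float
    deviation_a: float
    deviation_b: float


@dataclass(frozen=True)
class ChoiceModelBetas:
    """Regression weights of the factorised and linear (diagonal) choice models."""

    beta_factorised: float
    beta_linear: float
    intercept: float


# ---------------------------------------------------------------------------
# choice matrices

def choice_matrix(run: RunRecord) -> np.ndarray:
    """(2, 5, 5) accept probabilities of a trained run on the test grid."""
    p = np.asarray(run.test_traces["p_accept"], dtype=float)
    return p.reshape(2, 5, 5)


def flatten_choice_matrix(cm: np.ndarray) -> np.ndarray:
    """Concatenate the two 5x5 task matrices into the canonical 50-vector."""
    cm = np.asarray(cm, dtype=float)
    if cm.shape != (2, 5, 5):
        raise ValueError("choice matrix must have shape (2, 5, 5)")
    return cm.reshape(50)


def _grid_rewards() -> np.ndarray:
    return te.test_rewards().reshape(2, 5, 5)


def choice_accuracy(cm: np.ndarray, mask: np.ndarray | None = None) -> float:
    """Decision accuracy of a choice matrix over non-boundary conditions.

    ``mask`` optionally restricts scoring to a boolean (2,5,5) subset;
    boundary conditions are always excluded.
    """
    r = _grid_rewards()
    scored = r != 0
    if mask is not None:
        scored = scored & mask
    if not scored.any():
        raise ValueError("no non-boundary conditions selected")
    return float(np.mean(decisions_correct(cm[scored], r[scored])))


def _congruency_masks() -> tuple[np.ndarray, np.ndarray]:
    gx, gy = np.meshgrid(_LEVELS, _LEVELS, indexing="ij")
    con = (np.sign(gx) == np.sign(gy)) & (gx != 0) & (gy != 0)
    inc = (np.sign(gx) != np.sign(gy)) & (gx != 0) & (gy != 0)
    return (np.broadcast_to(con, (2, 5, 5)).copy(),
            np.broadcast_to(inc, (2, 5, 5)).copy())


def congruency_effect(cm: np.ndarray) -> tuple[float, float, float]:
    """(accuracy on congruent, on incongruent, difference congruent - incongruent)."""
    con, inc = _congruency_masks()
    acc_c = choice_accuracy(cm, con)
    acc_i = choice_accuracy(cm, inc)
    return acc_c, acc_i, acc_c - acc_i


# ---------------------------------------------------------------------------
# sigmoid (psychometric) fits

def lapse_logistic(x: np.ndarray, L: float, k: float, x0: float) -> np.ndarray:
    return L + (1.0 - 2.0 * L) * expit(k * (x - x0))


def dimension_bin_means(cm: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Accept fractions binned along the relevant / irrelevant dimension.

    Averages across tasks and across the other dimension: the relevant
    dimension of task 1 is x and of task 2 is y (and vice versa for the
    irrelevant dimension).
    """
    cm = np.asarray(cm, dtype=float)
    rel = 0.5 * (cm[0].mean(axis=1) + cm[1].mean(axis=0))
    irrel = 0.5 * (cm[0].mean(axis=0) + cm[1].mean(axis=1))
    return rel, irrel


def fit_sigmoid(bin_means: np.ndarray, levels: np.ndarray = _LEVELS) -> SigmoidFit:
    """Least-squares lapse-logistic fit to five bin means.

    A (near-)constant input cannot constrain the slope; it is returned as a
    flat fit (slope ~ 0) with the ``degenerate`` flag set.
    """
    y = np.asarray(bin_means, dtype=float)
    x = np.asarray(levels, dtype=float)
    if np.any((y < 0) | (y > 1)):
        raise ValueError("bin means must lie in [0, 1]")
    if np.ptp(y) < 1e-6:
        return SigmoidFit(lapse=min(float(y.mean()), 0.5), slope=0.0,
                          offset=0.0, degenerate=True)
    try:
        popt, _ = curve_fit(
            lapse_logistic, x, y,
            p0=[0.05, 1.0, 0.0],
            bounds=([0.0, 0.0, -5.0], [0.5, 50.0, 5.0]),
            maxfev=10000)
    except RuntimeError:
        return SigmoidFit(lapse=min(float(y.mean()), 0.5), slope=0.0,
                          offset=0.0, degenerate=True)
    return SigmoidFit(lapse=float(popt[0]), slope=float(popt[1]),
                      offset=float(popt[2]))


def fit_dimension_sigmoids(cm: np.ndarray) -> tuple[SigmoidFit, SigmoidFit]:
    """Separate sigmoid fits along the relevant and irrelevant dimensions."""
    rel, irrel = dimension_bin_means(cm)
    return fit_sigmoid(rel), fit_sigmoid(irrel)


# ---------------------------------------------------------------------------
# factorised / linear choice-model RDM regression

def model_choice_matrices() -> tuple[np.ndarray, np.ndarray]:
    """The factorised and linear (diagonal) model choice matrices.

    Factorised: accept probability 1 for rewarding, 0 for punished and 0.5
    for boundary conditions of each task's own rule.  Linear: the same coding
    applied to the single diagonal rule x + y, identical across tasks.
    """
    gx, gy = np.meshgrid(_LEVELS, _LEVELS, indexing="ij")
    fact = np.stack([0.5 * (np.sign(gx) + 1.0), 0.5 * (np.sign(gy) + 1.0)])
    diag = np.broadcast_to(0.5 * (np.sign(gx + gy) + 1.0), (2, 5, 5)).copy()
    return fact, diag


def choice_rdm(cm: np.ndarray) -> np.ndarray:
    """50x50 RDM of pairwise absolute accept-probability differences."""
    v = flatten_choice_matrix(cm)
    return squareform(pdist(v[:, None], metric="cityblock"))


def _z(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    if sd == 0:
        return v - v.mean()
    return (v - v.mean()) / sd


def lower_triangle(rdm: np.ndarray) -> np.ndarray:
    """Vectorised strict lower triangle of a square matrix."""
    rdm = np.asarray(rdm, dtype=float)
    i, j = np.tril_indices(rdm.shape[0], k=-1)
    return rdm[i, j]


def choice_model_rdm_regression(cm: np.ndarray) -> ChoiceModelBetas:
    """Regress the empirical choice RDM on the factorised and linear model RDMs.

    Lower triangles are z-scored before a joint OLS with intercept, so the
    two betas are comparable across runs.
    """
    fact, diag = model_choice_matrices()
    y = _z(lower_triangle(choice_rdm(cm)))
    Xf = _z(lower_triangle(choice_rdm(fact)))
    Xl = _z(lower_triangle(choice_rdm(diag)))
    X = np.column_stack([np.ones_like(y), Xf, Xl])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return ChoiceModelBetas(beta_factorised=float(beta[1]),
                            beta_linear=float(beta[2]),
                            intercept=float(beta[0]))


# ---------------------------------------------------------------------------
# decision-noise choice sampling

def sample_choices(logits: np.ndarray, temperature: float, n: int,
                   seed: int = 0) -> np.ndarray:
    """Fraction of accept choices from n Bernoulli draws per condition.

    Decision noise is modelled by a temperature on the logit:
    p = logistic(logit / T).  Returns a (2, 5, 5) choice matrix.
    """
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    if n < 1:
        raise ValueError("n must be >= 1")
    logits = np.asarray(logits, dtype=float).reshape(50)
    p = expit(logits / temperature)
    rng = np.random.default_rng(seed)
    counts = rng.binomial(n, p)
    return (counts / n).reshape(2, 5, 5)


# ---------------------------------------------------------------------------
# five-parameter psychophysical boundary model

_COORDS = np.array(list(itertools.product(_LEVELS, _LEVELS)), dtype=float)  # (25,2), x-major

#: ground-truth boundary-normal angles (degrees) for the two tasks
TRUE_NORMALS = (0.0, 90.0)


def psychophysical_predictions(theta_a: float, theta_b: float, L: float,
                               k: float, x0: float) -> np.ndarray:
    """Model accept probabilities for the 50 conditions.

    Stimulus coordinates are projected onto the boundary normal of each task
    (angles in degrees) and passed through the lapse-logistic transducer.
    """
    ta, tb = np.deg2rad(theta_a), np.deg2rad(theta_b)
    proj = np.concatenate([
        _COORDS @ np.array([np.cos(ta), np.sin(ta)]),
        _COORDS @ np.array([np.cos(tb), np.sin(tb)]),
    ])
    return lapse_logistic(proj, L, k, x0)


def _psycho_loss(params: np.ndarray, y: np.ndarray, clip: float) -> float:
    yhat = psychophysical_predictions(*params)
    yhat = np.clip(yhat, clip, 1.0 - clip)
    return float(-np.sum(np.log(1.0 - np.abs(y - yhat))))


def fold_angle(theta: float, truth: float) -> float:
    """Absolute angular deviation folded to [0, 90] degrees.

    A boundary normal is a line orientation: theta and theta + 180 are
    equivalent up to a slope sign flip, so deviations are taken mod 180 and
    reflected into [0, 90].
    """
    d = abs(theta - truth) % 180.0
    return min(d, 180.0 - d)


def fit_psychophysical(cm: np.ndarray, n_starts: int = 8,
                       clip: float = 1e-6) -> PsychophysicalFit:
    """Fit the 5-parameter boundary model to a choice matrix.

    The loss J = -sum log(1 - |y - yhat|) is multimodal in the boundary
    angles, so a bound-constrained quasi-Newton (L-BFGS-B) optimisation is
    restarted from the best candidates of a coarse angle grid.  Bounds:
    theta in [0, 359] deg, L in [0, 0.5], k in [0, 20], x0 in [-1, 1].
    """
    y = flatten_choice_matrix(cm)
    bounds = [(0.0, 359.0), (0.0, 359.0), (0.0, 0.5), (0.0, 20.0), (-1.0, 1.0)]

    angles = np.arange(0.0, 359.0, 45.0)
    cand = [(a, b) for a in angles for b in angles]
    losses = [_psycho_loss(np.array([a, b, 0.02, 2.0, 0.0]), y, clip)
              for a, b in cand]
    starts = [cand[i] for i in np.argsort(losses)[:n_starts]]

    best = None
    for a0, b0 in starts:
        res = minimize(_psycho_loss, x0=np.array([a0, b0, 0.02, 2.0, 0.0]),
                       args=(y, clip), method="L-BFGS-B", bounds=bounds,
                       options={"maxiter": 500, "ftol": 1e-10, "gtol": 1e-8})
        if best is None or res.fun < best.fun:
            best = res
    ta, tb, L, k, x0 = best.x
    dev_a = fold_angle(ta, TRUE_NORMALS[0])
    dev_b = fold_angle(tb, TRUE_NORMALS[1])
    return PsychophysicalFit(theta_a=float(ta), theta_b=float(tb),
                             lapse=float(L), slope=float(k), offset=float(x0),
                             loss=float(best.fun),
                             angular_bias=0.5 * (dev_a + dev_b),
                             deviation_a=dev_a, deviation_b=dev_b)


# ---------------------------------------------------------------------------
# grid-search behavioural fit

def grid_search_behaviour_fit(target: np.ndarray, alpha_grid, T_grid, config,
                              n_choices: int = 10000,
                              seed: int = 0) -> tuple[float, float, "np.ndarray"]:
    """Fit the sluggishness and decision temperature of a sluggish-Hebbian agent.

    For each alpha a sluggish-Hebbian run is trained (one per alpha, cached
    within the call); for each temperature, choices are sampled from its test
    logits and compared to the target choice matrix by mean squared error.
    Returns (alpha*, T*, discrepancy grid of shape (n_alpha, n_T)).
    """
    from dataclasses import replace
    from .learning_motifs import train

    alpha_grid = list(alpha_grid)
    T_grid = list(T_grid)
    if not alpha_grid or not T_grid:
        raise ValueError("grids must be non-empty")
    target = np.asarray(target, dtype=float)
    disc = np.empty((len(alpha_grid), len(T_grid)))
    for i, a in enumerate(alpha_grid):
        run = train(replace(config, alpha=float(a)))
        logits = run.test_traces["logit"]
        for j, T in enumerate(T_grid):
            cm = sample_choices(logits, T, n_choices, seed=seed + 7919 * j + i)
            disc[i, j] = np.mean((cm - target) ** 2)
    i, j = np.unravel_index(np.argmin(disc), disc.shape)
    return float(alpha_grid[i]), float(T_grid[j]), disc
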
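"""Stimuli, trials and curricula for the context-dependent blob categorisation task.

The environment consists of two binary accept/reject categorisation tasks
defined over a common 5x5 grid of stimuli.  Stimuli are grayscale images of
isotropic two-dimensional Gaussian "blobs" whose peak position varies in five
discrete steps along the x- and y-axis, coded as feature levels
{-2, -1, 0, 1, 2}.  In task 1 only the x-position is relevant and determines
the signed reward for accepting the stimulus; in task 2 only the y-position
matters.  Level 0 is the category boundary (reward 0, decision arbitrary).

Networks receive the flattened 25-pixel image concatenated with a 2-unit task
signal (one-hot by default), giving a 27-dimensional input.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
import yaml

#: Admissible feature levels along each stimulus dimension; 0 is the boundary.
LEVELS: tuple[int, ...] = (-2, -1, 0, 1, 2)

N_PIXELS = 25
N_TASK_UNITS = 2
N_INPUTS = N_PIXELS + N_TASK_UNITS

#: Congruency labels.
CONGRUENT = "congruent"
INCONGRUENT = "incongruent"
BOUNDARY = "boundary"


@dataclass(frozen=True)
class StimulusImage:
    """A rendered Gaussian-blob stimulus on the 5x5 pixel lattice."""

    pixels: np.ndarray  # shape (25,), flattened row-major (x-major)
    peak_x: int
    peak_y: int


@dataclass(frozen=True)
class Trial:
    """One task/stimulus event.

    ``reward`` equals the feature level of the task-relevant dimension
    (x for task 1, y for task 2), ranging over -2..2.
    """

    task: int  # 1 or 2
    x: int
    y: int
    reward: int
    congruent: str  # CONGRUENT | INCONGRUENT | BOUNDARY


@dataclass
class Curriculum:
    """An ordered sequence of training trials.

    blocked:     all task-1 trials precede all task-2 trials.
    interleaved: a seeded uniform shuffle of the union of both tasks' trials.
    Within each task, the 25 feature combinations are cycled in seeded
    shuffled order so that coverage is as even as possible at any n.
    """

    trials: list[Trial]
    kind: str
    n_per_task: int
    seed: int = 0


def _check_level(v: int, name: str) -> None:
    if v not in LEVELS:
        raise ValueError(f"{name} must be one of {LEVELS}, got {v!r}")


@lru_cache(maxsize=256)
def _blob_pixels(peak_x: int, peak_y: int, sigma: float) -> np.ndarray:
    gx, gy = np.meshgrid(LEVELS, LEVELS, indexing="ij")
    img = np.exp(-((gx - peak_x) ** 2 + (gy - peak_y) ** 2) / (2.0 * sigma**2))
    img = img / img.max()  # peak amplitude 1 at the peak cell
    img.flags.writeable = False
    return img.reshape(-1)


def render_blob(peak_x: int, peak_y: int, sigma: float = 1.0) -> StimulusImage:
    """Render an isotropic Gaussian blob centred on (peak_x, peak_y).

    The Gaussian is evaluated directly on the 5x5 feature lattice and
    normalised to unit amplitude at the peak cell.  With the default
    sigma = 1 lattice unit, blobs at adjacent grid positions partially
    overlap, so the input code carries metric information about the
    two-dimensional stimulus space (unlike a one-hot code).
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    _check_level(peak_x, "peak_x")
    _check_level(peak_y, "peak_y")
    return StimulusImage(_blob_pixels(peak_x, peak_y, float(sigma)), peak_x, peak_y)


def congruency(x: int, y: int) -> str:
    """Label a feature combination.

    Congruent trials demand the same response under both task rules
    (sign(x) == sign(y) != 0); trials with a level-0 coordinate sit on a
    category boundary and are excluded from congruency contrasts.
    """
    if x == 0 or y == 0:
        return BOUNDARY
    return CONGRUENT if np.sign(x) == np.sign(y) else INCONGRUENT


def make_trial(task: int, x: int, y: int) -> Trial:
    if task not in (1, 2):
        raise ValueError(f"task must be 1 or 2, got {task!r}")
    _check_level(x, "x")
    _check_level(y, "y")
    reward = x if task == 1 else y
    return Trial(task=task, x=x, y=y, reward=reward, congruent=congruency(x, y))


def _task_block(task: int, n: int, rng: np.random.Generator) -> list[Trial]:
    combos = [(x, y) for x in LEVELS for y in LEVELS]
    trials: list[Trial] = []
    while len(trials) < n:
        order = rng.permutation(len(combos))
        for i in order:
            if len(trials) >= n:
                break
            x, y = combos[i]
            trials.append(make_trial(task, x, y))
    return trials


def make_curriculum(kind: str, n_per_task: int, seed: int = 0) -> Curriculum:
    """Build a blocked or interleaved training curriculum.

    Both kinds contain identical multisets of trials for a given
    ``n_per_task``; they differ only in trial order.
    """
    if kind not in ("blocked", "interleaved"):
        raise ValueError(f"kind must be 'blocked' or 'interleaved', got {kind!r}")
    if n_per_task < 25:
        raise ValueError("n_per_task must be >= 25 to cover all 25 feature combinations")
    rng = np.random.default_rng(seed)
    t1 = _task_block(1, n_per_task, rng)
    t2 = _task_block(2, n_per_task, rng)
    trials = t1 + t2
    if kind == "interleaved":
        order = rng.permutation(len(trials))
        trials = [trials[i] for i in order]
    return Curriculum(trials=trials, kind=kind, n_per_task=n_per_task, seed=seed)


def one_hot_signal(task: int) -> np.ndarray:
    """Veridical contextual cue: [1,0] for task 1, [0,1] for task 2."""
    return np.array([1.0, 0.0]) if task == 1 else np.array([0.0, 1.0])


def network_input(trial: Trial, task_signal: np.ndarray | None = None,
                  sigma: float = 1.0) -> np.ndarray:
    """27-vector [25 blob pixels ; 2 task-signal entries] for one trial."""
    if task_signal is None:
        task_signal = one_hot_signal(trial.task)
    task_signal = np.asarray(task_signal, dtype=float)
    if task_signal.shape != (2,):
        raise ValueError("task_signal must have length 2")
    out = np.empty(N_INPUTS)
    out[:N_PIXELS] = _blob_pixels(trial.x, trial.y, float(sigma))
    out[N_PIXELS:] = task_signal
    return out


def test_grid() -> list[Trial]:
    """The 50 test conditions in canonical order: task-major, then x, then y."""
    return [make_trial(task, x, y) for task in (1, 2) for x in LEVELS for y in LEVELS]


@lru_cache(maxsize=8)
def _test_inputs_cached(sigma: float) -> np.ndarray:
    X = np.stack([network_input(t, sigma=sigma) for t in test_grid()])
    X.flags.writeable = False
    return X


def test_inputs(sigma: float = 1.0) -> np.ndarray:
    """(50, 27) matrix of test-grid inputs with veridical one-hot cues."""
    return _test_inputs_cached(float(sigma))


def test_rewards() -> np.ndarray:
    """(50,) signed rewards of the canonical test grid."""
    return np.array([t.reward for t in test_grid()], dtype=float)


# ---------------------------------------------------------------------------
# serialisation

def curriculum_to_frame(curriculum: Curriculum) -> pd.DataFrame:
    rows = [
        (i, t.task, t.x, t.y, t.reward, t.congruent)
        for i, t in enumerate(curriculum.trials)
    ]
    return pd.DataFrame(rows, columns=["index", "task", "x", "y", "reward", "congruency"])


def save_curriculum(curriculum: Curriculum, path: str) -> None:
    """Write one row per trial as tab-separated text."""
    curriculum_to_frame(curriculum).to_csv(path, sep="\t", index=False)


def load_curriculum_config(path: str) -> dict:
    """Read a key-value (YAML) curriculum config: kind, n_per_task, seed, sigma."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return dict(cfg or {})
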
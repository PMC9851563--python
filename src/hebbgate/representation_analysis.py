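"""Hidden-layer analyses: selectivity, RSA, weight summaries, classical MDS.

All functions operate on the canonical condition order (task-major, then x,
then y ascending) used everywhere in the package; activations are post-ReLU
responses of the trained network to the 50-condition test grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform
from scipy import stats

from . import task_environment as te
from .behavioural_analysis import lower_triangle, _z
from .network_core import NetworkParams
from .task_environment import N_PIXELS

_LEVELS = np.array(te.LEVELS, dtype=float)

TASK1_SELECTIVE = "task1_selective"
TASK2_SELECTIVE = "task2_selective"
AGNOSTIC = "agnostic"
SILENT = "silent"


@dataclass(frozen=True)
class SelectivityThresholds:
    """Operationalisation of "active", "silent" and "dimension-selective".

    activity_floor_frac   a unit counts as active in a task if its mean
                          activity there exceeds this fraction of the grand
                          mean activity of the whole layer.
    beta_ratio            the irrelevant-dimension |beta| must be strictly
                          below this fraction of the relevant-dimension
                          |beta| ("scales with the relevant but not the
                          irrelevant dimension").
    beta_floor            minimum relevant-dimension |beta| (activity units
                          per feature level).
    Defaults make the classifier exact on noise-free constructed units.
    """

    activity_floor_frac: float = 0.05
    beta_ratio: float = 1.0
    beta_floor: float = 0.01


@dataclass
class SelectivityResult:
    labels: list[str]
    betas: np.ndarray          # (n_units, 4): rel1, irrel1, rel2, irrel2
    fractions: dict[str, float]


def _selectivity_design() -> np.ndarray:
    """(50, 5) design: intercept, rel/irrel per task (zeroed outside the task)."""
    gx, gy = np.meshgrid(_LEVELS, _LEVELS, indexing="ij")
    x = np.concatenate([gx.ravel(), gx.ravel()])
    y = np.concatenate([gy.ravel(), gy.ravel()])
    in1 = np.repeat([1.0, 0.0], 25)
    in2 = 1.0 - in1
    return np.column_stack([np.ones(50), x * in1, y * in1, y * in2, x * in2])


def classify_selectivity(activations: np.ndarray,
                         thresholds: SelectivityThresholds | None = None
                         ) -> SelectivityResult:
    """Label each hidden unit by its task selectivity.

    Per unit, activity is regressed on four predictors: the relevant and
    irrelevant feature level within each task.  A unit is task-k selective if
    it is active in task k, near-silent in the other task, and its activity
    scales with the relevant but not the irrelevant dimension of task k.
    Units below the activity floor in both tasks are silent; everything else
    is task-agnostic.
    """
    th = thresholds or SelectivityThresholds()
    A = np.asarray(activations, dtype=float)
    if A.shape[0] != 50:
        raise ValueError("activations must be (50, n_units)")
    X = _selectivity_design()
    B, *_ = np.linalg.lstsq(X, A, rcond=None)   # (5, n_units)
    betas = B[1:].T                              # rel1, irrel1, rel2, irrel2

    floor = th.activity_floor_frac * max(A.mean(), 1e-12)
    mean1 = A[:25].mean(axis=0)
    mean2 = A[25:].mean(axis=0)
    tol = 1e-9  # guards the strict relevant > irrelevant comparison on ties
    labels = []
    for j in range(A.shape[1]):
        act1, act2 = mean1[j] > floor, mean2[j] > floor
        rel1, irrel1, rel2, irrel2 = np.abs(betas[j])
        if not act1 and not act2:
            labels.append(SILENT)
        elif act1 and not act2 and rel1 > th.beta_floor and irrel1 < th.beta_ratio * rel1 - tol:
            labels.append(TASK1_SELECTIVE)
        elif act2 and not act1 and rel2 > th.beta_floor and irrel2 < th.beta_ratio * rel2 - tol:
            labels.append(TASK2_SELECTIVE)
        else:
            labels.append(AGNOSTIC)
    n = len(labels)
    fractions = {lab: labels.count(lab) / n
                 for lab in (TASK1_SELECTIVE, TASK2_SELECTIVE, AGNOSTIC, SILENT)}
    fractions["task_selective"] = fractions[TASK1_SELECTIVE] + fractions[TASK2_SELECTIVE]
    return SelectivityResult(labels=labels, betas=betas, fractions=fractions)


# ---------------------------------------------------------------------------
# RDMs

def hidden_rdm(activations: np.ndarray) -> np.ndarray:
    """50x50 pairwise Euclidean distances between condition patterns."""
    A = np.asarray(activations, dtype=float)
    if A.shape[0] != 50:
        raise ValueError("activations must be (50, n_units)")
    return squareform(pdist(A, metric="euclidean"))


def _condition_coords() -> np.ndarray:
    """(50, 3) rows (t, x, y) in canonical order; t in {0, 1}."""
    gx, gy = np.meshgrid(_LEVELS, _LEVELS, indexing="ij")
    x = np.concatenate([gx.ravel(), gx.ravel()])
    y = np.concatenate([gy.ravel(), gy.ravel()])
    t = np.repeat([0.0, 1.0], 25)
    return np.column_stack([t, x, y])


def model_rdms() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """The grid, orthogonal and diagonal model RDMs.

    grid:       all three coordinates (t, x, y) encoded in both tasks.
    orthogonal: per task only the relevant feature survives — task 1 keeps
                (t, x), task 2 keeps (t, y) — leaving two orthogonal
                one-dimensional manifolds separated by the task coordinate.
    diagonal:   both tasks projected onto the main diagonal of stimulus
                space, (x + y)/sqrt(2), keeping the task coordinate: only the
                congruency-relevant combination is encoded.
    """
    X = _condition_coords()
    grid = squareform(pdist(X))

    Xo = X.copy()
    Xo[:25, 2] = 0.0   # task 1: drop y
    Xo[25:, 1] = 0.0   # task 2: drop x
    orth = squareform(pdist(Xo))

    c = np.cos(np.deg2rad(45.0))
    P = np.array([[1.0, 0.0, 0.0], [0.0, c, c]])
    diag = squareform(pdist(X @ P.T))
    return grid, orth, diag


@dataclass(frozen=True)
class RSACoefficients:
    beta_grid: float
    beta_orth: float
    beta_diag: float
    intercept: float


def rsa_regression(empirical: np.ndarray,
                   models: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None
                   ) -> RSACoefficients:
    """OLS of the z-scored empirical RDM lower triangle on the three models.

    Predictors are the z-scored lower triangles of the grid, orthogonal and
    diagonal model RDMs plus an intercept.
    """
    if models is None:
        models = model_rdms()
    y = _z(lower_triangle(empirical))
    cols = [_z(lower_triangle(m)) for m in models]
    X = np.column_stack([np.ones_like(y)] + cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise np.linalg.LinAlgError("model RDM design is rank-deficient")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return RSACoefficients(beta_grid=float(beta[1]), beta_orth=float(beta[2]),
                           beta_diag=float(beta[3]), intercept=float(beta[0]))


def rsa_group_tests(coeff_table: np.ndarray) -> dict[str, tuple[float, float]]:
    """One-sample t-tests of run-level RSA betas against zero.

    ``coeff_table`` is (n_runs, 3) with columns grid, orth, diag.  Returns
    {name: (t, p)}.
    """
    out = {}
    for i, name in enumerate(("grid", "orth", "diag")):
        t, p = stats.ttest_1samp(coeff_table[:, i], 0.0)
        out[name] = (float(t), float(p))
    return out


# ---------------------------------------------------------------------------
# weight summaries

def task_weight_correlation(params: NetworkParams) -> float:
    """Pearson r between the two task-weight columns (NaN if degenerate)."""
    a, b = params.task_weights[:, 0], params.task_weights[:, 1]
    if a.std() == 0.0 or b.std() == 0.0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def readout_magnitudes(params: NetworkParams, labels: list[str]) -> dict[str, float]:
    """Mean |readout weight| per selectivity class (NaN for empty classes)."""
    w = np.abs(params.w_out)
    out = {}
    for lab in (TASK1_SELECTIVE, TASK2_SELECTIVE, AGNOSTIC, SILENT):
        idx = [i for i, l in enumerate(labels) if l == lab]
        out[lab] = float(w[idx].mean()) if idx else float("nan")
    return out


def receptive_field_summary(params: NetworkParams,
                            labels: list[str]) -> dict[str, np.ndarray]:
    """Class-averaged input-weight maps, reshaped to the 5x5 pixel lattice."""
    W_img = params.W_in[:, :N_PIXELS]
    out = {}
    for lab in (TASK1_SELECTIVE, TASK2_SELECTIVE, AGNOSTIC, SILENT):
        idx = [i for i, l in enumerate(labels) if l == lab]
        out[lab] = (W_img[idx].mean(axis=0).reshape(5, 5) if idx
                    else np.full((5, 5), np.nan))
    return out


# ---------------------------------------------------------------------------
# classical MDS

def classical_mds(rdm: np.ndarray, dims: int = 3,
                  negative_eig_tol: float = 0.1) -> np.ndarray:
    """Torgerson's classical multidimensional scaling.

    Double-centres the squared-distance matrix, eigendecomposes it and
    returns the eigenvalue-ordered embedding (no rotation applied).  A
    warning-level error is raised if strongly negative eigenvalues indicate
    a markedly non-Euclidean RDM.
    """
    if dims < 1:
        raise ValueError("dims must be >= 1")
    D = np.asarray(rdm, dtype=float)
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    total = np.abs(vals).sum()
    if total > 0 and (-vals[vals < 0].sum() if (vals < 0).any() else 0.0) > negative_eig_tol * total:
        raise ValueError("RDM is strongly non-Euclidean (large negative eigenvalues)")
    pos = np.clip(vals[:dims], 0.0, None)
    return vecs[:, :dims] * np.sqrt(pos)
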
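"""Multi-seed experiment suites, synthetic choice agents and group statistics.

A suite trains one network per (condition cell, seed), applies the
behavioural and representational analyses and aggregates the per-run metrics
into a tidy table.  Presets reproduce the package's headline simulations at
desk scale (20 runs per cell by default; the full-scale run count is one
argument away).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from . import behavioural_analysis as ba
from . import representation_analysis as ra
from .learning_motifs import RunRecord, train
from .network_core import TrainConfig

log = logging.getLogger(__name__)


@dataclass
class ExperimentSpec:
    """A grid of training conditions crossed with seeds."""

    name: str
    cells: list[TrainConfig]          # one config per condition cell (seed ignored)
    n_runs: int = 20
    base_seed: int = 0

    def seeds(self) -> list[int]:
        return [self.base_seed + 1000 * i for i in range(self.n_runs)]


@dataclass
class GroupResult:
    """Per-run metric table plus group-level summaries."""

    name: str
    table: pd.DataFrame
    n_failed: int = 0

    def group_means(self) -> pd.DataFrame:
        num = self.table.select_dtypes("number").drop(columns=["seed"], errors="ignore")
        g = self.table.assign(**{c: num[c] for c in num})
        return g.groupby(["variant", "curriculum", "alpha"])[list(num.columns)].agg(["mean", "std"])


def run_metrics(run: RunRecord) -> dict:
    """Standard per-run summary metrics used by all suites."""
    cm = ba.choice_matrix(run)
    acc_c, acc_i, cdiff = ba.congruency_effect(cm)
    sel = ra.classify_selectivity(run.test_traces["post"])
    rsa = ra.rsa_regression(ra.hidden_rdm(run.test_traces["post"]))
    betas = ba.choice_model_rdm_regression(cm)
    cfg = run.config
    return {
        "variant": cfg.variant,
        "curriculum": cfg.curriculum,
        "alpha": cfg.alpha,
        "epsilon": cfg.epsilon,
        "eta": cfg.eta,
        "n_per_task": cfg.n_per_task,
        "seed": cfg.seed,
        "acc_task1": float(run.curve[-1, 0]),
        "acc_task2": float(run.curve[-1, 1]),
        "acc_mean": float(run.curve[-1].mean()),
        "acc_congruent": acc_c,
        "acc_incongruent": acc_i,
        "congruency_effect": cdiff,
        "frac_task_selective": sel.fractions["task_selective"],
        "frac_agnostic": sel.fractions[ra.AGNOSTIC],
        "beta_grid": rsa.beta_grid,
        "beta_orth": rsa.beta_orth,
        "beta_diag": rsa.beta_diag,
        "beta_factorised": betas.beta_factorised,
        "beta_linear": betas.beta_linear,
        "taskweight_corr": ra.task_weight_correlation(run.final_params),
    }


def run_suite(spec: ExperimentSpec) -> GroupResult:
    """Train and analyse every (cell, seed) combination.

    Individual run failures are logged and excluded with a count — never
    silently dropped.
    """
    if spec.n_runs < 1 or not spec.cells:
        raise ValueError("spec needs at least one cell and one run")
    rows, n_failed = [], 0
    for cell in spec.cells:
        for seed in spec.seeds():
            cfg = replace(cell, seed=seed)
            try:
                rows.append(run_metrics(train(cfg)))
            except Exception:
                n_failed += 1
                log.exception("run failed: %s seed=%d", cfg.variant, seed)
    return GroupResult(name=spec.name, table=pd.DataFrame(rows), n_failed=n_failed)


def welch_contrast(a: np.ndarray, b: np.ndarray) -> dict[str, float]:
    """Welch's two-sample t-test (unequal variances)."""
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return {"t": float(t), "p": float(p),
            "mean_a": float(np.mean(a)), "mean_b": float(np.mean(b))}


# ---------------------------------------------------------------------------
# presets

#: Human-scale learning-rate presets (200 trials per task).
HUMAN_SCALE = {
    "blocked": dict(epsilon=0.0905, eta=0.0026),
    "interleaved": dict(epsilon=0.0926, eta=0.000327),
}

#: Representative sluggishness for the "very sluggish" simulations.
HIGH_ALPHA = 0.9


def preset(name: str, n_per_task: int | None = None) -> list[TrainConfig]:
    """Condition cells for the named figure-style suite."""
    if name == "fig2":
        return [TrainConfig(variant="vanilla", curriculum="interleaved", epsilon=0.2),
                TrainConfig(variant="vanilla", curriculum="blocked", epsilon=0.03)]
    if name == "fig3":
        return [TrainConfig(variant="sluggish", curriculum="interleaved",
                            epsilon=0.2, alpha=float(a))
                for a in np.linspace(0.0, 0.95, 20)]
    if name == "fig4":
        return [TrainConfig(variant="manual_gating", curriculum="blocked", epsilon=0.01)]
    if name == "fig5":
        return [TrainConfig(variant="hebbian", curriculum="blocked",
                            epsilon=0.0377, eta=0.00021)]
    if name == "fig6":
        cells = []
        for cur in ("blocked", "interleaved"):
            hs = HUMAN_SCALE[cur]
            cells.append(TrainConfig(variant="vanilla", curriculum=cur,
                                     epsilon=0.2 if cur == "interleaved" else 0.03,
                                     n_per_task=200, eval_every=50))
            cells.append(TrainConfig(variant="sluggish_hebbian", curriculum=cur,
                                     alpha=0.1, n_per_task=200, eval_every=50, **hs))
        return cells
    if name == "fig8":
        n = n_per_task or 5000
        return [TrainConfig(variant="sluggish_hebbian", curriculum="blocked",
                            alpha=HIGH_ALPHA, epsilon=0.0377, eta=0.00021,
                            n_per_task=n),
                TrainConfig(variant="sluggish_hebbian", curriculum="interleaved",
                            alpha=HIGH_ALPHA, epsilon=0.2, eta=0.00021,
                            n_per_task=n)]
    raise ValueError(f"unknown preset {name!r} (s1 runs via block_length_sweep)")


PRESETS = ("fig2", "fig3", "fig4", "fig5", "fig6", "fig8", "s1")


# ---------------------------------------------------------------------------
# synthetic choice agents (stand-ins for behavioural data)

def make_synthetic_agent(kind: str, lapse: float = 0.0, slope: float = 10.0,
                         offset: float = 0.0, n: int | None = None,
                         seed: int = 0) -> np.ndarray:
    """Choice matrix of an idealised agent.

    factorised  one accurate boundary per task (step on the relevant
                dimension, 0.5 on the boundary).
    diagonal    a single shared boundary, accept iff x + y > 0.
    noisy       the factorised policy passed through a lapse-logistic
                transducer (given lapse/slope/offset) with optional binomial
                sampling of n choices per condition.
    """
    fact, diag = ba.model_choice_matrices()
    if kind == "factorised":
        return fact
    if kind == "diagonal":
        return diag
    if kind == "noisy":
        gx, gy = np.meshgrid(np.array(ba._LEVELS), np.array(ba._LEVELS), indexing="ij")
        p = np.stack([ba.lapse_logistic(gx, lapse, slope, offset),
                      ba.lapse_logistic(gy, lapse, slope, offset)])
        if n is not None:
            rng = np.random.default_rng(seed)
            p = rng.binomial(n, p) / n
        return p
    raise ValueError(f"unknown agent kind {kind!r}")


# ---------------------------------------------------------------------------
# block-length sensitivity

def block_length_sweep(lengths, config: TrainConfig | None = None,
                       n_runs: int = 5, base_seed: int = 0) -> GroupResult:
    """Task-1 retention of Hebbian vs plain SGD blocked training per block length.

    Hyperparameters are held fixed across lengths (only n_per_task varies);
    pass ``config`` to override the Hebbian cell's rates.
    """
    if any(l < 25 for l in lengths):
        raise ValueError("block lengths must be >= 25")
    base = config or TrainConfig(variant="hebbian", curriculum="blocked",
                                 epsilon=0.0377, eta=0.00021)
    rows = []
    for length in lengths:
        for hebb in (True, False):
            cfg0 = replace(base,
                           variant="hebbian" if hebb else "vanilla",
                           eta=base.eta if hebb else 0.0,
                           n_per_task=int(length),
                           eval_every=max(25, int(length) // 20))
            for i in range(n_runs):
                seed = base_seed + 1000 * i
                run = train(replace(cfg0, seed=seed))
                rows.append({"block_length": int(length),
                             "hebbian": hebb,
                             "seed": seed,
                             "acc_task1": float(run.curve[-1, 0]),
                             "acc_task2": float(run.curve[-1, 1])})
    return GroupResult(name="block_length_sweep", table=pd.DataFrame(rows))
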
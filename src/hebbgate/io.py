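"""Run serialisation: tabular text for trajectories, npz for checkpoints."""

from __future__ import annotations

import dataclasses
import os

import numpy as np
import pandas as pd
import yaml

from .learning_motifs import RunRecord
from .network_core import NetworkParams, TrainConfig


def save_run(run: RunRecord, out_dir: str) -> None:
    """Write a RunRecord as a directory of plain-text tables plus a checkpoint."""
    os.makedirs(out_dir, exist_ok=True)
    with open(os.path.join(out_dir, "config.yaml"), "w") as fh:
        yaml.safe_dump(dataclasses.asdict(run.config), fh)
    curve = pd.DataFrame({
        "trial": run.eval_steps,
        "acc_task1": run.curve[:, 0],
        "acc_task2": run.curve[:, 1],
        "taskweight_corr": run.taskweight_corr,
    })
    curve.to_csv(os.path.join(out_dir, "curve.tsv"), sep="\t", index=False)
    p = run.final_params
    np.savez(os.path.join(out_dir, "checkpoint.npz"),
             W_in=p.W_in, b_hidden=p.b_hidden, w_out=p.w_out,
             b_out=np.array(p.b_out), **{f"test_{k}": v for k, v in run.test_traces.items()})


def load_run(out_dir: str) -> RunRecord:
    with open(os.path.join(out_dir, "config.yaml")) as fh:
        config = TrainConfig(**yaml.safe_load(fh))
    curve = pd.read_csv(os.path.join(out_dir, "curve.tsv"), sep="\t")
    ck = np.load(os.path.join(out_dir, "checkpoint.npz"))
    params = NetworkParams(W_in=ck["W_in"], b_hidden=ck["b_hidden"],
                           w_out=ck["w_out"], b_out=float(ck["b_out"]))
    traces = {k[5:]: ck[k] for k in ck.files if k.startswith("test_")}
    return RunRecord(config=config,
                     eval_steps=curve["trial"].to_numpy(),
                     curve=curve[["acc_task1", "acc_task2"]].to_numpy(),
                     taskweight_corr=curve["taskweight_corr"].to_numpy(),
                     final_params=params, test_traces=traces)


def save_rdm(rdm: np.ndarray, path: str, header: str = "") -> None:
    """Plain numeric text matrix with an optional condition-order header."""
    np.savetxt(path, rdm, header=header)
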
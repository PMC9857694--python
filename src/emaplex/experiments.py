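"""Experiment driver: sweep the observed fraction, repeat with fresh random
maskings, and compare EMA / EM / random-model reconstructions.

The design is paired: within each (c, repetition) cell every method sees the
identical partial observation, and all seeds fan out deterministically from
one master seed, so a sweep is exactly reproducible.  Each method is granted
the true number of missing links per layer for top-k binarization, putting
the probabilistic methods and the random baseline on equal footing.
"""

from __future__ import annotations

import dataclasses
import time
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import MultiplexNetwork
from .ema import EmaConfig, run_ema
from .evaluate import (
    binarize_topk,
    evaluate_reconstruction,
    gmean,
    mcc,
    random_model,
    true_missing_counts,
)
from .observe import mask_nodes, unobserved_pair_mask

__all__ = ["SweepResult", "run_sweep", "ConvergenceTrace", "convergence_trace", "iterations_to_tolerance"]

METHODS = ("ema", "em", "rm")


@dataclass
class SweepResult:
    """Long-format sweep rows plus an aggregate view.

    ``rows`` has one record per (method, c, repetition, layer-or-"all") with
    G-mean, MCC, iteration count, final MAE and wall-clock runtime.
    """

    rows: pd.DataFrame

    def aggregate(self) -> pd.DataFrame:
        """Mean and std of each metric per (method, c, layer)."""
        g = self.rows.groupby(["method", "c", "layer"], sort=True)
        out = g[["gmean", "mcc", "iterations", "final_mae"]].agg(["mean", "std"])
        out.columns = ["_".join(col) for col in out.columns]
        return out.reset_index()


def _cell_seeds(master_seed: int, c_index: int, rep: int) -> tuple[int, int, int]:
    """Deterministic (mask, init, rm) seeds for one sweep cell."""
    ss = np.random.SeedSequence([int(master_seed), c_index, rep])
    mask_s, init_s, rm_s = ss.generate_state(3) % (2**31)
    return int(mask_s), int(init_s), int(rm_s)


def run_sweep(
    net: MultiplexNetwork,
    c_grid=tuple(round(0.1 * k, 1) for k in range(1, 10)),
    reps: int = 50,
    methods=METHODS,
    cfg: EmaConfig | None = None,
    master_seed: int = 0,
    shared_across_layers: bool = False,
) -> SweepResult:
    """Reconstruct and evaluate each method on each (c, repetition) cell."""
    cfg = cfg or EmaConfig()
    if reps < 1:
        raise ValueError("reps must be >= 1")
    for c in c_grid:
        if not 0.0 < c < 1.0:
            raise ValueError(f"observed fractions must lie in (0, 1), got {c}")
    unknown = set(methods) - set(METHODS)
    if unknown:
        raise ValueError(f"unknown methods: {sorted(unknown)}")

    records = []
    for ci, c in enumerate(c_grid):
        for rep in range(reps):
            mask_s, init_s, rm_s = _cell_seeds(master_seed, ci, rep)
            obs = mask_nodes(net, c, shared_across_layers, mask_s)
            k_layers = true_missing_counts(net, obs)
            for method in methods:
                t0 = time.perf_counter()
                iters, final_mae = 0, float("nan")
                if method == "rm":
                    preds = random_model(obs, k_layers, rm_s)
                    seed = rm_s
                else:
                    mode = cfg.a_step_mode if method == "ema" else "off"
                    run_cfg = dataclasses.replace(cfg, a_step_mode=mode, rng_seed=init_s)
                    res = run_ema(obs, run_cfg)
                    iters = res.iterations
                    final_mae = res.error_trace[-1]
                    preds = [
                        binarize_topk(res.p[l], unobserved_pair_mask(obs, lid), k_layers[l])
                        for l, lid in enumerate(net.layer_ids)
                    ]
                    seed = init_s
                runtime = time.perf_counter() - t0
                for layer, cc in evaluate_reconstruction(net, preds, obs).items():
                    records.append(
                        {
                            "method": method,
                            "c": c,
                            "rep": rep,
                            "seed": seed,
                            "layer": layer,
                            "gmean": gmean(cc),
                            "mcc": mcc(cc),
                            "iterations": iters,
                            "final_mae": final_mae,
                            "runtime": runtime,
                        }
                    )
    return SweepResult(rows=pd.DataFrame.from_records(records))


@dataclass
class ConvergenceTrace:
    ema_trace: list[float]
    em_trace: list[float]
    ema_iterations_at: dict[float, int | None]
    em_iterations_at: dict[float, int | None]


def iterations_to_tolerance(trace, tol: float) -> int | None:
    """1-based iteration at which the MAE first reaches ``tol`` (None if never)."""
    for i, err in enumerate(trace, start=1):
        if err <= tol:
            return i
    return None


def convergence_trace(obs, cfg: EmaConfig | None = None, tols=(1e-4, 1e-5)) -> ConvergenceTrace:
    """Per-iteration MAE sequences for EMA and EM on one observation,
    started from the identical random initialization."""
    cfg = cfg or EmaConfig()
    ema_res = run_ema(obs, dataclasses.replace(cfg, a_step_mode=cfg.a_step_mode if cfg.a_step_mode != "off" else "evidence"))
    em_res = run_ema(obs, dataclasses.replace(cfg, a_step_mode="off"))
    return ConvergenceTrace(
        ema_trace=list(ema_res.error_trace),
        em_trace=list(em_res.error_trace),
        ema_iterations_at={t: iterations_to_tolerance(ema_res.error_trace, t) for t in tols},
        em_iterations_at={t: iterations_to_tolerance(em_res.error_trace, t) for t in tols},
    )
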
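"""Metrics and the replicated experiment grid.

Prediction accuracy is measured by mean squared error on the
standardized outcome scale; clustering quality by the adjusted Rand
index (chance-corrected pair agreement, computed from the contingency
table, invariant to label switching and well defined for partitions
with different numbers of classes); categorical prediction by the
classification error rate.

``run_experiment`` drives the full protocol per grid cell and
replicate: generate a scenario dataset, split 4/1 by subject,
standardize on the training split, fit the requested method, and
evaluate on the held-out subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .baselines import BaselinePipeline, GeeSpec
from .inference import cluster_yx, predict_outcomes
from .scenarios import ScenarioConfig, generate_scenario
from .trainer import TrainConfig, split, standardize, train

__all__ = ["mse", "ari", "error_rate", "ExperimentCell", "MetricsTable",
           "evaluate_replicate", "run_experiment"]


def mse(y_true, y_hat) -> float:
    """Mean squared error over all N*L entries."""
    a = np.asarray(y_true, dtype=float)
    b = np.asarray(y_hat, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    return float(np.mean((a - b) ** 2))


def ari(labels_a, labels_b) -> float:
    """Adjusted Rand index from the pair-counting contingency formula."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("label vectors must be 1-d with equal length")
    n = len(a)
    if n < 2:
        raise ValueError("need at least 2 items")
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    cont = np.zeros((ai.max() + 1, bi.max() + 1))
    np.add.at(cont, (ai, bi), 1)

    def comb2(x):
        return x * (x - 1) / 2.0

    sum_ij = comb2(cont).sum()
    sum_a = comb2(cont.sum(axis=1)).sum()
    sum_b = comb2(cont.sum(axis=0)).sum()
    total = comb2(n)
    expected = sum_a * sum_b / total
    max_index = 0.5 * (sum_a + sum_b)
    if max_index == expected:       # both partitions trivial
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))


def error_rate(y_true, y_hat_class) -> float:
    """Fraction of misclassified entries (categorical outcomes)."""
    a = np.asarray(y_true)
    b = np.asarray(y_hat_class)
    if a.shape != b.shape:
        raise ValueError("shape mismatch")
    return float(np.mean(a != b))


# --------------------------------------------------------------------------
# experiment grid

@dataclass(frozen=True)
class ExperimentCell:
    """One table cell: scenario x method x (D, K) (+ working correlation)."""

    scenario: str
    method: str          # "vada" | "vade-mm" | "vae-gmm-mm" | "gmm-mm"
    D: int
    K: int
    working: str = "mm2"


@dataclass
class MetricsTable:
    """Aggregated mean +- sd per (scenario, method, D, K, metric)."""

    df: pd.DataFrame
    errors: list = field(default_factory=list)

    def to_long_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    def report(self, metric: str) -> pd.DataFrame:
        """Table-style pivot: scenario/method rows, one 'mean +- sd' cell."""
        sub = self.df[self.df.metric == metric].copy()
        sub["cell"] = [f"{m:.3f} ± {s:.3f}" for m, s in zip(sub["mean"], sub["sd"])]
        return sub.pivot_table(index=["scenario", "method"],
                               columns=["D", "K"], values="cell",
                               aggfunc="first")


def evaluate_replicate(cell: ExperimentCell, seed: int, *,
                       n_subjects: int = 2500, epochs: int = 500,
                       scenario_overrides: dict | None = None) -> dict:
    """Run one replicate of one grid cell; returns {metric name: value}.

    Metrics are computed on the standardized outcome scale; clustering
    ARIs compare held-out subject labels with the generating labels.
    """
    cfg = ScenarioConfig(code=cell.scenario, n_subjects=n_subjects, seed=seed,
                         **(scenario_overrides or {}))
    data, truth = generate_scenario(cfg)
    train_set, test_set = split(data, 0.8, seed)
    train_s, stats = standardize(train_set)
    test_s, _ = standardize(test_set, stats)
    out: dict[str, float] = {}

    if cell.method == "vada":
        tc = TrainConfig(D=cell.D, K=cell.K, epochs=epochs, seed=seed)
        nets, params, _ = train(train_s, tc)
        pred_test = predict_outcomes(nets, params, test_s.X, seed=seed)
        pred_train = predict_outcomes(nets, params, train_s.X, seed=seed)
        out["mse_test"] = mse(test_s.y, pred_test.y_hat)
        out["mse_train"] = mse(train_s.y, pred_train.y_hat)
        labels_yx, _ = cluster_yx(nets, params, test_s, seed=seed)
        out["ari_yx"] = ari(test_s.c_true, labels_yx)
        out["ari_x"] = ari(test_s.c_true, pred_test.labels_x)
        out["agree_yx_x"] = float(np.mean(labels_yx == pred_test.labels_x))
    else:
        tc = TrainConfig(D=max(cell.D, 1), K=cell.K, epochs=epochs, seed=seed)
        pipe = BaselinePipeline(cell.method, K=cell.K, D=cell.D,
                                gee=GeeSpec(working=cell.working),
                                train_config=tc, seed=seed).fit(train_s)
        y_hat, labels = pipe.predict(test_s)
        y_hat_train, _ = pipe.predict(train_s)
        out["mse_test"] = mse(test_s.y, y_hat)
        out["mse_train"] = mse(train_s.y, y_hat_train)
        out["ari"] = ari(test_s.c_true, labels)
    return out


def run_experiment(grid, n_replicates: int = 3, base_seed: int = 1, *,
                   n_subjects: int = 2500, epochs: int = 500,
                   scenario_overrides: dict | None = None) -> MetricsTable:
    """Replicate every grid cell and aggregate mean +- sd per metric.

    Replicate r of any cell uses seed ``base_seed + r`` end to end
    (generation, split, fitting), so cells are independent given seeds
    and any single cell can be reproduced in isolation.  Method failures
    are recorded per cell and do not abort the grid.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rows, errors = [], []
    for cell in grid:
        per_metric: dict[str, list] = {}
        seeds_used = []
        for r in range(n_replicates):
            seed = base_seed + r
            try:
                res = evaluate_replicate(cell, seed, n_subjects=n_subjects,
                                         epochs=epochs,
                                         scenario_overrides=scenario_overrides)
            except Exception as e:      # noqa: BLE001 - recorded, not fatal
                errors.append((cell, seed, repr(e)))
                continue
            seeds_used.append(seed)
            for k, v in res.items():
                per_metric.setdefault(k, []).append(v)
        for metric, vals in per_metric.items():
            vals = np.asarray(vals, dtype=float)
            rows.append({
                "scenario": cell.scenario, "method": cell.method,
                "D": cell.D, "K": cell.K, "metric": metric,
                "mean": vals.mean(),
                "sd": vals.std(ddof=1) if len(vals) > 1 else 0.0,
                "n_replicates": len(vals),
                "seeds": ",".join(map(str, seeds_used)),
            })
    return MetricsTable(pd.DataFrame(rows), errors)
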
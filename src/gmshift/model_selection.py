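"""Virtual leave-one-out model selection for trained graph machines.

Refitting a model N times to compute a true leave-one-out score is
impractical for thousands of carbons.  Instead, the virtual leave-one-out
(VLOO) score approximates each held-out prediction error to first order
using the leverages h_ii — the diagonal of the hat matrix built from the
output Jacobian Z at the trained parameters:

    h_ii = z_i^T (Z^T Z)^+ z_i,
    VLOO = sqrt( (1/N) * sum_i ( r_i / (1 - h_ii) )^2 ),

with r_i the training residual of record i in ppm.  For a model that is
linear in its parameters this is the exact PRESS leave-one-out error; for
graph machines it is a first-order approximation, and it is always at
least as large as the training RMSE.

Restarts of the multi-start protocol are ranked by their VLOO score, and
the k best form the prediction ensemble.  A complexity scan repeats the
whole protocol over a list of hidden-layer sizes.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, replace

import numpy as np

from .node_model import NodeFunctionParameters
from .training import ShiftDataset, TrainConfig, TrainedModel, multi_restart_train

logger = logging.getLogger(__name__)

#: relative singular-value cutoff for rank-deficient Jacobians
PINV_RCOND = 1e-10
#: leverages are clamped below 1 so the VLOO score stays finite
LEVERAGE_CLAMP = 1.0 - 1e-8


def output_jacobian_matrix(
    params: NodeFunctionParameters, dataset: ShiftDataset
) -> np.ndarray:
    """(N, q) matrix whose row i is the gradient of prediction i (in ppm)."""
    scaling = dataset.scaling()
    _, z = dataset.packed().forward_and_jacobian(params)
    z = z * scaling.half_range
    if not np.all(np.isfinite(z)):
        raise ValueError("non-finite output Jacobian")
    return z


def leverages(z: np.ndarray) -> np.ndarray:
    """Diagonal of the hat matrix Z (Z^T Z)^+ Z^T, clamped to [0, 1-1e-8].

    Before clamping the leverages sum to rank(Z); for a full-rank Jacobian
    that is q.  The pseudo-inverse handles rank-deficient cases such as
    over-parameterized restarts.
    """
    z = np.asarray(z, dtype=float)
    gram_inv = np.linalg.pinv(z.T @ z, rcond=PINV_RCOND, hermitian=True)
    h = np.einsum("ij,jk,ik->i", z, gram_inv, z)
    return np.clip(h, 0.0, LEVERAGE_CLAMP)


def vloo_score(residuals: np.ndarray, lev: np.ndarray) -> float:
    """Root mean square of the leverage-inflated residuals, in ppm."""
    residuals = np.asarray(residuals, dtype=float)
    lev = np.asarray(lev, dtype=float)
    if residuals.shape != lev.shape:
        raise ValueError("residuals and leverages must have equal length")
    press = residuals / (1.0 - lev)
    return float(np.sqrt(np.mean(press * press)))


def vloo_of_model(model: TrainedModel, dataset: ShiftDataset) -> float:
    """VLOO score of one trained model on its training set, in ppm."""
    pred = model.scaling.descale(dataset.packed().forward(model.params))
    r = dataset.shifts - pred
    z = output_jacobian_matrix(model.params, dataset)
    return vloo_score(r, leverages(z))


@dataclass(frozen=True)
class SelectionResult:
    """Ranking of trained models by VLOO score."""

    scores: tuple[float, ...]
    selected_indices: tuple[int, ...]
    mean_selected: float
    sd_selected: float
    h: int

    @property
    def k(self) -> int:
        return len(self.selected_indices)


def rank_and_select(
    models: list[TrainedModel], dataset: ShiftDataset, k: int
) -> SelectionResult:
    """Compute every model's VLOO score and keep the k smallest.

    Ties are broken by restart order (earlier restart first).  The VLOO
    score of each model is stored back on the model.
    """
    if k < 1 or k > len(models):
        raise ValueError(f"k={k} out of range for {len(models)} models")
    scores = []
    for m in models:
        m.vloo_score = vloo_of_model(m, dataset)
        scores.append(m.vloo_score)
    order = sorted(range(len(models)), key=lambda i: (scores[i], i))
    chosen = tuple(order[:k])
    chosen_scores = np.array([scores[i] for i in chosen])
    return SelectionResult(
        scores=tuple(scores),
        selected_indices=chosen,
        mean_selected=float(chosen_scores.mean()),
        sd_selected=float(chosen_scores.std()),
        h=models[0].h,
    )


@dataclass(frozen=True)
class ScanRow:
    """One complexity level of the scan."""

    h: int
    best_rmste: float
    mean_vloo: float
    sd_vloo: float
    seconds: float


def complexity_scan(
    dataset: ShiftDataset,
    h_values: list[int],
    config: TrainConfig,
    k: int = 25,
) -> list[ScanRow]:
    """Train the multi-restart protocol at each hidden-layer size.

    Each row reports the smallest RMSTE over the restarts, the mean and
    standard deviation of the k smallest VLOO scores, and wall-clock time.
    The appropriate complexity is the one where the mean VLOO score stops
    improving materially — larger h buys no generalization, only cost.
    """
    if not h_values:
        raise ValueError("h_values must be non-empty")
    rows = []
    for h in h_values:
        cfg = replace(config, h=h)
        t0 = time.perf_counter()
        models = multi_restart_train(dataset, cfg)
        sel = rank_and_select(models, dataset, k=min(k, len(models)))
        elapsed = time.perf_counter() - t0
        row = ScanRow(
            h=h,
            best_rmste=min(m.rmste for m in models),
            mean_vloo=sel.mean_selected,
            sd_vloo=sel.sd_selected,
            seconds=elapsed,
        )
        logger.info(
            "scan h=%d: best RMSTE %.4f, VLOO %.4f (%.4f), %.1fs",
            h, row.best_rmste, row.mean_vloo, row.sd_vloo, elapsed,
        )
        rows.append(row)
    return rows


def scan_table(rows: list[ScanRow]) -> str:
    """Delimited text rendering of a complexity scan (one row per h)."""
    lines = ["h\tbest_rmste_ppm\tmean_vloo_ppm\tsd_vloo_ppm\tseconds"]
    for r in rows:
        lines.append(
            f"{r.h}\t{r.best_rmste:.4f}\t{r.mean_vloo:.4f}\t{r.sd_vloo:.4f}\t{r.seconds:.2f}"
        )
    return "\n".join(lines) + "\n"
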
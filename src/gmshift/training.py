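"""Weight-shared least-squares training of graph machines.

All graph machines of a dataset share one node-function parameter vector
theta; training minimizes the sum of squared errors between the measured
chemical shifts and the graph-machine outputs over the whole set.  The
minimization uses the Levenberg-Marquardt algorithm: the normal matrix
J^T J (q x q, with q a few hundred at most) is formed explicitly from the
batched output Jacobian and solved with adaptive damping.

Because the cost surface is multimodal, a multi-restart protocol trains the
same architecture from many random initializations; model selection
(see :mod:`gmshift.model_selection`) then ranks the restarts by their
virtual leave-one-out score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.linalg import cho_factor, cho_solve, LinAlgError

from .chem_graph import TaggedMolecule, build_rooted_dag
from .node_model import (
    NodeFunctionParameters,
    PackedGraphs,
    ScalingSpec,
    input_count,
)

logger = logging.getLogger(__name__)


@dataclass
class ShiftDataset:
    """Annotated carbons: (tagged molecule, experimental shift in ppm)."""

    records: list[tuple[TaggedMolecule, float]]

    def __post_init__(self):
        if not self.records:
            raise ValueError("a shift dataset needs at least one record")
        shifts = np.array([s for _, s in self.records], dtype=float)
        if not np.all(np.isfinite(shifts)):
            raise ValueError("non-finite chemical shift in dataset")
        self._shifts = shifts
        self._packed: PackedGraphs | None = None

    @property
    def n_records(self) -> int:
        return len(self.records)

    @property
    def n_molecules(self) -> int:
        return len({self._molecule_key(m) for m, _ in self.records})

    @staticmethod
    def _molecule_key(mol: TaggedMolecule) -> str:
        from rdkit import Chem

        bare = Chem.Mol(mol.rdkit_mol)
        for atom in bare.GetAtoms():
            atom.SetAtomMapNum(0)
        return Chem.MolToSmiles(bare)

    @property
    def shifts(self) -> np.ndarray:
        return self._shifts

    def shift_range(self) -> tuple[float, float]:
        return float(self._shifts.min()), float(self._shifts.max())

    def scaling(self) -> ScalingSpec:
        """[-1, 1] target scaling over this dataset's shift range."""
        lo, hi = self.shift_range()
        if hi - lo < 1e-9:  # degenerate single-value set
            return ScalingSpec(center=lo, half_range=1.0)
        return ScalingSpec.from_range(lo, hi)

    def packed(self) -> PackedGraphs:
        """Batched DAG representation, built once and cached."""
        if self._packed is None:
            dags = [build_rooted_dag(m) for m, _ in self.records]
            self._packed = PackedGraphs.from_dags(dags)
        return self._packed

    def subset(self, indices) -> "ShiftDataset":
        return ShiftDataset(records=[self.records[i] for i in indices])


@dataclass(frozen=True)
class TrainConfig:
    """Levenberg-Marquardt and restart-protocol settings."""

    h: int = 8
    #: width of the state passed from child to parent; 1 is the plain
    #: single-output perceptron, wider states widen the per-edge channel
    state_dim: int = 1
    max_iterations: int = 300
    initial_damping: float = 1e-2
    damping_increase: float = 10.0
    damping_decrease: float = 10.0
    max_damping: float = 1e10
    cost_tolerance: float = 1e-8
    gradient_tolerance: float = 1e-10
    #: number of consecutive below-tolerance drops that terminate the run;
    #: LM on tanh networks plateaus and recovers, so one tiny step is not
    #: taken as convergence
    patience: int = 10
    #: "identity" damps with lambda*I, "diag" with lambda*diag(J^T J)
    #: (Marquardt scaling); identity behaves better on these landscapes
    damping_matrix: str = "identity"
    init_scale: float = 0.3
    restarts: int = 100
    master_seed: int = 0

    def __post_init__(self):
        if self.h < 1 or self.restarts < 1 or self.state_dim < 1:
            raise ValueError("h, state_dim and restart count must be >= 1")
        if min(self.initial_damping, self.damping_increase, self.damping_decrease,
               self.init_scale) <= 0 or self.max_iterations < 0 or self.patience < 1:
            raise ValueError("config values must be positive")
        if self.damping_matrix not in ("identity", "diag"):
            raise ValueError(f"unknown damping_matrix {self.damping_matrix!r}")

    def restart_seed(self, index: int) -> np.random.SeedSequence:
        return np.random.SeedSequence(entropy=self.master_seed, spawn_key=(index,))


@dataclass
class TrainedModel:
    """One trained graph-machine model plus its training diagnostics."""

    params: NodeFunctionParameters
    scaling: ScalingSpec
    rmste: float
    restart_index: int
    n_iterations: int
    #: tolerance-based convergence; False also when the iteration budget ran
    #: out while the cost was still improving
    converged: bool
    #: LM aborted: no acceptable step existed even at maximum damping
    failed: bool = False
    vloo_score: float | None = None
    cost_trace: list[float] = field(default_factory=list, repr=False)

    @property
    def h(self) -> int:
        return self.params.h


def cost(params: NodeFunctionParameters, dataset: ShiftDataset) -> float:
    """Sum of squared residuals on the scaled target scale."""
    scaling = dataset.scaling()
    y = scaling.scale(dataset.shifts)
    f = dataset.packed().forward(params)
    r = y - f
    return float(r @ r)


def rmste(model: TrainedModel, dataset: ShiftDataset) -> float:
    """Root-mean-square training error in ppm."""
    pred = model.scaling.descale(dataset.packed().forward(model.params))
    r = dataset.shifts - pred
    return float(np.sqrt(np.mean(r * r)))


def predictions(model: TrainedModel, dataset: ShiftDataset) -> np.ndarray:
    """Per-record shift estimates in ppm."""
    return model.scaling.descale(dataset.packed().forward(model.params))


def lm_fit(
    dataset: ShiftDataset,
    theta0: np.ndarray,
    config: TrainConfig,
    restart_index: int = 0,
) -> TrainedModel:
    """Levenberg-Marquardt minimization of the weight-shared cost.

    Accepted steps never increase the cost; a rejected step raises the
    damping and is retried.  Terminates on relative cost change below
    ``cost_tolerance``, on gradient norm below ``gradient_tolerance``, on
    ``max_iterations``, or — with ``converged=False`` — when the damped
    normal equations stay unsolvable at maximum damping.
    """
    scaling = dataset.scaling()
    packed = dataset.packed()
    y = scaling.scale(dataset.shifts)
    h = config.h
    d = config.state_dim
    n_in = input_count(d)

    def make_params(theta: np.ndarray) -> NodeFunctionParameters:
        return NodeFunctionParameters(h=h, theta=theta, n_in=n_in, state_dim=d)

    params = make_params(np.asarray(theta0, dtype=float).copy())

    f, z = packed.forward_and_jacobian(params)
    r = y - f
    current = float(r @ r)
    trace = [current]
    lam = config.initial_damping
    converged = False
    failed = False
    it = 0
    stall = 0
    eye = np.eye(params.q)
    while it < config.max_iterations:
        it += 1
        jtj = z.T @ z
        jtr = z.T @ r  # = -gradient/2 of the cost w.r.t. theta
        if np.linalg.norm(jtr) < config.gradient_tolerance:
            converged = True
            it -= 1
            break
        if config.damping_matrix == "diag":
            damp = np.diag(np.maximum(np.diag(jtj), 1e-12))
        else:
            damp = eye
        accepted = False
        while lam <= config.max_damping:
            try:
                c = cho_factor(jtj + lam * damp, lower=True)
                step = cho_solve(c, jtr)
            except LinAlgError:
                lam *= config.damping_increase
                continue
            trial = make_params(params.theta + step)
            # cost-only evaluation: the Jacobian is recomputed only for
            # accepted parameters, so rejected trials stay cheap
            f_t = packed.forward(trial)
            r_t = y - f_t
            new = float(r_t @ r_t)
            if np.isfinite(new) and new <= current:
                accepted = True
                rel_drop = (current - new) / max(current, 1e-300)
                f_t, z_t = packed.forward_and_jacobian(trial)
                params, f, z, r = trial, f_t, z_t, r_t
                current = new
                lam = max(lam / config.damping_decrease, 1e-14)
                trace.append(current)
                logger.debug(
                    "restart %d iter %d cost %.6e damping %.1e",
                    restart_index, it, current, lam,
                )
                stall = stall + 1 if rel_drop < config.cost_tolerance else 0
                if stall >= config.patience:
                    converged = True
                break
            lam *= config.damping_increase
        if not accepted:
            failed = True
            break
        if converged:
            break

    model = TrainedModel(
        params=params,
        scaling=scaling,
        rmste=float(np.sqrt(current / dataset.n_records)) * scaling.half_range,
        restart_index=restart_index,
        n_iterations=it,
        converged=converged and not failed,
        failed=failed,
        cost_trace=trace,
    )
    return model


def explore_refine_train(
    dataset: ShiftDataset, config: TrainConfig, refine_iterations: int
) -> tuple[TrainedModel, list[TrainedModel]]:
    """Budgeted protocol: short multi-restart exploration, then refinement.

    Restart fits reach basin-dependent plateaus quickly, so most of the
    restart budget only needs to identify a good basin; the best model (by
    RMSTE) is then trained further for ``refine_iterations``.  Returns the
    refined model and the exploration pool.
    """
    models = multi_restart_train(dataset, config)
    best = min(models, key=lambda m: m.rmste)
    refine_cfg = replace(config, max_iterations=refine_iterations)
    refined = lm_fit(
        dataset, best.params.theta.copy(), refine_cfg,
        restart_index=best.restart_index,
    )
    logger.info(
        "refined restart %d: RMSTE %.4f -> %.4f ppm",
        best.restart_index, best.rmste, refined.rmste,
    )
    return refined, models


def multi_restart_train(
    dataset: ShiftDataset, config: TrainConfig
) -> list[TrainedModel]:
    """Train ``config.restarts`` models from distinct random initializations.

    Restart seeds derive deterministically from the master seed, so the
    returned list — including every RMSTE — is reproducible bit for bit.
    """
    models = []
    for i in range(config.restarts):
        rng = np.random.default_rng(config.restart_seed(i))
        params0 = NodeFunctionParameters.random(
            config.h, rng, init_scale=config.init_scale,
            state_dim=config.state_dim,
        )
        model = lm_fit(dataset, params0.theta, config, restart_index=i)
        logger.info(
            "restart %d/%d: RMSTE %.4f ppm after %d iterations (converged=%s)",
            i + 1, config.restarts, model.rmste, model.n_iterations, model.converged,
        )
        models.append(model)
    return models
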
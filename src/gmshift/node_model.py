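"""Shared node function and recursive evaluation of graph machines.

Every node of every rooted DAG carries the same single-hidden-layer
perceptron (tanh hidden units, linear output).  Its inputs are a one-hot
encoding of the atom type over the ten supported heavy elements, the atom's
valence scaled to [0, 1], and up to four child outputs in canonical order
(unused slots are zero, the tanh-neutral value).  Evaluating the nodes in
topological order and reading the root output yields the graph-machine
estimate of the root carbon's chemical shift.

Because a whole training set shares one parameter vector, evaluation and
differentiation are batched: all nodes of equal composition depth, across
all graphs of a dataset, are processed in one matrix operation
(:class:`PackedGraphs`).  The single-graph helpers :func:`gm_forward` and
:func:`gm_jacobian` wrap the same engine.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

from .chem_graph import SUPPORTED_ELEMENTS, AtomRecord, RootedDAG

#: static inputs: one-hot atom type (10) + scaled valence (1)
N_STATIC = len(SUPPORTED_ELEMENTS) + 1
#: child-output slots per node
MAX_CHILDREN = 4
#: node-function inputs for the scalar (state_dim=1) node function
N_IN = N_STATIC + MAX_CHILDREN

_ELEMENT_INDEX = {sym: i for i, sym in enumerate(SUPPORTED_ELEMENTS)}


class ModelError(ValueError):
    """Dimension mismatch or structurally unsupported graph."""


def input_count(state_dim: int = 1) -> int:
    """Node-function input dimension for a given inter-node state size."""
    return N_STATIC + MAX_CHILDREN * state_dim


def parameter_count(h: int, n_in: int = N_IN, state_dim: int = 1) -> int:
    """Number of adjustable parameters of the node function.

    ``h`` hidden tanh units over ``n_in`` inputs plus bias, and a linear
    output layer of ``state_dim`` units over the hidden layer plus bias:
    ``h*(n_in+1) + state_dim*(h+1)``.  With the default scalar state this
    is ``h*(n_in+1) + h + 1``.
    """
    if h < 1:
        raise ValueError(f"hidden-unit count must be >= 1, got {h}")
    if state_dim < 1:
        raise ValueError(f"state dimension must be >= 1, got {state_dim}")
    return h * (n_in + 1) + state_dim * (h + 1)


def encode_node(atom: AtomRecord) -> np.ndarray:
    """Static input vector of one atom: one-hot element + valence/4."""
    if atom.symbol not in _ELEMENT_INDEX:
        from .chem_graph import UnsupportedElementError

        raise UnsupportedElementError(atom.symbol)
    x = np.zeros(N_STATIC)
    x[_ELEMENT_INDEX[atom.symbol]] = 1.0
    x[-1] = atom.valence / 4.0
    return x


@dataclass(frozen=True)
class ScalingSpec:
    """Affine map between chemical shifts (ppm) and the network output scale.

    Targets are scaled to [-1, 1] over the training range before
    optimization so the tanh layer works in its responsive region.
    """

    center: float
    half_range: float

    def __post_init__(self):
        if not self.half_range > 0:
            raise ValueError("half_range must be positive")

    @classmethod
    def from_range(cls, lo: float, hi: float) -> "ScalingSpec":
        return cls(center=(lo + hi) / 2.0, half_range=(hi - lo) / 2.0)

    @classmethod
    def identity(cls) -> "ScalingSpec":
        return cls(center=0.0, half_range=1.0)

    def scale(self, ppm):
        return (np.asarray(ppm, dtype=float) - self.center) / self.half_range

    def descale(self, unit):
        return np.asarray(unit, dtype=float) * self.half_range + self.center


@dataclass(frozen=True)
class NodeFunctionParameters:
    """Flat parameter vector of the shared node function.

    ``state_dim`` is the width of the channel between a node and its
    parent: each node emits a ``state_dim``-vector, and the first component
    of the root's state is the graph-machine output.  The scalar default
    matches the one-output perceptron; wider states carry more structural
    information per edge at the cost of ``MAX_CHILDREN * (state_dim - 1)``
    extra inputs.
    """

    h: int
    theta: np.ndarray
    n_in: int = N_IN
    state_dim: int = 1

    def __post_init__(self):
        expected = parameter_count(self.h, self.n_in, self.state_dim)
        if self.theta.shape != (expected,):
            raise ModelError(
                f"theta has shape {self.theta.shape}, expected ({expected},) "
                f"for h={self.h}, state_dim={self.state_dim}"
            )
        if not np.all(np.isfinite(self.theta)):
            raise ModelError("theta contains non-finite entries")

    @property
    def q(self) -> int:
        return self.theta.size

    def hidden_weights(self) -> np.ndarray:
        """(h, n_in+1) matrix; last column is the bias."""
        return self.theta[: self.h * (self.n_in + 1)].reshape(self.h, self.n_in + 1)

    def output_weights(self) -> np.ndarray:
        """(state_dim, h+1) matrix; last column is the bias.

        Returned one-dimensional (length h+1) for the scalar default, for
        backward compatibility of hand-written arithmetic.
        """
        tail = self.theta[self.h * (self.n_in + 1):]
        if self.state_dim == 1:
            return tail
        return tail.reshape(self.state_dim, self.h + 1)

    @classmethod
    def random(
        cls,
        h: int,
        rng: np.random.Generator,
        init_scale: float = 0.3,
        n_in: int | None = None,
        state_dim: int = 1,
    ) -> "NodeFunctionParameters":
        if n_in is None:
            n_in = input_count(state_dim)
        q = parameter_count(h, n_in, state_dim)
        return cls(
            h=h,
            theta=rng.uniform(-init_scale, init_scale, size=q),
            n_in=n_in,
            state_dim=state_dim,
        )


@dataclass
class _DepthGroup:
    x_static: np.ndarray   # (m, N_STATIC)
    child_slots: np.ndarray  # (m, MAX_CHILDREN), 0 = empty slot
    out_slots: np.ndarray  # (m,)
    records: np.ndarray    # (m,)
    # sparse (n_records, m) node-to-record scatter for gradient accumulation
    record_scatter: sparse.csr_matrix = None

    def finalize(self, n_records: int) -> None:
        m = len(self.records)
        self.record_scatter = sparse.csr_matrix(
            (np.ones(m), (self.records, np.arange(m))), shape=(n_records, m)
        )


@dataclass
class PackedGraphs:
    """A set of rooted DAGs flattened for batched evaluation.

    Nodes are grouped by composition depth (leaves depth 0); within one
    depth every node of every graph is independent, so forward evaluation
    and reverse-mode differentiation run as a handful of dense matrix
    operations per depth.  Global slot 0 is a constant zero feeding empty
    child slots.
    """

    n_records: int
    n_slots: int
    depth_groups: list[_DepthGroup]
    root_slots: np.ndarray
    _cache: dict = field(default_factory=dict, repr=False)

    @classmethod
    def from_dags(cls, dags: list[RootedDAG]) -> "PackedGraphs":
        by_depth: dict[int, list[tuple[np.ndarray, list[int], int, int]]] = {}
        root_slots = np.empty(len(dags), dtype=np.intp)
        slot = 1
        for rec, dag in enumerate(dags):
            slots = {}
            depth = {}
            for node in dag.topo_order:
                kids = dag.children[node]
                if len(kids) > MAX_CHILDREN:
                    raise ModelError(
                        f"node with {len(kids)} children exceeds the "
                        f"{MAX_CHILDREN}-slot encoding"
                    )
                d = 1 + max((depth[c] for c in kids), default=-1)
                depth[node] = d
                slots[node] = slot
                child = [slots[c] for c in kids] + [0] * (MAX_CHILDREN - len(kids))
                by_depth.setdefault(d, []).append(
                    (encode_node(dag.molecule.atoms[node]), child, slot, rec)
                )
                slot += 1
            root_slots[rec] = slots[dag.root]
        groups = []
        for d in sorted(by_depth):
            rows = by_depth[d]
            group = _DepthGroup(
                x_static=np.array([r[0] for r in rows]),
                child_slots=np.array([r[1] for r in rows], dtype=np.intp),
                out_slots=np.array([r[2] for r in rows], dtype=np.intp),
                records=np.array([r[3] for r in rows], dtype=np.intp),
            )
            group.finalize(len(dags))
            groups.append(group)
        return cls(
            n_records=len(dags), n_slots=slot, depth_groups=groups, root_slots=root_slots
        )

    def _check(self, params: NodeFunctionParameters) -> None:
        need = input_count(params.state_dim)
        if params.n_in != need:
            raise ModelError(
                f"params built for n_in={params.n_in}, need {need} "
                f"for state_dim={params.state_dim}"
            )

    def forward(self, params: NodeFunctionParameters) -> np.ndarray:
        """Raw (unscaled) root outputs, one per record."""
        self._check(params)
        d = params.state_dim
        w1 = params.hidden_weights()
        w2 = params.output_weights().reshape(d, params.h + 1)
        out = np.zeros((self.n_slots, d))
        for g in self.depth_groups:
            m = len(g.out_slots)
            x = np.concatenate([g.x_static, out[g.child_slots].reshape(m, -1)], axis=1)
            t = np.tanh(x @ w1[:, :-1].T + w1[:, -1])
            out[g.out_slots] = t @ w2[:, :-1].T + w2[:, -1]
        return out[self.root_slots, 0]

    def forward_and_jacobian(
        self, params: NodeFunctionParameters
    ) -> tuple[np.ndarray, np.ndarray]:
        """Root outputs and the (n_records, q) Jacobian d output / d theta.

        Weight sharing means each record's row sums the contributions of all
        nodes of its graph; a shared node (ring closure) receives the summed
        adjoints of its parents before propagating to its own inputs.
        """
        self._check(params)
        d = params.state_dim
        h, q = params.h, params.q
        w1 = params.hidden_weights()
        w2 = params.output_weights().reshape(d, h + 1)
        out = np.zeros((self.n_slots, d))
        tanhs = []
        xbias = []
        for g in self.depth_groups:
            m = len(g.out_slots)
            x = np.concatenate(
                [g.x_static, out[g.child_slots].reshape(m, -1), np.ones((m, 1))],
                axis=1,
            )
            t = np.tanh(x @ w1.T)
            out[g.out_slots] = t @ w2[:, :-1].T + w2[:, -1]
            tanhs.append(t)
            xbias.append(x)

        z = np.zeros((self.n_records, q))
        adj = np.zeros((self.n_slots, d))
        adj[self.root_slots, 0] = 1.0
        n_w1 = h * (params.n_in + 1)
        n_child = MAX_CHILDREN * d
        for g, t, x in zip(
            reversed(self.depth_groups), reversed(tanhs), reversed(xbias)
        ):
            m = len(g.out_slots)
            grad_state = adj[g.out_slots]  # (m, d)
            contrib = np.empty((m, q))
            # output-layer weights and biases, row-major over (d, h+1)
            tcat = np.concatenate([t, np.ones((m, 1))], axis=1)
            contrib[:, n_w1:] = (grad_state[:, :, None] * tcat[:, None, :]).reshape(
                m, d * (h + 1)
            )
            # hidden-layer weights
            hidden = (grad_state @ w2[:, :-1]) * (1.0 - t * t)  # (m, h)
            contrib[:, :n_w1] = (hidden[:, :, None] * x[:, None, :]).reshape(m, n_w1)
            # scatter node contributions onto their records (weight sharing)
            z += g.record_scatter @ contrib
            # propagate to children through the slot columns of w1
            child_adj = hidden @ w1[:, N_STATIC:N_STATIC + n_child]  # (m, 4d)
            flat_slots = g.child_slots.ravel()
            flat_vals = child_adj.reshape(m * MAX_CHILDREN, d)
            for j in range(d):
                adj[:, j] += np.bincount(
                    flat_slots, weights=flat_vals[:, j], minlength=self.n_slots
                )
            adj[0] = 0.0
        return out[self.root_slots, 0], z


def _single(dag: RootedDAG) -> PackedGraphs:
    return PackedGraphs.from_dags([dag])


def gm_forward(
    dag: RootedDAG, params: NodeFunctionParameters, scaling: ScalingSpec
) -> float:
    """Graph-machine estimate of the root carbon's shift, in ppm."""
    raw = _single(dag).forward(params)[0]
    return float(scaling.descale(raw))


def gm_jacobian(
    dag: RootedDAG, params: NodeFunctionParameters, scaling: ScalingSpec
) -> np.ndarray:
    """Gradient (length q) of :func:`gm_forward` with respect to theta."""
    _, z = _single(dag).forward_and_jacobian(params)
    return z[0] * scaling.half_range
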
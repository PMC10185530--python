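"""Directed message-passing network for task-specific molecule fingerprints.

Messages live on directed bond edges; each edge's update aggregates the
messages of edges feeding its source atom, excluding its own reverse edge.
After ``mp_steps`` updates the atom states are read out by an element-wise
mean into a ``hidden_dim`` (default 100) fingerprint. A two-hidden-layer
head (100/32) on the concatenation [fingerprint ‖ 50-d enzyme context]
serves both tasks: scalar regression for Michaelis-constant (KM)
pre-training, and a logistic output for enzyme-substrate classification
fine-tuning. After training, per-molecule fingerprints are extracted and
handed to the downstream gradient-boosted classifier.

KM targets are log10-scale and standardized internally; the Michaelis
constant spans orders of magnitude, and the pre-training task only needs
its relative structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator

from esp import _nn
from esp._nn import Tensor
from esp.molecule_features import ATOM_FDIM, BOND_FDIM, MolGraph

__all__ = ["GNNConfig", "DMPNNFingerprinter", "forward_fingerprint",
           "extract_fingerprints"]


@dataclass
class GNNConfig:
    hidden_dim: int = 100
    mp_steps: int = 3
    head_dims: tuple[int, int] = (100, 32)
    enzyme_context_dim: int = 50
    learning_rate: float = 5e-3
    batch_size: int = 16
    epochs: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hidden_dim < 1 or self.mp_steps < 1:
            raise ValueError("hidden_dim and mp_steps must be >= 1")
        if len(self.head_dims) != 2:
            raise ValueError("head must have exactly two hidden layers")


@dataclass
class _GraphConstants:
    """Per-graph constant matrices consumed by the forward pass."""

    atom_x: np.ndarray  # (n, ATOM_FDIM)
    edge_x: np.ndarray  # (2nb, ATOM_FDIM + BOND_FDIM)
    agg: np.ndarray  # (2nb, 2nb): incoming-to-source minus reverse
    atom_agg: np.ndarray  # (n, 2nb): edges pointing at each atom


def _graph_constants(graph: MolGraph) -> _GraphConstants:
    n, ne = graph.n_atoms, len(graph.directed_edges)
    edge_x = np.zeros((ne, ATOM_FDIM + BOND_FDIM))
    agg = np.zeros((ne, ne))
    atom_agg = np.zeros((n, ne))
    for k, (src, tgt, bond) in enumerate(graph.directed_edges):
        edge_x[k, :ATOM_FDIM] = graph.atom_features[src]
        edge_x[k, ATOM_FDIM:] = graph.bond_features[bond]
        atom_agg[tgt, k] = 1.0
    for k, (src, _, _) in enumerate(graph.directed_edges):
        for j, (_, tgt_j, _) in enumerate(graph.directed_edges):
            if tgt_j == src and j != graph.reverse_edge[k]:
                agg[k, j] = 1.0
    return _GraphConstants(graph.atom_features, edge_x, agg, atom_agg)


class DMPNNFingerprinter(BaseEstimator):
    """Directed message-passing molecule encoder with a task head.

    scikit-learn style: hyperparameters are constructor arguments, fitted
    state lives in trailing-underscore attributes (``params_``,
    ``pretrained_on_km_``). ``fit`` trains the classification task (with
    optional KM pre-training first via :meth:`pretrain_km`), ``transform``
    returns the task-specific fingerprints.
    """

    def __init__(self, hidden_dim: int = 100, mp_steps: int = 3,
                 head_dims: tuple[int, int] = (100, 32),
                 enzyme_context_dim: int = 50, learning_rate: float = 5e-3,
                 batch_size: int = 16, epochs: int = 30, seed: int = 0):
        self.hidden_dim = hidden_dim
        self.mp_steps = mp_steps
        self.head_dims = head_dims
        self.enzyme_context_dim = enzyme_context_dim
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.epochs = epochs
        self.seed = seed

    # -- parameters --------------------------------------------------------
    def _config(self) -> GNNConfig:
        return GNNConfig(self.hidden_dim, self.mp_steps, tuple(self.head_dims),
                         self.enzyme_context_dim, self.learning_rate,
                         self.batch_size, self.epochs, self.seed)

    def _init_params(self) -> dict[str, Tensor]:
        cfg = self._config()
        rng = np.random.default_rng(cfg.seed)
        D = cfg.hidden_dim
        h1, h2 = cfg.head_dims
        head_in = D + cfg.enzyme_context_dim
        p = {
            "W_in": _nn.parameter(_nn.glorot(rng, ATOM_FDIM + BOND_FDIM, D)),
            "W_msg": _nn.parameter(_nn.glorot(rng, D, D)),
            "W_atom": _nn.parameter(_nn.glorot(rng, ATOM_FDIM + D, D)),
            "W_h1": _nn.parameter(_nn.glorot(rng, head_in, h1)),
            "b_h1": _nn.parameter(np.zeros(h1)),
            "W_h2": _nn.parameter(_nn.glorot(rng, h1, h2)),
            "b_h2": _nn.parameter(np.zeros(h2)),
            "W_out": _nn.parameter(_nn.glorot(rng, h2, 1)),
            "b_out": _nn.parameter(np.zeros(1)),
        }
        return p

    def _ensure_params(self) -> None:
        if not hasattr(self, "params_"):
            self.params_ = self._init_params()
            self.pretrained_on_km_ = False

    # -- forward -----------------------------------------------------------
    def _fingerprint(self, const: _GraphConstants) -> Tensor:
        p = self.params_
        atom_x = Tensor(const.atom_x)
        if const.edge_x.shape[0] == 0:  # single-atom molecule: no messages
            pooled = Tensor(np.zeros((const.atom_x.shape[0], self.hidden_dim)))
        else:
            h0 = _nn.relu(Tensor(const.edge_x) @ p["W_in"])
            h = h0
            for _ in range(self.mp_steps):
                h = _nn.relu(h0 + (Tensor(const.agg) @ h) @ p["W_msg"])
            pooled = Tensor(const.atom_agg) @ h
        atom_states = _nn.relu(_nn.concat([atom_x, pooled], axis=1) @ p["W_atom"])
        return _nn.mean(atom_states, axis=0)

    def _head(self, fp: Tensor, context: np.ndarray) -> Tensor:
        p = self.params_
        z = _nn.concat([fp, Tensor(np.asarray(context, dtype=np.float64))], axis=0)
        a1 = _nn.relu(z @ p["W_h1"] + p["b_h1"])
        a2 = _nn.relu(a1 @ p["W_h2"] + p["b_h2"])
        return _nn.total(a2 @ p["W_out"] + p["b_out"])

    def _batch_logits(self, consts, contexts, idx) -> Tensor:
        outs = [self._head(self._fingerprint(consts[i]), contexts[i]) for i in idx]
        return _nn.stack_scalars(outs)

    # -- training ----------------------------------------------------------
    def _run_epochs(self, consts, contexts, targets, loss_kind: str,
                    epochs: int) -> list[float]:
        rng = np.random.default_rng(self._config().seed + 1)
        opt = _nn.Adam(list(self.params_.values()), lr=self.learning_rate)
        history = []
        n = len(consts)
        for _ in range(epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, self.batch_size):
                idx = order[start:start + self.batch_size]
                logits = self._batch_logits(consts, contexts, idx)
                if loss_kind == "bce":
                    loss = _nn.bce_loss(logits, targets[idx])
                else:
                    loss = _nn.mse_loss(logits, targets[idx])
                opt.zero_grad()
                _nn.backward(loss)
                opt.step()
                epoch_loss += float(loss.data) * len(idx)
            history.append(epoch_loss / n)
        return history

    def pretrain_km(self, graphs: list[MolGraph], contexts: np.ndarray,
                    log_km: np.ndarray, epochs: int | None = None
                    ) -> "DMPNNFingerprinter":
        """Pre-train on KM regression; targets are standardized log10 KM."""
        if len(graphs) == 0:
            raise ValueError("need at least one training pair")
        y = np.asarray(log_km, dtype=np.float64)
        if not np.all(np.isfinite(y)):
            raise ValueError("non-finite KM targets")
        self._ensure_params()
        sd = y.std()
        if sd == 0:
            import warnings

            warnings.warn("constant KM targets: degenerate pre-training input")
            sd = 1.0
        y = (y - y.mean()) / sd
        consts = [_graph_constants(g) for g in graphs]
        self.km_history_ = self._run_epochs(
            consts, np.asarray(contexts), y, "mse",
            self.epochs if epochs is None else epochs)
        self.pretrained_on_km_ = True
        return self

    def fit(self, graphs: list[MolGraph], contexts: np.ndarray,
            labels: np.ndarray, epochs: int | None = None
            ) -> "DMPNNFingerprinter":
        """Fine-tune for binary substrate classification (end-to-end).

        When :meth:`pretrain_km` ran first, its parameters are the
        initialization; otherwise training starts cold.
        """
        y = np.asarray(labels, dtype=np.float64)
        if set(np.unique(y)) != {0.0, 1.0}:
            raise ValueError("degenerate labels: need both classes present")
        self._ensure_params()
        consts = [_graph_constants(g) for g in graphs]
        self.fit_history_ = self._run_epochs(
            consts, np.asarray(contexts), y, "bce",
            self.epochs if epochs is None else epochs)
        return self

    # -- inference ---------------------------------------------------------
    def fingerprint(self, graph: MolGraph) -> np.ndarray:
        """Task-specific fingerprint of one molecule (length hidden_dim)."""
        if graph.atom_features.shape[1] != ATOM_FDIM:
            raise ValueError("atom feature dimension mismatch")
        self._ensure_params()
        return self._fingerprint(_graph_constants(graph)).data.copy()

    def predict_proba_pairs(self, graphs: list[MolGraph],
                            contexts: np.ndarray) -> np.ndarray:
        self._ensure_params()
        consts = [_graph_constants(g) for g in graphs]
        logits = self._batch_logits(consts, np.asarray(contexts),
                                    np.arange(len(consts)))
        return 1.0 / (1.0 + np.exp(-logits.data))

    def transform(self, graphs: dict[str, MolGraph]
                  ) -> tuple[dict[str, np.ndarray], list[list[str]]]:
        """Fingerprints for all molecules plus a vector-collision report."""
        table = {mid: self.fingerprint(g) for mid, g in graphs.items()}
        groups: dict[bytes, list[str]] = {}
        for mid, v in table.items():
            groups.setdefault(np.round(v, 12).tobytes(), []).append(mid)
        collisions = sorted([sorted(g) for g in groups.values() if len(g) >= 2])
        return table, collisions

    # -- persistence -------------------------------------------------------
    def save(self, path: str | Path) -> None:
        arrays = {k: v.data for k, v in self.params_.items()}
        np.savez(path, __pretrained=np.array([int(self.pretrained_on_km_)]),
                 **arrays)

    def load(self, path: str | Path) -> "DMPNNFingerprinter":
        data = np.load(path if str(path).endswith(".npz") else f"{path}.npz")
        self.params_ = {k: _nn.parameter(data[k]) for k in data.files
                        if k != "__pretrained"}
        self.pretrained_on_km_ = bool(data["__pretrained"][0])
        return self


def forward_fingerprint(model: DMPNNFingerprinter, graph: MolGraph) -> np.ndarray:
    return model.fingerprint(graph)


def extract_fingerprints(model: DMPNNFingerprinter, graphs: dict[str, MolGraph]):
    return model.transform(graphs)
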
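"""Structural connectivity: loading, validation, surrogate generation, damage reports.

The coupling substrate is a binary, symmetric, zero-diagonal adjacency matrix
over ``N`` regions.  Because the tractography-derived matrix used in the
original study is not redistributable, a seeded surrogate generator is
provided as a stand-in; any user-supplied matrix in delimited text form is
accepted as well.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources as _ilres
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "StructuralNetwork",
    "load_adjacency",
    "save_adjacency",
    "generate_surrogate",
    "edge_loss_map",
    "effective_edge_strengths",
    "aal78_labels",
]


class ConnectomeError(ValueError):
    """Raised when an adjacency matrix violates the structural contract."""


def _default_labels(n: int) -> list[str]:
    return [f"ROI_{i + 1}" for i in range(n)]


@dataclass
class StructuralNetwork:
    """Binary symmetric graph coupling the neural masses.

    Attributes
    ----------
    adjacency:
        ``(n, n)`` array with entries in ``{0, 1}``, symmetric, zero diagonal.
    labels:
        Region names, 1-based in all user-facing tables.
    """

    adjacency: np.ndarray
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency, dtype=float)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ConnectomeError(f"adjacency must be square, got shape {a.shape}")
        if a.shape[0] < 2:
            raise ConnectomeError("need at least 2 nodes")
        if np.any(np.diag(a) != 0):
            raise ConnectomeError("nonzero diagonal")
        if not np.array_equal(a, a.T):
            raise ConnectomeError("asymmetric matrix")
        vals = np.unique(a)
        if not np.all(np.isin(vals, [0.0, 1.0])):
            raise ConnectomeError(
                "entries must be binary (0/1); supply binarize_threshold to "
                "threshold a weighted matrix"
            )
        self.adjacency = a.astype(np.int8)
        if not self.labels:
            self.labels = _default_labels(a.shape[0])
        if len(self.labels) != a.shape[0]:
            raise ConnectomeError("label count does not match matrix size")
        if not self.is_connected:
            warnings.warn(
                "structural graph is disconnected; simulation will run but "
                "isolated components receive no inter-mass coupling",
                stacklevel=3,
            )

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    @property
    def density(self) -> float:
        n = self.n_nodes
        return self.n_edges / (n * (n - 1) / 2)

    @property
    def is_connected(self) -> bool:
        return nx.is_connected(nx.from_numpy_array(np.asarray(self.adjacency)))

    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1).astype(int)


def load_adjacency(
    path: str | Path,
    dialect: str = "auto",
    binarize_threshold: float | None = None,
    labels: list[str] | None = None,
) -> StructuralNetwork:
    """Read an ``N x N`` adjacency matrix from delimited text.

    Parameters
    ----------
    dialect:
        ``csv``, ``tsv``, ``whitespace`` or ``auto`` (sniff from the first line).
    binarize_threshold:
        If given, entries strictly greater than the threshold become 1, the
        rest 0.  Without it, non-binary inputs are rejected.
    """
    path = Path(path)
    text = path.read_text()
    if dialect == "auto":
        first = text.lstrip().splitlines()[0] if text.strip() else ""
        if "," in first:
            dialect = "csv"
        elif "\t" in first:
            dialect = "tsv"
        else:
            dialect = "whitespace"
    delims = {"csv": ",", "tsv": "\t", "whitespace": None}
    if dialect not in delims:
        raise ValueError(f"unknown dialect {dialect!r}")
    try:
        a = np.loadtxt(path, delimiter=delims[dialect], ndmin=2)
    except ValueError:
        # retry skipping a single header line
        a = np.loadtxt(path, delimiter=delims[dialect], ndmin=2, skiprows=1)
    if binarize_threshold is not None:
        a = (a > binarize_threshold).astype(np.int8)
        a = np.maximum(a, a.T)
        np.fill_diagonal(a, 0)
    return StructuralNetwork(a, labels=labels or [])


def save_adjacency(net: StructuralNetwork, path: str | Path, dialect: str = "csv") -> None:
    """Write the adjacency as delimited text; round-trips through :func:`load_adjacency`."""
    delims = {"csv": ",", "tsv": "\t", "whitespace": " "}
    np.savetxt(path, np.asarray(net.adjacency, dtype=int), fmt="%d", delimiter=delims[dialect])


def generate_surrogate(
    n_nodes: int,
    density: float,
    model: str = "modular",
    seed: int | None = None,
    n_modules: int = 5,
    intra_weight: float = 4.0,
    rewire_p: float = 0.1,
    max_tries: int = 200,
) -> StructuralNetwork:
    """Generate a connected binary surrogate connectome with an exact edge count.

    Edge count is ``round(density * N * (N - 1) / 2)``; sampling is repeated
    (fresh draws from the seeded stream) until the graph is connected, so the
    result is deterministic for a fixed seed.

    Models
    ------
    ``erdos_renyi``
        Uniform choice of ``m`` edges.
    ``modular``
        ``n_modules`` equal-size blocks; within-block pairs are
        ``intra_weight`` times as likely as between-block pairs.
    ``watts_strogatz``
        Ring lattice rewired with probability ``rewire_p``, then edges
        added/removed uniformly to hit the exact count.
    """
    if not 0.0 < density <= 1.0:
        raise ValueError("density must be in (0, 1]")
    n_pairs = n_nodes * (n_nodes - 1) // 2
    m = int(round(density * n_pairs))
    if m < n_nodes - 1:
        raise ValueError(
            f"density {density} gives {m} edges; at least {n_nodes - 1} are "
            "required for a connected graph"
        )
    rng = np.random.default_rng(seed)
    iu, ju = np.triu_indices(n_nodes, k=1)
    for _ in range(max_tries):
        if model == "erdos_renyi":
            pick = rng.choice(n_pairs, size=m, replace=False)
        elif model == "modular":
            module = np.arange(n_nodes) % n_modules
            w = np.where(module[iu] == module[ju], intra_weight, 1.0)
            pick = rng.choice(n_pairs, size=m, replace=False, p=w / w.sum())
        elif model == "watts_strogatz":
            k = max(2, 2 * int(round(m / n_nodes)))
            g = nx.watts_strogatz_graph(
                n_nodes, min(k, n_nodes - 1), rewire_p, seed=int(rng.integers(2**31))
            )
            a = nx.to_numpy_array(g, dtype=int)
            pick = _adjust_edge_count(a, m, rng)
        else:
            raise ValueError(f"unknown surrogate model {model!r}")
        a = np.zeros((n_nodes, n_nodes), dtype=np.int8)
        a[iu[pick], ju[pick]] = 1
        a += a.T
        if nx.is_connected(nx.from_numpy_array(a)):
            return StructuralNetwork(a)
    raise RuntimeError(
        f"could not draw a connected {model} graph in {max_tries} tries "
        f"(n={n_nodes}, density={density})"
    )


def _adjust_edge_count(a: np.ndarray, m: int, rng: np.random.Generator) -> np.ndarray:
    """Return upper-triangle pair indices of `a` adjusted to exactly m edges."""
    n = a.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    flat = a[iu, ju].astype(bool)
    present = np.flatnonzero(flat)
    absent = np.flatnonzero(~flat)
    if len(present) > m:
        drop = rng.choice(len(present), size=len(present) - m, replace=False)
        keep = np.delete(present, drop)
    elif len(present) < m:
        add = rng.choice(len(absent), size=m - len(present), replace=False)
        keep = np.concatenate([present, absent[add]])
    else:
        keep = present
    return keep


def effective_edge_strengths(net: StructuralNetwork, side_multipliers: np.ndarray) -> np.ndarray:
    """Weighted edge matrix: unit base strength times both endpoint-side multipliers."""
    w = np.asarray(side_multipliers, dtype=float)
    if w.shape != (net.n_nodes,):
        raise ValueError("side_multipliers must have one entry per node")
    return np.asarray(net.adjacency, dtype=float) * np.outer(w, w)


def edge_loss_map(
    strengths_t0: np.ndarray,
    strengths_t: np.ndarray,
    network: StructuralNetwork | None = None,
    top_k: int | None = None,
) -> pd.DataFrame:
    """Rank edges by absolute loss of connection strength between two time points.

    Returns a table with 1-based node indices sorted by ``loss`` descending,
    truncated to ``top_k`` rows when given.
    """
    w0 = np.asarray(strengths_t0, dtype=float)
    wt = np.asarray(strengths_t, dtype=float)
    if w0.shape != wt.shape or w0.ndim != 2 or w0.shape[0] != w0.shape[1]:
        raise ValueError(f"shape mismatch: {w0.shape} vs {wt.shape}")
    if network is not None:
        support = np.asarray(network.adjacency, dtype=bool)
        labels = network.labels
    else:
        support = (w0 != 0) | (wt != 0)
        labels = _default_labels(w0.shape[0])
    iu, ju = np.triu_indices(w0.shape[0], k=1)
    on = support[iu, ju]
    iu, ju = iu[on], ju[on]
    loss = w0[iu, ju] - wt[iu, ju]
    order = np.argsort(-loss, kind="stable")
    if top_k is not None:
        order = order[:top_k]
    return pd.DataFrame(
        {
            "node_i": iu[order] + 1,
            "node_j": ju[order] + 1,
            "label_i": [labels[i] for i in iu[order]],
            "label_j": [labels[j] for j in ju[order]],
            "strength_t0": w0[iu[order], ju[order]],
            "strength_t": wt[iu[order], ju[order]],
            "loss": loss[order],
        }
    )


def aal78_labels() -> list[str]:
    """78 cortical region names (left hemisphere first), shipped as a resource."""
    text = _ilres.files("addnet").joinpath("resources/aal78_labels.txt").read_text()
    labels = [ln.strip() for ln in text.splitlines() if ln.strip()]
    assert len(labels) == 78
    return labels
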
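"""Disease representation from the MeSH hierarchy via network embedding.

The MeSH tree numbers induce a relational network over disease headings:
heading *a* is linked to heading *b* whenever some tree number of *a* is
the dot-truncation parent of some tree number of *b* (``C04.557`` →
``C04``).  That undirected graph is embedded with a LINE-style
objective — stochastic edge sampling with negative sampling, first- or
second-order proximity — and each pair of embedded diseases gets a
similarity ``DM(a, b) = (cos(vₐ, v_b) + 1)/2 ∈ [0, 1]``.

The embedding is trained with plain SGD on minibatches of sampled
edges; negatives are drawn from the degree^0.75 unigram distribution.
Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .core_data import MeshDescriptorTable
from .errors import DataValidationError, DegenerateInputError, EntityLookupError
from .similarity import SimilarityMatrix

__all__ = [
    "MeshGraph",
    "EmbeddingTable",
    "tree_number_parent",
    "build_mesh_graph",
    "line_embed",
    "embedding_similarity",
    "embedding_similarity_matrix",
]


def tree_number_parent(tree_number: str) -> str | None:
    """Parent of a dot-delimited tree number (drop the last segment);
    top-level numbers (no dot) have no parent."""
    if "." not in tree_number:
        return None
    return tree_number.rsplit(".", 1)[0]


@dataclass(frozen=True)
class MeshGraph:
    """Undirected heading–heading graph induced by tree-number parentage."""

    graph: nx.Graph
    node_labels: dict[str, frozenset[str]]  # heading -> category letters

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def summary(self) -> dict:
        """Node/edge counts, label distribution, degree distribution."""
        degrees = [d for _, d in self.graph.degree()]
        label_counts: dict[str, int] = {}
        for letters in self.node_labels.values():
            for letter in letters:
                label_counts[letter] = label_counts.get(letter, 0) + 1
        return {
            "n_nodes": self.graph.number_of_nodes(),
            "n_edges": self.graph.number_of_edges(),
            "label_counts": dict(sorted(label_counts.items())),
            "degree_min": min(degrees, default=0),
            "degree_max": max(degrees, default=0),
            "degree_mean": float(np.mean(degrees)) if degrees else 0.0,
        }

    def write_edge_list(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for a, b in sorted(map(sorted, self.graph.edges())):
                fh.write(f"{a}\t{b}\n")


def build_mesh_graph(table: MeshDescriptorTable) -> MeshGraph:
    """Relational network over MeSH headings.

    Headings sharing a parent/child tree-number relation are linked;
    self-loops (a heading owning both a number and its parent) are
    dropped.  Node labels are the leading category letters of the owned
    tree numbers.  Headings with no resolvable relation remain isolated.
    """
    g = nx.Graph()
    owners: dict[str, set[str]] = {}  # a tree number may be owned by >1 heading
    labels: dict[str, set[str]] = {}
    for heading, numbers in table.records:
        g.add_node(heading)
        labels.setdefault(heading, set())
        for tn in numbers:
            owners.setdefault(tn, set()).add(heading)
            labels[heading].add(tn[0])
    for heading, numbers in table.records:
        for tn in numbers:
            parent = tree_number_parent(tn)
            if parent is None:
                continue
            for other in owners.get(parent, ()):
                if other != heading:
                    g.add_edge(heading, other)
    return MeshGraph(
        graph=g, node_labels={h: frozenset(s) for h, s in labels.items()}
    )


@dataclass(frozen=True)
class EmbeddingTable:
    """heading → real vector, plus the configuration it was trained with."""

    vectors: dict[str, np.ndarray]
    dim: int
    trained_config: dict
    training_log: tuple[float, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        for name, v in self.vectors.items():
            if v.shape != (self.dim,) or not np.all(np.isfinite(v)):
                raise DataValidationError(f"bad embedding vector for {name!r}")

    def to_tsv(self, path: str | Path) -> None:
        rows = {h: self.vectors[h] for h in sorted(self.vectors)}
        pd.DataFrame.from_dict(rows, orient="index").to_csv(
            path, sep="\t", header=[f"v{i}" for i in range(self.dim)]
        )


def _negative_table(g: nx.Graph, nodes: list[str], size: int = 100_000) -> np.ndarray:
    """Node indices laid out ∝ degree^0.75 for O(1) negative draws."""
    deg = np.array([g.degree(n) for n in nodes], dtype=float)
    p = deg**0.75
    p /= p.sum()
    counts = np.maximum(1, np.round(p * size)).astype(int)
    return np.repeat(np.arange(len(nodes)), counts)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 0.5 * (np.tanh(0.5 * np.clip(x, -30, 30)) + 1.0)


def line_embed(
    g: "MeshGraph | nx.Graph",
    dim: int = 64,
    order: str = "second",
    epochs: int = 1000,
    negatives: int = 5,
    lr: float = 0.025,
    seed: int = 0,
    batch_size: int = 1024,
    max_samples: int = 2_000_000,
) -> EmbeddingTable:
    """Embed a heading graph with the LINE objective.

    Each epoch draws ``|E|`` edges uniformly with replacement; for each
    edge (u, v) the model pushes σ(uᵀv′) toward 1 and, for ``negatives``
    nodes n sampled from degree^0.75, σ(uᵀn′) toward 0.  Second order
    (default) keeps separate context vectors v′; first order ties them to
    the node vectors.  The learning rate decays linearly.  Total edge
    samples are capped at ``max_samples``.

    Isolated nodes keep their (small) random initial vectors; downstream
    their similarity entries are masked undefined.
    """
    graph = g.graph if isinstance(g, MeshGraph) else g
    nodes = sorted(graph.nodes)
    edges = sorted(map(tuple, map(sorted, graph.edges())))
    if not edges:
        raise DegenerateInputError("cannot embed a graph with no edges")
    if order not in ("first", "second"):
        raise DataValidationError(f"order must be 'first' or 'second', got {order!r}")

    pos = {n: i for i, n in enumerate(nodes)}
    edge_idx = np.array([(pos[a], pos[b]) for a, b in edges], dtype=np.int64)
    rng = np.random.default_rng(seed)
    n = len(nodes)
    U = (rng.random((n, dim)) - 0.5) / dim
    C = (rng.random((n, dim)) - 0.5) / dim if order == "second" else U

    neg_table = _negative_table(graph, nodes)
    per_epoch = len(edges)
    total = min(epochs * per_epoch, max_samples)
    n_epochs = max(1, total // per_epoch)
    log = []
    step = 0
    for _ in range(n_epochs):
        # undirected: train each sampled edge in both directions
        sample = edge_idx[rng.integers(0, len(edges), size=per_epoch)]
        sample = np.concatenate([sample, sample[:, ::-1]])
        epoch_loss = 0.0
        for start in range(0, len(sample), batch_size):
            batch = sample[start:start + batch_size]
            src, dst = batch[:, 0], batch[:, 1]
            neg = neg_table[rng.integers(0, len(neg_table),
                                         size=(len(batch), negatives))]
            frac = step / max(1, 2 * n_epochs * ((per_epoch * 2 - 1) // batch_size + 1))
            eta = lr * max(1e-4, 1.0 - frac)
            step += 2

            u = U[src]                                   # (B, d)
            ctx = np.concatenate([dst[:, None], neg], axis=1)   # (B, 1+K)
            c = C[ctx]                                   # (B, 1+K, d)
            score = np.einsum("bd,bkd->bk", u, c)
            label = np.zeros_like(score)
            label[:, 0] = 1.0
            sig = _sigmoid(score)
            epoch_loss += float(
                -np.log(np.clip(sig[:, 0], 1e-12, None)).sum()
                - np.log(np.clip(1 - sig[:, 1:], 1e-12, None)).sum()
            )
            err = sig - label                            # (B, 1+K)
            grad_u = np.einsum("bk,bkd->bd", err, c)
            grad_c = err[:, :, None] * u[:, None, :]
            np.add.at(U, src, -eta * grad_u)
            np.add.at(C, ctx.ravel(), -eta * grad_c.reshape(-1, dim))
        log.append(epoch_loss / (2 * per_epoch))

    vectors = {name: U[i].copy() for i, name in enumerate(nodes)}
    return EmbeddingTable(
        vectors=vectors,
        dim=dim,
        trained_config={
            "order": order, "epochs": n_epochs, "negatives": negatives,
            "lr": lr, "seed": seed,
        },
        training_log=tuple(log),
    )


def embedding_similarity(emb: EmbeddingTable, a: str, b: str) -> float | None:
    """Shifted cosine DM(a, b) = (cos+1)/2 ∈ [0,1]; None for zero vectors."""
    try:
        va, vb = emb.vectors[a], emb.vectors[b]
    except KeyError as e:
        raise EntityLookupError(f"heading {e.args[0]!r} has no embedding") from None
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na == 0.0 or nb == 0.0:
        return None
    if a == b:
        return 1.0
    return float(np.clip((va @ vb / (na * nb) + 1.0) / 2.0, 0.0, 1.0))


def embedding_similarity_matrix(
    emb: EmbeddingTable, index: tuple[str, ...]
) -> SimilarityMatrix:
    """Assemble DM over a disease index; diseases without an embedding
    (or with a zero vector) get undefined entries."""
    n = len(index)
    values = np.full((n, n), np.nan)
    mask = np.zeros((n, n), dtype=bool)
    have = [i for i, name in enumerate(index)
            if name in emb.vectors and np.linalg.norm(emb.vectors[name]) > 0]
    if have:
        V = np.stack([emb.vectors[index[i]] for i in have])
        V = V / np.linalg.norm(V, axis=1, keepdims=True)
        block = np.clip((V @ V.T + 1.0) / 2.0, 0.0, 1.0)
        np.fill_diagonal(block, 1.0)
        values[np.ix_(have, have)] = block
        mask[np.ix_(have, have)] = True
    return SimilarityMatrix(values=values, index=tuple(index),
                            kind="mesh_embedding", mask=mask)
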
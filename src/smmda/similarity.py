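"""The three similarity families feeding the fusion step.

* Gaussian interaction-profile (GIP) kernels on both axes of the
  association matrix: ``K(x, y) = exp(-δ‖p(x) − p(y)‖²)`` where ``p`` is
  an entity's 0/1 interaction profile and the bandwidth δ is normalized
  by the mean squared profile norm.
* Disease semantic similarity over MeSH-derived DAGs: each ancestor of a
  disease contributes Δ^generations to its semantic value, and two
  diseases are similar in proportion to the contribution mass of their
  shared ancestors.
* miRNA functional similarity as the best-match average (BMA) of the
  semantic similarities between the two miRNAs' associated disease sets
  — or loaded from a precomputed matrix.

Similarity matrices carry an explicit per-entry "defined" mask: the
fusion cascade later falls back from sparse, partially-defined sources
(functional, semantic, embedding) to the always-defined GIP kernels.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist

from .core_data import AssociationMatrix, canonical_name
from .errors import (
    DataValidationError,
    DegenerateInputError,
    EntityLookupError,
    InvalidDAGError,
)

__all__ = [
    "SimilarityMatrix",
    "DiseaseDAG",
    "SemanticProfile",
    "SemanticConfig",
    "gip_bandwidth",
    "gip_similarity",
    "semantic_profile",
    "semantic_similarity",
    "semantic_similarity_matrix",
    "functional_similarity",
    "load_functional_similarity",
]

SYMMETRY_TOL = 1e-9

#: kinds with a defined-diagonal-equals-one contract
_UNIT_DIAG_KINDS = {"gip_mirna", "gip_disease", "semantic", "mesh_embedding"}


@dataclass(frozen=True)
class SimilarityMatrix:
    """Square, labelled, symmetric similarity matrix with a defined-mask.

    ``mask[i, j]`` is True where the entry is defined; undefined entries
    hold NaN in ``values`` and are resolved later by the fusion cascade.
    """

    values: np.ndarray
    index: tuple[str, ...]
    kind: str
    mask: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.index)
        if self.values.shape != (n, n) or self.mask.shape != (n, n):
            raise DataValidationError(
                f"{self.kind}: shape {self.values.shape} does not match index ({n})"
            )
        both = self.mask & self.mask.T
        v = np.where(both, self.values, 0.0)
        if not np.allclose(v, v.T, atol=SYMMETRY_TOL, rtol=0):
            raise DataValidationError(f"{self.kind}: matrix is not symmetric")
        defined = self.values[self.mask]
        if defined.size and (np.nanmin(defined) < -SYMMETRY_TOL or np.nanmax(defined) > 1 + SYMMETRY_TOL):
            raise DataValidationError(f"{self.kind}: defined entries outside [0, 1]")
        if self.kind in _UNIT_DIAG_KINDS:
            diag_defined = np.diag(self.mask)
            if not np.allclose(np.diag(self.values)[diag_defined], 1.0, atol=SYMMETRY_TOL):
                raise DataValidationError(f"{self.kind}: defined diagonal must be 1")

    @classmethod
    def total(cls, values: np.ndarray, index: tuple[str, ...], kind: str) -> "SimilarityMatrix":
        """A fully-defined matrix (mask all True)."""
        return cls(values=values, index=tuple(index), kind=kind,
                   mask=np.ones_like(values, dtype=bool))

    @property
    def is_total(self) -> bool:
        return bool(self.mask.all())

    def pos(self, name: str) -> int:
        try:
            return self.index.index(name)
        except ValueError:
            raise EntityLookupError(f"{name!r} not in {self.kind} index") from None

    def to_tsv(self, path: str | Path, mask_path: str | Path | None = None) -> None:
        pd.DataFrame(self.values, index=list(self.index), columns=list(self.index)).to_csv(
            path, sep="\t")
        if mask_path is not None:
            pd.DataFrame(self.mask.astype(int), index=list(self.index),
                         columns=list(self.index)).to_csv(mask_path, sep="\t")


def gip_bandwidth(profiles: np.ndarray, form: str = "reciprocal") -> float:
    """Bandwidth δ of the GIP kernel from a stack of 0/1 profiles.

    The mean squared profile norm ``s = (1/m) Σ‖pᵢ‖²`` normalizes a unit
    raw bandwidth: δ = 1/s (``form="reciprocal"``, the conventional GIP
    normalization).  ``form="printed"`` instead returns δ = s, the
    non-reciprocal variant in which the kernel narrows as the network
    densifies.
    """
    profiles = np.asarray(profiles, dtype=float)
    if profiles.ndim != 2 or profiles.shape[0] == 0:
        raise DegenerateInputError("need at least one profile")
    mean_sq = float(np.mean(np.sum(profiles**2, axis=1)))
    if mean_sq == 0.0:
        raise DegenerateInputError("all profiles are zero; GIP bandwidth undefined")
    if form == "reciprocal":
        return 1.0 / mean_sq
    if form == "printed":
        return mean_sq
    raise DataValidationError(f"unknown bandwidth form {form!r}")


def gip_similarity(
    A: AssociationMatrix, axis: str, *, bandwidth_form: str = "reciprocal"
) -> SimilarityMatrix:
    """GIP kernel matrix over one axis of the association matrix.

    ``axis="mirna"`` uses the columns of A (each miRNA's disease profile);
    ``axis="disease"`` the rows.  The result is total: the cascade's
    terminal fallback.
    """
    if axis == "mirna":
        profiles, index, kind = A.values.T, A.mirna_index, "gip_mirna"
    elif axis == "disease":
        profiles, index, kind = A.values, A.disease_index, "gip_disease"
    else:
        raise DataValidationError(f"axis must be 'mirna' or 'disease', got {axis!r}")
    delta = gip_bandwidth(profiles, form=bandwidth_form)
    sq = squareform(pdist(profiles.astype(float), metric="sqeuclidean"))
    K = np.exp(-delta * sq)
    np.fill_diagonal(K, 1.0)
    return SimilarityMatrix.total(K, tuple(index), kind)


@dataclass(frozen=True)
class SemanticConfig:
    """Semantic contribution factor Δ: each generation of ancestry
    contributes a factor Δ less.  Conventional default 0.5."""

    delta: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 < self.delta < 1.0):
            raise DataValidationError(f"delta must lie in (0, 1), got {self.delta}")


@dataclass(frozen=True)
class DiseaseDAG:
    """A disease D with its ancestor closure T(D) and child→parent edges."""

    disease: str
    nodes: frozenset[str]
    edges: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        if self.disease not in self.nodes:
            raise InvalidDAGError(f"{self.disease!r} missing from its own node set")
        for c, p in self.edges:
            if c not in self.nodes or p not in self.nodes:
                raise InvalidDAGError(f"edge {(c, p)!r} references unknown node")

    def parents(self, node: str) -> list[str]:
        return sorted(p for c, p in self.edges if c == node)

    def children(self, node: str) -> list[str]:
        return sorted(c for c, p in self.edges if p == node)


@dataclass(frozen=True)
class SemanticProfile:
    """Per-ancestor semantic contributions DD and their sum DV(D)."""

    disease: str
    contributions: Mapping[str, float]
    dv: float


def semantic_profile(dag: DiseaseDAG, cfg: SemanticConfig) -> SemanticProfile:
    """Semantic contributions of every node of DAG(D) to disease D.

    DD(D) = 1; for an ancestor d, DD(d) = max over its children d′ inside
    the DAG of Δ·DD(d′) — i.e. Δ^(shortest generation distance from D).
    DV(D) is the sum of all contributions.  Raises on cyclic input.
    """
    delta = cfg.delta
    memo: dict[str, float] = {dag.disease: 1.0}
    in_progress: set[str] = set()

    def dd(node: str) -> float:
        if node in memo:
            return memo[node]
        if node in in_progress:
            raise InvalidDAGError(f"cycle detected through node {node!r}")
        in_progress.add(node)
        children = dag.children(node)
        if not children:
            raise InvalidDAGError(
                f"node {node!r} is unreachable from {dag.disease!r} (no children in DAG)"
            )
        value = max(delta * dd(c) for c in children)
        in_progress.discard(node)
        memo[node] = value
        return value

    contributions = {node: dd(node) for node in sorted(dag.nodes)}
    return SemanticProfile(
        disease=dag.disease,
        contributions=contributions,
        dv=float(sum(contributions.values())),
    )


def semantic_similarity(pa: SemanticProfile, pb: SemanticProfile) -> float:
    """Shared-ancestor similarity: contribution mass of T(a)∩T(b) over DV(a)+DV(b)."""
    shared = pa.contributions.keys() & pb.contributions.keys()
    if not shared:
        return 0.0
    num = sum(pa.contributions[t] + pb.contributions[t] for t in shared)
    # the ratio is <= 1 analytically; clamp float roundoff
    return min(1.0, float(num / (pa.dv + pb.dv)))


def semantic_similarity_matrix(
    dags: Mapping[str, DiseaseDAG],
    index: tuple[str, ...],
    cfg: SemanticConfig | None = None,
) -> SimilarityMatrix:
    """Pairwise semantic similarity over a disease index.

    Diseases without a DAG get fully undefined rows/columns (mask False),
    which the fusion cascade later resolves via the GIP kernel.
    """
    cfg = cfg or SemanticConfig()
    n = len(index)
    profiles = {d: semantic_profile(dags[d], cfg) for d in index if d in dags}
    values = np.full((n, n), np.nan)
    mask = np.zeros((n, n), dtype=bool)
    names = [d for d in index if d in profiles]
    pos = {d: i for i, d in enumerate(index)}
    for a_i, a in enumerate(names):
        ia = pos[a]
        values[ia, ia] = 1.0
        mask[ia, ia] = True
        for b in names[a_i + 1:]:
            ib = pos[b]
            s = semantic_similarity(profiles[a], profiles[b])
            values[ia, ib] = values[ib, ia] = s
            mask[ia, ib] = mask[ib, ia] = True
    return SimilarityMatrix(values=values, index=tuple(index), kind="semantic", mask=mask)


def functional_similarity(
    mirna_diseases: Mapping[str, frozenset[str] | set[str]],
    DS: SimilarityMatrix,
) -> SimilarityMatrix:
    """miRNA functional similarity by best-match averaging (BMA).

    For disease sets D1, D2 of the two miRNAs::

        MF(m1, m2) = (Σ_{d∈D1} max_{d'∈D2} DS(d, d')
                      + Σ_{d∈D2} max_{d'∈D1} DS(d, d')) / (|D1| + |D2|)

    miRNAs with an empty disease set get undefined (masked) entries —
    including their own diagonal — so the fusion step falls back to the
    GIP kernel for them.
    """
    mirnas = tuple(sorted(mirna_diseases))
    ds_pos = {d: i for i, d in enumerate(DS.index)}
    dsets: dict[str, list[int]] = {}
    for m, diseases in mirna_diseases.items():
        idx = []
        for d in diseases:
            if d not in ds_pos:
                raise EntityLookupError(f"disease {d!r} of miRNA {m!r} not in DS index")
            idx.append(ds_pos[d])
        dsets[m] = sorted(idx)

    n = len(mirnas)
    values = np.full((n, n), np.nan)
    mask = np.zeros((n, n), dtype=bool)
    S = DS.values
    for i, m1 in enumerate(mirnas):
        a = dsets[m1]
        if not a:
            continue
        values[i, i] = 1.0
        mask[i, i] = True
        for j in range(i + 1, n):
            b = dsets[mirnas[j]]
            if not b:
                continue
            block = S[np.ix_(a, b)]
            bma = (block.max(axis=1).sum() + block.max(axis=0).sum()) / (len(a) + len(b))
            values[i, j] = values[j, i] = float(bma)
            mask[i, j] = mask[j, i] = True
    return SimilarityMatrix(values=values, index=mirnas, kind="functional", mask=mask)


def load_functional_similarity(
    path: str | Path, index: tuple[str, ...]
) -> SimilarityMatrix:
    """Load a precomputed square labelled functional-similarity TSV.

    The matrix is reindexed to the run's miRNA index; miRNAs absent from
    the file get undefined rows/columns.  Asymmetry beyond tolerance is a
    validation error.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = [canonical_name(str(x)) for x in df.index]
    df.columns = [canonical_name(str(x)) for x in df.columns]
    if list(df.index) != list(df.columns):
        raise DataValidationError(f"{path}: row and column labels differ")
    raw = df.to_numpy(dtype=float)
    if not np.allclose(raw, raw.T, atol=1e-6, rtol=0):
        raise DataValidationError(f"{path}: matrix is not symmetric")
    raw = (raw + raw.T) / 2.0

    n = len(index)
    values = np.full((n, n), np.nan)
    mask = np.zeros((n, n), dtype=bool)
    file_pos = {name: i for i, name in enumerate(df.index)}
    covered = [(i, file_pos[name]) for i, name in enumerate(index) if name in file_pos]
    if covered:
        ours, theirs = map(list, zip(*covered))
        values[np.ix_(ours, ours)] = raw[np.ix_(theirs, theirs)]
        mask[np.ix_(ours, ours)] = True
    return SimilarityMatrix(values=values, index=tuple(index), kind="functional", mask=mask)
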
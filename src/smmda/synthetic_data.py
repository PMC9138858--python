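"""A fully synthetic miRNA–disease world with planted low-rank structure.

Both the association matrix and the similarity surrogates derive from
the same latent factors, mirroring the guilt-by-association premise of
the predictor: miRNAs (rows of U) and diseases (rows of V) live in a
shared r-dimensional space; the probability of a link is
``σ(α + uᵢ·vⱼ)`` with the intercept α calibrated so the realized
density matches a target.  The functional-similarity surrogate is the
shifted cosine of U rows (restricted to a coverage fraction), and the
MeSH-like disease forest is grown by similarity-guided attachment in V,
so the semantic and embedding features genuinely carry signal about
held-out links.

Coverage knobs deliberately leave gaps: miRNAs outside ``mf_coverage``
lack functional similarity, diseases outside ``dag_coverage`` lack a
semantic DAG, and only ``dm_coverage`` of the DAG-covered diseases are
exported to the MeSH descriptor table — so every branch of both fusion
cascades is exercised.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

from .core_data import (
    AssociationList,
    AssociationMatrix,
    MeshDescriptorTable,
    write_association_list,
    write_mesh_descriptors,
)
from .errors import DataValidationError, DegenerateInputError
from .similarity import DiseaseDAG, SimilarityMatrix

__all__ = ["SyntheticWorld", "generate_world", "holdout_split", "write_world"]


@dataclass(frozen=True)
class SyntheticWorld:
    """Latent factors plus every input the pipeline consumes."""

    U: np.ndarray
    V: np.ndarray
    associations: AssociationMatrix
    mesh_table: MeshDescriptorTable
    dags: dict[str, DiseaseDAG]
    MF: SimilarityMatrix
    params: dict
    seed: int

    @property
    def mirnas(self) -> tuple[str, ...]:
        return self.associations.mirna_index

    @property
    def diseases(self) -> tuple[str, ...]:
        return self.associations.disease_index


def _calibrate_intercept(logits: np.ndarray, density: float) -> float:
    """Bisection for α with mean σ(α + logits) = density."""

    def excess(alpha: float) -> float:
        return float(np.mean(expit(alpha + logits))) - density

    lo, hi = -50.0, 50.0
    if excess(lo) > 0 or excess(hi) < 0:
        raise DegenerateInputError(f"density {density} is not attainable")
    return float(brentq(excess, lo, hi, xtol=1e-10))


def _grow_forest(
    diseases: list[str], V: np.ndarray, pos: dict[str, int],
    rng: np.random.Generator, n_roots: int = 3, guidance: float = 12.0,
) -> dict[str, str]:
    """Tree number per disease: roots C01..C0k, then similarity-guided
    attachment (parent sampled ∝ exp(guidance·cosine in V))."""
    order = list(diseases)
    rng.shuffle(order)
    Vn = V / np.maximum(np.linalg.norm(V, axis=1, keepdims=True), 1e-12)
    numbers: dict[str, str] = {}
    child_count: dict[str, int] = {}
    placed: list[str] = []
    for i, d in enumerate(order):
        if i < n_roots:
            numbers[d] = f"C{i + 1:02d}"
        else:
            sims = Vn[[pos[p] for p in placed]] @ Vn[pos[d]]
            w = np.exp(guidance * (sims - sims.max()))
            parent = placed[rng.choice(len(placed), p=w / w.sum())]
            k = child_count.get(parent, 0) + 1
            child_count[parent] = k
            numbers[d] = f"{numbers[parent]}.{k}"
        placed.append(d)
    return numbers


def _withhold_leaves(
    numbers: dict[str, str], keep: int, rng: np.random.Generator
) -> list[str]:
    """Shrink the forest to ``keep`` diseases by repeatedly dropping a
    random current leaf, so the survivors stay closed under tree-number
    parenthood (every remaining non-root keeps its parent)."""
    remaining = dict(numbers)
    while len(remaining) > keep:
        tns = set(remaining.values())
        leaves = sorted(
            d for d, tn in remaining.items()
            if not any(other != tn and other.startswith(tn + ".") for other in tns)
        )
        remaining.pop(leaves[rng.integers(len(leaves))])
    return sorted(remaining)


def _dag_from_chain(disease: str, tree_number: str,
                    owner_of: dict[str, str]) -> DiseaseDAG:
    """Ancestor chain of one tree number as a child→parent DAG."""
    nodes = {disease}
    edges = set()
    child_heading, tn = disease, tree_number
    while "." in tn:
        tn = tn.rsplit(".", 1)[0]
        parent_heading = owner_of[tn]
        nodes.add(parent_heading)
        edges.add((child_heading, parent_heading))
        child_heading = parent_heading
    return DiseaseDAG(disease=disease, nodes=frozenset(nodes),
                      edges=frozenset(edges))


def generate_world(
    nm: int = 120,
    nd: int = 90,
    r: int = 5,
    density: float = 0.07,
    mf_coverage: float = 0.6,
    dm_coverage: float = 0.7,
    dag_coverage: float = 0.9,
    seed: int = 3,
) -> SyntheticWorld:
    """Sample a synthetic world.

    Parameters mirror the study conditions of the evaluation: 120
    miRNAs × 90 diseases, rank-5 latent factors, 7% link density, 60%
    functional-similarity coverage, MeSH-table coverage 70% (of all
    diseases, drawn from the 90% that have DAGs).

    Raises if the requested density is unattainable or the counts are
    too small (nm, nd ≥ 4; 0 < density < 0.5).
    """
    if nm < 4 or nd < 4:
        raise DataValidationError("need at least 4 miRNAs and 4 diseases")
    if not (0.0 < density < 0.5):
        raise DataValidationError("density must lie in (0, 0.5)")
    for name, frac in (("mf_coverage", mf_coverage),
                       ("dm_coverage", dm_coverage),
                       ("dag_coverage", dag_coverage)):
        if not (0.0 <= frac <= 1.0):
            raise DataValidationError(f"{name} must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    mirnas = [f"mir-{i:04d}" for i in range(nm)]
    diseases = [f"disease-{j:04d}" for j in range(nd)]

    U = rng.standard_normal((nm, r))
    V = rng.standard_normal((nd, r))
    logits = U @ V.T  # (nm, nd)
    alpha = _calibrate_intercept(logits.ravel(), density)
    A_mat = (rng.random((nm, nd)) < expit(alpha + logits)).astype(np.int8)
    if not A_mat.any():
        raise DegenerateInputError("sampled world has no associations")
    # zero-padded names sort lexicographically in construction order, so the
    # full nm×nd matrix (including link-free entities) keeps a sorted index
    associations = AssociationMatrix(
        values=A_mat.T, disease_index=tuple(diseases), mirna_index=tuple(mirnas)
    )

    # MeSH-like forest over the DAG-covered diseases
    d_pos = {d: j for j, d in enumerate(diseases)}
    n_dag = int(round(dag_coverage * nd))
    dag_diseases = sorted(rng.choice(diseases, size=n_dag, replace=False).tolist())
    numbers = _grow_forest(dag_diseases, V, d_pos, rng)
    owner_of = {tn: d for d, tn in numbers.items()}
    dags = {d: _dag_from_chain(d, numbers[d], owner_of) for d in dag_diseases}

    n_mesh = min(int(round(dm_coverage * nd)), n_dag)
    mesh_diseases = _withhold_leaves(numbers, n_mesh, rng)
    mesh_table = MeshDescriptorTable(
        records=tuple((d, (numbers[d],)) for d in mesh_diseases)
    )

    # functional-similarity surrogate: shifted cosine of U rows, partial coverage
    n_mf = int(round(mf_coverage * nm))
    covered = sorted(rng.choice(nm, size=n_mf, replace=False).tolist())
    Un = U / np.maximum(np.linalg.norm(U, axis=1, keepdims=True), 1e-12)
    mirna_order = associations.mirna_index
    orig = {m: i for i, m in enumerate(mirnas)}
    covered_names = {mirnas[i] for i in covered}
    n_idx = len(mirna_order)
    mf_values = np.full((n_idx, n_idx), np.nan)
    mf_mask = np.zeros((n_idx, n_idx), dtype=bool)
    cov_idx = [k for k, m in enumerate(mirna_order) if m in covered_names]
    if cov_idx:
        rows = [orig[mirna_order[k]] for k in cov_idx]
        block = np.clip((Un[rows] @ Un[rows].T + 1.0) / 2.0, 0.0, 1.0)
        np.fill_diagonal(block, 1.0)
        mf_values[np.ix_(cov_idx, cov_idx)] = block
        mf_mask[np.ix_(cov_idx, cov_idx)] = True
    MF = SimilarityMatrix(values=mf_values, index=mirna_order,
                          kind="functional", mask=mf_mask)

    return SyntheticWorld(
        U=U, V=V, associations=associations, mesh_table=mesh_table, dags=dags,
        MF=MF,
        params={
            "nm": nm, "nd": nd, "r": r, "density": density,
            "mf_coverage": mf_coverage, "dm_coverage": dm_coverage,
            "dag_coverage": dag_coverage,
        },
        seed=seed,
    )


def holdout_split(
    world: SyntheticWorld, fraction: float, seed: int
) -> tuple[AssociationList, tuple[tuple[str, str], ...]]:
    """Hide a fraction of the known positives for link-recovery tests.

    Returns the retained training associations and the hidden positive
    pairs (disjoint by construction).
    """
    if not (0.0 <= fraction < 1.0):
        raise DataValidationError("holdout fraction must lie in [0, 1)")
    positives = world.associations.positive_pairs()
    n_hide = int(round(fraction * len(positives)))
    if fraction > 0 and n_hide == 0:
        raise DegenerateInputError("fraction too small to hide any positive")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(positives))
    hidden = tuple(positives[k] for k in sorted(order[:n_hide]))
    retained = [positives[k] for k in sorted(order[n_hide:])]
    if not retained:
        raise DegenerateInputError("holdout would remove every positive")
    return AssociationList.from_pairs(retained), hidden


def write_world(world: SyntheticWorld, directory: str | Path) -> dict[str, Path]:
    """Export the world in the formats the loaders read: association
    TSV, MeSH descriptor TSV, functional-similarity TSV (+ mask)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "associations": directory / "associations.tsv",
        "mesh": directory / "mesh_descriptors.tsv",
        "mf": directory / "functional_similarity.tsv",
        "mf_mask": directory / "functional_similarity.mask.tsv",
    }
    write_association_list(
        AssociationList.from_pairs(world.associations.positive_pairs()),
        paths["associations"],
    )
    write_mesh_descriptors(world.mesh_table, paths["mesh"])
    import pandas as pd

    covered = world.MF.mask.any(axis=0)
    names = [m for m, c in zip(world.MF.index, covered) if c]
    idx = [k for k, c in enumerate(covered) if c]
    pd.DataFrame(world.MF.values[np.ix_(idx, idx)], index=names,
                 columns=names).to_csv(paths["mf"], sep="\t")
    pd.DataFrame(world.MF.mask.astype(int), index=list(world.MF.index),
                 columns=list(world.MF.index)).to_csv(paths["mf_mask"], sep="\t")
    return paths
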
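"""End-to-end orchestration: inputs → fused features → CV evaluation.

Shared by the command-line interface and the evaluation scripts.  The
similarity stages (GIP kernels, semantic matrix, MeSH embedding, fusion)
are pure functions of the association matrix and the side inputs, so
they are computed once; the autoencoder and classifier are re-fit per
cross-validation fold by :func:`smmda.classifier_eval.cross_validate`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .classifier_eval import CVConfig, cross_validate, sample_negatives
from .core_data import AssociationMatrix, MeshDescriptorTable
from .errors import DegenerateInputError
from .fusion import FusedFeatureMatrix, PairDataset, fuse_disease, fuse_mirna, pair_features
from .mesh_embedding import build_mesh_graph, embedding_similarity_matrix, line_embed
from .similarity import (
    DiseaseDAG,
    SemanticConfig,
    SimilarityMatrix,
    gip_similarity,
    semantic_similarity_matrix,
)

__all__ = ["LineConfig", "PipelineConfig", "build_feature_matrices",
           "build_pair_dataset", "evaluate"]


@dataclass(frozen=True)
class LineConfig:
    # first-order proximity: the MeSH relational network is tree-like (no
    # triangles), where second-order proximity degenerates
    dim: int = 64
    order: str = "first"
    epochs: int = 1000
    negatives: int = 5
    lr: float = 0.025
    seed: int = 0


@dataclass(frozen=True)
class PipelineConfig:
    """Every tunable of the end-to-end run, serializable for provenance."""

    semantic: SemanticConfig = field(default_factory=SemanticConfig)
    line: LineConfig = field(default_factory=LineConfig)
    cv: CVConfig = field(default_factory=CVConfig)
    bandwidth_form: str = "reciprocal"
    seed: int = 0

    def as_dict(self) -> dict:
        from dataclasses import asdict

        return asdict(self)


def build_feature_matrices(
    A: AssociationMatrix,
    mesh_table: MeshDescriptorTable | None,
    dags: Mapping[str, DiseaseDAG] | None,
    MF: SimilarityMatrix | None,
    config: PipelineConfig | None = None,
) -> tuple[FusedFeatureMatrix, FusedFeatureMatrix]:
    """Compute MFM and DFM from the association matrix and side inputs.

    Missing side inputs simply leave their similarity source fully
    undefined, so the fusion cascade falls back to the GIP kernels.
    """
    config = config or PipelineConfig()
    GM = gip_similarity(A, "mirna", bandwidth_form=config.bandwidth_form)
    GD = gip_similarity(A, "disease", bandwidth_form=config.bandwidth_form)

    n_d = len(A.disease_index)
    undefined_d = SimilarityMatrix(
        values=np.full((n_d, n_d), np.nan), index=A.disease_index,
        kind="mesh_embedding", mask=np.zeros((n_d, n_d), dtype=bool),
    )
    if mesh_table is not None and len(mesh_table) > 0:
        graph = build_mesh_graph(mesh_table)
        try:
            emb = line_embed(
                graph, dim=config.line.dim, order=config.line.order,
                epochs=config.line.epochs, negatives=config.line.negatives,
                lr=config.line.lr, seed=config.line.seed,
            )
            DM = embedding_similarity_matrix(emb, A.disease_index)
        except DegenerateInputError:  # edgeless graph: no embedding feature
            DM = undefined_d
    else:
        DM = undefined_d

    if dags:
        DS = semantic_similarity_matrix(dags, A.disease_index, config.semantic)
    else:
        DS = SimilarityMatrix(
            values=np.full((n_d, n_d), np.nan), index=A.disease_index,
            kind="semantic", mask=np.zeros((n_d, n_d), dtype=bool),
        )

    if MF is None:
        n_m = len(A.mirna_index)
        MF = SimilarityMatrix(
            values=np.full((n_m, n_m), np.nan), index=A.mirna_index,
            kind="functional", mask=np.zeros((n_m, n_m), dtype=bool),
        )

    MFM = fuse_mirna(MF, GM)
    DFM = fuse_disease(DM, DS, GD)
    return MFM, DFM


def build_pair_dataset(
    A: AssociationMatrix,
    MFM: FusedFeatureMatrix,
    DFM: FusedFeatureMatrix,
    seed: int = 0,
    n_negatives: int | None = None,
) -> PairDataset:
    """Positive pairs from the association matrix plus an equal number
    (by default) of uniformly sampled unobserved pairs as negatives."""
    positives = A.positive_pairs()
    n_neg = len(positives) if n_negatives is None else n_negatives
    negatives = sample_negatives(A, n_neg, seed=seed)
    pairs = positives + list(negatives.pairs)
    labels = [1] * len(positives) + [0] * len(negatives.pairs)
    return pair_features(MFM, DFM, pairs, labels)


def evaluate(
    A: AssociationMatrix,
    mesh_table: MeshDescriptorTable | None,
    dags: Mapping[str, DiseaseDAG] | None,
    MF: SimilarityMatrix | None,
    config: PipelineConfig | None = None,
):
    """Full pipeline: features → pair dataset → k-fold CV.

    Returns (fold metrics, summary, provenance, MFM, DFM, dataset).
    """
    config = config or PipelineConfig()
    MFM, DFM = build_feature_matrices(A, mesh_table, dags, MF, config)
    ds = build_pair_dataset(A, MFM, DFM, seed=config.seed)
    folds, summary, provenance = cross_validate(ds, config.cv, seed=config.seed)
    return folds, summary, provenance, MFM, DFM, ds
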
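"""Piecewise fusion of the similarity sources into total feature matrices.

The miRNA feature matrix MFM prefers functional similarity and falls
back to the GIP kernel where it is undefined::

    MFM(mi, mj) = MF(mi, mj)  if defined, else  GM(mi, mj)

The disease feature matrix DFM cascades through three sources::

    DFM(di, dj) = DM  if both have a MeSH embedding,
                  DS  else if both have semantic DAGs,
                  GD  otherwise

The GIP kernels are total, so the cascades always terminate; a per-entry
``source_map`` records which branch fired.  Per-pair feature vectors are
the concatenation of the miRNA's MFM row with the disease's DFM row.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import AlignmentError, DataValidationError, EntityLookupError
from .similarity import SimilarityMatrix

__all__ = ["FusedFeatureMatrix", "PairDataset", "fuse_mirna", "fuse_disease",
           "pair_features"]


@dataclass(frozen=True)
class FusedFeatureMatrix:
    """Total square feature matrix plus per-entry source tags."""

    values: np.ndarray
    index: tuple[str, ...]
    source_map: np.ndarray  # dtype '<U2' entries like "MF", "GM", "DM", "DS", "GD"

    def __post_init__(self) -> None:
        n = len(self.index)
        if self.values.shape != (n, n) or self.source_map.shape != (n, n):
            raise DataValidationError("fused matrix shape mismatch")
        if np.isnan(self.values).any():
            raise DataValidationError("fused matrix contains undefined entries")

    def pos(self, name: str) -> int:
        try:
            return self.index.index(name)
        except ValueError:
            raise EntityLookupError(f"{name!r} not in fused index") from None

    def source_counts(self) -> dict[str, int]:
        tags, counts = np.unique(self.source_map, return_counts=True)
        return dict(zip(tags.tolist(), counts.tolist()))


def _cascade(layers: Sequence[tuple[str, SimilarityMatrix]]) -> FusedFeatureMatrix:
    index = layers[0][1].index
    for _, sm in layers[1:]:
        if sm.index != index:
            raise AlignmentError(
                f"{sm.kind} index does not match {layers[0][1].kind} index"
            )
    if not layers[-1][1].is_total:
        raise AlignmentError(
            f"terminal layer {layers[-1][0]} must be total (GIP kernel)"
        )
    n = len(index)
    values = np.full((n, n), np.nan)
    source = np.full((n, n), "", dtype="<U2")
    unresolved = np.ones((n, n), dtype=bool)
    for tag, sm in layers:
        take = unresolved & sm.mask
        values[take] = sm.values[take]
        source[take] = tag
        unresolved &= ~take
    return FusedFeatureMatrix(values=values, index=index, source_map=source)


def fuse_mirna(MF: SimilarityMatrix, GM: SimilarityMatrix) -> FusedFeatureMatrix:
    """MFM: functional similarity where defined, GIP kernel elsewhere."""
    return _cascade([("MF", MF), ("GM", GM)])


def fuse_disease(
    DM: SimilarityMatrix, DS: SimilarityMatrix, GD: SimilarityMatrix
) -> FusedFeatureMatrix:
    """DFM: MeSH-embedding similarity, then semantic, then GIP kernel."""
    return _cascade([("DM", DM), ("DS", DS), ("GD", GD)])


@dataclass(frozen=True)
class PairDataset:
    """Per-(miRNA, disease) feature rows with 0/1 labels.

    ``block_spec`` records the widths of the miRNA and disease feature
    blocks so consumers (e.g. the autoencoder) are self-describing.
    """

    features: np.ndarray
    labels: np.ndarray
    pair_ids: tuple[tuple[str, str], ...]
    block_spec: tuple[int, int]

    def __post_init__(self) -> None:
        n = len(self.pair_ids)
        if self.features.shape[0] != n or self.labels.shape != (n,):
            raise DataValidationError("pair dataset row-count mismatch")
        if self.features.shape[1] != sum(self.block_spec):
            raise DataValidationError("feature width does not match block_spec")
        if not np.isin(self.labels, (0, 1)).all():
            raise DataValidationError("labels must be 0/1")

    def __len__(self) -> int:
        return len(self.pair_ids)

    def subset(self, idx: np.ndarray) -> "PairDataset":
        return PairDataset(
            features=self.features[idx],
            labels=self.labels[idx],
            pair_ids=tuple(self.pair_ids[i] for i in np.atleast_1d(idx)),
            block_spec=self.block_spec,
        )

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.features,
                          columns=[f"f{i}" for i in range(self.features.shape[1])])
        df.insert(0, "label", self.labels)
        df.insert(0, "disease", [d for _, d in self.pair_ids])
        df.insert(0, "mirna", [m for m, _ in self.pair_ids])
        df.to_csv(path, sep="\t", index=False)


def pair_features(
    MFM: FusedFeatureMatrix,
    DFM: FusedFeatureMatrix,
    pairs: Sequence[tuple[str, str]],
    labels: Sequence[int],
    *,
    zscore: bool = False,
) -> PairDataset:
    """Feature row for (m, d): [MFM row of m ‖ DFM row of d].

    Width is |miRNA index| + |disease index|.  ``zscore=True`` optionally
    standardizes columns (features are already in [0, 1]; off by default).
    """
    if len(pairs) != len(labels):
        raise DataValidationError("pairs and labels length mismatch")
    m_pos = {name: i for i, name in enumerate(MFM.index)}
    d_pos = {name: i for i, name in enumerate(DFM.index)}
    rows = np.empty((len(pairs), len(MFM.index) + len(DFM.index)), dtype=np.float64)
    for r, (m, d) in enumerate(pairs):
        if m not in m_pos:
            raise EntityLookupError(f"miRNA {m!r} not in MFM index")
        if d not in d_pos:
            raise EntityLookupError(f"disease {d!r} not in DFM index")
        rows[r, : len(MFM.index)] = MFM.values[m_pos[m]]
        rows[r, len(MFM.index):] = DFM.values[d_pos[d]]
    if zscore:
        sd = rows.std(axis=0)
        sd[sd == 0] = 1.0
        rows = (rows - rows.mean(axis=0)) / sd
    return PairDataset(
        features=rows,
        labels=np.asarray(labels, dtype=np.int8),
        pair_ids=tuple((m, d) for m, d in pairs),
        block_spec=(len(MFM.index), len(DFM.index)),
    )
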
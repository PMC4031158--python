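"""Mapping gene expression onto embedded pathway grids.

Gene-level measurements (log2 RNA-seq RPKM or normalized microarray
intensities) are averaged over the genes annotated to each reaction,
z-transformed per reaction across the analyzed samples, and laid out on
the pathway's lattice-grid embedding — one grid per sample.  Empty grid
cells and reactions without any measured gene carry 0, the z-score mean,
so they are neutral for low-pass wavelet features.

Order of operations: pseudocount/log2 (RNA-seq only) -> gene-to-reaction
mean -> z-transform -> grid layout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .embedding import GridEmbedding
from .network import PathwayNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "ExpressionGrid",
    "preprocess_rpkm",
    "collapse_probesets",
    "reaction_expression",
    "z_transform",
    "lay_out_grids",
]


@dataclass
class ExpressionMatrix:
    """Gene x sample expression with a two-class sample annotation.

    ``values``: DataFrame indexed by gene id, columns = sample ids, on a
    log2 (or otherwise variance-stabilized) scale.  ``class_labels`` maps
    every sample to one of exactly two condition labels; ``pairs``
    optionally maps samples to a pairing key for matched designs
    (e.g. tumor and adjacent normal tissue from the same patient).
    """

    values: pd.DataFrame
    class_labels: dict[str, str] = field(default_factory=dict)
    pairs: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dupes[:10]}")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def validate_two_classes(self) -> tuple[str, str]:
        """Check the two-class contract and return (class_a, class_b), sorted.

        Class A is the lexicographically first label; signs of class
        effects are reported as mean(A) - mean(B) throughout.
        """
        missing = [s for s in self.samples if s not in self.class_labels]
        if missing:
            raise ValueError(f"samples without class label: {missing}")
        classes = sorted(set(self.class_labels[s] for s in self.samples))
        if len(classes) != 2:
            raise ValueError(f"expected exactly two classes, found {classes}")
        return classes[0], classes[1]

    def label_vector(self) -> np.ndarray:
        """Boolean vector over samples: True for class A (first sorted label)."""
        a, _ = self.validate_two_classes()
        return np.array([self.class_labels[s] == a for s in self.samples])


@dataclass
class ExpressionGrid:
    """One sample's z-scored reaction expression on a pathway's grid."""

    pathway_id: str
    sample_id: str
    grid: np.ndarray

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if not np.all(np.isfinite(self.grid)):
            raise ValueError("expression grid contains non-finite values")


def preprocess_rpkm(values: pd.DataFrame) -> pd.DataFrame:
    """log2-transform RPKM values after adding a dataset-wide pseudocount.

    The pseudocount is the smallest non-zero value of the whole matrix, so
    zeros map to a finite floor without distorting well-measured genes.
    """
    arr = np.asarray(values, dtype=float)
    if np.any(arr < 0):
        raise ValueError("RPKM values must be non-negative")
    nonzero = arr[arr > 0]
    if nonzero.size == 0:
        raise ValueError("all-zero expression matrix: no pseudocount can be derived")
    pseudo = float(nonzero.min())
    out = np.log2(arr + pseudo)
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def collapse_probesets(
    probe_values: pd.DataFrame, probe_to_gene: dict[str, str | list[str]]
) -> pd.DataFrame:
    """Collapse microarray probesets to one profile per gene.

    Probesets mapping to more than one gene id are discarded; multiple
    probesets of the same gene are averaged (arithmetic mean per sample).
    Probesets absent from the mapping are dropped.
    """
    gene_of_probe: dict[str, str] = {}
    for probe, genes in probe_to_gene.items():
        if isinstance(genes, str):
            genes = [genes]
        genes = list(dict.fromkeys(genes))
        if len(genes) == 1:
            gene_of_probe[probe] = genes[0]
    kept = [p for p in probe_values.index if p in gene_of_probe]
    sub = probe_values.loc[kept]
    genes = pd.Index([gene_of_probe[p] for p in kept], name="gene")
    collapsed = sub.groupby(genes).mean()
    return collapsed


def reaction_expression(
    net: PathwayNetwork, expr: ExpressionMatrix
) -> tuple[pd.DataFrame, pd.Series]:
    """Reaction x sample expression: mean over each node's measured genes.

    Returns the matrix (NaN rows for unmeasured reactions) and a boolean
    Series flagging which reactions had at least one measured gene.
    """
    values = expr.values
    gene_index = values.index
    out = np.full((net.n_nodes, len(expr.samples)), np.nan)
    measured = np.zeros(net.n_nodes, dtype=bool)
    for i, node in enumerate(net.nodes):
        genes = [g for g in net.node_genes[node] if g in gene_index]
        if genes:
            out[i] = values.loc[genes].to_numpy(dtype=float).mean(axis=0)
            measured[i] = True
        else:
            logger.debug("pathway %s: node %s has no measured gene", net.pathway_id, node)
    return (
        pd.DataFrame(out, index=net.nodes, columns=expr.samples),
        pd.Series(measured, index=net.nodes, name="measured"),
    )


def z_transform(profiles: pd.DataFrame) -> pd.DataFrame:
    """z-score each row (reaction) across samples; sample sd (ddof=1).

    Constant rows map to all-zero rather than NaN so wavelet inputs stay
    finite; rows that are entirely NaN (unmeasured reactions) stay NaN and
    become 0 at grid layout.
    """
    if profiles.shape[1] < 2:
        raise ValueError("z-transform requires at least 2 samples")
    arr = profiles.to_numpy(dtype=float)
    mean = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, ddof=1, keepdims=True)
    # a constant row can still have sd > 0 from rounding of the mean;
    # detect constancy by zero range instead
    constant = (np.ptp(arr, axis=1, keepdims=True) == 0) | (sd == 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (arr - mean) / sd
    z[np.broadcast_to(constant, z.shape)] = 0.0
    return pd.DataFrame(z, index=profiles.index, columns=profiles.columns)


def lay_out_grids(
    net: PathwayNetwork, embedding: GridEmbedding, reaction_z: pd.DataFrame
) -> list[ExpressionGrid]:
    """Place per-reaction z-scores on the embedding, one grid per sample.

    Cell (r, c) carries the z-score of the node placed there; unoccupied
    cells and unmeasured reactions carry 0.
    """
    missing = [v for v in net.nodes if v not in embedding.placement]
    if missing:
        raise ValueError(f"embedding does not place nodes: {missing}")
    extra = [v for v in reaction_z.index if v not in embedding.placement]
    if extra:
        raise ValueError(f"expression rows without a grid position: {extra}")
    rows, cols = embedding.grid.rows, embedding.grid.cols
    z = reaction_z.to_numpy(dtype=float)
    grids = []
    for j, sample in enumerate(reaction_z.columns):
        g = np.zeros((rows, cols))
        for i, node in enumerate(reaction_z.index):
            val = z[i, j]
            if np.isfinite(val):
                r, c = embedding.placement[node]
                g[r, c] = val
        grids.append(ExpressionGrid(pathway_id=net.pathway_id, sample_id=str(sample), grid=g))
    return grids
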
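"""Pairwise genetic similarity, UPGMA dendrograms, and within-batch summaries.

For two 0/1 band profiles the four per-pair counts are a (1,1), b (1,0),
c (0,1), d (0,0). The supported coefficients are

* ``simple_matching`` — (a + d) / (a + b + c + d)
* ``dice``            — 2a / (2a + b + c)   (default; the common choice for
  dominant markers, where shared absence is weak evidence)
* ``jaccard``         — a / (a + b + c)

Distances for clustering are 1 − similarity; UPGMA (average linkage) yields an
ultrametric tree whose node heights are half the cophenetic distances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import squareform
from skbio import TreeNode

__all__ = [
    "SimilarityMatrix",
    "Dendrogram",
    "pairwise_similarity",
    "upgma",
    "within_batch_similarity",
    "COEFFICIENTS",
]

COEFFICIENTS = ("simple_matching", "dice", "jaccard")


@dataclass
class SimilarityMatrix:
    """Symmetric sample-by-sample similarity in [0, 1] with unit diagonal."""

    values: pd.DataFrame
    method: str

    def __post_init__(self) -> None:
        v = self.values
        if not np.allclose(v.to_numpy(), v.to_numpy().T):
            raise ValueError("similarity matrix must be symmetric")
        if not np.allclose(np.diag(v.to_numpy()), 1.0):
            raise ValueError("similarity diagonal must be 1")
        if ((v.to_numpy() < -1e-12) | (v.to_numpy() > 1 + 1e-12)).any():
            raise ValueError("similarity entries must lie in [0, 1]")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    def to_csv(self, path: str | Path) -> None:
        self.values.to_csv(path, index_label="sample_id")


def pairwise_similarity(bm, method: str = "dice") -> SimilarityMatrix:
    """Pairwise binary similarity among samples of a band matrix.

    Two all-zero profiles give an indeterminate dice/jaccard ratio
    (a + b + c = 0); they are identical profiles, so similarity is defined
    as 1 with a warning.
    """
    if method not in COEFFICIENTS:
        raise ValueError(f"unknown coefficient {method!r}; choose from {COEFFICIENTS}")
    X = bm.values.to_numpy(dtype=float)
    n, m = X.shape
    if n < 2:
        raise ValueError("need at least 2 samples")
    a = X @ X.T
    b = X @ (1 - X).T
    c = b.T
    d = m - a - b - c
    if method == "simple_matching":
        sim = (a + d) / m
    else:
        denom = (2 * a + b + c) if method == "dice" else (a + b + c)
        num = 2 * a if method == "dice" else a
        degenerate = denom == 0
        if degenerate.any():
            warnings.warn(
                "all-zero profile pair(s): %s similarity of identical empty "
                "profiles defined as 1" % method,
                stacklevel=2,
            )
        with np.errstate(invalid="ignore", divide="ignore"):
            sim = np.where(degenerate, 1.0, num / np.where(degenerate, 1, denom))
    sim = np.clip((sim + sim.T) / 2, 0.0, 1.0)
    np.fill_diagonal(sim, 1.0)
    df = pd.DataFrame(sim, index=bm.values.index, columns=bm.values.index)
    return SimilarityMatrix(df, method)


@dataclass
class Dendrogram:
    """UPGMA tree plus its linkage bookkeeping.

    ``tree`` is a rooted :class:`skbio.TreeNode` with branch lengths such that
    every leaf sits at the same depth (ultrametric); ``merge_heights`` are the
    node heights (half the merge distances), non-decreasing.
    """

    tree: TreeNode
    linkage_matrix: np.ndarray
    sample_ids: list[str]

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2] / 2.0

    def newick(self) -> str:
        return str(self.tree).strip()

    def write_newick(self, path: str | Path) -> None:
        Path(path).write_text(self.newick() + "\n")

    def cophenetic_distances(self) -> pd.DataFrame:
        """Full tree distance between leaf pairs (twice the merge height)."""
        d = squareform(cophenet(self.linkage_matrix))
        return pd.DataFrame(d, index=self.sample_ids, columns=self.sample_ids)

    def ascii(self) -> str:
        return self.tree.ascii_art()


def upgma(sim: SimilarityMatrix) -> Dendrogram:
    """Average-linkage (UPGMA) tree on distance = 1 − similarity.

    Samples are put in lexicographic order before linkage so equal-height
    merges resolve to the lexicographically first pair: trees are
    bit-reproducible regardless of input row order.
    """
    ids = sorted(sim.sample_ids)
    if len(ids) < 2:
        raise ValueError("need at least 2 samples for a dendrogram")
    dist = 1.0 - sim.values.loc[ids, ids].to_numpy()
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(dist, checks=False), method="average")
    tree = TreeNode.from_linkage_matrix(Z, ids)
    return Dendrogram(tree, Z, ids)


def within_batch_similarity(
    sim: "SimilarityMatrix | pd.DataFrame", batch_map: dict | pd.Series
) -> pd.DataFrame:
    """Mean ± sample sd of off-diagonal pairwise values within each batch.

    Singleton batches have no pairs and are excluded with a warning. Returns a
    frame indexed by batch with columns ``mean``, ``sd``, ``n_pairs``.
    """
    values = sim.values if isinstance(sim, SimilarityMatrix) else sim
    bmap = pd.Series(batch_map)
    rows = {}
    for batch, members in bmap.groupby(bmap).groups.items():
        members = [s for s in members if s in values.index]
        if len(members) < 2:
            warnings.warn(f"batch {batch!r} has <2 samples; excluded", stacklevel=2)
            continue
        sub = values.loc[members, members].to_numpy()
        iu = np.triu_indices(len(members), k=1)
        pairs = sub[iu]
        rows[batch] = {
            "mean": float(pairs.mean()),
            "sd": float(pairs.std(ddof=1)) if len(pairs) > 1 else 0.0,
            "n_pairs": len(pairs),
        }
    return pd.DataFrame.from_dict(rows, orient="index")
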
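"""Downstream analysis: Z-scores, hierarchical clustering, term enrichment.

Significant proteins are row-standardized (Z-score across samples) and
clustered with Euclidean distance and average linkage; enrichment of
annotation terms (GMT gene sets) among a query list is tested with a
one-tailed Fisher/hypergeometric test, optionally with the conservative
EASE variant (one overlap member removed).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy

from .evidence import CountMatrix

__all__ = [
    "ClusterTree",
    "AnnotationSet",
    "zscore_matrix",
    "hclust_average",
    "cut_clusters",
    "enrich_terms",
    "read_gmt",
    "plot_heatmap",
]


@dataclass(frozen=True)
class ClusterTree:
    """Agglomerative clustering result.

    ``merges`` lists (cluster_i, cluster_j, height, size) in merge order,
    where indexes < n refer to leaves and index n+k to the cluster created
    by merge k; ``leaf_order`` is the dendrogram leaf ordering;
    ``labels`` names the leaves.
    """

    merges: tuple[tuple[int, int, float, int], ...]
    leaf_order: tuple[int, ...]
    labels: tuple[str, ...]

    @property
    def linkage(self) -> np.ndarray:
        """SciPy-format linkage matrix."""
        return np.array([list(m) for m in self.merges], dtype=float)

    def to_tsv(self, path: str | Path) -> None:
        with Path(path).open("w") as handle:
            handle.write("cluster_i\tcluster_j\theight\tsize\n")
            for i, j, h, s in self.merges:
                handle.write(f"{i}\t{j}\t{h:.6g}\t{s}\n")
            handle.write("#leaf_order\t" + "\t".join(self.labels[i] for i in self.leaf_order) + "\n")


@dataclass(frozen=True)
class AnnotationSet:
    """One annotation term (e.g. a GO biological process) and its members."""

    term_id: str
    term_name: str
    members: frozenset[str]


def zscore_matrix(
    matrix: CountMatrix | pd.DataFrame, rows: Sequence[str] | None = None
) -> pd.DataFrame:
    """Row-wise Z-scores: (x - row mean) / row sample sd (n-1 denominator).

    Constant rows map to all zeros (they carry no between-sample signal).
    Raises ``ValueError`` with fewer than 2 samples or when a requested row
    is absent.
    """
    df = matrix.counts if isinstance(matrix, CountMatrix) else matrix
    if df.shape[1] < 2:
        raise ValueError("Z-scoring needs at least 2 samples")
    if rows is not None:
        missing = [r for r in rows if r not in df.index]
        if missing:
            raise ValueError(f"rows not in matrix: {missing}")
        df = df.loc[list(rows)]
    values = df.to_numpy(dtype=float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (values - mean) / sd
    z[~np.isfinite(z)] = 0.0
    z[(sd == 0).repeat(values.shape[1], axis=1)] = 0.0
    return pd.DataFrame(z, index=df.index, columns=df.columns)


def hclust_average(points: pd.DataFrame | np.ndarray) -> ClusterTree:
    """Agglomerative clustering, Euclidean distance, average linkage.

    Inter-cluster distance is the arithmetic mean of all pairwise member
    distances (UPGMA), which makes merge heights non-decreasing.  Rows of
    ``points`` are the objects clustered.
    """
    if isinstance(points, pd.DataFrame):
        labels = tuple(str(i) for i in points.index)
        arr = points.to_numpy(dtype=float)
    else:
        arr = np.asarray(points, dtype=float)
        labels = tuple(str(i) for i in range(arr.shape[0]))
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise ValueError("clustering needs a 2-D array with at least 2 rows")
    if not np.isfinite(arr).all():
        raise ValueError("clustering input contains non-finite values")
    z = hierarchy.linkage(arr, method="average", metric="euclidean")
    merges = tuple(
        (int(row[0]), int(row[1]), float(row[2]), int(row[3])) for row in z
    )
    leaf_order = tuple(int(i) for i in hierarchy.leaves_list(z))
    return ClusterTree(merges=merges, leaf_order=leaf_order, labels=labels)


def cut_clusters(tree: ClusterTree, k: int) -> dict[str, int]:
    """Assign leaves to *k* flat clusters by cutting the dendrogram."""
    assign = hierarchy.fcluster(tree.linkage, t=k, criterion="maxclust")
    return {lab: int(c) for lab, c in zip(tree.labels, assign)}


def enrich_terms(
    query: Iterable[str],
    background: Iterable[str],
    annotation: Sequence[AnnotationSet],
    *,
    ease: bool = False,
) -> pd.DataFrame:
    """One-tailed Fisher (hypergeometric) enrichment per annotation term.

    For each term, the 2x2 table is [overlap, query - overlap;
    term-in-background - overlap, rest] and the p-value is the upper
    hypergeometric tail P(X >= overlap).  With ``ease=True`` the overlap is
    reduced by one (floored at 0) before testing — the conservative EASE
    score used by annotation tools.  Terms with zero overlap report p = 1.
    Duplicated ids are de-duplicated; a query id outside the background is
    an error.
    """
    query_set = set(query)
    bg = set(background)
    outside = query_set - bg
    if outside:
        raise ValueError(f"query ids outside background: {sorted(outside)[:5]}")
    n_bg = len(bg)
    n_q = len(query_set)
    rows = []
    for term in annotation:
        members = term.members & bg
        overlap = len(query_set & members)
        k_eff = max(overlap - 1, 0) if ease else overlap
        if k_eff == 0:
            p = 1.0
        else:
            # P(X >= k_eff) with population n_bg, successes |members|, draws n_q
            p = float(sps.hypergeom.sf(k_eff - 1, n_bg, len(members), n_q))
            p = min(1.0, p)
        rows.append(
            {
                "term_id": term.term_id,
                "term_name": term.term_name,
                "term_size": len(members),
                "overlap": overlap,
                "p": p,
            }
        )
    return pd.DataFrame(rows, columns=["term_id", "term_name", "term_size", "overlap", "p"])


def read_gmt(path: str | Path) -> list[AnnotationSet]:
    """Read gene sets in GMT format (term_id <TAB> term_name <TAB> members...)."""
    terms: list[AnnotationSet] = []
    with Path(path).open() as handle:
        for lineno, line in enumerate(handle, start=1):
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: GMT row needs >= 3 fields at line {lineno}")
            terms.append(
                AnnotationSet(
                    term_id=fields[0],
                    term_name=fields[1],
                    members=frozenset(f for f in fields[2:] if f),
                )
            )
    return terms


def plot_heatmap(
    z: pd.DataFrame,
    path: str | Path,
    row_tree: ClusterTree | None = None,
    col_tree: ClusterTree | None = None,
) -> None:
    """Save a clustered heat map of a Z-score matrix to *path*."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data = z
    if row_tree is not None:
        data = data.iloc[list(row_tree.leaf_order)]
    if col_tree is not None:
        data = data.iloc[:, list(col_tree.leaf_order)]
    fig, ax = plt.subplots(
        figsize=(max(4, 0.5 * data.shape[1] + 2), max(4, 0.12 * data.shape[0] + 2))
    )
    im = ax.imshow(data.to_numpy(), aspect="auto", cmap="RdBu_r")
    ax.set_xticks(range(data.shape[1]), labels=data.columns, rotation=90, fontsize=7)
    ax.set_yticks([])
    fig.colorbar(im, ax=ax, label="Z-score")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
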
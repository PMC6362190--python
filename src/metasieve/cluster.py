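"""Row-centered log2 hierarchical clustering of candidate-taxon hit rates.

For heatmap display, log2-transformed hit rates are centered by subtracting
each row's mean, then rows (taxa) and columns (samples) are clustered
agglomeratively with Pearson correlation distance (1 - r) and average
linkage.  Rows with zero variance have no defined correlation; they are
assigned distance 1 (the uncorrelated value) to every other item and logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform

from .abundance import HRMatrix
from .detect import DEFAULT_PSEUDOCOUNT, log2_transform

__all__ = ["ClusterResult", "center_rows", "hierarchical_cluster", "cluster_hr", "plot_heatmap"]

logger = logging.getLogger(__name__)


@dataclass
class ClusterResult:
    """Linkage trees and leaf orders for both axes plus the centered matrix."""

    matrix: pd.DataFrame  # centered log2 values
    row_linkage: np.ndarray | None
    col_linkage: np.ndarray | None
    row_order: list
    col_order: list

    @property
    def ordered(self) -> pd.DataFrame:
        return self.matrix.loc[self.row_order, self.col_order]

    def write(self, out_dir: str | Path, prefix: str = "cluster") -> None:
        out_dir = Path(out_dir)
        self.ordered.to_csv(out_dir / f"{prefix}_matrix_ordered.tsv", sep="\t")
        for name, link in (("rows", self.row_linkage), ("cols", self.col_linkage)):
            if link is not None:
                pd.DataFrame(
                    link, columns=["left", "right", "distance", "size"]
                ).to_csv(out_dir / f"{prefix}_linkage_{name}.tsv", sep="\t", index=False)


def center_rows(matrix: pd.DataFrame) -> pd.DataFrame:
    """Subtract each row's mean from every cell of the row."""
    if matrix.size == 0:
        raise ValueError("cannot center an empty matrix")
    return matrix.sub(matrix.mean(axis=1), axis=0)


def _correlation_distances(items: np.ndarray) -> np.ndarray:
    """Condensed 1 - Pearson distance matrix over the rows of ``items``,
    with zero-variance rows placed at distance 1 from everything."""
    n = items.shape[0]
    sd = items.std(axis=1)
    degenerate = sd == 0
    if degenerate.any():
        logger.warning(
            "%d item(s) with zero variance assigned correlation distance 1 to all others",
            int(degenerate.sum()),
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(items)
    dist = 1.0 - corr
    dist[degenerate, :] = 1.0
    dist[:, degenerate] = 1.0
    np.fill_diagonal(dist, 0.0)
    dist = np.clip(dist, 0.0, 2.0)
    # guard tiny asymmetries from floating point before condensing
    dist = (dist + dist.T) / 2.0
    return squareform(dist, checks=False)


def hierarchical_cluster(
    matrix: pd.DataFrame,
    axis: str = "rows",
    linkage_method: str = "average",
) -> tuple[np.ndarray, list]:
    """Agglomerative clustering of one axis under correlation distance.

    Returns ``(linkage, leaf_order)``; the linkage is the standard SciPy
    (n-1) x 4 merge table.  Deterministic for identical input: SciPy breaks
    distance ties by cluster index.
    """
    if axis not in ("rows", "cols"):
        raise ValueError(f"axis must be 'rows' or 'cols', got {axis!r}")
    items = matrix.to_numpy(dtype=float) if axis == "rows" else matrix.to_numpy(dtype=float).T
    labels = list(matrix.index) if axis == "rows" else list(matrix.columns)
    if items.shape[0] < 2:
        raise ValueError(f"need >= 2 items on axis {axis!r} to cluster")
    condensed = _correlation_distances(items)
    link = linkage(condensed, method=linkage_method)
    order = [labels[i] for i in leaves_list(link)]
    return link, order


def cluster_hr(
    hr: HRMatrix,
    taxa: list | None = None,
    samples: list | None = None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    linkage_method: str = "average",
    cluster_columns: bool = True,
) -> ClusterResult:
    """Center and cluster a (candidate) submatrix of log2 hit rates.

    ``taxa`` restricts rows (typically the taxa significant in at least one
    case sample); ``samples`` restricts columns (typically case + control).
    """
    values = log2_transform(hr, pseudocount)
    if taxa is not None:
        values = values.loc[list(taxa)]
    if samples is not None:
        values = values[list(samples)]
    centered = center_rows(values)
    row_link, row_order = hierarchical_cluster(centered, "rows", linkage_method)
    if cluster_columns and centered.shape[1] >= 2:
        col_link, col_order = hierarchical_cluster(centered, "cols", linkage_method)
    else:
        col_link, col_order = None, list(centered.columns)
    return ClusterResult(
        matrix=centered,
        row_linkage=row_link,
        col_linkage=col_link,
        row_order=row_order,
        col_order=col_order,
    )


def plot_heatmap(result: ClusterResult, path: str | Path) -> None:
    """Write a simple blue-black-yellow heatmap of the ordered matrix."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import LinearSegmentedColormap

    cmap = LinearSegmentedColormap.from_list("bby", ["blue", "black", "yellow"])
    ordered = result.ordered
    vmax = float(np.nanmax(np.abs(ordered.to_numpy()))) or 1.0
    fig, ax = plt.subplots(
        figsize=(max(4, 0.3 * ordered.shape[1]), max(4, 0.15 * ordered.shape[0]))
    )
    im = ax.imshow(ordered.to_numpy(), cmap=cmap, vmin=-vmax, vmax=vmax, aspect="auto")
    ax.set_xticks(range(ordered.shape[1]))
    ax.set_xticklabels(ordered.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(ordered.shape[0]))
    ax.set_yticklabels(ordered.index, fontsize=5)
    fig.colorbar(im, ax=ax, label="centered log2 HR")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
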
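"""PCR matrix construction, agglomerative ordering and rendering.

The heatmap's contract is the exported matrix and the row/column orderings;
the image is a convenience.  Each cell of the matrix is the PCR of one drug
class against one AE class (after upward AE propagation), so a cell equal
to 1 marks a class effect.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage as scipy_linkage

from .class_effects import collapse_to_ingredients, pcr
from .data_io import AssociationTable
from .hierarchy import Hierarchy, class_members, propagate_ae

logger = logging.getLogger(__name__)

__all__ = ["PcrMatrix", "ClusterResult", "pcr_matrix", "cluster_matrix", "plot_heatmap"]


@dataclass(frozen=True)
class PcrMatrix:
    """Drug-class x AE-class grid of PCR values in [0, 1]."""

    row_ids: tuple[str, ...]
    col_ids: tuple[str, ...]
    values: np.ndarray  # shape (len(row_ids), len(col_ids))

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.row_ids), len(self.col_ids)):
            raise ValueError("matrix shape does not match row/col ids")
        if self.values.size and (self.values.min() < 0 or self.values.max() > 1):
            raise ValueError("PCR values must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.row_ids), columns=list(self.col_ids)
        )

    def write_tsv(self, path: str | Path) -> None:
        df = self.to_frame()
        df.index.name = "class_id"
        # repr-precision floats so write -> read round-trips bit-exact
        df.to_csv(path, sep="\t", float_format="%.17g")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "PcrMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(
            row_ids=tuple(str(i) for i in df.index),
            col_ids=tuple(str(c) for c in df.columns),
            values=df.to_numpy(dtype=float),
        )


def pcr_matrix(
    table: AssociationTable,
    class_h: Hierarchy,
    ae_h: Hierarchy,
    class_ids: Sequence[str],
    ae_ids: Sequence[str],
    universe: set[str] | None = None,
) -> PcrMatrix:
    """Compute the PCR of every (drug class, AE class) pair.

    AE class membership is resolved through upward propagation, so
    ``ae_ids`` may sit at any level of the AE hierarchy.  Drug classes with
    no mapped ingredient are dropped with a warning; if none remain the
    matrix is undefined and an error is raised.
    """
    assoc = collapse_to_ingredients(table)
    known = ae_h.nodes
    assoc = {i: aes & known for i, aes in assoc.items()}
    propagated = propagate_ae(assoc, ae_h)
    if universe is None:
        universe = class_h.leaves - class_h.roots - set(class_ids)

    kept_rows: list[str] = []
    members_of: dict[str, set[str]] = {}
    for cid in class_ids:
        members = class_members(class_h, cid, universe)
        if not members:
            warnings.warn(f"class {cid} has no mapped ingredients; dropped")
            continue
        kept_rows.append(cid)
        members_of[cid] = members
    if not kept_rows:
        raise ValueError("no drug class has mapped ingredients; matrix undefined")

    for ae in ae_ids:
        if ae not in known:
            raise KeyError(f"AE id not in the AE hierarchy: {ae!r}")
    values = np.empty((len(kept_rows), len(ae_ids)))
    for i, cid in enumerate(kept_rows):
        members = members_of[cid]
        for j, ae in enumerate(ae_ids):
            positive = {m for m in members if ae in propagated.get(m, ())}
            values[i, j] = pcr(members, positive)
    return PcrMatrix(row_ids=tuple(kept_rows), col_ids=tuple(ae_ids), values=values)


@dataclass(frozen=True)
class ClusterResult:
    """Deterministic agglomerative ordering of a PCR matrix."""

    row_order: tuple[int, ...]
    col_order: tuple[int, ...]
    row_linkage: np.ndarray | None
    col_linkage: np.ndarray | None

    def ordering_json(self) -> str:
        return json.dumps(
            {"row_order": list(self.row_order), "col_order": list(self.col_order)}
        )


def _canonical_leaf_order(z: np.ndarray, data: np.ndarray) -> tuple[int, ...]:
    """Dendrogram leaf order made a function of cell values only.

    At every merge the two subtrees are emitted in lexicographic order of
    their smallest member row, so permuting the input rows permutes nothing
    in the output sequence (scipy's default leaf order follows merge
    indices, which do depend on input order).
    """
    n = data.shape[0]
    leaves_of: dict[int, list[int]] = {i: [i] for i in range(n)}
    for k, (left, right, _, _) in enumerate(z[:, :4]):
        li, ri = leaves_of.pop(int(left)), leaves_of.pop(int(right))
        key = lambda leaves: min(tuple(data[i]) for i in leaves)
        first, second = sorted((li, ri), key=key)
        leaves_of[n + k] = first + second
    (order,) = leaves_of.values()
    return tuple(order)


def _axis_order(data: np.ndarray, metric: str, method: str):
    if data.shape[0] < 2:
        return tuple(range(data.shape[0])), None
    z = scipy_linkage(data, method=method, metric=metric)
    return _canonical_leaf_order(z, data), z


def cluster_matrix(
    m: PcrMatrix, metric: str = "euclidean", linkage: str = "average"
) -> ClusterResult:
    """Order rows and columns by hierarchical agglomerative clustering.

    Re-running on the same matrix gives the same order.  A degenerate
    single-row or single-column matrix keeps its identity ordering with a
    warning.
    """
    if min(m.values.shape) < 2:
        warnings.warn("degenerate matrix (< 2 rows or columns): identity ordering")
    row_order, row_z = _axis_order(m.values, metric, linkage)
    col_order, col_z = _axis_order(m.values.T, metric, linkage)
    return ClusterResult(
        row_order=row_order, col_order=col_order, row_linkage=row_z, col_linkage=col_z
    )


def plot_heatmap(
    m: PcrMatrix,
    path: str | Path,
    cluster: ClusterResult | None = None,
    cmap: str = "viridis",
) -> None:
    """Render the (optionally clustered) PCR matrix to a raster or vector file.

    Rendering reorders rows/columns only; cell values are never altered.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if cluster is None:
        cluster = cluster_matrix(m)
    ro, co = list(cluster.row_order), list(cluster.col_order)
    data = m.values[np.ix_(ro, co)]
    fig, ax = plt.subplots(
        figsize=(max(4, 0.35 * len(co) + 2), max(3, 0.3 * len(ro) + 1.5))
    )
    im = ax.imshow(data, cmap=cmap, vmin=0.0, vmax=1.0, aspect="auto")
    ax.set_xticks(range(len(co)))
    ax.set_xticklabels([m.col_ids[j] for j in co], rotation=90, fontsize=7)
    ax.set_yticks(range(len(ro)))
    ax.set_yticklabels([m.row_ids[i] for i in ro], fontsize=7)
    fig.colorbar(im, ax=ax, label="PCR")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
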
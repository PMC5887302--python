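"""Embedding and visualisation: classical MDS, ordered heatmaps, zipfian plots.

The distance matrices produced by the metrics module are turned into the
framework's visual surfaces: a deterministic classical (Torgerson) MDS 2D
embedding for batch/sample QC overlays, average-linkage heatmap row and
column orderings with Newick dendrograms, and overlaid zipfian function
plots (self-information against log rank, one curve per sample).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .errors import PrismError
from .kmer import ZipfianCoSpectrum
from .metrics import DistanceMatrix

__all__ = ["Embedding", "mds_embed", "heatmap_order", "plot_zipfians"]


@dataclass
class Embedding:
    """2D (or higher) coordinates of embedded items plus a stress value."""

    item_ids: list[str]
    coordinates: np.ndarray  # (n, dims)
    stress: float

    def to_tsv(self, path: str | Path) -> None:
        dims = self.coordinates.shape[1]
        df = pd.DataFrame(
            self.coordinates, index=self.item_ids,
            columns=[f"dim{i + 1}" for i in range(dims)],
        )
        df.index.name = "item_id"
        df.to_csv(path, sep="\t")


def mds_embed(d: DistanceMatrix, dims: int = 2) -> Embedding:
    """Classical (Torgerson) multidimensional scaling.

    Double-centres -D^2/2, takes the top ``dims`` eigenpairs and scales the
    eigenvectors by sqrt(eigenvalue); negative eigenvalues (non-Euclidean
    distances) contribute zero coordinates.  Deterministic: each axis's
    sign is fixed so its first nonzero loading is positive.  The reported
    stress is Kruskal's stress-1 between the input and embedded distances
    (0 for an exactly Euclidean-embeddable matrix at sufficient dims).
    """
    n = len(d.item_ids)
    if dims >= n and n > 1:
        raise PrismError("invalid-dims", f"dims={dims} must be < n={n}")
    dm = d.d
    if np.allclose(dm, 0.0):
        return Embedding(list(d.item_ids), np.zeros((n, max(dims, 1))), 0.0)
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (dm**2) @ j
    b = (b + b.T) / 2.0
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(evals)[::-1][:dims]
    coords = np.zeros((n, dims))
    for a, idx in enumerate(order):
        lam = evals[idx]
        if lam > 1e-12:
            v = evecs[:, idx] * np.sqrt(lam)
            nz = np.flatnonzero(np.abs(v) > 1e-12)
            if len(nz) and v[nz[0]] < 0:
                v = -v
            coords[:, a] = v
    emb = squareform(
        np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1)),
        checks=False,
    )
    orig = squareform(dm, checks=False)
    denom = float(np.sum(orig**2))
    stress = float(np.sqrt(np.sum((orig - emb) ** 2) / denom)) if denom else 0.0
    return Embedding(list(d.item_ids), coords, stress)


def _leaf_order(link: np.ndarray, n: int, data: np.ndarray) -> list[int]:
    """Leaves of a linkage tree, recursively smaller-cluster-first.

    Size ties break on the lexicographically smallest member row, a
    content-based rule, so the order is equivariant under permutation of
    the input rows (a label-based tie-break would not be).
    """
    keys = [tuple(row) for row in data]
    sizes: dict[int, int] = {i: 1 for i in range(n)}
    minkey = {i: keys[i] for i in range(n)}
    children = {}
    for r, (a, b, _h, size) in enumerate(link):
        node = n + r
        a, b = int(a), int(b)
        children[node] = (a, b)
        sizes[node] = int(size)
        minkey[node] = min(minkey[a], minkey[b])

    def walk(node: int) -> list[int]:
        if node < n:
            return [node]
        a, b = children[node]
        first, second = (a, b)
        if (sizes[b], minkey[b]) < (sizes[a], minkey[a]):
            first, second = (b, a)
        return walk(first) + walk(second)

    return walk(n + len(link) - 1) if len(link) else list(range(n))


def _to_newick(link: np.ndarray, labels: Sequence[str]) -> str:
    """Newick string of a linkage tree; branch lengths are height gaps."""
    n = len(labels)
    if len(link) == 0:
        return f"({labels[0]}:0.0);" if n == 1 else ";"
    heights = {i: 0.0 for i in range(n)}
    children = {}
    for r, (a, b, h, _s) in enumerate(link):
        node = n + r
        children[node] = (int(a), int(b))
        heights[node] = float(h)

    def walk(node: int, parent_h: float) -> str:
        bl = max(parent_h - heights[node], 0.0)
        if node < n:
            return f"{labels[node]}:{bl:.6g}"
        a, b = children[node]
        h = heights[node]
        return f"({walk(a, h)},{walk(b, h)}):{bl:.6g}"

    root = n + len(link) - 1
    return walk(root, heights[root]) + ";"


def heatmap_order(
    matrix: np.ndarray,
    row_ids: Sequence[str] | None = None,
    col_ids: Sequence[str] | None = None,
    linkage: str = "average",
    metric: str = "euclidean",
) -> tuple[list[int], list[int], str, str]:
    """Hierarchically order a matrix's rows and columns for heatmap display.

    Rows and columns are clustered independently (agglomerative, average
    linkage by default, Euclidean metric).  Leaf order puts the smaller
    cluster first at every merge, deterministically.  Returns (row order,
    column order, row dendrogram, column dendrogram), dendrograms as Newick
    with branch lengths equal to merge-height differences.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2:
        raise PrismError("invalid-shape", "matrix must be 2-D")
    nr, nc = x.shape
    rids = list(row_ids) if row_ids is not None else [f"r{i}" for i in range(nr)]
    cids = list(col_ids) if col_ids is not None else [f"c{j}" for j in range(nc)]

    def one_axis(data: np.ndarray, labels: list[str]) -> tuple[list[int], str]:
        if len(data) == 1:
            return [0], f"({labels[0]}:0.0);"
        link = hierarchy.linkage(data, method=linkage, metric=metric)
        return _leaf_order(link, len(data), data), _to_newick(link, labels)

    row_order, row_nwk = one_axis(x, rids)
    col_order, col_nwk = one_axis(x.T, cids)
    return row_order, col_order, row_nwk, col_nwk


def plot_zipfians(
    zs: Sequence[ZipfianCoSpectrum],
    labels: Sequence[str] | None = None,
    out: str | Path = "zipfian.png",
) -> Path:
    """Overlay zipfian curves (h in nats vs ln rank), one per co-spectrum.

    Curves sharing a label share a colour and a single legend entry, so a
    lane of 192 samples with a handful of species groups stays readable.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if len(zs) == 0:
        raise PrismError("empty-input", "no co-spectra to plot")
    labs = list(labels) if labels is not None else [z.model_id for z in zs]
    groups = sorted(set(labs))
    cmap = plt.get_cmap("tab10")
    colour = {g: cmap(i % 10) for i, g in enumerate(groups)}
    fig, ax = plt.subplots(figsize=(7, 5))
    seen: set[str] = set()
    for z, lab in zip(zs, labs):
        ax.plot(
            np.log(z.ranks.astype(float)),
            z.h,
            color=colour[lab],
            linewidth=0.8,
            alpha=0.7,
            label=lab if lab not in seen else None,
        )
        seen.add(lab)
    ax.set_xlabel("ln rank")
    ax.set_ylabel("self-information (nats)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    out = Path(out)
    try:
        fig.savefig(out, dpi=120)
    except OSError as exc:
        raise PrismError("write-failed", str(exc)) from exc
    finally:
        plt.close(fig)
    return out
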
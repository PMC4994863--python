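"""Dimension reduction front-end of the ordering pipeline.

Raw expression is turned into the low-dimensional per-cell representation the
tree is built on, in five steps:

1. drop genes with zero expression in every cell;
2. group the remaining genes into H = 5% * G' clusters by hierarchical
   clustering (Euclidean distance, complete linkage) — averaging within gene
   clusters stabilises expression against drop-out events;
3. average each gene cluster per cell (the aggregated H x N matrix E);
4. standardize each row of E to zero mean / unit SD and run PCA with cells as
   observations;
5. keep the top K components, K chosen by fitting a continuous two-segment
   linear model to the scree v_i = sqrt(lambda_i) and taking the breakpoint
   that minimises the squared error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.decomposition import PCA

from .io import ExpressionMatrix


def round_half_away(x: float) -> int:
    """Round half away from zero (3.5 -> 4, -3.5 -> -4)."""
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def filter_zero_genes(m: ExpressionMatrix) -> ExpressionMatrix:
    """Keep exactly the genes with at least one nonzero value, order preserved."""
    keep = np.flatnonzero(np.any(m.values != 0, axis=1))
    if keep.size == 0:
        raise ValueError("empty matrix after filtering: all genes are zero everywhere")
    if keep.size == m.n_genes:
        return m
    return m.subset_genes(keep)


@dataclass
class GeneClustering:
    """Partition of the retained genes into H clusters (labels 1..H)."""

    n_clusters: int
    labels: np.ndarray
    member_lists: dict[int, list[str]]


def cluster_genes(m: ExpressionMatrix, fraction: float = 0.05) -> GeneClustering:
    """Group gene rows by complete-linkage hierarchical clustering.

    The tree is cut to ``H = max(1, round(fraction * G'))`` clusters where
    ``G'`` is the number of genes in ``m`` (assumed already zero-filtered).
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    g = m.n_genes
    if g < 2:
        raise ValueError("need at least 2 genes to cluster")
    h = max(1, round_half_away(fraction * g))
    if h == 1:
        labels = np.ones(g, dtype=int)
    else:
        z = linkage(m.values, method="complete", metric="euclidean")
        labels = fcluster(z, t=h, criterion="maxclust")
    # relabel to consecutive 1..H' in order of first appearance
    remap: dict[int, int] = {}
    out = np.empty(g, dtype=int)
    for i, lab in enumerate(labels):
        if lab not in remap:
            remap[lab] = len(remap) + 1
        out[i] = remap[lab]
    members: dict[int, list[str]] = {c: [] for c in range(1, len(remap) + 1)}
    for i, lab in enumerate(out):
        members[lab].append(m.gene_ids[i])
    return GeneClustering(n_clusters=len(remap), labels=out, member_lists=members)


@dataclass
class AggregatedMatrix:
    """H x N matrix of per-cluster mean expression (row h = cluster h mean)."""

    values: np.ndarray
    cluster_ids: list[str]
    cell_ids: list[str]


def aggregate_gene_clusters(m: ExpressionMatrix, gc: GeneClustering) -> AggregatedMatrix:
    """Average member-gene rows within each gene cluster, per cell."""
    if gc.labels.shape[0] != m.n_genes:
        raise ValueError(
            f"clustering covers {gc.labels.shape[0]} genes, matrix has {m.n_genes}"
        )
    h = gc.n_clusters
    vals = np.empty((h, m.n_cells), dtype=float)
    for c in range(1, h + 1):
        rows = np.flatnonzero(gc.labels == c)
        vals[c - 1] = m.values[rows].mean(axis=0)
    return AggregatedMatrix(
        values=vals,
        cluster_ids=[f"gc{c}" for c in range(1, h + 1)],
        cell_ids=list(m.cell_ids),
    )


def fit_piecewise_linear(
    x: np.ndarray, y: np.ndarray, breakpoints: np.ndarray
) -> tuple[float, dict[float, float], tuple[float, float, float, float]]:
    """Least-squares fit of a continuous two-segment line at each breakpoint.

    The model is ``f(x) = a + b*(x - k)`` for ``x <= k`` and
    ``a + c*(x - k)`` for ``x > k`` — continuity at the breakpoint ``k`` holds
    by construction, so each candidate is an ordinary 3-parameter least
    squares.  Returns the breakpoint with smallest SSE (ties: smallest k), the
    SSE per candidate, and the winning parameters as (alpha0, alpha1, beta0,
    beta1) of the equivalent two-intercept/two-slope form.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    sse_map: dict[float, float] = {}
    best: tuple[float, float] | None = None
    best_params = None
    for k in breakpoints:
        d = x - k
        design = np.column_stack(
            [np.ones_like(x), np.minimum(d, 0.0), np.maximum(d, 0.0)]
        )
        coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ coef
        sse = float(resid @ resid)
        sse_map[float(k)] = sse
        if best is None or sse < best[0] - 1e-12 * max(1.0, best[0]):
            a, b, c = coef
            best = (sse, float(k))
            best_params = (a - b * k, b, a - c * k, c)
    assert best is not None and best_params is not None
    return best[1], sse_map, tuple(float(p) for p in best_params)


def choose_num_pcs(v: np.ndarray, k_min: int = 2) -> int:
    """Pick the number of PCs as the breakpoint of a two-segment scree fit.

    ``v`` is the non-increasing scree (square roots of explained variances,
    indexed 1..m).  Each candidate breakpoint ``k`` in ``[k_min, m-1]`` is fit
    by constrained least squares over all m points; the k with smallest SSE
    wins, ties going to the smallest k.
    """
    v = np.asarray(v, dtype=float)
    m = v.shape[0]
    if m < 4:
        raise ValueError(f"scree needs at least 4 points, got {m}")
    if np.any(np.diff(v) > 1e-9 * max(1.0, float(np.abs(v).max()))):
        raise ValueError("scree must be non-increasing (sorted)")
    idx = np.arange(1, m + 1, dtype=float)
    k, _, _ = fit_piecewise_linear(idx, v, np.arange(k_min, m, dtype=float))
    return int(k)


@dataclass
class ScreeFit:
    """Scree vector with the selected breakpoint and per-candidate SSE."""

    v: np.ndarray
    chosen_k: int
    per_k_sse: dict[float, float]
    fit_params: tuple[float, float, float, float] | None


@dataclass
class ReducedMatrix:
    """Cells x K principal-component coordinates plus the scree diagnostics."""

    coords: np.ndarray
    scree: ScreeFit
    loadings: np.ndarray
    cell_ids: list[str] = field(default_factory=list)
    explained_variance: np.ndarray | None = None

    @property
    def n_cells(self) -> int:
        return self.coords.shape[0]

    @property
    def k(self) -> int:
        return self.coords.shape[1]


def reduce_dimension(
    a: AggregatedMatrix,
    max_pcs_for_fit: int = 20,
    k_override: int | None = None,
) -> ReducedMatrix:
    """Row-standardize the aggregated matrix and project cells onto top-K PCs.

    Each row (gene cluster) is scaled to mean 0 / SD 1 across cells (SD with
    ``ddof=1``); constant rows are dropped with a warning.  PCA treats cells
    as observations.  The scree is built from the leading
    ``min(max_pcs_for_fit, N-1, H)`` components and K comes from
    :func:`choose_num_pcs` unless ``k_override`` is given.  Component signs
    are fixed by making each PC's largest-magnitude loading positive.
    """
    vals = np.asarray(a.values, dtype=float)
    h, n = vals.shape
    if n < 3:
        raise ValueError("need at least 3 cells")
    if h < 2:
        raise ValueError("need at least 2 gene clusters")
    means = vals.mean(axis=1, keepdims=True)
    sds = vals.std(axis=1, ddof=1, keepdims=True)
    keep = np.flatnonzero(sds.ravel() > 0)
    if keep.size < h:
        warnings.warn(
            f"dropping {h - keep.size} constant gene-cluster rows before PCA",
            stacklevel=2,
        )
    std = (vals[keep] - means[keep]) / sds[keep]
    n_avail = min(n - 1, keep.size)
    pca = PCA(n_components=n_avail, svd_solver="full")
    scores = pca.fit_transform(std.T)  # cells x components
    comps = pca.components_  # components x H_kept
    # deterministic sign: largest-|loading| entry positive per component
    for j in range(comps.shape[0]):
        i = int(np.argmax(np.abs(comps[j])))
        if comps[j, i] < 0:
            comps[j] *= -1.0
            scores[:, j] *= -1.0
    lam = pca.explained_variance_
    m_fit = min(max_pcs_for_fit, n_avail)
    v = np.sqrt(lam[:m_fit])
    if k_override is not None:
        chosen_k = int(k_override)
        sse_map: dict[float, float] = {}
        params = None
    else:
        if m_fit < 4:
            raise ValueError(
                f"only {m_fit} PCs available; too few for the scree breakpoint "
                "fit — pass k_override"
            )
        idx = np.arange(1, m_fit + 1, dtype=float)
        kf, sse_map, params = fit_piecewise_linear(
            idx, v, np.arange(2, m_fit, dtype=float)
        )
        chosen_k = int(kf)
    k = min(max(chosen_k, 1), n_avail)
    scree = ScreeFit(v=v, chosen_k=chosen_k, per_k_sse=sse_map, fit_params=params)
    return ReducedMatrix(
        coords=scores[:, :k].copy(),
        scree=scree,
        loadings=comps[:k].T.copy(),
        cell_ids=list(a.cell_ids),
        explained_variance=lam.copy(),
    )
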
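"""Cell clustering in PC space.

Default model: a mixture of multivariate Gaussians with unconstrained
(full, per-component) covariances — "ellipsoidal, varying volume, shape and
orientation" — fit by EM for every candidate component count, the count
selected by BIC in the maximize convention ``2 logL - p log N``.  Cells get
the component of largest posterior probability.

Two ablations mirror the method comparisons: plain k-means (count picked by a
two-segment elbow fit on the unexplained-variance curve) and ``none`` (no
clustering: every cell is its own tree node).

Cluster centers used downstream are always the empirical means of the member
cells' PC coordinates, so all three methods feed the tree identically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.cluster import KMeans
from sklearn.exceptions import ConvergenceWarning
from sklearn.mixture import GaussianMixture

from .preprocess import ReducedMatrix, fit_piecewise_linear


@dataclass
class CellClusterModel:
    """Cluster assignment of N cells with per-cluster empirical centers."""

    method: str
    n_clusters: int
    labels: np.ndarray  # length N, values 1..n_clusters
    centers: np.ndarray  # n_clusters x K, empirical means of member cells
    cell_ids: list[str] = field(default_factory=list)
    posterior: np.ndarray | None = None
    bic_trace: dict[int, float] | None = None
    component_means: np.ndarray | None = None
    loglik_trace: list[float] | None = None

    @property
    def cells_per_cluster(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.n_clusters + 1)[1:]


def _n_gmm_params(c: int, k: int) -> int:
    """Free parameters of a c-component full-covariance Gaussian mixture."""
    return (c - 1) + c * k + c * k * (k + 1) // 2


def _em_fit(
    x: np.ndarray,
    c: int,
    seed: int,
    init: dict | None,
    max_iter: int = 200,
    tol: float = 1e-5,
) -> tuple[GaussianMixture, list[float]]:
    """Run EM one step at a time so the log-likelihood trace is observable.

    The per-sample mean log-likelihood must never decrease across EM steps
    (guaranteed by the EM ascent property); a decrease beyond numerical noise
    raises.
    """
    reg = 1e-6 * float(np.mean(np.var(x, axis=0))) + 1e-10
    kwargs = dict(
        n_components=c,
        covariance_type="full",
        reg_covar=reg,
        max_iter=1,
        warm_start=True,
        random_state=seed,
        init_params="random_from_data",
    )
    if init is not None:
        kwargs.update(init)
    gm = GaussianMixture(**kwargs)
    trace: list[float] = []
    prev = -np.inf
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for _ in range(max_iter):
            gm.fit(x)
            ll = float(gm.score(x))
            if ll < prev - 1e-8 * max(1.0, abs(prev)):
                raise RuntimeError(f"EM log-likelihood decreased: {prev} -> {ll}")
            trace.append(ll)
            if ll - prev < tol:
                break
            prev = ll
    return gm, trace


def _hierarchical_init(x: np.ndarray, c: int) -> dict | None:
    """Deterministic EM start from a complete-linkage partition of the cells."""
    labels = fcluster(linkage(x, method="complete"), t=c, criterion="maxclust")
    uniq = np.unique(labels)
    if uniq.size != c:
        return None
    k = x.shape[1]
    means = np.vstack([x[labels == u].mean(axis=0) for u in uniq])
    weights = np.array([(labels == u).mean() for u in uniq])
    precs = np.empty((c, k, k))
    for i, u in enumerate(uniq):
        var = x[labels == u].var(axis=0) + 1e-3 * np.var(x, axis=0) + 1e-10
        precs[i] = np.diag(1.0 / var)
    return dict(weights_init=weights, means_init=means, precisions_init=precs)


def _fit_gmm_candidate(
    x: np.ndarray, c: int, seed: int, n_restarts: int = 5
) -> tuple[GaussianMixture, list[float]] | None:
    """Best-of-inits EM fit for one component count; None if degenerate."""
    inits: list[dict | None] = []
    hier = _hierarchical_init(x, c)
    if hier is not None:
        inits.append(hier)
    inits.extend([None] * n_restarts)
    seeds = np.random.SeedSequence(seed).generate_state(len(inits)) % (2**31)
    best: tuple[float, GaussianMixture, list[float]] | None = None
    for init, s in zip(inits, seeds):
        try:
            gm, trace = _em_fit(x, c, int(s), init)
        except (RuntimeError, np.linalg.LinAlgError, ValueError):
            continue
        labels = gm.predict(x)
        if np.unique(labels).size != c:
            continue  # empty component: degenerate candidate
        ll = float(gm.score(x))
        if best is None or ll > best[0]:
            best = (ll, gm, trace)
    return None if best is None else (best[1], best[2])


def _empirical_centers(coords: np.ndarray, labels: np.ndarray, c: int) -> np.ndarray:
    return np.vstack([coords[labels == i].mean(axis=0) for i in range(1, c + 1)])


def select_kmeans_k(
    r: ReducedMatrix, candidate_range: range = range(2, 10), seed: int = 0
) -> int:
    """Elbow rule for the k-means cluster count.

    For each candidate count the proportion of total variance left unexplained
    by the partition (within-cluster SS / total SS) is computed; the same
    continuous two-segment linear model used for the scree is fit to that
    curve over the candidate counts and the breakpoint count is returned.  A
    breakpoint at the first candidate degenerates to a single straight line,
    so a featureless (e.g. all-zero) curve yields the smallest candidate.
    """
    x = r.coords
    counts = np.asarray(list(candidate_range), dtype=float)
    if x.shape[0] <= counts.max():
        raise ValueError("need more cells than the largest candidate count")
    tss = float(((x - x.mean(axis=0)) ** 2).sum())
    curve = np.empty(counts.shape[0])
    for i, c in enumerate(counts):
        km = KMeans(n_clusters=int(c), n_init=10, random_state=seed).fit(x)
        curve[i] = km.inertia_ / tss if tss > 0 else 0.0
    k, _, _ = fit_piecewise_linear(counts, curve, counts[:-1])
    return int(k)


def cluster_cells(
    r: ReducedMatrix,
    method: str = "gmm",
    n_clusters: int | None = None,
    candidate_range: range = range(2, 10),
    seed: int = 0,
) -> CellClusterModel:
    """Cluster cells in PC space by ``gmm`` (default), ``kmeans``, or ``none``.

    With ``n_clusters`` unset, the gmm count is chosen by BIC over
    ``candidate_range`` and the k-means count by :func:`select_kmeans_k`.
    ``none`` makes every cell its own singleton cluster.
    """
    x = np.asarray(r.coords, dtype=float)
    n = x.shape[0]
    if method == "none":
        labels = np.arange(1, n + 1)
        return CellClusterModel(
            method="none",
            n_clusters=n,
            labels=labels,
            centers=x.copy(),
            cell_ids=list(r.cell_ids),
        )

    if method == "kmeans":
        c = n_clusters if n_clusters is not None else select_kmeans_k(
            r, candidate_range, seed
        )
        km = KMeans(n_clusters=c, n_init=10, random_state=seed).fit(x)
        labels = km.labels_ + 1
        return CellClusterModel(
            method="kmeans",
            n_clusters=c,
            labels=labels,
            centers=_empirical_centers(x, labels, c),
            cell_ids=list(r.cell_ids),
        )

    if method != "gmm":
        raise ValueError(f"unknown clustering method: {method!r}")

    candidates = [n_clusters] if n_clusters is not None else list(candidate_range)
    if n_clusters is None and n <= max(candidate_range):
        raise ValueError("need more cells than the largest candidate count")
    bic_trace: dict[int, float] = {}
    fits: dict[int, tuple[GaussianMixture, list[float]]] = {}
    seeds = np.random.SeedSequence(seed).generate_state(len(candidates)) % (2**31)
    for c, s in zip(candidates, seeds):
        res = _fit_gmm_candidate(x, c, int(s))
        if res is None:
            warnings.warn(f"gmm candidate with {c} components is degenerate; skipped")
            continue
        gm, trace = res
        ll_total = float(gm.score(x)) * n
        bic_trace[c] = 2.0 * ll_total - _n_gmm_params(c, x.shape[1]) * np.log(n)
        fits[c] = (gm, trace)
    if not fits:
        raise RuntimeError(
            "every gmm candidate failed (singular covariances); try method='kmeans'"
        )
    best_c = max(sorted(fits), key=lambda c: bic_trace[c])
    gm, trace = fits[best_c]
    post = gm.predict_proba(x)
    labels = np.argmax(post, axis=1) + 1
    return CellClusterModel(
        method="gmm",
        n_clusters=best_c,
        labels=labels,
        centers=_empirical_centers(x, labels, best_c),
        cell_ids=list(r.cell_ids),
        posterior=post,
        bic_trace=bic_trace,
        component_means=gm.means_.copy(),
        loglik_trace=trace,
    )
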
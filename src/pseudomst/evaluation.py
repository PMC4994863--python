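"""Ordering-evaluation framework.

Three complementary views of an ordering's quality:

* **POS** — the pseudo-temporal ordering score: the normalized sum of signed
  pairwise collection-time differences along the ordering.  1 means the
  ordering perfectly agrees with collection time, -1 an exact reversal, and
  pairs collected at the same time contribute 0.
* **similarity** — the fraction of unordered cell pairs whose relative order
  is preserved between two orderings; a pair with a cell missing from either
  ordering counts as discordant.  Combined with cell subsampling or
  expression-noise perturbation and replicate averaging this measures
  robustness.
* **gold-gene ranking** — mean rank of independently known differential genes
  in a DE ranking, and counts recovered in the top R for a grid of R.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np

from .diffexpr import DEResult
from .io import ExpressionMatrix
from .preprocess import round_half_away
from .tree_ordering import OrderedPath


@dataclass
class TimeLabels:
    """Per-cell collection-time indices tau in {1..V}.

    Built from raw collection-time labels by ranking the distinct labels in
    ascending order; ``raw`` keeps the original label per cell for the
    optional raw-time POS weighting.
    """

    tau: dict[str, int]
    v: int
    raw: dict[str, float] | None = None

    @classmethod
    def from_matrix(cls, m: ExpressionMatrix) -> "TimeLabels":
        if m.collection_time is None:
            raise ValueError("matrix carries no collection_time labels")
        return cls.from_labels(m.cell_ids, m.collection_time)

    @classmethod
    def from_labels(cls, cell_ids: list[str], labels: np.ndarray) -> "TimeLabels":
        arr = np.asarray(labels)
        distinct = sorted(set(arr.tolist()))
        index = {lab: i + 1 for i, lab in enumerate(distinct)}
        tau = {c: index[lab] for c, lab in zip(cell_ids, arr.tolist())}
        raw = None
        try:
            raw = {c: float(lab) for c, lab in zip(cell_ids, arr.tolist())}
        except (TypeError, ValueError):
            pass
        return cls(tau=tau, v=len(distinct), raw=raw)


def pair_score(tau_i: float, tau_j: float, d_pi: float) -> float:
    """Pairwise score g for a cell at time-index tau_i ordered before one at
    tau_j: (tau_j - tau_i) / D.  Same-time pairs score exactly 0."""
    if tau_i == tau_j:
        return 0.0
    return (tau_j - tau_i) / d_pi


def _tau_vector(
    ordering: list[str], labels: TimeLabels, use_raw_times: bool
) -> np.ndarray:
    src = labels.raw if use_raw_times else labels.tau
    if use_raw_times and labels.raw is None:
        raise ValueError("raw time labels are not numeric")
    missing = [c for c in ordering if c not in src]
    if missing:
        raise ValueError(f"cells without a time label: {missing[:5]}")
    return np.asarray([src[c] for c in ordering], dtype=float)


def pos_denominator(tau: np.ndarray) -> float:
    """D = sum over unordered cell pairs of |tau_a - tau_b| — the numerator any
    time-sorted ordering attains, hence the tight normalizer."""
    n = tau.shape[0]
    srt = np.sort(tau)
    pos = np.arange(n, dtype=float)
    return float(np.sum(srt * (2 * pos - n + 1)))


def pos_score(
    ordering: list[str], labels: TimeLabels, use_raw_times: bool = False
) -> float:
    """Pseudo-temporal ordering score of one ordering against time labels.

    POS = [sum over ordered pairs i<j of (tau_j - tau_i)] / D, with D the sum
    of |tau_a - tau_b| over all unordered pairs.  Ranges over [-1, 1]; when all
    cells share one time point (D = 0) the score is defined as 0 with a
    warning.
    """
    if len(set(ordering)) != len(ordering):
        raise ValueError("ordering contains duplicate cells")
    tau = _tau_vector(ordering, labels, use_raw_times)
    n = tau.shape[0]
    d = pos_denominator(tau)
    if d == 0.0:
        warnings.warn("all cells share one time point; POS undefined, returning 0")
        return 0.0
    pos = np.arange(n, dtype=float)
    numerator = float(np.sum(tau * (2 * pos - n + 1)))
    return numerator / d


def similarity_score(pi1: list[str], pi2: list[str]) -> float:
    """Fraction of unordered pairs of the union with preserved relative order.

    A pair counts 1 only when both cells occur in both orderings with the same
    relative order; pairs involving a cell missing from either ordering count
    0 (treated as inconsistent).
    """
    if len(set(pi1)) != len(pi1) or len(set(pi2)) != len(pi2):
        raise ValueError("orderings must be duplicate-free")
    union = set(pi1) | set(pi2)
    a = len(union)
    if a < 2:
        raise ValueError("need at least 2 distinct cells across the two orderings")
    pos1 = {c: i for i, c in enumerate(pi1)}
    pos2 = {c: i for i, c in enumerate(pi2)}
    common = [c for c in pi1 if c in pos2]
    if len(common) >= 2:
        p1 = np.asarray([pos1[c] for c in common])
        p2 = np.asarray([pos2[c] for c in common])
        order = np.argsort(p1)
        s2 = p2[order]
        diff = s2[None, :] - s2[:, None]
        concordant = int(np.count_nonzero(np.triu(diff, k=1) > 0))
    else:
        concordant = 0
    return 2.0 * concordant / (a * (a - 1))


@dataclass
class PerturbationConfig:
    """One perturbation protocol: cell subsampling or expression noise."""

    scheme: str = "cell"  # "cell" or "expression"
    x: float = 0.9  # retained-cell fraction (cell scheme)
    kappa: float = 0.1  # residual scale (expression scheme)
    n_replicates: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scheme not in ("cell", "expression"):
            raise ValueError(f"unknown perturbation scheme: {self.scheme!r}")
        if self.scheme == "cell" and not 0 < self.x <= 1:
            raise ValueError("retained-cell fraction x must be in (0, 1]")
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")


def perturb_cells(m: ExpressionMatrix, x: float, seed: int = 0) -> ExpressionMatrix:
    """Subsample round(x*N) cells without replacement, columns bit-identical,
    original relative cell order preserved."""
    if not 0 < x <= 1:
        raise ValueError("x must be in (0, 1]")
    n_keep = round_half_away(x * m.n_cells)
    if n_keep < 3:
        raise ValueError(f"would keep only {n_keep} cells; need >= 3")
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(m.n_cells, size=n_keep, replace=False))
    return m.subset_cells(idx)


def perturb_expression(
    m: ExpressionMatrix, kappa: float, seed: int = 0
) -> ExpressionMatrix:
    """Add per-gene permuted, kappa-scaled mean residuals to the expression.

    For each gene the residuals around its cross-cell mean are scaled by
    kappa, permuted across cells (independently per gene) and added back.
    Per-gene means are conserved exactly; kappa = 0 is the identity.
    """
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    rng = np.random.default_rng(seed)
    vals = m.values.copy()
    for gi in range(vals.shape[0]):
        resid = vals[gi] - vals[gi].mean()
        vals[gi] = vals[gi] + kappa * rng.permutation(resid)
    return replace(m, values=vals)


def robustness(
    m: ExpressionMatrix,
    pipeline: Callable[[ExpressionMatrix], OrderedPath],
    cfg: PerturbationConfig,
) -> tuple[float, np.ndarray]:
    """Average ordering similarity between original and perturbed runs.

    The pipeline is run once on the original matrix and once per perturbed
    replicate; replicates whose pipeline raises are recorded as NaN and
    excluded from the mean (with a logged count).
    """
    base = pipeline(m)
    seeds = np.random.SeedSequence(cfg.seed).generate_state(cfg.n_replicates) % (2**31)
    sims = np.full(cfg.n_replicates, np.nan)
    failures = 0
    for i, s in enumerate(seeds):
        if cfg.scheme == "cell":
            pert = perturb_cells(m, cfg.x, int(s))
        else:
            pert = perturb_expression(m, cfg.kappa, int(s))
        try:
            rep = pipeline(pert)
        except Exception:
            failures += 1
            continue
        sims[i] = similarity_score(base.cell_order, rep.cell_order)
    if failures:
        warnings.warn(f"{failures} of {cfg.n_replicates} replicates failed; excluded")
    valid = sims[~np.isnan(sims)]
    if valid.size == 0:
        raise RuntimeError("every perturbation replicate failed")
    return float(valid.mean()), sims


def gold_gene_metrics(
    result: DEResult,
    gold: set[str],
    top_grid: list[int] | None = None,
) -> tuple[float, dict[int, int]]:
    """Mean DE rank of gold-standard genes and top-R recovery counts."""
    if top_grid is None:
        top_grid = list(range(200, 2001, 200))
    tested = set(result.table.index)
    present = gold & tested
    if not present:
        raise ValueError(
            f"no gold gene is among the tested genes; missing: {sorted(gold)[:10]}"
        )
    ranks = result.table.loc[sorted(present), "rank"].to_numpy()
    n_genes = len(result.table)
    counts = {int(r): int(np.sum(ranks <= min(r, n_genes))) for r in top_grid}
    return float(ranks.mean()), counts


@dataclass
class EvaluationReport:
    """Bundle of evaluation metrics with the configurations that produced them."""

    pos: float | None = None
    similarity_mean: float | None = None
    similarity_per_replicate: np.ndarray | None = None
    gold_mean_rank: float | None = None
    gold_top_counts: dict[int, int] | None = None
    configs: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        out: dict = dict(self.configs)
        if self.pos is not None:
            out["pos"] = self.pos
        if self.similarity_mean is not None:
            out["similarity_mean"] = self.similarity_mean
            out["similarity_per_replicate"] = [
                None if np.isnan(s) else float(s)
                for s in np.asarray(self.similarity_per_replicate)
            ]
        if self.gold_mean_rank is not None:
            out["gold_mean_rank"] = self.gold_mean_rank
            out["gold_top_counts"] = {str(k): v for k, v in (self.gold_top_counts or {}).items()}
        return out
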
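"""Synthetic single-cell trajectories with known latent pseudotime.

Cells sit on a latent axis t ~ Uniform(0, 1).  Trend genes follow a linear,
sigmoid, or transient shape in t (amplitude 3 on the log2 scale); the
remaining genes fluctuate around a constant baseline.  Gaussian noise, an
expression-dependent dropout (Bernoulli zeroing with probability
``dropout_rate * exp(-expression)``, so lowly expressed entries drop out
more), and equal-width binning of t into V collection-time points emulate the
structure of a log-transformed time-course experiment: time bins overlap in
transcriptome space, so collection time only roughly reflects the true order.

Defaults mirror a mid-sized time-course study: 300 cells, 500 genes of which
100 carry a trend, noise SD 1.0 (log2 units), dropout rate 0.2, 4 time
points.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import ExpressionMatrix

TREND_AMPLITUDE = 3.0  # log2-scale dynamic range of a trend gene
BASELINE_RANGE = (1.0, 4.0)  # log2-scale flat-gene baselines


@dataclass
class TrajectoryConfig:
    """Generative settings for one synthetic trajectory."""

    n_cells: int = 300
    n_genes: int = 500
    n_trend_genes: int = 100
    branch: bool = False
    branch_point: float = 0.5
    noise_sd: float = 1.0
    dropout_rate: float = 0.2
    n_timepoints: int = 4
    trend_shapes: tuple[str, ...] = ("linear", "sigmoid", "transient")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trend_genes > self.n_genes:
            raise ValueError("n_trend_genes cannot exceed n_genes")
        if not 0 < self.branch_point < 1:
            raise ValueError("branch_point must be in (0, 1)")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_timepoints < 1:
            raise ValueError("need at least 1 time point")
        bad = set(self.trend_shapes) - {"linear", "sigmoid", "transient"}
        if bad:
            raise ValueError(f"unknown trend shapes: {sorted(bad)}")


@dataclass
class TrajectoryTruth:
    """Ground truth accompanying a simulated matrix."""

    t: np.ndarray  # latent pseudotime in (0, 1), per cell
    branch_label: np.ndarray  # 0 (trunk / lineage A) or 1 (lineage B)
    time_bin: np.ndarray  # collection-time index 1..V
    trend_genes: list[str]
    shapes: dict[str, str] = field(default_factory=dict)


def _shape(name: str, t: np.ndarray) -> np.ndarray:
    if name == "linear":
        return t
    if name == "sigmoid":
        return 1.0 / (1.0 + np.exp(-10.0 * (t - 0.5)))
    if name == "transient":
        return np.exp(-((t - 0.5) ** 2) / (2 * 0.15**2))
    raise ValueError(f"unknown shape: {name!r}")


def simulate_trajectory(cfg: TrajectoryConfig) -> tuple[ExpressionMatrix, TrajectoryTruth]:
    """Simulate a (branched) trajectory on the log2 expression scale.

    Values are clamped at 0 before dropout so the output looks like
    log2(TPM + 1) data.  The same seed reproduces the output bit-identically.
    """
    rng = np.random.default_rng(cfg.seed)
    n, g = cfg.n_cells, cfg.n_genes
    t = rng.uniform(0.0, 1.0, n)
    branch_label = np.zeros(n, dtype=int)
    if cfg.branch:
        past = t > cfg.branch_point
        branch_label[past] = rng.integers(0, 2, int(past.sum()))

    gene_ids = [f"g{i + 1:04d}" for i in range(g)]
    cell_ids = [f"c{i + 1:04d}" for i in range(n)]
    trend_genes = gene_ids[: cfg.n_trend_genes]
    shapes: dict[str, str] = {}

    values = np.empty((g, n))
    base_lo, base_hi = BASELINE_RANGE
    for gi in range(g):
        if gi < cfg.n_trend_genes:
            shape = cfg.trend_shapes[gi % len(cfg.trend_shapes)]
            shapes[gene_ids[gi]] = shape
            u = t.copy()
            if cfg.branch and gi % 2 == 1:
                # divergent trend: lineage B retraces the trajectory past the split
                on_b = branch_label == 1
                u[on_b] = np.maximum(
                    0.0, cfg.branch_point - (t[on_b] - cfg.branch_point)
                )
            mean = base_lo + TREND_AMPLITUDE * _shape(shape, u)
        else:
            mean = np.full(n, rng.uniform(base_lo, base_hi))
        values[gi] = mean + rng.normal(0.0, cfg.noise_sd, n)
    np.maximum(values, 0.0, out=values)
    if cfg.dropout_rate > 0:
        p_drop = cfg.dropout_rate * np.exp(-values)
        values[rng.uniform(size=values.shape) < p_drop] = 0.0

    time_bin = np.minimum(
        np.floor(t * cfg.n_timepoints).astype(int) + 1, cfg.n_timepoints
    )
    m = ExpressionMatrix(
        values=values,
        gene_ids=gene_ids,
        cell_ids=cell_ids,
        collection_time=time_bin,
    )
    truth = TrajectoryTruth(
        t=t,
        branch_label=branch_label,
        time_bin=time_bin,
        trend_genes=trend_genes,
        shapes=shapes,
    )
    return m, truth


def simulate_scree(
    n_points: int,
    breakpoint: int,
    slopes: tuple[float, float],
    noise_sd: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Two-segment linear scree, continuous at the breakpoint, plus noise.

    Both slopes must be <= 0; the output is re-sorted non-increasing after
    adding noise (a valid scree is always non-increasing).
    """
    if not 2 <= breakpoint <= n_points - 1:
        raise ValueError("breakpoint must lie in [2, n_points - 1]")
    s1, s2 = slopes
    if s1 > 0 or s2 > 0:
        raise ValueError("scree slopes must be <= 0")
    rng = np.random.default_rng(seed)
    i = np.arange(1, n_points + 1, dtype=float)
    v0 = 10.0
    v = np.where(
        i <= breakpoint,
        v0 + s1 * (i - 1),
        v0 + s1 * (breakpoint - 1) + s2 * (i - breakpoint),
    )
    v = v + rng.normal(0.0, noise_sd, n_points)
    return np.sort(v)[::-1]
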
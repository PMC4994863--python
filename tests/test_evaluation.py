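import itertools

import numpy as np
import pytest

from pseudomst import (
    ExpressionMatrix,
    PerturbationConfig,
    TimeLabels,
    gold_gene_metrics,
    marker_only_ordering,
    perturb_cells,
    perturb_expression,
    pos_score,
    robustness,
    similarity_score,
)


def _labels(taus):
    cells = [f"c{i}" for i in range(len(taus))]
    return cells, TimeLabels.from_labels(cells, np.asarray(taus))


def brute_force_pos(ordering, tau_of):
    """POS by direct double sum, normalized by the max over all permutations."""
    def numerator(order):
        total = 0.0
        for i in range(len(order)):
            for j in range(i + 1, len(order)):
                total += tau_of[order[j]] - tau_of[order[i]]
        return total

    cells = list(ordering)
    best = max(numerator(list(p)) for p in itertools.permutations(cells))
    return numerator(cells) / best, best


# --------------------------------------------------------------------- POS


def test_time_sorted_ordering_scores_exactly_one():
    cells, labels = _labels([1, 1, 2, 2, 3, 3, 4, 4])
    ordering = sorted(cells, key=lambda c: labels.tau[c])
    assert pos_score(ordering, labels) == 1.0
    assert pos_score(ordering[::-1], labels) == -1.0


def test_pos_matches_exhaustive_permutation_oracle():
    cells, labels = _labels([1, 1, 2, 2, 3, 3])
    shuffled = [cells[i] for i in [4, 0, 3, 1, 5, 2]]
    expected, best = brute_force_pos(shuffled, labels.tau)
    assert pos_score(shuffled, labels) == pytest.approx(expected)
    # the tight bound: time-sorted numerator equals the permutation max
    srt = sorted(cells, key=lambda c: labels.tau[c])
    assert pos_score(srt, labels) == pytest.approx(1.0)
    assert pos_score(srt[::-1], labels) == pytest.approx(-1.0)


def test_pos_bounds_hold_for_every_permutation_of_small_fixture():
    cells, labels = _labels([1, 2, 2, 3])
    for perm in itertools.permutations(cells):
        s = pos_score(list(perm), labels)
        assert -1.0 <= s <= 1.0
        assert pos_score(list(perm)[::-1], labels) == pytest.approx(-s)


def test_pos_same_time_pairs_contribute_zero():
    from pseudomst import pair_score

    cells, labels = _labels([1, 1, 2, 3])
    assert pair_score(labels.tau["c0"], labels.tau["c1"], d_pi=7.0) == 0.0
    # swapping two same-time cells never changes POS
    base = pos_score(cells, labels)
    swapped = [cells[1], cells[0]] + cells[2:]
    assert pos_score(swapped, labels) == pytest.approx(base)


def test_pos_single_time_point_returns_zero_with_warning():
    cells, labels = _labels([2, 2, 2])
    with pytest.warns(UserWarning, match="one time point"):
        assert pos_score(cells, labels) == 0.0


def test_pos_unlabeled_cell_is_hard_error():
    _, labels = _labels([1, 2, 3])
    with pytest.raises(ValueError, match="without a time label"):
        pos_score(["c0", "zz"], labels)


def test_pos_raw_time_weighting_differs_from_index_weighting():
    cells = [f"c{i}" for i in range(4)]
    labels = TimeLabels.from_labels(cells, np.array([0, 24, 48, 720]))
    assert labels.tau == {"c0": 1, "c1": 2, "c2": 3, "c3": 4}
    mixed = [cells[1], cells[0], cells[2], cells[3]]
    s_idx = pos_score(mixed, labels)
    s_raw = pos_score(mixed, labels, use_raw_times=True)
    assert s_idx != pytest.approx(s_raw)
    assert pos_score(sorted(cells), labels, use_raw_times=True) == pytest.approx(1.0)


# -------------------------------------------------------------- similarity


def test_similarity_identity_reverse_disjoint():
    pi = [f"c{i}" for i in range(10)]
    assert similarity_score(pi, list(pi)) == 1.0
    assert similarity_score(pi, pi[::-1]) == 0.0
    assert similarity_score(pi[:5], pi[5:]) == 0.0  # disjoint cell sets


def test_similarity_is_symmetric_and_counts_missing_cells_as_discordant():
    pi1 = ["a", "b", "c", "d"]
    pi2 = ["b", "a", "c", "e"]
    s12 = similarity_score(pi1, pi2)
    assert s12 == similarity_score(pi2, pi1)
    # union has 5 cells -> 10 pairs; concordant pairs among common cells
    # {a,b,c}: (a,c) and (b,c) keep order, (a,b) flips -> 2/10
    assert s12 == pytest.approx(0.2)
    assert 0.0 <= s12 <= 1.0


def test_similarity_input_validation():
    with pytest.raises(ValueError, match="duplicate"):
        similarity_score(["a", "a"], ["a", "b"])
    with pytest.raises(ValueError, match="at least 2"):
        similarity_score(["a"], ["a"])


# ------------------------------------------------------------ perturbations


def test_perturb_cells_identity_count_and_reproducibility(labeled_matrix):
    m = labeled_matrix
    same = perturb_cells(m, 1.0, seed=0)
    assert same.cell_ids == m.cell_ids
    np.testing.assert_array_equal(same.values, m.values)

    sub = perturb_cells(m, 0.75, seed=1)
    assert sub.n_cells == 15  # round(0.75 * 20)
    for new_j, cell in enumerate(sub.cell_ids):
        old_j = m.cell_ids.index(cell)
        np.testing.assert_array_equal(sub.values[:, new_j], m.values[:, old_j])
    # original relative order is preserved
    idx = [m.cell_ids.index(c) for c in sub.cell_ids]
    assert idx == sorted(idx)

    assert perturb_cells(m, 0.75, seed=1).cell_ids == sub.cell_ids
    assert perturb_cells(m, 0.75, seed=2).cell_ids != sub.cell_ids
    with pytest.raises(ValueError, match=">= 3"):
        perturb_cells(m, 0.1, seed=0)


def test_perturb_expression_identity_and_exact_mean_conservation(labeled_matrix):
    m = labeled_matrix
    np.testing.assert_array_equal(perturb_expression(m, 0.0, seed=3).values, m.values)
    for kappa in (0.05, 0.25, 1.0):
        out = perturb_expression(m, kappa, seed=4)
        np.testing.assert_allclose(
            out.values.mean(axis=1), m.values.mean(axis=1), rtol=0, atol=1e-12
        )
        assert not np.array_equal(out.values, m.values)


def test_perturb_expression_matches_hand_computation():
    row = np.array([1.0, 2.0, 3.0, 4.0, 10.0])
    m = ExpressionMatrix(
        values=row[None, :],
        gene_ids=["g"],
        cell_ids=[f"c{i}" for i in range(5)],
    )
    seed = 9
    out = perturb_expression(m, 0.25, seed=seed)
    resid = row - row.mean()
    perm = np.random.default_rng(seed).permutation(resid)
    np.testing.assert_allclose(out.values[0], row + 0.25 * perm)


def test_perturb_expression_variance_inflates_by_one_plus_kappa_sq():
    rng = np.random.default_rng(5)
    row = rng.normal(0, 2.0, 400)
    m = ExpressionMatrix(
        values=row[None, :],
        gene_ids=["g"],
        cell_ids=[f"c{i}" for i in range(400)],
    )
    kappa = 0.5
    ratios = [
        perturb_expression(m, kappa, seed=s).values[0].var() / row.var()
        for s in range(40)
    ]
    # E[var'] ~ (1 + kappa^2) * var, up to the O(1/N) cross term
    assert np.mean(ratios) == pytest.approx(1 + kappa**2, abs=0.03)


# -------------------------------------------------------------- robustness


def _marker_pipeline(gene):
    def pipeline(m):
        return marker_only_ordering(m, gene)

    return pipeline


def test_robustness_identity_perturbation_is_one(labeled_matrix):
    cfg = PerturbationConfig(scheme="cell", x=1.0, n_replicates=5, seed=0)
    mean, per_rep = robustness(
        labeled_matrix, _marker_pipeline("g0"), cfg
    )
    assert mean == 1.0
    np.testing.assert_array_equal(per_rep, np.ones(5))


def test_robustness_default_runs_100_replicates(labeled_matrix):
    cfg = PerturbationConfig(scheme="cell", x=0.9, seed=1)
    assert cfg.n_replicates == 100
    mean, per_rep = robustness(labeled_matrix, _marker_pipeline("g1"), cfg)
    assert per_rep.shape == (100,)
    assert 0.0 <= mean <= 1.0


def test_expression_ignoring_pipeline_is_fully_robust_to_expression_noise(
    labeled_matrix,
):
    # a pipeline ordering by cell id ignores expression entirely: robustness 1
    def by_id(m):
        from pseudomst.tree_ordering import OrderedPath

        order = sorted(m.cell_ids)
        return OrderedPath(
            cluster_sequence=[],
            cell_order=order,
            pseudotime=np.arange(1, len(order) + 1),
        )

    cfg = PerturbationConfig(scheme="expression", kappa=0.25, n_replicates=10, seed=2)
    mean, _ = robustness(labeled_matrix, by_id, cfg)
    assert mean == 1.0  # robustness alone cannot certify a good ordering


def test_robustness_monotone_signal_beats_random_baseline():
    rng = np.random.default_rng(6)
    n = 80
    t = np.sort(rng.uniform(0, 1, n))
    trend = 5 * t + rng.normal(0, 0.2, n)
    m = ExpressionMatrix(
        values=np.vstack([trend, rng.normal(size=n)]),
        gene_ids=["trend", "noise"],
        cell_ids=[f"c{i}" for i in range(n)],
    )
    cfg = PerturbationConfig(scheme="cell", x=0.9, n_replicates=20, seed=3)
    good, _ = robustness(m, _marker_pipeline("trend"), cfg)

    def random_pipeline(mm):
        from pseudomst.tree_ordering import OrderedPath

        r = np.random.default_rng(abs(hash(tuple(mm.cell_ids))) % 2**31)
        order = list(np.asarray(mm.cell_ids)[r.permutation(mm.n_cells)])
        return OrderedPath(
            cluster_sequence=[],
            cell_order=order,
            pseudotime=np.arange(1, len(order) + 1),
        )

    bad, _ = robustness(m, random_pipeline, cfg)
    assert good > bad


def test_failed_replicates_are_excluded_with_warning(labeled_matrix):
    calls = {"n": 0}

    def flaky(m):
        calls["n"] += 1
        if calls["n"] % 2 == 0:
            raise RuntimeError("boom")
        return marker_only_ordering(m, "g0")

    cfg = PerturbationConfig(scheme="cell", x=0.9, n_replicates=6, seed=4)
    with pytest.warns(UserWarning, match="replicates failed"):
        mean, per_rep = robustness(labeled_matrix, flaky, cfg)
    assert np.isnan(per_rep).sum() == 3


# ---------------------------------------------------------------- gold genes


def _de_result(n_genes, seed=0):
    import pandas as pd

    from pseudomst.diffexpr import DEResult

    rng = np.random.default_rng(seed)
    ranks = rng.permutation(n_genes) + 1
    tab = pd.DataFrame(
        {"rank": ranks},
        index=pd.Index([f"g{i}" for i in range(n_genes)], name="gene_id"),
    )
    return DEResult(table=tab)


def test_gold_metrics_arithmetic_and_oracle():
    res = _de_result(50)
    top = {g for g in res.table.index if res.table.loc[g, "rank"] <= 5}
    mean_rank, counts = gold_gene_metrics(res, top, top_grid=[3, 5, 10])
    assert mean_rank == (5 + 1) / 2
    assert counts == {3: 3, 5: 5, 10: 5}

    # random gold set vs a direct set-intersection oracle per R
    rng = np.random.default_rng(1)
    res2 = _de_result(1000, seed=2)
    gold = set(rng.choice(list(res2.table.index), 10, replace=False))
    mean_rank2, counts2 = gold_gene_metrics(res2, gold)
    ranked = list(res2.table.sort_values("rank").index)
    for r, count in counts2.items():
        assert count == len(set(ranked[:r]) & gold)
    assert mean_rank2 == pytest.approx(
        np.mean([ranked.index(g) + 1 for g in gold])
    )


def test_gold_count_zero_below_best_rank_and_empty_intersection_errors():
    res = _de_result(100, seed=3)
    gold = {res.table["rank"].idxmax()}  # worst-ranked gene (rank 100)
    _, counts = gold_gene_metrics(res, gold, top_grid=[1, 99, 100])
    assert counts == {1: 0, 99: 0, 100: 1}
    with pytest.raises(ValueError, match="no gold gene"):
        gold_gene_metrics(res, {"absent1", "absent2"})
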
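"""Outcome comparisons across clusters: ANOVA, rank tests, post-hoc."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from archefda.outcome_association import (
    associate,
    conditional_density,
    count_separated_clusters,
    kruskal_wallis,
    oneway_anova,
    pairwise_adjust,
    pairwise_mean_tests,
    tukey_hsd,
)


def _labels(*groups):
    y, lab = [], []
    for name, vals in groups:
        y += list(vals)
        lab += [name] * len(vals)
    return np.array(y, float), np.array(lab)


# ---------------------------------------------------------------------------
# conditional densities


def test_single_member_cluster_is_one_gaussian_bump():
    y, lab = _labels(("S1", [2.0]), ("S2", [0.0, 0.1]))
    grid, curves = conditional_density(y, lab, bandwidth=1.0,
                                       grid=np.linspace(-4, 8, 1201))
    bump = curves["S1"]
    assert grid[np.argmax(bump)] == pytest.approx(2.0, abs=0.02)
    np.testing.assert_allclose(
        bump, stats.norm.pdf(grid, loc=2.0, scale=1.0), atol=1e-12
    )


def test_densities_integrate_to_one(rng):
    y, lab = _labels(("S1", rng.standard_normal(40)),
                     ("S2", rng.standard_normal(25) + 1))
    grid, curves = conditional_density(y, lab)
    for c in curves.values():
        assert np.trapezoid(c, grid) == pytest.approx(1.0, abs=1e-3)


def test_location_shift_moves_density_mode():
    rng = np.random.default_rng(31)
    y, lab = _labels(("S1", rng.standard_normal(500)),
                     ("S2", rng.standard_normal(500) + 1.0))
    grid, curves = conditional_density(y, lab)
    shift = grid[np.argmax(curves["S2"])] - grid[np.argmax(curves["S1"])]
    assert shift == pytest.approx(1.0, abs=0.35)


# ---------------------------------------------------------------------------
# one-way ANOVA


def test_identical_groups_give_zero_f():
    y, lab = _labels(("S1", [1, 2, 3]), ("S2", [1, 2, 3]))
    rec = oneway_anova(y, lab)
    assert rec.F == pytest.approx(0.0)
    assert rec.p == pytest.approx(1.0)


def test_hand_computed_sums_of_squares():
    y, lab = _labels(("S1", [0.0, 0.0]), ("S2", [1.0, 1.0]))
    rec = oneway_anova(y, lab)
    assert rec.ss_between == pytest.approx(1.0)
    assert rec.ss_within == pytest.approx(0.0)


def test_sum_of_squares_decomposition(rng):
    y, lab = _labels(("S1", rng.standard_normal(12)),
                     ("S2", rng.standard_normal(9) + 0.4),
                     ("S3", rng.standard_normal(15) - 0.2))
    rec = oneway_anova(y, lab)
    total = ((y - y.mean()) ** 2).sum()
    assert rec.ss_between + rec.ss_within == pytest.approx(total, abs=1e-8)
    assert rec.F >= 0
    # agreement with the reference implementation
    f_ref, p_ref = stats.f_oneway(y[lab == "S1"], y[lab == "S2"], y[lab == "S3"])
    assert rec.F == pytest.approx(f_ref)
    assert rec.p == pytest.approx(p_ref)


def test_separated_means_are_detected_with_high_power():
    rng = np.random.default_rng(44)
    rejections = 0
    for _ in range(20):
        y, lab = _labels(*[
            (f"S{m + 1}", rng.normal(mu, 0.4, 30))
            for m, mu in enumerate((0.6, 0.2, -0.2, -0.6))
        ])
        if oneway_anova(y, lab).p < 0.05:
            rejections += 1
    assert rejections == 20


def test_anova_needs_two_groups():
    y, lab = _labels(("S1", [1.0, 2.0]))
    with pytest.raises(ValueError, match="2 non-empty groups"):
        oneway_anova(y, lab)


# ---------------------------------------------------------------------------
# Kruskal-Wallis


def test_identical_groups_have_zero_h():
    y, lab = _labels(("S1", [1, 2, 3]), ("S2", [1, 2, 3]))
    h, p = kruskal_wallis(y, lab)
    assert h == pytest.approx(0.0)


def test_rank_formula_on_two_pairs():
    # groups (1,2) and (3,4): ranks (1,2) and (3,4); the closed-form rank
    # statistic H = 12/(N(N+1)) * sum n_i (Rbar_i - Rbar)^2 gives 2.4
    y, lab = _labels(("S1", [1.0, 2.0]), ("S2", [3.0, 4.0]))
    h, _ = kruskal_wallis(y, lab)
    ranks = stats.rankdata(y)
    rbar = ranks.mean()
    manual = 12.0 / (4 * 5) * sum(
        2 * (ranks[lab == g].mean() - rbar) ** 2 for g in ("S1", "S2")
    )
    assert h == pytest.approx(manual)
    assert h == pytest.approx(2.4)


def test_fully_tied_outcomes_give_zero_h():
    y, lab = _labels(("S1", [5.0, 5.0]), ("S2", [5.0, 5.0, 5.0]))
    h, p = kruskal_wallis(y, lab)
    assert h == 0.0
    assert p == 1.0


# ---------------------------------------------------------------------------
# Tukey HSD


def test_two_group_tukey_equals_pooled_t_test(rng):
    a, b = rng.standard_normal(12), rng.standard_normal(15) + 0.5
    y, lab = _labels(("S1", a), ("S2", b))
    recs = tukey_hsd(y, lab)
    _, p_t = stats.ttest_ind(a, b, equal_var=True)
    assert recs[0].p_adjusted == pytest.approx(p_t, abs=1e-9)


def test_identical_groups_are_never_separated():
    y, lab = _labels(("S1", [1.0, 2.0, 3.0]), ("S2", [1.0, 2.0, 3.0]),
                     ("S3", [1.0, 2.0, 3.0]))
    recs = tukey_hsd(y, lab)
    for r in recs:
        assert r.p_adjusted == pytest.approx(1.0)
        assert r.ci_low <= 0.0 <= r.ci_high


def test_balanced_four_group_ci_half_width_matches_closed_form(rng):
    groups = [("S%d" % (m + 1), rng.normal(m, 1.0, 10)) for m in range(4)]
    y, lab = _labels(*groups)
    recs = tukey_hsd(y, lab, familywise_alpha=0.05)
    rec_anova = oneway_anova(y, lab)
    q = stats.studentized_range.ppf(0.95, 4, rec_anova.df_within)
    half = q * np.sqrt(rec_anova.ms_within / 10)
    for r in recs:
        assert (r.ci_high - r.ci_low) / 2 == pytest.approx(half, rel=1e-6)


# ---------------------------------------------------------------------------
# p-value adjustment


def test_bonferroni_hand_example():
    np.testing.assert_allclose(
        pairwise_adjust([0.01, 0.02, 0.03], "bonferroni"), [0.03, 0.06, 0.09]
    )


def test_benjamini_hochberg_hand_example():
    np.testing.assert_allclose(
        pairwise_adjust([0.01, 0.02, 0.03], "benjamini_hochberg"),
        [0.03, 0.03, 0.03],
    )


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=12),
       st.sampled_from(["bonferroni", "benjamini_hochberg"]))
def test_adjusted_p_never_below_raw(p, method):
    adj = pairwise_adjust(p, method)
    assert np.all(adj >= np.asarray(p) - 1e-12)
    assert np.all(adj <= 1.0 + 1e-12)


# ---------------------------------------------------------------------------
# separated-cluster counting


class _Rec:
    def __init__(self, pair, p):
        self.pair = pair
        self.p_adjusted = p


def _pairwise(pvals):
    pairs = [("S1", "S2"), ("S1", "S3"), ("S1", "S4"),
             ("S2", "S3"), ("S2", "S4"), ("S3", "S4")]
    return [_Rec(pair, p) for pair, p in zip(pairs, pvals)]


def _four_group_labels(sizes=(5, 5, 5, 5)):
    return np.array(sum([["S%d" % (m + 1)] * s for m, s in enumerate(sizes)], []))


def test_all_pairs_significant_gives_four():
    labels = _four_group_labels()
    assert count_separated_clusters(_pairwise([0.01] * 6), labels) == 4


def test_one_merged_pair_gives_three():
    labels = _four_group_labels()
    pv = [0.01] * 6
    pv[5] = 0.4  # S3-S4 merge
    assert count_separated_clusters(_pairwise(pv), labels) == 3


def test_no_significant_pair_gives_one():
    labels = _four_group_labels()
    assert count_separated_clusters(_pairwise([0.9] * 6), labels) == 1


def test_small_clusters_are_excluded():
    labels = _four_group_labels(sizes=(5, 5, 5, 1))
    assert count_separated_clusters(_pairwise([0.01] * 6), labels, min_size=2) == 3


def test_fewer_than_two_qualifying_clusters():
    labels = _four_group_labels(sizes=(5, 1, 1, 1))
    assert count_separated_clusters(_pairwise([0.01] * 6), labels, min_size=2) == 1


def test_count_invariant_to_relabeling():
    labels = _four_group_labels()
    pv = [0.01, 0.01, 0.01, 0.5, 0.01, 0.01]  # S2-S3 merged
    base = count_separated_clusters(_pairwise(pv), labels)
    # swap the names S2 <-> S3 everywhere
    swap = {"S2": "S3", "S3": "S2"}
    labels2 = np.array([swap.get(l, l) for l in labels])
    recs2 = [_Rec((swap.get(a, a), swap.get(b, b)), r.p_adjusted)
             for r in _pairwise(pv) for a, b in [r.pair]]
    assert count_separated_clusters(recs2, labels2) == base == 3


def test_null_distribution_of_full_separation_is_rare():
    """Under a global null all four clusters come from one distribution,
    so seeing >= 2 separated clusters should be roughly as rare as the
    family-wise level."""
    rng = np.random.default_rng(7)
    hits = 0
    reps = 200
    for _ in range(reps):
        y = rng.standard_normal(48)
        labels = _four_group_labels(sizes=(12, 12, 12, 12))
        recs = tukey_hsd(y, labels, familywise_alpha=0.05)
        if count_separated_clusters(recs, labels) >= 2:
            hits += 1
    assert hits / reps < 0.10


# ---------------------------------------------------------------------------
# the composite report


def test_association_report_is_consistent(rng):
    y = np.concatenate([
        rng.normal(0.6, 0.4, 14), rng.normal(0.2, 0.4, 11),
        rng.normal(-0.2, 0.4, 13), rng.normal(-0.6, 0.4, 12),
        rng.normal(0.0, 1.0, 150),
    ])
    labels = np.array(["S1"] * 14 + ["S2"] * 11 + ["S3"] * 13 + ["S4"] * 12
                      + ["normal"] * 150)
    res = associate(y, labels, with_densities=True)
    assert res.group_sizes == {"S1": 14, "S2": 11, "S3": 13, "S4": 12}
    assert 0 <= res.n_separated <= 4
    assert len(res.pairwise) == 6
    assert res.anova.F >= 0
    assert "normal" in res.conditional_densities
    doc = res.to_dict()
    assert set(doc) >= {"group_sizes", "anova", "kruskal", "pairwise", "n_separated"}


def test_bonferroni_posthoc_route(rng):
    y = np.concatenate([rng.normal(m, 0.4, 10) for m in (0.6, 0.2, -0.2, -0.6)])
    labels = _four_group_labels(sizes=(10, 10, 10, 10))
    res = associate(y, labels, posthoc="bonferroni")
    assert all(r.method == "bonferroni" for r in res.pairwise)
    raw = [stats.ttest_ind(y[labels == a], y[labels == b], equal_var=True)[1]
           for a, b in [r.pair for r in res.pairwise]]
    np.testing.assert_allclose(
        [r.p_adjusted for r in res.pairwise],
        np.minimum(np.asarray(raw) * 6, 1.0), atol=1e-12,
    )


def test_pairwise_mean_tests_unknown_method(rng):
    y, lab = _labels(("S1", rng.standard_normal(5)), ("S2", rng.standard_normal(5)))
    with pytest.raises(ValueError, match="unknown adjustment"):
        pairwise_mean_tests(y, lab, method="holmes")
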
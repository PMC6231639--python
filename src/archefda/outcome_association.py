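"""Comparison of outcome distributions across archetype clusters.

The labeled outlier subgroups (S1..S4) are compared on a scalar outcome
with one-way ANOVA and the Kruskal-Wallis rank test, followed by
all-pairs Tukey HSD (Tukey-Kramer for unequal sizes) or p-value
adjustment by Bonferroni / Benjamini-Hochberg.  The headline summary is
the number of "completely separated" clusters: connected components of
the graph that joins two subgroups whenever their adjusted pairwise
difference is NOT significant, so that every pair across two different
components differs significantly.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

CLUSTER_LABELS = ("S1", "S2", "S3", "S4")


@dataclass
class AnovaRecord:
    df_between: int
    df_within: int
    ss_between: float
    ss_within: float
    ms_between: float
    ms_within: float
    F: float
    p: float


@dataclass
class PairwiseRecord:
    pair: tuple             # (label_a, label_b)
    mean_diff: float        # mean(a) - mean(b)
    ci_low: float
    ci_high: float
    p_adjusted: float
    method: str


@dataclass
class AssociationResult:
    group_sizes: dict
    anova: AnovaRecord
    kruskal: tuple          # (H, p)
    pairwise: list          # PairwiseRecord per pair
    n_separated: int
    conditional_densities: dict | None = None
    density_grid: np.ndarray | None = None

    def to_dict(self) -> dict:
        return {
            "group_sizes": self.group_sizes,
            "anova": vars(self.anova),
            "kruskal": {"H": self.kruskal[0], "p": self.kruskal[1]},
            "pairwise": [
                {"pair": list(r.pair), "mean_diff": r.mean_diff,
                 "ci_low": r.ci_low, "ci_high": r.ci_high,
                 "p_adjusted": r.p_adjusted, "method": r.method}
                for r in self.pairwise
            ],
            "n_separated": self.n_separated,
        }


def _groups(y, labels, include=CLUSTER_LABELS, min_size=1):
    y = np.asarray(y, float)
    labels = np.asarray(labels)
    out = {}
    for lab in include:
        vals = y[labels == lab]
        if len(vals) >= min_size:
            out[lab] = vals
    return out


def conditional_density(y, labels, bandwidth="auto", grid=None,
                        include=CLUSTER_LABELS + ("normal",)):
    """Gaussian-kernel outcome density per cluster on a shared grid.

    ``bandwidth="auto"`` uses Silverman's rule on the pooled outcomes.
    Returns (grid, {label: density curve}).
    """
    y = np.asarray(y, float)
    if bandwidth == "auto":
        n = y.size
        sd = y.std(ddof=1)
        iqr = np.subtract(*np.percentile(y, [75, 25]))
        scale = min(sd, iqr / 1.349) if iqr > 0 else sd
        bandwidth = 0.9 * scale * n ** (-0.2)
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    if grid is None:
        lo, hi = y.min() - 3 * bandwidth, y.max() + 3 * bandwidth
        grid = np.linspace(lo - 0.1 * (hi - lo), hi + 0.1 * (hi - lo), 401)
    grid = np.asarray(grid, float)
    curves = {}
    labels = np.asarray(labels)
    for lab in include:
        vals = y[labels == lab]
        if vals.size == 0:
            warnings.warn(f"cluster {lab} is empty; density skipped")
            continue
        u = (grid[:, None] - vals[None, :]) / bandwidth
        curves[lab] = np.exp(-0.5 * u * u).sum(axis=1) / (
            vals.size * bandwidth * np.sqrt(2 * np.pi)
        )
    return grid, curves


def oneway_anova(y, labels, include=CLUSTER_LABELS) -> AnovaRecord:
    """Classical one-way fixed-effects ANOVA over the labeled subgroups."""
    groups = _groups(y, labels, include)
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least 2 non-empty groups")
    ns = np.array([len(g) for g in groups.values()])
    n_tot = int(ns.sum())
    k = len(groups)
    if n_tot <= k:
        raise ValueError("ANOVA needs more observations than groups")
    allv = np.concatenate(list(groups.values()))
    gm = allv.mean()
    ss_b = float(sum(len(g) * (g.mean() - gm) ** 2 for g in groups.values()))
    ss_w = float(sum(((g - g.mean()) ** 2).sum() for g in groups.values()))
    df_b, df_w = k - 1, n_tot - k
    ms_b, ms_w = ss_b / df_b, ss_w / df_w
    if ms_w == 0:
        f = np.inf if ss_b > 0 else 0.0
        p = 0.0 if ss_b > 0 else 1.0
    else:
        f = ms_b / ms_w
        p = float(stats.f.sf(f, df_b, df_w))
    return AnovaRecord(df_b, df_w, ss_b, ss_w, ms_b, ms_w, float(f), p)


def kruskal_wallis(y, labels, include=CLUSTER_LABELS) -> tuple:
    """Tie-corrected Kruskal-Wallis H with chi-square reference."""
    groups = _groups(y, labels, include)
    if len(groups) < 2:
        raise ValueError("Kruskal-Wallis needs at least 2 non-empty groups")
    vals = list(groups.values())
    if all(np.all(v == vals[0][0]) for v in vals):
        return 0.0, 1.0  # all observations tied; no rank variation
    h, p = stats.kruskal(*vals)
    return float(h), float(p)


def tukey_hsd(y, labels, familywise_alpha=0.05, include=CLUSTER_LABELS):
    """All-pairs Tukey HSD records (Tukey-Kramer for unequal sizes).

    Groups with fewer than two members carry no within-group variance
    and are excluded from the family.
    """
    groups = _groups(y, labels, include, min_size=2)
    names = list(groups)
    if len(names) < 2:
        raise ValueError("Tukey HSD needs at least 2 groups")
    res = stats.tukey_hsd(*[groups[g] for g in names])
    ci = res.confidence_interval(confidence_level=1 - familywise_alpha)
    records = []
    for a, b in combinations(range(len(names)), 2):
        records.append(PairwiseRecord(
            pair=(names[a], names[b]),
            mean_diff=float(groups[names[a]].mean() - groups[names[b]].mean()),
            ci_low=float(ci.low[a, b]),
            ci_high=float(ci.high[a, b]),
            p_adjusted=float(res.pvalue[a, b]),
            method="tukey",
        ))
    return records


def pairwise_adjust(p_values, method="bonferroni"):
    """Bonferroni or Benjamini-Hochberg adjusted p-values, capped at 1."""
    p = np.asarray(p_values, float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    key = {"bonferroni": "bonferroni", "benjamini_hochberg": "fdr_bh", "bh": "fdr_bh"}
    if method not in key:
        raise ValueError(f"unknown adjustment method {method!r}")
    return multipletests(p, method=key[method])[1]


def pairwise_mean_tests(y, labels, method, familywise_alpha=0.05,
                        include=CLUSTER_LABELS):
    """All-pairs Welch-free two-sample t tests with p-value adjustment.

    Pooled-variance two-sample t per pair, then Bonferroni or BH across
    the family.  Confidence bounds are per-pair (unadjusted width) and
    reported for orientation only.
    """
    groups = _groups(y, labels, include, min_size=2)
    names = list(groups)
    raw, recs = [], []
    for a, b in combinations(names, 2):
        ga, gb = groups[a], groups[b]
        t, p = stats.ttest_ind(ga, gb, equal_var=True)
        raw.append(float(p))
        recs.append((a, b, float(ga.mean() - gb.mean()), ga, gb))
    adj = pairwise_adjust(raw, method)
    records = []
    for (a, b, diff, ga, gb), p_adj in zip(recs, adj):
        na, nb = len(ga), len(gb)
        df = na + nb - 2
        sp2 = (((ga - ga.mean()) ** 2).sum() + ((gb - gb.mean()) ** 2).sum()) / df
        half = stats.t.ppf(1 - familywise_alpha / 2, df) * np.sqrt(sp2 * (1 / na + 1 / nb))
        records.append(PairwiseRecord(
            pair=(a, b), mean_diff=diff, ci_low=diff - half, ci_high=diff + half,
            p_adjusted=float(p_adj), method=method,
        ))
    return records


def count_separated_clusters(pairwise, labels, familywise_alpha=0.05, min_size=2,
                             include=CLUSTER_LABELS) -> int:
    """Number of completely separated clusters.

    Clusters of size >= ``min_size`` are graph nodes; an edge joins two
    clusters whose adjusted pairwise p is >= the family-wise level (not
    separated).  The count is the number of connected components, so
    clusters in different components differ significantly from every
    cluster outside their own component.
    """
    labels = np.asarray(labels)
    qualifying = [lab for lab in include if np.sum(labels == lab) >= min_size]
    if len(qualifying) < 2:
        return len(qualifying)
    idx = {lab: i for i, lab in enumerate(qualifying)}
    rows, cols = [], []
    for rec in pairwise:
        a, b = rec.pair
        if a in idx and b in idx and rec.p_adjusted >= familywise_alpha:
            rows += [idx[a], idx[b]]
            cols += [idx[b], idx[a]]
    m = len(qualifying)
    graph = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(m, m))
    n_comp, _ = connected_components(graph, directed=False)
    return int(n_comp)


def associate(y, labels, familywise_alpha=0.05, posthoc="tukey", min_size=2,
              with_densities=False) -> AssociationResult:
    """Full association analysis of outcomes against archetype clusters.

    Outlier subgroups only (the "normal" group is excluded from the
    testing, though its density can still be drawn).
    """
    labels = np.asarray(labels)
    sizes = {lab: int(np.sum(labels == lab)) for lab in CLUSTER_LABELS}
    anova = oneway_anova(y, labels)
    kw = kruskal_wallis(y, labels)
    if posthoc == "tukey":
        pairwise = tukey_hsd(y, labels, familywise_alpha)
    else:
        pairwise = pairwise_mean_tests(y, labels, posthoc, familywise_alpha)
    n_sep = count_separated_clusters(pairwise, labels, familywise_alpha, min_size)
    grid = curves = None
    if with_densities:
        grid, curves = conditional_density(y, labels)
    return AssociationResult(
        group_sizes=sizes, anova=anova, kruskal=kw, pairwise=pairwise,
        n_separated=n_sep, conditional_densities=curves, density_grid=grid,
    )
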
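"""Quantification statistics: 2^(−ΔΔCT) expression analysis, the proteomics
differential filter, and a normality-routed group-comparison harness.

* ``ddct``: per-sample ΔCT against the arithmetic mean of housekeeping
  genes, ΔΔCT against the reference-group mean, fold change 2^(−ΔΔCT).
  Hypothesis tests belong on the ΔCT scale, which the output preserves.
* ``de_filter``: per-protein two-sample t-test on log2 abundances,
  Benjamini-Hochberg adjustment, and a three-part pass rule
  (q ≤ FDR, |log2FC| > cutoff, ≥ 2 peptides).
* ``group_compare``: routes to ANOVA + Bonferroni pairwise contrasts when
  every group passes a normality check, otherwise to Kruskal-Wallis +
  Dunn's test (two groups: t-test vs. rank-sum).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = ["ddct", "de_filter", "GroupCompareReport", "group_compare"]

DEFAULT_HOUSEKEEPING = ("Gapdh", "Gusb")


def ddct(
    table: pd.DataFrame,
    reference_group: str,
    housekeeping: Sequence[str] = DEFAULT_HOUSEKEEPING,
    sample_column: str = "sample",
    group_column: str = "group",
    gene_column: str = "gene",
    ct_column: str = "Ct",
) -> pd.DataFrame:
    """Relative expression by the 2^(−ΔΔCT) method.

    ΔCT = Ct(gene) − mean Ct(housekeeping) within each sample; ΔΔCT =
    ΔCT − mean ΔCT of the reference group for that gene; fold change =
    2^(−ΔΔCT). Returns one row per (sample, gene) for non-housekeeping
    genes, carrying ``dct`` (the scale on which statistics should be run),
    ``ddct`` and ``fold_change``.
    """
    for col in (sample_column, group_column, gene_column, ct_column):
        if col not in table.columns:
            raise KeyError(f"missing column '{col}'")
    if reference_group not in set(table[group_column]):
        raise ValueError(f"reference group {reference_group!r} not present")
    housekeeping = list(housekeeping)

    hk = table[table[gene_column].isin(housekeeping)]
    hk_mean = hk.groupby(sample_column)[ct_column].agg(["mean", "count"])
    bad = hk_mean[hk_mean["count"] < len(housekeeping)]
    missing_samples = set(table[sample_column]) - set(hk_mean.index)
    if len(bad) or missing_samples:
        culprits = sorted(set(bad.index) | missing_samples)
        raise ValueError(f"samples missing housekeeping genes: {culprits}")

    out = table[~table[gene_column].isin(housekeeping)].copy()
    out["dct"] = out[ct_column] - out[sample_column].map(hk_mean["mean"])
    ref_dct = (
        out[out[group_column] == reference_group]
        .groupby(gene_column)["dct"]
        .mean()
    )
    out["ddct"] = out["dct"] - out[gene_column].map(ref_dct)
    out["fold_change"] = 2.0 ** (-out["ddct"])
    return out.reset_index(drop=True)


def de_filter(
    table: pd.DataFrame,
    design: dict[str, Sequence[str]],
    fdr: float = 0.01,
    lfc_min: float = 0.5,
    min_peptides: int = 2,
    id_column: str = "protein_id",
    peptide_column: str = "peptides",
    equal_var: bool = False,
) -> pd.DataFrame:
    """Differential-abundance filter for a two-group protein table.

    Per protein: two-sided two-sample t-test on log2 abundances (Welch by
    default, classic equal-variance selectable), BH adjustment across all
    testable proteins, and ``passed`` requiring q ≤ ``fdr``, |log2FC| >
    ``lfc_min`` (log2FC = second group minus first) and at least
    ``min_peptides`` peptides. Proteins with undefined tests (constant
    abundances) get NaN p-values and never pass.
    """
    if len(design) != 2:
        raise ValueError("design must name exactly two groups")
    (ga, cols_a), (gb, cols_b) = design.items()
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("each group needs at least 2 samples")

    a = np.log2(table[list(cols_a)].to_numpy(dtype=float))
    b = np.log2(table[list(cols_b)].to_numpy(dtype=float))
    log2fc = b.mean(axis=1) - a.mean(axis=1)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        t, p = sps.ttest_ind(b, a, axis=1, equal_var=equal_var)
    p = np.asarray(p, dtype=float)
    degenerate = (a.std(axis=1) == 0) & (b.std(axis=1) == 0)
    p[degenerate] = np.nan

    q = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]

    peptides = table[peptide_column].to_numpy()
    passed = ok & (q <= fdr) & (np.abs(log2fc) > lfc_min) & (peptides >= min_peptides)
    return pd.DataFrame(
        {
            id_column: table[id_column].to_numpy(),
            "log2fc": log2fc,
            "t": t,
            "p": p,
            "q": q,
            "peptides": peptides,
            "passed": passed,
        }
    )


@dataclass
class GroupCompareReport:
    """Outcome of the normality-routed comparison of ≥ 2 groups."""

    route: str  # "parametric" | "nonparametric"
    omnibus_test: str
    omnibus_stat: float
    omnibus_p: float
    normality: pd.DataFrame
    pairwise: pd.DataFrame
    warnings: list[str] = field(default_factory=list)

    @property
    def significant(self) -> bool:
        return bool(self.omnibus_p < 0.05)


def _normality_p(x: np.ndarray, dagostino_min_n: int = 8) -> tuple[str, float]:
    """D'Agostino-Pearson for n >= 8, Shapiro-Wilk below (the omnibus
    moment test is unreliable at very small n)."""
    if x.size >= dagostino_min_n:
        stat, p = sps.normaltest(x)
        return "dagostino-pearson", float(p)
    stat, p = sps.shapiro(x)
    return "shapiro-wilk", float(p)


def _dunn_pairwise(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Dunn's z-tests on mean ranks with tie correction, Bonferroni-adjusted
    (the standard post-hoc companion of Kruskal-Wallis)."""
    names = list(groups)
    all_vals = np.concatenate([groups[g] for g in names])
    ranks = sps.rankdata(all_vals)
    n_total = all_vals.size
    rank_means, sizes, i = {}, {}, 0
    for g in names:
        k = groups[g].size
        rank_means[g] = ranks[i : i + k].mean()
        sizes[g] = k
        i += k
    _, tie_counts = np.unique(all_vals, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1))
    var_unit = n_total * (n_total + 1) / 12.0 - tie_term

    rows = []
    pairs = list(itertools.combinations(names, 2))
    for g1, g2 in pairs:
        se = np.sqrt(var_unit * (1.0 / sizes[g1] + 1.0 / sizes[g2]))
        z = (rank_means[g1] - rank_means[g2]) / se
        p = 2.0 * sps.norm.sf(abs(z))
        rows.append({"group_1": g1, "group_2": g2, "stat": float(z), "p": float(p)})
    df = pd.DataFrame(rows)
    df["p_adj"] = np.minimum(df["p"] * len(pairs), 1.0)
    return df


def _bonferroni_t_pairwise(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    rows = []
    pairs = list(itertools.combinations(groups, 2))
    for g1, g2 in pairs:
        t, p = sps.ttest_ind(groups[g1], groups[g2])
        rows.append({"group_1": g1, "group_2": g2, "stat": float(t), "p": float(p)})
    df = pd.DataFrame(rows)
    df["p_adj"] = np.minimum(df["p"] * len(pairs), 1.0)
    return df


def group_compare(
    data: pd.DataFrame,
    value_column: str = "value",
    group_column: str = "group",
    alpha_normality: float = 0.05,
) -> GroupCompareReport:
    """Compare ≥ 2 groups, choosing the test family from normality checks.

    Every group is screened for normality (D'Agostino-Pearson at n ≥ 8,
    Shapiro-Wilk below). If all groups pass at ``alpha_normality``:
    two groups -> two-tailed t-test; more -> one-way ANOVA with
    Bonferroni-corrected pairwise t contrasts. Otherwise: two groups ->
    Mann-Whitney U; more -> Kruskal-Wallis with Dunn's correction. Groups
    smaller than 3 cannot be screened; the harness then takes the
    nonparametric route and records a warning. The report always states
    the route taken.
    """
    groups = {
        str(g): np.asarray(sub[value_column], dtype=float)
        for g, sub in data.groupby(group_column, sort=True)
    }
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    warns: list[str] = []

    norm_rows = []
    all_normal = True
    for g, x in groups.items():
        if x.size < 3:
            warns.append(f"group {g!r} has n={x.size} < 3; normality not assessable")
            norm_rows.append({"group": g, "test": None, "p": np.nan, "normal": False})
            all_normal = False
            continue
        test, p = _normality_p(x)
        is_norm = p >= alpha_normality
        norm_rows.append({"group": g, "test": test, "p": p, "normal": is_norm})
        all_normal = all_normal and is_norm
    normality = pd.DataFrame(norm_rows)

    if all_normal:
        route = "parametric"
        if len(groups) == 2:
            stat, p = sps.ttest_ind(*groups.values())
            omnibus = "t-test"
        else:
            stat, p = sps.f_oneway(*groups.values())
            omnibus = "one-way ANOVA"
        pairwise = _bonferroni_t_pairwise(groups)
    else:
        route = "nonparametric"
        if len(groups) == 2:
            stat, p = sps.mannwhitneyu(*groups.values(), alternative="two-sided")
            omnibus = "mann-whitney-u"
        else:
            stat, p = sps.kruskal(*groups.values())
            omnibus = "kruskal-wallis"
        pairwise = _dunn_pairwise(groups)

    return GroupCompareReport(
        route=route,
        omnibus_test=omnibus,
        omnibus_stat=float(stat),
        omnibus_p=float(p),
        normality=normality,
        pairwise=pairwise,
        warnings=warns,
    )
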
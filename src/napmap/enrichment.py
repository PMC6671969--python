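"""Gene-set enrichment and gene-property comparisons.

Three statistical tools characterise the genes a screen flags:

* right-tailed Fisher exact tests of gene-set overlap (hypergeometric),
* right-tailed Mann–Whitney U comparisons of gene-property distributions
  between the extreme-phenotype deciles (top/bottom 10% by maximum
  absolute z-score) or against permuted gene sets,
* ordinary least-squares regression of abnormality strength (max |z|)
  on evolutionary-constraint metrics (dN/dS, s_het, RVIS, pLI, HIS).

Lower dN/dS and RVIS indicate stronger constraint, so their one-sided
comparisons default to the left tail; pLI, s_het and HIS to the right.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CONSTRAINT_DIRECTIONS
from .phenosim import PermutationTestResult


def select_extreme_deciles(
    calls: pd.DataFrame, frac: float = 0.10
) -> tuple[set[str], set[str]]:
    """Top and bottom ``frac`` of genes by maximum absolute z-score.

    Takes floor(frac * n) genes per tail; ties broken by stable gene-id
    order.  Genes without a defined ``max_abs_z`` are excluded before the
    cut.  A fraction so small that the tail would be empty is an error.
    """
    usable = calls.dropna(subset=["max_abs_z"])
    n = len(usable)
    k = int(np.floor(frac * n))
    if k < 1:
        raise ValueError(f"frac={frac} leaves an empty tail for n={n} genes")
    ordered = usable.sort_values(
        ["max_abs_z", "gene"], ascending=[False, True], kind="stable"
    )
    top = set(ordered["gene"].head(k))
    ordered_lo = usable.sort_values(
        ["max_abs_z", "gene"], ascending=[True, True], kind="stable"
    )
    bottom = set(ordered_lo["gene"].head(k))
    return top, bottom


@dataclass
class EnrichmentResult:
    """2x2 overlap table with a right-tailed Fisher p."""

    set_name: str
    a: int  # query and annotated
    b: int  # query only
    c: int  # annotated only
    d: int  # neither
    odds_ratio: float
    p_right: float
    p_bh: float = float("nan")


def fisher_enrichment(
    query: set[str],
    annotation_set: set[str],
    universe: set[str],
    set_name: str = "",
) -> EnrichmentResult:
    """Right-tailed Fisher exact test of overlap between two gene sets."""
    if not universe:
        raise ValueError("universe must be non-empty")
    if not query <= universe or not annotation_set <= universe:
        raise ValueError("query and annotation_set must be subsets of the universe")
    a = len(query & annotation_set)
    b = len(query - annotation_set)
    c = len(annotation_set - query)
    d = len(universe) - a - b - c
    odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
    return EnrichmentResult(set_name, a, b, c, d, float(odds), float(p))


def enrich_gene_sets(
    query: set[str],
    gene_sets: dict[str, list[str]],
    universe: set[str],
) -> pd.DataFrame:
    """Fisher enrichment of a query against a panel of sets, BH-adjusted."""
    from statsmodels.stats.multitest import multipletests

    rows = [
        fisher_enrichment(query, set(gs) & universe, universe, name)
        for name, gs in gene_sets.items()
    ]
    df = pd.DataFrame([r.__dict__ for r in rows])
    if len(df):
        df["p_bh"] = multipletests(df["p_right"], method="fdr_bh")[1]
    return df


def mwu_property_test(
    group_a: np.ndarray,
    group_b: np.ndarray,
    tail: str = "right",
) -> tuple[float, float]:
    """Mann–Whitney U of group_a vs group_b.

    ``tail="right"`` tests whether group_a's scores are stochastically
    larger.  Exact enumeration when n_a * n_b <= 400 and the data are
    tie-free; tie-corrected normal approximation otherwise.  Missing
    scores are dropped; an all-missing group is an error.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("a group has no non-missing scores")
    alternative = {"right": "greater", "left": "less", "two": "two-sided"}[tail]
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (len(a) * len(b) <= 400 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)


def permuted_set_comparison(
    scores: pd.Series,
    target: set[str],
    candidates: set[str],
    n_perm: int = 1000,
    seed: int = 0,
    smoothed: bool = False,
) -> PermutationTestResult:
    """Median score of the target genes vs random same-size candidate draws.

    Right-tailed empirical p: the fraction of permuted sets whose median
    is at least the target's.
    """
    if not target <= candidates:
        raise ValueError("target must be a subset of candidates")
    cand = sorted(candidates & set(scores.dropna().index))
    targ = [g for g in sorted(target) if g in scores.index]
    vals = scores.loc[targ].dropna()
    observed = float(vals.median())
    rng = np.random.default_rng(seed)
    pool = scores.loc[cand].to_numpy()
    k = len(vals)
    null = np.array([
        np.median(rng.choice(pool, size=k, replace=False)) for _ in range(n_perm)
    ])
    r = int((null >= observed).sum())
    p = (r + 1) / (n_perm + 1) if smoothed else r / n_perm
    return PermutationTestResult(
        observed=observed,
        null_mean=float(null.mean()),
        null_sd=float(null.std(ddof=1)) if n_perm > 1 else 0.0,
        n_perm=n_perm,
        p_empirical=float(p),
        null_values=null,
    )


def constraint_regression(
    calls: pd.DataFrame,
    annotations: pd.DataFrame,
    metric: str,
) -> tuple[float, float]:
    """OLS of abnormality strength (max |z|) on one constraint metric.

    Returns (slope, two-sided p).  Requires at least 10 genes with both
    quantities; a zero-variance metric is an error.
    """
    if metric not in annotations.columns:
        raise KeyError(f"unknown metric {metric!r}")
    merged = calls.dropna(subset=["max_abs_z"]).merge(
        annotations[["gene_id", metric]].dropna(),
        left_on="gene", right_on="gene_id",
    )
    if len(merged) < 10:
        raise ValueError(
            f"need >= 10 genes with both max_abs_z and {metric}, got {len(merged)}"
        )
    x = merged[metric].to_numpy(dtype=float)
    y = merged["max_abs_z"].to_numpy(dtype=float)
    if np.std(x) == 0:
        raise ValueError(f"metric {metric!r} has zero variance")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.pvalue)


def default_tail(metric: str) -> str:
    """One-sided tail for 'more constrained' per metric convention."""
    return "right" if CONSTRAINT_DIRECTIONS.get(metric, 1) > 0 else "left"
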
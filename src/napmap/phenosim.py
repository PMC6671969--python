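"""Phenotypic similarity over binarised abnormality profiles.

Gene-level abnormality profiles are built by re-scoring each (gene,
parameter) association as 1 when its BH-adjusted p is at or below a
cutoff (0.05 by default, cutoff inclusive) and 0 otherwise.  Similarity
between two genes uses a simplified Goodall3 index: a feature k shared by
both genes contributes 1 - f_k^2, where f_k is the proportion of genes in
the universe abnormal in k, and features absent in either gene contribute
nothing.  Rare shared defects therefore score high, and a gene with no
defects has similarity 0 to everything — similarity is never driven by
jointly normal anatomy.  Per-pair scores average the per-feature
contributions over all parameters pooled across the requested sections
(the screen aggregates its two analysed coronal sections).

A permutation test measures the phenotypic convergence of a gene module:
the observed mean pairwise similarity within the module against the same
statistic for random same-size gene subsets of the matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .catalogue import CORONAL_SIMILARITY_SECTIONS

logger = logging.getLogger(__name__)


@dataclass
class SimilarityMatrix:
    """Pairwise Goodall3 similarity plus the feature frequencies f_k."""

    genes: list[str]
    S: np.ndarray                 # symmetric, values in [0, 1], diag by convention 0
    f: pd.Series                  # abnormality frequency per parameter

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.S, index=self.genes, columns=self.genes)

    def pair(self, a: str, b: str) -> float:
        return float(self.S[self.genes.index(a), self.genes.index(b)])


@dataclass
class PermutationTestResult:
    observed: float
    null_mean: float
    null_sd: float
    n_perm: int
    p_empirical: float
    null_values: np.ndarray | None = None


def binarize(
    results: pd.DataFrame,
    catalogue: pd.DataFrame,
    cutoff: float = 0.05,
    sections: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Genes x parameters 0/1 abnormality profile matrix.

    bit = 1 iff the BH-adjusted p is <= ``cutoff`` (inclusive); missing or
    not-testable associations score 0 with a logged note.  Restricted to
    parameters of the given sections when provided.
    """
    pids = list(catalogue["parameter_id"])
    if sections is not None:
        pids = [p for p in pids if catalogue.loc[p, "section"] in sections]
    sub = results[results["parameter_id"].isin(pids)]
    n_untestable = int((~sub["testable"].astype(bool)).sum()
                       + (sub["testable"].astype(bool) & sub["p_bh"].isna()).sum())
    if n_untestable:
        logger.info(
            "binarize: %d not-testable associations scored as 0 (absence)",
            n_untestable,
        )
    bit = (sub["p_bh"] <= cutoff).astype(int)  # NaN compares False -> 0
    prof = (
        sub.assign(bit=bit)
        .pivot_table(index="gene", columns="parameter_id", values="bit",
                     aggfunc="max", fill_value=0)
        .reindex(columns=pids, fill_value=0)
    )
    prof.columns.name = None
    prof.index.name = "gene"
    return prof.astype(int)


def goodall3_matrix(
    profiles: pd.DataFrame,
    sections: tuple[str, ...] | None = None,
    catalogue: pd.DataFrame | None = None,
    universe: pd.Index | None = None,
) -> SimilarityMatrix:
    """Simplified Goodall3 similarity over binary profiles.

    ``profiles`` is the genes x parameters 0/1 matrix from
    :func:`binarize`.  Feature frequencies f_k are computed over the gene
    universe present in the matrix (or an explicit ``universe`` subset).
    The per-pair score is the mean over all pooled features of
    ``(1 - f_k^2) * bit_i * bit_j``.
    """
    if sections is not None:
        if catalogue is None:
            raise ValueError("sections filtering requires the parameter catalogue")
        keep = [
            c for c in profiles.columns
            if catalogue.loc[c, "section"] in sections
        ]
        profiles = profiles[keep]
    if universe is not None:
        profiles = profiles.loc[universe]
    if profiles.shape[0] < 2:
        raise ValueError("need at least 2 genes for a similarity matrix")
    genes = list(profiles.index)
    B = profiles.to_numpy(dtype=float)
    f = B.mean(axis=0)
    w = 1.0 - f**2
    S = (B * w) @ B.T / B.shape[1]
    np.fill_diagonal(S, 0.0)
    return SimilarityMatrix(genes, S, pd.Series(f, index=profiles.columns))


def goodall3_coronal(
    results: pd.DataFrame, catalogue: pd.DataFrame, cutoff: float = 0.05
) -> SimilarityMatrix:
    """Similarity over the two analysed coronal sections (the default view)."""
    prof = binarize(results, catalogue, cutoff, CORONAL_SIMILARITY_SECTIONS)
    return goodall3_matrix(prof)


def mean_pairwise_similarity(sim: SimilarityMatrix, genes: set[str]) -> float:
    idx = [sim.genes.index(g) for g in genes]
    if len(idx) < 2:
        raise ValueError("need at least 2 genes")
    sub = sim.S[np.ix_(idx, idx)]
    iu = np.triu_indices(len(idx), k=1)
    return float(sub[iu].mean())


def convergence_test(
    sim: SimilarityMatrix,
    module_genes: set[str],
    n_perm: int = 1000,
    seed: int = 0,
    smoothed: bool = False,
) -> PermutationTestResult:
    """Does a gene module converge on similar brain abnormalities?

    Observed statistic: mean pairwise similarity within the module.  Null:
    the same statistic over ``n_perm`` random same-size subsets of the
    matrix's genes.  Right-tailed empirical p; the plain fraction by
    default, ``(r + 1) / (n + 1)`` smoothing optionally.
    """
    missing = module_genes - set(sim.genes)
    if missing:
        raise KeyError(f"module genes absent from the similarity matrix: {sorted(missing)}")
    if len(module_genes) < 2:
        raise ValueError("module must contain at least 2 genes")
    rng = np.random.default_rng(seed)
    observed = mean_pairwise_similarity(sim, module_genes)
    k = len(module_genes)
    n_genes = len(sim.genes)
    iu = np.triu_indices(k, k=1)
    null = np.empty(n_perm)
    for i in range(n_perm):
        idx = rng.choice(n_genes, size=k, replace=False)
        null[i] = sim.S[np.ix_(idx, idx)][iu].mean()
    # tolerance absorbs summation-order noise when null stats tie the observed
    thresh = observed - 1e-9 * max(1.0, abs(observed))
    r = int((null >= thresh).sum())
    p = (r + 1) / (n_perm + 1) if smoothed else r / n_perm
    return PermutationTestResult(
        observed=observed,
        null_mean=float(null.mean()),
        null_sd=float(null.std(ddof=1)) if n_perm > 1 else 0.0,
        n_perm=n_perm,
        p_empirical=float(p),
        null_values=null,
    )
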
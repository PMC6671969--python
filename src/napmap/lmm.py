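"""Fast linear mixed model for one-parameter genotype association.

The screen's model is, per (line, parameter),

    y = b0 + b1 * genotype + u_batch + e,   u ~ N(0, s2_b),  e ~ N(0, s2_e)

with one random intercept per necropsy-date batch shared by the mutant
replicates and the wild-type pool.  Because the permutation FDR stage
re-runs this fit hundreds of thousands of times, the model is implemented
directly via the profile likelihood over the variance ratio
``lam = s2_b / s2_e``: for block-diagonal V = I + lam * Z Z' the GLS
solution, the V-weighted residual sum of squares and log|V| are all
closed-form functions of per-batch sufficient statistics, so one
likelihood evaluation costs O(n_batches) and the whole screen vectorises
across lines and a lambda grid.  ``statsmodels.MixedLM`` gives the same ML
fit and is used as an independent oracle in the test-suite, not here.

Inference on the genotype term is a likelihood-ratio test (ML fits of the
genotype model vs the intercept-only model).  Instead of referring
2*(ll1 - ll0) to chi-square(1) — anticonservative in the far tail at
screen-typical n, which inflates the false-discovery count at adaptive BH
thresholds — the statistic is mapped to an F scale,

    F = (n - 2) * (exp(LRT / n) - 1)  ~  F(1, n - 2),

which is asymptotically equivalent to the chi-square reference and exact
in the zero-batch-variance limit: when both ML variance-ratio estimates
sit at the boundary the model collapses to OLS and F is literally the
squared pooled two-sample t statistic.  A Wald z test at the fitted
variance ratio is available as an alternative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

# Lambda grid for profile-likelihood maximisation: 0 plus a dense log grid.
_LAM_GRID = np.concatenate([[0.0], np.logspace(-4, 4, 49)])


@dataclass
class LmmFit:
    """Result of one random-intercept genotype fit."""

    beta: float          # genotype effect, measurement scale
    se: float            # GLS standard error at the fitted variance ratio
    p: float             # default inference (LRT on the F(1, n-2) scale)
    p_wald: float        # Wald z p-value at the fitted variance ratio
    lrt: float           # LRT statistic, 2 * (ll1 - ll0), clipped at 0
    lam: float           # fitted variance ratio s2_b / s2_e (genotype model)
    loglik: float        # maximised ML log-likelihood (genotype model)
    n_mut: int
    n_wt: int
    boundary: bool       # True when the fit collapsed to OLS (lam = 0)
    testable: bool

    @classmethod
    def not_testable(cls, n_mut: int = 0, n_wt: int = 0) -> "LmmFit":
        nan = float("nan")
        return cls(nan, nan, nan, nan, nan, nan, nan, n_mut, n_wt, False, False)


def _model_lls(lam, m, t, q, nm, um, n):
    """Profile log-likelihoods of the genotype and null models.

    ``lam`` broadcasts against the leading axes of the per-batch arrays
    ``m`` (total count), ``t`` (sum), ``q`` (sum of squares), ``nm``
    (mutant count) and ``um`` (mutant sum); the trailing axis indexes
    batches.  Returns (ll1, ll0, beta, rss1, a_inv22) with the trailing
    batch axis reduced.
    """
    lam = np.asarray(lam, dtype=float)[..., None]
    c = lam / (1.0 + lam * m)
    a11 = np.sum(m - c * m * m, axis=-1)
    a12 = np.sum(nm - c * m * nm, axis=-1)
    a22 = np.sum(nm - c * nm * nm, axis=-1)
    b1 = np.sum(t - c * t * m, axis=-1)
    b2 = np.sum(um - c * t * nm, axis=-1)
    yy = np.sum(q - c * t * t, axis=-1)
    logdet = np.sum(np.log1p(lam * m), axis=-1)

    det = a11 * a22 - a12 * a12
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = (a11 * b2 - a12 * b1) / det
        alpha = (a22 * b1 - a12 * b2) / det
        rss1 = yy - b1 * alpha - b2 * beta
        rss0 = yy - b1 * b1 / a11
        a_inv22 = a11 / det

    def _ll(rss):
        with np.errstate(divide="ignore", invalid="ignore"):
            return -0.5 * (n * (np.log(2 * np.pi * rss / n) + 1.0) + logdet)

    return _ll(rss1), _ll(rss0), beta, rss1, a_inv22


def _refine(stats_arrs, n, lam0, which, n_iter=40):
    """Golden-section refinement of the per-line profile ML over log-lambda.

    ``lam0`` holds the best grid point per line; lines whose optimum is the
    lam = 0 boundary are left untouched.  ``which`` selects the genotype
    (0) or null (1) model's log-likelihood.
    """
    m, t, q, nm, um = stats_arrs
    lam0 = np.asarray(lam0, dtype=float)
    pos = lam0 > 0

    def ll_of(lam):
        out = _model_lls(lam, m, t, q, nm, um, n)
        return out[which]

    if not pos.any():
        return lam0, ll_of(lam0)
    # bracket one grid step either side in log space
    step = np.log(10) * 8 / 48
    lo = np.where(pos, np.log(np.maximum(lam0, 1e-300)) - step, 0.0)
    hi = np.where(pos, np.log(np.maximum(lam0, 1e-300)) + step, 0.0)
    invphi = (np.sqrt(5.0) - 1) / 2
    x1 = hi - invphi * (hi - lo)
    x2 = lo + invphi * (hi - lo)
    f1 = ll_of(np.where(pos, np.exp(x1), 0.0))
    f2 = ll_of(np.where(pos, np.exp(x2), 0.0))
    for _ in range(n_iter):
        take1 = f1 >= f2
        hi = np.where(take1, x2, hi)
        lo = np.where(take1, lo, x1)
        x1n = hi - invphi * (hi - lo)
        x2n = lo + invphi * (hi - lo)
        # the non-fresh point coincides with a previously evaluated one
        f_fresh = ll_of(np.where(pos, np.exp(np.where(take1, x1n, x2n)), 0.0))
        f1, f2 = np.where(take1, f_fresh, f2), np.where(take1, f1, f_fresh)
        x1, x2 = x1n, x2n
    lam_ref = np.where(pos, np.exp((lo + hi) / 2), 0.0)
    ll_ref = ll_of(lam_ref)
    # never accept a refinement that lost likelihood (flat ridges)
    ll_grid = ll_of(lam0)
    worse = ll_ref < ll_grid
    lam_ref = np.where(worse, lam0, lam_ref)
    ll_ref = np.where(worse, ll_grid, ll_ref)
    return lam_ref, ll_ref


def fit_lines(
    y_wt: np.ndarray,
    batch_wt: np.ndarray,
    y_mut: list[np.ndarray],
    batch_mut: list[np.ndarray],
    refine: bool = True,
) -> list[LmmFit]:
    """Fit the random-intercept genotype model for many lines at once.

    All lines share the wild-type pool ``(y_wt, batch_wt)``; line ``i``
    contributes mutant observations ``y_mut[i]`` in batches
    ``batch_mut[i]``.  Batch labels must be small non-negative integers.
    Lines with fewer than 2 mutant or 2 wild-type observations come back
    flagged not-testable.
    """
    y_wt = np.asarray(y_wt, dtype=float)
    batch_wt = np.asarray(batch_wt)
    n_lines = len(y_mut)
    all_batches = set(batch_wt.tolist())
    for b in batch_mut:
        all_batches.update(np.asarray(b).tolist())
    n_b = (max(all_batches) + 1) if all_batches else 1

    wt_n = np.bincount(batch_wt, minlength=n_b).astype(float)
    wt_t = np.bincount(batch_wt, weights=y_wt, minlength=n_b)
    wt_q = np.bincount(batch_wt, weights=y_wt**2, minlength=n_b)
    n_wt = len(y_wt)

    testable = np.array(
        [len(np.asarray(ym)) >= 2 and n_wt >= 2 for ym in y_mut]
    )
    idx = np.flatnonzero(testable)
    fits: list[LmmFit] = [
        LmmFit.not_testable(len(np.asarray(ym)), n_wt) for ym in y_mut
    ]
    if len(idx) == 0:
        return fits

    L = len(idx)
    nm = np.zeros((L, n_b))
    um = np.zeros((L, n_b))
    qm = np.zeros((L, n_b))
    for k, i in enumerate(idx):
        ym = np.asarray(y_mut[i], dtype=float)
        bm = np.asarray(batch_mut[i])
        nm[k] = np.bincount(bm, minlength=n_b)
        um[k] = np.bincount(bm, weights=ym, minlength=n_b)
        qm[k] = np.bincount(bm, weights=ym**2, minlength=n_b)

    m = wt_n[None, :] + nm
    t = wt_t[None, :] + um
    q = wt_q[None, :] + qm
    n = n_wt + nm.sum(axis=1)

    stats_g = (m[:, None, :], t[:, None, :], q[:, None, :],
               nm[:, None, :], um[:, None, :])
    ll1_g, ll0_g, _, _, _ = _model_lls(
        _LAM_GRID[None, :], *stats_g, n[:, None]
    )
    lam1 = _LAM_GRID[np.nanargmax(ll1_g, axis=1)]
    lam0 = _LAM_GRID[np.nanargmax(ll0_g, axis=1)]

    stats_arrs = (m, t, q, nm, um)
    if refine:
        lam1, ll1 = _refine(stats_arrs, n, lam1, which=0)
        lam0, ll0 = _refine(stats_arrs, n, lam0, which=1)
    else:
        ll1 = np.nanmax(ll1_g, axis=1)
        ll0 = np.nanmax(ll0_g, axis=1)

    ll1f, _, beta, rss1, a_inv22 = _model_lls(lam1, *stats_arrs, n)
    sigma2 = rss1 / np.maximum(n - 2, 1)  # unbiased, for the SE / Wald
    se = np.sqrt(np.maximum(sigma2 * a_inv22, 0.0))

    lrt = np.maximum(2.0 * (ll1 - ll0), 0.0)
    df2 = np.maximum(n - 2, 1)
    fstat = df2 * np.expm1(lrt / n)
    p = stats.f.sf(fstat, 1, df2)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = beta / se
    p_wald = 2.0 * stats.norm.sf(np.abs(tstat))

    boundary = (lam1 == 0.0) & (lam0 == 0.0)

    n_mut = nm.sum(axis=1).astype(int)
    for k, i in enumerate(idx):
        fits[i] = LmmFit(
            beta=float(beta[k]),
            se=float(se[k]),
            p=float(p[k]),
            p_wald=float(p_wald[k]),
            lrt=float(lrt[k]),
            lam=float(lam1[k]),
            loglik=float(ll1[k]),
            n_mut=int(n_mut[k]),
            n_wt=n_wt,
            boundary=bool(boundary[k]),
            testable=True,
        )
    return fits


def fit_single(
    y_wt: np.ndarray,
    batch_wt: np.ndarray,
    y_mut: np.ndarray,
    batch_mut: np.ndarray,
) -> LmmFit:
    """Convenience wrapper: one line against the wild-type pool."""
    return fit_lines(y_wt, batch_wt, [np.asarray(y_mut)], [np.asarray(batch_mut)])[0]
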
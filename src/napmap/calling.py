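"""Parameter-level association and gene-level NAP calling.

For each (mutant line, brain parameter) the screen fits a linear mixed
model — genotype fixed effect, random intercept per necropsy date — against
the shared wild-type pool, adjusts p-values with Benjamini–Hochberg within
a family, and calls a line a NAP (NeuroAnatomical Phenotype) line when any
parameter survives BH at the 0.1 threshold.  Calls are annotated with a
severity band (largest absolute significant percent change), a direction
class (decrease / increase / bidirectional) and the affected anatomical
categories.  A 100-permutation re-run of the whole caller provides the
empirical null used to confirm FDR control.  Lines kept on other genetic
backgrounds are analysed separately with a plain two-sample Student t-test
against their matched controls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import lmm
from .catalogue import ParameterDef, catalogue_frame
from .cohort import METADATA_COLUMNS, SEVERITY_BANDS, SEVERITY_ORDER, WT_LINE

logger = logging.getLogger(__name__)

RESULT_COLUMNS = [
    "line_id", "gene", "parameter_id", "beta", "percent_change", "z_score",
    "p_raw", "p_bh", "method", "n_mut", "n_wt", "testable",
]

LMM_BACKGROUNDS = ("pure_B6N",)


def parameter_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in METADATA_COLUMNS]


def _batch_codes(dates: pd.Series) -> np.ndarray:
    codes, _ = pd.factorize(dates, sort=True)
    return codes


def summarize_effects(
    table: pd.DataFrame, line_id: str, parameter_id: str
) -> tuple[float, float]:
    """Percent change and z-score of a line vs its matched wild types.

    percent_change = 100 * (mean_mut - mean_wt) / mean_wt and
    z = (mean_mut - mean_wt) / sd_wt, on animal-level values of the
    matched wild-type pool (same genetic background).  A zero wild-type
    SD leaves the z-score undefined (NaN).
    """
    mut = table[table["line_id"] == line_id]
    if mut.empty:
        raise KeyError(f"unknown line {line_id!r}")
    background = mut["background"].iloc[0]
    wt = table[(table["line_id"] == WT_LINE) & (table["background"] == background)]
    y_mut = mut[parameter_id].dropna().to_numpy(dtype=float)
    y_wt = wt[parameter_id].dropna().to_numpy(dtype=float)
    if len(y_mut) == 0 or len(y_wt) == 0:
        return float("nan"), float("nan")
    mean_wt = y_wt.mean()
    pc = 100.0 * (y_mut.mean() - mean_wt) / mean_wt
    sd_wt = y_wt.std(ddof=1) if len(y_wt) > 1 else 0.0
    z = (y_mut.mean() - mean_wt) / sd_wt if sd_wt > 0 else float("nan")
    return float(pc), float(z)


def fit_parameter_model(
    table: pd.DataFrame, line_id: str, parameter_id: str
) -> pd.Series:
    """Single (line, parameter) mixed-model association.

    Fits measurement ~ genotype with a random intercept per necropsy date,
    mutant replicates against the matched wild-type pool.  Returns one
    association row; insufficient observations yield a flagged
    not-testable row (p NaN), never a silent drop.
    """
    mut = table[table["line_id"] == line_id]
    if mut.empty:
        raise KeyError(f"unknown line {line_id!r}")
    background = mut["background"].iloc[0]
    wt = table[(table["line_id"] == WT_LINE) & (table["background"] == background)]
    dates = pd.concat([wt["necropsy_date"], mut["necropsy_date"]])
    codes = _batch_codes(dates)
    b_wt, b_mut = codes[: len(wt)], codes[len(wt):]

    y_wt = wt[parameter_id].to_numpy(dtype=float)
    y_mut = mut[parameter_id].to_numpy(dtype=float)
    ok_wt, ok_mut = ~np.isnan(y_wt), ~np.isnan(y_mut)
    fit = lmm.fit_single(y_wt[ok_wt], b_wt[ok_wt], y_mut[ok_mut], b_mut[ok_mut])
    if fit.testable and fit.boundary:
        logger.debug(
            "line %s parameter %s: batch variance at zero boundary, "
            "OLS/exact-t solution used", line_id, parameter_id,
        )
    pc, z = summarize_effects(table, line_id, parameter_id)
    return pd.Series(
        {
            "line_id": line_id,
            "gene": mut["gene"].iloc[0],
            "parameter_id": parameter_id,
            "beta": fit.beta,
            "percent_change": pc,
            "z_score": z,
            "p_raw": fit.p,
            "p_bh": float("nan"),
            "method": "lmm",
            "n_mut": fit.n_mut,
            "n_wt": fit.n_wt,
            "testable": fit.testable,
        }
    )


def ttest_fallback(
    table: pd.DataFrame, line_id: str, parameter_id: str
) -> pd.Series:
    """Two-sample equal-variance Student t-test against matched controls.

    Used for lines maintained on backgrounds analysed separately from the
    main pool; controls are the wild types sharing the line's background.
    """
    mut = table[table["line_id"] == line_id]
    if mut.empty:
        raise KeyError(f"unknown line {line_id!r}")
    background = mut["background"].iloc[0]
    wt = table[(table["line_id"] == WT_LINE) & (table["background"] == background)]
    y_mut = mut[parameter_id].dropna().to_numpy(dtype=float)
    y_wt = wt[parameter_id].dropna().to_numpy(dtype=float)
    if len(y_mut) < 2 or len(y_wt) < 2:
        p = beta = float("nan")
        testable = False
    else:
        res = stats.ttest_ind(y_mut, y_wt, equal_var=True)
        p = float(res.pvalue)
        beta = float(y_mut.mean() - y_wt.mean())
        testable = True
    pc, z = summarize_effects(table, line_id, parameter_id)
    return pd.Series(
        {
            "line_id": line_id,
            "gene": mut["gene"].iloc[0],
            "parameter_id": parameter_id,
            "beta": beta,
            "percent_change": pc,
            "z_score": z,
            "p_raw": p,
            "p_bh": float("nan"),
            "method": "ttest",
            "n_mut": len(y_mut),
            "n_wt": len(y_wt),
            "testable": testable,
        }
    )


def run_association(
    table: pd.DataFrame,
    parameters: list[str] | None = None,
    refine: bool = True,
) -> pd.DataFrame:
    """Fit every (line, parameter) pair of a screen.

    Lines on an LMM-eligible background share the vectorised mixed-model
    path; other backgrounds take the matched-control t-test.  Returns the
    association table (one row per line × parameter) with raw p-values;
    BH adjustment is a separate step (:func:`adjust_bh`).
    """
    if parameters is None:
        parameters = parameter_columns(table)
    is_wt = table["line_id"] == WT_LINE
    mut_tab = table[~is_wt]
    rows: list[dict] = []
    for background, grp in mut_tab.groupby("background", sort=True):
        wt = table[is_wt & (table["background"] == background)]
        line_ids = sorted(grp["line_id"].unique())
        gene_of = grp.drop_duplicates("line_id").set_index("line_id")["gene"]
        use_lmm = background in LMM_BACKGROUNDS
        dates = pd.concat([wt["necropsy_date"], grp["necropsy_date"]])
        codes = _batch_codes(dates)
        b_wt, b_mut_all = codes[: len(wt)], codes[len(wt):]
        line_arr = grp["line_id"].to_numpy()
        line_rows = {l: np.flatnonzero(line_arr == l) for l in line_ids}

        wt_vals = wt[parameters].to_numpy(dtype=float)
        mut_vals = grp[parameters].to_numpy(dtype=float)
        wt_means = np.nanmean(wt_vals, axis=0) if len(wt) else np.full(len(parameters), np.nan)
        wt_sds = (
            np.nanstd(wt_vals, axis=0, ddof=1) if len(wt) > 1
            else np.full(len(parameters), np.nan)
        )

        for j, pid in enumerate(parameters):
            y_wt = wt_vals[:, j]
            ok_wt = ~np.isnan(y_wt)
            y_col = mut_vals[:, j]
            y_mut_list, b_mut_list = [], []
            for l in line_ids:
                ridx = line_rows[l]
                ok = ~np.isnan(y_col[ridx])
                y_mut_list.append(y_col[ridx][ok])
                b_mut_list.append(b_mut_all[ridx][ok])
            if use_lmm:
                fits = lmm.fit_lines(
                    y_wt[ok_wt], b_wt[ok_wt], y_mut_list, b_mut_list,
                    refine=refine,
                )
                p_raw = [f.p for f in fits]
                beta = [f.beta for f in fits]
                n_mut = [f.n_mut for f in fits]
                n_wt_used = [f.n_wt for f in fits]
                testable = [f.testable for f in fits]
                method = "lmm"
            else:
                p_raw, beta, n_mut, n_wt_used, testable = [], [], [], [], []
                yw = y_wt[ok_wt]
                for ym in y_mut_list:
                    if len(ym) >= 2 and len(yw) >= 2:
                        p_raw.append(float(stats.ttest_ind(ym, yw, equal_var=True).pvalue))
                        beta.append(float(ym.mean() - yw.mean()))
                        testable.append(True)
                    else:
                        p_raw.append(float("nan"))
                        beta.append(float("nan"))
                        testable.append(False)
                    n_mut.append(len(ym))
                    n_wt_used.append(len(yw))
                method = "ttest"
            mw = wt_means[j]
            sw = wt_sds[j]
            for k, l in enumerate(line_ids):
                ym = y_mut_list[k]
                mm = ym.mean() if len(ym) else np.nan
                pc = 100.0 * (mm - mw) / mw if mw and np.isfinite(mw) else np.nan
                z = (mm - mw) / sw if sw and sw > 0 else np.nan
                rows.append(
                    {
                        "line_id": l,
                        "gene": gene_of[l],
                        "parameter_id": pid,
                        "beta": beta[k],
                        "percent_change": pc,
                        "z_score": z,
                        "p_raw": p_raw[k],
                        "p_bh": float("nan"),
                        "method": method,
                        "n_mut": n_mut[k],
                        "n_wt": n_wt_used[k],
                        "testable": testable[k],
                    }
                )
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def adjust_bh(
    results: pd.DataFrame,
    family: str = "global",
    group_col: str | None = None,
) -> pd.DataFrame:
    """Benjamini–Hochberg step-up adjustment within a family.

    ``family="global"`` adjusts over all testable (line, parameter) pairs
    (optionally within each ``group_col`` subproject); ``"per_parameter"``
    adjusts each parameter across lines separately.
    """
    out = results.copy()
    if out.empty:
        return out
    ok = out["testable"] & out["p_raw"].notna()
    if family == "global":
        keys = out[group_col] if group_col else pd.Series(0, index=out.index)
    elif family == "per_parameter":
        keys = out["parameter_id"]
    else:
        raise ValueError(f"unknown BH family {family!r}")
    out["p_bh"] = np.nan
    for key in pd.unique(keys[ok]):
        sel = ok & (keys == key)
        pvals = out.loc[sel, "p_raw"].to_numpy()
        if len(pvals):
            out.loc[sel, "p_bh"] = multipletests(pvals, method="fdr_bh")[1]
    return out


def classify_severity(percent_changes: list[float]) -> str:
    """Severity band of the largest-magnitude significant percent change.

    Bands on |percent change|: mild [0, 10), moderate [10, 20),
    severe [20, 40), very_severe [40, inf).
    """
    if len(percent_changes) == 0:
        raise ValueError("severity undefined for an empty change list")
    top = max(abs(float(c)) for c in percent_changes)
    for name in SEVERITY_ORDER:
        lo, hi = SEVERITY_BANDS[name]
        if lo <= top < hi:
            return name
    return "very_severe"


def classify_direction(changes: list[float]) -> str:
    """decrease / increase / bidirectional from signed significant changes."""
    arr = [float(c) for c in changes]
    if len(arr) == 0:
        raise ValueError("direction undefined for an empty change list")
    if any(c == 0 for c in arr):
        raise ValueError("an exactly zero change cannot be significant")
    neg, pos = any(c < 0 for c in arr), any(c > 0 for c in arr)
    if neg and pos:
        return "bidirectional"
    return "decrease" if neg else "increase"


NAP_COLUMNS = [
    "line_id", "gene", "is_nap", "n_significant", "significant_parameters",
    "severity", "direction", "categories_affected", "max_abs_z",
]


def call_naps(
    results: pd.DataFrame,
    params: list[ParameterDef] | pd.DataFrame,
    threshold: float = 0.1,
) -> pd.DataFrame:
    """Roll BH-adjusted associations up to gene-level NAP calls.

    A line is a NAP line when any parameter's BH-adjusted p is below
    ``threshold``.  Severity and direction are derived from the
    significant percent changes, affected categories via the parameter
    catalogue, and ``max_abs_z`` over all testable parameters.
    """
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    if results["p_bh"].isna().all() and results["testable"].any():
        raise ValueError("results must be BH-adjusted before calling (run adjust_bh)")
    cat = params if isinstance(params, pd.DataFrame) else catalogue_frame(params)
    category_of = cat["category"]
    calls = []
    for line, grp in results.groupby("line_id", sort=True):
        sig = grp[grp["p_bh"] < threshold]
        testable = grp[grp["testable"].astype(bool)]
        is_nap = len(sig) > 0
        # direction counts zero percent-changes by the sign of beta
        changes = [
            pc if pc != 0 else (1.0 if b > 0 else -1.0)
            for pc, b in zip(sig["percent_change"], sig["beta"])
        ]
        calls.append(
            {
                "line_id": line,
                "gene": grp["gene"].iloc[0],
                "is_nap": is_nap,
                "n_significant": len(sig),
                "significant_parameters": ";".join(sig["parameter_id"]),
                "severity": classify_severity(list(sig["percent_change"])) if is_nap else None,
                "direction": classify_direction(changes) if is_nap else None,
                "categories_affected": ";".join(
                    sorted(set(category_of.loc[p] for p in sig["parameter_id"]))
                ),
                "max_abs_z": (
                    float(np.nanmax(np.abs(testable["z_score"])))
                    if len(testable) else float("nan")
                ),
            }
        )
    return pd.DataFrame(calls, columns=NAP_COLUMNS)


@dataclass
class FdrCalibration:
    """Observed significant-line count against a permutation null."""

    observed: int
    null_counts: list[int]
    n_perm: int
    alpha: float

    @property
    def null_mean(self) -> float:
        return float(np.mean(self.null_counts))

    @property
    def null_sd(self) -> float:
        return float(np.std(self.null_counts, ddof=1)) if self.n_perm > 1 else 0.0


def _count_significant_lines(
    table: pd.DataFrame, alpha: float, family: str, refine: bool
) -> int:
    res = adjust_bh(run_association(table, refine=refine), family=family)
    return int((res.groupby("line_id")["p_bh"].min() < alpha).sum())


def permutation_fdr(
    table: pd.DataFrame,
    n_perm: int = 100,
    alpha: float = 0.1,
    seed: int = 0,
    family: str = "global",
    subproject_col: str | None = None,
) -> FdrCalibration:
    """Permutation check of FDR control.

    Re-runs the full calling pipeline ``n_perm`` times on data whose line
    labels are shuffled across mutant animals (within subproject, wild-type
    pool fixed) and compares the observed number of significant lines at
    BH ``alpha`` with the permutation null.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    observed = _count_significant_lines(table, alpha, family, refine=False)
    is_mut = (table["line_id"] != WT_LINE).to_numpy()
    null_counts = []
    for _ in range(n_perm):
        perm = table.copy()
        if subproject_col is None:
            groups = [np.flatnonzero(is_mut)]
        else:
            sub = table[subproject_col].to_numpy()
            groups = [
                np.flatnonzero(is_mut & (sub == s)) for s in np.unique(sub[is_mut])
            ]
        line_col = perm["line_id"].to_numpy().copy()
        gene_col = perm["gene"].to_numpy().copy()
        for idx in groups:
            shuf = rng.permutation(idx)
            line_col[idx] = line_col[shuf]
            gene_col[idx] = gene_col[shuf]
        perm["line_id"] = line_col
        perm["gene"] = gene_col
        null_counts.append(
            _count_significant_lines(perm, alpha, family, refine=False)
        )
    return FdrCalibration(observed, null_counts, n_perm, alpha)


def structure_correlations(
    table: pd.DataFrame,
    normalize: bool = False,
    total_area_param: str = "total_brain_area",
) -> pd.DataFrame:
    """Pearson correlations across parameters over wild-type animals.

    With ``normalize=True`` every parameter is first divided by the
    animal's total brain area.  Constant columns yield missing
    correlations (their diagonal stays 1 only when defined).
    """
    wt = table[table["line_id"] == WT_LINE]
    pcols = parameter_columns(table)
    vals = wt[pcols].astype(float)
    if normalize:
        if total_area_param not in vals.columns:
            raise KeyError(
                f"total brain area parameter {total_area_param!r} not found"
            )
        vals = vals.div(vals[total_area_param], axis=0)
    return vals.corr(method="pearson", min_periods=2)
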
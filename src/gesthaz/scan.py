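"""Per-variant association scans and the suggestive-hit comparison.

Linear regression of gestational duration (days) and logistic regression of
preterm delivery (< 259 days) on minor-allele dosage with genotyping-batch
covariates, restricted to spontaneous deliveries and variants with MAF >=
1%.  The linear scan uses the Frisch-Waugh projection (residualize outcome
and dosages on the shared covariates once), which is numerically identical
to the per-variant joint OLS fit but linear-time in the number of variants.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm

from .cohort import PRETERM_DAYS, Cohort

__all__ = [
    "linear_scan",
    "logistic_scan",
    "suggestive_concordance",
    "genomic_inflation_lambda",
]

logger = logging.getLogger(__name__)

SCAN_COLUMNS = ["id", "chrom", "pos", "ea", "oa", "eaf", "maf", "beta", "se", "p", "n"]


def _batch_design(pheno: pd.DataFrame) -> np.ndarray:
    """Intercept plus reference-coded genotyping-batch indicators."""
    batches = sorted(pheno["batch"].astype(str).unique())
    cols = [np.ones(len(pheno))]
    for b in batches[1:]:
        cols.append((pheno["batch"].astype(str) == b).to_numpy(float))
    return np.column_stack(cols)


def _variant_frame(cohort: Cohort, keep: np.ndarray) -> pd.DataFrame:
    v = cohort.variants.loc[keep].reset_index(drop=True)
    return pd.DataFrame(
        {
            "id": v["id"],
            "chrom": v["chrom"],
            "pos": v["pos"],
            "ea": v["effect_allele"],
            "oa": v["other_allele"],
        }
    )


def linear_scan(
    cohort: Cohort,
    min_maf: float = 0.01,
    exclude_nonspontaneous: bool = True,
) -> pd.DataFrame:
    """OLS scan of gestational duration on each variant's dosage.

    Returns one row per retained variant with GWAS summary-statistics
    columns (beta in days per effect allele).
    """
    sub = cohort.spontaneous_subset() if exclude_nonspontaneous else cohort
    y = sub.durations
    C = _batch_design(sub.pheno)
    G = sub.dosages
    eaf = np.nanmean(G, axis=0) / 2.0
    maf = np.minimum(eaf, 1 - eaf)
    missing = np.all(np.isnan(G), axis=0)
    if missing.any():
        logger.info("skipping %d all-missing dosage columns", int(missing.sum()))
    keep = (maf >= min_maf) & ~missing
    G = np.nan_to_num(G[:, keep])

    # Frisch-Waugh: residualize y and G on the covariates once
    Q, _ = np.linalg.qr(C)
    ry = y - Q @ (Q.T @ y)
    rG = G - Q @ (Q.T @ G)
    gss = np.einsum("ij,ij->j", rG, rG)
    beta = (rG.T @ ry) / gss
    df = len(y) - C.shape[1] - 1
    resid_ss = (ry @ ry) - beta * (rG.T @ ry)
    sigma2 = resid_ss / df
    se = np.sqrt(sigma2 / gss)
    z = beta / se
    out = _variant_frame(cohort, np.nonzero(keep)[0])
    out["eaf"] = eaf[keep]
    out["maf"] = maf[keep]
    out["beta"] = beta
    out["se"] = se
    out["p"] = 2 * norm.sf(np.abs(z))
    out["n"] = len(y)
    return out[SCAN_COLUMNS]


def _logistic_fit(X: np.ndarray, y: np.ndarray, max_iter: int = 50):
    """Plain IRLS logistic fit; returns (coef, cov) or None on separation."""
    p = X.shape[1]
    beta = np.zeros(p)
    beta[0] = np.log(max(y.mean(), 1e-10) / max(1 - y.mean(), 1e-10))
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1 - mu)
        H = (X.T * w) @ X
        grad = X.T @ (y - mu)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            return None
        beta = beta + step
        if np.max(np.abs(step)) < 1e-10:
            return beta, np.linalg.inv(H)
    return beta, np.linalg.inv((X.T * (mu * (1 - mu))) @ X)


def logistic_scan(
    cohort: Cohort,
    threshold_days: float = PRETERM_DAYS,
    min_maf: float = 0.01,
    exclude_nonspontaneous: bool = True,
) -> pd.DataFrame:
    """Logistic scan of preterm delivery (< ``threshold_days``) per variant.

    ``beta`` is the log odds ratio per effect allele.  Variants whose batch
    strata contain zero cases are flagged in the ``flag`` column.
    """
    sub = cohort.spontaneous_subset() if exclude_nonspontaneous else cohort
    y = (sub.durations < threshold_days).astype(float)
    C = _batch_design(sub.pheno)
    G = sub.dosages
    eaf = np.nanmean(G, axis=0) / 2.0
    maf = np.minimum(eaf, 1 - eaf)
    missing = np.all(np.isnan(G), axis=0)
    keep = (maf >= min_maf) & ~missing
    idx = np.nonzero(keep)[0]

    batch_labels = sub.pheno["batch"].astype(str).to_numpy()
    empty_strata = {
        b for b in np.unique(batch_labels) if y[batch_labels == b].sum() == 0
    }

    rows_beta, rows_se, flags = [], [], []
    for k in idx:
        g = np.nan_to_num(G[:, k])
        X = np.column_stack([C, g])
        fit = _logistic_fit(X, y)
        if fit is None:
            rows_beta.append(np.nan)
            rows_se.append(np.nan)
            flags.append("separation")
            continue
        b, V = fit
        rows_beta.append(b[-1])
        rows_se.append(np.sqrt(V[-1, -1]))
        flags.append("zero_case_stratum" if empty_strata else "")
    out = _variant_frame(cohort, idx)
    out["eaf"] = eaf[idx]
    out["maf"] = maf[idx]
    out["beta"] = rows_beta
    out["se"] = rows_se
    with np.errstate(invalid="ignore", divide="ignore"):
        out["p"] = 2 * norm.sf(np.abs(out["beta"] / out["se"]))
    out["n"] = len(y)
    out["flag"] = flags
    return out[SCAN_COLUMNS + ["flag"]]


def suggestive_concordance(
    scan_a: pd.DataFrame,
    scan_b: pd.DataFrame,
    p_threshold: float = 1e-5,
    prune_bp: float = 1.5e6,
    rule: str = "either",
) -> pd.DataFrame:
    """Pair effect sizes of suggestive variants across two scans.

    Variants below ``p_threshold`` in either scan (``rule="either"``; or
    ``"both"``) are pooled and pruned by distance: within each chromosome
    the variant with the smallest minimum p-value is kept and neighbors
    within ``prune_bp`` are removed, repeating outward.  Returns the paired
    (beta_a, beta_b) table for the surviving variants.
    """
    if rule not in {"either", "both"}:
        raise ValueError("rule must be 'either' or 'both'")
    m = scan_a.merge(scan_b, on="id", suffixes=("_a", "_b"))
    sug_a = m["p_a"] < p_threshold
    sug_b = m["p_b"] < p_threshold
    m = m[(sug_a | sug_b) if rule == "either" else (sug_a & sug_b)].copy()
    if m.empty:
        return pd.DataFrame(
            columns=["id", "chrom", "pos", "beta_a", "se_a", "p_a", "beta_b", "se_b", "p_b"]
        )
    bad_pos = m["pos_a"].isna()
    if bad_pos.any():
        logger.info("excluding %d suggestive variants without positions", int(bad_pos.sum()))
        m = m[~bad_pos]
    m["p_min"] = np.minimum(m["p_a"], m["p_b"])
    kept = []
    for _, grp in m.groupby("chrom_a"):
        grp = grp.sort_values("p_min")
        taken: list[float] = []
        for _, row in grp.iterrows():
            if all(abs(row["pos_a"] - q) > prune_bp for q in taken):
                taken.append(row["pos_a"])
                kept.append(row)
    out = pd.DataFrame(kept).rename(columns={"chrom_a": "chrom", "pos_a": "pos"})
    return out[
        ["id", "chrom", "pos", "beta_a", "se_a", "p_a", "beta_b", "se_b", "p_b"]
    ].reset_index(drop=True)


def genomic_inflation_lambda(pvalues) -> float:
    """Median-chi-square inflation factor (synthetic diagnostics only).

    This is the simple median(chi2)/0.456 lambda, not an LD-score-regression
    intercept; it is meant for sanity checks on simulated scans.
    """
    p = np.asarray(pvalues, dtype=float)
    p = p[np.isfinite(p)]
    return float(np.median(chi2.isf(p, 1)) / chi2.isf(0.5, 1))
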
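"""Polygenic-score construction and the PGS-stratified survival analyses.

The gestational-duration PGS is a weighted sum of effect-allele counts
(weights in days per allele, from an external training GWAS).  Downstream:
variance explained in duration, quantile-group PAMM curves against the
middle quantile, unadjusted preterm/very-preterm risks per quantile, counts
of rare deleterious alleles and homozygotes, and a genotype PCA with
per-component outcome associations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .cohort import PRETERM_DAYS, VERY_PRETERM_DAYS, Cohort
from .pamm import PammFit, PammSpec, fit_pamm, predict_curve
from .ped import expand_cohort, prepare_covariates
from .scan import _batch_design, _logistic_fit

__all__ = [
    "compute_pgs",
    "variance_explained",
    "quantile_group_pamm",
    "unadjusted_risks",
    "rare_deleterious_counts",
    "pca_and_association",
    "restrict_weights_to_hits",
    "wilson_ci",
]

logger = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _is_ambiguous(a1: str, a2: str) -> bool:
    return _COMPLEMENT.get(a1) == a2


def compute_pgs(cohort: Cohort, weights: pd.DataFrame) -> np.ndarray:
    """Per-individual polygenic score from a weight table.

    ``weights`` needs columns ``id, effect_allele, other_allele, weight``.
    Dosages are rounded to hard calls.  Weight-file alleles are matched to
    the cohort's variant orientation; swapped alleles contribute ``2 -
    count``; strand flips are resolved through the complement when
    unambiguous; palindromic (A/T, C/G) and otherwise mismatched variants
    are dropped with a log entry.

    Raises
    ------
    ValueError
        If no weight-file variant matches the cohort.
    """
    if weights["id"].duplicated().any():
        raise ValueError("weight table has duplicated variant IDs")
    hard = cohort.hard_calls()
    vmap = {vid: i for i, vid in enumerate(cohort.variants["id"])}
    score = np.zeros(cohort.n)
    used = dropped = 0
    for _, row in weights.iterrows():
        i = vmap.get(row["id"])
        if i is None:
            continue
        ea, oa = str(row["effect_allele"]), str(row["other_allele"])
        vea = str(cohort.variants["effect_allele"].iloc[i])
        voa = str(cohort.variants["other_allele"].iloc[i])
        if _is_ambiguous(ea, oa):
            logger.info("dropping palindromic variant %s", row["id"])
            dropped += 1
            continue
        cea, coa = _COMPLEMENT.get(ea, "?"), _COMPLEMENT.get(oa, "?")
        if (ea, oa) == (vea, voa) or (cea, coa) == (vea, voa):
            count = hard[:, i]
        elif (ea, oa) == (voa, vea) or (cea, coa) == (voa, vea):
            count = 2.0 - hard[:, i]
        else:
            logger.info("dropping allele-mismatched variant %s", row["id"])
            dropped += 1
            continue
        score += float(row["weight"]) * count
        used += 1
    if used == 0:
        raise ValueError("no weight-file variant could be matched to the cohort")
    if dropped:
        logger.info("PGS built from %d variants (%d dropped)", used, dropped)
    return score


def restrict_weights_to_hits(
    weights: pd.DataFrame,
    variants: pd.DataFrame,
    hits: pd.DataFrame,
    window_bp: int = 50_000,
) -> pd.DataFrame:
    """Keep only weights within ``window_bp`` of a top-hit position.

    ``hits`` needs ``chrom`` and ``pos`` columns; the window is closed on
    both ends, coordinates 1-based.  Weights themselves are unchanged.
    """
    pos = variants.set_index("id")[["chrom", "pos"]]
    keep = []
    for vid in weights["id"]:
        if vid not in pos.index:
            keep.append(False)
            continue
        chrom, p = pos.loc[vid, "chrom"], pos.loc[vid, "pos"]
        near = (
            (hits["chrom"].astype(str) == str(chrom))
            & (np.abs(hits["pos"] - p) <= window_bp)
        ).any()
        keep.append(bool(near))
    return weights[np.asarray(keep)].reset_index(drop=True)


def variance_explained(
    pgs: np.ndarray,
    cohort: Cohort,
    with_covariates: bool = False,
    covariates: pd.DataFrame | None = None,
) -> float:
    """R-squared of gestational duration explained by the PGS.

    Computed on spontaneous deliveries only.  Without covariates this is
    the plain OLS R^2 of duration on the score; with covariates it is the
    incremental R^2 of adding the score to the batch + clinical model.
    """
    pgs = np.asarray(pgs, dtype=float)
    if np.ptp(pgs) == 0:
        raise ValueError("PGS has zero variance")
    keep = cohort.spontaneous
    y = cohort.durations[keep]
    s = pgs[keep]

    def r2(X):
        X = np.column_stack([np.ones(len(y)), X])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        return 1.0 - (resid @ resid) / ((y - y.mean()) @ (y - y.mean()))

    if not with_covariates:
        return float(r2(s[:, None]))
    if covariates is None:
        covariates = prepare_covariates(cohort)
        covariates = pd.concat(
            [covariates, pd.DataFrame(_batch_design(cohort.pheno)[:, 1:])], axis=1
        )
    C = covariates.to_numpy(dtype=float)[keep]
    return float(r2(np.column_stack([C, s])) - r2(C))


def _quantile_groups(pgs: np.ndarray, n_groups: int) -> np.ndarray:
    if n_groups % 2 == 0:
        raise ValueError("n_groups must be odd so the middle group is the reference")
    # rank-based split: robust to heavily tied (few-variant) scores
    order = np.argsort(pgs, kind="stable")
    ranks = np.empty_like(order)
    ranks[order] = np.arange(len(pgs))
    return (ranks * n_groups) // len(pgs)


@dataclass
class QuantileGroupResult:
    """Joint PAMM over PGS quantile groups (middle group = reference)."""

    fit: PammFit
    curves: dict
    groups: np.ndarray
    n_groups: int


def quantile_group_pamm(
    pgs: np.ndarray,
    cohort: Cohort,
    n_groups: int = 5,
    covariates: pd.DataFrame | None = None,
    times=None,
    effect_dim: int = 10,
) -> QuantileGroupResult:
    """Fit one PAMM with a time-varying term per PGS quantile group.

    The middle quantile is the reference; each other group gets a constant
    term plus a smooth log-hazard-ratio curve against it.  Clinical
    covariates (default: :func:`prepare_covariates`) keep constant effects.
    """
    pgs = np.asarray(pgs, dtype=float)
    groups = _quantile_groups(pgs, n_groups)
    mid = n_groups // 2
    if covariates is None:
        covariates = prepare_covariates(cohort)
    cov = covariates.copy().reset_index(drop=True)
    group_cols = []
    for q in range(n_groups):
        if q == mid:
            continue
        name = f"q{q + 1}"
        cov[name] = (groups == q).astype(float)
        group_cols.append(name)
        n_ev = int(((groups == q) & cohort.spontaneous).sum())
        if n_ev == 0:
            logger.warning("PGS group %s has zero events; its curve will be wide", name)
    ped = expand_cohort(cohort, covariates=cov)
    spec = PammSpec(
        dosage_col=tuple(group_cols),
        covariate_cols=tuple(covariates.columns),
        effect_dim=effect_dim,
        time_varying=True,
    )
    fit = fit_pamm(ped, spec)
    if times is None:
        times = np.arange(fit.t_range[0], fit.t_range[1] + 1e-9, 7.0)
    curves = {c: predict_curve(fit, times, term=c) for c in group_cols}
    return QuantileGroupResult(fit=fit, curves=curves, groups=groups, n_groups=n_groups)


def wilson_ci(x: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Wilson score interval with continuity correction (prop.test default)."""
    if n == 0:
        raise ValueError("empty group")
    z = norm.ppf(1 - (1 - conf) / 2)
    p = x / n
    denom = 2 * (n + z * z)
    if x == 0:
        lo = 0.0
    else:
        lo = (
            2 * n * p + z * z - 1
            - z * np.sqrt(z * z - 2 - 1 / n + 4 * p * (n * (1 - p) + 1))
        ) / denom
    if x == n:
        hi = 1.0
    else:
        hi = (
            2 * n * p + z * z + 1
            + z * np.sqrt(z * z + 2 - 1 / n + 4 * p * (n * (1 - p) - 1))
        ) / denom
    return float(max(lo, 0.0)), float(min(hi, 1.0))


def unadjusted_risks(
    pgs: np.ndarray,
    cohort: Cohort,
    cutoffs=(PRETERM_DAYS, VERY_PRETERM_DAYS),
    n_groups: int = 5,
) -> pd.DataFrame:
    """Raw event fractions per PGS quantile with Wilson score CIs.

    Computed among spontaneous births only: the fraction delivering before
    each cutoff (preterm < 259 days, very preterm < 224 days by default).
    """
    pgs = np.asarray(pgs, dtype=float)
    groups = _quantile_groups(pgs, n_groups)
    keep = cohort.spontaneous
    dur = cohort.durations
    rows = []
    for q in range(n_groups):
        sel = keep & (groups == q)
        n = int(sel.sum())
        if n == 0:
            raise ValueError(f"PGS group {q + 1} contains no spontaneous births")
        for cut in cutoffs:
            x = int((dur[sel] < cut).sum())
            lo, hi = wilson_ci(x, n)
            rows.append(
                {
                    "group": q + 1,
                    "cutoff_days": cut,
                    "events": x,
                    "n": n,
                    "risk": x / n,
                    "ci_low": lo,
                    "ci_high": hi,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class RareAlleleReport:
    """Per-individual rare-deleterious-allele burden and its associations."""

    allele_counts: np.ndarray
    homozygote_counts: np.ndarray
    n_allele_variants: int
    n_homozygote_variants: int
    corr_alleles_pgs: float
    corr_homozygotes_pgs: float
    assoc: pd.DataFrame  # logistic log-OR and p per count type and outcome


def rare_deleterious_counts(
    cohort: Cohort,
    weights: pd.DataFrame,
    pgs: np.ndarray | None = None,
    freq_cut: float = 0.10,
    effect_cut: float = -0.001,
) -> RareAlleleReport:
    """Count rare deleterious effect alleles and homozygous genotypes.

    A variant qualifies when its PGS weight is at most ``effect_cut`` days
    (deleterious: shortens gestation) and its effect-allele frequency in
    the cohort is below ``freq_cut``.  Reports the correlation of both
    counts with the PGS and their logistic association with very-preterm
    delivery adjusting for the PGS.
    """
    hard = cohort.hard_calls()
    freqs = np.nanmean(cohort.dosages, axis=0) / 2.0
    vmap = {vid: i for i, vid in enumerate(cohort.variants["id"])}
    allele = np.zeros(cohort.n)
    hom = np.zeros(cohort.n)
    n_av = n_hv = 0
    for _, row in weights.iterrows():
        i = vmap.get(row["id"])
        if i is None:
            continue
        if float(row["weight"]) <= effect_cut and freqs[i] < freq_cut:
            allele += hard[:, i]
            hom += hard[:, i] == 2
            n_av += 1
            n_hv += 1
    if pgs is None:
        pgs = compute_pgs(cohort, weights)
    pgs = np.asarray(pgs, dtype=float)

    def corr(a):
        return float(np.corrcoef(a, pgs)[0, 1]) if np.ptp(a) > 0 else np.nan

    keep = cohort.spontaneous
    vptd = (cohort.durations < VERY_PRETERM_DAYS)[keep].astype(float)
    ptd = (cohort.durations < PRETERM_DAYS)[keep].astype(float)
    rows = []
    for label, counts in [("alleles", allele), ("homozygotes", hom)]:
        for oname, y in [("ptd", ptd), ("vptd", vptd)]:
            if np.ptp(counts[keep]) == 0 or y.sum() == 0:
                rows.append({"count": label, "outcome": oname, "log_or": np.nan, "p": np.nan})
                continue
            X = np.column_stack([np.ones(keep.sum()), pgs[keep], counts[keep]])
            fit = _logistic_fit(X, y)
            if fit is None:
                rows.append({"count": label, "outcome": oname, "log_or": np.nan, "p": np.nan})
                continue
            b, V = fit
            z = b[-1] / np.sqrt(V[-1, -1])
            rows.append(
                {
                    "count": label,
                    "outcome": oname,
                    "log_or": float(b[-1]),
                    "p": float(2 * norm.sf(abs(z))),
                }
            )
    return RareAlleleReport(
        allele_counts=allele,
        homozygote_counts=hom,
        n_allele_variants=n_av,
        n_homozygote_variants=n_hv,
        corr_alleles_pgs=corr(allele),
        corr_homozygotes_pgs=corr(hom),
        assoc=pd.DataFrame(rows),
    )


def ld_prune(
    hard: np.ndarray, window: int = 100, step: int = 10, r2_threshold: float = 0.2
) -> np.ndarray:
    """Greedy pairwise LD pruning in sliding windows (indep-pairwise style).

    Within each ``window``-variant window (advancing by ``step``), when two
    retained variants correlate at r^2 above the threshold, the later one
    is removed.  Returns the retained column indices.
    """
    m = hard.shape[1]
    keep = np.ones(m, dtype=bool)
    start = 0
    while True:
        end = min(start + window, m)
        idx = [i for i in range(start, end) if keep[i]]
        for a_pos in range(len(idx)):
            if not keep[idx[a_pos]]:
                continue
            for b_pos in range(a_pos + 1, len(idx)):
                i, j = idx[a_pos], idx[b_pos]
                if not keep[j]:
                    continue
                gi, gj = hard[:, i], hard[:, j]
                if np.ptp(gi) == 0 or np.ptp(gj) == 0:
                    continue
                r = np.corrcoef(gi, gj)[0, 1]
                if r * r > r2_threshold:
                    keep[j] = False
        if end == m:
            break
        start += step
    return np.nonzero(keep)[0]


@dataclass
class PcaResult:
    """Genotype PCA with per-component outcome associations."""

    scores: np.ndarray  # (n, k)
    loadings: pd.DataFrame  # variant metadata + loading_1..k + in_region
    explained: np.ndarray
    assoc: pd.DataFrame  # pc, outcome, log_or, p
    kept_variants: np.ndarray


def pca_and_association(
    cohort: Cohort,
    pgs: np.ndarray,
    n_pcs: int = 10,
    r2_threshold: float = 0.2,
    window: int = 100,
    step: int = 10,
    region: tuple[str, int, int] | None = None,
) -> PcaResult:
    """PCA of the pruned genotype matrix plus outcome associations.

    Variants are LD-pruned, the hard-call matrix is centered and scaled by
    sqrt(2 p (1-p)), and the top components are extracted by SVD.  Each PC
    is tested for association with preterm and very-preterm delivery in a
    logistic model adjusting for the PGS and genotyping batch.  ``region``
    (chrom, start, end) flags loadings inside a query region such as the
    MHC.
    """
    hard = cohort.hard_calls()
    kept = ld_prune(hard, window=window, step=step, r2_threshold=r2_threshold)
    poly = [i for i in kept if np.ptp(hard[:, i]) > 0]
    kept = np.asarray(poly, dtype=int)
    k = min(n_pcs, len(kept))
    if k < n_pcs:
        logger.warning("only %d variants after pruning; extracting %d PCs", len(kept), k)
    G = hard[:, kept]
    p = G.mean(axis=0) / 2.0
    Z = (G - 2 * p) / np.sqrt(2 * p * (1 - p))
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    scores = U[:, :k] * s[:k]
    loadings = cohort.variants.iloc[kept].reset_index(drop=True).copy()
    for j in range(k):
        loadings[f"loading_{j + 1}"] = Vt[j]
    if region is not None:
        chrom, lo, hi = region
        loadings["in_region"] = (
            (loadings["chrom"].astype(str) == str(chrom))
            & (loadings["pos"] >= lo)
            & (loadings["pos"] <= hi)
        )
    explained = s[:k] ** 2 / np.sum(s**2)

    keep = cohort.spontaneous
    dur = cohort.durations
    batch = _batch_design(cohort.pheno)[keep][:, 1:]
    base = np.column_stack(
        [np.ones(int(keep.sum())), np.asarray(pgs, float)[keep], batch]
    )
    # constant adjustment columns (e.g. a degenerate PGS) are dropped
    base = base[:, [0] + [j for j in range(1, base.shape[1]) if np.ptp(base[:, j]) > 0]]
    rows = []
    for oname, cut in [("ptd", PRETERM_DAYS), ("vptd", VERY_PRETERM_DAYS)]:
        y = (dur[keep] < cut).astype(float)
        for j in range(k):
            X = np.column_stack([base, scores[keep, j]])
            fit = _logistic_fit(X, y)
            if fit is None:
                rows.append({"pc": j + 1, "outcome": oname, "log_or": np.nan, "p": np.nan})
                continue
            b, V = fit
            z = b[-1] / np.sqrt(V[-1, -1])
            rows.append(
                {
                    "pc": j + 1,
                    "outcome": oname,
                    "log_or": float(b[-1]),
                    "p": float(2 * norm.sf(abs(z))),
                }
            )
    return PcaResult(
        scores=scores,
        loadings=loadings,
        explained=explained,
        assoc=pd.DataFrame(rows),
        kept_variants=kept,
    )
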
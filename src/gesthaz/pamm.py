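"""Piecewise-exponential additive hazard models (PAMM).

The hazard model h(t|g,z) = h0(t) exp(beta(t) g + z'gamma) is approximated
by Poisson regression on the interval-expanded (PED) table: within each
interval the hazard is constant, the event count is Poisson with a
log-exposure offset, and both log h0 and beta(t) are penalized cubic
regression splines evaluated at the interval end times T.

The fit maximizes the penalized Poisson log-likelihood by iteratively
reweighted least squares; smoothing parameters are selected by the
generalized Fellner-Schall update, which converges to the Laplace-REML
optimum.  The covariance reported is the Bayesian posterior covariance
(X'WX + S_lambda)^-1, the standard choice for smooth-term intervals.

Rows of the PED table that share a design point (same interval, dosage and
covariate pattern) are collapsed before fitting — the Poisson likelihood is
unchanged — which makes replicated simulation studies cheap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import chi2, norm

from .splines import CRSplineBasis, build_crs_basis

__all__ = [
    "PammSpec",
    "PammFit",
    "HazardCurve",
    "PammConvergenceError",
    "fit_pamm",
    "fit_linear_interaction",
    "test_nonlinear",
    "predict_curve",
]

logger = logging.getLogger(__name__)


class PammConvergenceError(RuntimeError):
    """Raised when the penalized IRLS fails to converge."""

    def __init__(self, message: str, gradient_norm: float):
        super().__init__(f"{message} (last gradient norm {gradient_norm:.3g})")
        self.gradient_norm = gradient_norm


@dataclass(frozen=True)
class PammSpec:
    """Model specification for a PAMM fit.

    baseline_dim:
        Basis dimension of the log-baseline-hazard smooth (0 = constant
        baseline, i.e. a plain intercept).
    effect_dim / time_varying:
        Dimension of the time-varying allele-effect smooth; with
        ``time_varying=False`` only the constant per-allele term ``beta_g``
        is fitted (the simplified, Cox-like model).
    dosage_col / covariate_cols:
        Column names in the PED table for the allele dosage g and the
        constant-effect covariates z.
    """

    baseline_dim: int = 11
    effect_dim: int = 10
    dosage_col: str | tuple[str, ...] | None = "g"
    covariate_cols: tuple[str, ...] = ()
    time_varying: bool = True
    linear_interaction: bool = False

    @property
    def dosage_cols(self) -> tuple[str, ...]:
        if self.dosage_col is None:
            return ()
        if isinstance(self.dosage_col, str):
            return (self.dosage_col,)
        return tuple(self.dosage_col)


@dataclass
class PammFit:
    """Fitted PAMM: coefficients, covariance and smoothing diagnostics."""

    coef: np.ndarray
    cov: np.ndarray
    names: list
    blocks: dict
    lambdas: dict
    edf: dict
    loglik: float
    deviance: float
    converged: bool
    iterations: int
    spec: PammSpec
    t_range: tuple
    baseline_basis: CRSplineBasis | None = None
    effect_basis: CRSplineBasis | None = None
    effect_constraint: np.ndarray | None = None
    t_center: float = 0.0
    n_rows: int = 0
    n_events: float = 0.0
    cov_unconditional: np.ndarray | None = None

    @property
    def beta_g(self) -> float:
        i = self.blocks["dosage"][0]
        return float(self.coef[i])

    @property
    def se_g(self) -> float:
        i = self.blocks["dosage"][0]
        return float(np.sqrt(self.cov[i, i]))

    def coef_table(self) -> pd.DataFrame:
        se = np.sqrt(np.diag(self.cov))
        return pd.DataFrame({"name": self.names, "coef": self.coef, "se": se})

    def interaction_p(self) -> float:
        """Wald p-value for the linear time x dosage interaction."""
        if "interaction" not in self.blocks:
            raise ValueError("fit has no linear interaction term")
        i = self.blocks["interaction"][0]
        z = self.coef[i] / np.sqrt(self.cov[i, i])
        return float(2.0 * norm.sf(abs(z)))

    def to_report(self) -> dict:
        """JSON-serializable fit summary."""
        return {
            "coef": dict(zip(self.names, map(float, self.coef))),
            "se": dict(zip(self.names, map(float, np.sqrt(np.diag(self.cov))))),
            "lambdas": {k: float(v) for k, v in self.lambdas.items()},
            "edf": {k: float(v) for k, v in self.edf.items()},
            "loglik": self.loglik,
            "deviance": self.deviance,
            "converged": self.converged,
            "n_events": self.n_events,
        }


@dataclass(frozen=True)
class HazardCurve:
    """Estimated log hazard ratio beta(t) with pointwise 95% CI."""

    times: np.ndarray
    estimate: np.ndarray
    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        if not (
            np.all(self.lower <= self.estimate + 1e-12)
            and np.all(self.estimate <= self.upper + 1e-12)
        ):
            raise ValueError("CI bounds must bracket the estimate")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": self.times,
                "log_hr": self.estimate,
                "lo95": self.lower,
                "hi95": self.upper,
            }
        )


def _aggregate(ped: pd.DataFrame, cols: list) -> pd.DataFrame:
    """Collapse PED rows sharing a design point (likelihood-exact)."""
    keys = ["t_end"] + cols
    n_unique = ped.drop_duplicates(keys).shape[0]
    if n_unique > 0.5 * len(ped):
        out = ped.copy()
        out["_count"] = 1.0
        return out
    grouped = (
        ped.groupby(keys, sort=False, observed=True)
        .agg(exposure=("exposure", "sum"), event=("event", "sum"), _count=("event", "size"))
        .reset_index()
    )
    return grouped


def _build_design(ped: pd.DataFrame, spec: PammSpec):
    """Assemble X, penalties and bookkeeping from an (aggregated) PED table."""
    t = ped["t_end"].to_numpy(dtype=float)
    counts = ped["_count"].to_numpy(dtype=float)
    cols, names, blocks, penalties = [], [], {}, {}
    pos = 0

    baseline_basis = None
    if spec.baseline_dim and spec.baseline_dim > 0:
        baseline_basis = build_crs_basis(t, spec.baseline_dim)
        B0 = baseline_basis.evaluate(t)
        cols.append(B0)
        names += [f"baseline_{i}" for i in range(B0.shape[1])]
        blocks["baseline"] = np.arange(pos, pos + B0.shape[1])
        penalties["baseline"] = baseline_basis.penalty
        pos += B0.shape[1]
    else:
        cols.append(np.ones((len(t), 1)))
        names.append("intercept")
        blocks["baseline"] = np.arange(pos, pos + 1)
        pos += 1

    effect_basis = None
    Q = None
    t_center = float(np.average(t, weights=counts))
    multi = len(spec.dosage_cols) > 1
    for col in spec.dosage_cols:
        tag = f":{col}" if multi else ""
        g = ped[col].to_numpy(dtype=float)
        if np.ptp(g) == 0:
            raise ValueError(
                f"dosage column {col!r} is constant; "
                "the genetic effect is not identifiable"
            )
        cols.append(g[:, None])
        names.append(f"beta_g{tag}")
        blocks[f"dosage{tag}"] = np.arange(pos, pos + 1)
        pos += 1
        if spec.time_varying:
            if effect_basis is None:
                effect_basis = build_crs_basis(t, spec.effect_dim)
                B1 = effect_basis.evaluate(t)
                # sum-to-zero over observed rows identifies the constant term
                csum = (B1 * counts[:, None]).sum(axis=0)[:, None]
                qfull, _ = np.linalg.qr(csum, mode="complete")
                Q = qfull[:, 1:]
                B1Q = B1 @ Q
            Z = B1Q * g[:, None]
            cols.append(Z)
            names += [f"effect{tag}_{i}" for i in range(Z.shape[1])]
            blocks[f"effect_smooth{tag}"] = np.arange(pos, pos + Z.shape[1])
            penalties[f"effect_smooth{tag}"] = Q.T @ effect_basis.penalty @ Q
            pos += Z.shape[1]
        if spec.linear_interaction:
            cols.append((g * (t - t_center))[:, None])
            names.append(f"beta_gt{tag}")
            blocks[f"interaction{tag}"] = np.arange(pos, pos + 1)
            pos += 1

    for c in spec.covariate_cols:
        cols.append(ped[c].to_numpy(dtype=float)[:, None])
        names.append(c)
    if spec.covariate_cols:
        blocks["covariates"] = np.arange(pos, pos + len(spec.covariate_cols))
        pos += len(spec.covariate_cols)

    X = np.hstack(cols)
    return X, names, blocks, penalties, baseline_basis, effect_basis, Q, t_center


def _penalty_matrix(p, blocks, penalties, lambdas):
    S = np.zeros((p, p))
    for name, Sj in penalties.items():
        idx = blocks[name]
        S[np.ix_(idx, idx)] += lambdas[name] * Sj
    return S


def _pirls(X, y, offset, S, beta0, max_iter=200, tol=1e-8):
    """Penalized IRLS for Poisson with log link and offset."""
    beta = beta0.copy()
    eta = X @ beta + offset
    mu = np.exp(eta)

    def pen_dev(b, m):
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(y > 0, y * np.log(y / m), 0.0)
        return 2.0 * np.sum(term - (y - m)) + b @ S @ b

    pd_old = pen_dev(beta, mu)
    grad_norm = np.inf
    for it in range(1, max_iter + 1):
        w = mu
        z = (eta - offset) + (y - mu) / mu
        XtW = X.T * w
        H = XtW @ X + S
        rhs = XtW @ z
        try:
            beta_new = np.linalg.solve(H, rhs)
        except np.linalg.LinAlgError:
            beta_new = np.linalg.lstsq(H, rhs, rcond=None)[0]
        # step-halving on the penalized deviance
        step = 1.0
        for _ in range(30):
            cand = beta + step * (beta_new - beta)
            eta_c = X @ cand + offset
            mu_c = np.exp(np.clip(eta_c, -700, 700))
            pd_new = pen_dev(cand, mu_c)
            if np.isfinite(pd_new) and pd_new <= pd_old + 1e-10:
                break
            step *= 0.5
        beta, eta, mu = cand, eta_c, mu_c
        grad_norm = float(np.linalg.norm(X.T @ (y - mu) - S @ beta))
        if abs(pd_old - pd_new) < tol * (abs(pd_new) + 0.1):
            return beta, mu, True, it, grad_norm
        pd_old = pd_new
    return beta, mu, False, max_iter, grad_norm


def _smoothing_uncertainty_cov(
    X, y, offset, beta, cov, p, blocks, penalties, ranks, lam
):
    """Coefficient covariance corrected for smoothing-parameter uncertainty.

    First-order correction V_c = V_b + J V_rho J' where J = d beta / d rho
    (rho = log lambda) and V_rho is the inverse Hessian of the Laplace
    REML criterion, estimated by central finite differences.  This is the
    standard remedy for the under-coverage of intervals that condition on
    the selected smoothing parameters.
    """
    keys = list(penalties)
    q = len(keys)
    rho = np.log([lam[k] for k in keys])
    emb = {}
    for name in keys:
        idx = blocks[name]
        Sj = np.zeros((p, p))
        Sj[np.ix_(idx, idx)] = penalties[name]
        emb[name] = Sj

    # J columns: implicit differentiation of the penalized score at beta-hat
    J = np.column_stack(
        [-lam[k] * (cov @ (emb[k] @ beta)) for k in keys]
    )

    def laml(rho_vec):
        lam_v = {k: float(np.exp(r)) for k, r in zip(keys, rho_vec)}
        S = sum(lam_v[k] * emb[k] for k in keys)
        b, mu, ok, _, _ = _pirls(X, y, offset, S, beta.copy())
        if not ok:
            return np.nan
        eta = X @ b + offset
        ll = float(np.sum(y * eta - np.exp(eta)))
        H = (X.T * mu) @ X + S
        _, logdet = np.linalg.slogdet(H)
        pen = 0.5 * float(b @ S @ b)
        return -(ll - pen) + 0.5 * logdet - 0.5 * sum(
            ranks[k] * r for k, r in zip(keys, rho_vec)
        )

    h = 0.5
    Hess = np.zeros((q, q))
    c0 = laml(rho)
    for i in range(q):
        ei = np.zeros(q)
        ei[i] = h
        cp, cm = laml(rho + ei), laml(rho - ei)
        Hess[i, i] = (cp - 2 * c0 + cm) / h**2
        for j in range(i + 1, q):
            ej = np.zeros(q)
            ej[j] = h
            cpp = laml(rho + ei + ej)
            cpm = laml(rho + ei - ej)
            cmp = laml(rho - ei + ej)
            cmm = laml(rho - ei - ej)
            Hess[i, j] = Hess[j, i] = (cpp - cpm - cmp + cmm) / (4 * h**2)
    if not np.all(np.isfinite(Hess)):
        return None
    w, U = np.linalg.eigh((Hess + Hess.T) / 2.0)
    w = np.maximum(w, 0.05)  # flat/boundary directions: bound the variance
    V_rho = (U / w) @ U.T
    Vc = cov + J @ V_rho @ J.T
    return (Vc + Vc.T) / 2.0


def fit_pamm(
    ped: pd.DataFrame,
    spec: PammSpec = PammSpec(),
    lambdas: dict | None = None,
    max_outer: int = 60,
) -> PammFit:
    """Fit the penalized-spline Poisson hazard model to a PED table.

    Parameters
    ----------
    ped : DataFrame
        Interval-expanded data from :func:`gesthaz.ped.expand_cohort` with
        columns ``t_end``, ``exposure``, ``event`` plus the dosage and
        covariate columns named in ``spec``.
    spec : PammSpec
    lambdas : dict, optional
        Fixed smoothing parameters keyed by smooth name (``baseline``,
        ``effect_smooth``); when omitted they are selected by
        Fellner-Schall REML iteration.

    Raises
    ------
    PammConvergenceError
        If the inner IRLS fails to converge.
    ValueError
        For a constant dosage column (degenerate covariate).
    """
    data_cols = [*spec.dosage_cols, *spec.covariate_cols]
    agg = _aggregate(ped, data_cols)
    X, names, blocks, penalties, b_basis, e_basis, Q, t_center = _build_design(agg, spec)
    y = agg["event"].to_numpy(dtype=float)
    offset = np.log(agg["exposure"].to_numpy(dtype=float))
    n, p = X.shape

    lam = {k: 1.0 for k in penalties}
    fixed = lambdas is not None
    if fixed:
        lam.update(lambdas)
    ranks = {k: int(np.linalg.matrix_rank(Sj)) for k, Sj in penalties.items()}

    # constant-rate start: every baseline coefficient at log(total rate)
    beta = np.zeros(p)
    rate = max(y.sum(), 0.5) / np.exp(offset).sum()
    beta[blocks["baseline"]] = np.log(rate)

    it_total = 0
    for outer in range(max_outer if (penalties and not fixed) else 1):
        S = _penalty_matrix(p, blocks, penalties, lam)
        beta, mu, ok, iters, gnorm = _pirls(X, y, offset, S, beta)
        it_total += iters
        if not ok:
            raise PammConvergenceError("penalized IRLS did not converge", gnorm)
        if fixed or not penalties:
            break
        XtWX = (X.T * mu) @ X
        H = XtWX + S
        Hinv = np.linalg.inv(H)
        changed = 0.0
        for name, Sj in penalties.items():
            idx = blocks[name]
            Sj_emb = np.zeros((p, p))
            Sj_emb[np.ix_(idx, idx)] = Sj
            tr_h = float(np.trace(Hinv @ Sj_emb))
            num = max(ranks[name] - lam[name] * tr_h, 1e-10)
            den = max(float(beta @ Sj_emb @ beta), 1e-12)
            new = float(np.clip(num / den, 1e-8, 1e10))
            changed = max(changed, abs(np.log(new) - np.log(lam[name])))
            lam[name] = new
        if changed < 0.02:
            S = _penalty_matrix(p, blocks, penalties, lam)
            beta, mu, ok, iters, gnorm = _pirls(X, y, offset, S, beta)
            it_total += iters
            break

    S = _penalty_matrix(p, blocks, penalties, lam)
    XtWX = (X.T * mu) @ X
    H = XtWX + S
    cov = np.linalg.inv(H)
    cov = (cov + cov.T) / 2.0
    edf_all = np.diag(cov @ XtWX)
    edf = {name: float(edf_all[blocks[name]].sum()) for name in blocks}

    cov_vc = None
    if penalties and not fixed:
        cov_vc = _smoothing_uncertainty_cov(
            X, y, offset, beta, cov, p, blocks, penalties, ranks, lam
        )

    eta = X @ beta + offset
    loglik = float(np.sum(y * eta - np.exp(eta) - gammaln(y + 1.0)))
    with np.errstate(divide="ignore", invalid="ignore"):
        dev_term = np.where(y > 0, y * np.log(y / np.exp(eta)), 0.0)
    deviance = float(2.0 * np.sum(dev_term - (y - np.exp(eta))))

    t = agg["t_end"].to_numpy(dtype=float)
    return PammFit(
        coef=beta,
        cov=cov,
        names=names,
        blocks=blocks,
        lambdas=dict(lam),
        edf=edf,
        loglik=loglik,
        deviance=deviance,
        converged=True,
        iterations=it_total,
        spec=spec,
        t_range=(float(t.min()), float(t.max())),
        baseline_basis=b_basis,
        effect_basis=e_basis,
        effect_constraint=Q,
        t_center=t_center,
        n_rows=int(len(ped)),
        n_events=float(y.sum()),
        cov_unconditional=cov_vc,
    )


def fit_linear_interaction(
    ped: pd.DataFrame, spec: PammSpec = PammSpec()
) -> PammFit:
    """Fit the linear time x dosage interaction variant.

    Replaces the effect spline with a parametric term ``beta_gt * g * (T -
    mean T)``; the Wald p-value for ``beta_gt`` is available as
    :meth:`PammFit.interaction_p`.
    """
    spec = replace(spec, time_varying=False, linear_interaction=True)
    return fit_pamm(ped, spec)


def test_nonlinear(fit: PammFit, term: str = "effect_smooth") -> float:
    """Wald test that the allele effect is constant over gestation.

    Null hypothesis: all effect-smooth coefficients are zero (the variant
    has a time-constant hazard ratio).  The statistic is beta_1' V_r^- beta_1
    with V_r^- the rank-r pseudo-inverse of the smooth's posterior
    covariance block, r being the rounded effective degrees of freedom —
    the standard penalized-smooth Wald test.
    """
    if term not in fit.blocks:
        raise ValueError(f"fit has no smooth term {term!r} to test")
    idx = fit.blocks[term]
    b = fit.coef[idx]
    V = fit.cov[np.ix_(idx, idx)]
    k = len(idx)
    r = int(np.clip(round(fit.edf[term]), 1, k))
    w, U = np.linalg.eigh(V)
    order = np.argsort(w)[::-1]
    w, U = w[order], U[:, order]
    keep = w[:r]
    tol = max(w[0], 0.0) * 1e-10
    usable = keep > tol
    if not usable.all():
        logger.info(
            "smooth covariance block rank-deficient: using %d of %d requested",
            int(usable.sum()),
            r,
        )
        keep = keep[usable]
        r = len(keep)
    proj = U[:, : len(keep)].T @ b
    stat = float(np.sum(proj**2 / keep))
    return float(chi2.sf(stat, r))


def predict_curve(fit: PammFit, times, term: str = "") -> HazardCurve:
    """Evaluate the estimated log hazard ratio beta(t) with pointwise CI.

    ``times`` are on the shifted-day scale used in fitting; requesting
    points outside the fitted range raises (no extrapolation).  With
    several dosage terms in the fit, ``term`` names the column (the curve
    returned is for ``dosage:<term>``).
    """
    times = np.asarray(times, dtype=float).ravel()
    lo, hi = fit.t_range
    if times.min() < lo - 1e-9 or times.max() > hi + 1e-9:
        raise ValueError(
            f"requested times outside the fitted range [{lo:g}, {hi:g}]"
        )
    tag = f":{term}" if term else ""
    if f"dosage{tag}" not in fit.blocks:
        raise ValueError(f"fit has no dosage term {term!r}")
    p = len(fit.coef)
    A = np.zeros((len(times), p))
    A[:, fit.blocks[f"dosage{tag}"][0]] = 1.0
    if f"effect_smooth{tag}" in fit.blocks:
        Z = fit.effect_basis.evaluate(times) @ fit.effect_constraint
        A[:, fit.blocks[f"effect_smooth{tag}"]] = Z
    if f"interaction{tag}" in fit.blocks:
        A[:, fit.blocks[f"interaction{tag}"][0]] = times - fit.t_center
    est = A @ fit.coef
    V = fit.cov if fit.cov_unconditional is None else fit.cov_unconditional
    se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", A, V, A), 0.0))
    z = norm.ppf(0.975)
    return HazardCurve(
        times=times, estimate=est, lower=est - z * se, upper=est + z * se
    )
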
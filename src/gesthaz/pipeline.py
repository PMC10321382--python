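"""End-to-end orchestration of the analysis stages.

A single :class:`RunConfig` (loadable from YAML) drives: cohort simulation
(or loading), association scans, per-variant PAMM fits with the
time-varying-effect test and both proportionality sensitivity analyses,
the liability-power report, and the PGS analyses.  Every stage is seeded
and the run directory receives a manifest listing outputs with checksums,
so a rerun with the same config reproduces every file.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as gio
from .cohort import Cohort
from .cox import fit_cox, zph_test
from .pamm import PammSpec, fit_linear_interaction, fit_pamm, predict_curve, test_nonlinear
from .ped import expand_cohort, prepare_covariates, shift_durations
from .pgs import compute_pgs, quantile_group_pamm, unadjusted_risks, variance_explained
from .power import power_report
from .scan import linear_scan, logistic_scan, suggestive_concordance
from .simulate import CohortConfig, EffectShape, bootstrap_phenotype, simulate_durations

__all__ = ["RunConfig", "run", "type1_experiment"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Pipeline settings; every stochastic stage derives from ``seed``."""

    out_dir: str = "gesthaz_run"
    seed: int = 1
    # simulation (used unless cohort_prefix points at existing data)
    cohort_prefix: str | None = None
    n: int = 20000
    mafs: tuple = (0.3, 0.2)
    effect_kinds: tuple = ("constant", "null")
    effect_magnitude: float = 0.2
    censor_frac: float = 0.15
    # stage toggles
    stages: tuple = ("simulate", "scan", "pamm", "power", "pgs")
    # model dimensions
    baseline_dim: int = 11
    effect_dim: int = 10
    # power report inputs
    power_K: float = 0.027
    power_n: int = 22247
    power_maf: float = 0.2
    power_alpha: float = 5e-8
    power_f: float = 0.8
    power_sd_days: float | None = 12.0
    # pgs
    pgs_weights: str | None = None
    pgs_groups: int = 5

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _cohort_from_config(cfg: RunConfig) -> Cohort:
    effects = tuple(
        EffectShape(kind, cfg.effect_magnitude if kind != "null" else 0.0)
        for kind in cfg.effect_kinds
    )
    sim = CohortConfig(
        n=cfg.n,
        mafs=tuple(cfg.mafs),
        effects=effects,
        censor_frac=cfg.censor_frac,
        seed=cfg.seed,
    )
    return simulate_durations(sim)


def run(config: RunConfig) -> Path:
    """Execute the configured stages in dependency order.

    Returns the run directory; raises with the stage name on failure.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}, "files": {}}
    stage = "setup"
    try:
        stage = "simulate"
        t0 = time.time()
        if config.cohort_prefix:
            cohort = gio.read_cohort(config.cohort_prefix)
        else:
            cohort = _cohort_from_config(config)
        if "simulate" in config.stages and not config.cohort_prefix:
            paths = gio.write_cohort(cohort, out / "cohort")
            manifest["files"].update({k: str(v) for k, v in paths.items()})
        manifest["stages"]["simulate"] = {
            "seconds": round(time.time() - t0, 2),
            "records": cohort.n,
        }
        logger.info("stage simulate: n=%d", cohort.n)

        covariates = prepare_covariates(cohort)

        if "scan" in config.stages and cohort.n_variants:
            stage = "scan"
            t0 = time.time()
            lin = linear_scan(cohort)
            logi = logistic_scan(cohort)
            lin.to_csv(out / "scan_linear.tsv", sep="\t", index=False)
            logi.to_csv(out / "scan_logistic.tsv", sep="\t", index=False)
            conc = suggestive_concordance(lin, logi)
            conc.to_csv(out / "scan_concordance.tsv", sep="\t", index=False)
            manifest["stages"]["scan"] = {
                "seconds": round(time.time() - t0, 2),
                "records": len(lin),
            }

        if "pamm" in config.stages and cohort.n_variants:
            stage = "pamm"
            t0 = time.time()
            reports, curve_frames = {}, []
            dur = shift_durations(cohort.durations)
            ev = cohort.spontaneous
            cov_cols = tuple(covariates.columns)
            ped = expand_cohort(cohort, covariates=covariates)
            for j, vid in enumerate(cohort.variants["id"]):
                pedj = ped.copy()
                pedj["g"] = cohort.dosages[:, j][pedj["subject"].to_numpy()]
                spec = PammSpec(
                    baseline_dim=config.baseline_dim,
                    effect_dim=config.effect_dim,
                    covariate_cols=cov_cols,
                )
                fit = fit_pamm(pedj, spec)
                rep = fit.to_report()
                rep["p_nonlinear"] = test_nonlinear(fit)
                rep["p_linear_interaction"] = fit_linear_interaction(
                    pedj, spec
                ).interaction_p()
                X = np.column_stack(
                    [cohort.dosages[:, j], covariates.to_numpy(dtype=float)]
                )
                cx = fit_cox(dur, ev, X)
                rep["cox_beta"] = float(cx.coef[0])
                rep["cox_se"] = float(cx.se[0])
                _, rep["p_zph"] = zph_test(cx, dur, ev, X, covariate=0)
                reports[str(vid)] = rep
                crv = predict_curve(
                    fit, np.arange(fit.t_range[0], fit.t_range[1] + 1e-9, 7.0)
                ).to_frame()
                crv.insert(0, "id", vid)
                curve_frames.append(crv)
            (out / "pamm_fits.json").write_text(json.dumps(reports, indent=1))
            pd.concat(curve_frames).to_csv(out / "pamm_curves.tsv", sep="\t", index=False)
            manifest["stages"]["pamm"] = {
                "seconds": round(time.time() - t0, 2),
                "records": len(reports),
            }

        if "power" in config.stages:
            stage = "power"
            rep = power_report(
                K=config.power_K,
                n=config.power_n,
                maf=config.power_maf,
                alpha=config.power_alpha,
                f=config.power_f,
                sd_y=config.power_sd_days,
            )
            (out / "power_report.json").write_text(json.dumps(rep.as_dict(), indent=1))
            manifest["stages"]["power"] = {"records": 1}

        if "pgs" in config.stages and cohort.n_variants:
            stage = "pgs"
            t0 = time.time()
            if config.pgs_weights:
                weights = gio.read_weights(config.pgs_weights)
            else:
                # default demo weights: every simulated variant, -0.3 d/allele
                weights = cohort.variants.copy()
                weights["weight"] = -0.3
            pgs = compute_pgs(cohort, weights)
            res = {
                "r2": variance_explained(pgs, cohort),
                "r2_with_covariates": variance_explained(
                    pgs, cohort, with_covariates=True
                ),
            }
            risks = unadjusted_risks(pgs, cohort, n_groups=config.pgs_groups)
            risks.to_csv(out / "pgs_risks.tsv", sep="\t", index=False)
            qg = quantile_group_pamm(pgs, cohort, n_groups=config.pgs_groups)
            frames = []
            for name, crv in qg.curves.items():
                f = crv.to_frame()
                f.insert(0, "group", name)
                frames.append(f)
            pd.concat(frames).to_csv(out / "pgs_curves.tsv", sep="\t", index=False)
            (out / "pgs_report.json").write_text(json.dumps(res, indent=1))
            manifest["stages"]["pgs"] = {"seconds": round(time.time() - t0, 2)}

        for p in sorted(out.iterdir()):
            if p.name != "manifest.json" and p.is_file():
                manifest["files"][p.name] = _checksum(p)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        return out
    except Exception as exc:  # noqa: BLE001 - annotate with the failing stage
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc


def type1_experiment(
    cohort: Cohort | None = None,
    n: int = 2000,
    replicates: int = 200,
    maf: float = 0.3,
    alpha: float = 0.05,
    seed: int = 1,
    baseline_dim: int = 11,
    effect_dim: int = 10,
) -> dict:
    """Type-I-error calibration of the time-varying-effect test.

    For each replicate the phenotype is bootstrap-resampled from the
    cohort, a null locus at the given MAF is simulated, the full
    time-varying PAMM is fitted, and the non-linearity p-value recorded.
    Returns the rejection fraction at ``alpha`` with its exact
    (Clopper-Pearson) 95% binomial CI.
    """
    from scipy.stats import beta as beta_dist

    if cohort is None:
        cohort = simulate_durations(CohortConfig(n=n, mafs=(), effects=(), seed=seed))
    rng = np.random.default_rng(seed)
    pvals, failures = [], 0
    spec = PammSpec(baseline_dim=baseline_dim, effect_dim=effect_dim)
    for r in range(replicates):
        boot = bootstrap_phenotype(cohort, seed=int(rng.integers(2**31 - 1)))
        g = (rng.random(boot.n) < maf).astype(float) + (rng.random(boot.n) < maf)
        ped = expand_cohort(boot)
        ped["g"] = g[ped["subject"].to_numpy()]
        try:
            fit = fit_pamm(ped, spec)
            pvals.append(test_nonlinear(fit))
        except Exception:  # noqa: BLE001 - per-replicate failures are counted
            failures += 1
    pvals = np.asarray(pvals)
    k = int((pvals < alpha).sum())
    nrep = len(pvals)
    lo = beta_dist.ppf(0.025, k, nrep - k + 1) if k > 0 else 0.0
    hi = beta_dist.ppf(0.975, k + 1, nrep - k) if k < nrep else 1.0
    return {
        "replicates": nrep,
        "failures": failures,
        "alpha": alpha,
        "rejections": k,
        "fraction": k / nrep if nrep else np.nan,
        "ci_low": float(lo),
        "ci_high": float(hi),
        "pvalues": pvals,
    }
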
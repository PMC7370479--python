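"""Pipeline orchestration: simulate -> estimate -> validate, with CSV stages.

Every stage writes an RFC-4180 CSV (full-precision floats) and can be re-run
in isolation from the previous stage's file.  A run manifest (JSON) records
the configuration, seed, package version, row counts and the number of
datasets excluded because their estimated test performed no better than
chance.

The ``full`` preset is the validation study's design: 1,000 scenarios x
1,000 replicate datasets.  Reduced presets are for smoke tests and are
recorded as such in the manifest.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import datasim, frequentist as fq, scenarios as sc, validation
from .gibbs import McmcConfig, gibbs_batch
from .model import ALL_METHODS, PrevalenceModel

__all__ = [
    "RunConfig",
    "run_pipeline",
    "estimate_single",
    "frequentist_estimates_table",
    "bayes_estimates_table",
    "build_estimates",
]

ESTIMATE_COLUMNS = [
    "scenario_id", "replicate_id", "method",
    "point_raw", "point", "lower", "upper", "length",
]

PRESETS = {
    "full": dict(n_scenarios=1000, n_replicates=1000,
                 mcmc=McmcConfig(n_chains=3, n_burnin=5000, n_samples=6667)),
    "reduced": dict(n_scenarios=10, n_replicates=10,
                    mcmc=McmcConfig(n_chains=3, n_burnin=200, n_samples=500)),
}


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one end-to-end pipeline run."""

    n_scenarios: int = 1000
    n_replicates: int = 1000
    seed: int = 0
    level: float = 0.95
    methods: tuple[str, ...] = ALL_METHODS
    outdir: str = "prevest-run"
    preset: str = "full"
    mcmc: McmcConfig = field(default_factory=McmcConfig)

    @classmethod
    def from_preset(cls, preset: str, seed: int = 0, outdir: str = "prevest-run",
                    **overrides) -> "RunConfig":
        if preset not in PRESETS:
            raise ValueError(f"unknown preset {preset!r}")
        base = dict(PRESETS[preset])
        base.update(overrides)
        return cls(seed=seed, outdir=outdir, preset=preset, **base)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        doc = yaml.safe_load(text)  # YAML is a superset of JSON
        mcmc_doc = doc.pop("mcmc", {})
        mcmc = McmcConfig(**mcmc_doc) if mcmc_doc else McmcConfig()
        doc["methods"] = tuple(doc.get("methods", ALL_METHODS))
        return cls(mcmc=mcmc, **doc)

    def to_jsonable(self) -> dict:
        d = asdict(self)
        d["methods"] = list(self.methods)
        return d


# ---------------------------------------------------------------------------
# batch estimation
# ---------------------------------------------------------------------------

def _with_sizes(data: pd.DataFrame, scen: pd.DataFrame) -> pd.DataFrame:
    return data.merge(scen[["scenario_id", "n", "n_se", "n_sp"]],
                      on="scenario_id", how="left", validate="many_to_one")


def frequentist_estimates_table(data: pd.DataFrame, scen: pd.DataFrame,
                                methods=fq.FREQUENTIST_METHODS, level: float = 0.95,
                                lr_adjustment=fq.LangReiczigelAdjustment()) -> pd.DataFrame:
    """Long estimates table for the frequentist methods over retained datasets.

    Clopper-Pearson, Wald-RG and Lang-Reiczigel are fully vectorised; the
    Sterne and Blaker test inversions run per dataset and are meant for
    reduced-scale tables.
    """
    d = _with_sizes(data[data["case"] != "excluded"], scen)
    raw = fq.rogan_gladen(d["ap_hat"].to_numpy(), d["se_hat"].to_numpy(), d["sp_hat"].to_numpy())
    point = np.clip(raw, 0.0, 1.0)
    fp = 1.0 - d["sp_hat"].to_numpy()
    denom = d["se_hat"].to_numpy() - fp
    frames = []

    def base(method) -> pd.DataFrame:
        return pd.DataFrame({
            "scenario_id": d["scenario_id"].to_numpy(),
            "replicate_id": d["replicate_id"].to_numpy(),
            "method": method,
            "point_raw": raw,
            "point": point,
            "case": d["case"].to_numpy(),
        })

    for method in methods:
        if method in ("clopper_pearson", "sterne", "blaker"):
            if method == "clopper_pearson":
                lo_ap, hi_ap = fq.clopper_pearson_interval(
                    d["x"].to_numpy(), d["n"].to_numpy(), level)
            else:
                lo_ap = np.empty(len(d))
                hi_ap = np.empty(len(d))
                for i, (xi, ni) in enumerate(zip(d["x"].to_numpy(), d["n"].to_numpy())):
                    lo_ap[i], hi_ap[i] = fq.exact_binomial_ci(int(xi), int(ni), level, method)
            t = base(method)
            t["lower"] = np.clip((lo_ap - fp) / denom, 0.0, 1.0)
            t["upper"] = np.clip((hi_ap - fp) / denom, 0.0, 1.0)
        elif method == "wald_rogan_gladen":
            _, _, lo, hi = fq._wald_rg_arrays(
                d["ap_hat"].to_numpy(), d["se_hat"].to_numpy(), d["sp_hat"].to_numpy(),
                d["n"].to_numpy(), d["n_se"].to_numpy(), d["n_sp"].to_numpy(), level)
            t = base(method)
            t["lower"], t["upper"] = lo, hi
        elif method == "lang_reiczigel":
            adenom, araw, apoint, lo, hi = fq._lang_reiczigel_arrays(
                d["x"].to_numpy(dtype=float), d["x_se"].to_numpy(dtype=float),
                d["x_sp"].to_numpy(dtype=float), d["n"].to_numpy(dtype=float),
                d["n_se"].to_numpy(dtype=float), d["n_sp"].to_numpy(dtype=float),
                level, lr_adjustment)
            t = base(method)
            t["lower"], t["upper"] = lo, hi
            bad = adenom <= 0.0  # adjusted test no better than chance; vanishingly rare
            if np.any(bad):
                t.loc[bad, ["lower", "upper"]] = np.nan
        else:
            raise ValueError(f"unknown frequentist method {method!r}")
        t["length"] = t["upper"] - t["lower"]
        frames.append(t)
    return pd.concat(frames, ignore_index=True)


def bayes_estimates_table(data: pd.DataFrame, scen: pd.DataFrame,
                          cfg: McmcConfig, compute_ess: bool = True) -> pd.DataFrame:
    """Long estimates table (method=bayes_hdi) over retained datasets."""
    d = _with_sizes(data[data["case"] != "excluded"], scen)
    fit = gibbs_batch(d[["x", "n", "x_se", "n_se", "x_sp", "n_sp"]], cfg,
                      compute_ess=compute_ess)
    t = pd.DataFrame({
        "scenario_id": d["scenario_id"].to_numpy(),
        "replicate_id": d["replicate_id"].to_numpy(),
        "method": "bayes_hdi",
        "point_raw": np.nan,
        "point": fit["point"].to_numpy(),
        "lower": fit["lower"].to_numpy(),
        "upper": fit["upper"].to_numpy(),
        "case": d["case"].to_numpy(),
        "psrf": fit["psrf"].to_numpy(),
        "ess": fit["ess"].to_numpy(),
        "converged": fit["converged"].to_numpy(),
    })
    t["length"] = t["upper"] - t["lower"]
    return t


def build_estimates(data: pd.DataFrame, scen: pd.DataFrame, cfg: RunConfig,
                    log=print) -> pd.DataFrame:
    freq = [m for m in cfg.methods if m in fq.FREQUENTIST_METHODS]
    frames = []
    if freq:
        frames.append(frequentist_estimates_table(data, scen, freq, cfg.level))
    if "bayes_hdi" in cfg.methods:
        mcmc = replace(cfg.mcmc, seed=cfg.seed)
        bt = bayes_estimates_table(data, scen, mcmc)
        n_bad = int((~bt["converged"]).sum())
        if n_bad and log:
            for row in bt.loc[~bt["converged"], ["scenario_id", "replicate_id", "psrf"]].itertuples(index=False):
                log(f"WARN: non-converged Bayesian fit scenario={row.scenario_id} "
                    f"replicate={row.replicate_id} psrf={row.psrf:.3f}")
        frames.append(bt)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# pipeline stages
# ---------------------------------------------------------------------------

def _write_csv(df: pd.DataFrame, path: Path) -> None:
    try:
        df.to_csv(path, index=False)
    except BaseException:
        path.unlink(missing_ok=True)  # no partial stage outputs
        raise


def _error_tables(estimates: pd.DataFrame, scen: pd.DataFrame):
    errors = validation.estimation_errors(estimates, scen)
    coverage = validation.coverage_by_scenario(estimates, scen)
    lengths = validation.interval_lengths(estimates)
    return errors, coverage, lengths


def _deming_table(estimates: pd.DataFrame, scen: pd.DataFrame) -> pd.DataFrame:
    """Bayes-vs-RGE error regression and HDI-vs-Lang-Reiczigel length regression."""
    rows = []
    merged = validation.estimation_errors(estimates, scen)
    bayes = merged[merged["method"] == "bayes_hdi"]
    freq_methods = [m for m in merged["method"].unique() if m != "bayes_hdi"]
    if len(bayes) and freq_methods:
        # all frequentist methods share the truncated RGE point; use any one
        ref = merged[merged["method"] == freq_methods[0]]
        pair = ref.merge(bayes, on=["scenario_id", "replicate_id"], suffixes=("_rge", "_bayes"))
        fit = validation.deming_fit(pair["error_rge"], pair["error_bayes"])
        rows.append({"comparison": "bayes_error_on_rge_error", **_deming_row(fit)})
    if len(bayes) and "lang_reiczigel" in set(merged["method"]):
        ln = validation.interval_lengths(estimates)
        lr = ln[ln["method"] == "lang_reiczigel"]
        bl = ln[ln["method"] == "bayes_hdi"]
        pair = lr.merge(bl, on=["scenario_id", "replicate_id"], suffixes=("_lr", "_bayes"))
        pair = pair.dropna(subset=["length_lr", "length_bayes"])
        fit = validation.deming_fit(pair["length_lr"], pair["length_bayes"])
        rows.append({"comparison": "hdi_length_on_lr_length", **_deming_row(fit)})
    return pd.DataFrame(rows)


def _deming_row(fit: validation.DemingFit) -> dict:
    return {"slope": fit.slope, "intercept": fit.intercept,
            "slope_lower": fit.slope_ci[0], "slope_upper": fit.slope_ci[1],
            "r": fit.r, "n": fit.n}


def run_pipeline(cfg: RunConfig, log=print) -> dict:
    """Execute all stages and return the run manifest (also written to disk)."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)

    if log:
        log(f"[1/4] simulating {cfg.n_scenarios} parameter sets")
    scen = sc.draw_scenarios(cfg.n_scenarios, cfg.seed)
    _write_csv(scen, out / "scenarios.csv")

    if log:
        log(f"[2/4] simulating {cfg.n_replicates} datasets per scenario")
    data = datasim.simulate_datasets(scen, cfg.n_replicates, cfg.seed)
    _write_csv(data, out / "data.csv")
    n_excluded = int((data["case"] == "excluded").sum())

    if log:
        log(f"[3/4] estimating with methods: {', '.join(cfg.methods)}")
    estimates = build_estimates(data, scen, cfg, log=log)
    _write_csv(estimates[[c for c in estimates.columns]], out / "estimates.csv")

    if log:
        log("[4/4] validating estimates against simulated truth")
    errors, coverage, lengths = _error_tables(estimates, scen)
    _write_csv(errors, out / "errors.csv")
    _write_csv(coverage, out / "coverage_by_scenario.csv")
    _write_csv(lengths, out / "lengths.csv")
    deming = _deming_table(estimates, scen)
    _write_csv(deming, out / "deming_results.csv")
    coef = validation.residual_error_regression(errors, scen)
    _write_csv(coef, out / "regression_coefficients.csv")

    manifest = {
        "package_version": __version__,
        "config": cfg.to_jsonable(),
        "n_datasets_total": int(cfg.n_scenarios * cfg.n_replicates),
        "n_excluded": n_excluded,
        "n_datasets_retained": int(cfg.n_scenarios * cfg.n_replicates - n_excluded),
        "rows": {
            "scenarios": len(scen), "data": len(data), "estimates": len(estimates),
            "errors": len(errors), "coverage_by_scenario": len(coverage),
            "lengths": len(lengths), "deming_results": len(deming),
            "regression_coefficients": len(coef),
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def estimate_single(x: int, n: int, x_se: int, n_se: int, x_sp: int, n_sp: int,
                    level: float = 0.95, methods=ALL_METHODS,
                    mcmc: McmcConfig | None = None) -> pd.DataFrame:
    """Estimate a prevalence from user-supplied counts with every method."""
    model = PrevalenceModel(x, n, x_se, n_se, x_sp, n_sp)
    return model.fit_all(methods=methods, level=level, mcmc=mcmc)
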
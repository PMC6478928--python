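"""End-to-end analysis orchestration.

Glues the stages together the way the study runs them: read the site and
incubation tables and the atmospheric curve, estimate the radiocarbon
turnover time τ₁₄C per site (with its ±1σ interval), the incubation
turnover τᵢ and cumulative DOC (replicate fluxes averaged before the
ratio), apply the QC exclusions, then run the blocked sequential ANOVA in
its permuted orderings (climate table and per-driver table) plus the
Pearson correlation summary, and write everything to an output directory.

Per-site failures (an un-invertible Δ¹⁴C, a saturated trap) degrade to
warnings and NaN rows, never a crash; the run log records every decision.
"""

from __future__ import annotations

import json
import os
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import driver_stats, incubation as inc, site_design
from .atmos14c import read_curve, AtmosphericCurve
from .driver_stats import ModelSpec
from .incubation import IncubationSeries, TrapSpec
from .radiocarbon import RadiocarbonMeasurement
from .turnover14c import (
    ModelConfig,
    NoSolutionError,
    invert_tau,
    tau_uncertainty,
)

__all__ = ["RunConfig", "ResultBundle", "run_full_analysis",
           "estimate_turnover_14c", "estimate_turnover_incubation",
           "TABLE1_ORDERINGS", "table2_orderings"]

#: Climate-table term orderings: the moisture×temperature interaction model
#: with the two main-effect orders swapped.
TABLE1_ORDERINGS = (
    ("BGR", "MI", "TI", "MI:TI", "PCo1", "PCo2"),
    ("BGR", "TI", "MI", "TI:MI", "PCo1", "PCo2"),
)

TABLE2_DRIVERS = ("pH", "clay", "slope", "orientation")


def table2_orderings(driver: str) -> tuple:
    """Three positions of a single driver around the block + climate core."""
    core = ("BGR", "MI", "TI", "MI:TI")
    return (
        (driver,) + core,
        ("BGR", driver, "MI", "TI", "MI:TI"),
        core + (driver,),
    )


@dataclass
class RunConfig:
    """Paths and switches for one full analysis run."""

    sites_path: str
    incubation_path: str
    curve_path: str
    outdir: str
    sampling_year: float = 2014.5
    space: str = "fraction_modern"
    include_doc_in_taui: bool = False
    trap: TrapSpec = field(default_factory=TrapSpec)
    exclusions: dict | None = None  # response → tuple of site ids; None = defaults
    seed: int = 0
    force: bool = False

    def validate(self) -> None:
        for p in (self.sites_path, self.incubation_path, self.curve_path):
            if not os.path.exists(p):
                raise FileNotFoundError(f"required input missing: {p}")


@dataclass
class ResultBundle:
    estimates: pd.DataFrame
    climate_reports: dict      # response → ConsistencyReport
    driver_reports: dict       # (response, driver) → ConsistencyReport
    pearson: pd.DataFrame
    log: list


SITE_COLUMNS = ("site_id", "region", "delta14c_obs", "toc_initial", "dry_mass")
INCUBATION_COLUMNS = ("site_id", "replicate", "day", "co2c_g", "doc_g")


def _require(df: pd.DataFrame, cols, what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{what} table missing required columns: {missing}")


def estimate_turnover_14c(
    sites: pd.DataFrame,
    curve: AtmosphericCurve,
    model_cfg: ModelConfig,
    sampling_year: float,
    log: list | None = None,
) -> pd.DataFrame:
    """Per-site τ₁₄C inversion with ±1σ intervals; failures become NaN rows."""
    rows = []
    for _, site in sites.iterrows():
        meas = RadiocarbonMeasurement(
            delta14c=float(site["delta14c_obs"]),
            sigma=float(site.get("delta14c_sigma", 0.0)),
            sampling_year=sampling_year,
        )
        row = {"site_id": site["site_id"]}
        try:
            sol = invert_tau(meas, curve, model_cfg)
            lo, hi = (
                tau_uncertainty(meas, curve, model_cfg)
                if meas.sigma > 0
                else (sol.tau, sol.tau)
            )
            row.update(tau_14c=sol.tau, tau_14c_lo=lo, tau_14c_hi=hi,
                       n_roots=sol.n_roots_found, branch=sol.branch)
        except NoSolutionError as exc:
            if log is not None:
                log.append(f"site {site['site_id']}: τ14C not invertible ({exc})")
            warnings.warn(f"site {site['site_id']}: {exc}", stacklevel=2)
            row.update(tau_14c=np.nan, tau_14c_lo=np.nan, tau_14c_hi=np.nan,
                       n_roots=0, branch="none")
        rows.append(row)
    return pd.DataFrame(rows)


def estimate_turnover_incubation(
    sites: pd.DataFrame,
    incubation: pd.DataFrame,
    trap: TrapSpec = TrapSpec(),
    include_doc: bool = False,
    log: list | None = None,
) -> pd.DataFrame:
    """Per-site τᵢ and cumulative DOC.

    Replicates are aggregated at the flux level (mean CO₂-C per interval
    and mean DOC per leach across replicates) before the stock/flux ratio.
    Saturated sites keep their DOC but get NaN τᵢ and a flag.
    """
    rows = []
    site_meta = sites.set_index("site_id")
    for sid, grp in incubation.groupby("site_id", sort=False):
        mean_flux = grp.groupby("day", sort=True)[["co2c_g", "doc_g"]].mean()
        days = tuple(int(d) for d in mean_flux.index)
        doc_days = tuple(d for d in days if mean_flux.loc[d, "doc_g"] > 0)
        series = IncubationSeries(
            site_id=sid,
            interval_end_days=days,
            co2c_per_interval=tuple(mean_flux["co2c_g"]),
            leach_days=doc_days if doc_days else inc.LEACH_DAYS,
            doc_per_leach=tuple(mean_flux.loc[list(doc_days), "doc_g"])
            if doc_days
            else (),
            toc_initial=float(site_meta.loc[sid, "toc_initial"]),
            dry_mass=float(site_meta.loc[sid, "dry_mass"]),
        )
        saturated = inc.flag_saturation(series, trap)
        doc = inc.cumulative_doc(series)
        if saturated:
            if log is not None:
                log.append(f"site {sid}: NaOH trap saturated; τᵢ withheld")
            rows.append({"site_id": sid, "tau_i": np.nan, "annual_flux": np.nan,
                         "cum_loss_frac": np.nan, "doc": doc, "saturated": True})
            continue
        result = inc.tau_incubation(series, trap, include_doc=include_doc)
        rows.append({"site_id": sid, "tau_i": result.tau_i,
                     "annual_flux": result.annual_flux,
                     "cum_loss_frac": result.cum_loss_frac,
                     "doc": doc, "saturated": False})
    return pd.DataFrame(rows)


def _ensure_design_columns(sites: pd.DataFrame, log: list) -> pd.DataFrame:
    """Attach climate categories and PCo axes if the table lacks them."""
    out = sites.copy()
    if "mi_cat" not in out.columns or "ti_cat" not in out.columns:
        log.append("climate categories recomputed from site medians")
        out = out.join(site_design.climate_categories(out))
    if "pco1" not in out.columns or "pco2" not in out.columns:
        log.append("PCo1/PCo2 recomputed by PCoA (Gower) over the site table")
        pco1, pco2, _ = site_design.pcoa_soil_landform(out)
        out["pco1"], out["pco2"] = pco1, pco2
    return out


def analyze_study(
    sites: pd.DataFrame,
    incubation: pd.DataFrame,
    curve: AtmosphericCurve,
    sampling_year: float = 2014.5,
    model_cfg: ModelConfig | None = None,
    compute_uncertainty: bool = False,
) -> pd.DataFrame:
    """In-memory estimation stage: per-site τ₁₄C, τᵢ, DOC and QC flags.

    The file-free core of :func:`run_full_analysis`, convenient for
    simulation studies.  Skips the ±1σ re-inversions unless asked.
    """
    log: list[str] = []
    s = sites if compute_uncertainty else sites.assign(delta14c_sigma=0.0)
    t14 = estimate_turnover_14c(
        s, curve, model_cfg or ModelConfig(), sampling_year, log
    )
    ti = estimate_turnover_incubation(sites, incubation, log=log)
    est = sites.merge(t14, on="site_id", how="left").merge(
        ti, on="site_id", how="left"
    )
    return _ensure_design_columns(est, log)


def run_full_analysis(config: RunConfig) -> ResultBundle:
    """Run the whole chain and write results under ``config.outdir``."""
    config.validate()
    if os.path.isdir(config.outdir) and os.listdir(config.outdir):
        if not config.force:
            raise FileExistsError(
                f"output dir {config.outdir} is not empty (use force=True)"
            )
    os.makedirs(config.outdir, exist_ok=True)
    log: list[str] = []

    sites = pd.read_csv(config.sites_path)
    _require(sites, SITE_COLUMNS, "sites")
    incub = pd.read_csv(config.incubation_path)
    _require(incub, INCUBATION_COLUMNS, "incubation")
    curve = read_curve(config.curve_path)
    model_cfg = ModelConfig(space=config.space)
    log.append(f"loaded {len(sites)} sites, curve {curve.start:.1f}–{curve.end:.1f}")

    t14 = estimate_turnover_14c(sites, curve, model_cfg, config.sampling_year, log)
    ti = estimate_turnover_incubation(
        sites, incub, config.trap, config.include_doc_in_taui, log
    )
    est = sites.merge(t14, on="site_id", how="left").merge(
        ti, on="site_id", how="left"
    )
    est = _ensure_design_columns(est, log)

    climate_reports, driver_reports = {}, {}
    for response in ("log_tau14c", "log_taui", "doc"):
        excl = (config.exclusions or {}).get(response)
        specs = [
            ModelSpec(response=response, term_order=order, exclusions=excl)
            for order in TABLE1_ORDERINGS
        ]
        data = est.dropna(subset=["tau_14c"] if response == "log_tau14c"
                          else ["tau_i"] if response == "log_taui" else ["doc"])
        climate_reports[response] = driver_stats.order_consistency(data, specs)
        log.append(f"{response}: climate table on {len(data)} sites "
                   f"(exclusions {driver_stats.DEFAULT_EXCLUSIONS.get(response, ()) if excl is None else excl})")
        for driver in TABLE2_DRIVERS:
            specs2 = [
                ModelSpec(response=response, term_order=order, exclusions=excl)
                for order in table2_orderings(driver)
            ]
            driver_reports[(response, driver)] = driver_stats.order_consistency(
                data, specs2
            )

    pe = est.copy()
    pe["log_tau_14c"] = np.log(pe["tau_14c"])
    pe["log_tau_i"] = np.log(pe["tau_i"])
    pairs = [("tau_14c", "tau_i"), ("log_tau_14c", "log_tau_i"), ("ph", "clay")]
    if "dryness" in pe.columns:
        pe["moisture"] = -pe["dryness"].astype(float)  # water balance sign
        pairs.append(("moisture", "ph"))
    pearson = driver_stats.pearson_summary(pe, pairs)

    _write_outputs(config, est, climate_reports, driver_reports, pearson, log)
    return ResultBundle(
        estimates=est,
        climate_reports=climate_reports,
        driver_reports=driver_reports,
        pearson=pearson,
        log=log,
    )


def _write_outputs(config, est, climate_reports, driver_reports, pearson, log):
    fmt = "%.10g"
    est.to_csv(os.path.join(config.outdir, "estimates.csv"),
               index=False, float_format=fmt)
    pearson.to_csv(os.path.join(config.outdir, "pearson.csv"),
                   index=False, float_format=fmt)
    consistency = {}
    for resp, rep in climate_reports.items():
        rep.verdicts.to_csv(
            os.path.join(config.outdir, f"climate_{resp}.csv"), float_format=fmt
        )
        consistency[resp] = rep.verdicts["verdict"].to_dict()
    rows = []
    for (resp, driver), rep in driver_reports.items():
        verdict = rep.verdicts.loc[driver_stats._canonical(driver), "verdict"]
        codes = [rep.tables[i].loc[
            {driver_stats._canonical(t): t for t in rep.orderings[i]}[
                driver_stats._canonical(driver)], "code"]
            for i in range(len(rep.tables))]
        rows.append({"response": resp, "driver": driver, "verdict": verdict,
                     "codes": "/".join(codes)})
        consistency[f"{resp}:{driver}"] = verdict
    pd.DataFrame(rows).to_csv(
        os.path.join(config.outdir, "driver_table.csv"), index=False
    )
    with open(os.path.join(config.outdir, "consistency.json"), "w") as fh:
        json.dump(consistency, fh, indent=2, sort_keys=True)
    cfg = asdict(config)
    cfg["trap"] = asdict(config.trap)
    with open(os.path.join(config.outdir, "run_config.json"), "w") as fh:
        json.dump(cfg, fh, indent=2, sort_keys=True)
    with open(os.path.join(config.outdir, "run_log.txt"), "w") as fh:
        fh.write("\n".join(log) + "\n")
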
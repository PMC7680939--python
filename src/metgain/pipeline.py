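"""End-to-end pipeline: data -> site filter -> ME classes -> MET fits ->
gains -> biplot.

Stages mirror how an international trial series is analyzed in practice:
(i) every location-year is fitted on its own and locations with line-mean
heritability below a threshold are discarded; (ii) locations are classified
into megaenvironments from climate/management metadata and refined by yield
clustering; (iii) each trial-year is fitted with the MET mixed model within
every requested scope (all locations, each ME); (iv) the 10%
highest-yielding lines are expressed against the long-term and local checks
and regressed on years; (v) the most recent trial gets a site-regression
biplot of country means.

All artifacts are CSV/JSON under the output directory; a run manifest
records the seed, stage log and any FA-to-diagonal fallbacks.  A rerun with
the same configuration and seed reproduces the outputs byte for byte.
"""

from __future__ import annotations

import json
import logging
import os
import time
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .errors import ConfigurationError, ValidationError
from .gains import GainSeries, build_gain_series, estimate_gain
from .io import read_records, write_records
from .me_classify import assignments_frame, classify_sites, refine_by_cluster
from .met import MetSpec, fit_met
from .simulate import SimConfig, simulate_series
from .single_site import filter_sites, fit_single_site
from .sreg import country_mean_table, me_blup_correlations, sreg_decompose

logger = logging.getLogger("metgain")

SCOPES_DEFAULT = ("all", "ME1", "ME4", "ME5")


@dataclass
class PipelineConfig:
    sim: SimConfig | None = None
    input_dir: str | None = None
    h2_threshold: float = 0.05
    scopes: tuple = SCOPES_DEFAULT
    met: MetSpec = field(default_factory=MetSpec)
    references: tuple = ("attila", "local_check")
    hyl_fraction: float = 0.10
    biplot_scaling: str = "standardized"
    min_sites_per_scope: int = 2
    seed: int = 0
    out_dir: str = "metgain_out"

    def validate(self) -> None:
        if (self.sim is None) == (self.input_dir is None):
            raise ConfigurationError(
                "exactly one of sim / input_dir must be given"
            )


def stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed."""
    return (int(master) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; returns the report bundle also written to disk."""
    config.validate()
    out = config.out_dir
    os.makedirs(out, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "stages": [],
        "dropped_sites": [],
        "fa_fallbacks": [],
    }

    def log_stage(name, t0):
        manifest["stages"].append({"stage": name, "seconds": round(time.time() - t0, 3)})

    # ---- stage 1: data -------------------------------------------------
    t0 = time.time()
    if config.sim is not None:
        sim_cfg = config.sim
        sim_cfg.seed = stage_seed(config.seed, "simulate")
        records, meta, truth = simulate_series(sim_cfg)
        write_records(records, meta, out)
    else:
        records, meta = read_records(config.input_dir)
        if meta is None:
            raise ValidationError("site metadata (sites.csv) required for ME classification")
    log_stage("data", t0)

    # ---- stage 2: single-site fits and heritability filter -------------
    t0 = time.time()
    site_rows = []
    kept_by_year: dict[int, list] = {}
    for year, ydf in records.groupby("year"):
        fits = [fit_single_site(sdf) for _, sdf in ydf.groupby("site")]
        kept, dropped = filter_sites(fits, threshold=config.h2_threshold)
        kept_by_year[int(year)] = kept
        for f in fits:
            site_rows.append(
                {"year": int(year), "site": f.site_id, "sigma2_sb": f.sigma2_sb,
                 "sigma2_e": f.sigma2_e, "sigma2_g": f.sigma2_g, "h2": f.h2,
                 "converged": f.converged,
                 "kept": f.site_id in kept}
            )
        for sid, reason in dropped:
            manifest["dropped_sites"].append({"year": int(year), "site": sid, "reason": reason})
            logger.info("year %s: dropped site %s (%s)", year, sid, reason)
    sitefits = pd.DataFrame(site_rows)
    sitefits.to_csv(os.path.join(out, "sitefits.csv"), index=False)
    log_stage("single_site", t0)

    # ---- stage 3: megaenvironment classification -----------------------
    t0 = time.time()
    assignments = classify_sites(meta)
    site_means = records.groupby("site")["yield"].mean()
    assignments = refine_by_cluster(
        assignments, site_means, k=2, meta=meta,
        seed=stage_seed(config.seed, "kmeans"),
    )
    adf = assignments_frame(assignments)
    adf.to_csv(os.path.join(out, "assignments.csv"), index=False)
    me_of_site = dict(zip(adf["site_id"], adf["me"]))
    log_stage("me_classify", t0)

    # ---- stage 4: MET fits per (year x scope) --------------------------
    t0 = time.time()
    fits: dict[tuple, object] = {}
    for year in sorted(kept_by_year):
        for scope in config.scopes:
            sites = [
                s for s in kept_by_year[year]
                if scope == "all" or me_of_site.get(s) == scope
            ]
            if len(sites) < config.min_sites_per_scope:
                logger.info("year %s scope %s: only %d sites, skipped", year, scope, len(sites))
                continue
            sub = records[(records["year"] == year) & records["site"].isin(sites)]
            spec = MetSpec(
                fa_order=config.met.fa_order,
                model_variant=config.met.model_variant,
                max_iter=config.met.max_iter,
                tol=config.met.tol,
                n_starts=config.met.n_starts,
                seed=stage_seed(config.seed, f"met:{year}:{scope}"),
                per_site_residual=config.met.per_site_residual,
                fallback_to_diagonal=config.met.fallback_to_diagonal,
            )
            fit = fit_met(sub, spec)
            fits[(year, scope)] = fit
            if fit.fallback_from_fa:
                manifest["fa_fallbacks"].append({"year": year, "scope": scope})
                logger.info("year %s scope %s: FA did not converge, used diagonal", year, scope)
    if not any(scope == "all" for (_, scope) in fits) and "all" in config.scopes:
        raise ValidationError("no sites retained for the across-locations analysis")
    if not fits:
        raise ValidationError("no sites retained for any requested scope")
    log_stage("met", t0)

    # ---- stage 5: gains ------------------------------------------------
    t0 = time.time()
    gain_rows = []
    series_store: dict[tuple, GainSeries] = {}
    for scope in config.scopes:
        fits_by_year = {yr: f for (yr, sc), f in fits.items() if sc == scope}
        if len(fits_by_year) < 3:
            continue
        for reference in config.references:
            series = build_gain_series(
                fits_by_year, reference, fraction=config.hyl_fraction,
                scope_name=scope,
            )
            est = estimate_gain(series)
            series_store[(scope, reference)] = series
            gain_rows.append(
                {"scope": scope, "reference": reference,
                 "slope_pct_per_year": est.slope_pct_per_year,
                 "slope_kg_per_ha_year": est.slope_kg_per_ha_year,
                 "slope_se": est.slope_se, "p_value": est.p_value,
                 "n_points": est.n_points}
            )
    gains_df = pd.DataFrame(gain_rows)
    gains_df.to_csv(os.path.join(out, "gains.csv"), index=False)
    points = pd.concat(
        [s.points.assign(scope=sc, reference=ref) for (sc, ref), s in series_store.items()],
        ignore_index=True,
    ) if series_store else pd.DataFrame()
    points.to_csv(os.path.join(out, "gain_points.csv"), index=False)
    log_stage("gains", t0)

    # ---- stage 6: ME BLUP correlations and final-trial biplot ----------
    t0 = time.time()
    corr_rows = []
    for year in sorted(kept_by_year):
        by_me = {sc: f for (yr, sc), f in fits.items() if yr == year and sc != "all"}
        if len(by_me) >= 2:
            try:
                r, p = me_blup_correlations(by_me)
            except (ValidationError, ConfigurationError):
                continue
            for a in r.index:
                for b in r.columns:
                    if a < b:
                        corr_rows.append(
                            {"year": year, "me_a": a, "me_b": b,
                             "r": r.loc[a, b], "p": p.loc[a, b]}
                        )
    pd.DataFrame(corr_rows).to_csv(os.path.join(out, "me_correlations.csv"), index=False)

    biplot_summary = None
    last_year = max(kept_by_year)
    fit_me1 = fits.get((last_year, "ME1")) or fits.get((last_year, "all"))
    if fit_me1 is not None and meta is not None:
        countries = meta.set_index("site_id")["country"]
        try:
            table = country_mean_table(fit_me1, countries)
            result = sreg_decompose(table, scaling=config.biplot_scaling)
            result.genotype_scores.to_csv(os.path.join(out, "biplot_genotypes.csv"))
            result.environment_scores.to_csv(os.path.join(out, "biplot_environments.csv"))
            biplot_summary = {
                "year": last_year,
                "pct_explained_12": result.pct_explained_12,
                "vertex_genotypes": result.vertex_genotypes,
                "sector_winners": result.sector_winners,
            }
        except ValidationError as exc:
            logger.info("biplot skipped: %s", exc)
    log_stage("sreg_biplot", t0)

    manifest["biplot"] = biplot_summary
    with open(os.path.join(out, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=str)
    return {
        "gains": gains_df,
        "sitefits": sitefits,
        "assignments": adf,
        "fits": fits,
        "manifest": manifest,
        "biplot": biplot_summary,
    }
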
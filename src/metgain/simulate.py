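"""Synthetic international wheat yield-trial series with known ground truth.

Emulates an ESWYT-like setting: each trial-year distributes a fresh set of
50 entries (entry 1 a site-specific local check, one entry the long-term
check cultivar ``ATTILA``) to a network of locations spread over three
megaenvironments (optimally irrigated ME1, drought-stressed ME4,
heat-stressed ME5).  Each location grows the trial as a resolvable
alpha-lattice: 2 replicates, each partitioned into 5 sub-blocks of 10 plots.

The generative model mirrors the analysis models downstream: site means plus
random replicate, sub-block and plot-residual effects; genotype main effects
with a configurable linear trend across trial-years relative to the
long-term check; and genotype-by-environment effects drawn per trial with a
factor-analytic covariance Lambda Lambda' + Psi across sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError

ATTILA = "ATTILA"
LOCAL_CHECK = "LOCAL_CHECK"
CHECK_LABELS = (ATTILA, LOCAL_CHECK)

RECORD_COLUMNS = ["genotype", "site", "year", "rep", "subblock", "yield"]
META_COLUMNS = [
    "site_id",
    "country",
    "tmin_coolest_quarter",
    "precip_wettest_quarter",
    "irrigated",
    "sowing",
]

# 90th percentile of the standard normal: the local check sits near the top
# decile of the test-line distribution at its site.
_Z90 = 1.2815515655446004

_COUNTRY_POOLS = {
    "ME1": ["Mexico", "India", "Pakistan", "Egypt", "China", "Iran"],
    "ME4": ["Morocco", "Turkey", "Kazakhstan", "Argentina"],
    "ME5": ["Bangladesh", "Sudan", "Nigeria"],
}


@dataclass
class SimConfig:
    """Configuration of one simulated trial series.

    Variance parameters are standard deviations in Mg ha^-1 unless noted.
    ``trend_pct_per_year`` is the true annual genetic gain of newly entered
    test lines, as a percentage of the long-term check's expected yield.
    """

    n_trials: int = 8
    n_genotypes: int = 50
    n_sites_per_me: dict = field(
        default_factory=lambda: {"ME1": 22, "ME4": 9, "ME5": 7}
    )
    n_reps: int = 2
    n_subblocks: int = 5
    trend_pct_per_year: float = 1.67
    site_mean_range: dict = field(
        default_factory=lambda: {
            "ME1": (4.0, 7.0),
            "ME4": (1.5, 3.5),
            "ME5": (2.5, 4.5),
        }
    )
    fa_order: int = 1
    sigma_g: float = 0.2
    loading_scale: float = 0.7
    psi_range: tuple = (0.02, 0.10)
    sigma_rep: float = 0.10
    sigma_sb: float = 0.15
    sigma_e: float = 0.40
    missing_site_rate: float = 0.0
    lowh2_site_rate: float = 0.0
    lowh2_inflation: float = 20.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_genotypes < 3:
            raise ConfigurationError("need at least 3 entries (two checks + a test line)")
        if self.n_genotypes % self.n_subblocks != 0:
            raise ConfigurationError(
                f"{self.n_subblocks} sub-blocks cannot partition "
                f"{self.n_genotypes} entries into equal plots"
            )
        for name in ("sigma_g", "loading_scale", "sigma_rep", "sigma_sb", "sigma_e"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if not (0 <= self.missing_site_rate < 1 and 0 <= self.lowh2_site_rate <= 1):
            raise ConfigurationError("rates must lie in [0, 1)")
        if self.psi_range[0] < 0 or self.psi_range[1] < self.psi_range[0]:
            raise ConfigurationError("psi_range must be 0 <= lo <= hi")
        if self.n_reps < 1 or self.n_trials < 1:
            raise ConfigurationError("n_reps and n_trials must be positive")
        if self.fa_order < 0:
            raise ConfigurationError("fa_order must be >= 0")
        total_sites = sum(self.n_sites_per_me.values())
        if total_sites < 2:
            raise ConfigurationError("need at least 2 sites")


@dataclass
class SimTruth:
    """Ground truth of a simulated series, for recovery checks."""

    true_trend_pct: float
    mu_reference: float
    true_sigma_g: float
    true_sigma_e: float
    true_Sigma_ge: dict  # trial-year -> DataFrame (site x site)
    true_genotype_effects: dict  # trial-year -> Series genotype -> Mg/ha
    lc_effects: dict  # trial-year -> Series site -> Mg/ha
    site_means: pd.Series
    site_me: pd.Series
    lowh2_sites: dict  # trial-year -> list of site ids


def reference_yield(config: SimConfig) -> float:
    """Expected check yield used to scale the trend: site-count-weighted
    mean of the megaenvironment site-mean midpoints."""
    tot, wsum = 0.0, 0
    for me, n in config.n_sites_per_me.items():
        lo, hi = config.site_mean_range[me]
        tot += n * 0.5 * (lo + hi)
        wsum += n
    return tot / wsum


def _make_sites(config: SimConfig, rng: np.random.Generator):
    rows = []
    site_me = {}
    site_means = {}
    idx = 0
    for me, n_sites in sorted(config.n_sites_per_me.items()):
        pool = _COUNTRY_POOLS.get(me, [f"{me}_LAND"])
        lo, hi = config.site_mean_range[me]
        for j in range(n_sites):
            idx += 1
            sid = f"{me}_S{idx:02d}"
            country = pool[j % len(pool)]
            if me == "ME1":
                row = dict(
                    tmin_coolest_quarter=rng.uniform(3.5, 10.5),
                    precip_wettest_quarter=rng.uniform(420.0, 900.0),
                    irrigated=True,
                    sowing="normal",
                )
            elif me == "ME4":
                row = dict(
                    tmin_coolest_quarter=rng.uniform(3.5, 10.5),
                    precip_wettest_quarter=rng.uniform(110.0, 390.0),
                    irrigated=False,
                    sowing="normal",
                )
            else:  # ME5: hot; either genuinely tropical or simulated by late sowing
                if rng.random() < 0.3:
                    row = dict(
                        tmin_coolest_quarter=rng.uniform(5.0, 10.0),
                        precip_wettest_quarter=rng.uniform(420.0, 900.0),
                        irrigated=True,
                        sowing="late",
                    )
                else:
                    row = dict(
                        tmin_coolest_quarter=rng.uniform(11.5, 16.0),
                        precip_wettest_quarter=rng.uniform(450.0, 1200.0),
                        irrigated=bool(rng.random() < 0.5),
                        sowing="normal",
                    )
            rows.append(dict(site_id=sid, country=country, **row))
            site_me[sid] = me
            site_means[sid] = rng.uniform(lo, hi)
    meta = pd.DataFrame(rows, columns=META_COLUMNS)
    return meta, pd.Series(site_me, name="me"), pd.Series(site_means, name="site_mean")


def trial_entry_labels(trial_year: int, n_genotypes: int) -> list[str]:
    """Entry list of one trial: local check, long-term check, fresh test lines."""
    n_test = n_genotypes - 2
    return [LOCAL_CHECK, ATTILA] + [
        f"T{trial_year:02d}G{j:02d}" for j in range(1, n_test + 1)
    ]


def simulate_series(config: SimConfig):
    """Generate a complete trial series.

    Returns ``(records, meta, truth)``: a long-format plot table, the site
    metadata table, and the :class:`SimTruth` ground truth.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    meta, site_me, site_means = _make_sites(config, rng)
    sites = list(site_means.index)
    s = len(sites)
    mu_ref = reference_yield(config)
    plots_per_sb = config.n_genotypes // config.n_subblocks

    truth = SimTruth(
        true_trend_pct=config.trend_pct_per_year,
        mu_reference=mu_ref,
        true_sigma_g=config.sigma_g,
        true_sigma_e=config.sigma_e,
        true_Sigma_ge={},
        true_genotype_effects={},
        lc_effects={},
        site_means=site_means,
        site_me=site_me,
        lowh2_sites={},
    )

    frames = []
    for t in range(1, config.n_trials + 1):
        entries = trial_entry_labels(t, config.n_genotypes)
        n_test = config.n_genotypes - 2
        trend_shift = config.trend_pct_per_year * t * mu_ref / 100.0
        g_eff = pd.Series(0.0, index=entries)
        g_eff[ATTILA] = 0.0
        g_eff[entries[2:]] = rng.normal(trend_shift, config.sigma_g, size=n_test)
        # the local check tracks the top decile of contemporary test lines
        lc = pd.Series(
            trend_shift
            + _Z90 * config.sigma_g
            + rng.normal(0.0, 0.2 * config.sigma_g, size=s),
            index=sites,
        )
        truth.true_genotype_effects[t] = g_eff
        truth.lc_effects[t] = lc

        lam = rng.normal(0.0, config.loading_scale, size=(s, config.fa_order))
        psi = rng.uniform(config.psi_range[0], config.psi_range[1], size=s)
        sigma_ge = lam @ lam.T + np.diag(psi)
        truth.true_Sigma_ge[t] = pd.DataFrame(sigma_ge, index=sites, columns=sites)
        # GE effects per entry: ge_i = Lambda f_i + sqrt(psi) * eps_i
        factors = rng.normal(size=(config.n_genotypes, config.fa_order))
        ge = factors @ lam.T + rng.normal(size=(config.n_genotypes, s)) * np.sqrt(psi)
        ge = pd.DataFrame(ge, index=entries, columns=sites)

        n_low = int(round(config.lowh2_site_rate * s))
        low_sites = list(rng.choice(sites, size=n_low, replace=False)) if n_low else []
        truth.lowh2_sites[t] = low_sites

        missing: set[tuple[str, str]] = set()
        if config.missing_site_rate > 0:
            for sid in sites:
                for gname in entries[2:]:
                    if rng.random() < config.missing_site_rate:
                        missing.add((gname, sid))

        for sid in sites:
            sig_e = config.sigma_e * (
                config.lowh2_inflation if sid in low_sites else 1.0
            )
            present = [g for g in entries if (g, sid) not in missing]
            for rep in range(1, config.n_reps + 1):
                rep_eff = rng.normal(0.0, config.sigma_rep)
                sb_eff = rng.normal(0.0, config.sigma_sb, size=config.n_subblocks)
                layout = rng.permutation(entries)
                for pos, gname in enumerate(layout):
                    sb = pos // plots_per_sb + 1
                    if gname not in present:
                        continue
                    eff = lc[sid] if gname == LOCAL_CHECK else g_eff[gname]
                    y = (
                        site_means[sid]
                        + rep_eff
                        + sb_eff[sb - 1]
                        + eff
                        + ge.at[gname, sid]
                        + rng.normal(0.0, sig_e)
                    )
                    frames.append((gname, sid, t, rep, sb, max(y, 0.01)))

    records = pd.DataFrame(frames, columns=RECORD_COLUMNS)
    return records, meta, truth
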
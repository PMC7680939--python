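"""Genetic-gain estimation from BLUP-predicted yields.

Per trial-year, the 10% highest-yielding lines (HYL) are selected on their
BLUP-predicted yield within the analysis scope (checks excluded); their mean
predicted yield is expressed as a percentage of a check — the long-term
check cultivar or the local check — giving one point per trial.  Ordinary
least squares of those percentages on the trial-year index estimates the
annual gain in % yr^-1; a parallel regression of the absolute HYL-minus-
check difference gives the gain in kg ha^-1 yr^-1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import ConfigurationError, ValidationError
from .met import MetFit, MetSpec, fit_met, predict_yield
from .simulate import ATTILA, LOCAL_CHECK

REFERENCES = ("attila", "local_check")
_REF_LABEL = {"attila": ATTILA, "local_check": LOCAL_CHECK}


@dataclass
class GainSeries:
    """Relative-yield points of one trial series under one reference."""

    points: pd.DataFrame  # columns: trial_year, hyl_mean, check_value, relative_pct
    reference: str  # "attila" | "local_check"
    scope: str = "all"


@dataclass
class GainEstimate:
    """Fitted annual gain."""

    slope_pct_per_year: float
    slope_kg_per_ha_year: float
    intercept: float
    slope_se: float
    p_value: float
    n_points: int
    degenerate: bool = False  # constant series: slope 0, p undefined


def select_hyl(fit: MetFit, fraction: float = 0.10, exclude=(ATTILA, LOCAL_CHECK),
               scope="overall") -> list[str]:
    """The ceil(fraction * n) test lines with highest predicted yield.

    Ties are broken by genotype label, so the selection is deterministic and
    independent of record ordering.
    """
    if not (0.0 < fraction <= 1.0):
        raise ConfigurationError(f"fraction must be in (0, 1], got {fraction}")
    candidates = [g for g in fit.genotypes if g not in set(exclude)]
    n_sel = math.ceil(fraction * len(candidates))
    preds = pd.Series(
        {g: predict_yield(fit, g, scope) for g in candidates}
    )
    order = sorted(preds.index, key=lambda g: (-preds[g], g))
    return order[:n_sel]


def relative_yield(fit: MetFit, hyl, reference: str, scope="overall"):
    """HYL mean, check value, and their ratio in percent.

    ``reference`` is "attila" (the long-term check) or "local_check".
    """
    if reference not in REFERENCES:
        raise ConfigurationError(f"reference must be one of {REFERENCES}")
    ref_label = _REF_LABEL[reference]
    if ref_label not in fit.blup_g.index:
        raise ValidationError(
            f"reference entry {ref_label!r} absent from the fitted trial"
        )
    hyl_mean = float(np.mean([predict_yield(fit, g, scope) for g in hyl]))
    check_value = predict_yield(fit, ref_label, scope)
    if check_value <= 0:
        raise ValidationError(
            f"check prediction {check_value:.3f} <= 0; relative yield undefined"
        )
    return hyl_mean, check_value, 100.0 * hyl_mean / check_value


def build_gain_series(fits_by_year: dict[int, MetFit], reference: str,
                      scope_sites=None, fraction: float = 0.10,
                      scope_name: str = "all") -> GainSeries:
    """One relative-yield point per trial-year from per-trial MET fits.

    ``scope_sites`` maps trial-year to the site subset defining the scope
    (None = all sites of that fit).
    """
    rows = []
    for year in sorted(fits_by_year):
        fit = fits_by_year[year]
        scope = scope_sites[year] if scope_sites is not None else "overall"
        hyl = select_hyl(fit, fraction=fraction, scope=scope)
        hyl_mean, check, rel = relative_yield(fit, hyl, reference, scope)
        rows.append(
            {"trial_year": year, "hyl_mean": hyl_mean, "check_value": check,
             "relative_pct": rel}
        )
    return GainSeries(points=pd.DataFrame(rows), reference=reference,
                      scope=scope_name)


def estimate_gain(series: GainSeries) -> GainEstimate:
    """OLS of relative yield (and absolute difference) on trial-year."""
    pts = series.points
    if len(pts) < 3:
        raise ValidationError(f"need >= 3 points for regression, got {len(pts)}")
    years = pts["trial_year"].to_numpy(dtype=float)
    if np.ptp(years) == 0:
        raise ValidationError("all trial years identical; slope undefined")
    rel = pts["relative_pct"].to_numpy(dtype=float)
    diff_kg = (pts["hyl_mean"] - pts["check_value"]).to_numpy(dtype=float) * 1000.0
    X = sm.add_constant(years)
    if np.allclose(rel, rel[0]):
        return GainEstimate(0.0, 0.0, float(rel[0]), 0.0, float("nan"),
                            len(pts), degenerate=True)
    res = sm.OLS(rel, X).fit()
    res_kg = sm.OLS(diff_kg, X).fit()
    return GainEstimate(
        slope_pct_per_year=float(res.params[1]),
        slope_kg_per_ha_year=float(res_kg.params[1]),
        intercept=float(res.params[0]),
        slope_se=float(res.bse[1]),
        p_value=float(res.pvalues[1]),
        n_points=len(pts),
    )


def compare_variants(records_by_year: dict[int, pd.DataFrame],
                     variants=("fa", "no_gxe"), reference: str = "attila",
                     base_spec: MetSpec | None = None,
                     fraction: float = 0.10) -> pd.DataFrame:
    """Gain estimates under two or more MET model variants, side by side.

    Returns one row per variant plus a "difference" row (first minus second)
    for the leading pair.
    """
    variants = list(variants)
    if len(variants) < 2:
        raise ConfigurationError("need at least two model variants to compare")
    base = base_spec or MetSpec()
    rows = []
    slopes = {}
    for variant in variants:
        spec = MetSpec(
            fa_order=base.fa_order, model_variant=variant, max_iter=base.max_iter,
            tol=base.tol, n_starts=base.n_starts, seed=base.seed,
        )
        fits = {yr: fit_met(rec, spec) for yr, rec in records_by_year.items()}
        est = estimate_gain(
            build_gain_series(fits, reference, fraction=fraction)
        )
        slopes[variant] = est
        rows.append(
            {"variant": variant, "slope_pct_per_year": est.slope_pct_per_year,
             "slope_kg_per_ha_year": est.slope_kg_per_ha_year,
             "slope_se": est.slope_se, "p_value": est.p_value,
             "n_points": est.n_points}
        )
    a, b = variants[0], variants[1]
    rows.append(
        {"variant": f"{a}-minus-{b}",
         "slope_pct_per_year": slopes[a].slope_pct_per_year - slopes[b].slope_pct_per_year,
         "slope_kg_per_ha_year": slopes[a].slope_kg_per_ha_year - slopes[b].slope_kg_per_ha_year,
         "slope_se": float("nan"), "p_value": float("nan"),
         "n_points": slopes[a].n_points}
    )
    return pd.DataFrame(rows)
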
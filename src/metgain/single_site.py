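"""Single-location analysis of one alpha-lattice trial.

The model for plot yield is  y = mu + rep + subblock(rep) + genotype + e,
with replicates and genotypes fixed and sub-blocks within replicates random.
Variance components (sigma2_sb, sigma2_e) are estimated by REML; genotype
adjusted means are the generalized-least-squares fixed-effect solutions,
averaged over replicates.

Heritability needs a genotype variance, so a companion refit with genotype
random (replicates still fixed) supplies sigma2_g; line-mean heritability is
h2 = sigma2_g / (sigma2_g + sigma2_e / r) with r the average number of
replications per entry.  Sites with h2 below a threshold (default 0.05) are
discarded from combined analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from ._reml import BlockSpec, MarginalModel, indicator_matrix
from .errors import ValidationError

_LOG_BOUNDS = (-23.0, 6.0)
_ZERO_TOL = 1e-8


@dataclass
class SiteFit:
    """REML fit of one location."""

    site_id: str
    genotype_estimates: pd.Series  # adjusted means, Mg/ha
    replicate_effects: pd.Series
    sigma2_sb: float
    sigma2_e: float
    sigma2_g: float
    h2: float
    converged: bool
    n_reps: float = 2.0
    h2_warning: bool = False
    reml_loglik: float = float("nan")


def _design(records: pd.DataFrame, genotype_fixed: bool):
    """Fixed design and random-effect incidence for one site."""
    geno = pd.Categorical(records["genotype"])
    rep = pd.Categorical(records["rep"])
    sb = pd.Categorical(
        records["rep"].astype(str) + ":" + records["subblock"].astype(str)
    )
    n = len(records)
    cols = [np.ones(n)]
    for lev in rep.categories[1:]:
        cols.append((rep == lev).astype(float))
    if genotype_fixed:
        for lev in geno.categories[1:]:
            cols.append((np.asarray(geno) == lev).astype(float))
    X = np.column_stack(cols)
    Z_sb = indicator_matrix(sb.codes, len(sb.categories))
    blocks = [Z_sb]
    if not genotype_fixed:
        blocks.insert(0, indicator_matrix(geno.codes, len(geno.categories)))
    return X, blocks, geno, rep


def _reml_fit(model: MarginalModel, n_var: int, start: np.ndarray):
    """Maximize the restricted likelihood over log-variances.

    Parameter vector: log of (block variances..., residual variance).
    """

    def neg(params):
        vs = np.exp(params)
        blocks = [
            BlockSpec("diag", values=np.full(sl.stop - sl.start, v))
            for v, sl in zip(vs[:-1], model.block_slices)
        ]
        return -model.reml_loglik(blocks, vs[-1])

    res = minimize(
        neg,
        start,
        method="L-BFGS-B",
        bounds=[_LOG_BOUNDS] * n_var,
        options={"maxiter": 200},
    )
    return np.exp(res.x), -res.fun, bool(res.success)


def site_reml_loglik(records: pd.DataFrame, sigma2_sb: float, sigma2_e: float,
                     sigma2_g: float | None = None) -> float:
    """Restricted log-likelihood of the single-site model at given variances.

    With ``sigma2_g`` None, genotypes are fixed effects (the estimation
    model for adjusted means); otherwise genotypes are random with that
    variance (the heritability variant).
    """
    genotype_fixed = sigma2_g is None
    X, blocks, _, _ = _design(records, genotype_fixed=genotype_fixed)
    model = MarginalModel(records["yield"].to_numpy(dtype=float), X, blocks)
    variances = ([] if genotype_fixed else [sigma2_g]) + [sigma2_sb]
    specs = [
        BlockSpec("diag", values=np.full(b.shape[1], max(v, 1e-12)))
        for v, b in zip(variances, blocks)
    ]
    return model.reml_loglik(specs, sigma2_e)


def fit_single_site(records: pd.DataFrame) -> SiteFit:
    """Fit the single-location model to the plots of one site."""
    sites = records["site"].unique()
    if len(sites) != 1:
        raise ValidationError(f"expected one site, got {list(sites)}")
    if records["rep"].nunique() < 2:
        raise ValidationError("need at least 2 replicates")
    if records["genotype"].nunique() < 2:
        raise ValidationError("need at least 2 genotypes")
    counts = records.groupby("rep").size()
    if (counts == 0).any():
        raise ValidationError("replicate with zero plots")

    y = records["yield"].to_numpy(dtype=float)
    var0 = max(np.var(y), 1e-4)
    start = np.log([0.1 * var0 + 1e-6, 0.5 * var0])

    # variant 1: genotype fixed -> adjusted means, sigma2_sb, sigma2_e
    Xf, blocks_f, geno, rep = _design(records, genotype_fixed=True)
    model_f = MarginalModel(y, Xf, blocks_f)
    (s2_sb, s2_e), loglik, ok_f = _reml_fit(model_f, 2, start)
    beta, _, _ = model_f.solve(
        [BlockSpec("diag", values=np.full(b.shape[1], max(s2_sb, 1e-10)))
         for b in blocks_f],
        s2_e,
    )
    n_rep_lv = len(rep.categories)
    rep_eff = np.concatenate([[0.0], beta[1 : n_rep_lv]])
    gen_eff = np.concatenate([[0.0], beta[n_rep_lv:]])
    base = beta[0] + rep_eff.mean()
    adjusted = pd.Series(base + gen_eff, index=list(geno.categories))
    replicate_effects = pd.Series(rep_eff - rep_eff.mean(), index=list(rep.categories))

    # variant 2: genotype random -> sigma2_g for heritability
    Xr, blocks_r, _, _ = _design(records, genotype_fixed=False)
    model_r = MarginalModel(y, Xr, blocks_r)
    start_r = np.log([0.3 * var0 + 1e-6, 0.1 * var0 + 1e-6, 0.5 * var0])
    (s2_g, s2_sb_r, s2_e_r), _, ok_r = _reml_fit(model_r, 3, start_r)

    r_bar = float(records.groupby("genotype").size().mean())
    fit = SiteFit(
        site_id=str(sites[0]),
        genotype_estimates=adjusted,
        replicate_effects=replicate_effects,
        sigma2_sb=0.0 if s2_sb < _ZERO_TOL else float(s2_sb),
        sigma2_e=float(max(s2_e, 1e-10)),
        sigma2_g=0.0 if s2_g < _ZERO_TOL else float(s2_g),
        h2=0.0,
        converged=bool(ok_f and ok_r),
        n_reps=r_bar,
        reml_loglik=float(loglik),
    )
    fit.h2 = estimate_heritability(fit, sigma2_e=float(max(s2_e_r, 1e-10)))
    return fit


def estimate_heritability(fit: SiteFit, sigma2_e: float | None = None) -> float:
    """Line-mean heritability h2 = s2_g / (s2_g + s2_e / r), clipped to [0, 1].

    ``sigma2_e`` defaults to the fit's residual variance; the random-genotype
    refit passes its own residual estimate.
    """
    s2_e = fit.sigma2_e if sigma2_e is None else sigma2_e
    denom = fit.sigma2_g + s2_e / fit.n_reps
    if denom <= _ZERO_TOL:
        fit.h2_warning = True
        return 0.0
    return float(np.clip(fit.sigma2_g / denom, 0.0, 1.0))


def filter_sites(fits, threshold: float = 0.05):
    """Partition site fits into kept and dropped (with reason codes).

    Returns ``(kept_site_ids, dropped)`` where dropped is a list of
    ``(site_id, reason)`` with reason in {"low_h2", "not_converged"}.
    """
    kept, dropped = [], []
    for fit in fits:
        if not fit.converged:
            dropped.append((fit.site_id, "not_converged"))
        elif fit.h2 < threshold:
            dropped.append((fit.site_id, "low_h2"))
        else:
            kept.append(fit.site_id)
    return kept, dropped
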
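"""Site-regression (SREG/GGE) analysis of genotype x environment tables.

The genotype x environment table of mean yields is centered by environment
(and optionally standardized), then decomposed by SVD.  The first two
components give the biplot: genotype and environment scores under symmetric
singular-value partitioning (each side scaled by sqrt(sigma_i)).  The
convex-hull polygon of genotype scores and the perpendicular sectors of its
edges identify the winning genotype in each environment sector
("which-won-where").  Environment correlations are plain Pearson
correlations of genotype means between environment pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import ConvexHull, QhullError

from .errors import ConfigurationError, ValidationError
from .met import MetFit, predict_yield


@dataclass
class GxETable:
    """Complete genotype x environment matrix of mean yields (Mg/ha)."""

    values: pd.DataFrame  # genotypes x environments

    def __post_init__(self):
        v = self.values
        if v.shape[0] < 3 or v.shape[1] < 2:
            raise ValidationError("need >= 3 genotypes and >= 2 environments")
        if v.isna().all(axis=1).any() or v.isna().all(axis=0).any():
            raise ValidationError("fully missing row or column in GxE table")

    @property
    def genotype_labels(self):
        return list(self.values.index)

    @property
    def environment_labels(self):
        return list(self.values.columns)


@dataclass
class BiplotResult:
    genotype_scores: pd.DataFrame  # g x 2
    environment_scores: pd.DataFrame  # e x 2
    singular_values: np.ndarray
    pct_explained_12: float
    vertex_genotypes: list
    sector_winners: dict  # environment -> genotype
    scaling: str = "standardized"


def sreg_decompose(table: GxETable, scaling: str = "standardized",
                   partitioning: str = "symmetric") -> BiplotResult:
    """SVD of the environment-centered (optionally standardized) table.

    ``partitioning`` controls how the singular values are split between the
    two score sets: "symmetric" (sqrt on both sides, the biplot default),
    "genotype" (genotype-metric: singular values on the genotype side), or
    "environment" (environment-metric).  Axis signs are fixed
    deterministically, so output does not depend on the linear-algebra
    backend.
    """
    if scaling not in ("centered", "standardized"):
        raise ConfigurationError(f"unknown scaling {scaling!r}")
    if partitioning not in ("symmetric", "genotype", "environment"):
        raise ConfigurationError(f"unknown partitioning {partitioning!r}")
    M = table.values
    if M.isna().any().any():
        raise ValidationError("GxE table has missing cells; fill or drop rows first")
    Z = M - M.mean(axis=0)
    if scaling == "standardized":
        sd = M.std(axis=0, ddof=1)
        zero = sd.index[sd <= 0]
        if len(zero):
            raise ValidationError(
                f"zero-variance environment(s) under standardization: {list(zero)}"
            )
        Z = Z / sd
    U, svals, Vt = np.linalg.svd(Z.to_numpy(), full_matrices=False)
    total = float(np.sum(svals**2))
    pct12 = 100.0 * float(np.sum(svals[:2] ** 2)) / total
    if partitioning == "symmetric":
        dg = de = np.sqrt(svals[:2])
    elif partitioning == "genotype":
        dg, de = svals[:2], np.ones(2)
    else:
        dg, de = np.ones(2), svals[:2]
    gscore = U[:, :2] * dg
    escore = Vt[:2].T * de
    # deterministic orientation: environment scores sum >= 0 per axis
    # (genotype scores are centered, so their mean cannot orient the axis);
    # near-zero sums fall back to the sign of the largest-magnitude score
    for axis in range(2):
        ssum = escore[:, axis].sum()
        if abs(ssum) < 1e-9 * (np.abs(escore[:, axis]).max() + 1e-300):
            ssum = escore[np.argmax(np.abs(escore[:, axis])), axis]
        if ssum < 0:
            gscore[:, axis] = -gscore[:, axis]
            escore[:, axis] = -escore[:, axis]
    gdf = pd.DataFrame(gscore, index=M.index, columns=["PC1", "PC2"])
    edf = pd.DataFrame(escore, index=M.columns, columns=["PC1", "PC2"])
    result = BiplotResult(
        genotype_scores=gdf,
        environment_scores=edf,
        singular_values=svals,
        pct_explained_12=pct12,
        vertex_genotypes=[],
        sector_winners={},
        scaling=scaling,
    )
    try:
        vertices, winners = which_won_where(result)
        result.vertex_genotypes = vertices
        result.sector_winners = winners
    except ValidationError:
        pass  # degenerate geometry; polygon left empty
    return result


def which_won_where(result: BiplotResult):
    """Polygon vertices and per-environment sector winners.

    The winner of an environment's sector is the hull-vertex genotype whose
    score has the largest inner product with the environment's score — the
    genotype with the highest reconstructed rank-2 yield there.
    """
    G = result.genotype_scores.to_numpy()
    labels = list(result.genotype_scores.index)
    if len(labels) < 3:
        raise ValidationError("need >= 3 genotypes for the polygon")
    try:
        hull = ConvexHull(G)
    except QhullError as exc:
        raise ValidationError(f"degenerate genotype scores (collinear?): {exc}") from None
    vertex_idx = list(hull.vertices)
    vertices = [labels[i] for i in vertex_idx]
    winners = {}
    for env, escore in result.environment_scores.iterrows():
        e = escore.to_numpy()
        proj = [float(G[i] @ e) for i in vertex_idx]
        winners[env] = vertices[int(np.argmax(proj))]
    return vertices, winners


def environment_correlations(table: GxETable, min_common: int = 3):
    """Pairwise Pearson correlations of genotype means between environments.

    Pairs with fewer than ``min_common`` commonly observed genotypes are
    reported as NaN.  Returns (correlation matrix, p-value matrix); p-values
    are two-sided from the t distribution with n-2 degrees of freedom.
    """
    envs = table.environment_labels
    r = pd.DataFrame(np.eye(len(envs)), index=envs, columns=envs)
    p = pd.DataFrame(np.zeros((len(envs), len(envs))), index=envs, columns=envs)
    for i, a in enumerate(envs):
        for j in range(i + 1, len(envs)):
            b = envs[j]
            pair = table.values[[a, b]].dropna()
            if len(pair) < min_common:
                r.loc[a, b] = r.loc[b, a] = np.nan
                p.loc[a, b] = p.loc[b, a] = np.nan
                continue
            rr, pp = stats.pearsonr(pair[a], pair[b])
            r.loc[a, b] = r.loc[b, a] = rr
            p.loc[a, b] = p.loc[b, a] = pp
    return r, p


def country_mean_table(fit: MetFit, site_countries: pd.Series) -> GxETable:
    """Genotype x country table of mean BLUP-adjusted yields.

    Country means are unweighted means of the per-site predictions over that
    country's fitted sites.
    """
    groups: dict[str, list] = {}
    for site in fit.sites:
        if site in site_countries.index:
            groups.setdefault(str(site_countries[site]), []).append(site)
    if len(groups) < 2:
        raise ValidationError("need sites from >= 2 countries")
    cols = {}
    for country, sites in sorted(groups.items()):
        cols[country] = [
            predict_yield(fit, g, sites) for g in fit.genotypes
        ]
    return GxETable(pd.DataFrame(cols, index=fit.genotypes))


def me_blup_correlations(fits_by_me: dict[str, MetFit], min_common: int = 3):
    """Correlations of genotype BLUP yields between megaenvironments.

    Each fit contributes one column of scope-level predicted yields; the
    genotype sets must overlap.  Delegates to the environment-correlation
    machinery.
    """
    if len(fits_by_me) < 2:
        raise ConfigurationError("need fits for >= 2 megaenvironments")
    cols = {}
    for me, fit in sorted(fits_by_me.items()):
        cols[me] = pd.Series(
            {g: predict_yield(fit, g, "overall") for g in fit.genotypes}
        )
    df = pd.DataFrame(cols)
    common = df.dropna()
    if len(common) < min_common:
        raise ValidationError("megaenvironment fits share too few genotypes")
    return environment_correlations(GxETable(df), min_common=min_common)
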
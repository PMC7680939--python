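"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's evaluation strategy: the restricted
likelihood is computed as the log-density of an orthonormal basis of error
contrasts applied to the fully assembled dense marginal covariance.
"""

import numpy as np
import pandas as pd
from scipy.linalg import null_space
from scipy.stats import multivariate_normal


def dense_restricted_loglik(y, X, V):
    """log N(K'y; 0, K'VK) for orthonormal K spanning null(X')."""
    K = null_space(np.asarray(X, dtype=float).T)
    z = K.T @ np.asarray(y, dtype=float)
    return float(
        multivariate_normal.logpdf(z, mean=np.zeros(len(z)), cov=K.T @ V @ K)
    )


def met_dense_V(records, sigma2_g, rep_variances, sigma_ge, sigma2_e):
    """Marginal covariance of the MET model assembled element by element."""
    sites = sorted(records["site"].unique())
    site_idx = {s: i for i, s in enumerate(sites)}
    sc = records["site"].map(site_idx).to_numpy()
    gmap = {g: i for i, g in enumerate(sorted(records["genotype"].unique()))}
    gc = records["genotype"].map(gmap).to_numpy()
    rc = records["rep"].to_numpy()
    n = len(records)
    V = np.zeros((n, n))
    for a in range(n):
        for b in range(n):
            v = 0.0
            if sc[a] == sc[b] and rc[a] == rc[b]:
                v += rep_variances[sc[a]]
            if gc[a] == gc[b]:
                v += sigma2_g
                if sigma_ge is not None:
                    v += sigma_ge[sc[a], sc[b]]
            if a == b:
                v += sigma2_e
            V[a, b] = v
    return V


def met_site_design(records):
    """Site-indicator fixed-effect design matrix."""
    sites = sorted(records["site"].unique())
    site_idx = {s: i for i, s in enumerate(sites)}
    X = np.zeros((len(records), len(sites)))
    X[np.arange(len(records)), records["site"].map(site_idx)] = 1.0
    return X


def single_site_design(records, genotype_fixed=True):
    """Intercept + drop-first replicate (+ genotype) dummies, matching a
    fixed-effects model with those factors."""
    rep = pd.Categorical(records["rep"])
    geno = pd.Categorical(records["genotype"])
    cols = [np.ones(len(records))]
    for lev in rep.categories[1:]:
        cols.append((np.asarray(rep) == lev).astype(float))
    if genotype_fixed:
        for lev in geno.categories[1:]:
            cols.append((np.asarray(geno) == lev).astype(float))
    return np.column_stack(cols)


def single_site_dense_V(records, sigma2_sb, sigma2_e, sigma2_g=None):
    """Marginal covariance of the single-site model (sub-blocks random
    within replicate; genotypes random iff sigma2_g given)."""
    sb = (records["rep"].astype(str) + ":" + records["subblock"].astype(str)).to_numpy()
    geno = records["genotype"].to_numpy()
    n = len(records)
    V = sigma2_e * np.eye(n)
    for a in range(n):
        for b in range(n):
            if sb[a] == sb[b]:
                V[a, b] += sigma2_sb
            if sigma2_g is not None and geno[a] == geno[b]:
                V[a, b] += sigma2_g
    return V
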
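"""Multi-environment trial (MET) mixed model with factor-analytic G x E.

Model for plot yield across s sites and r replicates per site:

    y = X b + Z_r u_r + Z_g u_g + Z_ge u_ge + e

with site means b fixed; replicate-within-site effects u_r ~ N(0, sigma2_r_j)
(heterogeneous across sites); genotype main effects u_g ~ N(0, sigma2_g I);
interaction effects u_ge with, per genotype, an s x s across-site covariance
Sigma_ge; and residuals e ~ N(0, sigma2_e I).  Sigma_ge is structured as

    fa        Sigma_ge = Lambda Lambda' + Psi      (rank-k loadings, diag Psi)
    diagonal  Sigma_ge = diag(psi_1..psi_s)        (site-specific, no covariance)
    cs        Sigma_ge = psi I                     (one shared interaction variance)
    no_gxe    the u_ge term is dropped entirely

Variance parameters are estimated by REML (L-BFGS-B on log-variances and raw
loadings, multi-start).  For complete balanced data the restricted likelihood
factorises exactly into (i) within-cell genotype contrasts, whose covariance
is the small s*r x s*r matrix C = sigma2_g J + Sigma_ge (x) J_r + sigma2_e I,
and (ii) replicate-mean contrasts, from which the per-site replicate
variances profile out in closed form.  This fast path has analytic gradients
and agrees with the dense evaluation to numerical precision; unbalanced data
fall back to a Woodbury evaluation of the full marginal covariance.

Lambda is identified by zeroing its strict upper triangle; every reported
quantity depends on Lambda only through Sigma_ge.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize

from ._reml import LOG2PI, PENALIZED_LOGLIK, BlockSpec, MarginalModel, indicator_matrix
from .errors import ConfigurationError, ValidationError

_LOG_LB, _LOG_UB = -23.0, 6.0
_LAM_BOUND = 10.0

VARIANTS = ("fa", "diagonal", "cs", "no_gxe")


@dataclass
class MetSpec:
    """Fitting options for the MET model."""

    fa_order: int = 1
    model_variant: str = "fa"
    max_iter: int = 300
    tol: float = 1e-8
    n_starts: int = 5
    seed: int = 0
    per_site_residual: bool = False
    fallback_to_diagonal: bool = True

    def validate(self, n_sites: int) -> None:
        if self.model_variant not in VARIANTS:
            raise ConfigurationError(f"unknown model variant {self.model_variant!r}")
        if self.model_variant == "fa" and self.fa_order >= n_sites:
            raise ConfigurationError(
                f"fa_order={self.fa_order} must be < number of sites ({n_sites})"
            )
        if self.fa_order < 0 or self.tol <= 0:
            raise ConfigurationError("fa_order >= 0 and tol > 0 required")


@dataclass
class MetParams:
    """One point in MET variance-parameter space."""

    sites: list
    variant: str
    sigma2_g: float
    rep_variances: np.ndarray  # per site
    loadings: np.ndarray  # s x k (k may be 0)
    specific_vars: np.ndarray  # per site
    sigma2_e: float

    @property
    def sigma_ge(self) -> np.ndarray:
        s = len(self.sites)
        if self.variant == "no_gxe":
            return np.zeros((s, s))
        return self.loadings @ self.loadings.T + np.diag(self.specific_vars)


@dataclass
class MetFit:
    """REML solution of the MET model."""

    site_means: pd.Series
    rep_variances: pd.Series
    sigma2_g: float
    loadings: pd.DataFrame
    specific_vars: pd.Series
    Sigma_ge: pd.DataFrame
    sigma2_e: float
    blup_g: pd.Series
    blup_ge: pd.DataFrame  # genotype x site (zeros for no_gxe)
    reml_loglik: float
    converged: bool
    variant: str
    n_params: int
    fallback_from_fa: bool = False
    site_resid_vars: pd.Series | None = None
    spec: MetSpec | None = None

    @property
    def sites(self) -> list:
        return list(self.site_means.index)

    @property
    def genotypes(self) -> list:
        return list(self.blup_g.index)

    @property
    def aic(self) -> float:
        return -2.0 * self.reml_loglik + 2.0 * self.n_params

    def ge_correlations(self) -> pd.DataFrame:
        """Implied between-site correlations of G x E effects."""
        sd = np.sqrt(np.diag(self.Sigma_ge.to_numpy()))
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = self.Sigma_ge.to_numpy() / np.outer(sd, sd)
        return pd.DataFrame(corr, index=self.sites, columns=self.sites)


# ---------------------------------------------------------------------------
# data preparation
# ---------------------------------------------------------------------------


class _MetData:
    """Categorical coding and (if possible) balanced sufficient statistics."""

    def __init__(self, records: pd.DataFrame):
        if records["site"].nunique() < 2:
            raise ValidationError("MET analysis needs records from >= 2 sites")
        self.records = records
        self.geno = pd.Categorical(records["genotype"])
        self.site = pd.Categorical(records["site"])
        self.genotypes = list(self.geno.categories)
        self.sites = list(self.site.categories)
        self.g = len(self.genotypes)
        self.s = len(self.sites)
        self.y = records["yield"].to_numpy(dtype=float)
        self.rep_labels = np.sort(records["rep"].unique())
        self.R = len(self.rep_labels)
        self.balanced_stats = self._try_balance()
        self._model: MarginalModel | None = None

    def _try_balance(self):
        g, s, R = self.g, self.s, self.R
        if R < 2 or len(self.records) != g * s * R:
            return None
        rep_code = pd.Categorical(
            self.records["rep"], categories=self.rep_labels
        ).codes.astype(np.int64)
        gc = np.asarray(self.geno.codes, dtype=np.int64)
        sc = np.asarray(self.site.codes, dtype=np.int64)
        idx = (gc * s + sc) * R + rep_code
        if np.bincount(idx, minlength=g * s * R).max() != 1:
            return None
        Y = np.empty(g * s * R)
        Y[idx] = self.y
        Y = Y.reshape(g, s, R)
        m_jr = Y.mean(axis=0)  # site-rep means
        dev = (Y - m_jr[None]).reshape(g, s * R)
        S_A = dev.T @ dev
        SS = ((m_jr - m_jr.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        return {"S_A": S_A, "SS": SS, "m_jr": m_jr}

    @property
    def model(self) -> MarginalModel:
        """Dense/Woodbury marginal model (built on demand)."""
        if self._model is None:
            site_codes = np.asarray(self.site.codes, dtype=np.int64)
            X = np.asarray(indicator_matrix(site_codes, self.s).todense())
            rep_code = pd.Categorical(
                self.records["rep"], categories=self.rep_labels
            ).codes.astype(np.int64)
            site_rep = site_codes * self.R + rep_code
            Z_r = indicator_matrix(site_rep, self.s * self.R)
            geno_codes = np.asarray(self.geno.codes, dtype=np.int64)
            Z_g = indicator_matrix(geno_codes, self.g)
            ge_col = geno_codes * self.s + site_codes
            Z_ge = indicator_matrix(ge_col, self.g * self.s)
            self._model = MarginalModel(self.y, X, [Z_r, Z_g, Z_ge])
            self._model_no_ge = MarginalModel(self.y, X, [Z_r, Z_g])
        return self._model

    def _blocks(self, params: MetParams):
        rep_vals = np.repeat(np.maximum(params.rep_variances, 1e-12), self.R)
        blocks = [
            BlockSpec("diag", values=rep_vals),
            BlockSpec("diag", values=np.full(self.g, max(params.sigma2_g, 1e-12))),
        ]
        if params.variant != "no_gxe":
            blocks.append(BlockSpec("kron", sigma=params.sigma_ge, copies=self.g))
        return blocks

    def site_weights(self, site_vars: np.ndarray) -> np.ndarray:
        """Per-observation residual-variance weights from per-site variances."""
        return site_vars[np.asarray(self.site.codes)]

    def general_loglik(self, params: MetParams, resid_weights=None) -> float:
        model = self.model
        blocks = self._blocks(params)
        if params.variant == "no_gxe":
            return self._model_no_ge.reml_loglik(blocks, params.sigma2_e, resid_weights)
        return model.reml_loglik(blocks, params.sigma2_e, resid_weights)

    def general_solve(self, params: MetParams, resid_weights=None):
        model = self.model
        blocks = self._blocks(params)
        use_ge = params.variant != "no_gxe"
        if use_ge:
            beta, blups, loglik = model.solve(blocks, params.sigma2_e, resid_weights)
        else:
            beta, blups, loglik = self._model_no_ge.solve(
                blocks, params.sigma2_e, resid_weights
            )
        blup_g = pd.Series(blups[1], index=self.genotypes)
        if use_ge:
            blup_ge = pd.DataFrame(
                blups[2].reshape(self.g, self.s),
                index=self.genotypes,
                columns=self.sites,
            )
        else:
            blup_ge = pd.DataFrame(0.0, index=self.genotypes, columns=self.sites)
        return pd.Series(beta, index=self.sites), blup_g, blup_ge, loglik


# ---------------------------------------------------------------------------
# balanced fast path: restricted likelihood + analytic gradient
# ---------------------------------------------------------------------------


def _fast_loglik(data: _MetData, sigma2_g, sigma_ge, sigma2_e,
                 rep_variances=None, want_grad=False):
    """Profile restricted likelihood of the balanced MET model.

    With ``rep_variances=None`` the per-site replicate variances are profiled
    out in closed form; otherwise they are held at the given values (used
    only for cross-validation against the general path).
    """
    st = data.balanced_stats
    g, s, R = data.g, data.s, data.R
    m = s * R
    C = sigma2_g + np.kron(sigma_ge, np.ones((R, R)))
    C = C + sigma2_e * np.eye(m)
    try:
        cF = cho_factor(C)
    except np.linalg.LinAlgError:
        return (PENALIZED_LOGLIK, None) if want_grad else PENALIZED_LOGLIK
    logdetC = 2.0 * float(np.sum(np.log(np.diag(cF[0]))))
    A = cho_solve(cF, np.eye(m))
    tr_CinvS = float(np.sum(A * st["S_A"]))
    lA = -0.5 * ((g - 1) * (m * LOG2PI + logdetC) + tr_CinvS)
    if rep_variances is None:
        if R < 2:
            raise ValidationError("balanced path requires >= 2 replicates")
        v_free = g * st["SS"] / (R - 1)
        v = np.maximum(v_free, sigma2_e)
        clamped = v_free <= sigma2_e
    else:
        v = g * np.asarray(rep_variances) + sigma2_e
        clamped = np.zeros(s, dtype=bool)
    lB = -0.5 * float(np.sum((R - 1) * np.log(2.0 * np.pi * v) + g * st["SS"] / v))
    ll = lA + lB
    if not want_grad:
        return ll if np.isfinite(ll) else PENALIZED_LOGLIK
    B = A @ st["S_A"] @ A
    G = (g - 1) * A - B
    Gbar = G.reshape(s, R, s, R).sum(axis=(1, 3))
    d_s2g = -0.5 * float(G.sum())
    d_s2e = -0.5 * float(np.trace(G))
    if clamped.any():
        vc = v[clamped]
        d_s2e += float(
            np.sum(-0.5 * ((R - 1) / vc - g * st["SS"][clamped] / vc**2))
        )
    return ll, (d_s2g, Gbar, d_s2e)


def _profiled_rep_variances(data: _MetData, sigma2_e: float) -> np.ndarray:
    st = data.balanced_stats
    g, R = data.g, data.R
    v = g * st["SS"] / (R - 1)
    return np.maximum(v - sigma2_e, 0.0) / g


# ---------------------------------------------------------------------------
# parameter packing
# ---------------------------------------------------------------------------


def _tri_indices(s: int, k: int):
    return [(a, c) for a in range(s) for c in range(k) if c <= a]


class _Packer:
    def __init__(self, s: int, k: int, variant: str):
        self.s, self.k, self.variant = s, k, variant
        self.tri = _tri_indices(s, k) if variant == "fa" else []
        if variant == "fa":
            self.n = 1 + len(self.tri) + s + 1
        elif variant == "diagonal":
            self.n = 1 + s + 1
        elif variant == "cs":
            self.n = 1 + 1 + 1
        else:
            self.n = 2

    def bounds(self):
        b = [(_LOG_LB, _LOG_UB)]
        b += [(-_LAM_BOUND, _LAM_BOUND)] * len(self.tri)
        if self.variant == "fa":
            b += [(_LOG_LB, _LOG_UB)] * self.s
        elif self.variant == "diagonal":
            b += [(_LOG_LB, _LOG_UB)] * self.s
        elif self.variant == "cs":
            b += [(_LOG_LB, _LOG_UB)]
        b += [(_LOG_LB, _LOG_UB)]
        return b

    def pack(self, sigma2_g, lam, psi, sigma2_e):
        parts = [math.log(max(sigma2_g, 1e-10))]
        if self.variant == "fa":
            parts += [lam[a, c] for a, c in self.tri]
            parts += list(np.log(np.maximum(psi, 1e-10)))
        elif self.variant == "diagonal":
            parts += list(np.log(np.maximum(psi, 1e-10)))
        elif self.variant == "cs":
            parts.append(math.log(max(float(np.mean(psi)), 1e-10)))
        parts.append(math.log(max(sigma2_e, 1e-10)))
        return np.clip(np.asarray(parts), _LOG_LB, _LOG_UB)

    def unpack(self, theta):
        s, k = self.s, self.k
        sigma2_g = math.exp(theta[0])
        i = 1
        lam = np.zeros((s, k if self.variant == "fa" else 0))
        if self.variant == "fa":
            for a, c in self.tri:
                lam[a, c] = theta[i]
                i += 1
            psi = np.exp(theta[i : i + s])
            i += s
        elif self.variant == "diagonal":
            psi = np.exp(theta[i : i + s])
            i += s
        elif self.variant == "cs":
            psi = np.full(s, math.exp(theta[i]))
            i += 1
        else:
            psi = np.zeros(s)
        sigma2_e = math.exp(theta[-1])
        return sigma2_g, lam, psi, sigma2_e

    def grad(self, theta, d_s2g, Gbar, d_s2e):
        """Chain rule from (d/d sigma2_g, d/d Sigma_ge, d/d sigma2_e)."""
        sigma2_g, lam, psi, sigma2_e = self.unpack(theta)
        out = np.zeros(self.n)
        out[0] = d_s2g * sigma2_g
        i = 1
        if self.variant == "fa":
            dlam = -(Gbar @ lam)  # d lA / d Lambda
            for a, c in self.tri:
                out[i] = dlam[a, c]
                i += 1
            dpsi = -0.5 * np.diag(Gbar)
            out[i : i + self.s] = dpsi * psi
            i += self.s
        elif self.variant == "diagonal":
            dpsi = -0.5 * np.diag(Gbar)
            out[i : i + self.s] = dpsi * psi
            i += self.s
        elif self.variant == "cs":
            out[i] = -0.5 * float(np.trace(Gbar)) * psi[0]
            i += 1
        out[-1] = d_s2e * sigma2_e
        return out


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------


def reml_loglik(records: pd.DataFrame, params: MetParams) -> float:
    """Restricted log-likelihood of the MET model at given parameters.

    Evaluated through the Woodbury identity on the exact marginal covariance
    V(y) = Z_r R Z_r' + Z_g G Z_g' + Z_ge GE Z_ge' + sigma2_e I.
    """
    data = _MetData(records)
    if list(params.sites) != data.sites:
        raise ValidationError("params.sites must match the sites in the records")
    return data.general_loglik(params)


def _mom_start(data: _MetData, k: int):
    """Method-of-moments warm start for the variance parameters."""
    rec = data.records
    cell = rec.groupby(["genotype", "site"], observed=True)["yield"]
    cell_means = cell.mean().unstack().reindex(
        index=data.genotypes, columns=data.sites
    )
    cell_var = cell.var()
    s2e0 = float(np.nanmean(cell_var)) if np.isfinite(cell_var).any() else 0.1
    s2e0 = max(s2e0, 1e-4)
    dev = cell_means - cell_means.mean(axis=0)
    S = dev.cov(min_periods=2).to_numpy()
    S = np.where(np.isfinite(S), S, 0.0)
    off = S[~np.eye(data.s, dtype=bool)]
    s2g0 = max(float(np.mean(off)) if off.size else 0.01, 1e-4)
    sigma0 = S - s2g0 - (s2e0 / data.R) * np.eye(data.s)
    sigma0 = 0.5 * (sigma0 + sigma0.T)
    w, V = np.linalg.eigh(sigma0)
    lam0 = np.zeros((data.s, k))
    for c in range(k):
        j = data.s - 1 - c
        lam0[:, c] = V[:, j] * math.sqrt(max(w[j], 1e-4))
    psi0 = np.clip(np.diag(sigma0) - (lam0**2).sum(axis=1), 1e-4, None)
    rep0 = np.full(data.s, max(0.02 * s2e0, 1e-4))
    return s2g0, lam0, psi0, s2e0, rep0


def _optimize(data: _MetData, spec: MetSpec, variant: str, starts):
    """Run L-BFGS-B from each start; return the best solution.

    Start vectors on the balanced fast path hold only the packed structural
    parameters; on the general path they are prefixed by s per-site log
    replicate variances and, when ``per_site_residual`` is set, suffixed by
    s per-site log residual variances replacing the shared one.
    """
    k = spec.fa_order if variant == "fa" else 0
    packer = _Packer(data.s, k, variant)
    use_fast = data.balanced_stats is not None and not spec.per_site_residual
    s = data.s

    if use_fast:
        def objective(theta):
            sigma2_g, lam, psi, sigma2_e = packer.unpack(theta)
            sigma_ge = (
                lam @ lam.T + np.diag(psi)
                if variant != "no_gxe"
                else np.zeros((s, s))
            )
            ll, grads = _fast_loglik(data, sigma2_g, sigma_ge, sigma2_e, want_grad=True)
            if grads is None:
                return -ll, np.zeros(packer.n)
            return -ll, -packer.grad(theta, *grads)
        jac = True
        bounds = packer.bounds()
    elif spec.per_site_residual:
        def objective(theta):
            rep_vars = np.exp(theta[:s])
            core = np.append(theta[s : s + packer.n - 1], 0.0)  # sigma2_e slot unused
            sigma2_g, lam, psi, _unused = packer.unpack(core)
            site_vars = np.exp(theta[s + packer.n - 1 :])
            params = MetParams(data.sites, variant, sigma2_g, rep_vars, lam, psi, 1.0)
            w = data.site_weights(site_vars)
            return -data.general_loglik(params, resid_weights=w)
        jac = None
        bounds = (
            [(_LOG_LB, _LOG_UB)] * s + packer.bounds()[:-1] + [(_LOG_LB, _LOG_UB)] * s
        )
    else:
        def objective(theta):
            rep_vars = np.exp(theta[:s])
            sigma2_g, lam, psi, sigma2_e = packer.unpack(theta[s:])
            params = MetParams(
                data.sites, variant, sigma2_g, rep_vars, lam, psi, sigma2_e
            )
            return -data.general_loglik(params)
        jac = None
        bounds = [(_LOG_LB, _LOG_UB)] * s + packer.bounds()

    best = None
    best_success_fun = np.inf
    for theta0 in starts:
        res = minimize(
            objective,
            theta0,
            jac=jac,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": spec.max_iter, "ftol": 1e-10, "gtol": 1e-6},
        )
        if res.success:
            best_success_fun = min(best_success_fun, res.fun)
        if best is None or res.fun < best.fun:
            best = res
    sol = best.x
    # converged if the best optimum was reached by a run the optimizer
    # itself declared converged (within tol of the overall best value)
    converged = best.success or (
        best_success_fun < best.fun + spec.tol * (1.0 + abs(best.fun))
    )
    site_resid = None
    if use_fast:
        sigma2_g, lam, psi, sigma2_e = packer.unpack(sol)
        rep_vars = _profiled_rep_variances(data, sigma2_e)
    elif spec.per_site_residual:
        rep_vars = np.exp(sol[:s])
        core = np.append(sol[s : s + packer.n - 1], 0.0)
        sigma2_g, lam, psi, _unused = packer.unpack(core)
        site_resid = np.exp(sol[s + packer.n - 1 :])
        sigma2_e = float(np.mean(site_resid))
    else:
        rep_vars = np.exp(sol[:s])
        sigma2_g, lam, psi, sigma2_e = packer.unpack(sol[s:])
    params = MetParams(data.sites, variant, sigma2_g, rep_vars, lam, psi, sigma2_e)
    return _OptResult(
        params, -best.fun, bool(converged), packer, sol, use_fast, site_resid
    )


@dataclass
class _OptResult:
    params: MetParams
    loglik: float
    success: bool
    packer: "_Packer"
    sol: np.ndarray
    fast: bool
    site_resid: np.ndarray | None


def _starts_for(data, spec, variant, packer, use_fast, rng, nested_core=None):
    """Start vectors: method-of-moments, the embedded nested solution, and
    seeded jitters of the moment start (the FA surface gets the full
    multi-start; the unimodal-in-practice nested variants get two)."""
    s2g0, lam0, psi0, s2e0, rep0 = _mom_start(data, packer.k or 1)
    lam0 = lam0[:, : packer.k] if packer.k else np.zeros((data.s, 0))
    base = packer.pack(s2g0, lam0, psi0, s2e0)
    if use_fast:
        prefix, suffix = np.array([]), np.array([])
    elif spec.per_site_residual:
        prefix = np.log(rep0)
        suffix = np.full(data.s, base[-1])
        base = base[:-1]
    else:
        prefix, suffix = np.log(rep0), np.array([])
    starts = [np.concatenate([prefix, base, suffix])]
    if nested_core is not None:
        core = nested_core
        if spec.per_site_residual:
            core, s2e_slot = nested_core[:-1], nested_core[-1]
            nested_suffix = np.full(data.s, s2e_slot)
        else:
            nested_suffix = suffix
        starts.append(np.concatenate([prefix, core, nested_suffix]))
    n_extra = (
        max(spec.n_starts - len(starts), 0)
        if variant == "fa"
        else max(min(spec.n_starts, 2) - len(starts), 0)
    )
    pb = packer.bounds()
    lo = np.array([b[0] for b in pb])
    hi = np.array([b[1] for b in pb])
    if spec.per_site_residual:
        lo, hi = lo[:-1], hi[:-1]
    for _ in range(n_extra):
        jit = np.clip(base + rng.normal(0.0, 0.5, size=len(base)), lo, hi)
        starts.append(np.concatenate([prefix, jit, suffix]))
    return starts


def _embed_nested(packer_from: "_Packer", theta_from, packer_to: "_Packer"):
    """Translate a fitted nested solution into a start for the larger model.

    Loadings enter at 1e-4 (exact zero is a stationary point of the FA
    surface) and specific variances at a floor just above the bound, so the
    start's likelihood is within numerical slack of the nested optimum and
    the optimizer can only improve on it.
    """
    s = packer_to.s
    sigma2_g, _, psi, sigma2_e = packer_from.unpack(theta_from)
    psi_to = (
        np.maximum(psi, 1e-9)
        if packer_from.variant != "no_gxe"
        else np.full(s, 1e-9)
    )
    if packer_to.variant == "fa":
        lam = np.full((s, packer_to.k), 1e-4)
        return packer_to.pack(sigma2_g, lam, psi_to, sigma2_e)
    if packer_to.variant in ("diagonal", "cs"):
        return packer_to.pack(sigma2_g, np.zeros((s, 0)), psi_to, sigma2_e)
    raise ConfigurationError("nested embedding undefined")


def fit_met(records: pd.DataFrame, spec: MetSpec | None = None) -> MetFit:
    """REML fit of the MET model.

    Nested variants are fitted in sequence (no_gxe, then cs/diagonal, then
    fa as requested), each warm-started from the previous solution, so the
    optimized restricted likelihoods respect the nesting order.  If the FA
    fit fails to converge and ``fallback_to_diagonal`` is set, the diagonal
    fit is returned instead with ``fallback_from_fa=True``.
    """
    spec = spec or MetSpec()
    data = _MetData(records)
    spec.validate(data.s)
    rng = np.random.default_rng(spec.seed)
    use_fast = data.balanced_stats is not None and not spec.per_site_residual

    chain = {"no_gxe": ["no_gxe"], "cs": ["no_gxe", "cs"],
             "diagonal": ["no_gxe", "diagonal"],
             "fa": ["no_gxe", "diagonal", "fa"]}[spec.model_variant]
    nested_core = None
    nested_packer = None
    result = None
    for variant in chain:
        packer = _Packer(data.s, spec.fa_order if variant == "fa" else 0, variant)
        nested = (
            _embed_nested(nested_packer, nested_core, packer)
            if nested_core is not None
            else None
        )
        starts = _starts_for(data, spec, variant, packer, use_fast, rng, nested)
        result = _optimize(data, spec, variant, starts)
        if result.fast:
            nested_core = result.sol
        elif spec.per_site_residual:
            nested_core = np.append(
                result.sol[data.s : data.s + result.packer.n - 1],
                math.log(max(result.params.sigma2_e, 1e-10)),
            )
        else:
            nested_core = result.sol[data.s :]
        nested_packer = result.packer

    fallback = False
    if spec.model_variant == "fa" and not result.success and spec.fallback_to_diagonal:
        fallback = True
        packer_d = _Packer(data.s, 0, "diagonal")
        starts = _starts_for(data, spec, "diagonal", packer_d, use_fast, rng)
        result = _optimize(data, spec, "diagonal", starts)

    params, loglik, ok = result.params, result.loglik, result.success

    # canonical sign: each loading column's mean >= 0
    lam = params.loadings
    for c in range(lam.shape[1]):
        if lam[:, c].sum() < 0:
            lam[:, c] = -lam[:, c]

    if result.site_resid is not None:
        weights = data.site_weights(result.site_resid)
        site_means, blup_g, blup_ge, general_ll = data.general_solve(
            replace(params, sigma2_e=1.0), weights
        )
    else:
        site_means, blup_g, blup_ge, general_ll = data.general_solve(params)
    k = lam.shape[1]
    fit = MetFit(
        site_means=site_means,
        rep_variances=pd.Series(params.rep_variances, index=data.sites),
        sigma2_g=params.sigma2_g,
        loadings=pd.DataFrame(
            lam, index=data.sites, columns=[f"F{c+1}" for c in range(k)]
        ),
        specific_vars=pd.Series(params.specific_vars, index=data.sites),
        Sigma_ge=pd.DataFrame(params.sigma_ge, index=data.sites, columns=data.sites),
        sigma2_e=params.sigma2_e,
        blup_g=blup_g,
        blup_ge=blup_ge,
        reml_loglik=float(loglik),
        converged=bool(ok),
        variant=params.variant,
        n_params=result.packer.n + data.s,
        fallback_from_fa=fallback,
        site_resid_vars=(
            pd.Series(result.site_resid, index=data.sites)
            if result.site_resid is not None
            else None
        ),
        spec=spec,
    )
    return fit


def predict_yield(fit: MetFit, genotype: str, scope="overall") -> float:
    """BLUP-based yield prediction for one genotype.

    ``scope`` is either "overall" (mean over all fitted sites), a single
    site label, or an iterable of site labels (e.g. the sites of one
    megaenvironment or country).
    """
    if genotype not in fit.blup_g.index:
        raise KeyError(f"unknown genotype {genotype!r}")
    if isinstance(scope, str) and scope != "overall":
        if scope not in fit.site_means.index:
            raise KeyError(f"unknown site {scope!r}")
        sites = [scope]
    elif isinstance(scope, str):
        sites = fit.sites
    else:
        sites = list(scope)
        unknown = set(sites) - set(fit.sites)
        if unknown:
            raise KeyError(f"unknown sites {sorted(unknown)}")
        if not sites:
            raise KeyError("empty site scope")
    vals = [
        fit.site_means[s] + fit.blup_g[genotype] + fit.blup_ge.at[genotype, s]
        for s in sites
    ]
    return float(np.mean(vals))
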
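"""Per-variant binomial mixed-model divergence test with permutation FDR.

At each variant the alt read count in sample i of the late generation is
modeled as

    alt_i ~ Binomial(depth_i, p_i),   logit(p_i) = b0 + b1 * treat_i + u_i,
    u_i ~ Normal(0, sigma^2),

with one random intercept per replicate population, so the random effect
absorbs drift and pool-sampling overdispersion while the treatment effect
b1 captures correlated divergence between the selected and control groups.
The marginal likelihood integrates u_i out by adaptive Gauss-Hermite
quadrature; the test is a two-sided Wald z on b1 (likelihood-ratio fallback
under quasi-complete separation).

Significance is calibrated empirically: the model is refit under every
balanced relabeling of the samples (9 for a 3-vs-3 design), and at a grid
of p-value thresholds the false discovery rate is the ratio of the average
permuted exceedance count to the observed one.  Variants below the largest
threshold with FDR under alpha are the significantly diverged variants
(SDV).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.polynomial.hermite_e import hermegauss
from scipy import stats
from scipy.special import expit, gammaln, logsumexp, xlog1py, xlogy

from .filtering import BiallelicVariantTable
from .tables import design_is_balanced

GRAD_TOL = 1e-8
MAX_ITER = 200
SEPARATION_BETA = 12.0
SIGMA_BOUNDARY = 1e-3


@dataclass
class GlmmFit:
    beta0: float
    beta1: float
    sigma_u: float
    se1: float
    z: float
    p: float
    converged: bool
    loglik: float
    separated: bool = False


@dataclass
class PermutationScheme:
    """All balanced relabelings of the samples, minus the observed one.

    Each relabeling is a boolean vector marking which samples carry the
    "selected" label; group-label swaps are identified (the complement of a
    relabeling is the same partition).
    """

    observed: np.ndarray
    relabelings: list[np.ndarray] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.relabelings)


def _gh_nodes(n_nodes: int):
    x, w = hermegauss(n_nodes)           # weight exp(-x^2/2)
    logw = np.log(w) - 0.5 * math.log(2.0 * math.pi)
    return x, logw


def _posterior_modes(alt, depth, eta, sg, n_iter=30):
    """Mode and curvature of the per-observation integrand over v ~ N(0,1).

    g(v) = alt*log p + (depth-alt)*log(1-p) - v^2/2 with
    p = expit(eta + sg*v); g is strictly concave so damped Newton converges.
    Returns (v*, c) with c = -g''(v*) >= 1.
    """
    v = np.zeros_like(eta)
    for _ in range(n_iter):
        p = expit(eta + sg * v)
        g1 = sg * (alt - depth * p) - v
        g2 = -(sg * sg) * depth * p * (1.0 - p) - 1.0
        step = g1 / g2
        v = v - np.clip(step, -4.0, 4.0)
    p = expit(eta + sg * v)
    c = (sg * sg) * depth * p * (1.0 - p) + 1.0
    return v, c


def _log_binom_coef(alt, depth):
    return (gammaln(depth + 1.0) - gammaln(alt + 1.0)
            - gammaln(depth - alt + 1.0))


class _QuadratureModel:
    """Batched marginal likelihood, score and observed information.

    Shapes: alt/depth (S, m) counts, treat (m,) in {0,1}; parameter arrays
    are (S, k) where the k columns select design columns (1, t[, v]) - the
    same machinery fits the null model (no treatment column) for the
    likelihood-ratio fallback.
    """

    def __init__(self, alt, depth, treat, n_nodes=15, with_treatment=True):
        self.alt = np.asarray(alt, dtype=float)
        self.depth = np.asarray(depth, dtype=float)
        self.treat = np.asarray(treat, dtype=float)
        self.x, self.logw = _gh_nodes(n_nodes)
        self.with_treatment = with_treatment
        self.n_par = 3 if with_treatment else 2
        self.lbc = _log_binom_coef(self.alt, self.depth).sum(axis=1)

    def _eta(self, theta, alt):
        b0 = theta[:, 0][:, None]
        if self.with_treatment:
            return b0 + theta[:, 1][:, None] * self.treat[None, :]
        return np.broadcast_to(b0, alt.shape)

    def loglik(self, theta):
        return self._moments(theta, want_derivs=False)

    def _moments(self, theta, rows=None, want_derivs=True):
        if rows is None:
            alt, depth, lbc = self.alt, self.depth, self.lbc
        else:
            alt, depth, lbc = self.alt[rows], self.depth[rows], self.lbc[rows]
        eta = self._eta(theta, alt)
        sg = theta[:, -1][:, None]
        vstar, c = _posterior_modes(alt, depth, eta, sg)
        tau = np.sqrt(1.0 / c)                        # (S, m)
        # adaptive nodes v_k = v* + tau x_k; hermegauss weights integrate
        # against exp(-x^2/2), so the Jacobian and exp(+x^2/2) re-enter the
        # log-weights
        v = vstar[..., None] + tau[..., None] * self.x    # (S, m, K)
        p = expit(eta[..., None] + sg[..., None] * v)
        g = (xlogy(alt[..., None], p)
             + xlog1py(depth[..., None] - alt[..., None], -p)
             - 0.5 * v * v)
        lw = self.logw + 0.5 * self.x * self.x + np.log(tau)[..., None]
        terms = g + lw
        logI = logsumexp(terms, axis=2)               # (S, m)
        ll = logI.sum(axis=1) + lbc                   # (S,)
        if not want_derivs:
            return ll
        omega = np.exp(terms - logI[..., None])       # posterior weights
        r = alt[..., None] - depth[..., None] * p     # residuals at nodes
        dpq = depth[..., None] * p * (1.0 - p)
        t = self.treat[None, :, None]
        if self.with_treatment:
            xs = (np.ones_like(v), np.broadcast_to(t, v.shape), v)
        else:
            xs = (np.ones_like(v), v)
        k = self.n_par
        score = np.zeros((alt.shape[0], k))
        info = np.zeros((alt.shape[0], k, k))
        s_obs = [np.sum(omega * r * xs[a], axis=2) for a in range(k)]
        for a in range(k):
            score[:, a] = s_obs[a].sum(axis=1)
        for a in range(k):
            for b in range(a, k):
                xab = xs[a] * xs[b]
                e_h = np.sum(omega * dpq * xab, axis=2)
                e_ss = np.sum(omega * r * r * xab, axis=2)
                # Louis: obs info = E[-H_c] - Var(score_c), per observation
                iab = (e_h - (e_ss - s_obs[a] * s_obs[b])).sum(axis=1)
                info[:, a, b] = iab
                info[:, b, a] = iab
        return ll, score, info


def _initial_theta(alt, depth, treat, with_treatment=True):
    phat = (alt + 0.5) / (depth + 1.0)
    lo = np.log(phat / (1.0 - phat))
    sel = treat.astype(bool)
    m1 = lo[:, sel].mean(axis=1)
    m0 = lo[:, ~sel].mean(axis=1)
    resid = np.concatenate([lo[:, sel] - m1[:, None],
                            lo[:, ~sel] - m0[:, None]], axis=1)
    sd = np.maximum(resid.std(axis=1), 0.1)
    if with_treatment:
        return np.column_stack([m0, m1 - m0, sd])
    return np.column_stack([lo.mean(axis=1), sd])


def _fit_batch_model(model: _QuadratureModel, theta0,
                     max_iter=MAX_ITER, grad_tol=GRAD_TOL):
    """Damped (Levenberg-style) Newton ascent, vectorized over sites."""
    theta = theta0.copy()
    S, k = theta.shape
    lam = np.full(S, 1e-3)
    ll, score, info = model._moments(theta)
    active = np.ones(S, dtype=bool)
    converged = np.zeros(S, dtype=bool)
    eye = np.eye(k)
    for _ in range(max_iter):
        gmax = np.abs(score).max(axis=1)
        converged = gmax < grad_tol
        active = ~converged
        if not active.any():
            break
        idx = np.where(active)[0]
        H = info[idx] + lam[idx][:, None, None] * eye
        try:
            step = np.linalg.solve(H, score[idx][..., None])[..., 0]
        except np.linalg.LinAlgError:
            step = score[idx] / lam[idx][:, None]
        cand = theta[idx] + np.clip(step, -4.0, 4.0)
        ll_new, score_new, info_new = model._moments(cand, rows=idx)
        better = ll_new >= ll[idx] - 1e-12
        acc = idx[better]
        theta[acc] = cand[better]
        ll[acc] = ll_new[better]
        score[acc] = score_new[better]
        info[acc] = info_new[better]
        lam[acc] = np.maximum(lam[acc] * 0.3, 1e-10)
        rej = idx[~better]
        lam[rej] = np.minimum(lam[rej] * 10.0, 1e8)
    theta[:, -1] = np.abs(theta[:, -1])   # likelihood is even in sigma
    return theta, ll, score, info, converged


def fit_glmm_batch(alt, depth, treat, n_nodes: int = 15,
                   max_iter: int = MAX_ITER,
                   grad_tol: float = GRAD_TOL) -> pd.DataFrame:
    """Fit the binomial random-intercept GLMM at every site.

    ``alt``/``depth`` are (n_sites, n_samples) arrays and ``treat`` a 0/1
    vector.  Returns one row per site with the fit, Wald z and p, and a
    separation flag (for separated or non-converged sites the reported p
    comes from a likelihood-ratio test against the no-treatment model).
    """
    alt = np.atleast_2d(np.asarray(alt, dtype=float))
    depth = np.atleast_2d(np.asarray(depth, dtype=float))
    treat = np.asarray(treat, dtype=float)
    if (depth <= 0).any():
        raise ValueError("all samples must have positive depth")
    if treat.sum() < 2 or (1 - treat).sum() < 2:
        raise ValueError("need at least two samples per treatment group")
    model = _QuadratureModel(alt, depth, treat, n_nodes=n_nodes)
    theta0 = _initial_theta(alt, depth, treat)
    theta, ll, score, info, converged = _fit_batch_model(
        model, theta0, max_iter=max_iter, grad_tol=grad_tol)

    S = theta.shape[0]
    se1 = np.full(S, np.nan)
    # Wald SE from the observed information; at the sigma boundary fall
    # back to the fixed-effects (GLM) information at sigma = 0.
    boundary = theta[:, 2] < SIGMA_BOUNDARY
    with np.errstate(invalid="ignore"):
        for i in range(S):
            if boundary[i]:
                eta = theta[i, 0] + theta[i, 1] * treat
                p = expit(eta)
                w = depth[i] * p * (1.0 - p)
                xtx = np.array([[w.sum(), (w * treat).sum()],
                                [(w * treat).sum(), (w * treat).sum()]])
                cov = _safe_inv(xtx)
            else:
                cov = _safe_inv(info[i])
            if cov is not None:
                v = cov[1, 1]
                se1[i] = math.sqrt(v) if v > 0 else np.nan

    z = theta[:, 1] / se1
    p_wald = 2.0 * stats.norm.sf(np.abs(z))
    separated = ((np.abs(theta[:, 1]) > SEPARATION_BETA)
                 | ~np.isfinite(se1) | (se1 > 100.0))
    p = p_wald.copy()
    if separated.any():
        idx = np.where(separated)[0]
        null_model = _QuadratureModel(alt[idx], depth[idx], treat,
                                      n_nodes=n_nodes, with_treatment=False)
        th0 = _initial_theta(alt[idx], depth[idx], treat,
                             with_treatment=False)
        _, ll0, _, _, _ = _fit_batch_model(null_model, th0,
                                           max_iter=max_iter,
                                           grad_tol=grad_tol)
        lr = np.maximum(2.0 * (ll[idx] - ll0), 0.0)
        p[idx] = stats.chi2.sf(lr, df=1)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return pd.DataFrame({
        "beta0": theta[:, 0], "beta1": theta[:, 1], "sigma_u": theta[:, 2],
        "se1": se1, "z": z, "p": p, "converged": converged,
        "loglik": ll, "separated": separated,
    })


def _safe_inv(m):
    try:
        return np.linalg.inv(m)
    except np.linalg.LinAlgError:
        return None


def fit_site_glmm(alt, depth, treat, n_nodes: int = 15) -> GlmmFit:
    """Fit a single variant; see :func:`fit_glmm_batch`."""
    row = fit_glmm_batch(np.asarray(alt)[None, :], np.asarray(depth)[None, :],
                         treat, n_nodes=n_nodes).iloc[0]
    return GlmmFit(beta0=row.beta0, beta1=row.beta1, sigma_u=row.sigma_u,
                   se1=row.se1, z=row.z, p=row.p, converged=bool(row.converged),
                   loglik=row.loglik, separated=bool(row.separated))


# ---------------------------------------------------------------------------
# Permutations and empirical FDR


def enumerate_permutations(treat: np.ndarray) -> PermutationScheme:
    """All balanced two-group relabelings except the observed partition.

    For 2k samples split k vs k there are C(2k, k)/2 - 1 such relabelings
    (group labels are interchangeable, so each unordered partition counts
    once).  Unbalanced designs are rejected; subsample to balance first.
    """
    treat = np.asarray(treat).astype(bool)
    m = len(treat)
    k = int(treat.sum())
    if 2 * k != m:
        raise ValueError("permutation FDR needs a balanced design "
                         f"(got {k} vs {m - k}); subsample replicates to "
                         "equal group sizes first")
    observed = frozenset(np.where(treat)[0])
    seen = set()
    relabelings = []
    for combo in itertools.combinations(range(m), k):
        part = frozenset(combo)
        comp = frozenset(range(m)) - part
        key = min(tuple(sorted(part)), tuple(sorted(comp)))
        if key in seen:
            continue
        seen.add(key)
        if part == observed or comp == observed:
            continue
        lab = np.zeros(m, dtype=bool)
        lab[list(part)] = True
        relabelings.append(lab)
    return PermutationScheme(observed=treat, relabelings=relabelings)


@dataclass
class FdrCurve:
    grid: np.ndarray
    s_obs: np.ndarray
    mean_perm: np.ndarray
    fdr: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"threshold": self.grid, "s_obs": self.s_obs,
                             "mean_perm": self.mean_perm, "fdr": self.fdr})


def permutation_fdr(p_obs: np.ndarray, p_perm: np.ndarray,
                    alpha: float = 0.05, grid: np.ndarray | None = None,
                    monotonize: bool = False):
    """Empirical FDR: mean permuted exceedance count over observed count.

    ``p_perm`` has shape (n_relabelings, n_variants) and must come from the
    same variant set as ``p_obs``.  The threshold grid defaults to the
    distinct observed p-values; both counts use a strict "< P".  Returns
    ``(FdrCurve, threshold, sdv mask)`` where the threshold is the largest
    grid value with FDR below alpha (None when no threshold qualifies).
    """
    p_obs = np.asarray(p_obs, dtype=float)
    if p_obs.size == 0:
        raise ValueError("no observed p-values")
    p_perm = np.atleast_2d(np.asarray(p_perm, dtype=float))
    if grid is None:
        grid = np.unique(p_obs)
    grid = np.asarray(grid, dtype=float)
    obs_sorted = np.sort(p_obs)
    s_obs = np.searchsorted(obs_sorted, grid, side="left")
    perm_sorted = np.sort(p_perm, axis=1)
    s_perm = np.stack([np.searchsorted(row, grid, side="left")
                       for row in perm_sorted])
    mean_perm = s_perm.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        fdr = np.where(s_obs > 0, mean_perm / s_obs, np.nan)
    if monotonize:
        # q-value-style: smallest FDR at or above each threshold
        rev = fdr[::-1]
        fdr = np.fmin.accumulate(rev)[::-1]
    curve = FdrCurve(grid=grid, s_obs=s_obs, mean_perm=mean_perm, fdr=fdr)
    ok = (s_obs > 0) & np.isfinite(fdr) & (fdr < alpha)
    threshold = float(grid[ok][-1]) if ok.any() else None
    sdv = (p_obs < threshold) if threshold is not None else \
        np.zeros_like(p_obs, dtype=bool)
    return curve, threshold, sdv


# ---------------------------------------------------------------------------
# Full scan


@dataclass
class ScanResult:
    results: pd.DataFrame
    fdr_curve: FdrCurve
    threshold: float | None
    metadata: dict


def run_divergence_scan(table: BiallelicVariantTable, design: pd.DataFrame,
                        alpha: float = 0.05, generation: int | None = None,
                        mask: pd.DataFrame | None = None,
                        n_nodes: int = 15) -> ScanResult:
    """GLMM + exhaustive permutation FDR on the late-generation samples.

    ``mask`` is an optional interval table (arm, start, end; 0-based
    half-open, e.g. a heterochromatin analogue read from BED) whose variants
    are excluded from SDV reporting but still fitted.  Sites with zero depth
    in any late-generation sample are dropped before fitting.
    """
    if not design_is_balanced(design):
        raise ValueError("permutation FDR needs a balanced design "
                         "(equal replicates per treatment within a "
                         "generation); subsample replicates first")
    if generation is None:
        generation = int(design["generation"].max())
    late = design[design["generation"] == generation]
    sample_pos = {s: j for j, s in enumerate(table.samples)}
    idx = [sample_pos[s] for s in late["sample"]]
    treat = (late["treatment"] == "selected").to_numpy()

    alt = table.alt_counts[idx].T          # (n_sites, n_samples)
    dep = table.depths[idx].T
    usable = (dep > 0).all(axis=1)
    sub = table.subset(usable)
    alt, dep = alt[usable], dep[usable]

    obs = fit_glmm_batch(alt, dep, treat.astype(float), n_nodes=n_nodes)
    scheme = enumerate_permutations(treat)
    p_perm = np.empty((scheme.n, len(obs)))
    for j, lab in enumerate(scheme.relabelings):
        p_perm[j] = fit_glmm_batch(alt, dep, lab.astype(float),
                                   n_nodes=n_nodes)["p"].to_numpy()
    curve, threshold, sdv = permutation_fdr(obs["p"].to_numpy(), p_perm,
                                            alpha=alpha)
    results = pd.concat([sub.sites.reset_index(drop=True), obs], axis=1)
    for j in range(scheme.n):
        results[f"p_perm{j + 1}"] = p_perm[j]
    masked = np.zeros(len(results), dtype=bool)
    if mask is not None and len(mask):
        pos0 = results["pos"].to_numpy() - 1
        for _, row in mask.iterrows():
            masked |= ((results["arm"] == row["arm"]).to_numpy()
                       & (pos0 >= row["start"]) & (pos0 < row["end"]))
    results["masked"] = masked
    results["sdv"] = sdv & ~masked
    meta = {"alpha": alpha, "generation": generation, "n_nodes": n_nodes,
            "grad_tol": GRAD_TOL, "max_iter": MAX_ITER,
            "n_permutations": scheme.n, "threshold": threshold,
            "n_tested": len(results), "n_sdv": int(results["sdv"].sum())}
    return ScanResult(results=results, fdr_curve=curve, threshold=threshold,
                      metadata=meta)
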
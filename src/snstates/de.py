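"""Per-gene differential expression with a negative-binomial mixed model.

Counts for one gene are modeled as (optionally zero-inflated) negative
binomial with a log link: ``log mu = X beta + offset + b_subject`` with
``b_subject ~ N(0, sigma^2)`` on the log scale. The random intercept is
integrated out by a Laplace approximation of the marginal likelihood
(the inner mode is found by damped per-subject Newton steps); fixed
effects, the per-gene dispersion and the random-effect SD are estimated
jointly by L-BFGS-B, and Wald p-values come from the numerical Hessian
of the marginal log-likelihood at the optimum.

Estimates are on the natural-log scale; ``estimate_to_log2fc`` converts
them to log2 fold-changes via log2(e^estimate).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, sparse, special, stats
from statsmodels.stats.multitest import multipletests

from .io import CountMatrix

LOG2E = float(np.log2(np.e))

DEFAULT_MIN_SUBJECT_NUCLEI = {
    "astrocytes": 50,
    "microglia": 50,
    "excitatory_neurons": 60,
    "inhibitory_neurons": 60,
    "oligodendrocytes": 60,
    "opcs": 66,
}


def estimate_to_log2fc(estimate):
    """log2FC = log2(e^estimate) = estimate * log2(e)."""
    return np.asarray(estimate, dtype=float) * LOG2E


def bh_correct(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (NaNs are passed through)."""
    p = np.asarray(pvalues, dtype=float)
    q = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.sum():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


@dataclass
class NBMixedFit:
    """Result of one gene fit. ``coef``/``se``/``p`` follow design columns."""

    coef: np.ndarray
    se: np.ndarray
    p: np.ndarray
    sigma: float
    dispersion: float
    zi_prob: float
    loglik: float
    converged: bool
    message: str = ""


def _nb_logpmf(y, mu, r):
    return (
        special.gammaln(y + r)
        - special.gammaln(r)
        - special.gammaln(y + 1)
        + r * np.log(r / (r + mu))
        + y * np.log(mu / (r + mu) + 1e-300)
    )


def _obs_loglik_and_grad(y, eta, r, pi):
    """Per-observation log-likelihood and d/deta, for NB or ZINB."""
    mu = np.exp(eta)
    ll = _nb_logpmf(y, mu, r)
    grad = y - (y + r) * mu / (r + mu)
    if pi > 0:
        zero = y == 0
        if zero.any():
            p0 = np.exp(r * np.log(r / (r + mu[zero])))
            mix = pi + (1 - pi) * p0
            ll_z = np.log(mix)
            # d p0/d eta = -p0 * r * mu / (r + mu)
            grad_z = (1 - pi) * (-p0 * r * mu[zero] / (r + mu[zero])) / mix
            ll = np.where(zero, 0.0, ll + np.log1p(-pi))
            ll[zero] = ll_z
            grad = grad.copy()
            grad[zero] = grad_z
    return ll, grad


def _inner_mode(y, eta0, r, pi, subj, n_subj, sigma2, b0=None):
    """Maximize the joint log-likelihood over subject intercepts b.

    Damped Newton with a numerically differentiated curvature; the NB
    case is strictly concave in b so this converges quickly.
    """
    b = np.zeros(n_subj) if b0 is None else b0.copy()
    eps = 1e-5
    for _ in range(100):
        eta = eta0 + b[subj]
        _, g_obs = _obs_loglik_and_grad(y, eta, r, pi)
        if pi > 0:
            _, g_hi = _obs_loglik_and_grad(y, eta + eps, r, pi)
            _, g_lo = _obs_loglik_and_grad(y, eta - eps, r, pi)
            curv = (g_hi - g_lo) / (2 * eps)
        else:
            mu = np.exp(eta)
            curv = -(y + r) * r * mu / (r + mu) ** 2
        grad = np.bincount(subj, weights=g_obs, minlength=n_subj) - b / sigma2
        hess = np.bincount(subj, weights=-curv, minlength=n_subj) + 1.0 / sigma2
        hess = np.maximum(hess, 1e-8)
        step = np.clip(grad / hess, -2.0, 2.0)
        b = b + step
        if np.max(np.abs(step)) < 1e-10:
            break
    return b, hess


def _marginal_nll(params, y, X, subj, n_subj, offset, zi, cache):
    p = X.shape[1]
    beta = params[:p]
    r = np.exp(-params[p])  # r = 1/dispersion
    sigma = np.exp(params[p + 1])
    pi = special.expit(params[p + 2]) if zi else 0.0
    eta0 = X @ beta + offset
    b, hess = _inner_mode(y, eta0, r, pi, subj, n_subj, sigma**2, cache.get("b"))
    cache["b"] = b
    ll_obs, _ = _obs_loglik_and_grad(y, eta0 + b[subj], r, pi)
    ll = np.bincount(subj, weights=ll_obs, minlength=n_subj)
    ll += -0.5 * b**2 / sigma**2 - np.log(sigma) - 0.5 * np.log(hess)
    return -float(np.sum(ll))


def _num_hessian(f, x, eps=1e-4):
    n = len(x)
    H = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            def fx(di, dj):
                z = x.copy()
                z[i] += di
                z[j] += dj
                return f(z)

            H[i, j] = H[j, i] = (
                fx(eps, eps) - fx(eps, -eps) - fx(-eps, eps) + fx(-eps, -eps)
            ) / (4 * eps * eps)
    return H


def fit_nb_mixed(
    y: np.ndarray,
    X: np.ndarray,
    subject_ids,
    offset: np.ndarray | None = None,
    zi: bool = False,
    max_iter: int = 200,
    tol: float = 1e-8,
) -> NBMixedFit:
    """Fit the NB (or ZINB) mixed model for a single gene.

    ``X`` must include an intercept column. All-zero genes and fits that
    run into the parameter bounds are reported with ``converged=False``
    rather than raising.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if np.any(y < 0) or not np.allclose(y, np.round(y)):
        raise ValueError("counts must be non-negative integers")
    subj_codes, subj_index = np.unique(np.asarray(subject_ids), return_inverse=True)
    n_subj = len(subj_codes)
    if n_subj < 2:
        raise ValueError("at least two subjects are required")
    p = X.shape[1]
    nan = np.full(p, np.nan)
    if y.sum() == 0:
        return NBMixedFit(nan, nan, nan, np.nan, np.nan, np.nan, np.nan, False, "all-zero gene")
    offset = np.zeros_like(y) if offset is None else np.asarray(offset, dtype=float)

    # moment start: intercept near log mean (offset-adjusted)
    x0 = np.zeros(p + 2 + (1 if zi else 0))
    x0[0] = np.log(y.mean() + 1e-8) - offset.mean()
    x0[p] = 0.0  # log dispersion
    x0[p + 1] = -1.2  # log sigma
    if zi:
        x0[p + 2] = -2.0
    bounds = [(-30.0, 30.0)] * p + [(-12.0, 6.0), (-8.0, 3.0)]
    if zi:
        bounds.append((-10.0, 10.0))
    cache: dict = {}
    res = optimize.minimize(
        _marginal_nll,
        x0,
        args=(y, X, subj_index, n_subj, offset, zi, cache),
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": max_iter, "ftol": tol},
    )
    est = res.x
    at_bound = any(
        est[i] <= lo + 1e-6 or est[i] >= hi - 1e-6 for i, (lo, hi) in enumerate(bounds[:p])
    )
    converged = bool(res.success) and not at_bound
    se = np.full(p, np.nan)
    pvals = np.full(p, np.nan)
    if converged:
        H = _num_hessian(
            lambda z: _marginal_nll(z, y, X, subj_index, n_subj, offset, zi, dict(cache)),
            est,
        )
        try:
            cov = np.linalg.inv(H)
            var = np.diag(cov)[:p]
            if np.any(var <= 0):
                converged = False
            else:
                se = np.sqrt(var)
                pvals = 2 * stats.norm.sf(np.abs(est[:p]) / se)
        except np.linalg.LinAlgError:
            converged = False
    return NBMixedFit(
        coef=est[:p],
        se=se,
        p=pvals,
        sigma=float(np.exp(est[p + 1])),
        dispersion=float(np.exp(est[p])),
        zi_prob=float(special.expit(est[p + 2])) if zi else 0.0,
        loglik=-float(res.fun),
        converged=converged,
        message=str(res.message),
    )


@dataclass
class DESpec:
    """What to contrast and how.

    ``contrast`` is one of ``state_vs_rest``, ``state_vs_state`` or
    ``group_vs_control``. Sex is always a covariate; age of death is
    added for genetic contrasts unless the group is autosomal dominant
    (where age and status are confounded). A log-total-UMI offset is on
    by default so the raw-count model is depth-invariant.
    """

    contrast: str = "state_vs_rest"
    level: str | None = None  # state or group of interest
    reference: str | None = None  # second state, or control group label
    cell_type: str | None = None
    include_aod: bool = False
    use_offset: bool = True
    zi: bool = False
    min_gene_nuclei: int = 10
    min_subject_nuclei: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_MIN_SUBJECT_NUCLEI)
    )


def _design_from_meta(meta: pd.DataFrame, spec: DESpec, target: np.ndarray):
    cols = ["intercept", "contrast"]
    mats = [np.ones(len(meta)), target.astype(float)]
    if meta["sex"].nunique() > 1:
        mats.append((meta["sex"] == meta["sex"].iloc[0]).to_numpy(float))
        cols.append("sex")
    if spec.include_aod and meta["aod"].nunique() > 1:
        aod = meta["aod"].to_numpy(float)
        mats.append((aod - aod.mean()) / max(aod.std(), 1e-12))
        cols.append("aod")
    return np.column_stack(mats), cols


def _subject_filter(meta: pd.DataFrame, spec: DESpec) -> pd.Series:
    if spec.cell_type is None:
        return pd.Series(True, index=meta.index)
    thr = spec.min_subject_nuclei.get(spec.cell_type, 60)
    counts = meta.groupby("subject_id")["barcode"].count()
    good = counts[counts > thr].index  # strict >
    return meta["subject_id"].isin(good)


def de_scan(
    cm: CountMatrix,
    metadata: pd.DataFrame,
    spec: DESpec,
    genes: list[str] | None = None,
) -> pd.DataFrame:
    """One NB mixed-model fit per gene; BH correction within the scan.

    Returns a table with the natural-log estimate, SE, p, BH q, log2FC
    and convergence flag. Non-converged genes keep their row but are
    excluded from the BH family.
    """
    meta = metadata.set_index("barcode").loc[cm.barcodes].reset_index()
    if spec.cell_type is not None:
        mask = (meta["cell_type"] == spec.cell_type).to_numpy()
    else:
        mask = np.ones(len(meta), bool)
    mask &= _subject_filter(meta, spec).to_numpy()

    if spec.contrast == "state_vs_rest":
        if spec.level is None:
            raise ValueError("state_vs_rest requires level")
        sub = meta[mask]
        target = (sub["cell_state"] == spec.level).to_numpy()
        if target.sum() == 0 or target.all():
            raise ValueError(f"state {spec.level!r} empty or exhaustive after filtering")
    elif spec.contrast == "state_vs_state":
        if spec.level is None or spec.reference is None:
            raise ValueError("state_vs_state requires level and reference")
        mask &= meta["cell_state"].isin([spec.level, spec.reference]).to_numpy()
        sub = meta[mask]
        target = (sub["cell_state"] == spec.level).to_numpy()
    elif spec.contrast == "group_vs_control":
        if spec.level is None or spec.reference is None:
            raise ValueError("group_vs_control requires level and reference")
        mask &= meta["genotype_group"].isin([spec.level, spec.reference]).to_numpy()
        sub = meta[mask]
        target = (sub["genotype_group"] == spec.level).to_numpy()
    else:
        raise ValueError(f"unknown contrast {spec.contrast!r}")
    if target.sum() == 0 or (~target).sum() == 0:
        raise ValueError("contrast has an empty level after filtering")

    idx = np.flatnonzero(mask)
    X_counts = cm.values[idx]
    subjects = sub["subject_id"].to_numpy()
    design, cols = _design_from_meta(sub, spec, target)
    offset = None
    if spec.use_offset:
        tot = np.asarray(X_counts.sum(axis=1)).ravel()
        offset = np.log(np.maximum(tot, 1.0))

    keep_genes = np.asarray((X_counts > 0).sum(axis=0)).ravel() >= spec.min_gene_nuclei
    names = np.asarray(cm.gene_names)
    if genes is not None:
        keep_genes &= np.isin(names, genes)

    rows = []
    dense = None
    for g in np.flatnonzero(keep_genes):
        y = np.asarray(X_counts[:, g].todense()).ravel()
        fit = fit_nb_mixed(y, design, subjects, offset=offset, zi=spec.zi)
        rows.append(
            {
                "gene": names[g],
                "estimate": fit.coef[1],
                "se": fit.se[1],
                "p": fit.p[1],
                "log2fc": float(estimate_to_log2fc(fit.coef[1])),
                "sigma": fit.sigma,
                "dispersion": fit.dispersion,
                "n_nuclei": int(len(y)),
                "converged": fit.converged,
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "gene", "estimate", "se", "p", "log2fc",
            "sigma", "dispersion", "n_nuclei", "converged",
        ],
    )
    if len(out):
        p_for_bh = out["p"].where(out["converged"], np.nan)
        out["q"] = bh_correct(p_for_bh)
    else:
        out["q"] = []
    return out
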
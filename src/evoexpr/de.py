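"""Negative-binomial GLM differential expression.

The fitting core is a log-link NB GLM solved by iteratively reweighted
least squares, vectorized across genes that share a design matrix.
Dispersions are estimated by maximizing the Cox-Reid adjusted profile
likelihood (APL): a common dispersion maximizes the summed APL, and
tagwise dispersions maximize the per-gene APL plus a weighted shared-APL
penalty that shrinks them toward the common value (prior weight expressed
in genes-equivalent, default 10).

Contrasts are tested with likelihood-ratio tests of nested designs and
p-values are Benjamini-Hochberg adjusted. A gene is called only when
q < alpha AND |log2FC| exceeds the fold-change threshold (both strict).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .datamodel import CountDataset
from .normalize import NormalizedDataset

__all__ = [
    "GLMFit",
    "DispersionEstimates",
    "DEResult",
    "fit_nbglm",
    "nb_loglik",
    "nb_deviance",
    "adjusted_profile_loglik",
    "estimate_dispersions",
    "lrt_contrast",
    "bh_adjust",
    "call_de",
    "run_contrast",
    "CONTRASTS",
]

CONTRASTS = ("regime_in_F", "regime_in_M", "sex_in_E", "sex_in_L", "interaction")

_MAX_ITER = 50
_DEV_TOL = 1e-8


# ---------------------------------------------------------------------------
# likelihood primitives
# ---------------------------------------------------------------------------

def nb_loglik(y: np.ndarray, mu: np.ndarray, phi) -> np.ndarray:
    """Per-gene NB log-likelihood summed over samples; phi=0 is Poisson."""
    y = np.asarray(y, dtype=float)
    mu = np.maximum(np.asarray(mu, dtype=float), 1e-300)
    phi = np.asarray(phi, dtype=float)
    if phi.ndim == 0:
        phi = np.full(y.shape[:-1] or (1,), float(phi))
    phi_col = phi[..., None]
    out = np.empty(y.shape)
    pois = phi_col <= 1e-12
    pois_b = np.broadcast_to(pois, y.shape)
    out[pois_b] = (y * np.log(mu) - mu - special.gammaln(y + 1.0))[pois_b]
    with np.errstate(divide="ignore", invalid="ignore"):
        r = 1.0 / np.where(pois, 1.0, phi_col)
        nb = (special.gammaln(y + r) - special.gammaln(r)
              - special.gammaln(y + 1.0)
              + y * np.log(phi_col * mu / (1.0 + phi_col * mu))
              - r * np.log1p(phi_col * mu))
    out[~pois_b] = nb[~pois_b]
    return out.sum(axis=-1)


def nb_deviance(y: np.ndarray, mu: np.ndarray, phi) -> np.ndarray:
    """NB deviance 2*(loglik(saturated) - loglik(mu)); phi=0 is Poisson."""
    y = np.asarray(y, dtype=float)
    mu = np.maximum(np.asarray(mu, dtype=float), 1e-300)
    phi = np.asarray(phi, dtype=float)
    if phi.ndim == 0:
        phi = np.full(y.shape[:-1] or (1,), float(phi))
    phi_col = phi[..., None]
    with np.errstate(divide="ignore", invalid="ignore"):
        ylogy = np.where(y > 0, y * np.log(np.where(y > 0, y, 1.0) / mu), 0.0)
        pois_term = 2.0 * (ylogy - (y - mu))
        nb_term = 2.0 * (ylogy - (y + 1.0 / np.where(phi_col > 0, phi_col, 1.0))
                         * np.log((1.0 + phi_col * y) / (1.0 + phi_col * mu)))
    dev = np.where(phi_col <= 1e-12, pois_term, nb_term)
    return dev.sum(axis=-1)


# ---------------------------------------------------------------------------
# vectorized IRLS fit
# ---------------------------------------------------------------------------

@dataclass
class GLMFit:
    """Fitted NB GLMs for a block of genes sharing one design."""

    coef: np.ndarray        # (G, p) natural-log scale
    mu: np.ndarray          # (G, N) fitted means
    deviance: np.ndarray    # (G,)
    converged: np.ndarray   # (G,) bool
    design: np.ndarray      # (N, p)
    offsets: np.ndarray     # (N,) or (G, N)
    phi: np.ndarray         # (G,)


def fit_nbglm(counts: np.ndarray, design: np.ndarray, offsets: np.ndarray,
              phi) -> GLMFit:
    """Fit log-link NB GLMs by IRLS, one per row of ``counts``.

    ``counts`` may be 1-D (one gene) or (G, N). ``offsets`` are log
    effective library sizes, shape (N,) or (G, N). ``phi`` is a scalar or
    per-gene vector of NB dispersions (0 means Poisson).
    """
    y = np.atleast_2d(np.asarray(counts, dtype=float))
    G, N = y.shape
    X = np.asarray(design, dtype=float)
    if X.ndim != 2 or X.shape[0] != N:
        raise ValueError("design must be (n_samples, p)")
    p = X.shape[1]
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("design matrix is not full rank")
    off = np.asarray(offsets, dtype=float)
    off2 = np.broadcast_to(off, (G, N)) if off.ndim == 1 else off
    phi_v = np.asarray(phi, dtype=float)
    if phi_v.ndim == 0:
        phi_v = np.full(G, float(phi_v))

    # init from a least-squares fit on shifted log counts
    z0 = np.log(y + 0.5) - off2
    beta, *_ = np.linalg.lstsq(X, z0.T, rcond=None)
    beta = beta.T  # (G, p)

    eta = beta @ X.T + off2
    mu = np.exp(np.clip(eta, -700, 700))
    dev = nb_deviance(y, mu, phi_v)
    converged = np.zeros(G, dtype=bool)
    active = np.ones(G, dtype=bool)

    for _ in range(_MAX_ITER):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        mu_a = np.maximum(mu[idx], 1e-8)
        w = mu_a / (1.0 + phi_v[idx, None] * mu_a)        # Fisher weights
        z = (eta[idx] - off2[idx]) + (y[idx] - mu_a) / mu_a  # working response
        Xw = X[None, :, :] * w[:, :, None]                 # (g, N, p)
        XtWX = np.einsum("ni,gnj->gij", X, Xw)
        XtWz = np.einsum("gnj,gn->gj", Xw, z)
        XtWX += 1e-10 * np.eye(p)[None, :, :]
        try:
            new_beta = np.linalg.solve(XtWX, XtWz[:, :, None])[:, :, 0]
        except np.linalg.LinAlgError:
            new_beta = np.stack([
                np.linalg.lstsq(XtWX[g], XtWz[g], rcond=None)[0]
                for g in range(idx.size)
            ])
        new_eta = new_beta @ X.T + off2[idx]
        new_mu = np.exp(np.clip(new_eta, -700, 700))
        new_dev = nb_deviance(y[idx], new_mu, phi_v[idx])

        # step-halve genes whose deviance got worse
        worse = new_dev > dev[idx] + 1e-10
        halvings = 0
        while np.any(worse) and halvings < 10:
            new_beta[worse] = 0.5 * (new_beta[worse] + beta[idx][worse])
            new_eta[worse] = new_beta[worse] @ X.T + off2[idx][worse]
            new_mu[worse] = np.exp(np.clip(new_eta[worse], -700, 700))
            new_dev[worse] = nb_deviance(y[idx][worse], new_mu[worse],
                                         phi_v[idx][worse])
            worse = new_dev > dev[idx] + 1e-10
            halvings += 1

        rel = np.abs(new_dev - dev[idx]) / (np.abs(dev[idx]) + 0.1)
        beta[idx], eta[idx], mu[idx] = new_beta, new_eta, new_mu
        done = rel < _DEV_TOL
        converged[idx[done]] = True
        dev[idx] = new_dev
        active[idx[done]] = False

    return GLMFit(coef=beta, mu=mu, deviance=dev, converged=converged,
                  design=X, offsets=off, phi=phi_v)


def adjusted_profile_loglik(counts: np.ndarray, design: np.ndarray,
                            offsets: np.ndarray, phi) -> np.ndarray:
    """Cox-Reid adjusted profile log-likelihood per gene at dispersion phi."""
    fit = fit_nbglm(counts, design, offsets, phi)
    y = np.atleast_2d(np.asarray(counts, dtype=float))
    ll = nb_loglik(y, fit.mu, fit.phi)
    mu = np.maximum(fit.mu, 1e-8)
    w = mu / (1.0 + fit.phi[:, None] * mu)
    X = fit.design
    XtWX = np.einsum("ni,gnj->gij", X, X[None, :, :] * w[:, :, None])
    sign, logdet = np.linalg.slogdet(XtWX + 1e-12 * np.eye(X.shape[1]))
    return ll - 0.5 * logdet


# ---------------------------------------------------------------------------
# dispersion estimation
# ---------------------------------------------------------------------------

@dataclass
class DispersionEstimates:
    common: float
    tagwise: np.ndarray
    prior_weight: float
    grid: np.ndarray
    apl_grid: np.ndarray  # (G, K) per-gene APL evaluated on the grid


def _interp_argmax(grid_log: np.ndarray, values: np.ndarray) -> np.ndarray:
    """Vectorized quadratic-interpolated argmax over a log-phi grid.

    ``values`` is (G, K); returns log-phi of the per-row maximum, using a
    parabola through the max and its neighbours (edge rows return the edge).
    """
    V = np.atleast_2d(values)
    k = np.argmax(V, axis=1)
    K = V.shape[1]
    out = grid_log[k].astype(float)
    inner = (k > 0) & (k < K - 1)
    if np.any(inner):
        i = k[inner]
        rows = np.flatnonzero(inner)
        y0 = V[rows, i - 1]
        y1 = V[rows, i]
        y2 = V[rows, i + 1]
        x0, x1, x2 = grid_log[i - 1], grid_log[i], grid_log[i + 1]
        denom = (y0 - 2 * y1 + y2)
        ok = denom < -1e-12
        shift = np.zeros_like(y1)
        # vertex of the parabola on an (approximately) uniform grid
        shift[ok] = 0.5 * (y0[ok] - y2[ok]) / denom[ok] * (x2[ok] - x0[ok]) / 2.0
        shift = np.clip(shift, (x0 - x1), (x2 - x1))
        out[rows] = x1 + shift
    return out


def estimate_dispersions(counts: np.ndarray, design: np.ndarray,
                         offsets: np.ndarray, prior_weight: float = 10.0,
                         grid_range: tuple[float, float] = (1e-4, 10.0),
                         grid_points: int = 21) -> DispersionEstimates:
    """Common and tagwise NB dispersions via Cox-Reid APL on a log grid."""
    y = np.atleast_2d(np.asarray(counts, dtype=float))
    if np.any(y.sum(axis=1) == 0):
        raise ValueError("all-zero gene rows must be filtered before "
                         "dispersion estimation")
    N, p = np.asarray(design).shape
    if N - p < 2:
        raise ValueError("need >= 2 residual degrees of freedom")
    grid = np.geomspace(grid_range[0], grid_range[1], grid_points)
    grid_log = np.log(grid)
    apl = np.column_stack([
        adjusted_profile_loglik(y, design, offsets, phi) for phi in grid
    ])
    shared = apl.mean(axis=0)
    common = float(np.exp(_interp_argmax(grid_log, shared[None, :])[0]))
    score = apl + prior_weight * shared[None, :]
    tagwise = np.exp(_interp_argmax(grid_log, score))
    return DispersionEstimates(common=common, tagwise=tagwise,
                               prior_weight=prior_weight, grid=grid,
                               apl_grid=apl)


# ---------------------------------------------------------------------------
# testing and calling
# ---------------------------------------------------------------------------

def lrt_contrast(full: GLMFit, reduced: GLMFit) -> tuple[np.ndarray, np.ndarray]:
    """LRT statistic and chi-square p-value from nested fits."""
    p_full = full.design.shape[1]
    p_red = reduced.design.shape[1]
    df = np.linalg.matrix_rank(full.design) - np.linalg.matrix_rank(reduced.design)
    if df <= 0:
        raise ValueError("reduced design must be strictly nested in the full design")
    # nesting check: reduced columns must lie in the span of the full design
    proj, *_ = np.linalg.lstsq(full.design, reduced.design, rcond=None)
    if not np.allclose(full.design @ proj, reduced.design, atol=1e-8):
        raise ValueError("designs are not nested")
    stat = np.maximum(reduced.deviance - full.deviance, 0.0)
    pval = stats.chi2.sf(stat, df)
    return stat, pval


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


def call_de(log2fc: np.ndarray, q: np.ndarray, alpha: float = 0.05,
            fc_threshold: float = 1.0) -> np.ndarray:
    """'up'/'down'/'ns' calls; both thresholds are strict inequalities."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    log2fc = np.asarray(log2fc, dtype=float)
    q = np.asarray(q, dtype=float)
    call = np.full(log2fc.shape, "ns", dtype=object)
    sig = q < alpha
    call[sig & (log2fc > fc_threshold)] = "up"
    call[sig & (log2fc < -fc_threshold)] = "down"
    return call


@dataclass
class DEResult:
    """Per-gene test results for one named contrast."""

    contrast: str
    table: pd.DataFrame  # gene, log2fc, mean_logcpm, lr, p, q, call
    alpha: float
    fc_threshold: float

    def called_genes(self) -> set[str]:
        return set(self.table.loc[self.table["call"] != "ns", "gene"])

    def gene_set(self) -> set[str]:
        return set(self.table["gene"])


# ---------------------------------------------------------------------------
# contrast orchestration for the regime x sex design
# ---------------------------------------------------------------------------

def _group_design(regime: np.ndarray, sex: np.ndarray) -> tuple[np.ndarray, list[str]]:
    """One-hot means design over the four regime x sex groups."""
    labels = [f"{r}{s}" for r, s in zip(regime, sex)]
    levels = ["EF", "EM", "LF", "LM"]
    X = np.column_stack([[1.0 if l == lev else 0.0 for l in labels]
                         for lev in levels])
    present = X.sum(axis=0) > 0
    if not present.all():
        raise ValueError("all four regime x sex groups must be present")
    return X, levels


_CONTRAST_VECTORS = {
    # L minus E within sex; M minus F within regime; order EF, EM, LF, LM
    "regime_in_F": np.array([-1.0, 0.0, 1.0, 0.0]),
    "regime_in_M": np.array([0.0, -1.0, 0.0, 1.0]),
    "sex_in_E": np.array([-1.0, 1.0, 0.0, 0.0]),
    "sex_in_L": np.array([0.0, 0.0, -1.0, 1.0]),
    # interaction: (LM - EM) - (LF - EF)
    "interaction": np.array([1.0, -1.0, -1.0, 1.0]),
}


def _reduced_design(X: np.ndarray, contrast: str) -> np.ndarray:
    merge = {
        "regime_in_F": (0, 2), "regime_in_M": (1, 3),
        "sex_in_E": (0, 1), "sex_in_L": (2, 3),
    }
    if contrast == "interaction":
        # additive model: intercept + male + late
        male = X[:, 1] + X[:, 3]
        late = X[:, 2] + X[:, 3]
        return np.column_stack([np.ones(X.shape[0]), male, late])
    i, j = merge[contrast]
    keep = [k for k in range(4) if k not in (i, j)]
    merged = X[:, i] + X[:, j]
    return np.column_stack([merged] + [X[:, k] for k in keep])


def run_contrast(dataset: CountDataset, normalized: NormalizedDataset,
                 contrast: str, dispersions: DispersionEstimates | None = None,
                 alpha: float = 0.05, fc_threshold: float = 1.0,
                 prior_count: float = 0.5,
                 prior_weight: float = 10.0) -> DEResult:
    """Fit the four-group NB GLM on one tissue subset and test a contrast.

    ``dataset`` must already be restricted to a single tissue and filtered;
    ``normalized`` must match its genes and samples.
    """
    if contrast not in CONTRASTS:
        raise ValueError(f"unknown contrast {contrast!r}")
    if list(normalized.gene_ids) != list(dataset.gene_ids):
        raise ValueError("normalized genes do not match dataset")
    tissues = set(dataset.factor("tissue"))
    if len(tissues) != 1:
        raise ValueError("run_contrast expects a single-tissue dataset")

    X, _ = _group_design(dataset.factor("regime"), dataset.factor("sex"))
    offsets = np.log(normalized.effective_lib_sizes)
    counts = dataset.counts

    if dispersions is None:
        dispersions = estimate_dispersions(counts, X, offsets,
                                           prior_weight=prior_weight)
    phi = dispersions.tagwise

    full = fit_nbglm(counts, X, offsets, phi)
    reduced = fit_nbglm(counts, _reduced_design(X, contrast), offsets, phi)
    stat, pval = lrt_contrast(full, reduced)

    # prior-count-stabilized logFC: augment counts in proportion to library
    # size, refit at the same dispersions, contrast the coefficients
    eff = normalized.effective_lib_sizes
    prior = prior_count * eff / eff.mean()
    aug = counts + prior[None, :]
    fc_fit = fit_nbglm(aug, X, offsets, phi)
    cvec = _CONTRAST_VECTORS[contrast]
    log2fc = (fc_fit.coef @ cvec) / np.log(2.0)

    bad = ~(full.converged & reduced.converged)
    if np.any(bad):
        warnings.warn(
            f"{int(bad.sum())} gene(s) failed to converge; excluded from calls")
        pval = pval.copy()
        pval[bad] = 1.0
        stat = stat.copy()
        stat[bad] = 0.0

    q = bh_adjust(pval)
    call = call_de(log2fc, q, alpha=alpha, fc_threshold=fc_threshold)
    call[bad] = "ns"

    table = pd.DataFrame({
        "gene": dataset.gene_ids,
        "log2fc": log2fc,
        "mean_logcpm": normalized.mean_logcpm(),
        "lr": stat,
        "p": pval,
        "q": q,
        "call": call,
    })
    return DEResult(contrast=contrast, table=table, alpha=alpha,
                    fc_threshold=fc_threshold)
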
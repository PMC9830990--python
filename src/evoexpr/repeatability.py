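"""Multivariate repeatability of expression divergence.

Samples are ordinated by PCA of the centered (not scaled) log2-cpm matrix.
For a regime x sex x tissue group, repeatability is

    R = D / (D + d)

where D is the Euclidean distance between the E and L centroids of the
group's sex x tissue stratum in the retained component space and d is the
mean distance of the group's replicate samples to their own centroid.
Confidence intervals come from a gene bootstrap: genes are resampled with
replacement and the whole ordination plus R is recomputed per replicate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .normalize import NormalizedDataset

__all__ = ["Ordination", "RepeatabilityEstimate", "ordinate_pca",
           "repeatability_R", "bootstrap_ci", "repeatability_table"]


@dataclass
class Ordination:
    sample_ids: list[str]
    scores: np.ndarray              # samples x k
    explained: np.ndarray           # variance fractions, length k
    groups: dict[str, tuple[str, str, str]]  # sample -> (regime, sex, tissue)

    def group_members(self, regime: str, sex: str, tissue: str) -> np.ndarray:
        return np.array([
            i for i, s in enumerate(self.sample_ids)
            if self.groups[s] == (regime, sex, tissue)
        ])

    def centroid(self, regime: str, sex: str, tissue: str) -> np.ndarray:
        idx = self.group_members(regime, sex, tissue)
        if idx.size == 0:
            raise ValueError(f"no samples in group ({regime}, {sex}, {tissue})")
        return self.scores[idx].mean(axis=0)


@dataclass
class RepeatabilityEstimate:
    regime: str
    sex: str
    tissue: str
    R: float
    D: float
    d: float
    ci_low: float | None = None
    ci_high: float | None = None
    n_boot: int = 0


def _pca_scores(matrix: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Scores and explained-variance fractions from a samples x features matrix."""
    n = matrix.shape[0]
    centered = matrix - matrix.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(centered, full_matrices=False)
    # fix signs for determinism: largest-magnitude loading positive
    scores = u * s
    for j in range(scores.shape[1]):
        i = np.argmax(np.abs(scores[:, j]))
        if scores[i, j] < 0:
            scores[:, j] = -scores[:, j]
    var = s ** 2
    total = var.sum()
    explained = var / total if total > 0 else np.zeros_like(var)
    return scores[:, :k], explained[:k]


def ordinate_pca(normalized: NormalizedDataset, design_lookup, k: int = 16) -> Ordination:
    """PCA ordination of all samples from the log2-cpm matrix.

    ``design_lookup`` maps sample id to an object with regime/sex/tissue
    attributes (e.g. ``CountDataset.design``). ``k`` retained components;
    capped errors if it exceeds min(samples - 1, genes).
    """
    mat = normalized.logcpm.T  # samples x genes
    n, g = mat.shape
    if k > min(n - 1, g):
        raise ValueError(f"k={k} exceeds min(samples - 1, genes) = {min(n - 1, g)}")
    scores, explained = _pca_scores(mat, k)
    groups = {
        s: (design_lookup[s].regime, design_lookup[s].sex, design_lookup[s].tissue)
        for s in normalized.sample_ids
    }
    return Ordination(sample_ids=list(normalized.sample_ids), scores=scores,
                      explained=explained, groups=groups)


def repeatability_R(ordination: Ordination, regime: str, sex: str,
                    tissue: str) -> RepeatabilityEstimate:
    """Point estimate of R for one regime x sex x tissue group (no CI)."""
    idx = ordination.group_members(regime, sex, tissue)
    if idx.size < 2:
        raise ValueError(
            f"group ({regime}, {sex}, {tissue}) has {idx.size} replicate "
            "sample(s); need >= 2")
    cent_e = ordination.centroid("E", sex, tissue)
    cent_l = ordination.centroid("L", sex, tissue)
    D = float(np.linalg.norm(cent_e - cent_l))
    own = ordination.centroid(regime, sex, tissue)
    d = float(np.mean(np.linalg.norm(ordination.scores[idx] - own, axis=1)))
    R = 0.0 if (D + d) == 0 else D / (D + d)
    return RepeatabilityEstimate(regime=regime, sex=sex, tissue=tissue,
                                 R=R, D=D, d=d)


def bootstrap_ci(normalized: NormalizedDataset, design_lookup, regime: str,
                 sex: str, tissue: str, k: int = 16, n_boot: int = 1000,
                 seed: int = 0, refit_pca: bool = True) -> RepeatabilityEstimate:
    """Percentile 95% CI for R by resampling genes with replacement."""
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    base_ord = ordinate_pca(normalized, design_lookup, k=k)
    est = repeatability_R(base_ord, regime, sex, tissue)
    rng = np.random.default_rng(seed)
    G = normalized.logcpm.shape[0]
    reps = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, G, size=G)
        if refit_pca:
            boot = NormalizedDataset(
                gene_ids=[normalized.gene_ids[i] for i in idx],
                sample_ids=list(normalized.sample_ids),
                factors=normalized.factors,
                lib_sizes=normalized.lib_sizes,
                effective_lib_sizes=normalized.effective_lib_sizes,
                logcpm=normalized.logcpm[idx],
            )
            ordn = ordinate_pca(boot, design_lookup, k=k)
        else:
            ordn = base_ord
        reps[b] = repeatability_R(ordn, regime, sex, tissue).R
    lo, hi = np.percentile(reps, [2.5, 97.5])
    return RepeatabilityEstimate(regime=regime, sex=sex, tissue=tissue,
                                 R=est.R, D=est.D, d=est.d,
                                 ci_low=float(lo), ci_high=float(hi),
                                 n_boot=n_boot)


def repeatability_table(normalized: NormalizedDataset, design_lookup,
                        k: int = 16, n_boot: int = 0,
                        seed: int = 0) -> list[RepeatabilityEstimate]:
    """Estimates for every regime x sex x tissue group present in the data."""
    ordn = ordinate_pca(normalized, design_lookup, k=k)
    seen = sorted(set(ordn.groups.values()))
    out = []
    for regime, sex, tissue in seen:
        if n_boot:
            out.append(bootstrap_ci(normalized, design_lookup, regime, sex,
                                    tissue, k=k, n_boot=n_boot, seed=seed))
        else:
            out.append(repeatability_R(ordn, regime, sex, tissue))
    return out
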
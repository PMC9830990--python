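"""Expression filtering, cpm, TMM scaling factors, and log2-cpm matrices.

TMM follows the standard recipe: the reference sample is the one whose
75th-percentile cpm is closest to the mean 75th percentile; per sample the
log2 ratios (M) and average log2 abundances (A) are computed over genes
positive in both sample and reference, the extreme 30% of M values and 5%
of A values are trimmed, and the factor is two to the precision-weighted
mean of the surviving M values. Factors are rescaled to geometric mean 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datamodel import CountDataset

__all__ = [
    "NormalizedDataset",
    "compute_cpm",
    "filter_genes",
    "tmm_factors",
    "logcpm_matrix",
]


@dataclass
class NormalizedDataset:
    gene_ids: list[str]
    sample_ids: list[str]
    factors: np.ndarray          # TMM scaling factor per sample
    lib_sizes: np.ndarray        # raw library sizes
    effective_lib_sizes: np.ndarray
    logcpm: np.ndarray           # genes x samples log2-cpm, prior applied

    def __post_init__(self) -> None:
        if np.any(self.factors <= 0):
            raise ValueError("scaling factors must be positive")
        gm = np.exp(np.mean(np.log(self.factors)))
        if abs(gm - 1.0) > 1e-8:
            raise ValueError(f"geometric mean of factors is {gm}, expected 1")

    def mean_logcpm(self) -> np.ndarray:
        return self.logcpm.mean(axis=1)


def compute_cpm(dataset: CountDataset, factors: np.ndarray | None = None) -> np.ndarray:
    """Counts per million; with ``factors`` uses effective library sizes."""
    lib = dataset.library_sizes()
    if factors is not None:
        lib = lib * np.asarray(factors, dtype=float)
    if np.any(lib <= 0):
        raise ValueError("zero library size")
    return dataset.counts / (lib / 1e6)


def filter_genes(dataset: CountDataset, min_samples: int = 3,
                 cpm_threshold: float = 2.0) -> CountDataset:
    """Keep genes with raw cpm strictly above the threshold in enough samples.

    The cpm uses the original library sizes; they are not recomputed after
    dropping genes (single pass), so the operation is idempotent.
    """
    cpm = dataset.counts / (dataset.library_sizes() / 1e6)
    keep = (cpm > cpm_threshold).sum(axis=1) >= min_samples
    return dataset.subset_genes(keep)


def _tmm_pair(obs: np.ndarray, ref: np.ndarray, obs_lib: float, ref_lib: float,
              trim_m: float = 0.30, trim_a: float = 0.05) -> float:
    """log2 TMM factor of one sample against the reference."""
    both = (obs > 0) & (ref > 0)
    if not np.any(both):
        raise ValueError("sample shares no positive genes with the reference")
    p_obs = obs[both] / obs_lib
    p_ref = ref[both] / ref_lib
    m = np.log2(p_obs / p_ref)
    a = 0.5 * np.log2(p_obs * p_ref)
    # asymptotic variance of M from the binomial delta method
    w = (obs_lib - obs[both]) / (obs_lib * obs[both]) + \
        (ref_lib - ref[both]) / (ref_lib * ref[both])

    finite = np.isfinite(m) & np.isfinite(a)
    m, a, w = m[finite], a[finite], w[finite]
    if m.size == 0:
        return 0.0
    if np.max(np.abs(m)) < 1e-6:
        return 0.0

    n = m.size
    lo_m, hi_m = np.floor(n * trim_m) + 1, n + 1 - (np.floor(n * trim_m) + 1)
    lo_a, hi_a = np.floor(n * trim_a) + 1, n + 1 - (np.floor(n * trim_a) + 1)
    rank_m = np.argsort(np.argsort(m, kind="stable"), kind="stable") + 1
    rank_a = np.argsort(np.argsort(a, kind="stable"), kind="stable") + 1
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not np.any(keep):
        return 0.0
    return float(np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep]))


def tmm_factors(dataset: CountDataset, trim_m: float = 0.30,
                trim_a: float = 0.05) -> np.ndarray:
    """Per-sample TMM scaling factors with geometric mean 1."""
    counts = dataset.counts.astype(float)
    if counts.shape[1] < 2:
        raise ValueError("TMM requires at least 2 samples")
    lib = dataset.library_sizes()
    if np.any((counts > 0).sum(axis=0) == 0):
        raise ValueError("a sample has no positive counts")
    cpm = counts / (lib / 1e6)
    q75 = np.quantile(cpm, 0.75, axis=0)
    ref_idx = int(np.argmin(np.abs(q75 - q75.mean())))
    log_factors = np.empty(counts.shape[1])
    for j in range(counts.shape[1]):
        if j == ref_idx:
            log_factors[j] = 0.0
            continue
        try:
            log_factors[j] = _tmm_pair(counts[:, j], counts[:, ref_idx],
                                       lib[j], lib[ref_idx], trim_m, trim_a)
        except ValueError as exc:
            raise ValueError(
                f"sample {dataset.sample_ids[j]!r}: {exc}") from exc
    factors = np.exp2(log_factors)
    return factors / np.exp(np.mean(np.log(factors)))


def logcpm_matrix(dataset: CountDataset, factors: np.ndarray | None = None,
                  prior_count: float = 0.5) -> NormalizedDataset:
    """log2-cpm with a library-size-scaled prior count; finite everywhere."""
    if prior_count <= 0:
        raise ValueError("prior_count must be > 0")
    lib = dataset.library_sizes()
    if factors is None:
        factors = tmm_factors(dataset)
    factors = np.asarray(factors, dtype=float)
    eff = lib * factors
    # prior in cpm units, scaled proportionally to each effective library
    # size: log-cpm is then invariant to rescaling counts and library together
    prior = prior_count * eff / 1e6
    logcpm = np.log2((dataset.counts + prior) / (eff + 2.0 * prior) * 1e6)
    return NormalizedDataset(
        gene_ids=list(dataset.gene_ids),
        sample_ids=list(dataset.sample_ids),
        factors=factors,
        lib_sizes=lib,
        effective_lib_sizes=eff,
        logcpm=logcpm,
    )
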
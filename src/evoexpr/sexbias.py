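"""Sex-bias classification and downstream comparisons.

A gene is female-biased (FB) or male-biased (MB) in a regime when the
male-minus-female contrast in that regime is significant at the q and
fold-change thresholds; unbiased (UB) otherwise. Built on top of that:
DE-set overlap accounting, two-proportion chi-square tests, enrichment of
gene classes among DE genes, Brown-Mood median tests with bootstrap CIs,
cross-regime sex-bias correlation, homology best-hit selection, candidate
enrichment, and plain hypergeometric term enrichment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import GeneSetMap, HomologyHitTable
from .de import DEResult, bh_adjust

__all__ = [
    "SexBiasTable", "OverlapTable", "EnrichmentResult", "MedianTestResult",
    "classify_sex_bias", "overlap_table", "proportion_test",
    "sexbias_de_enrichment", "median_difference_test", "sexbias_correlation",
    "best_hit_selection", "candidate_enrichment", "term_enrichment",
    "pearson_chi2",
]


# ---------------------------------------------------------------------------
# sex-bias classification
# ---------------------------------------------------------------------------

@dataclass
class SexBiasTable:
    """Per-gene FB/MB/UB class per regime; logFC sign is male minus female."""

    table: pd.DataFrame  # gene, class_E, class_L, log2fc_E, log2fc_L, biased_either

    def genes_in_class(self, regime: str, cls: str) -> set[str]:
        col = f"class_{regime}"
        return set(self.table.loc[self.table[col] == cls, "gene"])

    def biased_union(self) -> set[str]:
        return set(self.table.loc[self.table["biased_either"], "gene"])


def _bias_class(log2fc: np.ndarray, q: np.ndarray, alpha: float,
                fc: float) -> np.ndarray:
    out = np.full(log2fc.shape, "UB", dtype=object)
    sig = q < alpha
    out[sig & (log2fc < -fc)] = "FB"
    out[sig & (log2fc > fc)] = "MB"
    return out


def classify_sex_bias(de_sex_E: DEResult, de_sex_L: DEResult,
                      alpha: float = 0.05, fc: float = 1.0) -> SexBiasTable:
    """Classify each gene as FB/MB/UB per regime from the two sex contrasts."""
    te = de_sex_E.table.set_index("gene")
    tl = de_sex_L.table.set_index("gene")
    if set(te.index) != set(tl.index):
        raise ValueError("the two sex-contrast results cover different genes")
    tl = tl.loc[te.index]
    cls_e = _bias_class(te["log2fc"].to_numpy(), te["q"].to_numpy(), alpha, fc)
    cls_l = _bias_class(tl["log2fc"].to_numpy(), tl["q"].to_numpy(), alpha, fc)
    table = pd.DataFrame({
        "gene": te.index,
        "class_E": cls_e,
        "class_L": cls_l,
        "log2fc_E": te["log2fc"].to_numpy(),
        "log2fc_L": tl["log2fc"].to_numpy(),
        "biased_either": (cls_e != "UB") | (cls_l != "UB"),
    }).reset_index(drop=True)
    return SexBiasTable(table=table)


# ---------------------------------------------------------------------------
# overlap accounting
# ---------------------------------------------------------------------------

@dataclass
class OverlapTable:
    female_only: int
    male_only: int
    both: int
    neither: int

    @property
    def union(self) -> int:
        return self.female_only + self.male_only + self.both


def overlap_table(de_F: DEResult | set, de_M: DEResult | set,
                  universe: set | None = None,
                  restrict_to: set | None = None) -> OverlapTable:
    """Cross-classify genes by whether they are called in each sex.

    Accepts DEResult objects (universe inferred from their gene sets) or
    raw call sets (universe must then be given explicitly or defaults to
    the union of the call sets).
    """
    if isinstance(de_F, DEResult):
        calls_f = de_F.called_genes()
        uni = de_F.gene_set()
    else:
        calls_f = set(de_F)
        uni = None
    if isinstance(de_M, DEResult):
        calls_m = de_M.called_genes()
        uni_m = de_M.gene_set()
        if uni is not None and uni != uni_m:
            raise ValueError("female and male results cover different universes")
        uni = uni_m if uni is None else uni
    else:
        calls_m = set(de_M)
    if universe is not None:
        uni = set(universe)
    if uni is None:
        uni = calls_f | calls_m
    if restrict_to is not None:
        uni = uni & set(restrict_to)
        calls_f = calls_f & uni
        calls_m = calls_m & uni
    both = len(calls_f & calls_m)
    f_only = len(calls_f - calls_m)
    m_only = len(calls_m - calls_f)
    neither = len(uni) - both - f_only - m_only
    return OverlapTable(female_only=f_only, male_only=m_only, both=both,
                        neither=neither)


# ---------------------------------------------------------------------------
# chi-square machinery
# ---------------------------------------------------------------------------

def pearson_chi2(table: np.ndarray, correction: bool = False) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table; optional Yates correction."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if np.any(t < 0):
        raise ValueError("negative cell count")
    row = t.sum(axis=1)
    col = t.sum(axis=0)
    n = t.sum()
    if np.any(row == 0) or np.any(col == 0):
        raise ValueError("empty margin in contingency table")
    expected = np.outer(row, col) / n
    diff = np.abs(t - expected)
    if correction:
        diff = np.maximum(diff - 0.5, 0.0)
    chi2 = float(np.sum(diff ** 2 / expected))
    p = float(stats.chi2.sf(chi2, df=1))
    return chi2, p


def proportion_test(x1: int, n1: int, x2: int, n2: int,
                    correction: bool = False) -> tuple[float, int, float]:
    """Two-proportion Pearson chi-square (df = 1)."""
    for x, n in ((x1, n1), (x2, n2)):
        if n <= 0:
            raise ValueError("group sizes must be positive")
        if not 0 <= x <= n:
            raise ValueError("successes must lie in [0, n]")
    table = np.array([[x1, n1 - x1], [x2, n2 - x2]], dtype=float)
    if x1 / n1 == x2 / n2:
        return 0.0, 1, 1.0
    chi2, p = pearson_chi2(table, correction=correction)
    return chi2, 1, p


def sexbias_de_enrichment(sexbias: SexBiasTable, de_union: set, universe: set,
                          cls: str, regime: str = "E") -> tuple[float, float, float]:
    """Chi-square of class membership vs DE membership over the universe.

    Returns (chi2, p, odds_ratio). ``cls`` is 'FB' or 'MB'; membership uses
    the given regime's classification.
    """
    if cls not in ("FB", "MB"):
        raise ValueError("cls must be 'FB' or 'MB'")
    if not de_union <= universe:
        raise ValueError("de_union must be a subset of the universe")
    in_class = sexbias.genes_in_class(regime, cls) & universe
    if not in_class:
        raise ValueError(f"no {cls} genes in the universe (degenerate)")
    a = len(in_class & de_union)
    b = len(in_class - de_union)
    c = len(de_union - in_class)
    d = len(universe) - a - b - c
    chi2, p = pearson_chi2(np.array([[a, b], [c, d]]))
    odds = (a * d) / (b * c) if b * c > 0 else np.inf
    return chi2, p, odds


# ---------------------------------------------------------------------------
# median tests and correlation
# ---------------------------------------------------------------------------

@dataclass
class MedianTestResult:
    z: float
    p: float
    ci_low: float
    ci_high: float
    median_diff: float


def median_difference_test(expr_E: np.ndarray, expr_L: np.ndarray,
                           n_boot: int = 10000, seed: int = 0) -> MedianTestResult:
    """Brown-Mood two-sample median test with a bootstrap CI.

    Z is signed: positive when the E median exceeds the L median. The CI is
    a percentile bootstrap of median(E) - median(L) resampling each vector
    independently.
    """
    x = np.asarray(expr_E, dtype=float)
    y = np.asarray(expr_L, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty input vector")
    pooled = np.concatenate([x, y])
    med = np.median(pooled)
    diff = float(np.median(x) - np.median(y))

    a = int(np.sum(x > med))   # E above pooled median
    b = int(np.sum(y > med))
    n1, n2 = x.size, y.size
    t = a + b
    n = n1 + n2
    if t == 0 or t == n:
        import warnings
        warnings.warn("all values tie with the pooled median; degenerate test")
        z, p = 0.0, 1.0
    else:
        # hypergeometric normal approximation for the count above the median
        mean_a = n1 * t / n
        var_a = n1 * n2 * t * (n - t) / (n ** 2 * (n - 1))
        z = float((a - mean_a) / np.sqrt(var_a)) if var_a > 0 else 0.0
        p = float(2.0 * stats.norm.sf(abs(z)))
        p = min(p, 1.0)

    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        bx = x[rng.integers(0, n1, size=n1)]
        by = y[rng.integers(0, n2, size=n2)]
        boots[i] = np.median(bx) - np.median(by)
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return MedianTestResult(z=z, p=p, ci_low=float(lo), ci_high=float(hi),
                            median_diff=diff)


def sexbias_correlation(sexbias: SexBiasTable) -> dict:
    """Pearson correlation of sex-bias logFC between regimes on biased genes.

    Computed over the union of genes sex-biased in either regime; the CI is
    via the Fisher z transform; df = n - 2.
    """
    sub = sexbias.table[sexbias.table["biased_either"]]
    n = len(sub)
    if n < 3:
        raise ValueError(f"need >= 3 biased genes, got {n}")
    x = sub["log2fc_E"].to_numpy()
    y = sub["log2fc_L"].to_numpy()
    r, p = stats.pearsonr(x, y)
    df = n - 2
    z = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    se = 1.0 / np.sqrt(n - 3)
    zcrit = stats.norm.ppf(0.975)
    ci = (float(np.tanh(z - zcrit * se)), float(np.tanh(z + zcrit * se)))
    return {"r": float(r), "df": df, "ci": ci, "p": float(p), "n": n}


# ---------------------------------------------------------------------------
# homology candidates and enrichment
# ---------------------------------------------------------------------------

def best_hit_selection(hits: HomologyHitTable) -> pd.DataFrame:
    """Best subject per query: minimal e-value, ties by maximal bit score.

    Remaining ties resolve to the first occurrence (stable).
    """
    df = hits.rows
    if df.empty:
        return df.iloc[0:0].copy()
    df = df.reset_index(drop=True)
    df["_order"] = np.arange(len(df))
    best = (df.sort_values(["e_value", "bit_score", "_order"],
                           ascending=[True, False, True], kind="stable")
              .groupby("query_id", sort=False)
              .head(1)
              .sort_values("_order")
              .drop(columns="_order")
              .reset_index(drop=True))
    return best


def candidate_enrichment(candidates: set, de_union: set,
                         universe: set) -> tuple[float, float]:
    """Chi-square of candidate membership vs DE membership."""
    if not candidates:
        raise ValueError("empty candidate set")
    if not candidates <= universe or not de_union <= universe:
        raise ValueError("candidates and de_union must be subsets of the universe")
    a = len(candidates & de_union)
    b = len(candidates - de_union)
    c = len(de_union - candidates)
    d = len(universe) - a - b - c
    return pearson_chi2(np.array([[a, b], [c, d]]))


@dataclass
class EnrichmentResult:
    table: pd.DataFrame
    # columns: term, overlap, term_size, selected_size, universe_size,
    # odds_ratio, p, q


def term_enrichment(selected: set, universe: set,
                    terms: GeneSetMap) -> EnrichmentResult:
    """One-sided hypergeometric upper-tail enrichment per term, BH adjusted.

    Term gene sets are intersected with the universe; terms with an empty
    intersection are skipped.
    """
    if not selected <= universe:
        raise ValueError("selected genes must be a subset of the universe")
    N = len(universe)
    n_sel = len(selected)
    rows = []
    for term, members in terms.sets.items():
        in_uni = members & universe
        if not in_uni:
            continue
        K = len(in_uni)
        k = len(in_uni & selected)
        # P[X >= k], X ~ Hypergeometric(N, K, n_sel)
        p = float(stats.hypergeom.sf(k - 1, N, K, n_sel))
        denom = (K - k) * (n_sel - k)
        num = k * (N - K - n_sel + k)
        odds = num / denom if denom > 0 else np.inf
        rows.append((term, k, K, n_sel, N, odds, p))
    df = pd.DataFrame(rows, columns=["term", "overlap", "term_size",
                                     "selected_size", "universe_size",
                                     "odds_ratio", "p"])
    df["q"] = bh_adjust(df["p"].to_numpy()) if len(df) else np.array([])
    return EnrichmentResult(table=df)
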
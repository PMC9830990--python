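"""Replicated experimental-evolution count simulation with ground truth.

Counts are drawn from a negative-binomial model on relative expression:

    count[g, s] ~ NB(mean = L_s * 2**eta[g, s] / sum_g 2**eta[g, s], phi_g)

with ``eta`` built from a per-gene baseline, a tissue shift, a sex effect,
a per-sex regime effect, and a per-line random effect. Effects are sparse
and recorded in a truth table so downstream inference can be scored.

Sign convention used throughout the package: log fold changes are
male minus female (so female-biased means negative) and L minus E for the
regime contrast.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .datamodel import CountDataset, SampleInfo, TISSUES

__all__ = ["SimulationConfig", "TruthTable", "simulate_dataset", "simulate_null"]


@dataclass
class SimulationConfig:
    n_genes: int = 17000
    n_lines_per_regime: int = 4
    tissues: tuple[str, ...] = TISSUES
    library_size_range: tuple[float, float] = (5e6, 2e7)
    baseline_log2_mean: float = 5.0
    baseline_log2_sd: float = 2.0
    dispersion_median: float = 0.05
    dispersion_log_sd: float = 0.5
    frac_sex_biased: dict[str, float] = field(
        default_factory=lambda: {"abdomen": 0.35, "head_thorax": 0.05}
    )
    frac_regime_de: float = 0.06
    frac_interaction: float = 0.005
    effect_size_rate: float = 1.0  # |log2FC| ~ 1 + Exponential(rate)
    effect_size_fixed: float | None = None  # overrides the draw when set
    sigma_line: float = 0.15
    rng_seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.n_lines_per_regime < 1:
            raise ValueError("n_lines_per_regime must be >= 1")
        for t in self.tissues:
            if t not in TISSUES:
                raise ValueError(f"unknown tissue {t!r}")
        lo, hi = self.library_size_range
        if lo <= 0 or hi < lo:
            raise ValueError("library_size_range must be positive and ordered")
        for name, frac in {
            **{f"frac_sex_biased[{t}]": v for t, v in self.frac_sex_biased.items()},
            "frac_regime_de": self.frac_regime_de,
            "frac_interaction": self.frac_interaction,
        }.items():
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {frac}")
        if self.sigma_line < 0:
            raise ValueError("sigma_line must be >= 0")
        if self.dispersion_median < 0:
            raise ValueError("dispersion_median must be >= 0")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["tissues"] = list(self.tissues)
        d["library_size_range"] = list(self.library_size_range)
        return d


@dataclass
class TruthTable:
    """Per-gene ground truth for one simulated dataset."""

    table: pd.DataFrame
    # columns: gene, dispersion, and per tissue: sexbias_log2fc_E_<t>,
    # sexbias_log2fc_L_<t>, class_E_<t>, class_L_<t>,
    # regime_log2fc_F_<t>, regime_log2fc_M_<t>, interaction_<t>

    def genes_with_regime_effect(self, tissue: str, sex: str) -> set[str]:
        col = f"regime_log2fc_{sex}_{tissue}"
        mask = self.table[col] != 0.0
        return set(self.table.loc[mask, "gene"])

    def interaction_genes(self, tissue: str) -> set[str]:
        mask = self.table[f"interaction_{tissue}"]
        return set(self.table.loc[mask, "gene"])


def _classify(log2fc: np.ndarray) -> np.ndarray:
    out = np.full(log2fc.shape, "UB", dtype=object)
    out[log2fc <= -1.0] = "FB"
    out[log2fc >= 1.0] = "MB"
    # effects drawn from 1 + Exp are always |fc| > 1; zeros stay UB
    out[log2fc == 0.0] = "UB"
    return out


def _effect_sizes(rng: np.random.Generator, k: int, rate: float,
                  fixed: float | None) -> np.ndarray:
    if fixed is not None:
        return np.full(k, float(fixed))
    return 1.0 + rng.exponential(scale=1.0 / rate, size=k)


def _signed_effects(rng: np.random.Generator, n: int, k: int, rate: float,
                    fixed: float | None = None) -> np.ndarray:
    """Sparse vector with k nonzero signed effects, |effect| ~ 1 + Exp(rate)."""
    eff = np.zeros(n)
    if k == 0:
        return eff
    idx = rng.choice(n, size=k, replace=False)
    mag = _effect_sizes(rng, k, rate, fixed)
    sign = rng.choice([-1.0, 1.0], size=k)
    eff[idx] = sign * mag
    return eff


def simulate_dataset(config: SimulationConfig) -> tuple[CountDataset, TruthTable]:
    """Simulate counts plus ground truth under the full effect model."""
    return _simulate(config, null=False)


def simulate_null(config: SimulationConfig) -> tuple[CountDataset, TruthTable]:
    """Simulate with all sex/regime/interaction effects zeroed.

    Line random effects and per-gene dispersions are retained so the null
    keeps the correct noise structure.
    """
    return _simulate(config, null=True)


def _simulate(config: SimulationConfig, null: bool) -> tuple[CountDataset, TruthTable]:
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    G = config.n_genes
    nl = config.n_lines_per_regime
    genes = [f"g{i:05d}" for i in range(G)]

    baseline = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, size=G)
    if config.dispersion_median > 0:
        phi = np.exp(rng.normal(np.log(config.dispersion_median),
                                config.dispersion_log_sd, size=G))
    else:
        phi = np.zeros(G)
    # mild tissue shift so the two tissues are distinguishable ordinations
    tissue_shift = {t: rng.normal(0.0, 0.3, size=G) for t in config.tissues}

    truth_cols: dict[str, np.ndarray] = {
        "gene": np.array(genes), "dispersion": phi, "baseline_log2": baseline,
    }

    sex_eff: dict[str, np.ndarray] = {}
    regime_eff: dict[tuple[str, str], np.ndarray] = {}
    interaction: dict[str, np.ndarray] = {}
    for t in config.tissues:
        k_sex = int(round(config.frac_sex_biased.get(t, 0.0) * G))
        se = _signed_effects(rng, G, k_sex, config.effect_size_rate,
                             config.effect_size_fixed)
        k_de = int(round(config.frac_regime_de * G))
        k_int = int(round(config.frac_interaction * G))
        shared = _signed_effects(rng, G, k_de, config.effect_size_rate,
                                 config.effect_size_fixed)
        int_mask = np.zeros(G, dtype=bool)
        if k_int:
            int_idx = rng.choice(G, size=k_int, replace=False)
            int_mask[int_idx] = True
        re_f = shared.copy()
        re_m = shared.copy()
        if k_int:
            # interaction genes get independent per-sex regime effects
            mag_f = _effect_sizes(rng, k_int, config.effect_size_rate,
                                  config.effect_size_fixed)
            mag_m = _effect_sizes(rng, k_int, config.effect_size_rate,
                                  config.effect_size_fixed)
            re_f[int_mask] = rng.choice([-1.0, 1.0], size=k_int) * mag_f
            re_m[int_mask] = rng.choice([-1.0, 1.0], size=k_int) * mag_m
        if null:
            se = np.zeros(G)
            re_f = np.zeros(G)
            re_m = np.zeros(G)
            int_mask = np.zeros(G, dtype=bool)
        sex_eff[t] = se
        regime_eff[("F", t)] = re_f
        regime_eff[("M", t)] = re_m
        interaction[t] = int_mask

        # sex-bias truth per regime: E regime bias = se; L regime bias differs
        # when the regime response differs between sexes
        bias_e = se
        bias_l = se + (re_m - re_f)
        truth_cols[f"sexbias_log2fc_E_{t}"] = bias_e
        truth_cols[f"sexbias_log2fc_L_{t}"] = bias_l
        truth_cols[f"class_E_{t}"] = _classify(bias_e)
        truth_cols[f"class_L_{t}"] = _classify(bias_l)
        truth_cols[f"regime_log2fc_F_{t}"] = re_f
        truth_cols[f"regime_log2fc_M_{t}"] = re_m
        truth_cols[f"interaction_{t}"] = int_mask

    # line random effects: per gene x line, shared across that line's libraries
    lines = [("E", i + 1) for i in range(nl)] + [("L", i + 1) for i in range(nl)]
    line_eff = {
        rl: rng.normal(0.0, config.sigma_line, size=G) if config.sigma_line > 0
        else np.zeros(G)
        for rl in lines
    }

    sample_ids: list[str] = []
    design: dict[str, SampleInfo] = {}
    columns: list[np.ndarray] = []
    lo, hi = config.library_size_range
    for regime, line in lines:
        for sex in ("F", "M"):
            for tissue in config.tissues:
                sid = f"{regime}{line}_{sex}_{'abd' if tissue == 'abdomen' else 'ht'}"
                sample_ids.append(sid)
                design[sid] = SampleInfo(regime=regime, line=line, sex=sex,
                                         tissue=tissue)
                eta = baseline + tissue_shift[tissue] + line_eff[(regime, line)]
                if sex == "M":
                    eta = eta + sex_eff[tissue]
                if regime == "L":
                    eta = eta + regime_eff[(sex, tissue)]
                rel = np.exp2(eta)
                rel = rel / rel.sum()
                if lo == hi:
                    libsize = lo
                else:
                    libsize = np.exp(rng.uniform(np.log(lo), np.log(hi)))
                mu = libsize * rel
                if config.dispersion_median > 0:
                    # NB as gamma-poisson: shape 1/phi, scale mu*phi
                    lam = rng.gamma(shape=1.0 / phi, scale=mu * phi)
                    col = rng.poisson(lam)
                else:
                    col = rng.poisson(mu)
                columns.append(col)

    counts = np.column_stack(columns).astype(np.int64)
    dataset = CountDataset(gene_ids=genes, sample_ids=sample_ids,
                           counts=counts, design=design)
    truth = TruthTable(table=pd.DataFrame(truth_cols))
    return dataset, truth
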
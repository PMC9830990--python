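"""End-to-end orchestration: simulate, normalize, DE, repeatability,
sex-bias, and a machine-readable JSON summary.

The summary is a pure function of (config, seed): all randomness flows
through the config seed, and the JSON is written with sorted keys so
reruns are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import de as de_mod
from .datamodel import CountDataset, write_table
from .normalize import filter_genes, logcpm_matrix, tmm_factors
from .repeatability import repeatability_table
from .sexbias import classify_sex_bias, overlap_table, proportion_test
from .simulate import SimulationConfig, simulate_dataset, simulate_null

__all__ = ["PipelineConfig", "load_config", "run_pipeline"]

log = logging.getLogger("evoexpr")

_SIM_KEYS = {f.name for f in dataclasses.fields(SimulationConfig)}


@dataclass
class PipelineConfig:
    alpha: float = 0.05
    fc_threshold: float = 1.0
    pca_components: int = 16
    n_boot: int = 0
    seed: int = 0
    null: bool = False
    prior_weight: float = 10.0
    stages: tuple[str, ...] = ("simulate", "normalize", "de",
                               "repeatability", "sexbias")
    simulation: dict = field(default_factory=dict)

    def validate(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.fc_threshold < 0:
            raise ValueError("fc_threshold must be >= 0")
        if self.pca_components < 1:
            raise ValueError("pca_components must be >= 1")
        unknown = set(self.simulation) - _SIM_KEYS
        if unknown:
            raise ValueError(f"unknown simulation keys: {sorted(unknown)}")

    def simulation_config(self) -> SimulationConfig:
        kwargs = dict(self.simulation)
        kwargs.setdefault("rng_seed", self.seed)
        if "tissues" in kwargs:
            kwargs["tissues"] = tuple(kwargs["tissues"])
        if "library_size_range" in kwargs:
            kwargs["library_size_range"] = tuple(kwargs["library_size_range"])
        return SimulationConfig(**kwargs)


_KNOWN_KEYS = {f.name for f in dataclasses.fields(PipelineConfig)}


def load_config(path) -> PipelineConfig:
    """Load a YAML pipeline config; unknown keys are rejected by name."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError("config must be a YAML mapping")
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    if "stages" in raw:
        raw["stages"] = tuple(raw["stages"])
    cfg = PipelineConfig(**raw)
    cfg.validate()
    return cfg


def _de_summary(result) -> dict:
    calls = result.table["call"]
    return {
        "n_genes": int(len(result.table)),
        "n_up": int((calls == "up").sum()),
        "n_down": int((calls == "down").sum()),
        "n_called": int((calls != "ns").sum()),
    }


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run every enabled stage and write per-stage TSVs plus summary JSON."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: list[str] = []
    summary: dict = {"config": {
        "alpha": config.alpha, "fc_threshold": config.fc_threshold,
        "pca_components": config.pca_components, "n_boot": config.n_boot,
        "seed": config.seed, "null": config.null,
    }}

    def _finish_stage(name: str) -> None:
        manifest.append(name)
        (outdir / "MANIFEST").write_text("\n".join(manifest) + "\n")
        log.info("stage complete: %s", name)

    stage = "simulate"
    try:
        sim_cfg = config.simulation_config()
        simulate = simulate_null if config.null else simulate_dataset
        dataset, truth = simulate(sim_cfg)
        _write_dataset(dataset, outdir)
        write_table(truth.table, outdir / "truth.tsv")
        _finish_stage(stage)

        results: dict = {}
        tissues = sorted(set(dataset.factor("tissue")))
        de_results: dict = {}
        norm_all = None
        for tissue in tissues:
            stage = f"normalize[{tissue}]"
            sub = dataset.subset_samples(dataset.factor("tissue") == tissue)
            sub = filter_genes(sub)
            factors = tmm_factors(sub)
            norm = logcpm_matrix(sub, factors)
            write_table({"sample": norm.sample_ids,
                         "tmm_factor": factors,
                         "lib_size": norm.lib_sizes},
                        outdir / f"tmm_{tissue}.tsv")
            _finish_stage(stage)

            if "de" in config.stages:
                stage = f"de[{tissue}]"
                X, _ = de_mod._group_design(sub.factor("regime"),
                                            sub.factor("sex"))
                offsets = np.log(norm.effective_lib_sizes)
                disp = de_mod.estimate_dispersions(
                    sub.counts, X, offsets, prior_weight=config.prior_weight)
                for contrast in de_mod.CONTRASTS:
                    res = de_mod.run_contrast(
                        sub, norm, contrast, dispersions=disp,
                        alpha=config.alpha, fc_threshold=config.fc_threshold)
                    de_results[(tissue, contrast)] = res
                    write_table(res.table, outdir / f"de_{tissue}_{contrast}.tsv")
                    results.setdefault("de", {}).setdefault(tissue, {})[
                        contrast] = _de_summary(res)
                results.setdefault("dispersion", {})[tissue] = {
                    "common": disp.common,
                    "tagwise_median": float(np.median(disp.tagwise)),
                }
                _finish_stage(stage)

        if "repeatability" in config.stages:
            stage = "repeatability"
            full_filtered = filter_genes(dataset)
            norm_all = logcpm_matrix(full_filtered, tmm_factors(full_filtered))
            k = min(config.pca_components, len(norm_all.sample_ids) - 1)
            estimates = repeatability_table(norm_all, dataset.design, k=k,
                                            n_boot=config.n_boot,
                                            seed=config.seed)
            results["repeatability"] = [
                {"regime": e.regime, "sex": e.sex, "tissue": e.tissue,
                 "R": e.R, "D": e.D, "d": e.d,
                 "ci_low": e.ci_low, "ci_high": e.ci_high}
                for e in estimates
            ]
            write_table(
                {"regime": [e.regime for e in estimates],
                 "sex": [e.sex for e in estimates],
                 "tissue": [e.tissue for e in estimates],
                 "R": [e.R for e in estimates],
                 "D": [e.D for e in estimates],
                 "d": [e.d for e in estimates]},
                outdir / "repeatability.tsv")
            _finish_stage(stage)

        if "sexbias" in config.stages and "de" in config.stages:
            stage = "sexbias"
            for tissue in tissues:
                sb = classify_sex_bias(de_results[(tissue, "sex_in_E")],
                                       de_results[(tissue, "sex_in_L")],
                                       alpha=config.alpha,
                                       fc=config.fc_threshold)
                write_table(sb.table, outdir / f"sexbias_{tissue}.tsv")
                n = len(sb.table)
                counts = {
                    f"{cls}_{reg}": int((sb.table[f"class_{reg}"] == cls).sum())
                    for cls in ("FB", "MB") for reg in ("E", "L")
                }
                sb_summary = {"n_genes": n, **counts}
                for cls in ("FB", "MB"):
                    xe, xl = counts[f"{cls}_E"], counts[f"{cls}_L"]
                    if 0 < xe < n and 0 < xl < n:
                        chi2, _, p = proportion_test(xe, n, xl, n)
                        sb_summary[f"prop_test_{cls}"] = {"chi2": chi2, "p": p}
                ov = overlap_table(de_results[(tissue, "regime_in_F")],
                                   de_results[(tissue, "regime_in_M")])
                sb_summary["overlap"] = {
                    "female_only": ov.female_only, "male_only": ov.male_only,
                    "both": ov.both, "neither": ov.neither, "union": ov.union,
                }
                results.setdefault("sexbias", {})[tissue] = sb_summary
            _finish_stage(stage)

        summary["results"] = results
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    out = json.dumps(summary, sort_keys=True, indent=2, default=_json_default)
    (outdir / "summary.json").write_text(out + "\n")
    return summary


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _write_dataset(dataset: CountDataset, outdir: Path) -> None:
    import pandas as pd

    counts = pd.DataFrame(dataset.counts, index=dataset.gene_ids,
                          columns=dataset.sample_ids)
    counts.index.name = "gene"
    counts.to_csv(outdir / "counts.tsv", sep="\t")
    design = pd.DataFrame({
        "sample": dataset.sample_ids,
        "regime": [dataset.design[s].regime for s in dataset.sample_ids],
        "line": [dataset.design[s].line for s in dataset.sample_ids],
        "sex": [dataset.design[s].sex for s in dataset.sample_ids],
        "tissue": [dataset.design[s].tissue for s in dataset.sample_ids],
    })
    design.to_csv(outdir / "design.tsv", sep="\t", index=False)
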
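# evoexpr

Analysis toolkit for sex-specific transcriptome divergence in replicated
experimental-evolution designs: two selection regimes (E/L), replicate
lines, two sexes, and two tissue pools per line.

The package covers the full analysis chain on a gene × sample count matrix:

- **`evoexpr.datamodel`** — count/design/GMT/homology-table IO with strict
  validation (TSV in, TSV out).
- **`evoexpr.simulate`** — negative-binomial count simulator reproducing the
  design's statistical structure (sex-bias, regime, sex-by-regime
  interaction, and replicate-line effects), with a per-gene ground-truth
  table. Fully seeded and deterministic.
- **`evoexpr.normalize`** — cpm, expression filtering (> 2 cpm in ≥ 3
  samples), TMM scaling factors (30 % M-trim / 5 % A-trim,
  precision-weighted), and prior-count log2-cpm.
- **`evoexpr.de`** — log-link negative-binomial GLMs fitted by IRLS
  (vectorized across genes), Cox–Reid adjusted-profile-likelihood dispersion
  estimation (common + tagwise with shrinkage toward the common value),
  likelihood-ratio tests for regime-within-sex, sex-within-regime and
  interaction contrasts, Benjamini–Hochberg FDR, and calling at
  q < 0.05 with |log2FC| > 1 (both strict).
- **`evoexpr.repeatability`** — PCA ordination (covariance based), group
  centroids, the repeatability statistic R = D/(D + d) per
  regime × sex × tissue group, and gene-bootstrap percentile CIs.
- **`evoexpr.sexbias`** — FB/MB/UB classification per regime
  (logFC sign convention: male − female), DE-set overlap accounting,
  two-proportion chi-square tests, class-vs-DE enrichment, Brown–Mood
  median tests with bootstrap CIs, cross-regime sex-bias correlation,
  homology best-hit selection, candidate-gene enrichment, and plain
  hypergeometric term enrichment with BH adjustment.
- **`evoexpr.curves`** — bounded nonlinear least-squares fits of the
  saturating divergence model `Y = 1 + a(1 − b^X)` per sex and Welch-type
  between-sex comparison of the parameters.
- **`evoexpr.pipeline` / `evoexpr.cli`** — orchestration with YAML config,
  per-stage TSV outputs, a completed-stage MANIFEST, and a deterministic
  JSON summary.

## CLI

Every stage is available as a subcommand of `evoexpr`:

```sh
evoexpr simulate --seed 1 --outdir out/             # counts/design/truth TSVs
evoexpr normalize --counts out/counts.tsv --design out/design.tsv --outdir out/
evoexpr de --counts out/counts.tsv --design out/design.tsv \
    --tissue abdomen --contrast regime_in_F --out out/de.tsv
evoexpr repeatability --counts out/counts.tsv --design out/design.tsv \
    --seed 1 --out out/rep.tsv
evoexpr sexbias --de-sex-e out/de_E.tsv --de-sex-l out/de_L.tsv --out out/sb.tsv
evoexpr enrich --selected sel.txt --universe uni.txt --gmt terms.gmt --out out/go.tsv
evoexpr candidates --hits hits.tsv --candidates cand.txt \
    --de-genes de.txt --universe uni.txt --out out/cand.json
evoexpr curvefit --series lifespan.tsv --out out/curve.json
evoexpr all --seed 1 --outdir out/run                # full pipeline + summary.json
```

Contrast names: `regime_in_F`, `regime_in_M` (L − E within sex),
`sex_in_E`, `sex_in_L` (M − F within regime), and `interaction`.

## Notes on conventions

- Sex-bias log fold changes are male − female everywhere: FB ⇔ negative.
- Gene filtering uses raw (pre-TMM) cpm and a single pass; it is idempotent.
- Tagwise dispersion shrinkage uses a fixed prior weight (default 10
  genes-equivalent) toward the common dispersion, not an abundance trend.
- The bootstrap for repeatability resamples genes and refits the PCA per
  replicate (configurable).
- Term enrichment is a plain (non-conditional) hypergeometric upper tail.
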
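# chiralome

Downstream analysis toolkit for untargeted chiral (DATAN-derivatized)
LC-MS metabolomics, with metabolome–transcriptome integration.

The package covers the post-alignment stages of a small two-group chiral
metabolomics study:

* **Probabilistic quotient normalization (PQN)** against the median study
  spectrum, with QC pools normalized against the same reference.
* **Enantiomer-pair detection**: features whose m/z differ by < 5 ppm and
  whose retention times differ by < 3 min (both strict, configurable) are
  candidate enantiomer pairs; conflicts are resolved greedily by ascending
  ppm, then RT difference. Pair members get abundance-ordered E1/E2 labels
  (E1 = lower mean intensity).
* **Swap verification**: the (+)- and (−)-forms of the chiral derivatizing
  agent invert the elution order of a true enantiomer pair, so the E1/E2
  intensity ratio inverts between the plus- and minus-agent QC pools; a
  pair is `verified` when both log-ratios exceed `swap_tau` in magnitude
  with opposite signs.
* **Annotation** against a standards library by accurate mass and RT.
* **Differential testing**: per-feature one-tailed Welch t-tests (observed
  or fixed direction), log2 fold changes, significance tiers
  (significant / borderline 0.05–0.06 / not significant), pair-level
  significance gating, E1+E2 pooled tests, plus exact Wilcoxon rank-sum and
  two-tailed t-tests for clinical characteristics. All p-values are
  reported unadjusted.
* **Integration**: CV gene filter (0 < CV < 0.25), fold-change gene filter,
  Pearson gene–metabolite edges (r ≥ 0.7, positive only), overlap with
  pathway gene sets, and joint pathway enrichment (per-omics hypergeometric
  tests, unweighted Fisher combination, degree-centrality topology impact).
* **Synthetic data**: a generator producing feature tables with planted
  enantiomer pairs, group effects, exchange-constructed QC pools, TPM
  matrices with planted correlations and CV bands, and pathway sets — all
  with a machine-readable ground-truth file, so every stage is testable
  without any external download.

## CLI

```bash
# generate a synthetic study with ground truth
chiralome simulate --preset paper-like --seed 42 --out sim/

# full pipeline
chiralome run \
  --features sim/features.tsv --samples sim/samples.csv \
  --standards sim/standards.csv --expression sim/expression.tsv \
  --pathways sim/pathways.gmt --topology sim/topology.tsv \
  --out results/

# individual stages
chiralome normalize --features ... --samples ... --out out/
chiralome pair      --features ... --samples ... --out out/
chiralome test      --features ... --samples ... --out out/
chiralome integrate --features ... --samples ... --standards ... \
                    --expression ... --pathways ... --out out/
```

Outputs are plain CSV tables (`pairs.csv`, `results.csv`, `volcano.csv`,
`edges.csv`, `overlap.csv`, `pathways.csv`, …) plus `manifest.json` echoing
the full configuration, per-stage record counts and input/output digests;
identical inputs and config reproduce byte-identical results.

Every threshold lives in `AnalysisConfig` and can be supplied as a YAML
file via `--config` (keys match the dataclass fields, e.g. `ppm_max`,
`rt_pair_max`, `alpha`, `borderline_hi`, `cv_hi`, `r_min`, `swap_tau`,
`tail_mode`).

### Input formats

* feature table — TSV with `feature_id`, `mz`, `rt` columns (MS-DIAL-style
  aliases such as `Average Mz` / `Average Rt(min)` are accepted) and one
  column per sample; zeros and unparseable cells are treated as missing
* sample sheet — CSV: `sample,group,is_qc,datan_chirality`
* standards library — CSV: `compound,enantiomer,expected_mz,expected_rt`
  (enantiomer one of D, L, E1, E2, achiral)
* expression matrix — TSV, genes × samples, TPM
* pathway sets — GMT; members prefixed `cpd:` are compounds, the rest genes
* pathway topology — TSV edge list: `pathway_id, node_a, node_b`

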
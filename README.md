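# apmspipe

Semi-quantitative analysis of affinity-purification mass-spectrometry
(AP-MS) studies quantified by spectral counting, built around the design
used to map the EZH2 (PRC2 methyltransferase) interactome in HL-60 acute
myeloid leukaemia cells: bait immunoprecipitations in two treatment
conditions (untreated vs all-*trans* retinoic acid), isotype (IgG)
controls, and a pan-methyl-lysine pull-down.

It is written for proteomics analysts who start from post-database-search
tables (a protein × sample spectral-count matrix, a sample manifest, a
peptide-evidence table) and want a reproducible, scriptable version of the
common screening cascade:

1. **Interactome** — per-prey floored fold change FC = max(x̄_bait, 0.1) /
   max(x̄_IgG, 0.1); a one-sided Fisher exact test on the 2×2 table
   [x_bait, N_bait−x_bait; x_IgG, N_IgG−x_IgG] with Benjamini–Hochberg
   correction; a Poisson-mixture interaction confidence score
   r_j = π·Pois(x_j; λ₁) / [π·Pois(x_j; λ₁) + (1−π)·Pois(x_j; λ₀)]
   averaged over bait replicates (λ₀ = floored control mean, λ₁ = bait
   mean clamped to ≥ λ₀, π = 0.5); and a contaminant-frequency filter.
   High confidence = FC ≥ 2 ∧ score ≥ 0.8 ∧ q ≤ 0.05 ∧ not contaminant.
2. **Differential interactome** — a four-gate cascade: ≥ 1.5× over IgG,
   condition ratio ≥ 2 or ≤ 0.5, matched-pair direction consistency, and
   detection in more than one bait sample.
3. **Methylproteome** — methyl-site calling from probability-gated peptide
   evidence (protein ≥ 99.9%, peptide ≥ 80%), per-condition occupancy
   `n_mod/n_total` with one-decimal half-away rounding, pan-methyl
   enrichment (≥ 1.5× over IgG), and three-way triangulation of candidate
   direct substrates (co-IP in ≥ 2 runs ∧ pan-methyl enriched ∧ called
   site).
4. **Network** — Markov clustering (MCL, inflation 2.0) of the
   high-confidence interactome and exact hypergeometric term enrichment
   against GMT annotations.

A synthetic-study generator with known ground truth (negative-binomial
background, planted interactors, condition effects, contaminants, and
binomially sampled methyl spectra) makes every stage testable end to end.

## Worked example

The package bundles the methyl-peptide evidence of the EZH2 study as
`apmspipe.examples.ezh2_methyl_evidence()` together with its 13-sample
design (7 bait IPs, 5 IgG, 1 pan-methyl):

```python
from apmspipe import call_methyl_sites, format_occupancy
from apmspipe.examples import ezh2_example_manifest, ezh2_methyl_evidence

sites = call_methyl_sites(ezh2_methyl_evidence(), ezh2_example_manifest())
for s in sites:
    if s.protein_id == "eEF1A1":
        print(s.protein_id, f"K{s.position}", s.state.value,
              format_occupancy(s.untreated), format_occupancy(s.treated))
```

prints

```
eEF1A1 K55 me2 11.9% 5.9%
eEF1A1 K165 me2 0% 5.9%
```

i.e. the elongation factor eEF1A1 carries di-methylated K55 (7 of 59
covering spectra before treatment, 11.9% occupancy) and K165; positions
are computed as `peptide start + offset − 1` (K55 = 52 + 4 − 1). Twenty
sites are called in total; one histone H3.1 row whose stated coordinates
contradict its sequence length is flagged and excluded from calling, as a
real parsed search-engine export would be.

The full pipeline runs from the shell:

```sh
apmspipe simulate --seed 1 --out-dir data/
apmspipe run-all data/manifest.tsv data/counts.tsv \
    --evidence data/evidence.tsv --contaminants data/contaminants.tsv \
    --out-dir results/
```

which writes `interactome.tsv`, `differential.tsv`, `methyl_sites.tsv`,
`candidate_targets.tsv`, `clusters.tsv` and a `run_report.json` carrying
the resolved thresholds and input checksums; identical inputs and config
give bit-identical outputs.

## Limitations

The confidence score is a deliberately small two-component Poisson
posterior, not a replicate-order-statistic model; it under-scores preys
whose bait counts are strongly bimodal across conditions (those are the
differential cascade's quarry). Cohort-level hit counts from any specific
published study are not reproducible without its raw data. See
`docs/methods.md` for the model details and numerical conventions.
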
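# Methods

## Data model

An AP-MS study is three tables. The **sample manifest** assigns each
immunoprecipitation an antibody class (`bait`, `isotype_control`,
`pan_methyl`), a treatment condition (`untreated`, `treated`), an MS run
id, and optionally a matched-pair id; a pair must have exactly two members
in opposite conditions. The **count matrix** holds nonnegative integer
spectral (or peptide) counts per protein group and sample; a blank cell
means "no spectra observed" and reads as 0, which is the correct semantics
for spectral counting (absence of evidence, not missing data). The
**peptide evidence** table carries peptide sequences with 1-based,
inclusive protein coordinates (initiator methionine counted),
identification probabilities, and methyl annotations encoded
`K4:me2;K11:me1` as offsets within the peptide.

Published peptide tables often contain formatting characters (bold
markers around modified residues, line-break hyphens); sequences are
normalized by stripping `*`, `-` and whitespace before any length or
residue check. A record whose stated span disagrees with its normalized
length, or whose annotated residue does not match the sequence, is
*flagged* (`coords_consistent = False`) rather than dropped: it stays in
the parsed output but is excluded from site calling, and position mapping
refuses it with an explicit error. Real exports contain such rows; the
bundled worked example includes one.

## Quantitation

**Exclusive counts.** Proteins are first grouped by a minimal Occam rule:
identical peptide sets merge into one group (id = sorted members joined
by `+`), and a protein whose peptide set is strictly contained in
another's merges into that superset's group. A peptide then contributes
its spectra to a (group, sample) cell only if it maps to exactly one
group. This is the smallest protein-inference rule under which
"exclusive" is well defined; no full parsimony solver is attempted.

**Fold change.** Group aggregation uses per-sample *means*, not sums, so
the unequal group sizes of the emulated design (7 bait vs 5 IgG) do not
bias the ratio. A floor of 0.1 replaces any group mean below it before
the ratio — so a prey absent from IgG gets a finite, large fold change
and a prey absent everywhere gets exactly 1. The floor applies to the
aggregated mean, and is one shared configuration value across all stages.

**Exact test.** Per protein, the one-sided (enrichment) Fisher exact
p-value of the table [x_bait, N_bait−x_bait; x_IgG, N_IgG−x_IgG], where
the column totals are the summed spectra of each group over *all*
quantified proteins. The table construction is a design choice (the
screening literature varies here) and is isolated behind
`fisher_enrichment`; p-values are the upper hypergeometric tail
(scipy), cross-checked in the tests against exact rational enumeration,
and BH-adjusted across proteins (statsmodels).

## Interaction confidence score

The score stands in for heavyweight external interaction-scoring tools
while remaining fully specified and testable. Per protein:

* background rate λ₀ = max(mean IgG count, floor);
* interaction rate λ₁ = max(mean bait count, λ₀) — clamped so the
  "interaction" component never sits below background;
* per bait replicate j with count x_j, the posterior weight of the
  interaction component under a two-component Poisson mixture with prior
  π (default 0.5):
  r_j = π·Pois(x_j; λ₁) / [π·Pois(x_j; λ₁) + (1−π)·Pois(x_j; λ₀)];
* score = plain mean of r_j over all bait replicates (computed in
  log-space for stability).

Two consequences are worth knowing. When the bait mean does not exceed
the control mean, the clamp makes the likelihood ratio exactly 1 and the
score equals the prior — zero bait counts give 0.5, not less. And because
λ₁ is estimated from the bait counts themselves, the score is *not*
globally monotone in individual bait counts: raising one count raises λ₁
and can lower the posterior of low-count replicates. The monotonicity
that does hold — and is property-tested — is per-replicate monotonicity
at fixed rates. The score is also conservative for preys whose bait
counts are strongly bimodal across treatment conditions (a single λ₁ fits
neither condition); such preys are exactly what the differential cascade
is for. Aggregation (plain mean vs top-k) and π are configurable.

**Verdict.** High confidence requires all four gates: fold change ≥ 2,
score ≥ 0.8, BH-adjusted exact-test q ≤ 0.05, and no contaminant flag.
The q gate can be disabled (`q_threshold: 1`); it is on by default
because the score alone admits preys that are mildly but *consistently*
elevated across replicates by chance (the fitted λ₁ rewards consistency),
and the exact test — which pools evidence across the group totals —
rejects these cleanly.

**Contaminant filter.** A protein is flagged iff it appears in more than
half of the reference control experiments *and* its bait mean is not
≥ 2× the profile's expected background count (floored). The second
clause lets genuinely enriched frequent fliers survive. Proteins absent
from the profile are never flagged.

## Differential cascade

Four gates in fixed order, first failure recorded per protein:

1. **IgG gate** — all-bait mean ≥ 1.5× floored IgG mean.
2. **Ratio gate** — untreated/treated group-mean ratio (both floored)
   ≥ 2 or ≤ 0.5; symmetric by construction.
3. **Consistency gate** — each matched pair votes via its own floored
   ratio; a pair inside the dead zone (0.83, 1.2), or with no detection,
   abstains; every voting pair must agree with the global direction.
   With no pairs in the manifest the gate is skipped with a warning.
4. **Presence gate** — detection (count > 0) in more than one bait
   sample, both conditions counted.

The dead-zone bounds are configuration keys; the defaults bracket
"no meaningful change" at roughly ±20%. Unpaired bait samples contribute
to group means but not to the consistency vote. The cascade is gates-only
(no multiplicity control), so its selective set on null data is not
FDR-controlled — the acceptance script reports its empirical
false-discovery proportion alongside sensitivity.

## Methyl sites, occupancy, triangulation

Site calling keeps evidence with protein probability ≥ 0.999 and peptide
probability ≥ 0.80, both inclusive (the permissive end of the usual
80–95% peptide-threshold range; a single configurable value). Counts
aggregate per (protein, absolute position, methyl state) and per
condition by summing over samples; per-sample occupancies are available
separately for transparency. A site undetected in both conditions is
dropped.

Occupancy is `n_mod / n_total` covering spectra. Percent is rounded
half away from zero to one decimal (exact decimal arithmetic, so ties
like 21.875 → 21.9 are deterministic); integer percents print without a
decimal ("5%", "50%", "100%"); zero covering spectra print "ND".

Absolute position = peptide start + offset − 1, initiator Met counted.
Where an external source states a different residue label for the same
site (off-by-one conventions around the initiator Met are common), the
computed position is authoritative and the stated label is preserved as
an annotation (`author_label`) that never enters computation.

Pan-methyl enrichment keeps proteins whose pan-methyl mean is ≥ 1.5×
the floored pooled-IgG mean (inclusive; pooled controls rather than a
run-matched control, a documented choice). A candidate direct substrate
must co-purify with the bait in ≥ 2 distinct MS runs, be pan-methyl
enriched, and carry a called site.

## Network stage

MCL on the weighted interaction graph: self-loops at the maximum incident
edge weight (configurable), column normalization, then alternating
expansion (matrix power 2) and inflation (elementwise power 2.0 +
renormalize) with pruning below 1e-5 until the maximum matrix change is
below 1e-6. Clusters come from attractor rows of the limit matrix;
attractors that exchange flow form one attractor system; a node attracted
to several attractors joins its highest-flow attractor, ties broken by
lexicographic node id — so the partition is deterministic and every node
lands in exactly one cluster.

Term enrichment of a cluster is the exact upper-tail hypergeometric
probability of the observed overlap, BH-corrected across terms;
zero-overlap terms are reported with their (trivial) p rather than
skipped. The default universe is the analyzed interactome, not the whole
annotation file — this materially changes p-values and is therefore
configurable and recorded in the run report.

## Synthetic studies

`generate_study` emulates the study design: 4 untreated + 3 treated bait
IPs (2 matched pairs), 5 IgG controls, 1 pan-methyl IP, spread over 5 MS
runs. Counts are negative-binomial with mean 2.0 spectra and dispersion
k = 10 (variance = m + m²/k; k → ∞ recovers Poisson) — low-abundance,
mildly overdispersed background, which is what spectral counts of
background preys look like. Planted interactors (default 20 of 500) have
bait means scaled 5×; condition-specific interactors are a separate
category scaled 5× in all baits and a further 4× in one condition;
contaminants (5%) are elevated 5× in *all* samples including controls and
appear in the generated contaminant-frequency profile. Methyl sites sit
on planted interactors with Beta(2, 8) occupancy per condition and
binomial modified-spectrum counts at Poisson-distributed depth (default
mean 25 per condition, 400 in the occupancy-recovery experiment so every
site comfortably exceeds 200 covering spectra, where binomial sampling
error alone is ~1.9 pp sd). All randomness flows through one seeded
generator; a config and seed determine the study byte-for-byte.

What the generator does *not* emulate: retention-time or spectrum-level
structure, search-engine score distributions, protein-length effects on
spectral counts, correlated contaminant profiles, or shared peptides
(synthetic peptides are unique to their protein). Passing recovery tests
therefore demonstrate the statistical pipeline's behavior under its own
model assumptions, not performance on real LC-MS/MS data.

Problem sizes used by the test suite and acceptance script (500 proteins
for recovery, 300 × 20 seeds for the null, 100 sites at depth 400 for
occupancy, graphs ≤ 12 nodes for the clustering oracle) are chosen to
make the statistical checks sharp while keeping a full run in seconds.

## Known limitations

* The confidence score is a screening heuristic, not a calibrated
  posterior; its 0.8 default cut-off trades sensitivity for precision,
  and preys with heterogeneous bait counts (including genuinely
  condition-specific interactors) score conservatively. Measured on
  synthetic studies at default conditions, the high-confidence set's
  sensitivity for 5×-enriched uniform interactors is ~0.8 with
  essentially zero false-discovery proportion; the acceptance script
  reports both.
* The differential cascade controls no error rate; it reproduces a
  gates-only screening procedure faithfully, including its false
  positives at low counts.
* No site-localization scoring: a methyl annotation is taken at the
  stated peptide offset.
* GMT annotations are used as given — no GO-DAG propagation.
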
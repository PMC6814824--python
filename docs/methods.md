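# Methods

## Study design emulated by the generator

The synthetic study reproduces a 16-array single-channel microarray
design: 2 genotypes (control, db/db) × 2 ages (6, 20 weeks) × 4
replicates, with both lncRNA and mRNA probes on the same array.  The
default scaled-down array carries 2,000 lncRNA and 1,500 mRNA probes
(full-scale counts of ~36k/25k are reachable through the config; the
defaults keep the whole pipeline in seconds).  Per-probe log2 baselines
are drawn Normal(8, 1.5), a typical single-channel dynamic range of
roughly 3–13 log2 units.

Three kinds of structure are planted, and recorded in `PlantedTruth` as
the oracle for recovery tests:

**Differential expression.**  Per age contrast, a fraction `frac_de`
(default 5%) of probes receive a genotype log2 offset `±log2(FC)` with
FC ~ Uniform(2.5, 8), applied to the db/db group at that age.  The lower
bound is constrained ≥ 2 so every planted effect clears the pipeline's
two-fold filter; the noise-free group-mean ratio equals the drawn FC
exactly (tested at σ → 0).

**Hub modules.**  `n_hubs` (default 5) lncRNAs each drive a disjoint
module of `module_size` (default 25) mRNAs.  Hub and members share a
per-sample latent factor z with loading
β = σ_module · sqrt(r*/(1 − r*)), which makes the population pairwise
correlation equal the target r* (default 0.999).  Three modelling
choices matter here and were made deliberately:

- *One fold change per module.*  The hub and its members share a single
  drawn FC (and direction), so the genotype offset is common signal; with
  per-probe fold changes the offset heterogeneity alone caps pairwise
  correlation near 0.97–0.99, below the 0.995 edge threshold.
- *The latent is standardized within each age block*, so the realized
  within-age variance of z is exactly 1.  At n = 8 samples the sample
  variance of an unstandardized latent ranges over roughly 0.3–2, which
  makes the realized module correlation fluctuate far below the target
  in bad draws.
- *Module probes get their own residual SD* `sigma_module` (default
  0.05, vs the array-level `sigma_noise` = 0.25) *and elevated baselines*
  Normal(9, 0.5).  Tightly co-regulated transcripts plausibly share most
  of their variance; more importantly, scaling β against σ = 0.25 would
  require ±8 log2 units of latent swing, far outside the array's dynamic
  range, where the log2 pseudocount floor and quantile normalization's
  rank substitution compress the signal and destroy the planted
  correlations.  With the defaults, module swings stay within ~±4 log2
  units of a mid-high baseline.

A consequence worth stating: the latent variance that produces
|r| ≥ 0.995 is within-group variance from the t-test's point of view, so
hub/module probes are only weakly detectable by a 4-vs-4 test.  The two
recovery properties are therefore measured where each is well-posed:
DE sensitivity/specificity on studies with `n_hubs = 0`, and hub/module
recovery on networks built over the planted DE sets.  No
parameterization can make both hold end-to-end simultaneously — high
shared within-group variance is exactly what a ≥ 0.995 correlation
requires.

**Positional classes.**  Coding genes (3 exons of 1 kb, introns of 3 kb)
are laid out on a 16-kb slot grid; each lncRNA is placed so its class is
unambiguous under the classifier's precedence rules: sense-overlapping
lncRNAs straddle exon 2 on the host's strand, antisense ones straddle
exon 3 on the opposite strand, intronic ones sit wholly inside intron 2,
bidirectional ones sit ≤ 1 kb upstream of the host TSS on the opposite
strand, and intergenic ones occupy otherwise-empty slots kilobases from
any gene.  Equal class counts by default; composition is configurable.

**Detection flags.**  Per sample, intensities below the
`flag_absent_quantile` (default 5%) quantile are flagged Absent, those
between that quantile and twice it Marginal, the rest Present.  Flag
semantics on real arrays are scanner-specific; this emulation produces
the right *kind* of filtering behaviour (low-intensity probes drop out)
without claiming calibration.

**qPCR.**  Validation Cts are generated as
`Ct = 32 − log2(intensity) + N(0, σ_ct)` for targets and a
constant-abundance reference gene at Ct ≈ 18, i.e. Ct inversely
proportional to log template abundance on the same RNA the arrays
measured.

## Pipeline parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `min_detected` | 4 | samples (of 16) | detection filter threshold |
| pseudocount | 1.0 | intensity | guards log2 at zero fluorescence |
| `preprocess_order` | normalize_first | — | normalize full matrix, then drop undetected probes; `filter_first` available (the source protocols are loose on the order; both give identical calls on well-detected probes) |
| `de_method` | welch_t | — | unequal-variance t; `student_t`, `mann_whitney` (exact null for groups ≤ 8 — at n = 4 vs 4 the normal approximation is poor) selectable |
| `fc_threshold` | 2.0 | linear FC | two-fold volcano filter |
| `p_threshold` | 0.05 | — | raw-p gate; BH q reported alongside, optional `q_threshold` gate off by default |
| `r_threshold` | 0.995 | Pearson r | co-expression edge cutoff |
| `network_p_threshold` | 0.05 | — | correlation-test gate (t transform, df = n−2) |
| `sample_scope` | age_specific | — | correlate over the 8 samples of one age; `all_samples` available |
| `top_k` | 5 | hubs | hub report size |
| `kappa_threshold` | 0.03 | Cohen's kappa | term-grouping cutoff; conventional tools default nearer 0.4 — 0.03 groups aggressively and is deliberately configurable |
| `q_cut` | 0.05 | BH q | enrichment significance for grouping |
| `bidirectional_window` | 1000 | bp | divergent-promoter convention |

## Numerical choices

- **Quantile normalization ties**: within-column ties receive the mean of
  the reference values over the tied ranks, so ties stay ties.  With
  ties, the exact "identical multiset per column" property necessarily
  gives way to tie preservation (columns with different tie patterns
  cannot both keep ties and share a multiset); for tie-free data the
  multiset identity holds to 1e-9 and normalization is idempotent.
- **Degenerate tests**: both groups constant and equal → p = 1 (no
  evidence); constant but unequal → p = 0.  Zero-variance vectors yield
  no correlation edge rather than NaN propagation; under the correlation
  distance a zero-variance profile is at distance 1 from everything.
- **|r| = 1** maps to p = 0 by convention (the t transform diverges).
- **Determinism**: all generator draws flow from
  `numpy.random.default_rng([seed, stream])`; DE tables sort by
  (p, probe_id), edges by (lnc_id, mrna_id), hub ranking by (degree desc,
  Σ|r| desc, id asc); clustering inputs are pre-sorted by probe id so
  leaf orders are permutation-invariant.  `run-all` manifests hash every
  artifact; same config + seed → identical hashes.
- **BH q-values** are computed via `statsmodels` (`fdr_bh`) and checked
  in the tests against an independent brute-force step-up oracle.

## What passing tests do and do not show

The generator plants exactly the structure the pipeline looks for:
Gaussian log2 noise, a single shared latent per module, clean group
labels, and classes that are unambiguous by construction.  Real arrays
add probe-level biases, batch and dye effects, spatial artifacts,
cross-hybridization, annotation ambiguity (overlapping hosts, multi-exon
lncRNAs), and biological correlation structure far messier than disjoint
modules.  Recovery at 100% here therefore validates the *implementation*
(the filters, statistics and graph operations do what they claim), not
the biological operating characteristics of the thresholds on real data.
The |r| > 0.995 cutoff at n = 8 in particular is extremely permissive to
co-differential expression: any two strongly deregulated transcripts
correlate near 0.95 over an 8-sample two-group layout, which is why hub
identification needs the degree ranking rather than edge presence alone.

## Known limitations

- Strand-flip symmetry of the classifier holds for four of five classes;
  the bidirectional class is inherently orientation-dependent (flipping
  both strands turns head-to-head into tail-to-tail).
- The classifier is gene-level: multi-isoform structures and enhancer
  RNAs are out of scope.
- Moderated-variance (empirical-Bayes) testing is deliberately not used;
  the contract is the plain FC + t-test volcano filter.
- Term maps are user-supplied; no ontology topology is used, and printed
  term lists from any particular GO/KEGG release are version-dependent.
- ΔΔCt assumes amplification efficiency 2.0; efficiency-corrected
  variants are out of scope.
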
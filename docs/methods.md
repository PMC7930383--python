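# Methods

## Study design being emulated

The package targets a two/three-group esophageal-mucosa 16S design:
physiologically normal esophagus (`PN`), pre-cancer (`PreT`) and tumor
(`T`). The default synthetic cohort is 11 PN + 18 T samples — the size of
the discovery cohort the analyses were designed around — with a genus-level
layer of 50 taxa spread over the seven dominant phyla (Firmicutes,
Bacteroidetes, Proteobacteria, Fusobacteria, Thermi, Spirochetes,
Actinobacteria) plus a small unassigned remainder.

## Generative model

For each sample:

1. **Depth** ~ NegativeBinomial(mean 40,410 reads, size 11.1 → CV ≈ 0.30).
   The mean echoes the per-sample clean-tag scale of the emulated study.
2. **Richness mask**: each taxon is present with probability
   `richness_retention[group]` (PN 0.95, T 0.80, PreT 0.875). This is how
   the tumor group's observed-OTU deficit is produced; it is presence
   masking, not abundance shrinkage, so richness and composition effects
   are independently tunable.
3. **Fractions** ~ Dirichlet(concentration × group profile restricted to
   present taxa), concentration 50 (per-taxon CVs of tens of percent,
   typical of tissue 16S overdispersion).
4. **Counts** ~ Multinomial(depth, fractions).

Group composition shifts are multiplicative fold-changes on the baseline
(PN) profile, re-closed to sum to one: fold 3.0 on the 11
signature-increased genera, 0.3 on the 8 signature-decreased genera, 1.0 on
filler genera; `PreT` uses the geometric midpoint. These folds put the
default cohort in the strong-dysbiosis regime (near-perfect MDI
discrimination and weighted-UniFrac ANOSIM R in the 0.6–0.8 range) that the
emulated study reports. Because the composition is closed, neutral-fold
filler taxa still shift in *relative* abundance between groups; the
differential tests rightly flag some of them — that is compositional
reality, not a false positive of the generator.

Seeding: the cohort seed is expanded into a named substream per sample
(`SeedSequence(seed, spawn_key=(crc32(sample_id), ...))`), so per-sample
draws are independent of group ordering and adding samples never perturbs
existing ones. Identical config + seed ⇒ bit-identical cohort.

### Calibration to the printed phylum means

The generator's contract is that the *cohort-size-weighted overall expected
phylum means* equal the dominant-phyla percentages the emulated study
prints (Fusobacteria 7.43, Actinobacteria 0.70, Bacteroidetes 28.93,
Firmicutes 35.76, Proteobacteria 23.21, Spirochetes 1.57, Thermi 1.91;
the remaining 0.49 is an unassigned bucket so the composition closes to
one — the printed values sum to 99.51). Two subtleties:

* The baseline profile is solved by a multiplicative fixed point so that
  the weighted mean of the per-group profiles hits the target exactly
  (residual < 1e-13) under the default 11:18 weighting.
* Masking + renormalization inflates surviving taxa on average
  (E[q_i z_i / Σ q_j z_j] > q_i for small taxa), a ~5% relative bias on
  Fusobacteria at the default retentions if ignored. The fixed point
  therefore iterates on the **post-masking expected composition**,
  computed by exact enumeration over the presence patterns of the eight
  largest taxa with a second-order delta correction for the near-constant
  small-taxon remainder (accurate to <0.5% relative against brute-force
  Monte Carlo; see the test suite). The `truth` output reports these
  realized per-group expected fractions.

Whether the printed overall abundances are pooled-read or
mean-of-sample-fraction averages is not stated in the source analyses; the
generator treats them as mean sample fractions.

## Diversity and test conventions

* Shannon in **nats**; Simpson as the unbiased dominance
  Σ n_i(n_i−1)/(N(N−1)); Good's coverage 1 − F1/N. No rarefaction —
  calculators run on raw counts, depth being a simulation control.
* Two-group comparisons: Wilcoxon rank-sum with midranks; ≥3 groups:
  Kruskal–Wallis with tie correction. P-values by **full enumeration** of
  label assignments when ≤ 20,000 exist (p = count/total, so p > 0), else
  seeded permutation with the plus-one estimator (b+1)/(B+1).
* ANOSIM: R = (mean between-group rank − mean within-group rank)/(n(n−1)/4)
  on midranked distances, one-sided p; same enumeration/permutation rule.
* Mantel: correlation of strictly-upper-triangle entries, d2 permuted
  jointly over rows/columns; two-sided p by default. A scalar covariate
  (MDI, a genus's abundance) enters as the |Δx| distance matrix; a
  zero-variance covariate returns r = 0, p = 1, flagged degenerate.
* UniFrac: unweighted = unique/observed branch length; weighted defaults to
  the normalized variant. Verified against an exhaustive
  branch-enumeration oracle and scikit-bio.
* PCoA: Gower double-centering of −d²/2; negative eigenvalues are reported
  and flagged, their axes dropped, and excluded from the
  explained-proportion numerator; no Lingoes/Cailliez correction.
* Metastats-style test: Welch t on relative abundances with permutation p;
  taxa nonzero in < 25% of samples in both groups fall back to a two-sided
  Fisher exact test on pooled counts; BH q-values over all taxa (BH via
  statsmodels).
* LEfSe-style selection: deterministic single-feature variant — abundances
  scaled to 1e6 per sample, Kruskal–Wallis screen, effect =
  log10(max(|scaled group-mean difference|, 1)), biomarker if p < 0.05 and
  effect > 3. The cited tool's 30-fold bootstrap and subclass logic are
  omitted deliberately: with one two-class contrast the discriminant is
  one-dimensional and the calibrated effect reduces to the mean difference
  (any variance ridge cancels).
* MDI: log base 10, computed as a difference of logs so that swapping the
  increased/decreased sets negates the score exactly. Pseudocount defaults
  to half the smallest nonzero relative abundance — it keeps scores finite
  without dominating the sums; MDI is invariant to common rescaling only
  when ε is rescaled with it. Relative abundances are used (per-sample
  depth cancels in the ratio).
* ROC: operating points at every distinct threshold (ties merged, via
  scikit-learn), AUC by the Mann–Whitney rank identity, 95% CI by seeded
  stratified bootstrap percentile (2.5/97.5), p from the two-sided
  Mann–Whitney test of AUC ≠ 0.5. A "Wilson/Brown"-type proportion CI is
  not used: its application to an AUC is ambiguous; the choice is recorded
  in the ROC output metadata. Positive class is `T` and higher MDI predicts
  `T`; the direction is fixed, never auto-flipped.

## Pipeline

`run_pipeline` composes: simulate/load → phylum/genus aggregation → alpha
diversity + group tests → UniFrac (both variants) + PCoA + ANOSIM →
Metastats + LEfSe → signature (fixed `escc` or derived from biomarkers) →
MDI → MDI-vs-richness and MDI-vs-beta correlations → ROC. Differential,
MDI and ROC stages use the fixed PN-vs-T contrast; alpha/beta stages use
all groups. One global seed is expanded into named per-stage substreams, so
results are byte-reproducible and adding a stage does not disturb earlier
draws. All thresholds (p < 0.05, LDA > 3, 999 permutations, 1000 Metastats
permutations, 2000 bootstrap draws) are config fields with those defaults.

## Problem sizes used in the checks

The test suite and acceptance script run at desk scale, chosen as the
smallest sizes that make the statistical assertions sharp: 100 seeded
default cohorts (29 samples each) for the discrimination and
richness-coupling regimes; 400 samples at depth 50,000 for phylum-mean
recovery (3 Monte-Carlo-SE band over 7 phyla); 500 null replicates per test
(exact enumeration at n = 12 for ANOSIM/Wilcoxon, 199 permutations for
Mantel, 150 cohorts × 20 taxa for Metastats) for type-I calibration at
α = 0.05 within [0.03, 0.07]; 200 cohorts for bootstrap-CI coverage.

## What the generator does and does not show

Passing tests demonstrate internal correctness (oracle equivalence,
calibration under the null, determinism) and that the analysis recovers
planted structure of the configured kind and size. They do **not**
demonstrate performance on real 16S data: the generator has no OTU-level
phylogenetic substructure below genus, no chimeras/contamination, no
compositional zero-inflation beyond Bernoulli masking, and presence/absence
never responds to abundance shifts (at the default depth every un-masked
taxon is detected). Consequently unweighted UniFrac carries no group signal
in default cohorts even though the weighted variant separates strongly —
on real data, abundance shifts crossing the detection limit would add
presence structure. The headline AUCs of the emulated study (95.96%/93.75%)
derive from restricted-access human data and are deliberately not
reproduction targets; the default simulation is instead calibrated to the
same qualitative regime (AUC ≥ 0.9 in ≥ 90% of seeds).

## Known limitations

* The LEfSe variant is single-feature and two-class only; no cladogram or
  multi-class one-against-all logic.
* Fisher's exact fallback on pooled counts ignores within-group
  overdispersion; it is the cited tool's heuristic, kept for fidelity, and
  only engaged for sparse taxa.
* PCoA offers no negative-eigenvalue correction.
* The mask-closure calibration is approximate beyond second order
  (relative error < 0.5% at default retentions).
* With tiny groups, bootstrap percentile CIs for AUC are discrete and can
  be anti-conservative near AUC = 1; the CI is clamped to bracket the point
  estimate.
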
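# Methods

This note documents the models, rules and numerical choices behind
`phylostrat`, and what the synthetic validation studies do and do not
demonstrate.

## Dating model

A pfam family's age is the midpoint of the branch above the MRCA of the
species that carry it: age = (age(MRCA) + age(parent(MRCA)))/2. The
midpoint is the natural point estimate when the origin is known only to
lie on that branch. For a single-species family the MRCA is the leaf, so
the age is half the terminal branch's parent age (such families are
normally removed by the two-species filter; the convention matters only
for synthetic edge cases).

Strata older than the species tree use fixed calibrations (all in MY):

| stratum | age | rule |
|---|---|---|
| LUCA | 4090 | family on the curated LUCA list, or present in all three domains of life |
| post-LUCA | 3145 | shared with exactly one of bacteria/archaea; halfway between LUCA (4090) and the emergence of eukaryotes (2200) |
| FECA | 2230 | present in non-protist eukaryotes and ≥1 Excavata species |

Lineage subsets for trend fits: *ancient* = older than the LECA (2101);
*recent animal* / *recent plant* = younger than the plant vs animal+fungi
split (1496) and present in that kingdom but not the other;
*intermediate* = between the cutoffs. Protists are used only as dating
outgroups and contribute no property datapoints. Ages are stored in MY and
converted to BY inside regressions so slopes read "per billion years".

## Clustering index

The normalized index of dispersion ψ compares the variance of ±1
hydrophobicity block sums (s = 6 residues per block) to its
sampling-without-replacement expectation K (formulas in the README). Frames
are the first p = max(1, L mod 6) start offsets, truncating the tail;
there are arithmetically p+1 possible offsets but p is used, resolving the
truncation convention in favour of the printed frame count. Degenerate
inputs — length < 2s, or any frame all one sign (K = 0) — yield a missing
value rather than a number; missing ψ values are excluded from means and
regressions with counts recorded. X (unknown residue) scores −1 for
clustering and is excluded from composition, mirroring the treatment of
rare codes conservatively.

The exact calibration E[ψ] = 1 under random arrangement holds because each
block is a uniform without-replacement sample of the composition; the test
suite verifies the permutation average exactly at L = 12 and by Monte
Carlo at L = 120.

## Disorder

Per-residue disorder scores in [0,1] are consumed as input (an external
predictor's table); the pipeline never predicts disorder ab initio. A
family instance's ISD is the mean score over its annotated interval;
`mean_isd_noC` averages the same profile over non-cysteine positions (when
scores are supplied externally the predictor cannot be re-run on a
cysteine-excised sequence; the excision transform itself is provided for
surrogate-based workflows, where rescoring is possible). The bundled
surrogate profile generator is a centered moving average (default window 7,
shrinking at edges) of per-residue propensities — deliberately simple
plumbing so tests and demonstrations need no external binary.

## Quality filters

Filters run in sequence but are pure predicates, so their intersection is
order-independent. Keyword matching is case-insensitive substring search
with `*` read as a prefix wildcard (the stem suffices). The Dollo
contamination test simulates, per species-count k, the loss count of
uniformly random k-subsets (default 1000 replicates, cached per tree and
k) and rejects a family when z > −2, i.e. when its loss count is *not*
clearly below the random-contamination expectation. Families in at least
half the species are kept untested; a degenerate null (sd = 0, tiny trees)
keeps the family with a note. Genes containing any excluded family are
dropped entirely.

Empirical note: the null mean of losses rises with k only while presence
is sparse (on a balanced 64-leaf tree it peaks near k ≈ 22 and then dips
slightly as absent clades merge); the property test asserts monotonicity
over the sparse regime where it holds.

## Homology datapoints

One datapoint per pfam: the flat, unweighted mean over all instances
across all species (not a per-species mean of means). Transmembrane status
of a family is the majority over instances, and TM / non-TM partitions are
analyzed separately, never pooled. Gene-level analyses key genes by their
oldest pfam; ties among equally-oldest pfams resolve to the co-occurrence
cluster (P(AB | A or B) ≥ 50% links, single-link closure, group id = the
lexicographically smallest member); ties spanning unlinked groups fall to
the smallest group id with a logged warning.

## Trend statistics

Slopes are ordinary least-squares fits of property on age (BY), reported
with SE, R², two-sided p and 95% CI; at least 3 datapoints are required
and outliers are included. Composition profiles fit each amino acid's
percentage separately (the 20 slopes are mutually constrained to sum to
zero). Profile correlations use Spearman (average ranks, t-approximation
for p) or Pearson; the SE of a Spearman ρ uses the Fisher transformation,
se_z = √(1.06/(n−3)), back-transformed to a ρ interval. Raw property
values are regressed by default; Box-Cox (maximum-likelihood λ, recorded
shift for non-positive values) and arcsine transforms are options. The
one-tailed sign test returns the exact binomial tail (e.g. 6 of 9 positive
→ 130/512 ≈ 0.254). No multiple-testing correction is applied; p-values
are reported raw.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes —
nothing more (no substitution or indel process, no real predictor):

- **Tree**: animals, plants, fungi, an Excavata outgroup, and a second
  protist group, attached at the calibration nodes (FECA 2230, LECA 2101,
  kingdom split 1496, animal–fungi split 1105 MY); random reproducible
  within-clade topology. Defaults: 24/16/12/4/4 leaves.
- **Histories**: each family is born at a stratum-appropriate node (LUCA
  80, post-LUCA 120, FECA 60, backbone 120, animal 280, plant 90, fungus
  50 by default); losses prune whole subtrees as a Poisson process
  (default 0.02 per branch per 100 MY); families with fewer than two
  surviving species are redrawn. True age = branch midpoint (or the
  stratum calibration), so the dating rule is exact when no loss moves the
  MRCA. Backbone births use the LECA and kingdom-split nodes only, so no
  flat-trend family is *born* into the recent-animal age range (losses can
  still misplace one — a genuine property of the method that the truth
  table lets us quantify).
- **Sequences**: per-instance lengths uniform in [100, 300]. The
  hydrophobic fraction target is baseline (≈0.33) plus a lineage slope
  times age (+0.015/BY in animal-born families by default). Arrangement is
  a two-state Markov chain whose persistence is calibrated by simulation
  (500 replicates per hydrophobic-fraction bucket at a fixed length of
  150, cached; residual length dependence of ψ is age-independent) to hit
  a target ψ = 1.10 − 0.039·age(BY), the planted universal clustering
  trend. Clustering is planted through arrangement, not composition, so
  the two metrics stay independently controllable. Disorder propensities
  are the family's ISD target (0.36 − 0.062·age for animal-born; flat
  0.26/0.24/0.22 for plant/fungus/ancient) minus a term proportional to
  the centered hydrophobicity indicator (disorder co-varies with local
  hydrophilicity), plus residue noise, smoothed by the surrogate window.
  Pfam-level noise: ISD 0.03, ψ 0.05, hydrophobic fraction 0.02.
- **Composition fine structure**: clade-born families drift along fixed
  per-lineage amino-acid preference axes (serine/proline in animals,
  cysteine/acidic residues in plants, mirroring reported young-domain
  enrichments; default 0.25/BY). An optional recruitment-order tilt (off
  by default) models amino-acid availability as tracking the consensus
  recruitment order until the LECA and frozen afterwards: pre-LECA
  families carry an age-proportional, abundance-compensated tilt (slope
  linear in rank) and younger families inherit the final LECA-era level.
  This reproduces the signature of an early-availability signal: the
  slope-vs-recruitment-order correlation strengthens as younger families
  are excluded.
- **Contaminants and filter fodder**: contaminants get uniformly random
  sparse presence (k in [6, 14] by default), baseline composition, ψ ≈ 1
  and no trends; fodder families carry metadata crafted to trip each
  annotation/keyword/two-species screen. Both are flagged in the truth
  table.
- TM families (10%) receive two 21-residue helices inside the domain; a
  few ordinary genes get a 15-residue sub-threshold helix to exercise the
  >18 boundary.

Everything is byte-reproducible from the seed; `write_dataset` emits only
plain-text formats (newick, FASTA, TSV).

### What passing tests show — and what they do not

The generator matches the analysis' assumptions by construction: losses
are the only source of dating error, disorder tracks hydrophilicity
monotonically, instances of a family are exchangeable, and contamination
is uniformly random. Passing recovery tests therefore demonstrate that the
pipeline is correctly implemented and statistically calibrated under its
own model — not that real proteomes satisfy that model. In particular the
generator has no homology-detection bias, no GC-content confounding, no
rate variation among lineages, and its "disorder predictor" is the
surrogate, not a physical model.

## Validation studies and problem sizes

- `experiments.default_study`: one full run at the default scale
  (60 species, 800 families + 40 contaminants + 30 fodder; ≈15,000
  instances; Dollo null 1000 replicates). Checks: Spearman ρ > 0.99
  between true and assigned ages, ≥95% of families within one stratum of
  truth, ≥90% of contaminants rejected, disorder trend significant only in
  the recent-animal subset, clustering trend negative overall with all
  subset CIs overlapping the global estimate.
- `experiments.recovery_experiment`: 100 independent reduced-scale runs
  (22 species, ~120 families, lengths 90–180, Dollo null 200 replicates —
  sizes chosen so the whole study completes in about a minute). For each
  run the planted disorder, hydrophobic-fraction and clustering slopes are
  compared with the 95% CI of the corresponding fit; coverage is ≥90% for
  each. Fits condition on the cohort that truly carries each trend (the
  truth table's birth lineage): this isolates estimator calibration from
  phylostratum misassignment, which the default study quantifies
  separately via the lineage-tag subsets.

## Known limitations

- The spec-level dating rules interpolate, they do not estimate: no
  uncertainty is attached to an assigned age, and midpoint dating is
  systematically biased young when losses prune the oldest descendants.
- The Dollo null assumes uniformly random contamination; structured
  contamination (e.g. one contaminated sequencing center serving related
  species) would evade it.
- The keyword screen is a blunt instrument inherited from curation
  practice; it is exact-string based and language-dependent.
- Quantile summaries use linear interpolation between order statistics —
  one convention among several, recorded here because box-plot whiskers at
  the 9/91 quantiles are sensitive to it in small classes.
- The bundled amino-acid property table uses conventional literature-
  derived scales (consensus recruitment ranks, 1−mean-RSA hydrophobicity,
  approximate changeability and ATP-cost values); analyses that depend on
  a specific published scale should supply their own table.
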
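# Methods

This note records the statistical conventions the package implements, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical decisions a maintainer would need
to reproduce or change the behaviour.

## Data model and coordinates

All sequences are rCRS-aligned, plus-strand, uppercase strings over
{A, C, G, T, N, -}. Coordinates are 1-based inclusive nucleotide positions
("np"), the convention of the human mtDNA literature; a region
`start:end` has length `end − start + 1`. `N` (uncalled base) and `-`
(alignment gap) are both treated as non-called for every distance or
identity computation (pairwise deletion). The canonical control-region
windows are exposed as constants: HVS-I 16033–16365 and HVS-II 73–340 for
haplotype diversity (joint haplotypes are the ascending-coordinate
concatenation of the two windows), 16000–16410 for nucleotide diversity,
and 16064–16400 for the F<sub>ST</sub> analyses — the windows that
maximise overlap across published ancient datasets.

Sample filters mirror the quality workflow of haplogroup-assignment
pipelines: a sample enters downstream analyses if it has a haplogroup
label, meets the score and coverage thresholds (`>=`, so a score of
exactly 0.8 passes a 0.8 threshold; a missing value fails any positive
threshold), and is not on an explicit exclusion list (e.g. contamination
flags). Consensus sex gives precedence to the molecular call; an
anthropological/genetic disagreement keeps the genetic call and raises a
conflict flag.

## Diversity estimators

* **Haplotype diversity.** HD = n(1 − Σpᵢ²)/(n − 1) over exact-match
  haplotype classes, with the Nei (1987) sampling variance
  V = (2/(n(n−1)))·[2(n−2)(Σpᵢ³ − (Σpᵢ²)²) + Σpᵢ² − (Σpᵢ²)²]; the reported
  sd is √V. Identity is exact string equality after uppercasing — an `N`
  never matches, so partially called sequences are not silently merged.
  (For reference, a fully distinct sample of n = 31 gives HD = 1.0000 with
  sd 0.0082 under this variance.)
* **Nucleotide diversity.** π is the mean over pairs of (differences /
  jointly called sites), i.e. each pair is normalised by its own called
  overlap before averaging — robust to the ragged coverage of ancient
  consensus sequences; complete deletion is available via a flag. The
  variance is Tajima's (1983) total variance
  V = (n+1)/(3(n−1))·π/L + 2(n²+n+3)/(9n(n−1))·π², which includes the
  evolutionary (stochastic) component, matching the classical toolchain's
  output.

## Distances and Φ statistics

The default sequence distance is the raw count of differing jointly
called positions ("differences") — the haplotypic convention in which the
squared distance entering AMOVA is the difference count itself. The
p-distance and the Tamura–Nei (TN93) closed form (with optional gamma
rate heterogeneity, user-supplied shape α) are available; since
substitution-model selection is out of scope, no default α is claimed,
and a saturated pair raises an error naming the offending logarithm
domain violation. A pair whose pooled composition lacks one of the four
bases falls back to the p-distance (the standard degenerate limit).

AMOVA follows the Excoffier–Smouse–Quattro sums of squares on pairwise
squared distances with the method-of-moments coefficients for unequal
sample sizes. A one-group design yields the two-level decomposition
(σ²ₐ undefined, Φ<sub>ST</sub> only); a design with one population per
group sets σ²ᵦ = 0 (no within-group level). Negative components are
reported as computed and flagged, never truncated — negative pairwise
Φ<sub>ST</sub> values are meaningful output. The "total variance" reported
is the component sum, the convention of the classical AMOVA tables;
Φ<sub>CT</sub> = σ²ₐ/total, Φ<sub>SC</sub> = σ²ᵦ/(σ²ᵦ+σ²𝒸),
Φ<sub>ST</sub> = (σ²ₐ+σ²ᵦ)/total. Pairwise population Φ<sub>ST</sub> is
exactly the two-level decomposition restricted to the pair (shared code
path, so the consistency is structural, not numerical).

**Permutation tests.** Three schemes: Φ<sub>ST</sub> permutes individuals
among populations ignoring groups; Φ<sub>SC</sub> permutes individuals
among populations within groups; Φ<sub>CT</sub> permutes whole populations
among groups (the standard choice; the alternative individual-level
scheme was considered and rejected as non-standard). Every p-value uses
p = (1 + #{permuted ≥ observed})/(n_perm + 1), so p is never 0 — where a
published table prints "p = 0.00000" this implementation reports the
minimum attainable value instead. When fewer distinct permutations exist
than requested, sampling proceeds with replacement and a warning is
emitted. Note that the attainable minimum of the population-level
Φ<sub>CT</sub> test is set by the probability that a random permutation
reproduces the observed partition (e.g. 1/15 for six populations in three
equal groups), not by 1/(n_perm+1).

**Grouping search.** Candidates are explicit partitions of the analysed
populations (YAML/JSON files; `enumerate_groupings` generates all set
partitions of the non-fixed populations given a fixed block, for the
workflow that pins a homogeneous early-farmer block and varies the rest).
The optimum maximises Φ<sub>CT</sub> (ties within 1e-9) and, among those,
minimises Φ<sub>SC</sub> — lexicographic because the two criteria can
disagree; the full ranked table is always emitted and a Pareto-conflict
flag is raised when the Φ<sub>SC</sub> global minimiser is a different
candidate.

**Multiple testing and embedding.** Benjamini–Hochberg step-up adjustment
is applied once per unordered population pair (strict lower triangle).
For MDS, negative F<sub>ST</sub> entries are clamped to 0 and the diagonal
forced to 0 first: a negative F<sub>ST</sub> is statistically
indistinguishable from zero differentiation, and nonmetric stress
requires non-negative dissimilarities. Classical MDS is principal
coordinates (double-centred squared dissimilarities, eigendecomposition);
nonmetric MDS is SMACOF with isotonic regression, one classical-seeded
start plus seeded random restarts, reporting Kruskal stress-1.

## Haplogroup binning, clustering, PCA, Fisher

Bin assignment is longest-matching-prefix over the scheme's rules (so
`H5a1` → H5, not H; `HV0a` → the V/HV0 bin, not HV), with macro-class
bins (Asian founder clades A, C, D, F, G, Z; African L) matched by first
letter after all prefix rules fail, and a terminal `others` fallback. The
three shipped schemes are code constants (a YAML loader accepts custom
schemes). Zero-count bins are retained so all matrices share a scheme's
column space, and `others` participates in clustering/PCA like any bin.

Ward clustering uses the squared-update ("Ward.D2") Lance–Williams
variant on Euclidean distances between frequency rows. Bootstrap support
resamples bin columns with replacement (the convention of cluster-support
tools for frequency profiles; row resampling available behind a flag) and
reports the plain bootstrap proportion — the percentage of replicate
trees containing the identical leaf set. PCA is column-centred,
unscaled (covariance) — bins already share a scale — via SVD; scores,
per-bin loadings and explained-variance fractions are returned.

Fisher's test on an R×C haplogroup table is the exact two-sided
hypergeometric test for 2×2 and a fixed-margins Monte-Carlo estimate
otherwise: tables are sampled by Patefield's algorithm, and
p = (1 + #{P(table) ≤ P(observed)})/(n_sim + 1). Zero-total bins are
dropped before testing.

## Minimum spanning networks and deduplication

Haplotypes are exact-identity classes; the node label is the
lexicographically first member id. The MSN at ε = 0 is the union of all
minimum spanning trees, built by Kruskal over equal-weight batches: an
edge is kept iff its endpoints lie in different components of the
strictly-lighter subgraph (the standard characterisation of
MST-membership). ε > 0 additionally admits every edge within ε of the
weight at which the network first became connected. Deduplication removes
potential maternal relatives by connected component of the
identical-sequence graph — from each component the lexicographically
first sample is kept, so a triple of identical sequences loses two
members (component semantics, not pair semantics).

## Shared haplotypes and lineages

Sharing requires the full compared region called in both sequences;
partially called target haplotypes are excluded and counted rather than
wildcard-matched (wildcards inflate sharing). Percentages are computed
over distinct haplotypes, with an individuals-weighted percentage emitted
alongside, because published sharing figures mix the two denominators.
Ancestral assignment orders reference populations by epoch
(HG < EN < MN < LN/EBA < IA < present) and assigns each target haplotype
to the earliest epoch containing an identical haplotype; no match is
"novel". Restricted to one reference epoch this reduces exactly to the
classical shared fraction.

## Synthetic data: what it emulates and what it does not

The generator is a founder-divergence model, not a coalescent: a random
root sequence; per truth-group founders carrying a Poisson
(`founder_divergence`) number of mutations from the root on distinct
sites, so two groups are separated by roughly twice that many
substitutions minus rare coincident hits; individuals are their
population founder plus
Poisson(θw) private mutations at uniform positions (optionally
transition-biased to exercise TN93). Haplogroup labels are drawn from
per-population profiles, sex from a Bernoulli ratio, and duplicate /
one-difference pairs are planted as copies of existing samples. This
yields exactly controllable within/between variance and exact ground
truth — which is what the estimators under test need — but no
genealogical correlation structure, no recombination (correct for
mtDNA), no damage or coverage artefacts beyond uncalled-site handling,
and no realistic site-frequency spectrum. Passing tests therefore
demonstrate correctness of the estimators and the inference machinery,
not robustness to every property of real ancient DNA.

Default generator conditions used by the validation battery, chosen once
as representative of the HVS-scale data the methods target:

* **AMOVA oracle agreement**: 50 datasets, 4–6 populations of 3–8
  individuals, L = 120, d ∈ [0, 8], θw ∈ [0.5, 4]; components must match
  an independent double-loop implementation to 1e-10.
* **Permutation calibration**: exchangeable data (d = 0) with θw = 8 over
  L = 400 and deliberately unequal sample sizes (9/12 for the pairwise
  test; 6–11 across six populations for Φ<sub>CT</sub>), 200 replicates at
  n_perm = 199. Unequal sizes and high diversity matter: with equal
  sizes and few segregating sites the two-population Φ<sub>ST</sub>
  degenerates to a function of a single small-integer sum, the
  permutation distribution collapses onto a handful of tied values, and
  the exact p-value is valid but far from uniform. The calibration
  property is only well-posed where the statistic is effectively
  continuous.
* **Grouping recovery**: six populations in three groups of two, n = 20
  each, L = 337, d = 8, θw = 1, the 90 candidate partitions into three
  groups; the generating partition must be selected in ≥ 95 of 100 seeds.

## Reproducibility

Every stochastic routine takes an explicit seed; the pipeline derives
per-stage seeds from the master seed by `seed·1000 + stage_index`
(mod 2³¹) so stages can be re-run in isolation. Stage manifests record
input SHA-256 checksums, parameters and seeds. Identical config + seed
produces byte-identical numeric outputs (asserted in the test suite).

## Known limitations

* Haplogroup *calling* from sequence is out of scope; the package bins
  labels produced elsewhere.
* The TN93 gamma shape has no default — model selection is the user's
  responsibility.
* The Fisher R×C test is Monte-Carlo beyond 2×2; exactness is only
  guaranteed for the 2×2 special case.
* Locus-by-locus AMOVA, >3 hierarchy levels, median-joining networks,
  Mantel tests and migration-rate estimation are deliberately absent.
* The published-table analyses shipped with the package reproduce the
  desk-scale counts exactly; sequence-level published values (full-genome
  HD/π, pairwise F<sub>ST</sub> tables against reference compilations)
  require the deposited sequence data and reference panels, which are not
  redistributed here.
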
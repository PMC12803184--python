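# Methods

This note documents the statistical procedures implemented in
`acetylatlas`, the defaults and why they hold, what the synthetic data
generator does and does not emulate, and the numerical choices made where
the design was genuinely open.

## Identification filtering

A site-report row is retained when (i) its modification title contains
`Acetyl (K)`, (ii) its site-localization probability is **strictly**
greater than 0.75, and (iii) both the protein-group and precursor q-values
are at most 0.01. The probability comparison is strict and the q-value
comparison inclusive; the boundary cases (probability exactly 0.75
rejected, q-value exactly 0.01 kept) are pinned by tests. Duplicate rows
sharing a collapse key — several precursors covering one modified residue —
are merged by taking the per-run **maximum** intensity: conservative,
order-independent, and insensitive to how many precursors happened to be
identified. (Summing would double-count shared signal; averaging would
let low-quality precursors dilute the site.) Duplicate keys that disagree
on protein or position raise an integrity error rather than silently
merging distinct sites.

## Detection, normalization, imputation

*Detection rule.* A site is detected in a tissue when at least
`min_replicates = 2` replicates of **one** sex quantified it there; a site
detected in no tissue is removed. Zero intensities are treated as missing
(DIA software uses 0 and blank interchangeably for non-quantified cells,
and 0 is not a valid log2 input).

*Normalization.* After log2 transform, each run is shifted so its
observed median equals its tissue's pooled median (the median of all
observed values across the tissue's runs, both sexes). Aligning within
tissue rather than to a global constant preserves genuine between-tissue
abundance differences; a `median_norm_target: global` switch provides the
alternative. Shifts are per-run constants, so within-run contrasts are
untouched.

*Imputation.* Missing cells are left-censored: low-abundance measurements
are preferentially unobserved. Each row (feature) with observed mean μ and
sample SD σ (n−1 denominator) has its missing cells drawn independently
from Normal(μ − 1.8σ, (0.3σ)²) — a downshift of 1.8 log2 units in σ units
with a narrowed width. Rows with σ = 0 (possible only with exactly equal
replicates) fall back to the matrix-wide median of positive row SDs. All
draws come from one seeded generator; observed cells are never touched,
and the imputed mask records exactly which cells were filled.

*Summaries.* Tissue × sex summaries prefer observed replicate means and
fall back to imputed means only where a group has no observation. Final
row standardization uses the population (n) denominator — a display
convention for heatmap z-scores; the across-tissue statistics used for
term selection (below) use the sample (n−1) convention, with a config
switch (`sd_ddof`) either way. Both conventions pass the selection
fixtures tested.

## Clustering, group ORA, PCA

Standardized profiles are clustered with Euclidean distance and average
linkage (scipy's implementation; an independent O(n³) re-implementation
validates the cophenetic distances in tests), and the dendrogram is cut
into `n_cut_groups = 400` groups (bounded by the row count). Each group is
tested per GO term against all other groups with a 2×2 Fisher exact test,
one-sided in the over-representation direction by default
(`ora_alternative` exposes two-sided), at α = 0.05.

PCA treats tissue-sex samples as observations and sites as features
(scikit-learn, full SVD). Component signs are fixed by making the
largest-|loading| entry of each component positive, so outputs are
reproducible. Top-loading extraction ranks features by |loading| per
component, with a helper for the intersection of the PC1 and PC2 top
sets.

## Ontology handling and term selection

The is-a hierarchy is held as a child→parent edge map (read from a
two-column edge list or the `is_a` edges of an OBO file) with memoized
ancestor sets and cycle detection. Annotation closure adds every ancestor
of each direct term, so a protein annotated to a leaf counts for all
containing categories.

Per-tissue enrichment tests each term's annotated proteins among the
tissue's acetyl proteins against the rest of the background universe.
The universe is the detected (non-enriched) proteome — here, every
protein in the supplied FASTA — falling back to the acetyl proteins when
no proteome is given. Cells where no test is computable (a tissue with no
acetyl proteins) are set to p = 1.0 exactly, and −log10(1.0) = 0.

Term selection keeps terms whose −log10 p across tissues has SD > 0.6,
minimum < 0.6, and maximum > 3 (all strict) — i.e., terms that are
strongly enriched somewhere and near-null somewhere else. Overlap pruning
removes one member of each pair whose annotated-protein sets overlap by
more than 90 %, where overlap = |A∩B| / min(|A|, |B|); exactly 90 % keeps
both. The member with the larger maximum −log10 p survives (ties broken
by lexicographically smaller id) so the pruned list is deterministic and
keeps the more informative term. Parent–child pruning then drops any term
that is an ancestor of another retained term. Per-tissue uniqueness
Z-scores each term's −log10 p vector across tissues and ranks by
z(tissue) − mean z(other tissues); constant terms score 0; the "other 14
tissues" wording generalizes to n−1 for any design.

## Motif logos

Foreground flanks are the ±7-residue windows around acetyl sites (from
the site report); the background is every lysine in the proteome, with
termini padded by `_`. Padding characters are excluded from frequencies,
so edge columns are not diluted. Information content per position uses
the uniform 20-residue background, IC = log2 20 + Σ p log p, without a
small-sample correction (a proteome-composition background is a config
option). Foreground/background comparison adds a pseudocount of 0.5 per
residue per position to both matrices before taking log2 ratios — absent
residues stay finite with minimal distortion — and excludes the center
position (all-K in both sets by construction).

## Structural context

PDB files are parsed by fixed columns (v3.3 ATOM/HETATM records), taking
the first model of multi-model files. pLDDT is read from the B-factor
field — the convention of predicted-structure archives — per residue; if
atoms of one residue disagree, their mean is used with a warning.

SASA uses the Shrake–Rupley algorithm implemented directly: `n_points =
100` quasi-uniform points per atom placed by the deterministic
golden-section spiral on the sphere of radius r_vdW + probe (probe
1.4 Å, the water-probe convention; vdW radii C 1.70, N 1.55, O 1.52,
S 1.80, H 1.20, P 1.80, default 1.70 Å). A point is accessible iff it
lies strictly outside every other atom's expanded sphere — a point
exactly on a neighbor's sphere counts as accessible, which makes
coincident-atom cases deterministic. Neighbor search uses a k-d tree with
the exact occlusion radius bound. Hydrogens and heteroatoms are included
by default, with toggles for both. Accuracy anchors: an isolated atom is
exact by construction (all points accessible); two intersecting equal
spheres agree with the closed-form spherical-cap area 2πR(R + d/2) within
2 % at 960 points; and per-atom values agree with Biopython's
implementation within 5 % on a test helix.

Sites join structures by residue index (predicted models number residues
by sequence position); a site whose structural residue is not lysine is
flagged and excluded from distributions, and sites without a structure
are dropped with a log entry.

## Variant mapping and fold enrichment

Variant rows join sites on (mouse protein, position); every variant row
either joins or is counted unmatched. Joined rows whose reference residue
is not lysine are excluded with a warning. Free-text clinical labels
normalize via {Pathogenic, Likely pathogenic} → pathogenic and {Benign,
Likely benign} → non-pathogenic, everything else uncertain. K→Q is
flagged as an acetyl-mimic (glutamine removes the lysine positive charge,
as acetylation does); K→R is charge-preserving; K→E/D charge-reversing.

For the fold-enrichment curve, each site's abundance is the mean of its
detected (never imputed) log2 values, restricted to runs in tissues where
the site passes the detection rule — stray sub-detection singletons in
other tissues would otherwise drag the mean by several log2 units. Sites
are ranked and split into `n_rank_bins = 10` equal-count bins (ties broken
by site key for determinism); fold = bin pathogenic fraction / overall
pathogenic fraction, so the site-count-weighted mean of folds is exactly 1
and bin pathogenic counts sum to the total.

## Synthetic data generator

The generator emulates the target study design — 15 tissues × 2 sexes ×
3 replicates, 2 000 acetyl sites on 400 proteins — and writes exactly the
files the pipeline reads, plus a JSON truth record. Defaults:

* Proteins are uniform-random 20-letter sequences of length 200–400
  (so lysine frequency ≈ 5 %); 800 additional background proteins carry
  no sites and pad the enrichment universe to a realistic acetyl:detected
  ratio of about 1:3.
* 20 % of sites are tissue-specific, placed on 7 dedicated proteins per
  tissue, with home-tissue abundance ~23 log2 units and an off-state
  latent level of 10; the rest are common sites with per-site base
  abundance N(20, 1.5²), present in each tissue with probability 0.6.
  Replicate noise is N(0, 0.4²).
* Missingness is left-censored: P(missing | x) = sigmoid((16 − x)/1) of
  the latent log2 intensity, so ~18 % of cells at 17.5 and ~99.8 % at the
  off-state level are missing. The off-state level (10) is set low enough
  that a false extra "detected" tissue (≥ 2 strays in one tissue × sex)
  is rare, while stray singletons still occur.
* One ontology leaf term per tissue annotates exactly that tissue's
  dedicated proteins; 40 filler terms annotate random proteins under a
  five-branch tree with occasional shortcut edges (acyclic by
  construction).
* Glutamate is planted at flank position −1 in 60 % of site flanks
  (an upstream-acidic preference), rewritten into the proteome so the
  report flanks and FASTA agree.
* Structures are ideal α-helix CA traces (2.3 Å radius, 1.5 Å rise,
  100°/residue) with planted per-residue pLDDT in the B-factor; one
  lysine per chosen protein is buried under a 40-atom heteroatom shell,
  one well-separated lysine stays exposed.
* Every site receives one mouse→human variant row; the pathogenic label
  probability is a logistic in the site's z-scored true abundance with
  slope 20. The slope and full coverage were chosen by a truth-level
  Monte Carlo (2 000 replicates) so that the empirical decile fold curve
  is monotone non-decreasing in ≥ 99 % of seeds — with partial coverage
  or a shallow slope, binomial noise in saturated or flat bins breaks
  strict monotonicity far more often. A strength-0 switch removes the
  association for flat-curve checks. About 5 % extra rows map to
  non-site lysines to exercise unmatched-row accounting.

Every generator is a pure function of its parameters and one seed; a
repeated seed reproduces all files byte for byte.

**What the generator does not emulate:** peptide-level identification
(sites appear directly, not via peptides), correlated co-regulation
between sites on one protein, realistic amino-acid composition or
disorder in sequences and structures (helix CA traces only — absolute
SASA values are not protein-like, only contrasts such as buried vs
exposed are meaningful), search-engine score distributions, batch
effects beyond per-run shifts, and ortholog mapping ambiguity. Passing
tests therefore demonstrate correctness of the computations and
recoverability of planted signal under the stated noise model, not
performance on real tissue data.

## Problem sizes and runtime

The default test suite and the acceptance script run the full atlas-like
scenario (90 runs, 2 000 sites, 1 200 proteins, 20 structures) in a few
seconds per pipeline pass on one CPU; clustering cuts 400 groups, and
SASA runs at 100 points per atom on CA-trace structures. The
Fisher-versus-enumeration sweep covers every 2×2 table with N ≤ 30.

## Known limitations

* Group ORA treats sites (leaves) as independent units even when several
  sites share one protein's annotations.
* The overlap-pruning keep-rule depends on the enrichment matrix when one
  is supplied; without it, ties fall back to lexicographic order only.
* `cut_tree` group labels follow scipy's ordering; group identities are
  stable only up to relabeling under row permutation.
* The Shrake–Rupley point test is strict-interior; SASA therefore has a
  small upward bias of order 1/n_points at contact surfaces.
* Imputation is feature-wise; with very few observed values the row SD is
  a noisy scale estimate, which the detection filter (≥ 2 observations)
  only partially mitigates.
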
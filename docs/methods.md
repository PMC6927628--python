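# Methods

This note documents the models, defaults, and numerical choices behind
`hybriddetect`, and what the synthetic-data generator does and does not
emulate.

## Dominant-marker data model

Markers are scored strictly binary (1 = band present, 0 = absent).
Dominant fingerprints (RAPD, AFLP) cannot distinguish heterozygotes from
homozygous band carriers, so a band corresponds to "at least one
presence allele" at a biallelic locus whose other allele is a recessive
null.  Missing data is not modelled: a "?" state would change every
downstream definition (band categories, diagnostics, Dice), and
bench-scored dominant datasets are normally reported complete.

Band categories follow the standard conventions: *monomorphic* = present
in every scored specimen, *polymorphic* = present in at least one but
not all, *unique to a taxon* = present in ≥ 1 specimen of that taxon and
in none of the other, *diagnostic* (species-specific) = present in every
specimen of one parental group and absent from every specimen of the
other.  Query (putative hybrid) specimens never influence unique or
diagnostic calls, so the diagnostic sets are invariant to adding
queries.  Loci carried only by outgroup specimens are removed before
categorisation and reported.  Strict fixation is the default for
diagnostics; a `diagnostic_tolerance` parameter (max violating specimens
per parental group, default 0) is exposed because real studies sometimes
accept near-fixed markers without stating a rule.  Because the
literature is ambiguous about whether "species-specific" totals include
within-species-polymorphic unique bands, both the unique and the
diagnostic sets are computed and reported separately.

## Distances, trees, ordination

Pairwise similarity is Dice, S = 2a/(2a+b+c): shared absences are
uninformative for dominant markers and are ignored.  Distance is
D = 1 − S, bounded in [0,1].  Specimens with no bands at all have
undefined similarity and are rejected.

UPGMA uses average linkage (SciPy) with merge heights equal to half the
average inter-cluster distance, giving an ultrametric rooted tree
(verified to 1e-9).  Neighbor joining uses the Saitou–Nei criterion via
scikit-bio; negative branch-length estimates (possible on non-additive
inputs) are clamped to zero and logged.  Bootstrap support resamples
loci (columns) with replacement at the original count; replicates that
produce an all-absent specimen are redrawn (at most 100 retries).
Support is the percentage of replicate trees containing each internal
bipartition of the point-estimate tree — unrooted splits for NJ, rooted
clades for UPGMA.  Whether resampling should respect marker-method
strata is genuinely open; combined-matrix resampling is the default and
`stratify_by_source` resamples within each locus source instead.

PCoA is classical scaling: double-centre the squared-distance matrix and
eigendecompose.  Dice distances are mildly non-Euclidean; no
Cailliez/Lingoes correction is applied by default, negative eigenvalues
are excluded from the variance denominator, and their absolute mass is
reported so distortion can be assessed.  Distance matrices export to
square PHYLIP and delimited text for external split-network software;
split networks themselves are out of scope.

## Hybrid index

With m_A markers diagnostic for parent A and m_B for parent B, and a
specimen carrying c of the B markers and lacking a of the A markers:

* raw: (c + a) / (m_A + m_B)
* normalized: (c/m_B + a/m_A) / 2

Both variants are always computed and reported because the two
conventions coexist in practice and differ whenever m_A ≠ m_B: raw
weights every marker equally, normalized weights each parental set
equally and is exactly 0.5 at full additivity.  Display rounding is
half-up at 2 decimals; full precision is kept internally.

Class calls are made from configurable intervals on the index (defaults:
pure ≤ 0.2 or ≥ 0.8, F1 window 0.4–0.6, backcross otherwise), with two
marker-count guards: a pure call requires zero opposite-parent markers —
a pure-range index with foreign markers is flagged *introgressed* — and
an F1 call requires at least one marker from each parent.  The
thresholds are configuration, not constants, because class boundaries
are conventional rather than derived.  Likelihood-based assignment of
cross classes (NewHybrids-style posteriors) is deliberately out of
scope.

## Admixture model for dominant markers

A simplified STRUCTURE-type model: admixture ON, correlated frequencies
OFF, recessive-allele coding for dominant data.  Each individual i has
memberships Q_i ~ Dirichlet(alpha, …, alpha) (alpha fixed, default 1.0);
each cluster k has independent band-presence allele frequencies
p_kl ~ Beta(1,1).  Individuals are diploid; gene copies independently
pick a cluster from Q_i and an allele from that cluster, and the band
phenotype is the dominance OR of the two copies:

    Pr(band | Q_i, P) = 1 − (Σ_k q_ik (1 − p_kl))².

The Gibbs sweep augments latent variables per individual-locus: the
number of presence alleles given the phenotype (for a shown band,
Pr(two copies) = θ/(2 − θ) with θ the mixture presence probability),
then a cluster of origin per copy by Bayes' rule, then conjugate
updates P | counts ~ Beta and Q | counts ~ Dirichlet.  Frequencies are
clamped to [1e-9, 1 − 1e-9].  Runs are bit-reproducible under a fixed
seed.  The reported log-likelihood is the phenotype log-likelihood
averaged over retained sweeps (what the ΔK statistic consumes).  Default
desk-scale chains are 2 000 burn-in + 10 000 sweeps with thinning 10;
production-scale settings (10⁵/2×10⁵, 10 replicates) are plain
configuration.  Sampling alpha is not implemented; alpha is a fixed
hyperparameter.

ΔK = |mean L(K+1) − 2·mean L(K) + mean L(K−1)| / sd L(K) over replicate
runs, defined for interior K only; a K with zero replicate sd is flagged
and excluded from the argmax.  Label switching across replicates is
resolved by permuting cluster columns to minimise the total absolute
difference from a reference replicate — exhaustive over K! permutations
for K ≤ 8, Hungarian assignment above (the cost is column-separable, so
the assignment solution is also exact); full CLUMPP-style similarity
machinery is out of scope.

## Sequence diagnostics

Inputs are pre-aligned (alignment computation is out of scope);
alignment columns are the coordinate frame, 0-based internally and
1-based in every report.  A diagnostic SNP is a column where each
parental group is fixed for a different non-gap state;
`min_group_fixation` (default 1.0) relaxes fixation to a modal-state
fraction, since published "unambiguous marker" filters are rarely
stated.  A diagnostic indel is a maximal run of columns all-gap in every
sequence of one group and gap-free in every sequence of the other;
partially gapped columns never qualify.  Clones are scored per site as
A-state, B-state, or novel (any third state, including gaps at SNP
columns and partial gaps across indel runs); counts always sum to the
number of diagnostic sites.

## In-silico PCR-RFLP

Digestion is exact string matching of the recognition site on a linear
molecule, cutting at the enzyme's offset.  The built-in panel covers
AluI, DraI, HindIII, HinfI, MboI, MseI, MspI, PstI, TaqI and XbaI — all
palindromic cutters, so forward-strand matching covers both strands;
custom enzymes can be supplied as name → (recognition, cut offset).
IUPAC ambiguity codes are honoured in recognition sites (HinfI's GANTC)
but an N in the *sequence* never matches — conservative digestion.  The
digest is cross-checked against the Bio.Restriction implementation in
the test suite.  Haplotypes group specimens with identical multi-enzyme
fragment-length profiles (optional per-fragment bp tolerance, default
0); ids are assigned in a canonical order of the profiles so they are
stable under specimen reordering.  A haplotype × specimen-group table
supports maternal-parent inference.

## Synthetic-data generator

The generator emulates the study design the analysis assumes, with
defaults chosen once:

* 10 + 10 parental specimens, 5 F1s, no backcrosses unless requested;
* 51 A-diagnostic + 44 B-diagnostic loci (the study-scale configuration)
  among 595 total;
* diagnostic loci fixed (presence-allele frequency 1 vs 0) — this is
  what "unambiguous species-specific marker" means by construction;
* background loci draw independent per-species band-allele frequencies
  from U(0.1, 0.9); the range is validated to exclude fixation so
  background loci cannot be structurally diagnostic.  Neutrality and
  independence are assumptions of convenience — no within-species
  frequency spectrum is available to calibrate against;
* parental genotypes in Hardy–Weinberg proportions; F1 = one gamete
  from each species; BC1 = one recurrent-parent gamete plus one gamete
  drawn allele-wise from an F1 (unlinked loci, so non-recurrent
  diagnostic presence alleles transmit with probability ½);
* phenotypes by strict dominance;
* hybrid-novel bands — a real phenomenon attributed to heteroduplex
  formation or meiotic rearrangement — are modelled phenomenologically:
  each background locus is reserved as hybrid-novel with probability
  `novel_band_rate` (default 0.05, matching the order of magnitude of
  novel-band fractions reported for dominant fingerprints of hybrids),
  its parental frequencies set to 0 and each hybrid showing it with
  probability 0.8;
* optional uniform scoring errors (default 0).

What this does *not* emulate: within-species genealogy (no coalescent),
linkage, later-generation hybrid classes (F2, BC2+), comigration of
non-homologous bands, or any mechanistic model of novel bands.  Tests
passing on these simulations therefore demonstrate correctness of the
analysis chain under its own assumptions, not robustness to the ways
real fingerprints violate them (band homoplasy above all).

The alignment simulator plants an exact number of fixed SNP differences
and group-specific gap runs at non-overlapping random positions, adds
decoy within-group polymorphism at non-planted columns only, and builds
clones as parental mosaics with optional novel states.  The plastid
simulator applies caller-specified edits to a shared backbone to create
haplotypes and hands each specimen its maternal lineage's sequence
verbatim — strict maternal inheritance, no heteroplasmy.

## Determinism and problem sizes

Every stochastic stage takes an explicit seed; the pipeline derives
per-stage seeds by hashing (global seed, stage name) with SHA-256
truncated to 31 bits, so adding a stage never shifts existing streams.
The test suite and the acceptance script run at desk scale by choice:
recovery experiments use 200 simulated hybrids per class, and ΔK
selection uses 25 specimens × 200 loci with three replicate chains of
2 000 + 10 000 sweeps for K = 1..4, which reproduces the K = 2 choice
decisively (ΔK at K = 2 exceeds the runner-up by more than an order of
magnitude).

## Known limitations

* No missing-data state; matrices must be complete.
* Dice-based trees inherit band-homoplasy biases of dominant markers;
  supports should be read as repeatability, not as clade probability.
* The admixture sampler assumes unlinked loci and uncorrelated cluster
  frequencies; with few loci and closely related clusters the ΔK
  statistic can be unstable at small replicate counts.
* Class calls from index intervals are conventions; specimens near
  interval edges should be inspected alongside their marker counts.
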
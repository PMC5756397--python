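# Methods

This note records the models, conventions and deliberate design choices
behind `ascbias`, in the order the pipeline applies them.

## Data model

Two sources describe the same populations. The *array* side is an
individuals × SNPs matrix of alternative-allele dosages (0/1/2, NaN for a
missing call), each sample assigned to a population. The *reference* side is
a populations × SNPs table of alternative-read counts and sequencing depths
from pooled whole-genome sequencing, with the number of pooled individuals
per population. Both reduce to a populations × loci matrix of
alternative-allele frequencies — allele counts over 2×(called diploids) on
the array side, read proportions on the pooled side — and every diversity
statistic is a function of that matrix plus the per-population sample sizes.

## Harmonization

Loci are matched across sources by (chromosome, position), 1-based as in
VCF, with chromosome names compared as exact strings after stripping an
optional `chr` prefix. Four discard steps run in a fixed order: SNPs with
undefined positions; *all* members of any within-dataset position collision;
loci absent from the other source or on a disallowed chromosome (default
allowed set: "1"…"28", configurable because synthetic data use arbitrary
names); loci whose ref or alt allele disagrees between sources. Mismatches
are dropped, never repaired — no strand flipping, liftover or multi-allelic
decomposition is attempted, matching the discard-not-repair philosophy of
array/sequence harmonization. Duplicate-position removal is applied to both
datasets (not only the array) with separately logged counts; the retained
reference records adopt the array-side SNP ids so that downstream subset
lists are a shared currency.

## Filters

*Call-rate QC* retains SNPs with call rate strictly above 0.99, then samples
strictly above 0.95 — the strictness mirrors the usual ">99%" phrasing of
array QC protocols. *MAF filtering* retains loci with min(p, 1−p) ≥ 0.05
computed on the full pooled sample, so exactly-5% loci survive. *Reference
polymorphism* ("GG" versions) retains loci segregating in designated
reference populations; "polymorphic" defaults to the pooled reference sample
having a frequency strictly inside (0, 1), with `each`/`any` per-population
modes available since either reading is defensible. The composition order of
the eight versions is prune → reference-polymorphism → MAF.

*LD pruning* slides a window of 50 retained SNPs, advancing 5, per
chromosome. The default pairwise mode removes, from any retained pair with
dosage r² > 1 − 1/VIF = 0.5 (pairwise-complete observations, composite LD on
unphased dosages), the member with the lower overall MAF — ties removing the
later-positioned SNP; the pair with the largest r² is resolved first. A
`vif` mode instead removes the SNP whose variance inflation factor from a
multiple regression on the other window SNPs exceeds the cap, largest first.
Both modes exist because the window/step/VIF parameterization and the
"remove the lower-MAF member of a correlated pair" description are two
different mechanisms; the pairwise mode is the default as the more explicit
contract. The per-chromosome pass repeats until a full pass removes nothing.
A single sliding pass cannot guarantee idempotence (removals can bring
previously distant SNPs into a common window); iterating to a fixed point
can, at the cost of typically one extra cheap pass, and makes "pruning a
pruned set removes nothing" an invariant rather than an accident.

## Diversity statistics

F_ST is the variance-of-frequencies estimator s²/(p̄(1−p̄)) with the
sample-size-weighted s² whenever sizes differ, and the reported value is the
*mean of per-locus ratios* ("averaged across loci" read literally); a
ratio-of-sums mode exists for sensitivity analysis. Loci with p̄(1−p̄) = 0
are excluded from F_ST (the ratio is undefined) but monomorphic loci still
contribute H_e = 0 within a population — fixation is real information about
within-population diversity, and the reference spectrum's last bin keeps
fixed-alternative loci for the same reason. Nei's distance uses the 1972
standard-distance biallelic form with the J sums over the loci non-missing
in both members of each pair; a non-positive identity is reported as +inf
with a warning rather than an exception, since one degenerate pair should
not abort a matrix.

PCA operates on the column-centered populations × loci frequency matrix via
SVD — the only representation available for pooled data, and therefore the
comparable one across both sources; an individual-dosage mode
(mean-imputed) exists for array-only exploration. Variance explained is
relative to total variance. Loci with any missing frequency are dropped
before centering.

The allele-frequency spectrum uses 40 bins of width 0.025, left-closed with
a closed last bin so a frequency of exactly 1 is counted.

Genic classification is positional overlap with gene intervals, 1-based
inclusive on both ends; GFF3 is read natively (1-based) and BED converted
from its 0-based half-open convention.

## Trees and tree distances

Neighbor joining is the standard Q-criterion agglomeration with two fixed
conventions: ties in Q break toward the smallest node-creation-order index
pair, and negative estimated branch lengths are clamped to zero and counted
(no redistribution). Both make runs bit-reproducible.

Two tree distances are reported. The partition (Penny–Hendy) distance
counts the non-trivial tip bipartitions induced by exactly one of the two
trees — 0 iff the topologies agree, 2 for two conflicting resolved
quartets. The branch-length distance is the branch-score form: branches are
matched by the bipartition they induce, matched pairs contribute the squared
length difference, unmatched branches their squared length, and the result
is the square root of the total. When topologies agree this reduces exactly
to the Euclidean distance between branch-length vectors ("the branch lengths
that need to be erased"); it is *not* the geodesic tree-space distance,
which interpolates through intermediate topologies and would require a
different algorithm entirely. All branches, terminal and internal, enter the
sum. The two child edges of a bifurcating root are merged into one branch so
rooted and unrooted serializations of the same tree compare as equal.

## The comparison harness

Array-derived statistics are always the regression *response* and
reference-derived statistics the *predictor* (slope > 1 then reads
"the array overestimates, more so for diverse populations"); an orientation
flag is unnecessary because `regress(y, x)` is exposed directly. Per-pair
F_ST values are pooled as observations of one regression. Because distances
between Nei matrices scale with the number of loci, each version is judged
against 100 replicate reference subsets *of the same SNP count*, drawn
without replacement from the full reference locus set; replicate r uses the
deterministic stream seed+r so any single replicate can be regenerated in
isolation. Replicate-vs-replicate distances provide the null distribution;
all C(n,2) pairs are used up to 1,000, beyond which a seeded subsample keeps
the cost bounded. Report JSON is serialized with sorted keys and NaN mapped
to null, so identical seeds give byte-identical files.

## The synthetic generator

The generator emulates the statistical structure the analysis consumes, not
sequences. Population frequencies follow the Balding–Nichols model: each
locus draws an ancestral frequency p₀, and each population draws
p ~ Beta(p₀(1−F)/F, (1−p₀)(1−F)/F) with its own drift parameter F (star
topology), or recursively along a newick tree whose edge lengths are
per-edge F values. This was chosen over coalescent simulation deliberately:
the pipeline consumes frequency-level data, Balding–Nichols has closed-form
moments (E[2p(1−p)] = 2p₀(1−p₀)(1−F)) that make calibration testable, and it
runs in seconds. Genotypes are Hardy–Weinberg draws; within LD blocks each
haplotype shares one uniform "template" value across the block, re-drawn
per locus with probability 1−`ld_decay`, which preserves the Bernoulli(p)
marginal exactly while inducing tunable within-block r² — enough to exercise
window-based pruning, though it is not a recombination map. Pooled reads are
Poisson-depth binomial draws from the realized sample frequencies (the DNA
actually in the pool), with no sequencing-error model beyond binomial
sampling. Ascertainment draws the discovery panel once (seeded), and keeps
loci polymorphic in the panel with panel MAF at or above the cutoff, MAF
computed on the 2×(panel individuals) allele sample as in array design
practice.

What the generator does *not* model — genotyping error, reference-genome
mapping bias, variable pool composition, selection, real LD decay — bounds
what passing tests show: they demonstrate the pipeline's statistics and the
direction and mechanism of discovery-panel bias, not magnitudes expected on
any particular real dataset.

### Packaged scenarios

- `default_bias` — 8 populations, star topology, F = 0.02…0.30 (two
  wild-like high-diversity populations, two "commercial" panel lines at
  F = 0.08/0.12, four more-drifted breeds), ancestral frequencies
  Beta(0.5, 1.5) (rare-heavy, mean 0.25), 50,000 loci, 10 diploids per
  population, 4+4 panel, MAF cutoff 0.05, 20X pools, 0.5% array
  missingness. Sample sizes and coverage mirror a realistic pooled-WGS
  diversity panel; the locus count keeps a full comparison run near 15
  seconds while leaving Monte-Carlo noise far below the effects measured.
- `null` — the panel is everyone and the cutoff 0, so the array keeps every
  segregating locus: the no-bias control.
- `strong_ld` — 4 populations, 5,000 loci in 20-SNP blocks with
  template-copy fidelity 0.95 and 20 diploids per population (stable r²
  estimates), for exercising the pruner.

## Numerical conventions

Missing data are NaN throughout; frequencies from zero depth or all-missing
genotype columns are NaN and excluded pairwise. Dosage validation admits
only {0, 1, 2, NaN}. Identity-forced negative zeros and −1e−16-type
rounding in Nei distances are clamped to 0. All randomness derives from one
root seed through crc32-tagged substreams (`_rng.substream`), so stages are
independently reproducible and a CLI run is byte-deterministic.

## Known limitations

Pooled F_ST uses the number of pooled individuals as the sample size, which
ignores the extra variance of read sampling at finite depth; at 20X this
second-stage variance slightly inflates pooled-side s². The pairwise-mode
pruner guarantees its window contract only at the window positions it
visits (every 5th retained SNP); pairs further than the window width apart
are never tested, as in any windowed pruner. PCA on population frequencies
weights populations equally regardless of sample size. The `vif` pruning
mode costs one least-squares solve per SNP per window and is meant for
small panels, not full arrays.
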
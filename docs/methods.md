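# Methods

## The synthetic community

The generator emulates a pond mesocosm in which a rare virus genotype is
selected after its host strain is added. One random backbone genome (length
drawn uniformly in 44–46 kb unless fixed; GC 0.63) is mutated into species
ancestors, species ancestors into group ancestors, and group ancestors into
genome "members":

| layer | per-site divergence (default) | role |
|---|---|---|
| species vs backbone, outside islands | 0.12 | genus-level backbone mosaic |
| species vs backbone, inside islands | 0.30 | species-specific hypervariable island |
| group vs species ancestor | 0.02 | nine intra-species variant groups |
| member vs group ancestor | 0.002 | near-identical isolates per group |

Species 1 carries `n_groups` (default 9) groups of `genomes_per_group`
(default 2) genomes; every further species is a single genome, mirroring a
study system where one species had a lone isolate. Unrelated background
genomes (GC 0.5) provide off-target reads.

Mutations are substitutions only, applied as i.i.d. site resampling:
a hit site is redrawn from the genome base profile restricted to the three
other bases. This keeps identity arithmetic exact (no alignment ambiguity),
preserves GC under divergence, and allows back-substitutions; consequently
the *realised* pairwise identities, not the nominal rates, are what the
generator validates — after emission it checks by direct site counting that
within-species identity exceeds 0.95 and between-species identity lies in
(0.70, 0.95), rejecting configurations that break the planted taxonomy.
The config-level check of the same bands uses closed-form expectations and
carries a 0.02 slack, because layered mutation rounds are not independent;
the post-hoc count is authoritative.

**Island placement.** Islands diverge *between* species only; within a
species the island is conserved among all members. This is the only
placement consistent with keeping within-species identity above the species
threshold (a 3 kb island at 0.30 divergence inside a 45 kb species would
drop genome-wide identity to ~0.93), and it reproduces the observed
mechanism: at t0 the focal genome's profile is covered across the shared
backbone by reads of the *other*, abundant species — the "close relatives
sharing part of their genomes" — which fail inside the island, producing
the low-recruitment signal; the sweeping genotype and its within-species
companions later fill it.

**Abundance trajectory.** The sweep genotype follows a logistic
`f(t) = A·σ(r(t−m))` with midpoint `m` pinned at the median timepoint and
`(A, r)` solved (Brent) so that `f(t₀) = f₀ = 10⁻⁴` and
`f(t_end) = f_end = 0.5`. Its within-species companions (the rest of the
natural species-like population) rise in parallel with total mass `f(t)`,
the resident species absorbs `1 − background − 2f(t)` (floored at 0), the
background holds a fixed share (default 0.1), and weights are renormalised.
Note that with these endpoints the logistic saturates before the final
timepoint (`f(336 h) ≈ 0.49990` vs `f(672 h) = 0.5`), so the *expected*
read-count difference between the last two samples (~0.1 read) is far below
counting noise (σ ≈ 21 reads at 5000 reads/sample): observed trajectories
rise strictly to a plateau and then fluctuate within it, which is how
downstream checks treat "increasing abundance".

**Reads.** Fixed length (250 bp), uniform starts, random strand, per-base
substitution errors at 0.005; read ids are opaque serials assigned after
shuffling, so origin lives only in the truth record. Amplicon pools use a
lower default error (5 × 10⁻⁴) because they stand in for merged paired-end
consensus reads: with single-pass error on a ~900 bp amplicon nearly every
read is unique, and 100%-identity phylotyping degenerates to one phylotype
per read.

**What the generator does not emulate** — and hence what green tests do not
show about real data: indels and structural variation, recombination and
mosaicism beyond the planted island, quality-score-correlated errors,
paired-end structure, terminal redundancy, uneven coverage (GC bias),
within-sample strain phylogenies, and any host (16S) community.

## Recruitment

Placement is exact k-mer seeding (k = 15, both strands) followed by scoring
of each candidate diagonal with the maximal-scoring ungapped local segment
(match +1, mismatch −1), found by a vectorised maximum-subarray scan;
identity = matches / alignment columns over that segment, read coverage =
aligned columns / read length. Because the simulator is substitution-only,
ungapped alignment is exact, and the e-value screen of BLAST-style
recruitment is replaced by the two filters the downstream logic actually
consumes: read coverage ≥ 0.70 (inclusive boundary) and an identity floor.
Tie-breaking is total and documented: score, aligned columns, identity,
genome id (lexicographic), strand (+ before −), genome start; within a
diagonal, smallest end then smallest start. Index and query positions can
be subsampled (`step`, `query_step`); an error-free stretch of
k + step − 1 bases guarantees a seed, and the pipeline default
(`query_step=2`) keeps sensitivity ≈ 96% even for the ~79%-identity
cross-species placements that the island analysis relies on.

Two mapping modes mirror the two published uses: best-hit across a
reference set (abundance bookkeeping) and per-reference mapping of all
reads (recruitment plots, population capture, codon variants).

## Dynamics

- Genotype abundance uses the quoted formula with the genotype filter
  (read_cov ≥ 0.7, identity = 1.0); report layers multiply by 1000 for
  display. Fold change between consecutive timepoints is reported missing
  (not infinite) when the previous value is 0.
- Population capture: denominator identity ≥ 0.95, numerator identity
  = 1.0, both after the coverage filter; undefined (None) on an empty
  denominator. Sequencing errors deflate the numerator — at 0.005/base only
  28.6% of 250 bp reads are error-free — so pipeline capture values sit
  well below the planted genotype fraction; the estimator itself is
  unbiased on error-free pools, which is what the calibration tests check.
- Island calling is window-based (the original islands were identified
  visually): non-overlapping 500 bp windows, a window is "low" when its
  mean depth ≤ 0.2 × the genome **median** depth (median, not mean, so the
  island itself cannot drag the denominator), adjacent low windows merge,
  and merged runs ≥ 1000 bp are reported. Genomes whose median depth is at
  or below 5 are "absent" and yield no calls. Island status over time:
  "filled" when the island's depth ratio reaches 0.8 (inclusive). Depth
  profiles for island work use identity floor 0.7, matching the recruitment
  plots' permissive floor rather than the species threshold — the island
  signal *is* the difference between backbone placements (~79% identity,
  retained) and island placements (~56% identity, rejected or trimmed).

## Taxonomy

Dereplication keeps genomes ≥ 43 kb and collapses a genome that aligns to
a longer retained one at identity ≥ 1.0 over ≥ 80% of its own length
(equal-length exact-identity pairs reduce to sequence equality).
Intergenomic similarity is "VIRIDIC-style": the shorter genome is cut into
1 kb windows (step 500), each placed by the ungapped aligner; identity is
the alignment-weighted mean and the score is
`identity × min(aligned fraction of either genome) × 100`. VIRIDIC's exact
formula is not restated in the literature this mirrors; this operational
form keeps the two ingredients (identity, aligned fraction) explicit.
Species and genera are single-linkage components at > 95 and ≥ 70 —
pairwise ICTV-style thresholds operationalised as connected components,
computed on canonically sorted ids so assignment is input-order invariant.

Intra-species groups: reciprocal-best-match AAI between translated ORF sets
(equal-length protein pairs by direct comparison; unequal by edit
distance), Bray–Curtis dissimilarity between AAI matrix rows,
average-linkage hierarchy. The cut is configurable (group count or height);
the default cuts at the largest gap between successive merge heights, which
is well-defined whenever between-group dissimilarity dominates within-group
(the recovery tests require a ratio ≥ 5, comfortably met at the default
0.02/0.002 divergences). Per group the longest genome is the reference
(ties: fewest ambiguous bases, then smallest id) — "largest and most
complete", with completeness beyond length not operationalised.

ORF calling (used when planted annotations are disabled): maximal
start-to-stop frames ≥ 300 nt on six frames, standard code, longest-first
non-overlap selection.

## Diversity

Phylotypes are exact-sequence clusters: after a reference screen (fraction
of a read's 21-mers contained in the reference genomes' k-mer set ≥ 0.25 —
a deterministic stand-in for the published similarity-search filter whose
role is to drop spurious sequences), exact duplicates collapse and a
shorter read that is an exact substring of a longer retained read joins
that phylotype. Rarefaction draws once per sample without replacement
(multivariate hypergeometric, seeded); the Shannon index uses natural log.

Codon variants follow the DiversiTools flag conventions: codon coverage
counts only reads spanning all three positions; codons below coverage 5
are skipped; an alternative codon is counted only with ≥ 4 reads *and*
≥ 1% frequency (percent reading of the frequency flag); counted
alternatives are classified against the reference codon under the standard
code; `pN/(pN+pS)` is reported per ORF and undefined when nothing was
counted. Pileups take only fully aligned reads — with substitution-only
data a trimmed alignment signals a read that does not belong at that locus.

## Community distance

Bottom-s MinHash (s = 10000) over canonical k-mers (k = 21, smaller hash of
k-mer/reverse complement) with multiplicity ≥ 2, hashed by a fixed
splitmix64 mixer so sketches are machine- and run-independent. Distance is
the Mash formula on the Jaccard estimate from the bottom-s′ of the merged
union, capped at 1 for disjoint sketches. An exact-Jaccard (unsketched)
counterpart exists purely as a cross-check.

## Problem sizes and determinism

The default replay is sized for a laptop: ~45 kb genomes, 19 isolates +
3 background genomes, 2 ponds × 5 timepoints × 5000 reads, 2000-read
amplicon pools rarefied to 1000 (the published normalisation depths of
11 421 and 61 195 belong to the real datasets; the pool sizes here are the
package's own scaled choice). A full run takes tens of seconds; every
random draw descends from the config seed through fixed per-operation
offsets, outputs carry no timestamps, and reruns are byte-identical.

## Known limitations

Real metaviromes carry indels, recombination and coverage biases that the
substitution-only model excludes, so the aligner's ungapped design and the
exact-identity filters are tuned to this simulator, not to raw Illumina
data. Capture fractions are systematically deflated by sequencing error
(quantified above) rather than corrected; island boundaries snap to the
500 bp window grid; and single-linkage species components can chain in
principle, although the planted divergence bands keep them far from the
thresholds here.
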
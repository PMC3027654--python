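# Methods

`fernbarcode` implements a regional two-locus DNA-barcoding workflow for
ferns: a reference database of the plastid coding marker *rbcL*
(~1300 bp) and the faster-evolving noncoding *trnL-F* region (~900 bp,
*trnL* intron plus *trnL–trnF* spacer), evaluated and applied with two
complementary comparison strategies — distance-based (barcoding gap) and
character-based (maximum-parsimony monophyly with bootstrap support).
This note records the models, the defaults and the design choices made
where the design was genuinely open.

## Reference database and species complexes

A reference set holds, per marker, one or more trusted sequences for
every taxon of a regional species pool. Because the fern chloroplast is
maternally inherited and non-recombining, recent allopolyploids share
their cpDNA verbatim with their maternal donor (and apomictic aggregates
behave the same way). No plastid marker can separate such species, so
they are collapsed into a single *species complex* label before any
analysis: the complex is named after its diploid cpDNA donor
("<donor> s.l."), or after a representative member when the donor is not
in the database. Complexes must be disjoint and confined to one genus.
Subspecies are treated as taxa in their own right. Sequences are
upper-cased, `U` is mapped to `T`, and identifiers are unique per
(sequence, marker) pair — one individual contributes one row per marker
under a shared id, which is how the combined matrix joins partitions.

## Combined character matrix and simple indel coding

Reference alignments are inputs (the workflow assumes curated, manually
checked alignments; the simulator emits the true alignment), and the
package deliberately implements no multiple sequence alignment. Each
marker contributes a nucleotide partition and, optionally, a partition
of binary gap characters produced by simple indel coding: every distinct
maximal internal gap run of length ≥ `min_len` observed in at least one
sequence becomes one presence/absence character; a sequence scores
*present* when its own run spans exactly the character's columns,
*missing* when one of its runs strictly contains them (a larger deletion
makes the smaller event unobservable), otherwise *absent*. Terminal gap
runs are treated as missing data, not deletion events — partial
sequences truncate, they do not delete. `min_len` defaults to 3 so that
±1 bp slippage around the homopolymer run in the spacer is not scored as
an evolutionary event. Coordinates are 0-based, half-open throughout.
Indel characters are coded for both markers by default (the coding
marker rarely yields any). Taxa absent from a marker are filled with `?`
across that marker's nucleotide and indel columns.

## Distances and the barcoding gap

Distances are uncorrected P-distances on the combined nucleotide data
with pairwise deletion: for each pair, sites where either sequence shows
a gap, `?`, or an ambiguity code are excluded; the distance is
mismatches over the remaining comparable sites, and a pair with zero
comparable sites is flagged undefined rather than given a number.
Pairwise (not complete) deletion is the only scheme compatible with
partial per-marker coverage; excluding ambiguity codes rather than
fractionally matching them keeps the statistic the plain "P-distance"
as commonly reported (configurable in principle via the encoding, and
documented here as the fixed default).

Per effective taxon the analysis reports the maximal intraspecific
distance (undefined for single-sequence taxa), the minimal
interspecific distance with its nearest neighbour(s) — ties are all
reported, because plastid-identical complexes make exact ties real —
and their ratio. A taxon is *discriminated* when the minimal
interspecific distance exceeds the maximal intraspecific one. Complexes
are collapsed first, so distances between complex members are
intra-label and never count as interspecific. Aggregates include the
overall mean nearest-neighbour distance and per-genus means of the
minimal distance to a congener (monotypic genera report none).

## Maximum parsimony engine

The matrix is encoded as 4-bit state-set masks (ambiguity codes keep
their base sets; gaps and `?` are the full set and can never force a
change; binary indel characters use a two-state alphabet and are scored
as ordinary equally weighted characters). Site patterns are compressed
with integer weights; patterns whose state sets share a common base
across all taxa cost zero on every topology and are removed while the
original site count is retained, so Fitch lengths are exact.

Tree length is Fitch's two-pass count, rooted arbitrarily at the first
leaf (the score is rooting-invariant). `exhaustive_search` enumerates
every unrooted binary topology by stepwise edge insertion (refused above
9 taxa, i.e. 135,135 topologies) and is the correctness oracle for the
heuristic. `heuristic_search` follows the classic recipe: repeated
random-addition-order stepwise building (first-best attachment; all
stochasticity lives in the seeded addition order), then best-improvement
hill climbing through the SPR neighbourhood (NNI available as a cheaper
option; TBR is not implemented — on matrices of this size SPR from
random additions reaches the same optima, and oracle equivalence on
small instances is the correctness surface). Distinct co-optimal final
trees are retained up to `max_trees` (default 100). The hot kernels
(postorder Fitch pass, stepwise insertion scan, SPR sweep) are
numba-compiled; everything else is numpy/Python.

The nonparametric bootstrap resamples the *original* number of sites
with replacement (constant sites included, so variable-pattern weights
follow the correct binomial law), reruns the heuristic per replicate,
and lets each replicate distribute one unit vote evenly over its
distinct co-optimal trees; a replicate that happens to draw zero
variable sites contributes an unresolved star. Supports are percentages
of replicates per bipartition; the majority-rule consensus keeps splits
strictly above the threshold (default 50%, where pairwise compatibility
is guaranteed) but every observed split's frequency remains queryable,
which is what identification uses. Replicate r draws its random stream
from a seed sequence spawned as (seed, r), so runs are reproducible.
A known approximation: with few addition cycles the engine can
under-sample a replicate's co-optimal trees, which slightly inflates
support for arbitrarily resolved groups when the data are very weak;
with the clean signal this pipeline targets the effect is negligible.

Monophyly queries (`group_support`) return the support of the edge
splitting off exactly the queried group, a sentinel (`NOT_A_CLADE`)
when no such edge exists, and 100 for singleton groups. The resolution
criterion everywhere is bootstrap support > 70%.

## Identification

Two methods are run per query, one query at a time:

*Similarity.* The query is globally aligned to every reference of a
marker with free terminal gaps (match +1, mismatch −1, gap open −4,
extend −1) and ranked by maximal percent identity (MPI): identities over
the terminal-gap-free overlap. Both strands are tried; the orientation
with the higher alignment *score* wins (scores, not identities, because
a wrong-strand query slides past the reference on free end gaps and can
fake 100% identity over a negligible overlap — hits overlapping fewer
than `min_overlap` = 100 sites are discarded for the same reason).
Genus assignment requires every hit above the MPI threshold (95%) to
involve a single genus, for each available marker; conflicting genera
between markers abstain. Species assignment requires the top-MPI
stratum (hits tied at the maximum, tie tolerance 0 by default) to map
to exactly one effective taxon above the threshold; markers that
resolve a unique taxon vote, and disagreement between voting markers
demotes to genus. A complex label is assigned at COMPLEX rank, never as
a species.

*Tree.* The query is pairwise-aligned to its top-MPI reference per
marker and written into that reference's columns of the combined matrix
(query-specific insertions are discarded — placing them would require
realigning the references; terminal truncation becomes `?`, internal
deletions `-`, and indel characters are scored from the reconstructed
row, with spans outside the query's coverage set to missing). A
bootstrap parsimony analysis of references + query follows (20
replicates in query mode). The query is assigned to the finest group —
all sequences of one effective taxon, then of one genus — forming a
clade with support > 70%; support in (50, 70] is reported as
insufficient with the candidate named. Queries whose best identity
falls below 60% are declared unalignable.

The combined verdict is the finest rank on which the non-abstaining
methods agree; species-rank disagreement demotes to the shared genus
with a conflict note. A COMPLEX verdict is afterwards refined by the
nuclear *PgiC* fragment-length rules when band observations exist: the
observed band set must exactly match one member's expectation (single
band for a diploid parent, double band for the hybrid-derived
allotetraploid); members with indistinguishable expectations stay
unresolved. Out-of-region taxa are handled by construction — the
regional database simply does not contain them — rather than by
post-hoc filtering of hits.

Thresholds (95% MPI, 70% bootstrap, the (50, 70] "insufficient" band,
60% identity floor, 100-site overlap floor) live in one
`IdentificationConfig` object. Search presets: database assessment uses
1000 bootstrap replicates × 100 addition cycles, query mode 20
replicates (`FULL_DATABASE_SEARCH`, `QUERY_SEARCH`); tests and
the acceptance script run query bootstraps with 2 addition cycles per
replicate, a desk-scale setting that the oracle-equivalence results
justify for matrices of this size.

## Synthetic data

The generator reproduces the statistical structure the analysis
assumes, at desk scale. Default preset (`nw_europe_ferns`): 5 core
genera × 3 species × 2 individuals plus one deeply divergent monotypic
genus represented by rbcL only (the real pool's ancient lineages whose
spacer cannot be aligned with the rest), and one two-member species
complex (donor + allotetraploid) inside the shallow genus. Divergences
are expected substitutions/site on the length-weighted combined data:
intraspecific 0.002, interspecific 0.035 (0.007 within the one shallow
genus, mimicking the hardest congeners), intergeneric 0.09. Species
within a genus split at depths uniform in [0.5, 0.55] × the genus's
interspecific divergence, so each species' nearest-neighbour distance
sits just above it; with one shallow genus the overall mean
nearest-neighbour distance lands near 0.03 and the shallow genus mean
near 0.005–0.008. The noncoding marker evolves twice as fast as the
coding one, with both rates scaled so the combined expectation matches
the nominal divergences.

Sequences evolve site-independently under a Jukes–Cantor process
(Poisson substitution counts per branch, uniform base exchange) —
uncorrected distances and equal-weights parsimony gain nothing from a
richer model. The noncoding marker additionally accumulates deletions
(0.02 events per substitution, geometric lengths of mean 4) placed
inside a protected 50 bp margin and never overlapping, so the true
alignment is emitted directly; and it carries a homopolymer C-run whose
length jitters by ±1 per individual — below the indel-coding length
threshold, as intended. Complex members copy their donor's individual
sequences byte-for-byte on both plastid markers, and complex queries
descend from the donor's lineage, as uniparental plastid inheritance
dictates. Queries evolve a fresh individual from the species ancestor,
are cut to a contiguous window of fractional coverage
Normal(0.85, 0.05) clipped to (0.3, 1], lose trnL-F with probability
0.05 (amplification failures hit the noncoding marker; the coding
backbone amplifies reliably), and are reverse-complemented with
probability 0.2. Everything is deterministic given the seed.

What the simulator does *not* emulate — and hence what passing tests do
not show about real data: alignment uncertainty and alignment error
(true alignments are emitted), codon structure and among-site rate
heterogeneity, sequencing error and chromatogram quality, contamination
and mixed templates, insertions (deletions only), and taxa genuinely
missing from the reference pool. Results on real databases depend on
those factors, especially on curation of the reference alignments.

## Numerical choices and degenerate inputs

Ties in stepwise addition and hill climbing are broken first-best in a
fixed scan order, so a run is a pure function of the seed. Nearest-
neighbour ties in the distance analysis are reported in full.
A taxon pair with no comparable sites propagates as an undefined
(flagged) distance; a taxon undefined against everything yields a
flagged record. An intraspecific maximum of exactly 0 makes the
ratio infinite but leaves the discrimination verdict well defined.
Consensus supports are clamped to [0, 100] against floating-point
accumulation. Trees with two leaves or three leaves short-circuit the
search; matrices with no variable patterns score zero on every
topology and bootstrap to a star.

## Problem sizes used by the test suite and acceptance script

Oracle equivalence runs 50 random matrices of 5–9 taxa and 20–60
characters with ~17% missing data. The simulation preset produces 32
rbcL and 30 trnL-F sequences over 15 effective taxa (~2215 combined
characters); end-to-end identification evaluates 100 queries with 20
bootstrap replicates × 2 addition cycles each. These sizes are the
package's chosen desk-scale study conditions; all thresholds (95% MPI,
70% support, 50% consensus) are the workflow's standard values, not
tuned quantities.

## Known limitations

TBR branch swapping and branch lengths beyond change counts are not
implemented; likelihood/Bayesian inference and model-corrected
distances (JC/K2P) are out of scope by design. The identification
pipeline assumes the regional database is complete for the queried
region; a query whose species is absent will be attracted to its
nearest relative, and only the distance evidence (a conspicuously low
MPI) flags the problem. PgiC resolution is an exact band-set lookup;
gel-measurement tolerance would need to be folded into the band table.
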
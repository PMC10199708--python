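# Methods

This note documents the models and procedures `t2tannot` implements,
the parameters that matter, what the synthetic-data generator does and
does not emulate, and the numerical choices made where the design was
genuinely open. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Coordinate and sequence conventions

All intervals are 0-based half-open internally; GFF3 (1-based
inclusive) and VCF (1-based positions) are converted at the I/O
boundary in both directions, so on-disk coordinates round-trip
exactly. Sequences are normalized to {A,C,G,T,N}; `N` participates in
no repeat match (any comparison involving `N` counts as a mismatch).
The target assemblies are gap-free, so `N` occurs only in synthetic
controls.

## Tandem-repeat scanner

**Model.** A tandem array of period *p* satisfies
`seq[i] == seq[i+p]` throughout its span. The scanner evaluates, for
every candidate period in [`min_period`, `max_period`] (default
30–500 bp), the boolean lag-*p* match vector and a sliding window of
length *p* over it; window starts whose match fraction reaches
`min_identity` (default 0.80, chosen to correspond to the conventional
80%-match parameterization of tandem-repeat finders) mark candidate
regions.

**Boundary handling.** Candidate regions are trimmed to the outermost
run of `min(16, p)` consecutive matches — a run this long has chance
probability ≈ 0.25^16 in random sequence, so boundaries snap to the
array proper rather than to isolated background matches. Regions of
the same period separated by at most 3 periods are rejoined (a
diverged array fragments where windowed identity dips), and finally
boundaries grow copy-by-copy while flanking full copies still match
the majority-vote consensus at `min_identity`. Copy numbers are
fractional (span / period, one decimal in tabular output) so partial
trailing copies are counted.

**Harmonic ambiguity.** An exact tandem of period *p* is also a
tandem of every multiple of *p*. Periods are processed in ascending
order and a candidate whose period is an integer multiple of an
overlapping accepted array's period is discarded, so each array is
reported at the smallest period clearing the identity threshold.
Deliberate higher-order units (a dimer whose two halves have diverged
beyond `1 − min_identity`) survive, because their base period fails
the threshold. `group_harmonics` then assigns each array to the family
of the smallest base period *b* such that the array's consensus, cut
into `period/b` pieces, matches the family's base monomer at
`identity_min` under rotation on either strand. Families therefore
unify e.g. {107, 214, 321} while keeping an unrelated 214-bp monomer
separate.

**Overlap resolution.** Non-harmonic arrays of different periods
overlapping by < 50% of the shorter span coexist (satellites of
different families genuinely interleave); larger overlaps are decided
by identity × span score, ties keeping the smaller period. This is a
pinned, tested convention rather than a claim about biology.

**Counting convention.** The per-period summary counts distinct repeat
units per distinct *period*; arrays of the same period with unrelated
consensus sequences are pooled there (the family table distinguishes
them). This choice is documented because "number of distinct repeat
units" is ambiguous between per-period and per-consensus counting.

## Telomere discovery and calling

Discovery scans a terminal window (default 150 kb — comfortably larger
than any plant telomere while excluding interstitial telomeric
repeats) at both chromosome ends for tandem runs of units 5–12 bp.
Runs are attributed to the canonical unit (lexicographic minimum over
all rotations of both strands), units whose primitive root is shorter
than 5 bp are excluded (an AT microsatellite read at length 6 is not a
telomere unit), and a unit is tallied only where it forms a run of at
least 20 copies, so incidental two-copy background repeats cannot win.
The winner is the unit covering the most terminal bp; per-chromosome
coverage is returned as evidence.

Calling measures, per arm, the maximal run of the unit in any rotation
on either strand. Matches are chained only when phase-consistent
(start positions congruent modulo the unit length): inside an exact
array every position starts *some* rotation, so phase-free coverage
would spill a few bases into flanking sequence and break the exact
identity `copies × unit_length = array_length`. Runs interrupted by at
most one unit length of non-matching sequence are bridged (a single
substitution interrupts matches for less than one unit). Presence
requires 50 copies by default — no threshold is canonical here; 50 is
well below the smallest arrays the callers are validated on (180
copies) and is configurable.

## Centromere calling

Inputs are the tandem arrays, the harmonic families and the gene/TE
feature set. The centromeric family defaults to the genome-wide
most-abundant family by bp; a chromosome-specific family overrides it
where its local bp exceeds the default family's by a factor of 2
(default), capturing chromosomes whose centromere is built from an
alternative monomer (135-bp, 66-bp, 187-bp classes and similar).

Candidates on a chromosome are maximal runs of target-family arrays
bridged across gaps ≤ `max_gap` (500 kb); the call is the candidate
with the most array bp, at least `min_array_bp` (50 kb), whose mean
per-bp gene+TE density inside is strictly below the mean outside.
That depletion test is an explicit formalization of what is otherwise
judged by eye in a genome browser; candidates failing it remain in a
diagnostics table, which also serves chromosomes with satellite-dense
regions in several places. At most one call per chromosome is made.
Captured genes are those overlapping the call by ≥ 1 bp.

## Gene clusters and R genes

Genes are ordered per chromosome by start coordinate (ordinals), each
carrying a set of domain accessions. For every accession, each maximal
run of ≥ `seed_run` (3) consecutive carriers seeds a cluster that
collects all carriers within `extend` (30) ordinals of the run;
distance is measured in gene ordinals, not bp. With multi-domain genes
the seed requires one accession common to all three consecutive genes
(the most permissive reading; a strict single-domain mode is a config
flag). Same-accession clusters whose collected ordinal ranges overlap
are merged — the natural reading when two seed runs claim overlapping
territory, pinned by tests. Cluster IDs are deterministic
(`chrom:accession:leftmost-ordinal`), and results are invariant to
input ordering.

Similarity hits (BLAST outfmt-6-like) are filtered by e-value < 1e-5,
identity strictly > 30%, and a shared-domain requirement, with
symmetric closure. Under the default pipeline the filtered hits
describe the duplication landscape without constraining membership; an
optional mode drops members lacking a kept hit to another member. For
synthetic tests a toy scorer built on biopython's local aligner
(BLOSUM62, gap open −11 / extend −1) produces hit tables with a
Karlin–Altschul pseudo-e-value (K = 0.041, λ = 0.267), so no external
aligner is needed; it is not intended for real proteomes.

R-gene classification is purely architectural and fully config-driven:
flagged if domains intersect {NB-ARC, TIR, C-JID}, or if a
leucine-rich-repeat accession co-occurs with a protein-kinase
accession (the receptor-kinase resistance architecture).

## Heterozygosity hotspots

Filtering applies, in order and with first-failing-rule attribution:
exactly two alleles; no missing genotypes; all GQ ≥ 30; minor allele
frequency ≥ 0.01 over all called genotypes (which also removes
invariant sites). Filtering is idempotent and each removal is tallied
by rule. Sharing partitions filtered sites into heterozygous-in-all
vs heterozygous-in-a-proper-subset; the shared percentage is reported
to one decimal.

Window profiles count pooled heterozygous sites (shared sites once) in
non-overlapping 100-kb windows tiling from 0; per-sample profiles are
available. The hotspot threshold is the empirical 95th percentile of
*nonzero* window counts — restricting to nonzero windows keeps the
threshold from collapsing to 0 on sparse genomes, and is configurable.
Qualifying windows merge into fragments, bridging up to one
non-qualifying window (multi-megabase hotspot regions tolerate local
dips); fragments need ≥ 2 qualifying windows. The procedure requires
≥ 20 windows genome-wide, otherwise the top-5% quantile is degenerate
and an error is raised.

## Synthetic-genome generator

The generator emits exactly the structure the callers assume, each
piece recorded in a truth set verifiable by re-scanning:

* Background sequence is i.i.d. uniform ACGT. Only repeat contrast
  matters to the scanners, so no attempt is made to model real base
  composition, GC skew or k-mer structure.
* Telomeres are exact tandem arrays of a 7-bp unit (TTTAGGG) flush
  with the termini, 200–2,000 copies per arm by default (the range a
  chromosome-scale plant assembly typically shows), with per-arm
  omission for absence testing. The unit is conserved, hence the
  default mutation rate of 0.
* Centromeric satellite: a base monomer (107 bp by default) generated
  randomly once per seed — real satellite consensus sequences are
  genome-specific, so truth monomers are synthetic by construction and
  no test compares monomer *content* to any external sequence. Arrays
  are emitted as blocks of monomer copies with a configurable share of
  literal 2×/3× concatemer copies and 2% per-copy substitution
  (divergence exercises the identity thresholds; telomere units do
  not need it). Each chromosome's region sits at a configurable
  position as `n_blocks` blocks separated by short background gaps, so
  "captured genes" can exist inside a call. Chromosome-specific
  alternative monomer lengths (135, 66, 56, 187 bp, …) are supported.
* TE and gene annotations are feature-level: GFF3 intervals over
  background sequence, never overlapping planted arrays or each other,
  with placement probability reduced 5-fold (default) in a
  pericentromeric zone (the satellite region ± 50 kb). Every consumer
  of these annotations works on densities, and inserting actual
  repeated TE sequence would risk incidental tandem structure the
  design does not intend — so TE *sequence* evolution is deliberately
  not modeled.
* Gene domain labels draw 1–3 accessions from a background vocabulary;
  planted clusters add a dedicated accession to a consecutive seed run
  plus scattered nearby genes, and that accession is withheld from the
  background so recovery can be asserted exactly.
* SNP sets: site positions follow a Poisson process at a background
  per-bp rate, multiplied inside hotspot intervals; each site is
  heterozygous in all samples with probability `shared_fraction`
  (default 0.853) or in 1–3 uniformly chosen samples otherwise; a
  configurable fraction of sites (default 5%) receives one
  sub-threshold GQ so the filter stage has work to do. Overlapping
  hotspot intervals are merged with a warning.

Everything is deterministic given the mandatory seed (two runs of the
same spec produce byte-identical FASTA). Because the generator omits
indels, segmental duplications, nested TEs and assembly error, passing
recovery tests demonstrates correctness of the *procedures* under
their stated assumptions, not performance on real assemblies.

## Benchmark problem sizes

The standard scenarios (`t2tannot.benchmarks`) use: a 19-chromosome
genome of 1–2 Mb chromosomes for telomere/centromere recovery (the
chromosome count of a grapevine-class genome at roughly 5% of real
chromosome length, which preserves every length scale that matters —
terminal windows, array sizes, gaps — while keeping a full scan in the
minutes range); a 5-Mb genome for satellite-fraction recovery with
197.5 kb (3.95%) planted; and a ~472-Mb, 19-chromosome coordinate
system (sequence-free — the hotspot pipeline needs only positions)
with nine multi-window hotspot intervals on eight chromosomes for the
top-5% procedure. The multi-genome centromere property test runs 5
genomes of 4 × ~400-kb chromosomes. `scripts/acceptance.py` re-runs
the first three scenarios at a caller-supplied seed.

## Known limitations

* The scanner tolerates substitutions but not indels: an indel shifts
  the register at its period and ends the array. Wraparound
  dynamic-programming detection (as in full tandem-repeat finders) is
  out of scope.
* Higher-order-repeat *phasing* (which monomer variant occupies which
  position) and satellite phylogenetics are not modeled; families are
  grouped by consensus identity only.
* Centromere calls rest on satellite + depletion evidence alone; no
  chromatin (CENH3) evidence is integrated.
* The R-gene rule is a domain-architecture heuristic; it cannot
  distinguish pseudogenes or split models.
* The hotspot threshold is a genome-wide quantile; strong chromosome-
  scale rate differences would shift it and are not normalized away.
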
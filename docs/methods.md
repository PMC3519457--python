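# Methods

## The model

A cross-assembly is a single de novo assembly of the pooled reads of two or
more metagenomic samples.  Because an assembler links reads by shared
(sub)sequence rather than by homology to a database, a contig is a
reference-free "shared entity": the per-contig read counts `r_ki` (reads in
contig *k* from sample *i*) carry all the between-sample signal this package
uses.  Singleton reads — reads incorporated into no contig — are reported
for reference but excluded from every distance computation; consequently
`p_ki = r_ki / r_i` (with `r_i = Σ_k r_ki` the *assembled* reads of sample
*i*) is a genuine probability distribution over contigs, which the
`wootters` formula requires.

The package does not assemble.  It consumes the ACE file any consed-dialect
assembler writes, plus the per-sample read files, whose only required
content is the read identifiers (sequences may be stripped for privacy; the
dinucleotide baseline is then unavailable).  Identifiers must be unique
across all samples — membership is attributed purely by identifier, so a
collision would silently corrupt counts; collisions are therefore a hard
error, as are ACE read identifiers that match no sample (reported up to 20
at a time, after one retry with a trailing `.<digits>` fragment suffix
stripped, a 454/consed convention).  A read listed twice within one contig
is counted once: membership, not alignment multiplicity, defines the count.

## Distance formulas

Four formulas map a sample pair to [0, 1]; all are implemented directly from
their closed forms (see README for the table).

* `shot` and `minimum` are presence/absence based.  The `shot` similarity is
  the root mean square of `c_ij/c_i` and `c_ij/c_j`; since an RMS of two
  fractions never exceeds their maximum, `shot ≥ minimum` holds always,
  strictly when `c_i ≠ c_j` and `c_ij > 0` (verified on 1000 random tallies).
* `wootters` is the Bhattacharyya angle `arccos Σ√(p_ki p_kj)` between the
  two contig-abundance distributions, a true metric with an interpretation
  as the number of distinguishable statistical fluctuations separating the
  distributions.  We scale by 2/π so disjoint support gives exactly 1,
  commensurate with the other formulas; the unscaled radian value is
  available via `dist_wootters(..., scaled=False)`.
* `reads` mirrors `shot` on read fractions, which damps the tendency of long
  contigs to attract stray reads from unrelated samples.

Numerical notes: the Bhattacharyya coefficient is accumulated over sorted
terms for run-to-run reproducibility and clamped to [0, 1] before `arccos`;
input vectors must sum to 1 within 1e-9.  Self-comparisons are not
special-cased, and because `arccos` amplifies rounding near coefficient 1 to
~√ε, a self-distance can be of order 1e-8 rather than exactly 0 — tests
budget 1e-7 for it.  Similarities are clamped at 1 before subtraction so
distances never go (negligibly) negative.

The dinucleotide baseline follows the classic genome-signature convention:
each read and its reverse complement are counted separately (no junction
windows across reads), ambiguous bases break windows, and
`ρ*_XY = f*_XY / (f*_X f*_Y)`.  The sample distance is the mean absolute
odds-ratio difference, `δ* = (1/16) Σ |ρ*ᵃ − ρ*ᵇ|`, an exact pseudometric.
The 1/16 averaging constant rescales all distances uniformly and cannot
affect any clustering.  Profiles are exactly invariant under
reverse-complementing any read, by construction.

## BioNJ

Trees are built with BioNJ: NJ pair selection by the Q-criterion, standard
NJ branch lengths, and a variance-weighted reduction whose mixing weight λ
(clamped to [0, 1], from a running variance matrix initialized to the input
distances) minimizes the variance of the reduced estimates.  On additive
matrices any λ gives the same exact reduction, so the implementation
inherits NJ's exactness there — the test suite checks topology and all
leaf-to-leaf path lengths to 1e-9 on random trees, and that λ pinned to 1/2
(`variance_weighting=False`) reproduces classical NJ.  Q-ties are broken on
the lexicographically smallest pair of subtree-minimum labels, making trees
deterministic across platforms.  For two taxa the single distance is split
equally between the pendant edges.  Negative branch lengths (possible on
non-additive input) are kept in the tree object and clamped to zero only at
Newick serialization (default on).  Rooting of drawn cladograms is cosmetic;
the equal-angle layout treats the final agglomeration point as the hub.

## The synthetic testbed

`crossmeta.synthetic` generates everything the validation experiments need;
every fixture carries exact ground truth (read provenance, contig
composition, true overlap), and all generators are bit-reproducible given
(seed, parameters).

**Genomes.** Random sequences with per-pool GC ranges; pools play the role
of phyla (low-GC vs high-GC vs a mid-GC contaminant pool).  Two optional
realism features, each of which exists because a distance in the package
needs it:

* *Dinucleotide bias* (`random_dinuc_bias`): sequences are drawn from a
  first-order Markov chain whose transition matrix carries a pool-specific
  log-normal bias (σ = 0.25), with the stationary composition fixed-point
  corrected back to the GC target.  Without it, iid genomes have ρ* ≈ 1
  regardless of GC — odds ratios divide composition out — and the signature
  baseline would have nothing to detect; real lineages carry exactly such
  biases (CpG/TpA depletion and the like).
* *Within-pool homology* (`divergence`): all genomes of a pool are derived
  from one ancestor by a given fraction of substitutions (default 0.03 where
  used), so different species of one pool share long identical stretches the
  way congeneric bacteria do.  This is what lets samples containing
  *different* species from the same pool cross-assemble, as in the noise
  experiment.

**Reads.** Pyrosequencing-like: length normal(450, 100) truncated to
[50, genome length], uniform start and strand, 2 % per-base errors split
85 % substitutions / 15 % indels (insertions and deletions equally), with
the error probability multiplied by 3 inside homopolymer runs ≥ 3 nt.  The
homopolymer term is a deliberately simple multiplicative inflation, not a
flowgram model; the distances depend only weakly on error microstructure.

**Toy cross-assembler.** Single-linkage clustering of reads sharing at least
`min_shared = 2` exact canonical 21-mers; multi-read clusters become contigs
and are emitted as a valid consed-dialect ACE file (CO/AF records, dummy
offsets) together with the true per-contig genome and sample composition.
Requiring two k-mer witnesses is deliberately conservative, mirroring the
advice to assemble strictly to avoid chimeras.  It is a stand-in for a real
assembler, not a re-implementation of one: no consensus sequence, no
overlap layout, no error correction.

**Experiments** (desk-scale replicas; sizes chosen so each runs in about a
minute on one core):

* *Overlap series*: 12 samples of 10 species (20 kb genomes, 2000
  reads/sample); the reference and step 1 share all species, each further
  step replaces one more species with a genome from the other pool, down to
  zero overlap.  Each step is cross-assembled pairwise with the reference.
  Expectation: every distance falls monotonically with overlap; observed
  Spearman ρ = −1.0 for all four formulas and the dinuc baseline.
* *Abundance pairs*: 4 pairs of samples over one shared 10-species set;
  partners share a logarithmic (rank-halving) abundance vector, pairs differ
  by permutation.  Genomes are 300 kb at 1500 reads/sample, i.e. ~1.5–2×
  joint coverage: the same sub-1× per-sample fragmentation regime as the
  original megabase-genome experiment, which yields ~1000 small contigs.
  That regime matters — presence/absence formulas need many independent
  contigs whose per-sample presence is probabilistic; at high coverage per
  genome the qualitative signal collapses to a handful of contigs and
  drowns in noise.  Expectation: each pair recovered as sisters in the BioNJ
  tree of every formula; observed 16/16.
* *Noise gradient*: 3 samples from a high-GC pool and 6 from a low-GC pool
  (distinct species per sample, homologous within a pool via 3 %
  divergence from a 150 kb ancestor), contaminated with 0–100 % reads drawn
  uniformly from a shared 40 × 50 kb contaminant pool.  The contaminant
  space is deliberately large relative to the contaminant read mass, so
  noise reads mostly stay singletons and contamination acts by *diluting*
  the within-pool signal — the regime of the original design, where the
  noise pool spanned hundreds of megabase genomes.  Expectation: the
  internal branch separating the pools is positive at 0 % noise, shrinks
  monotonically, and vanishes at 100 %; observed Spearman ρ = −1.0 for all
  four formulas.

**What the testbed does not emulate:** real assembler behavior (consensus
calling, chimeras, coverage-dependent breaking), flowgram-accurate
homopolymer errors, genome rearrangements and horizontal transfer, uneven
genome sizes within a community, and any taxonomic structure beyond
"pools".  Passing these experiments therefore shows that the accounting,
formulas and trees behave correctly on data with the *statistical* structure
of the original experiments; it does not certify any particular assembler's
output, and distances from real cross-assemblies inherit whatever biases the
chosen assembler has.

## Output conventions

Sample order everywhere (matrix rows/columns, table columns, plot axes) is
input argument order.  `output.contigs2reads.txt` is tab-separated with a
header row, one row per contig, then a `# singletons` section listing each
sample's unassembled read identifiers; its exact layout is this package's
reconstruction (column order and singleton formatting were never formally
specified by the original tool).  Distance matrices are written both as
labeled TSV and relaxed PHYLIP.  Zero counts on logarithmic scatter axes are
drawn at 0.9 so they remain visible while staying below the smallest real
count of 1.  Triangle-plot marker area scales with total contig reads (a
display choice).  All plots write a companion `.tsv` with the plotted
coordinates so every displayed value is machine-checkable.
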
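# Methods

## The procedure

Given shotgun paired-end reads of a target species mapped (externally) onto
a related species' hard-masked reference, the pipeline has two internal
stages and one evaluation stage:

1. **Consensus.** For every reference sequence, read bases of mapped,
   primary alignments are piled up per reference position (M/=/X CIGAR
   operations only). The consensus has exactly one base per reference
   position, so reference distances transfer unchanged to the consensus —
   this coordinate preservation is what makes reference-derived insert
   sizes meaningful for the target genome.
2. **Systematic mate-pair sampling.** Fragments of exact outer length *I*
   are taken at starts 0, s, 2s, … and their two ends emitted as a read
   pair (FASTQ pair per library).
3. **Metrics.** N50/L50/Nx contiguity statistics for comparing assemblies
   built with and without the in silico libraries.

## Consensus caller

The caller is a deliberately simple majority/ambiguity model, declared
replaceable: downstream sampling needs only bases and depths, not genotype
likelihoods.

* A column with depth below `min_call_depth` (default 1), or whose
  reference base is `N`, is called `N`. Hard masking is therefore
  preserved: a masked reference position can never contribute read bases to
  a library.
* Otherwise the majority base is called; ties break toward A < C < G < T
  (deterministic, and in practice almost always superseded by the
  ambiguity rule below).
* If the second-ranked base has at least `min_allele_count` reads (default
  2) **and** at least `allele_fraction` of the column (default 0.25), the
  two-fold IUPAC code of the top two bases is emitted — allelic differences
  in the target become ambiguity codes in the libraries. If the
  third-ranked base *also* passes both thresholds the column is not
  credibly biallelic and falls back to the majority base; only two-fold
  codes are ever emitted (diploid assumption).
* Filters: records with unmapped/secondary/supplementary flags are excluded
  (configurable), as are records below `min_mapq` (default 0) and bases
  below `min_baseq` (default Phred 13). These defaults are declared, not
  inferred from any external tool's settings.
* Indels are ignored: insertions never enter the consensus and deleted
  positions are called from whatever reads still cover them. This is the
  price of coordinate preservation; divergence-scale indel handling belongs
  to the mapper.

The consensus is serialized as FASTQ (quality = `min(depth, 40)` Phred+33)
plus an exact depth sidecar (`ref_id`, 0-based position, depth for covered
positions), because the FASTQ quality alone saturates at depth 40.

## Sampling model

* **Offset step.** `s = max(1, floor(2r/c))`. Under systematic tiling each
  interior position is covered by `2r/s` read bases, so this step realizes
  the target coverage *c* exactly up to integer rounding; the clamp at 1
  caps realizable coverage at `2r`.
* **Eligibility.** Both read footprints `[start, start+r)` and
  `[start+I−r, start+I)` must be depth ≥ `min_depth` (default 3) and free
  of `N`. The unread interior gap is deliberately *not* inspected: only
  footprint bases enter reads, and requiring coverage across, say, a 100 kb
  gap would make long-insert libraries vanish for no benefit. This is a
  documented choice; the alternative (whole-fragment checking) would be a
  one-line change.
* **Orientation.** FR (inward-pointing, paired-end convention) by default,
  RF (outward, classic mate-pair convention) as a flag. Assemblers accept
  either via their own library configuration, so the simpler convention is
  the default.
* **Naming.** `label:ref_id:start:insert` with `/1`, `/2` suffixes; labels
  may not contain `:` so the name parses unambiguously even when reference
  ids contain colons. Round-trip verification of any pair is a string
  operation plus two slices.
* **Qualities** of emitted reads are copied from the depth-derived
  consensus qualities at the source positions (reversed where the read is
  reverse-complemented), so downstream tools see a coverage-based
  confidence signal.
* Candidate starts restart at 0 on each consensus record; fragments never
  span record boundaries, and an insert longer than the record yields an
  empty library rather than an error. Sampling uses no randomness at all:
  identical inputs give byte-identical libraries. Work is one prefix-sum
  pass plus O(1) per candidate start, so run time is linear in consensus
  length and target coverage and essentially independent of insert size.

## Synthetic data generator

The generator emulates the method's study conditions so the pipeline can be
tested closed-loop:

* **Reference**: i.i.d. uniform ACGT background with `repeat_copies`
  near-identical copies (default ten 2 kb copies at 98% identity) of one
  repeat element. One copy is placed per equal-width slot at a random
  position with a 10% guard margin at each slot edge — copies cannot
  overlap, adjacent copies are separated by a unique segment of guaranteed
  minimum length, and placement is deterministic per seed. A hard-masked
  variant (repeat intervals as `N`) is emitted alongside.
* **Query**: per-site substitutions at `snp_rate` (default 0.02,
  cross-species primate scale) and indel events at `indel_rate` (default
  0.001, lengths uniform in 1–10 bp), with the full query-vs-reference
  alignment retained as M/I/D runs. Every event is recorded.
* **Reads**: FR paired-end shredding with normal insert lengths (default
  400 ± 40 bp), uniform fragment starts, random source strand, optional
  per-base substitution errors, constant Phred 40 qualities, default 30x —
  the coverage regime the method expects from its shotgun input. Realistic
  quality profiles, PCR duplicates and adapters are out of scope.
* **Truth SAM**: each read is placed at its true reference interval with an
  indel-aware CIGAR derived from the global alignment (edge insertions
  soft-clipped, edge deletions trimmed, reads wholly inside a novel
  insertion written unmapped). This replaces the external mapper in tests,
  which means mapping ambiguity in repeats is *not* simulated — reads from
  repeat copies land at their true positions. Passing tests therefore
  demonstrate the consensus/sampling/linkage machinery, not mapper
  robustness; with a real mapper, repeat regions would instead lose
  coverage or be masked, which the hard-masked-reference path models.
* **Linkage score**: the reference split at the planted repeat intervals
  defines unique contigs; junction *k* (between contigs *k* and *k*+1,
  across repeat *k*) counts as recovered when some emitted pair has one
  read footprint entirely in each flanking contig. Mate coordinates live on
  the reference/consensus axis, so the reference-coordinate repeat
  intervals are used (query intervals are also recorded, mapped through the
  indel alignment). Geometry makes the score sharp: an insert shorter than
  `repeat_length + 2r` can never span, while the slot-placement guarantees
  make every junction spannable by sufficiently long inserts.

## Verification conditions and problem sizes

The test suite and acceptance script run the closed loop at desk scale:
10 kb–1 Mb consensus sequences, a 200 kb / ten-repeat mechanism
demonstration at 30x reads, a 60 kb zero-divergence identity check, and a
50 kb diploid mixture (two haplotypes at 20x each, heterozygous sites at
0.006/site) for the ambiguity caller. At combined 40x, a 50/50 site fails
the minor-allele thresholds (count ≥ 2, fraction ≥ 0.25) with binomial
probability well below 1%, which is the basis of the ≥ 99% recovery check
at depth ≥ 8. Whole-genome-scale claims (N50 gains on real primate data)
require external read sets, a mapper and an assembler and are outside what
the package itself verifies.

## Numerical and degenerate-input choices

* SAM positions are 1-based as the format requires; everything internal is
  0-based half-open, converted only at the SAM/FASTA boundary.
* Soft-masked (lowercase) reference bases are uppercased, not masked; `N`
  is the only masking signal, matching the hard-masking recommendation.
* The allele-fraction comparison uses a 1e-9 slack so an exactly-25% minor
  allele passes regardless of floating-point rounding.
* `compute_metrics([])` returns all-zero metrics rather than raising; Nx
  ties include the boundary sequence (`cumsum >= x%·total`, side =
  left).
* Pileup accepts unsorted alignments; the cost is holding one 4×L count
  matrix per reference sequence in memory.
* Duplicate FASTA ids, alignments to unknown references, alignments
  projecting beyond the reference end, out-of-range fragment starts and
  duplicate library labels are hard errors; an insert exceeding the
  sequence length is an empty result, not an error.

## Known limitations

* The consensus caller is not a genotype-likelihood model; at low depth its
  ambiguity calls are threshold-driven.
* One repeat family with uniform copies; multi-family and nested repeat
  structure are not simulated.
* Multi-sample consensus (several individuals/species mapped to one
  reference) and merging libraries across multiple references are not
  implemented; multiple references are supported as independent runs.
* BAM/CRAM input is not required by the core (SAM text only); mapping and
  assembly are external hooks by design.
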
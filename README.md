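# silicomate

**In silico mate-pair scaffolding libraries from a cross-species mapping
consensus.**

De novo short-read assemblies of non-model genomes stall at repeats: without
long-range information, low-complexity regions and transposable elements
leave a multitude of ambiguous paths and the assembly fragments into small
contigs. Physical mate-pair libraries supply that long-range information but
are expensive and error-prone (chimaeras, paired-end contamination). When a
related species has a good reference genome, there is a cheaper route:

1. map the target species' paired-end shotgun reads onto the (hard-masked)
   reference of the related species;
2. call a **coordinate-preserving consensus** of the mapped reads per
   reference chromosome — one base per reference position, `N` where nothing
   maps or the reference is masked, IUPAC ambiguity codes (R, Y, S, W, K, M)
   where the target carries two alleles;
3. **systematically sample exact-insert mate pairs** from that consensus and
   feed them to the assembler as scaffolding libraries.

Because the consensus keeps the reference coordinate system, a fragment of
outer length *I* taken at consensus positions `[s, s+I)` carries a true
long-range distance constraint of the target's own sequence. Sampling is
deterministic: fragment starts are placed every `s = max(1, ⌊2r/c⌋)` bases
(read length *r*, target coverage *c*, so interior read-base coverage is
`2r/s ≈ c`), each fragment has *exactly* the configured insert size, and a
candidate is skipped if any base of either read footprint has pileup depth
below 3 (configurable) or is `N`. There is no upper limit on the insert
size, so super-scaffolding libraries of hundreds of kilobases are possible
wherever the reference sequences are long enough.

The package is a library plus a `silicomate` command with five
subcommands — `consensus`, `simulate`, `metrics`, `synth`, `pipeline` — and
a synthetic-data generator that emulates every input (repeat-bearing
reference, diverged query, shredded paired-end reads, truth alignments in
SAM), so the whole method is verifiable closed-loop without downloads or an
external mapper. Read mapping and assembly themselves are out of scope; the
`pipeline` subcommand can invoke them as user-configured external hooks.

## Worked example

Generate a synthetic dataset (200 kb genome, ten 2 kb repeat copies, 2%
divergence, 30x paired-end reads with truth alignments), build the
consensus against the hard-masked reference, and sample three scaffolding
libraries:

```sh
silicomate synth --length 200000 --repeats 10x2000 --snp-rate 0.02 \
    --coverage 30 --seed 42 --out-dir demo/fix
# wrote fixture set (60002 reads) to demo/fix

silicomate consensus --ref demo/fix/reference.masked.fa \
    --sam demo/fix/truth.sam --out demo/consensus.fq
# wrote 1 consensus records to demo/consensus.fq

printf 'pe500 500 100 10\nmp5k 5000 100 10\nmp20k 20000 100 10\n' > demo/libs.cfg
silicomate simulate --consensus demo/consensus.fq \
    --depths demo/consensus.fq.depths.tsv --config demo/libs.cfg \
    --out-dir demo/libs
# pe500   7893 pairs
# mp5k    6945 pairs
# mp20k   6737 pairs
```

Each library is a `<label>_1.fastq` / `<label>_2.fastq` pair plus a
`manifest.tsv` row. Pair counts shrink slightly with larger inserts only
through the boundary term (fewer fragments fit) and through footprints
rejected at the masked repeats — the method's coverage filter at work. Read
names encode the provenance, e.g. `mp5k:synref:20:5000/1` is the first read
of the fragment starting at consensus position 20 (0-based) with insert
5000 on sequence `synref`; the quality string encodes the per-base pileup
depth (capped at Phred 40). `silicomate metrics assembly.fa` reports
N50/L50-style contiguity statistics for any FASTA, for before/after
comparison of assemblies.

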
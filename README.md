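# mircurate

Rule-based curation of plant small-RNA hairpin candidates: from candidate
precursors (sequence + dot-bracket structure + MFE, as produced by an
external folder) and aligned read stacks to confidence-tiered miRNA
calls, conserved/novel family assignment, isomiR typing, TPM expression
tables and differential-expression flags. A synthetic-data generator
produces hairpins, read stacks and multi-sample experiments with known
ground truth, so the whole pipeline is testable without any downloads.

## What it does

1. **Hairpin geometry** (`mircurate.hairpin`) — dot-bracket parsing into
   pair tables, star-interval inference for canonical 2-nt 3'-overhang
   duplexes, duplex profiles (mismatches, asymmetric bulges, overhangs,
   paired fractions), MFE per nucleotide.
2. **Read evidence** (`mircurate.evidence`) — exact arm counts, excision
   fraction, 5' homogeneity, library detection and arm dominance over a
   windowed (2 nt up / 5 nt down) arm assignment.
3. **Confidence classification** (`mircurate.classify`) — seven curation
   rules with printed boundary semantics, a rescue clause for a single
   structural violation backed by precise excision, and
   high / very-high-confidence tiers. All thresholds configurable.
4. **Homology & isomiRs** (`mircurate.homology`) — conserved/novel calls
   against a miRBase-style mature FASTA (≤2 mismatches), single-linkage
   family clustering for novels, and isomiR detection/typing (5' shifts
   ≤4 nt, ≤1 internal mismatch, 50%-of-reference or >10,000-read
   retention; 3' templated/nontemplated/deletion and polymorphic types).
5. **Expression** (`mircurate.expression`) — windowed quantification,
   TPM (counts × 1e6 / genome-mapped reads — note the denominator is
   genome-mapped, not miRNA-mapped, reads, kept as the source convention),
   median-of-ratios size factors, a simplified negative-binomial Wald
   test with BH FDR (this is *not* DESeq2 and claims no numerical
   equivalence with it), and the 2^-ddCt qPCR utility.
6. **Synthetic data** (`mircurate.simulate`) — hairpins with exactly
   requested defect geometry, deterministic or multinomial read stacks
   with controllable excision/homogeneity/star abundance, planted-category
   batches, 3-stage × 3-replicate count matrices with planted fold
   changes, and a complete on-disk fixture bundle.
7. **QC & pipeline** (`mircurate.qc`, `mircurate.pipeline`,
   `mircurate.cli`) — FASTQ adapter trimming and clean-read filters,
   length/first-base composition stats, and the end-to-end orchestrator.

## CLI

```sh
# generate a synthetic fixture bundle (precursors, stacks, samples,
# known matures, truth, config)
mircurate simulate --out-dir demo --n-precursors 27 --seed 1

# run the full pipeline; prints the summary JSON
mircurate run demo/config.yaml

# individual stages
mircurate qc reads.fastq --adapter TGGAATTCTCGGGTGCCAAGG --out clean.fastq
mircurate classify --precursors p.tsv --stacks s.tsv --out calls.tsv
mircurate isomir   --precursors p.tsv --stacks s.tsv --out isomirs.tsv
mircurate quantify --precursors p.tsv --stacks s.tsv --samples samples.tsv \
    --out counts.tsv --tpm-out tpm.tsv
mircurate de --counts counts.tsv --samples samples.tsv --out de.tsv
```

`run` writes, under the configured `output_dir`: `classification.tsv`,
`homology.tsv`, `isomirs.tsv`, `counts.tsv`, `tpm.tsv`, `de.tsv`,
`composition_*.tsv`, `summary.json` and a `thresholds.yaml` provenance
sidecar. The pipeline is a pure function of (inputs, config): reruns are
byte-identical.

## File formats

- precursors: TSV (`id`, `sequence`, `structure`, `mfe`,
  `n_genome_hits`), or FASTA plus a 3-line-per-record structure sidecar
  (`>id` / dot-bracket / `mfe=<float>`);
- read stacks: TSV (`precursor_id`, `library_id`, `start`,
  `read_sequence`, `count`), 0-based starts on the precursor;
- sample sheet: TSV (`sample_id`, `stage`, `replicate`,
  `genome_mapped_reads`) with stages young/intermediate/mature;
- known matures: FASTA with miRBase-style ids (family parsed from the
  name, e.g. `ath-miR156a` → MIR156).

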
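# ssfilter

Post-assembly triage for **strand-specific de novo transcriptome
assemblies** (dUTP protocol). Starting from a redundant set of putative
transcripts grouped into assembler components, `ssfilter`:

1. tallies proper-pair orientations and computes the **SSLR**
   (strand-specific log ratio, `log2(read1-on-plus / read2-on-plus)` with a
   symmetric 0.5 pseudocount) — negative for sense transcripts under the
   dUTP chemistry;
2. removes antisense **leakage duplicates**: reverse-complement copies
   that match a genuine transcript in the alternate orientation over >80%
   of the shorter member, with SSLRs < −2.5 / > +1.5 and <10% length
   difference (a hermetic k-mer fallback replaces BLASTN when no external
   hit table is supplied);
3. applies a **read-pair support filter** (default: keep ≥ 20 proper
   pairs) and counts **coverage dips** (>5-fold change between adjacent
   100 bp windows);
4. calls **six-frame ORFs** (≥ 300 bp), restricts to the strand of the
   longest ORF, and reconciles them with externally predicted
   priority ORFs (plus-strand priority first, then minus, then builtin,
   rejecting >50%-of-the-shorter overlaps);
5. scores every transcript with a **19-metric weighted aggregate**
   (homology coverage, component-relative lengths, SSLR concordance, ORF
   consistency, coverage dips) and keeps **one representative per
   component** when its score strictly exceeds 14; optional best-e-value
   **LCA** taxonomic assignment;
6. optionally computes descriptive two-pool **differential-expression
   ratios** (pooled total > 50 reads, zero counts → 0.5) normalized by
   **mode centering** on a 0.1-wide histogram; and
7. optionally runs a **substitution-site scan** against the assembly
   consensus (depth > 20, allele fractions > 5% relaxed / > 20% strict).

A seeded simulator (`ssfilter simulate`) generates every input the
pipeline consumes — transcripts with planted ORFs, leakage twins,
unstranded contamination, proper-pair SAM alignments with orientation
leakage and planted substitution sites, tabular homology hits, and
two-pool counts — together with truth tables, so the whole pipeline is
testable offline.

## CLI

```bash
ssfilter simulate --seed 1 --out simdata/          # synthetic dataset + truth
ssfilter sslr simdata/pairs.sam --out sslr.tsv     # orientation tallies + SSLR
ssfilter leakage simdata/transcripts.fasta sslr.tsv --out discards.tsv
ssfilter filter sslr.tsv --min-pairs 20 --out support.tsv
ssfilter orfs simdata/transcripts.fasta --out orfs.gff3
ssfilter de counts_a.tsv counts_b.tsv --out de.tsv
ssfilter variants simdata/pairs.sam --out sites.tsv --vcf sites.vcf
ssfilter pipeline --config pipeline.yaml --out run/
```

`pipeline.yaml` names the inputs and overrides any threshold:

```yaml
fasta: simdata/transcripts.fasta
sam: simdata/pairs.sam
uniref_hits: simdata/uniref_hits.tsv   # outfmt-6 + qlen,slen columns
nr_hits: simdata/nr_hits.tsv
self_hits: simdata/self_hits.tsv       # optional; builtin fallback otherwise
counts_a: simdata/counts_a.tsv         # optional DE stage
counts_b: simdata/counts_b.tsv
min_pairs: 20
min_score: 14.0
```

The pipeline writes `sslr.tsv`, `leakage_discards.tsv`, `coverage.tsv`,
`orfs.gff3`, `scores.tsv` (all 19 metrics per transcript),
`representatives.tsv`/`.fasta`, optional `de.tsv` and `sites.tsv`/`.vcf`,
and a `manifest.json` whose per-stage counts are conserved
(`input = output + Σ discarded-by-reason`). Exit codes: 0 ok, 2 usage
error, 3 data error.

## Formats

* **FASTA** — Trinity-style IDs `comp<i>_c<j>_seq<k>` give the component
  `comp<i>_c<j>`; other IDs need a sidecar component map.
* **SAM (text)** — all alignment lines are counted (multi-mapped reads
  contribute everywhere they map); FLAG 0x400 duplicates are honored by
  the variant scan and by `--drop-duplicates`.
* **BLAST tabular** — outfmt-6 with `qlen`/`slen` appended as columns
  13–14 (or 12 columns plus sidecar length tables).
* Coordinates are 1-based inclusive everywhere (SAM/GFF3/BLAST
  convention).

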
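# evopool

Population-level mutation detection for experimental-evolution resequencing.
A pooled DNA sample is sequenced as one library, so every variant appears in a
fraction of reads proportional to its frequency in the population. `evopool`
implements the full detection protocol as a tested pipeline:

* **`evopool.sim`** — synthetic pooled populations: random references,
  haplotype pools carrying planted SNPs/indels/large deletions at known
  frequencies, ~100 bp paired-end reads from ~230 bp fragments at
  configurable depth (default 285×), plus injectable artifact classes
  (strand-biased G/C mismatch clusters, read-end-only mismatches) with full
  truth tables. Everything downstream is testable without any downloads.
* **`evopool.pileup`** — per-site evidence columns (base counts by strand,
  quality sums, read-end offsets, indel/soft-clip support) from in-memory
  simulated reads or coordinate-sorted SAM/BAM, with mate-overlap
  deduplication; read-pair insert statistics and discordant-pair extraction.
* **`evopool.caller`** — pooled SNP calling with a log-likelihood-ratio score
  over a discrete frequency grid (haplotype number, default 10) and a
  continuous allele-frequency estimate down to a 5% design floor;
  count-based small-indel calling (reads showing the indel vs reads that do
  not, with a minimum-support rule).
* **`evopool.filters`** — automated false-positive rules that annotate calls:
  `STRAND_CTX` (strand-biased G/C mismatch context, exact conditional test),
  `READ_POS` (alternate allele never seen mid-read), `NEAR_SV` (large
  indel/clip signature nearby), plus founder subtraction
  (`novel` / `in_founder` status; nothing is deleted).
* **`evopool.sv`** — large-variant evidence: discordant-pair clustering into
  breakpoint candidates and soft-clip consensus refinement to base
  resolution; BEDPE and symbolic-allele VCF export.
* **`evopool.annotate`** — GFF3/GenBank gene models, coding / promoter /
  intergenic classification and codon-level consequences (translation
  table 11): synonymous, nonsynonymous, nonsense, frameshift, in-frame indel.
* **`evopool.evaluate`** — closed-loop validation: truth matching, false
  positive/negative rates, allele-frequency agreement, and detection power
  curves over full pipeline replicates.

## Command line

```bash
evopool all --config configs/demo.yaml --out runs/demo
```

chains simulate → pileup → call → filter → sv → evaluate in memory and writes
`reference.fasta`, paired FASTQ, a coordinate-sorted truth SAM, truth TSVs,
`calls.vcf` (+ TSV mirror), `sv.bedpe`/`sv.vcf`, `report.json` and a
provenance block echoing every threshold and seed. Each stage is also
available standalone:

```bash
evopool simulate --config cfg.yaml --out runs/sim
evopool call     --sam runs/sim/truth.sam --reference runs/sim/reference.fasta --out calls.vcf
evopool filter   --vcf calls.vcf --sam runs/sim/truth.sam --reference runs/sim/reference.fasta \
                 --founder founder.vcf --out filtered.vcf
evopool sv       --sam runs/sim/truth.sam --reference runs/sim/reference.fasta --out sv_out
evopool annotate --vcf filtered.vcf --reference runs/sim/reference.fasta --gff genes.gff3 --out annotated.tsv
evopool evaluate --vcf filtered.vcf --truth runs/sim/truth_variants.tsv --genome-size 100000 --out report.json
```

Reruns with the same configuration are byte-deterministic.

## Notes on conventions

* Coordinates are 1-based and fully closed in all user-facing outputs;
  indel alleles are VCF-style left-anchored.
* Read offsets are distances to the nearer read end, so "middle of the read"
  is symmetric; the default middle zone starts at 25% of the read length.
* Filters only annotate (VCF FILTER column: PASS or flag names); reporting
  decides what to drop.
* Allele-frequency agreement is always measured against the realized
  (post-rounding) pool frequency, not the requested one.
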
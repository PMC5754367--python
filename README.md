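# epitrio

Toolkit for discovering heritable *secondary epimutations*: promoter
hypermethylation of a gene caused by a DNA variant in a neighboring,
antisense-overlapping gene. The package implements the full discovery arc as
reusable, tested components:

1. **epigram** — per-clone, per-CpG methylation calls from bisulfite clone
   sequences, conversion-efficiency QC (strict >95% filter), SNP-based allele
   tagging, and mono-allelic epimutation calling.
2. **methylome** — case/control methylation-array scans (signed Δβ, Welch
   t-test, Bonferroni), ENCODE-style beta categorization (UU ≤ 0.2 < PM < 0.6
   ≤ MM), control-cohort carrier screening over a probe block, and
   allele-frequency estimation with a one-significant-figure ceiling.
3. **epild** — epi-linkage disequilibrium between adjacent CpG probes from
   categorized dosages, via two-locus haplotype EM and the composite
   haplotype method, plus epi-haplotype block assembly.
4. **trioscan** — geometric scanning of gene annotation for tail-to-tail and
   head-to-head sense–antisense gene pairs and reverse–forward–reverse /
   forward–reverse–forward trios sharing a bidirectional-promoter CpG island.
5. **antisense** — strand-aware read classification, coverage-based antisense
   readthrough detection across a trio, and splice-acceptor disruption
   consequence prediction (terminal-exon skipping with polyA loss).
6. **segregation** — damage-class and rarity filtering (MAF > 0.001 removed)
   plus co-segregation of variants with epimutation carrier status.
7. **synthetic_data** — deterministic generators for every input format the
   pipeline consumes, with planted ground truth serialized alongside.
8. **io_formats** — BED3/6, BED12, GFF3 subset, and beta-matrix TSV readers
   and writers; internal coordinates are 0-based half-open throughout.

## Command line

All stages are exposed under a single `epitrio` entry point:

```sh
# end-to-end rediscovery demo on synthetic data
epitrio run-all --simulate --seed 7 --out out/

# individual stages
epitrio simulate clones --seed 3 --out sim/
epitrio epigram --clones sim/clones.fa --ref sim/reference.fa \
    --config sim/reference.config --out epi/
epitrio simulate cohort --seed 3 --out sim/
epitrio mvp --cases sim/cases.tsv --controls sim/controls.tsv \
    --delta 0.3 --out mvp.tsv
epitrio carriers --cohort sim/controls.tsv --block sim/block_probes.txt \
    --out carriers.json
epitrio epild --cohort sim/controls.tsv --method both --r2-min 0.8 --out ld/
epitrio simulate annotation --seed 5 --out ann/
epitrio trioscan --genes ann/annotation.gff3 --islands ann/islands.bed \
    --window 1000 --out scan/
epitrio simulate reads --seed 5 --readthrough-frac 0.5 --out rd/
epitrio antisense --reads rd/reads.bed --genes rd/genes.gff3 \
    --islands rd/island.bed --out anti/
epitrio simulate variants --seed 5 --out var/
epitrio segregate --variants var/variants.tsv --status var/status.tsv \
    --maf-max 0.001 --out segregating.tsv
```

`run-all` writes a versioned machine-readable `summary.json` containing the
epimutation call, carrier count and allele-frequency bound, epi-haplotype
blocks, trio calls, segregating variants, the splice consequence, and the
readthrough call. Logs go to stderr; rerunning with the same seed reproduces
identical outputs.

## Conventions

- Coordinates are 0-based half-open internally; GFF3 (1-based inclusive) is
  converted at the parse/serialize boundary only.
- Strand is mandatory internally; strandless BED input defaults to `+` with a
  logged warning.
- Missing beta values and missing CpG calls are representable and excluded
  from all means and tests, never imputed.
- Undefined r² (monomorphic probe) is reported as missing, never coerced to
  0, and breaks epi-haplotype blocks.
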
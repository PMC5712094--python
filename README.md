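# uvbsrna

A small-RNA sequencing analysis toolkit for two-condition (control vs
UVB-treatment style) experiments, with a first-class synthetic-data backend so
the whole pipeline is testable offline against known ground truth.

Stages:

1. **simulate** — generate a toy reference bundle (genome with designed miRNA
   precursor hairpins, ncRNA/repeat/exon/intron annotation, mature-miRNA
   database, transcripts with planted target sites) and gzip FASTQ libraries
   (`CK1..CKn` / `T1..Tn`) with planted expression ratios and labelled
   contaminant reads (adapter-only, poly-A, too short/long, low-quality,
   N-containing).
2. **clean** — adapter trimming and QC filtering of raw reads into collapsed
   18–30 nt tags, with a per-library QC report whose categories reconcile
   exactly to the raw totals, plus length distributions.
3. **classify** — exact genome mapping (both strands) and annotation-class
   assignment (miRNA > rRNA > tRNA > snRNA > snoRNA > scRNA > repeat > exon >
   intron > unannotated).
4. **discover** — known-miRNA matching (equal length, Hamming distance ≤ 2,
   deterministic tie-breaking, family collapsing) and novel hairpin discovery:
   tag clustering, window extraction, folding with a self-contained
   stacked-pair Nussinov engine, and Mireap-style acceptance criteria.
5. **targets** — plant-style miRNA target prediction on ungapped duplexes with
   positional mismatch scoring (G:U wobble = 0.5), six acceptance rules, and a
   duplex/perfect-complement MFE-ratio test (≥ 0.75).
6. **de** — formulaic differential expression: reads-per-million
   normalization, log2 fold change, a two-sided exact binomial count test,
   significance classes (|FC| > 1 with p < 0.01 / 0.01 ≤ p ≤ 0.05) and
   ratio-based regulation calls (> 2 up, < 1/2 down).
7. **phenotype** — total chlorophyll from absorbances
   (`20.29·A645 + 8.05·A663`) and 2^−ΔΔCt qRT-PCR relative expression.

## CLI

Every stage is a subcommand of `uvbsrna`:

```bash
uvbsrna simulate --outdir sim --seed 1 --depth 50000 --replicates 3
uvbsrna clean --fastq sim/libraries/CK1.fastq.gz --fastq sim/libraries/T1.fastq.gz --out clean/
uvbsrna classify --tags clean/tags.fa --genome sim/reference/genome.fa \
    --gff sim/reference/annotation.gff3 --out classes.tsv
uvbsrna discover --tags clean/tags.fa --genome sim/reference/genome.fa \
    --mirbase sim/reference/mirna_mature.fa --out discovery/
uvbsrna targets --mirna sim/reference/mirna_mature.fa \
    --transcripts sim/reference/transcripts.fa --out hits.tsv
uvbsrna de --counts counts.tsv --design design.tsv --out de.tsv
uvbsrna phenotype chlorophyll --in absorbances.tsv --out chl.tsv
uvbsrna phenotype ddct --in ct.tsv --calibrator CK_mature --out rel.tsv
```

The full pipeline runs from a single YAML config (see
`uvbsrna.pipeline.PipelineConfig.from_dict` for the schema):

```bash
uvbsrna run --config config.yaml
```

With a simulation block in the config the report additionally contains a
ground-truth confusion summary (QC category accuracy, known/novel recovery,
DE direction sensitivity and error counts). Reruns with the same config and
seed are byte-identical.

## Notes on the energy model

Folding and duplex "MFE" use one deliberately simple, self-contained model:
Watson-Crick + G:U pairs, minimum loop 3, and an energy that is the sum of
stacked-pair weights (−2 per G:C-closed stack, −1 otherwise). It is exactly
reproducible and oracle-verifiable by exhaustive enumeration; its absolute
values are model units, not kcal/mol. Hairpin acceptance therefore uses a
length-normalized score threshold (default −0.5/nt) alongside the absolute
one, which cleanly separates designed stems from shuffled sequence.
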
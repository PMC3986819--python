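# neophase

Haplotype-resolved transcript reconstruction for two barely diverged
homologous chromosomes (a young X/Y pair, here called neoX/neoY), from a
mixed "male" transcript assembly plus sex-specific genomic and RNA-seq
reads.

The core idea: map male genomic reads (an equal mixture of both
haplotypes) and female genomic reads (one haplotype) against the male
transcripts, categorize variant sites by their sex pattern, rewrite each
transcript to carry only the Y-specific alleles, and keep the regions that
are RNA-supported and contain at least one haplotype-diagnostic variant.
Downstream modules assign reference IDs by reciprocal best hit, scaffold
fragments against reference proteins, classify ORF integrity (frameshifts
and premature stop codons with 3'UTR metrics), quantify allele-resolved
expression with a deterministic EM, measure uncorrected divergence after
conserved-block filtering, and screen for deleted vs. silenced gene copies
from coverage.

## Layout

| module | role |
| --- | --- |
| `neophase.seqio` | FASTA/FASTQ/TSV IO and shared sequence types |
| `neophase.mapper` | exact and affine-gap scored read mapping, pileups |
| `neophase.haplotype` | exon splitting, site calling/categorization (CAT1/2/3), rewriting, RNA-support filtering |
| `neophase.annotate` | RBH ID assignment, fragment merge/scaffold, ORF and 3'UTR classification |
| `neophase.quant` | EM read assignment between homologs, FPKM |
| `neophase.divergence` | three-way alignment, block filtering, p-distance |
| `neophase.screens` | deletion and silencing coverage screens |
| `neophase.simdata` | synthetic two-haplotype datasets with full ground truth |
| `neophase.cli_report` | pipeline orchestration, summary statistics, CLI |

## CLI

```sh
# simulate a dataset with ground truth
neophase simulate --seed 42 --n-genes 50 --outdir sim/

# simulate + run the whole pipeline + write every stage artifact
neophase all --seed 42 --n-genes 50 --outdir run/

# run the pipeline on explicit files
neophase phase --male-transcripts male.fasta --female-transcripts female.fasta \
    --male-genomic male.fastq --female-genomic female.fastq \
    --rna rna_male.fastq --reference-cds ref_cds.fasta --outdir run/

# standalone stages
neophase annotate-orfs --transcripts neoY.fasta --reference-cds ref_cds.fasta --out orfs.tsv
neophase quantify --transcripts all.fasta --rna rna.fastq --out abundance.tsv
neophase divergence --neox x.fasta --neoy y.fasta --outgroup out.fasta --out div.tsv
neophase report --indir run/
```

Exit codes: 0 ok, 2 input error, 3 stage failure. `--config` accepts a
`key = value` file overriding any simulation parameter; every pipeline
threshold lives in `PipelineConfig` / `CallerParams` / `MapperParams`
with its published default.

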
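# tandemscape

Characterize the tandem-repeat landscape of a gene from haplotype-phased
long-read assemblies.

Variable number tandem repeats (VNTRs) — loci where a unit of ≥ 7 bp is
repeated in tandem a variable number of times — are hard to genotype from
short reads and easy to miss entirely when they are long, GC-rich and
refractory to PCR. Haplotype-resolved assemblies make them accessible: each
haplotype carries the full repeat array, so copy number, unit-level sequence
purity, inheritance fidelity and linkage to surrounding SNPs can all be read
off directly. `tandemscape` implements that end-to-end analysis for a single
gene, modeled on the dopamine transporter gene *SLC6A3* and its
hypervariable, 82%-GC, 38-bp-unit intron-8 repeat with alleles from 3.4 to
133.4 copies. It is aimed at researchers analyzing repeat variation in a
candidate gene across a cohort of phased assemblies.

## What it computes

- **Gene extraction** — locate the gene in a contig via two flanking anchor
  sequences (searched on both strands, each required to occur exactly once)
  and orient it 5′→3′. The *SLC6A3* UTR anchors are built in as defaults.
- **Repeat detection** — candidate arrays are seeded by exact k-mer
  recurrence at each candidate period *p* (a position votes for *p* when its
  k-mer recurs *p* bases downstream), refined by unit-stepping extension and
  an x-drop boundary scan, and decomposed into units by wraparound dynamic
  programming against the cyclic consensus. Copy number is the spanned
  length over the unit length, reported to one decimal; divergence is the
  mean per-unit edit distance to the consensus, normalized by unit length.
  Candidates failing a mononucleotide-shuffle significance test
  (α = 0.05) or exceeding divergence 0.05 are discarded; overlaps resolve
  to the lowest (p-value, divergence).
- **Harmonization** — stable TR IDs across haplotypes by single-linkage
  clustering on consensus identity (≥ 0.8, canonical rotation) *and* 50 bp
  flank identity (≥ 0.9), the strict more-than-half presence rule, doubled-
  motif reduction (a 2×38 bp consensus collapses to 38 bp), and VNTR
  flagging (≥ 2 distinct copy-number alleles).
- **Mola charts** — per-unit grids over haplotypes: multicolor (one seeded
  color per distinct unit sequence) and 3-color (per-unit global alignment
  score against the consensus on a red/white/blue gradient anchored at
  min/median/max), plus a homopolymer-collapse sensitivity analysis (runs
  ≥ 4 collapse to one base).
- **Population genetics** — substitution-only SNP calling on
  reference-projected haplotypes (keeplength semantics, MAF > 5%, VNTR
  intervals excluded), LD as squared Pearson correlation over haplotype
  vectors (SNPs as minor-allele indicators, VNTRs as copy numbers),
  per-locus heterozygosity (fraction of individuals with two different
  1-decimal alleles), one-way ANOVA of copy number on ancestry, and trio
  transmission analysis with per-VNTR mismatch/indel counts from
  EMBOSS-needle-default affine alignment (+5/−4, gap 10/0.5, free end gaps).
- **G4 / PWM scanning** — run-based G-quadruplex propensity scores
  (±min(run, 4) per base in G/C runs), 25-base sliding windows at threshold
  1.6, merged hit regions, per-bin coverage profiles; generic JASPAR PWM
  scanning on both strands with relative log-odds scores.
- **Synthetic cohorts** — a generator that emulates the study design (32
  individuals / 64 haplotypes, ~30 loci, five VNTRs including the
  hypervariable one, SNPs with configurable LD to a VNTR, ancestry labels,
  three trios with de novo indels, CLR/CCS-like noise) with complete
  ground-truth bookkeeping, so every stage is testable without downloads.

## Worked example

```python
import numpy as np
from tandemscape.synthetic import default_cohort_spec, generate_cohort
from tandemscape.repeats import annotate_gene
from tandemscape.harmonize import assign_ids, summarize_catalog
from tandemscape.popgen import genotype_table, heterozygosity

cohort = generate_cohort(default_cohort_spec(), seed=1)
sequences = cohort.sequences()
rng = np.random.default_rng(1234)
per_hap = {lab: annotate_gene(seq, seed=int(rng.integers(2**31)), contig=lab)
           for lab, seq in sorted(sequences.items())}
catalog = assign_ids(per_hap, sequences)
print(len(catalog), len(catalog.vntrs))

hy = max(catalog.vntrs, key=lambda l: len(l.allele_table))
genotypes = genotype_table(catalog, on_missing="drop")
print(hy.tr_id, len(hy.allele_table),
      min(hy.allele_table), max(hy.allele_table),
      round(heterozygosity(genotypes, hy.tr_id), 3))
```

prints

```
33 5
TR24 14 3.4 133.4 0.938
```

i.e. 33 harmonized loci of which 5 are copy-number variable; the
hypervariable locus (here `TR24`) carries 14 distinct alleles spanning 3.4
to 133.4 copies of its 38-mer, and 30 of the 32 individuals are
heterozygous for it (0.938). The catalog rows from
`summarize_catalog(catalog, ...)` give, per locus, the consensus length,
allele count, major-allele copy number, heterozygosity, interval and GC%.

The same run from a shell:

```bash
tandemscape run --out landscape_run --seed 1
```

writes `catalog.tsv`, `repeats.tsv`/`repeats.bed`, per-VNTR Mola SVGs and
cell tables, `snps.tsv`, `ld_matrix.tsv`, `g4_profile.tsv`,
`trio_report.tsv` and a provenance `config.yaml` into `landscape_run/`.
Subcommands `extract`, `annotate`, `harmonize`, `mola`, `snps`, `ld`,
`trio`, `g4`, `pwm` and `simulate` run the individual stages on your own
FASTA/TSV inputs, communicating through plain-text files.

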
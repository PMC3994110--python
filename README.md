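# srnaome

Annotation of the small-RNA complement (sRNAome) of a plant genome from
small-RNA sequencing reads. Starting from raw FASTQ with the 3′ adapter
still attached, the pipeline trims, quality- and length-filters (every base
≥ Q20, 17–26 nt), collapses reads to unique tags, maps them exhaustively
with 0–1 mismatches on both strands, and classifies the loci they derive
from:

- **known miRNAs** — exact (0-mismatch, T≡U) matches to a mature miRNA
  reference set, per entry and per family;
- **novel miRNA hairpins** — genome loci passing the accepted plant
  criteria: hairpin window ≤ 150 nt, mature read support ≥ 10, a star
  partner with ≤ 5 unpaired mature nucleotides in the duplex (2-nt 3′
  overhangs), and ≥ 0.8 of the locus read count in the Dicer size range
  (20–24 nt); matures are classified against same-species and pan-plant
  references (known / plant homolog / antisense of known / new family
  member / novel), with isomiR annotation;
- **miRNA targets** — Allen-type penalty scoring (match 0, G:U 0.5,
  mismatch 1, gap 2; doubled at mature positions 2–13; cutoff 3.0),
  cleavage vs translational-inhibition calls, and degradome (PARE)
  validation of cleavage sites;
- **NAT pairs and nat-siRNAs** — cis pairs (opposite-strand genomic
  overlap > 50 nt), trans pairs (reverse-complement identity run > 100 nt
  between distant loci), unclassified pairs (≥ 1 transcript unplaced),
  duplex validation by RNA hybridization, one-to-one / one-to-many /
  many-to-many network classification, overlap vs non-overlap read
  densities (reads/kb), Wilcoxon rank-sum enrichment, and ≥ 2-fold strand
  bias calls;
- **phased siRNA (PHAS) clusters** — sliding 9-cycle windows of 21-nt
  registers; distinct 5′ positions (minus strand shifted +2 for the Dicer
  overhang) are collapsed modulo 21 and the dominant register is scored
  with a hypergeometric tail, Bonferroni-corrected for register selection;
  significance at the genome (α = 0.001) or transcript (α = 0.0034) level;
  phase-initiating miRNA target sites with register drift, one-hit/two-hit
  model and degradome support;
- **repeat-associated siRNAs** — non-miRNA tags mapped to a repeat library
  with ≤ 1 mismatch; per-repeat totals, strand bias and size distribution.

A first-class synthetic-data generator (`srnaome.synthetic_data`) builds
genomes with planted, ground-truthed instances of every locus class and
emits sRNA + degradome reads, so recall and precision of the whole pipeline
are measurable exactly.

## Worked example

```
srnaome generate --seed 5 --out-dir bundle5
srnaome run --bundle bundle5 --out-dir run5 --seed 5
```

prints the per-stage read accounting:

```
                     stage  unique  total
           adapter_trimmed     NaN 2558.0
              high_quality     NaN 2558.0
           length_filtered  1567.0 2558.0
               known_mirna     2.0  200.0
          novel_mirna_loci     5.0  500.0
                 nat_sirna     NaN  603.0
    phased_clusters_genome     3.0    NaN
phased_clusters_transcript     3.0    NaN
                   rasirna     NaN  600.0
```

Reading it: all 2558 simulated reads carried the adapter and survived
quality filtering; they collapse to 1567 unique tags. 200 reads match the
two known mature miRNAs planted in the species reference. All five planted
hairpins are accepted as miRNA loci (the two whose matures are in the
reference classify as `known_same_species`, the rest as `novel`), each with
its planted mature count of 100. 603 reads fall in validated NAT pairs,
three significant phased clusters are found in both genome and transcript
mode (each with its planted 22-nt 5′-U initiator in register), and all
three planted repeats spawn rasiRNA clusters totalling 600 reads.
`run5/` holds the per-module tables (`novel_mirna.tsv/gff3`,
`nat_pairs.tsv`, `nat_summary.tsv`, `phas_*.tsv/bed`, `rasirna.tsv`,
`targets.tsv`, `size_profile.tsv`), each stamped with the config hash.

The same analyses are available per stage (`srnaome preprocess|map|mirna|
targets|nat|phas|rasirna`) and as library functions.

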
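# Methods

This note records the models, thresholds and design choices behind each
stage, what the synthetic data does and does not emulate, and the known
limitations.

## Preprocessing (`srnaome.sio`)

Reads are Sanger/Illumina-1.8+ FASTQ (Phred+33); other quality encodings
are rejected loudly rather than silently mis-decoded. Adapter removal is a
semiglobal alignment of read suffixes against the adapter prefix,
substitutions only, with defaults `min_overlap=3`, `max_error_rate=0.1`;
the best alignment maximises matching bases, ties resolved toward the
longer overlap. Reads without a qualifying match are kept and flagged —
discarding them is not warranted for 3′-adapter protocols where long
inserts can push the adapter off the read end. Reads in which the adapter
starts at position 0 have no insert and are dropped (counted separately, so
trimming reports always partition the input).

Quality filtering defaults to the strictest reading of a Q20 threshold:
*every* base ≥ Q20. A fraction-of-bases mode (`quality_mode="fraction"`)
is available. N-containing reads are rejected at this stage because N can
never satisfy the exact-match operations downstream. Length selection is
17–26 nt inclusive. Collapsing to unique tags orders output by descending
count then lexicographically, making every downstream table deterministic.

## Mapping (`srnaome.align`)

Small-RNA analysis needs every placement, not a best hit. The mapper
reports all positions on all references, both strands, at Hamming distance
≤ 1 (no indels — the method is mismatch-only by design). Completeness comes
from the pigeonhole principle: with ≤ 1 mismatch at least one half of the
query is exact, so exact-scanning both halves and verifying candidates
cannot miss a hit; tests check this against a full-scan oracle. `N` never
matches anything, including another `N`. Coordinates are 0-based half-open
internally and 1-based only in GFF3/SAM output. Multi-mapping tags carry
their full read count at every placement; consumers decide weighting
(rasiRNA offers a unique-only mode). This is the simplest bookkeeping that
keeps per-locus totals interpretable, at the cost of counting a
multi-mapped read more than once across loci — summaries mark such tags.

## miRNA analysis (`srnaome.mirna`)

Known matching is identity-only (T≡U), deliberately excluding isomiRs, so
"known miRNA reads" means exact catalogue evidence.

Novel loci: genome hits are clustered with a 100-nt maximum gap, then each
candidate is tested in order against (a) a hairpin window of at most 150 nt
containing the locus reads, (b) mature (most abundant tag, ties to the
5′-most) read support ≥ 10, (c) existence of a star partner, (d) Dicer-size
fraction ≥ 0.8. Rejections name the first failed criterion, which makes
the accounting of discarded candidates meaningful. All bounds are
inclusive: 150-nt windows, 0.8 fractions, and 5 unpaired duplex
nucleotides are accepted; 151/0.79/6 are not.

Folding is the ViennaRNA MFE structure. The hairpin search folds windows
of 60–150 nt (5-nt steps in both length and offset) containing the read
span on the mature's strand, keeps windows where the mature's pairing
partners all lie on one opposite arm, derives the star interval from the
duplex geometry (2-nt 3′ overhangs; star ends clamped to the window), and
requires ≤ 5 unpaired mature nucleotides outside the mature's own 3′
overhang. Among qualifying windows the lowest-energy one is reported, so
the precursor interval may be wider than the minimal planted hairpin while
always containing it. The Dicer size range is 20–24 nt, matching the span
plant miRNAs occupy. Up to one additional mature/star duplex per precursor
is reported when an independent tag reaches the read floor and forms its
own qualifying duplex.

Classification precedence is sequence-based: exact same-species match >
exact other-plant match > reverse complement of a same-species entry >
same-species mature at a new locus (`novel_family_member`, applied when
known locus coordinates are supplied) > novel. isomiR relationships are
annotated for end shifts up to ±3 nt.

## Target prediction and degradome validation (`srnaome.targets`)

The scorer is the Allen-type penalty table used across plant target
predictors: per position, match 0, G:U wobble 0.5, mismatch 1, gap 2;
penalties doubled at mature positions 2–13 (seed); cutoff 3.0. This fixed
table makes "default parameters" concrete and deterministic. The default
scan is ungapped (site length = mature length); a mismatch at mature
positions 9–11 switches the predicted mode from cleavage to translational
inhibition, and the cleavage position is the transcript base opposite
mature position 10.

Degradome tags are mapped sense-strand with 0 mismatches; a site is
supported when the tag count within ±1 nt of the cleavage position is ≥ 2
and equals the transcript's maximum peak (the category-0-like rule;
an above-median mode is available). The full five-category degradome
taxonomy and T-plots are out of scope.

## NAT discovery and statistics (`srnaome.nat`)

cis pairs need same chromosome, opposite strands and genomic intersection
strictly > 50 nt; trans pairs need a maximal reverse-complement identity
run strictly > 100 nt between genomically non-intersecting transcripts
(k-mer seeding with exact extension, so run lengths at the boundary are
exact); pairs with ≥ 1 unplaced transcript use the trans criterion and form
the `unclassified` cohort. Transcripts that intersect genomically are the
cis criterion's business and are never trans.

Duplex validation cofolds the two overlap sequences and counts only
intermolecular base pairs; valid means intermolecular paired fraction ≥ 0.5
with negative hybrid energy. Local duplex folding (RNAduplex-style) was
rejected here because it over-pairs unrelated random 200-mers (measured
mean paired fraction 0.54), which would make the threshold meaningless;
cofolding separates cleanly (random ≈ 0.15, perfect complements 1.0).
trans/unclassified overlaps are exact reverse complements by construction
and validate trivially.

Densities: overlap density pools reads from both transcripts over the
overlap length counted once (the two overlap intervals describe the same
duplex region); non-overlap density covers the summed remainders of both
transcripts. A read belongs to the region holding its midpoint. Cohort
enrichment is a two-sided Wilcoxon rank-sum test (exact null for cohorts
≤ 25 without ties, tie-corrected normal approximation otherwise) — rank-sum
rather than signed-rank because the two density sets are compared as
samples. Strand bias attributes overlap reads to the transcript they match
in sense orientation; fold = max/min with a pseudocount of 1 on both counts
when the minimum is zero; biased means fold ≥ 2 (inclusive) with ≥ 10
attributed reads.

## Phasing (`srnaome.phas`)

Only tags of exactly the phase size (21 nt default) enter. Effective 5′
positions collapse the two strands of a Dicer duplex into one register:
plus-strand start as-is, minus-strand start +2. Windows of 9 phase cycles
(189 nt) slide by one cycle; windows with ≥ 4 distinct occupied positions
are scored. The raw statistic is the hypergeometric tail probability of
observing ≥ k occupied cycles in one fixed register given n occupied slots
among 21 × 9; because the scored register is the *dominant* one among 21
candidates, the window p-value multiplies the tail by the phase size
(Bonferroni over registers). Without this correction, diffuse read clouds
(a dozen random 21-nt positions, as NAT overlaps produce) reach nominal
significance in a few percent of windows — measured, not hypothetical.
Overlapping significant windows merge into maximal clusters carrying their
best window's register and p. Significance is strict (`p < α`) at the
genome (0.001) or transcript (0.0034) adjusted level; an
`alpha_family / n_tests` computation is also available. Distinct positions,
not abundances, enter the statistic; an abundance-weighted variant is a
known extension, not implemented.

Initiators: any target site within one phase length of a cluster is
recorded with its signed drift from the dominant register (range
[−10, +10] for 21-nt phases), in-register meaning drift 0; the initiator's
length and 5′ nucleotide are kept because 22-nt 5′-U miRNAs are the
canonical one-hit triggers; two or more sites of one miRNA on a cluster
mark the two-hit model.

**Known limitation.** At the transcript-mode α = 0.0034, regions that
produce many uniformly scattered 21-nt reads (NAT overlaps under heavy
background) still reach significance occasionally (k = 4 of n ≈ 7 occupied
positions gives corrected p ≈ 0.0017). Under the noisy synthetic condition
this costs the phased class roughly one false cluster every few studies;
genome mode at α = 0.001 is stricter.

## rasiRNA (`srnaome.rasirna`)

Tags identical to a known mature are removed first, so no tag is both
miRNA and rasiRNA. The remainder map to the repeat consensus library with
≤ 1 mismatch, both strands; a tag contributes once per repeat it hits
(full count, multi-repeat tags marked), and silent repeats are listed. The
summary reports per-repeat strand split, fold bias (max/min, pseudocount 1)
and length histogram, plus the global size distribution.

## Synthetic data (`srnaome.synthetic_data`)

The generator emulates a pooled plant-leaf sRNA library: dominant 24-nt
(37 %) and 21-nt (31 %) size classes in the background mixture, high
redundancy concentrated in few tags (planted matures at 100 reads), a
species mature-miRNA reference containing a subset of planted matures plus
decoys, and a degradome whose tags start at planted cleavage positions.
Planted classes, all deterministic for (config, seed):

- hairpins: perfect-stem precursors (21-nt mature + 15-nt loop + reverse
  complement), which satisfy the hairpin criteria by construction;
- cis-NATs: opposite-strand transcript pairs overlapping 150 nt on the
  genome; trans-NATs: a 150-nt reverse-complement run planted across
  chromosomes; unclassified: one transcript without coordinates;
  overlap reads at 50× the non-overlap density with a 3-fold strand bias;
- phased loci: a planted 22-nt 5′-U initiator whose perfect-complement
  target site puts the cleavage position exactly on register 0, phased
  21-nt reads on both strands with the 2-nt overhang geometry;
- repeats: 300-nt consensus sequences in 3 genomic copies with a 24-nt
  dominant read mixture on both strands;
- background: genome-derived (mappable) and random (unmappable) tags in a
  configured ratio.

Default problem sizes (two 30-kb chromosomes, ~2.5 k reads per study) keep
a full pipeline run near fifteen seconds while every class retains enough
planted instances for exact recall/precision accounting. What the
generator does *not* emulate: realistic Illumina error profiles (errors
are uniform substitutions), introns (transcripts are contiguous genome
segments), isomiR clouds around matures, expression variation between
libraries, and chimeric/ligation artefacts. Passing tests therefore show
algorithmic correctness on clean and moderately noisy data, not robustness
to every artefact of real libraries.

## Numerical and degenerate-input choices

- All printed thresholds are enforced with their stated strictness:
  > 50 / > 100 nt overlaps strict; ≥ 10 reads, ≥ 0.8 Dicer fraction,
  ≤ 150 nt hairpin, ≤ 5 unpaired, ≥ 2-fold bias inclusive; p < α strict.
- Ties: mature selection prefers the 5′-most among equally abundant tags;
  dominant-register ties prefer the lower register index; collapse orders
  by count then sequence.
- Empty inputs: empty read sets flow through to empty outputs (no crash);
  empty tag collections are rejected only where a profile is meaningless;
  zero-length overlap regions are excluded from densities with a warning;
  identical enrichment cohorts give p = 1, direction none.
- Seeds: every stochastic component takes a NumPy `default_rng` seed;
  pipeline outputs embed the config hash so reruns are verifiable.
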
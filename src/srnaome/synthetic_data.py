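"""Synthetic sRNA-seq study generator with planted, ground-truthed loci.

Builds a random genome carrying planted instances of every locus class the
pipeline detects — miRNA hairpins that satisfy the plant hairpin criteria by
construction, cis/trans/unclassified NAT pairs, phased siRNA loci anchored
on an initiator miRNA cleavage site, and multi-copy repeats — then emits
small-RNA reads (with 3' adapter and qualities) and degradome tags from
those loci over a configurable background.  Everything is deterministic for
a fixed (config, seed) and the planted truth is serializable, so pipeline
recall/precision can be measured exactly.

The default read mixture mirrors a typical plant leaf library: 24-nt reads
dominate (~37%) followed by 21-nt (~31%), with high redundancy concentrated
in a few tags.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from srnaome.align import revcomp
from srnaome.mirna import MatureReference
from srnaome.nat import TranscriptModel, UNKNOWN
from srnaome.sio import ReadRecord

BASES = np.array(list("ACGT"))
DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"  # TruSeq small-RNA 3' adapter

# default library size mixture over 17-26 nt: 24-nt dominant, then 21-nt
DEFAULT_SIZE_MIX = {
    17: 0.03, 18: 0.03, 19: 0.04, 20: 0.05, 21: 0.31,
    22: 0.06, 23: 0.05, 24: 0.37, 25: 0.03, 26: 0.03,
}


@dataclass
class GeneratorConfig:
    """Counts and sizes of every planted class plus background shape."""

    chrom_length: int = 30000
    n_chroms: int = 2
    n_hairpins: int = 5
    mature_count: int = 100
    star_count: int = 10
    n_known_hairpins: int = 2  # hairpins whose mature goes into the species reference
    n_cis_nat: int = 4
    n_trans_nat: int = 4
    n_unclassified_nat: int = 2
    cis_overlap: int = 150
    trans_run: int = 150
    transcript_length: int = 500
    nat_overlap_reads: int = 60
    nat_density_ratio: float = 50.0  # overlap vs non-overlap read density
    nat_bias_fold: float = 3.0
    n_phased: int = 3
    phase_size: int = 21
    phase_cycles: int = 10
    phase_reads_per_position: int = 3
    initiator_length: int = 22
    n_repeats: int = 3
    repeat_length: int = 300
    repeat_copies: int = 3
    repeat_reads: int = 200
    repeat_size_mix: dict[int, float] = field(
        default_factory=lambda: {24: 0.55, 21: 0.10, 22: 0.09, 23: 0.09, 20: 0.17}
    )
    n_background_tags: int = 300
    background_unmappable_fraction: float = 0.3
    n_extra_species_refs: int = 10
    n_plant_refs: int = 10
    locus_spacing: int = 400


@dataclass
class PlantedHairpin:
    chrom: str
    start: int
    end: int
    mature_seq: str
    star_seq: str
    mature_count: int
    star_count: int
    known_id: str = ""  # non-empty when the mature is in the species reference


@dataclass
class PlantedNat:
    t1: str
    t2: str
    pair_type: str
    overlap_len: int
    t1_interval: tuple[int, int]
    t2_interval: tuple[int, int]
    density_ratio: float
    bias_fold: float
    overlap_reads: int
    nonoverlap_reads: int


@dataclass
class PlantedPhas:
    transcript_id: str
    chrom: str
    g_offset: int  # genomic start of the transcript
    anchor: int  # transcript-local 5' position of the first phased siRNA
    cycles: int
    initiator_id: str
    initiator_seq: str
    cleavage_pos: int  # transcript-local; equals anchor
    reads_per_position: int


@dataclass
class PlantedRepeat:
    repeat_id: str
    consensus: str
    copies: list[tuple[str, int]]
    reads: int


@dataclass
class TruthSet:
    seed: int
    config: GeneratorConfig
    hairpins: list[PlantedHairpin] = field(default_factory=list)
    nats: list[PlantedNat] = field(default_factory=list)
    phased: list[PlantedPhas] = field(default_factory=list)
    repeats: list[PlantedRepeat] = field(default_factory=list)
    background_regions: list[tuple[str, int, int]] = field(default_factory=list)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=1, default=list)
        if path is not None:
            Path(path).write_text(text)
        return text

    @staticmethod
    def from_json(source: str | Path) -> "TruthSet":
        if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source and source.endswith(".json")):
            source = Path(source).read_text()
        d = json.loads(source)
        cfg = GeneratorConfig(**{
            k: ({int(kk): vv for kk, vv in v.items()} if isinstance(v, dict) else v)
            for k, v in d["config"].items()
        })
        return TruthSet(
            seed=d["seed"],
            config=cfg,
            hairpins=[PlantedHairpin(**{**h, }) for h in d["hairpins"]],
            nats=[PlantedNat(**{**n,
                               "t1_interval": tuple(n["t1_interval"]),
                               "t2_interval": tuple(n["t2_interval"])})
                  for n in d["nats"]],
            phased=[PlantedPhas(**p) for p in d["phased"]],
            repeats=[PlantedRepeat(**{**r, "copies": [tuple(c) for c in r["copies"]]})
                     for r in d["repeats"]],
            background_regions=[tuple(b) for b in d["background_regions"]],
        )


@dataclass
class SyntheticReference:
    genome: dict[str, str]
    transcripts: list[TranscriptModel]
    species_matures: list[MatureReference]
    plant_matures: list[MatureReference]
    repeat_library: dict[str, str]
    truth: TruthSet


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(BASES, size=n))


class _Layout:
    """Sequential allocation of non-overlapping genomic slots."""

    def __init__(self, chroms: Sequence[str], length: int, spacing: int):
        self.chroms = list(chroms)
        self.length = length
        self.spacing = spacing
        self.cursor = {c: spacing for c in chroms}
        self.which = 0

    def take(self, size: int, chrom: str | None = None) -> tuple[str, int]:
        if chrom is None:
            chrom = self.chroms[self.which % len(self.chroms)]
            self.which += 1
        start = self.cursor[chrom]
        if start + size + self.spacing > self.length:
            raise ValueError(
                f"planted sequence exceeds chromosome length {self.length}; "
                "increase chrom_length or reduce planted counts"
            )
        self.cursor[chrom] = start + size + self.spacing
        return chrom, start


def make_reference(config: GeneratorConfig | None = None, seed: int = 1) -> SyntheticReference:
    """Deterministically build genome, transcripts, references and truth.

    Hairpins are perfect-stem precursors (mature + loop + reverse
    complement) that satisfy the hairpin criteria by construction; cis-NAT
    transcripts overlap antisense on the genome; trans-NAT transcripts share
    a planted reverse-complement run across chromosomes; phased loci carry
    an initiator target site whose cleavage position anchors register 0;
    repeats are planted in several copies.
    """
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(seed)
    chrom_names = [f"chr{i + 1}" for i in range(cfg.n_chroms)]
    genome = {c: list(_rand_seq(rng, cfg.chrom_length)) for c in chrom_names}
    layout = _Layout(chrom_names, cfg.chrom_length, cfg.locus_spacing)
    truth = TruthSet(seed=seed, config=cfg)
    transcripts: list[TranscriptModel] = []
    species: list[MatureReference] = []
    plant: list[MatureReference] = []

    def plant_seq(chrom: str, start: int, seq: str) -> None:
        genome[chrom][start : start + len(seq)] = list(seq)

    # --- miRNA hairpins -------------------------------------------------
    for i in range(cfg.n_hairpins):
        mature = _rand_seq(rng, 21)
        loop = _rand_seq(rng, 15)
        precursor = mature + loop + revcomp(mature)
        chrom, start = layout.take(len(precursor))
        plant_seq(chrom, start, precursor)
        known_id = ""
        if i < cfg.n_known_hairpins:
            known_id = f"syn-miR{100 + i}"
            species.append(MatureReference(known_id, mature, f"miR{100 + i}", "syn"))
        truth.hairpins.append(
            PlantedHairpin(
                chrom=chrom, start=start, end=start + len(precursor),
                mature_seq=mature, star_seq=revcomp(mature),
                mature_count=cfg.mature_count, star_count=cfg.star_count,
                known_id=known_id,
            )
        )

    # decoy reference entries never planted in the genome
    for i in range(cfg.n_extra_species_refs):
        species.append(
            MatureReference(f"syn-miR{200 + i}", _rand_seq(rng, 21), f"miR{200 + i}", "syn")
        )
    for i in range(cfg.n_plant_refs):
        plant.append(
            MatureReference(f"pln-miR{300 + i}", _rand_seq(rng, 21), f"miR{300 + i}", "pln")
        )

    # --- cis-NAT pairs --------------------------------------------------
    tlen, ov = cfg.transcript_length, cfg.cis_overlap
    for i in range(cfg.n_cis_nat):
        chrom, start = layout.take(2 * tlen - ov)
        a_start, a_end = start, start + tlen
        b_start, b_end = start + tlen - ov, start + 2 * tlen - ov
        t1 = TranscriptModel(f"cisA_{i}", "".join(genome[chrom][a_start:a_end]), chrom, a_start, a_end, "+")
        t2 = TranscriptModel(
            f"cisB_{i}", revcomp("".join(genome[chrom][b_start:b_end])), chrom, b_start, b_end, "-"
        )
        transcripts += [t1, t2]
        truth.nats.append(
            PlantedNat(
                t1=t1.transcript_id, t2=t2.transcript_id, pair_type="cis",
                overlap_len=ov,
                t1_interval=(tlen - ov, tlen), t2_interval=(tlen - ov, tlen),
                density_ratio=cfg.nat_density_ratio, bias_fold=cfg.nat_bias_fold,
                overlap_reads=cfg.nat_overlap_reads,
                nonoverlap_reads=_nonoverlap_reads(cfg, tlen, ov),
            )
        )

    # --- trans-NAT pairs (and unclassified: one transcript unplaced) ----
    for i in range(cfg.n_trans_nat + cfg.n_unclassified_nat):
        unplaced = i >= cfg.n_trans_nat
        kind = "uncl" if unplaced else "trans"
        chrom1, s1 = layout.take(tlen)
        t1_seq = "".join(genome[chrom1][s1 : s1 + tlen])
        run = cfg.trans_run
        seg_start = (tlen - run) // 2
        segment = t1_seq[seg_start : seg_start + run]
        if unplaced:
            t2_seq = _rand_seq(rng, tlen)
            pos2 = (tlen - run) // 2
            t2_seq = t2_seq[:pos2] + revcomp(segment) + t2_seq[pos2 + run :]
            t1 = TranscriptModel(f"{kind}A_{i}", t1_seq, chrom1, s1, s1 + tlen, "+")
            t2 = TranscriptModel(f"{kind}B_{i}", t2_seq)
        else:
            chrom2, s2 = layout.take(tlen)
            pos2 = (tlen - run) // 2
            plant_seq(chrom2, s2 + pos2, revcomp(segment))
            t2_seq = "".join(genome[chrom2][s2 : s2 + tlen])
            t1 = TranscriptModel(f"{kind}A_{i}", t1_seq, chrom1, s1, s1 + tlen, "+")
            t2 = TranscriptModel(f"{kind}B_{i}", t2_seq, chrom2, s2, s2 + tlen, "+")
        transcripts += [t1, t2]
        truth.nats.append(
            PlantedNat(
                t1=t1.transcript_id, t2=t2.transcript_id,
                pair_type="unclassified" if unplaced else "trans",
                overlap_len=run,
                t1_interval=(seg_start, seg_start + run),
                t2_interval=(pos2, pos2 + run),
                density_ratio=cfg.nat_density_ratio, bias_fold=cfg.nat_bias_fold,
                overlap_reads=cfg.nat_overlap_reads,
                nonoverlap_reads=_nonoverlap_reads(cfg, tlen, run),
            )
        )

    # --- phased loci with planted initiator target site ----------------
    for i in range(cfg.n_phased):
        region = cfg.phase_size * cfg.phase_cycles + 60
        chrom, start = layout.take(region)
        initiator = "T" + _rand_seq(rng, cfg.initiator_length - 1)  # 22 nt, 5' U
        init_id = f"syn-miR{400 + i}"
        species.append(
            MatureReference(init_id, initiator, f"miR{400 + i}", "syn")
        )
        anchor = 40  # transcript-local first phased position
        # perfect-complement target site so the cleavage position (opposite
        # mature position 10) lands exactly on the anchor
        site = revcomp(initiator)
        site_start = anchor - (cfg.initiator_length - 10)
        plant_seq(chrom, start + site_start, site)
        t = TranscriptModel(
            f"phas_{i}", "".join(genome[chrom][start : start + region]),
            chrom, start, start + region, "+",
        )
        transcripts.append(t)
        truth.phased.append(
            PlantedPhas(
                transcript_id=t.transcript_id, chrom=chrom, g_offset=start,
                anchor=anchor, cycles=cfg.phase_cycles,
                initiator_id=init_id, initiator_seq=initiator,
                cleavage_pos=anchor, reads_per_position=cfg.phase_reads_per_position,
            )
        )

    # --- repeats --------------------------------------------------------
    repeat_library: dict[str, str] = {}
    for i in range(cfg.n_repeats):
        consensus = _rand_seq(rng, cfg.repeat_length)
        rid = f"REP{i + 1}"
        repeat_library[rid] = consensus
        copies = []
        for _ in range(cfg.repeat_copies):
            chrom, start = layout.take(cfg.repeat_length)
            plant_seq(chrom, start, consensus)
            copies.append((chrom, start))
        truth.repeats.append(
            PlantedRepeat(repeat_id=rid, consensus=consensus, copies=copies,
                          reads=cfg.repeat_reads)
        )

    # --- background regions (rest of the genome, for mappable noise) ----
    for chrom in chrom_names:
        lo = layout.cursor[chrom]
        if lo < cfg.chrom_length - 200:
            truth.background_regions.append((chrom, lo, cfg.chrom_length))

    genome_str = {c: "".join(s) for c, s in genome.items()}
    return SyntheticReference(
        genome=genome_str,
        transcripts=transcripts,
        species_matures=species,
        plant_matures=plant,
        repeat_library=repeat_library,
        truth=truth,
    )


def _nonoverlap_reads(cfg: GeneratorConfig, tlen: int, ov: int) -> int:
    non_len = 2 * (tlen - ov)
    density = (cfg.nat_overlap_reads / ov) / cfg.nat_density_ratio
    return max(0, round(density * non_len))


@dataclass
class NoiseConfig:
    error_rate: float = 0.0  # per-base substitution probability
    low_quality_rate: float = 0.0  # fraction of reads given one sub-threshold base
    quality_floor: int = 30
    quality_ceiling: int = 40
    read_length: int = 36
    adapter: str = DEFAULT_ADAPTER
    background_multiplier: float = 1.0


def _mutate(seq: str, rng: np.random.Generator, rate: float) -> str:
    if rate <= 0:
        return seq
    chars = list(seq)
    for i in range(len(chars)):
        if rng.random() < rate:
            chars[i] = str(rng.choice([b for b in "ACGT" if b != chars[i]]))
    return "".join(chars)


def simulate_reads(
    reference: SyntheticReference,
    noise: NoiseConfig | None = None,
    seed: int = 1,
) -> tuple[list[ReadRecord], list[ReadRecord]]:
    """Emit (sRNA reads with adapter, degradome reads) from the truth set.

    With ``error_rate=0`` the per-locus read counts equal the truth counts
    exactly.  Each emitted insert gets the 3' adapter appended, the result
    truncated to ``read_length``, and qualities drawn in
    [quality_floor, quality_ceiling].
    """
    cfg = reference.truth.config
    noise = noise or NoiseConfig()
    rng = np.random.default_rng(seed)
    genome = reference.genome
    tx = {t.transcript_id: t for t in reference.transcripts}
    inserts: list[str] = []

    # hairpin mature/star reads
    for h in reference.truth.hairpins:
        inserts += [h.mature_seq] * h.mature_count
        inserts += [h.star_seq] * h.star_count

    # NAT reads: overlap reads split by the configured strand bias between
    # the two transcripts; non-overlap reads uniform on both transcripts
    for n in reference.truth.nats:
        t1, t2 = tx[n.t1], tx[n.t2]
        c1 = round(n.overlap_reads * n.bias_fold / (1 + n.bias_fold))
        c2 = n.overlap_reads - c1
        for t, (lo, hi), c in ((t1, n.t1_interval, c1), (t2, n.t2_interval, c2)):
            for _ in range(c):
                L = int(rng.integers(21, 25))
                p = int(rng.integers(lo, hi - L + 1))
                inserts.append(t.seq[p : p + L])
        for _ in range(n.nonoverlap_reads):
            t, (lo, hi) = ((t1, n.t1_interval), (t2, n.t2_interval))[int(rng.integers(2))]
            L = int(rng.integers(21, 25))
            # uniform over the non-overlap remainder
            choices = [(0, lo), (hi, len(t.seq))]
            choices = [(a, b) for a, b in choices if b - a > L]
            if not choices:
                continue
            a, b = choices[int(rng.integers(len(choices)))]
            p = int(rng.integers(a, b - L + 1))
            inserts.append(t.seq[p : p + L])

    # phased reads: both strands with the 2-nt overhang geometry
    for ph in reference.truth.phased:
        t = tx[ph.transcript_id]
        for k in range(ph.cycles):
            p = ph.anchor + k * cfg.phase_size
            plus = t.seq[p : p + cfg.phase_size]
            minus = revcomp(t.seq[p - 2 : p - 2 + cfg.phase_size])
            inserts += [plus] * ph.reads_per_position
            inserts += [minus] * ph.reads_per_position

    # repeat reads: 24-nt dominant mixture, both strands of the consensus
    lengths = sorted(cfg.repeat_size_mix)
    probs = np.array([cfg.repeat_size_mix[L] for L in lengths])
    probs = probs / probs.sum()
    for r in reference.truth.repeats:
        for _ in range(r.reads):
            L = int(rng.choice(lengths, p=probs))
            p = int(rng.integers(0, len(r.consensus) - L + 1))
            s = r.consensus[p : p + L]
            if rng.random() < 0.5:
                s = revcomp(s)
            inserts.append(s)

    # background: genome-derived (mappable) and random (unmappable) tags
    bg_lengths = sorted(DEFAULT_SIZE_MIX)
    bg_probs = np.array([DEFAULT_SIZE_MIX[L] for L in bg_lengths])
    bg_probs = bg_probs / bg_probs.sum()
    n_bg = round(cfg.n_background_tags * noise.background_multiplier)
    regions = reference.truth.background_regions
    for _ in range(n_bg):
        L = int(rng.choice(bg_lengths, p=bg_probs))
        count = int(rng.integers(1, 4))
        if regions and rng.random() > cfg.background_unmappable_fraction:
            chrom, lo, hi = regions[int(rng.integers(len(regions)))]
            p = int(rng.integers(lo, hi - L))
            s = genome[chrom][p : p + L]
            if rng.random() < 0.5:
                s = revcomp(s)
        else:
            s = _rand_seq(rng, L)
        inserts += [s] * count

    srna = _package_reads(inserts, rng, noise, prefix="sr")

    # degradome: tags whose 5' ends sit at planted cleavage positions, plus
    # uniform positional noise on the phased transcripts
    deg_inserts: list[str] = []
    for ph in reference.truth.phased:
        t = tx[ph.transcript_id]
        tag = t.seq[ph.cleavage_pos : ph.cleavage_pos + 20]
        deg_inserts += [tag] * 20
        for _ in range(5):
            p = int(rng.integers(0, len(t.seq) - 20))
            deg_inserts.append(t.seq[p : p + 20])
    degradome = _package_reads(deg_inserts, rng, NoiseConfig(
        error_rate=0.0, read_length=20, adapter="", quality_floor=noise.quality_floor,
        quality_ceiling=noise.quality_ceiling,
    ), prefix="deg")
    return srna, degradome


def _package_reads(
    inserts: Sequence[str], rng: np.random.Generator, noise: NoiseConfig, prefix: str
) -> list[ReadRecord]:
    reads = []
    for i, insert in enumerate(inserts):
        seq = _mutate(insert, rng, noise.error_rate)
        if noise.adapter:
            seq = (seq + noise.adapter)[: noise.read_length]
        quals = rng.integers(noise.quality_floor, noise.quality_ceiling + 1, size=len(seq)).tolist()
        if noise.low_quality_rate > 0 and rng.random() < noise.low_quality_rate:
            quals[int(rng.integers(len(quals)))] = int(rng.integers(2, 15))
        reads.append(ReadRecord(f"{prefix}{i}", seq, [int(q) for q in quals]))
    return reads


def write_reference(reference: SyntheticReference, out_dir: str | Path) -> None:
    """FASTA/TSV/JSON serialization of the reference bundle."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "genome.fa", "w") as fh:
        for c, s in reference.genome.items():
            fh.write(f">{c}\n{s}\n")
    with open(out / "transcripts.fa", "w") as fh:
        for t in reference.transcripts:
            fh.write(f">{t.transcript_id}\n{t.seq}\n")
    with open(out / "transcripts.tsv", "w") as fh:
        fh.write("transcript_id\tchrom\tg_start\tg_end\tstrand\n")
        for t in reference.transcripts:
            fh.write(f"{t.transcript_id}\t{t.chrom}\t{t.g_start}\t{t.g_end}\t{t.strand}\n")
    for name, refs in (("matures_species.fa", reference.species_matures),
                       ("matures_plant.fa", reference.plant_matures)):
        with open(out / name, "w") as fh:
            for m in refs:
                fh.write(f">{m.mirna_id}\n{m.seq}\n")
    with open(out / "repeats.fa", "w") as fh:
        for rid, s in reference.repeat_library.items():
            fh.write(f">{rid}\n{s}\n")
    reference.truth.to_json(out / "truth.json")


def load_transcripts(fasta: str | Path, coords_tsv: str | Path) -> list[TranscriptModel]:
    from Bio.SeqIO.FastaIO import SimpleFastaParser

    coords: dict[str, tuple[str, int, int, str]] = {}
    with open(coords_tsv) as fh:
        header = fh.readline()
        for line in fh:
            tid, chrom, s, e, strand = line.rstrip("\n").split("\t")
            coords[tid] = (chrom, int(s), int(e), strand)
    out = []
    with open(fasta) as fh:
        for title, seq in SimpleFastaParser(fh):
            tid = title.split()[0]
            chrom, s, e, strand = coords.get(tid, (UNKNOWN, -1, -1, "+"))
            out.append(TranscriptModel(tid, seq.upper(), chrom, s, e, strand))
    return out
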
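"""Known-miRNA matching and novel miRNA hairpin prediction.

Known matching is exact (T=U, no isomiRs): a tag counts toward a mature
reference entry iff the sequences are identical.

Novel prediction follows the accepted plant-miRNA locus criteria: genome
hits are clustered into candidate loci; each locus must fit a hairpin window
of at most 150 nt; the most abundant tag (the mature) needs a minimum read
support (default 10); a star partner on the opposite arm must form a duplex
with at most 5 unpaired mature nucleotides under the canonical 2-nt 3'
overhang geometry; and at least a 0.8 fraction of the locus read count must
lie in the Dicer size range (20-24 nt).  Folding is the ViennaRNA MFE
structure.  Accepted matures are classified against a same-species and a
pan-plant mature reference set (exact match > plant homolog > antisense of
a known entry > new family member at a new locus > novel), with isomiR
relationships (end shifts up to +/-3 nt) annotated alongside.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import RNA

from srnaome.align import AlignmentHit, revcomp
from srnaome.sio import ReadTag, _open_text

DICER_RANGE = (20, 24)  # nt, inclusive


@dataclass(frozen=True)
class MatureReference:
    """A mature miRNA reference entry (miRBase-style)."""

    mirna_id: str
    seq: str  # DNA alphabet
    family: str = ""
    species_tag: str = ""

    @staticmethod
    def from_header(header: str, seq: str) -> "MatureReference":
        """Parse ids like ``mdm-miR166a`` / ``ath-miR173-5p``: species prefix
        and family (letters+digits after miR/let)."""
        mirna_id = header.split()[0]
        m = re.match(r"^([a-z]{3,4})-((?:miR|let)[-]?\d+)", mirna_id, flags=re.I)
        species = m.group(1) if m else ""
        family = m.group(2).replace("-", "") if m else mirna_id
        return MatureReference(mirna_id, seq.upper().replace("U", "T"), family, species)


def load_mature_fasta(path: str | Path) -> list[MatureReference]:
    from Bio.SeqIO.FastaIO import SimpleFastaParser

    refs: list[MatureReference] = []
    seen: set[str] = set()
    with _open_text(path) as handle:
        for title, seq in SimpleFastaParser(handle):
            ref = MatureReference.from_header(title, seq)
            if ref.mirna_id in seen:
                raise ValueError(f"duplicate mature id {ref.mirna_id!r}")
            seen.add(ref.mirna_id)
            refs.append(ref)
    return refs


@dataclass
class Candidate:
    """A clustered genomic interval with the hits supporting it."""

    ref_id: str
    start: int
    end: int
    hits: list[AlignmentHit]


@dataclass
class MirnaLocus:
    """An accepted hairpin precursor locus."""

    ref_id: str
    start: int  # precursor window, 0-based half-open, forward strand
    end: int
    strand: str
    precursor_seq: str  # on the precursor (mature) strand
    structure: str  # dot-bracket of precursor_seq
    energy: float  # kcal/mol
    mature_seq: str
    mature_arm: str  # '5p' or '3p'
    mature_count: int
    star_seq: str
    star_arm: str
    star_count: int
    dicer_fraction: float
    classification: str = "unclassified"
    isomir_of: list[str] = field(default_factory=list)
    extra_pairs: list[tuple[str, int, str, int]] = field(default_factory=list)


@dataclass(frozen=True)
class Rejection:
    reason: str  # first failed criterion
    detail: str = ""


def match_known(
    tags: Iterable[ReadTag], reference: Sequence[MatureReference]
) -> pd.DataFrame:
    """Exact (0-mismatch, T=U) matching of tags to mature reference entries.

    Returns one row per (tag, entry) identity with the tag count assigned to
    the entry and its family; a tag identical to several entries appears for
    each.  Columns: mirna_id, family, seq, count.
    """
    by_seq: dict[str, list[MatureReference]] = {}
    for ref in reference:
        by_seq.setdefault(ref.seq, []).append(ref)
    rows = []
    for tag in tags:
        for ref in by_seq.get(tag.seq, ()):
            rows.append((ref.mirna_id, ref.family, tag.seq, tag.count))
    return pd.DataFrame(rows, columns=["mirna_id", "family", "seq", "count"])


def family_counts(matches: pd.DataFrame) -> pd.DataFrame:
    if matches.empty:
        return pd.DataFrame(columns=["family", "count"])
    return (
        matches.groupby("family", as_index=False)["count"].sum().sort_values(
            ["count", "family"], ascending=[False, True], ignore_index=True
        )
    )


def cluster_loci(hits: Sequence[AlignmentHit], max_gap: int = 100) -> list[Candidate]:
    """Merge hits into maximal candidate loci.

    Successive hit intervals on the same reference separated by at most
    ``max_gap`` nt join one candidate; the candidate spans their union.
    """
    out: list[Candidate] = []
    for _, ref_hits in _group_by_ref(hits):
        ref_hits = sorted(ref_hits, key=lambda h: (h.start, h.end))
        cur: list[AlignmentHit] = []
        cur_end = None
        for h in ref_hits:
            if cur and h.start - cur_end > max_gap:
                out.append(Candidate(cur[0].ref_id, min(x.start for x in cur), cur_end, cur))
                cur = []
                cur_end = None
            cur.append(h)
            cur_end = h.end if cur_end is None else max(cur_end, h.end)
        if cur:
            out.append(Candidate(cur[0].ref_id, min(x.start for x in cur), cur_end, cur))
    out.sort(key=lambda c: (c.ref_id, c.start))
    return out


def _group_by_ref(hits: Sequence[AlignmentHit]):
    groups: dict[str, list[AlignmentHit]] = {}
    for h in hits:
        groups.setdefault(h.ref_id, []).append(h)
    return sorted(groups.items())


def fold_hairpin(seq: str) -> tuple[str, float]:
    """MFE secondary structure (dot-bracket) and free energy of a sequence.

    Accepts DNA or RNA alphabet, 40-300 nt.  Deterministic for fixed input.
    """
    if not 40 <= len(seq) <= 300:
        raise ValueError(f"fold_hairpin: length {len(seq)} outside [40, 300]")
    structure, energy = RNA.fold(seq.upper().replace("T", "U"))
    return structure, float(energy)


def _pair_table(structure: str) -> list[int]:
    """0-based pairing table: pt[i] = partner of i, or -1 if unpaired."""
    pt = RNA.ptable(structure)
    return [pt[i + 1] - 1 for i in range(len(structure))]


def duplex_unpaired(structure: str, m_start: int, m_end: int) -> int:
    """Unpaired mature nucleotides in the mature/star duplex.

    ``[m_start, m_end)`` is the mature interval on the folded sequence.  The
    last two mature positions form the 2-nt 3' overhang of the duplex and are
    excluded from the count.
    """
    pt = _pair_table(structure)
    core = range(m_start, m_end - 2)
    return sum(1 for i in core if pt[i] == -1)


def duplex_ok(structure: str, m_start: int, m_end: int, max_unpaired: int = 5) -> bool:
    """Accept a mature/star duplex iff at most ``max_unpaired`` (inclusive)
    mature nucleotides are unpaired."""
    return duplex_unpaired(structure, m_start, m_end) <= max_unpaired


def _star_from_structure(structure: str, m_start: int, m_end: int) -> tuple[int, int] | None:
    """Star interval implied by the duplex geometry (2-nt 3' overhangs).

    Returns 0-based half-open (s_start, s_end) on the folded sequence, or
    None when the mature has no consistent partner arm (self-pairing or no
    paired base).
    """
    pt = _pair_table(structure)
    partners = [(i, pt[i]) for i in range(m_start, m_end) if pt[i] != -1]
    if not partners:
        return None
    ps = [p for _, p in partners]
    # opposite arm: every partner strictly outside the mature, all one side
    if any(m_start <= p < m_end for p in ps):
        return None
    if not (all(p < m_start for p in ps) or all(p >= m_end for p in ps)):
        return None
    first_i, first_p = partners[0]  # 5'-most paired mature base
    last_i, last_p = partners[-1]  # 3'-most paired mature base
    # 2-nt 3' overhang on the star: shift both ends by +2 toward the star 3'
    s_start = max(0, last_p - (m_end - 1 - last_i) + 2)
    s_end = min(len(structure), first_p + (first_i - m_start) + 2 + 1)
    if s_end - s_start < 15:
        return None
    return s_start, s_end


@dataclass
class LocusConfig:
    min_mature_reads: int = 10
    max_hairpin: int = 150  # nt, inclusive
    max_unpaired: int = 5  # mature nt in duplex, inclusive
    min_dicer_fraction: float = 0.8  # inclusive
    dicer_range: tuple[int, int] = DICER_RANGE
    min_window: int = 60
    window_step: int = 5
    max_duplexes: int = 2


def evaluate_mirna_locus(
    candidate: Candidate,
    genome: dict[str, str],
    config: LocusConfig | None = None,
) -> MirnaLocus | Rejection:
    """Test a candidate locus against the plant miRNA hairpin criteria.

    Checked in order; the rejection names the first failure:
      hairpin_span   — no window of <= max_hairpin nt contains the locus reads
      min_mature_reads — most abundant tag below the read floor
      star_duplex    — no folded window yields a star partner on the opposite
                       arm with <= max_unpaired unpaired mature nucleotides
      dicer_fraction — locus read count in the Dicer size range below 0.8
    """
    cfg = config or LocusConfig()
    if not candidate.hits:
        raise ValueError("candidate has no hits")
    span_start = min(h.start for h in candidate.hits)
    span_end = max(h.end for h in candidate.hits)
    if span_end - span_start > cfg.max_hairpin:
        return Rejection("hairpin_span", f"read span {span_end - span_start} nt")

    mature_hit = _most_abundant(candidate.hits)
    if mature_hit.count < cfg.min_mature_reads:
        return Rejection(
            "min_mature_reads", f"mature count {mature_hit.count} < {cfg.min_mature_reads}"
        )

    fold = _best_hairpin_window(candidate, mature_hit, genome, cfg, span_start, span_end)
    if fold is None:
        return Rejection("star_duplex", "no window with a qualifying mature/star duplex")

    total = sum(h.count for h in candidate.hits)
    lo, hi = cfg.dicer_range
    dicer = sum(h.count for h in candidate.hits if lo <= len(h.tag_seq) <= hi)
    dicer_fraction = dicer / total
    if dicer_fraction < cfg.min_dicer_fraction:
        return Rejection("dicer_fraction", f"{dicer_fraction:.3f} < {cfg.min_dicer_fraction}")

    locus = fold
    locus.dicer_fraction = dicer_fraction
    _attach_extra_pairs(locus, candidate, cfg)
    return locus


def _most_abundant(hits: Sequence[AlignmentHit]) -> AlignmentHit:
    """Most abundant distinct tag; ties broken by 5'-most placement."""
    best = None
    for h in sorted(hits, key=lambda h: (-h.count, h.start, h.strand, h.tag_seq)):
        if best is None:
            best = h
    return best


def _window_seq(genome: dict[str, str], ref_id: str, start: int, end: int, strand: str) -> str:
    seq = genome[ref_id][start:end]
    return revcomp(seq) if strand == "-" else seq


def _best_hairpin_window(
    candidate: Candidate,
    mature_hit: AlignmentHit,
    genome: dict[str, str],
    cfg: LocusConfig,
    span_start: int,
    span_end: int,
) -> MirnaLocus | None:
    """Lowest-energy folding window passing the structure checks.

    Windows of ``min_window``..``max_hairpin`` nt (stepped) that contain the
    read span are folded on the mature's strand; a window qualifies when the
    mature lies on one arm, a star interval exists on the opposite arm, and
    the duplex leaves at most ``max_unpaired`` mature nucleotides unpaired.
    """
    ref_len = len(genome[candidate.ref_id])
    span = span_end - span_start
    best: tuple[float, MirnaLocus] | None = None
    strand = mature_hit.strand
    for wlen in range(max(cfg.min_window, span), cfg.max_hairpin + 1, cfg.window_step):
        lo_off = max(0, span_end - wlen)
        hi_off = min(span_start, ref_len - wlen)
        for wstart in range(lo_off, hi_off + 1, cfg.window_step):
            wend = wstart + wlen
            seq = _window_seq(genome, candidate.ref_id, wstart, wend, strand)
            structure, energy = fold_hairpin(seq)
            if energy >= 0:
                continue
            if strand == "+":
                m_start = mature_hit.start - wstart
            else:
                m_start = wend - mature_hit.end
            m_end = m_start + len(mature_hit.tag_seq)
            star = _star_from_structure(structure, m_start, m_end)
            if star is None:
                continue
            if not duplex_ok(structure, m_start, m_end, cfg.max_unpaired):
                continue
            s_start, s_end = star
            mature_arm = "5p" if m_start < s_start else "3p"
            locus = MirnaLocus(
                ref_id=candidate.ref_id,
                start=wstart,
                end=wend,
                strand=strand,
                precursor_seq=seq,
                structure=structure,
                energy=energy,
                mature_seq=mature_hit.tag_seq,
                mature_arm=mature_arm,
                mature_count=mature_hit.count,
                star_seq=seq[s_start:s_end],
                star_arm="3p" if mature_arm == "5p" else "5p",
                star_count=_star_support(candidate.hits, seq[s_start:s_end]),
                dicer_fraction=0.0,
            )
            if best is None or energy < best[0]:
                best = (energy, locus)
    return best[1] if best else None


def _star_support(hits: Sequence[AlignmentHit], star_seq: str) -> int:
    return sum(h.count for h in hits if h.tag_seq == star_seq)


def _attach_extra_pairs(locus: MirnaLocus, candidate: Candidate, cfg: LocusConfig) -> None:
    """Record up to ``max_duplexes - 1`` additional mature/star pairs.

    A further pair requires an independent tag (not the mature or star) with
    at least ``min_mature_reads`` support inside the precursor.
    """
    seen = {locus.mature_seq, locus.star_seq}
    extras: list[tuple[str, int, str, int]] = []
    for h in sorted(candidate.hits, key=lambda h: (-h.count, h.start, h.tag_seq)):
        if len(extras) >= cfg.max_duplexes - 1:
            break
        if h.tag_seq in seen or h.count < cfg.min_mature_reads:
            continue
        if locus.strand == "+":
            m_start = h.start - locus.start
        else:
            m_start = locus.end - h.end
        m_end = m_start + len(h.tag_seq)
        if m_start < 0 or m_end > len(locus.precursor_seq):
            continue
        star = _star_from_structure(locus.structure, m_start, m_end)
        if star is None:
            continue
        if duplex_unpaired(locus.structure, m_start, m_end) > cfg.max_unpaired:
            continue
        s_start, s_end = star
        star_seq = locus.precursor_seq[s_start:s_end]
        extras.append((h.tag_seq, h.count, star_seq, _star_support(candidate.hits, star_seq)))
        seen.add(h.tag_seq)
        seen.add(star_seq)
    locus.extra_pairs = extras


def classify_mature(
    locus: MirnaLocus,
    species_refs: Sequence[MatureReference],
    plant_refs: Sequence[MatureReference],
    known_loci: Sequence[tuple[str, int, int]] | None = None,
) -> str:
    """Classify an accepted locus's mature sequence.

    Precedence: exact same-species match (at a known locus when known locus
    coordinates are supplied) > exact other-plant match > reverse complement
    of a same-species entry > same-species mature at a new locus
    (``novel_family_member``) > ``novel``.  isomiR relationships (end shifts
    of up to 3 nt against same-species entries) are annotated on the locus.
    """
    mature = locus.mature_seq
    species_by_seq: dict[str, list[MatureReference]] = {}
    for r in species_refs:
        species_by_seq.setdefault(r.seq, []).append(r)
    plant_seqs = {r.seq for r in plant_refs}

    locus.isomir_of = sorted(
        {r.mirna_id for r in species_refs if _is_isomir(mature, r.seq)}
    )

    if mature in species_by_seq:
        if known_loci is not None and not _overlaps_known(locus, known_loci):
            cls = "novel_family_member"
        else:
            cls = "known_same_species"
    elif mature in plant_seqs:
        cls = "plant_homolog"
    elif revcomp(mature) in species_by_seq:
        cls = "antisense_of_known"
    else:
        cls = "novel"
    locus.classification = cls
    return cls


def _overlaps_known(locus: MirnaLocus, known_loci: Sequence[tuple[str, int, int]]) -> bool:
    return any(
        rid == locus.ref_id and locus.start < end and start < locus.end
        for rid, start, end in known_loci
    )


def _is_isomir(a: str, b: str, max_shift: int = 3) -> bool:
    """End-shift variants: identical after trimming up to max_shift nt total
    from the ends of the longer onto the shorter, sharing a common core."""
    if a == b:
        return False
    if abs(len(a) - len(b)) > max_shift:
        return False
    # a is an isomiR of b if one is a substring of the other, or they share
    # a common overlap with <=max_shift total end-shift on each side
    for shift5 in range(-max_shift, max_shift + 1):
        # align a's start at b's position shift5
        start_a = max(0, -shift5)
        start_b = max(0, shift5)
        ov = min(len(a) - start_a, len(b) - start_b)
        if ov < max(len(a), len(b)) - max_shift:
            continue
        if a[start_a : start_a + ov] == b[start_b : start_b + ov]:
            return True
    return False


def loci_to_frame(loci: Sequence[MirnaLocus]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                l.ref_id, l.start, l.end, l.strand, l.mature_seq, l.mature_arm,
                l.mature_count, l.star_seq, l.star_count, f"{l.dicer_fraction:.4f}",
                f"{l.energy:.2f}", l.classification, ",".join(l.isomir_of),
            )
            for l in loci
        ],
        columns=[
            "ref_id", "start", "end", "strand", "mature_seq", "mature_arm",
            "mature_count", "star_seq", "star_count", "dicer_fraction",
            "energy", "classification", "isomir_of",
        ],
    )


def write_loci_gff3(loci: Sequence[MirnaLocus], path: str | Path) -> None:
    """Precursor + mature + star features, 1-based inclusive GFF3."""
    with open(path, "w") as out:
        out.write("##gff-version 3\n")
        for i, l in enumerate(loci, 1):
            pid = f"MIR_novel_{i}"
            out.write(
                f"{l.ref_id}\tsrnaome\tmiRNA_primary_transcript\t{l.start + 1}\t{l.end}\t"
                f".\t{l.strand}\t.\tID={pid};classification={l.classification}\n"
            )
            for kind, seq in (("miRNA", l.mature_seq), ("miRNA_star", l.star_seq)):
                off = l.precursor_seq.find(seq)
                if off < 0:
                    continue
                if l.strand == "+":
                    s = l.start + off
                else:
                    s = l.end - off - len(seq)
                out.write(
                    f"{l.ref_id}\tsrnaome\t{kind}\t{s + 1}\t{s + len(seq)}\t.\t{l.strand}\t.\t"
                    f"ID={pid}.{kind};Parent={pid}\n"
                )


def write_precursor_fasta(loci: Sequence[MirnaLocus], path: str | Path) -> None:
    with open(path, "w") as out:
        for i, l in enumerate(loci, 1):
            out.write(f">MIR_novel_{i} {l.ref_id}:{l.start}-{l.end}({l.strand})\n{l.precursor_seq}\n")
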
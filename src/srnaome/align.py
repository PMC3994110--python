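"""Exhaustive short-tag alignment with 0 or 1 mismatches.

Small-RNA analysis needs *all* placements of each tag on a reference set
(genome, transcriptome or repeat library), on both strands, within a strict
Hamming budget — no indels.  Lookup uses pigeonhole seeding: with at most one
mismatch, at least one half of the query matches the reference exactly, so
scanning for both halves and verifying candidates by Hamming distance is
complete.  ``N`` never matches anything, including another ``N``.

Coordinates are 0-based half-open on the forward reference strand; a minus
hit means the reverse complement of the tag matches the forward window.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from srnaome.sio import ReadTag, _open_text

_RC = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


@dataclass(frozen=True)
class AlignmentHit:
    """Placement of a tag on a reference window.

    ``start`` is the 0-based offset of the window on the forward strand; the
    window spans ``[start, start + len(tag_seq))``.  ``count`` carries the
    tag's full redundant read count at every placement (downstream consumers
    decide multi-mapper weighting).
    """

    tag_seq: str
    ref_id: str
    start: int
    strand: str  # '+' or '-'
    mismatches: int
    count: int

    @property
    def end(self) -> int:
        return self.start + len(self.tag_seq)


class TagIndex:
    """All-occurrence lookup structure over a set of named references."""

    MIN_QUERY = 8
    MAX_QUERY = 40

    def __init__(self, references: dict[str, str]):
        if not references:
            raise ValueError("empty reference set")
        self.refs: dict[str, str] = {}
        for ref_id, seq in references.items():
            seq = seq.upper()
            if set(seq) - set("ACGTN"):
                raise ValueError(f"reference {ref_id!r}: non-ACGTN characters")
            self.refs[ref_id] = seq

    @property
    def lengths(self) -> dict[str, int]:
        return {rid: len(s) for rid, s in self.refs.items()}

    def _candidates(self, ref: str, query: str) -> set[int]:
        """Candidate start offsets by exact occurrence of either query half."""
        half = len(query) // 2
        cands: set[int] = set()
        for seed, shift in ((query[:half], 0), (query[half:], half)):
            pos = ref.find(seed)
            while pos != -1:
                start = pos - shift
                if 0 <= start <= len(ref) - len(query):
                    cands.add(start)
                pos = ref.find(seed, pos + 1)
        return cands

    def lookup(self, query: str, max_mismatch: int) -> list[tuple[str, int, int]]:
        """All (ref_id, start, mismatches) with Hamming distance <= max_mismatch."""
        if not self.MIN_QUERY <= len(query) <= self.MAX_QUERY:
            raise ValueError(
                f"query length {len(query)} outside supported range "
                f"[{self.MIN_QUERY}, {self.MAX_QUERY}]"
            )
        out: list[tuple[str, int, int]] = []
        for ref_id, ref in self.refs.items():
            if len(query) > len(ref):
                continue
            if max_mismatch == 0:
                if "N" in query:  # N never matches, even N-vs-N
                    continue
                pos = ref.find(query)
                while pos != -1:
                    out.append((ref_id, pos, 0))
                    pos = ref.find(query, pos + 1)
                continue
            for start in sorted(self._candidates(ref, query)):
                mm = _hamming(ref[start : start + len(query)], query, max_mismatch)
                if mm is not None:
                    out.append((ref_id, start, mm))
        return out


def _hamming(window: str, query: str, budget: int) -> int | None:
    """Mismatch count if <= budget else None; N mismatches everything."""
    mm = 0
    for a, b in zip(window, query):
        if a != b or a == "N":
            mm += 1
            if mm > budget:
                return None
    return mm


def build_index(references: dict[str, str] | Iterable[tuple[str, str]]) -> TagIndex:
    """Build an all-occurrence index from ``{ref_id: seq}`` or (id, seq) pairs.

    Duplicate reference ids are an error.
    """
    if not isinstance(references, dict):
        refs: dict[str, str] = {}
        for ref_id, seq in references:
            if ref_id in refs:
                raise ValueError(f"duplicate reference id {ref_id!r}")
            refs[ref_id] = seq
        references = refs
    return TagIndex(references)


def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA -> {id: sequence}; duplicate ids are an error."""
    from Bio.SeqIO.FastaIO import SimpleFastaParser

    refs: dict[str, str] = {}
    with _open_text(path) as handle:
        for title, seq in SimpleFastaParser(handle):
            rid = title.split()[0]
            if rid in refs:
                raise ValueError(f"duplicate reference id {rid!r}")
            refs[rid] = seq.upper()
    return refs


def map_tags(
    tags: Iterable[ReadTag],
    index: TagIndex,
    max_mismatch: int = 1,
    report_both_strands: bool = True,
) -> list[AlignmentHit]:
    """Report every placement of every tag within the mismatch budget.

    Deterministic ordering: (ref_id, start, strand, tag_seq).
    """
    if max_mismatch not in (0, 1):
        raise ValueError(f"max_mismatch must be 0 or 1, got {max_mismatch}")
    hits: list[AlignmentHit] = []
    for tag in tags:
        for ref_id, start, mm in index.lookup(tag.seq, max_mismatch):
            hits.append(AlignmentHit(tag.seq, ref_id, start, "+", mm, tag.count))
        if report_both_strands:
            rc = revcomp(tag.seq)
            for ref_id, start, mm in index.lookup(rc, max_mismatch):
                hits.append(AlignmentHit(tag.seq, ref_id, start, "-", mm, tag.count))
    hits.sort(key=lambda h: (h.ref_id, h.start, h.strand, h.tag_seq))
    return hits


def hits_to_frame(hits: Sequence[AlignmentHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (h.tag_seq, h.ref_id, h.start, h.end, h.strand, h.mismatches, h.count)
            for h in hits
        ],
        columns=["tag_seq", "ref_id", "start", "end", "strand", "mismatches", "count"],
    )


def write_hits_tsv(hits: Sequence[AlignmentHit], path: str | Path) -> None:
    hits_to_frame(hits).to_csv(path, sep="\t", index=False)


def write_sam(hits: Sequence[AlignmentHit], index: TagIndex, path: str | Path) -> None:
    """Minimal SAM: header plus mandatory fields and the NM tag.

    Minus-strand hits store the reverse complement of the tag (SAM stores the
    sequence as it matches the forward reference) with flag 16.
    """
    with open(path, "w") as out:
        out.write("@HD\tVN:1.6\tSO:unsorted\n")
        for rid, length in index.lengths.items():
            out.write(f"@SQ\tSN:{rid}\tLN:{length}\n")
        for i, h in enumerate(hits):
            flag = 16 if h.strand == "-" else 0
            seq = revcomp(h.tag_seq) if h.strand == "-" else h.tag_seq
            out.write(
                f"tag{i}_x{h.count}\t{flag}\t{h.ref_id}\t{h.start + 1}\t255\t"
                f"{len(seq)}M\t*\t0\t0\t{seq}\t*\tNM:i:{h.mismatches}\n"
            )
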
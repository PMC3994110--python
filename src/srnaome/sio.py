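"""Small-RNA read preprocessing and I/O.

Raw reads arrive as FASTQ with the 3' sequencing adapter still attached.
This module trims the adapter (semiglobal suffix-of-read vs prefix-of-adapter
alignment, substitutions only), applies the quality and length filters used
for sRNA libraries (every base >= Q20; 17-26 nt inserts), collapses surviving
reads to unique tags with redundant counts, and computes the per-length
size/redundancy profile of a library.

Read counts partition exactly at every stage: trimmed + untrimmed = input;
kept + each rejection reason = input; sum of tag counts = kept reads.
"""

from __future__ import annotations

import gzip
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, TextIO

import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

VALID_BASES = frozenset("ACGTN")
PHRED_OFFSET = 33  # Sanger / Illumina 1.8+; other encodings are rejected


class AdapterConfigError(ValueError):
    """Raised for an unusable adapter/trimming configuration."""


class ReadFormatError(ValueError):
    """Raised for malformed read sequences or qualities."""


@dataclass
class ReadRecord:
    """One sequencing read: id, sequence over {A,C,G,T,N}, per-base Phred scores."""

    read_id: str
    seq: str
    quals: list[int]
    adapter_trimmed: bool | None = None  # None = trimming not attempted yet

    def __post_init__(self) -> None:
        if not self.seq:
            raise ReadFormatError(f"read {self.read_id!r}: empty sequence")
        if len(self.seq) != len(self.quals):
            raise ReadFormatError(
                f"read {self.read_id!r}: sequence length {len(self.seq)} != "
                f"quality length {len(self.quals)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class ReadTag:
    """A unique small-RNA sequence with its redundant read count."""

    seq: str
    count: int

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError(f"tag {self.seq}: count must be >= 1, got {self.count}")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class TrimReport:
    """Partition of trimming outcomes; ``empty`` counts adapter-only reads
    (adapter at position 0, leaving no insert), which are dropped."""

    trimmed: int = 0
    untrimmed: int = 0
    empty: int = 0

    @property
    def total(self) -> int:
        return self.trimmed + self.untrimmed + self.empty


@dataclass
class FilterReport:
    """Partition of the input reads: kept + every rejection reason == total."""

    kept: int = 0
    rejected_quality: int = 0
    rejected_length: int = 0
    rejected_n: int = 0

    @property
    def total(self) -> int:
        return self.kept + self.rejected_quality + self.rejected_length + self.rejected_n

    def as_dict(self) -> dict[str, int]:
        return {
            "kept": self.kept,
            "rejected_quality": self.rejected_quality,
            "rejected_length": self.rejected_length,
            "rejected_n": self.rejected_n,
            "total": self.total,
        }


def _open_text(path: str | Path, mode: str = "rt") -> TextIO:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)  # type: ignore[return-value]
    return open(path, mode)


def read_fastq(path: str | Path) -> Iterator[ReadRecord]:
    """Stream a (optionally gzipped) FASTQ file as ReadRecords.

    Quality strings are decoded at Phred+33.  Characters below '!' or above
    'J'+5 are treated as evidence of a non-Sanger encoding and rejected.
    """
    with _open_text(path) as handle:
        for title, seq, qual in FastqGeneralIterator(handle):
            seq = seq.upper()
            bad = set(seq) - VALID_BASES
            if bad:
                raise ReadFormatError(
                    f"read {title.split()[0]!r}: non-ACGTN characters {sorted(bad)}"
                )
            quals = [ord(c) - PHRED_OFFSET for c in qual]
            if any(q < 0 or q > 62 for q in quals):
                raise ReadFormatError(
                    f"read {title.split()[0]!r}: quality characters outside the "
                    "Sanger/Illumina-1.8+ (Phred+33) range; other encodings are not supported"
                )
            yield ReadRecord(title.split()[0], seq, quals)


def write_fastq(reads: Iterable[ReadRecord], path: str | Path) -> None:
    with _open_text(path, "wt") as out:
        for r in reads:
            qual = "".join(chr(q + PHRED_OFFSET) for q in r.quals)
            out.write(f"@{r.read_id}\n{r.seq}\n+\n{qual}\n")


def _best_adapter_start(seq: str, adapter: str, min_overlap: int, max_error_rate: float) -> int | None:
    """Best start position of the adapter prefix within the read suffix.

    Considers every read position i; the overlap is the adapter prefix laid
    over seq[i:].  A candidate qualifies when overlap >= min_overlap and
    mismatches/overlap <= max_error_rate.  Best = most matching bases;
    ties go to the earlier (longer-overlap) position.  Returns None when no
    candidate qualifies.
    """
    n = len(seq)
    best_i: int | None = None
    best_matches = -1
    for i in range(0, n - min_overlap + 1):
        overlap = min(n - i, len(adapter))
        if overlap < min_overlap:
            break
        window = seq[i : i + overlap]
        mism = sum(1 for a, b in zip(window, adapter) if a != b)
        if mism / overlap > max_error_rate:
            continue
        matches = overlap - mism
        if matches > best_matches:
            best_matches = matches
            best_i = i
    return best_i


def trim_adapter(
    reads: Iterable[ReadRecord],
    adapter: str,
    min_overlap: int = 3,
    max_error_rate: float = 0.1,
) -> tuple[list[ReadRecord], TrimReport]:
    """Remove the 3' adapter from each read.

    The best-scoring alignment of a read suffix against the adapter prefix
    with error rate <= ``max_error_rate`` is removed together with everything
    3' of it; quality scores are truncated in lockstep.  Reads without a
    qualifying match are kept untrimmed with ``adapter_trimmed=False``.
    """
    adapter = adapter.upper()
    if not adapter:
        raise AdapterConfigError("adapter sequence is empty")
    if min_overlap < 1 or len(adapter) < min_overlap:
        raise AdapterConfigError(
            f"need adapter length ({len(adapter)}) >= min_overlap ({min_overlap}) >= 1"
        )
    if not 0 <= max_error_rate < 0.5:
        raise AdapterConfigError(f"max_error_rate must be in [0, 0.5), got {max_error_rate}")
    if set(adapter) - VALID_BASES:
        raise AdapterConfigError(f"adapter contains non-ACGTN characters: {adapter}")

    out: list[ReadRecord] = []
    report = TrimReport()
    for r in reads:
        bad = set(r.seq) - VALID_BASES
        if bad:
            raise ReadFormatError(f"read {r.read_id!r}: non-ACGTN characters {sorted(bad)}")
        i = _best_adapter_start(r.seq, adapter, min_overlap, max_error_rate)
        if i is None:
            report.untrimmed += 1
            out.append(ReadRecord(r.read_id, r.seq, list(r.quals), adapter_trimmed=False))
            continue
        if i == 0:  # adapter-only read, no insert left
            report.empty += 1
            continue
        report.trimmed += 1
        out.append(ReadRecord(r.read_id, r.seq[:i], list(r.quals[:i]), adapter_trimmed=True))
    return out, report


def filter_reads(
    reads: Iterable[ReadRecord],
    min_phred: int = 20,
    min_len: int = 17,
    max_len: int = 26,
    quality_mode: str = "per_base",
    min_fraction: float = 0.9,
) -> tuple[list[ReadRecord], FilterReport]:
    """Quality- and length-filter reads.

    A read is kept iff it contains no N, its quality passes (default: every
    base >= ``min_phred``; ``quality_mode='fraction'`` instead requires at
    least ``min_fraction`` of bases at or above the threshold), and
    ``min_len <= length <= max_len``.  The report partitions the input;
    rejection reasons are checked in the order N > quality > length.
    """
    if min_len > max_len:
        raise ValueError(f"min_len ({min_len}) > max_len ({max_len})")
    if min_phred < 0:
        raise ValueError(f"min_phred must be >= 0, got {min_phred}")
    if quality_mode not in ("per_base", "fraction"):
        raise ValueError(f"unknown quality_mode {quality_mode!r}")

    kept: list[ReadRecord] = []
    report = FilterReport()
    for r in reads:
        if "N" in r.seq:
            report.rejected_n += 1
            continue
        if quality_mode == "per_base":
            ok = all(q >= min_phred for q in r.quals)
        else:
            ok = sum(q >= min_phred for q in r.quals) >= min_fraction * len(r.quals)
        if not ok:
            report.rejected_quality += 1
            continue
        if not min_len <= len(r.seq) <= max_len:
            report.rejected_length += 1
            continue
        report.kept += 1
        kept.append(r)
    return kept, report


def collapse(reads: Iterable[ReadRecord]) -> list[ReadTag]:
    """Collapse reads to unique tags.

    One tag per distinct sequence; the sum of tag counts equals the number of
    input reads.  Output order is deterministic: descending count, then
    lexicographic sequence.
    """
    counts = Counter(r.seq for r in reads)
    return [
        ReadTag(seq, c)
        for seq, c in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]


def size_profile(
    tags: Iterable[ReadTag], min_len: int = 17, max_len: int = 26
) -> pd.DataFrame:
    """Per-length redundant/non-redundant read profile over [min_len, max_len].

    Columns: length, redundant (sum of counts), nonredundant (number of tags),
    redundant_pct / nonredundant_pct (percentages over the in-range totals),
    redundancy (1 - nonredundant/redundant; 0 where the length is absent).
    """
    tags = list(tags)
    if not tags:
        raise ValueError("size_profile: empty tag collection")
    rows = []
    for L in range(min_len, max_len + 1):
        in_len = [t for t in tags if len(t) == L]
        red = sum(t.count for t in in_len)
        nonred = len(in_len)
        rows.append({"length": L, "redundant": red, "nonredundant": nonred})
    df = pd.DataFrame(rows)
    tot_red = df["redundant"].sum()
    tot_nonred = df["nonredundant"].sum()
    df["redundant_pct"] = 100.0 * df["redundant"] / tot_red if tot_red else 0.0
    df["nonredundant_pct"] = 100.0 * df["nonredundant"] / tot_nonred if tot_nonred else 0.0
    df["redundancy"] = [
        1.0 - (n / r) if r > 0 else 0.0 for n, r in zip(df["nonredundant"], df["redundant"])
    ]
    return df


def write_tags_fasta(tags: Iterable[ReadTag], path: str | Path) -> None:
    """Collapsed tags as FASTA with headers ``tag<rank>_x<count>`` (rank from 1)."""
    with _open_text(path, "wt") as out:
        for rank, t in enumerate(tags, start=1):
            out.write(f">tag{rank}_x{t.count}\n{t.seq}\n")


def read_tags_fasta(path: str | Path) -> list[ReadTag]:
    from Bio.SeqIO.FastaIO import SimpleFastaParser

    tags = []
    with _open_text(path) as handle:
        for title, seq in SimpleFastaParser(handle):
            count = int(title.rsplit("_x", 1)[1])
            tags.append(ReadTag(seq.upper(), count))
    return tags


def write_tags_tsv(tags: Iterable[ReadTag], path: str | Path) -> None:
    pd.DataFrame([(t.seq, t.count) for t in tags], columns=["seq", "count"]).to_csv(
        path, sep="\t", index=False
    )


def write_size_profile_tsv(profile: pd.DataFrame, path: str | Path) -> None:
    profile.to_csv(path, sep="\t", index=False, float_format="%.6f")
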
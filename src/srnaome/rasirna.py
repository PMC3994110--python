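"""Repeat-associated siRNA (rasiRNA) assignment and summaries.

Tags that exactly match a known mature miRNA are removed first, so no tag is
counted both as a miRNA and a rasiRNA.  The remainder map to a repeat
library (transposons, satellites, integrated viruses) allowing one mismatch
on either strand; per-repeat clusters report totals, the strand split and
fold bias, and the length histogram.  Heterochromatin-associated rasiRNAs
are typically 24 nt, so the global size distribution is of direct interest.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from srnaome import align
from srnaome.mirna import MatureReference
from srnaome.nat import strand_bias_counts
from srnaome.sio import ReadTag


@dataclass
class RepeatCluster:
    repeat_id: str
    total_count: int
    plus_count: int
    minus_count: int
    length_counts: dict[int, int]  # read length -> count
    strand_bias_fold: float
    dominant_length: int
    multi_repeat_tags: int = 0  # tags in this cluster that also hit other repeats


def filter_mirna_tags(
    tags: Iterable[ReadTag], known_matures: Sequence[MatureReference]
) -> tuple[list[ReadTag], list[ReadTag]]:
    """Partition tags into (retained, removed-as-known-miRNA).

    Removal is exact sequence identity (T=U) to any known mature.
    """
    known = {m.seq for m in known_matures}
    retained, removed = [], []
    for t in tags:
        (removed if t.seq in known else retained).append(t)
    return retained, removed


def assign_repeats(
    tags: Sequence[ReadTag],
    repeat_library: dict[str, str],
    max_mismatch: int = 1,
    unique_only: bool = False,
) -> tuple[list[RepeatCluster], list[str]]:
    """Map tags to the repeat library and build per-repeat clusters.

    Every placement is reported; a tag hitting several repeats contributes
    its full count to each cluster (``unique_only=True`` restricts to tags
    hitting exactly one repeat).  Returns (clusters sorted by descending
    total, repeat ids with zero hits).  A tag placed several times within
    one repeat is counted once per repeat per strand orientation set —
    concretely, per (tag, repeat) the count enters once, on the strand of
    its first placement.
    """
    index = align.build_index(repeat_library)
    hits = align.map_tags(tags, index, max_mismatch=max_mismatch, report_both_strands=True)

    # one (tag, repeat) contribution regardless of placement multiplicity
    per_tag_repeat: dict[tuple[str, str], align.AlignmentHit] = {}
    repeats_per_tag: dict[str, set[str]] = {}
    for h in hits:
        per_tag_repeat.setdefault((h.tag_seq, h.ref_id), h)
        repeats_per_tag.setdefault(h.tag_seq, set()).add(h.ref_id)

    by_repeat: dict[str, list[align.AlignmentHit]] = {rid: [] for rid in repeat_library}
    for (tag_seq, rid), h in per_tag_repeat.items():
        if unique_only and len(repeats_per_tag[tag_seq]) > 1:
            continue
        by_repeat[rid].append(h)

    clusters: list[RepeatCluster] = []
    empty: list[str] = []
    for rid in sorted(repeat_library):
        rhits = by_repeat[rid]
        if not rhits:
            empty.append(rid)
            continue
        plus = sum(h.count for h in rhits if h.strand == "+")
        minus = sum(h.count for h in rhits if h.strand == "-")
        lengths: dict[int, int] = {}
        for h in rhits:
            lengths[len(h.tag_seq)] = lengths.get(len(h.tag_seq), 0) + h.count
        fold, _ = strand_bias_counts(plus, minus, min_reads=0, threshold=2.0)
        dominant = max(lengths.items(), key=lambda kv: (kv[1], -kv[0]))[0]
        clusters.append(
            RepeatCluster(
                repeat_id=rid,
                total_count=plus + minus,
                plus_count=plus,
                minus_count=minus,
                length_counts=lengths,
                strand_bias_fold=fold,
                dominant_length=dominant,
                multi_repeat_tags=sum(
                    1 for h in rhits if len(repeats_per_tag[h.tag_seq]) > 1
                ),
            )
        )
    clusters.sort(key=lambda c: (-c.total_count, c.repeat_id))
    return clusters, empty


def summarize_sizes(
    clusters: Sequence[RepeatCluster], min_len: int = 17, max_len: int = 26
) -> pd.DataFrame:
    """Global rasiRNA size distribution: counts and fraction per length."""
    totals: dict[int, int] = {L: 0 for L in range(min_len, max_len + 1)}
    for c in clusters:
        for L, n in c.length_counts.items():
            if min_len <= L <= max_len:
                totals[L] += n
    grand = sum(totals.values())
    return pd.DataFrame(
        [
            {"length": L, "count": n, "fraction": n / grand if grand else 0.0}
            for L, n in sorted(totals.items())
        ]
    )


def clusters_to_frame(
    clusters: Sequence[RepeatCluster], min_len: int = 17, max_len: int = 26
) -> pd.DataFrame:
    rows = []
    for c in clusters:
        row = {
            "repeat_id": c.repeat_id,
            "total": c.total_count,
            "plus": c.plus_count,
            "minus": c.minus_count,
            "bias_fold": c.strand_bias_fold,
            "dominant_length": c.dominant_length,
            "multi_repeat_tags": c.multi_repeat_tags,
        }
        for L in range(min_len, max_len + 1):
            row[f"len_{L}"] = c.length_counts.get(L, 0)
        rows.append(row)
    return pd.DataFrame(rows)
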
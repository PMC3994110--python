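"""Natural antisense transcript (NAT) discovery and nat-siRNA statistics.

cis-NAT pairs are transcripts on opposite strands of the same locus whose
genomic intervals intersect by more than 50 nt (strict).  trans-NAT pairs
come from non-overlapping loci but share a maximal exact reverse-complement
run of more than 100 nt (strict).  Pairs in which at least one transcript
has no genomic coordinates are tested with the trans sequence criterion and
labelled ``unclassified``.  Duplex formation of the overlap sequences is
checked by RNA hybridization (ViennaRNA cofold, counting intermolecular
pairs).  Per-pair small-RNA statistics compare read density (reads/kb) in
the overlap against the rest of the pair, cohort enrichment uses a two-sided
Wilcoxon rank-sum test, and strand bias is the fold difference between reads
attributable to the two transcripts of a duplex.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import RNA
from scipy import stats

from srnaome.align import AlignmentHit, revcomp

UNKNOWN = "UNKNOWN"


@dataclass(frozen=True)
class TranscriptModel:
    """A transcript with its sequence (incl. up to 300 nt flanks) and, when
    known, its genomic placement (0-based half-open)."""

    transcript_id: str
    seq: str
    chrom: str = UNKNOWN
    g_start: int = -1
    g_end: int = -1
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.chrom != UNKNOWN:
            if self.g_start < 0 or self.g_end <= self.g_start:
                raise ValueError(
                    f"transcript {self.transcript_id!r}: malformed coordinates "
                    f"[{self.g_start}, {self.g_end})"
                )
            if self.g_end - self.g_start != len(self.seq):
                raise ValueError(
                    f"transcript {self.transcript_id!r}: genomic span "
                    f"{self.g_end - self.g_start} != sequence length {len(self.seq)}"
                )

    @property
    def placed(self) -> bool:
        return self.chrom != UNKNOWN

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class OverlapRegion:
    """Overlap mapped into each transcript's local coordinates (half-open)."""

    t1_interval: tuple[int, int]
    t2_interval: tuple[int, int]
    length: int
    genomic_interval: tuple[int, int] | None = None  # cis only


@dataclass
class NatPair:
    """An unordered NAT pair; canonical orientation t1 < t2."""

    t1: str
    t2: str
    pair_type: str  # 'cis' | 'trans' | 'unclassified'
    overlaps: list[OverlapRegion]
    duplex_valid: bool | None = None

    def __post_init__(self) -> None:
        if self.t1 == self.t2:
            raise ValueError(f"self-pair {self.t1!r}")
        if self.t1 > self.t2:
            self.t1, self.t2 = self.t2, self.t1
            self.overlaps = [
                OverlapRegion(o.t2_interval, o.t1_interval, o.length, o.genomic_interval)
                for o in self.overlaps
            ]
        if not self.overlaps:
            raise ValueError(f"pair {self.t1}-{self.t2}: no overlap regions")


@dataclass
class NatStats:
    pair: NatPair
    overlap_density: float  # reads/kb
    nonoverlap_density: float
    strand_counts: tuple[int, int]  # (t1_derived, t2_derived)
    bias_fold: float
    biased: bool


def _local(t: TranscriptModel, g_lo: int, g_hi: int) -> tuple[int, int]:
    """Genomic interval -> transcript-local interval (5'->3' of the transcript)."""
    if t.strand == "+":
        return g_lo - t.g_start, g_hi - t.g_start
    return t.g_end - g_hi, t.g_end - g_lo


def find_cis_pairs(
    transcripts: Sequence[TranscriptModel], min_overlap: int = 50
) -> list[NatPair]:
    """Opposite-strand transcripts of one locus with genomic intersection
    strictly greater than ``min_overlap`` nt."""
    placed = [t for t in transcripts if t.placed]
    by_chrom: dict[str, list[TranscriptModel]] = {}
    for t in placed:
        by_chrom.setdefault(t.chrom, []).append(t)
    pairs: list[NatPair] = []
    for chrom in sorted(by_chrom):
        ts = sorted(by_chrom[chrom], key=lambda t: (t.g_start, t.transcript_id))
        for i, a in enumerate(ts):
            for b in ts[i + 1 :]:
                if b.g_start >= a.g_end:
                    break
                if a.strand == b.strand:
                    continue
                lo = max(a.g_start, b.g_start)
                hi = min(a.g_end, b.g_end)
                if hi - lo <= min_overlap:
                    continue
                region = OverlapRegion(
                    t1_interval=_local(a, lo, hi),
                    t2_interval=_local(b, lo, hi),
                    length=hi - lo,
                    genomic_interval=(lo, hi),
                )
                if a.transcript_id < b.transcript_id:
                    pairs.append(NatPair(a.transcript_id, b.transcript_id, "cis", [region]))
                else:
                    pairs.append(NatPair(b.transcript_id, a.transcript_id, "cis",
                                         [OverlapRegion(region.t2_interval,
                                                        region.t1_interval,
                                                        region.length,
                                                        region.genomic_interval)]))
    pairs.sort(key=lambda p: (p.t1, p.t2))
    return pairs


def _genomic_disjoint(a: TranscriptModel, b: TranscriptModel) -> bool:
    if a.chrom != b.chrom:
        return True
    return a.g_end <= b.g_start or b.g_end <= a.g_start


def _antisense_runs(s1: str, s2: str, min_run: int, k: int = 20) -> list[tuple[int, int, int]]:
    """Maximal exact reverse-complement runs > min_run between s1 and s2.

    Seed k-mers of s1 against revcomp(s2) and extend along the diagonal.
    Returns (start1, start2, length) with start2 on s2's own (sense) axis.
    """
    r2 = revcomp(s2)
    seeds: dict[str, list[int]] = {}
    for i in range(len(s1) - k + 1):
        seeds.setdefault(s1[i : i + k], []).append(i)
    seen: set[tuple[int, int]] = set()
    runs: list[tuple[int, int, int]] = []
    for j in range(len(r2) - k + 1):
        for i in seeds.get(r2[j : j + k], ()):
            diag = i - j
            # extend left
            a, b = i, j
            while a > 0 and b > 0 and s1[a - 1] == r2[b - 1]:
                a -= 1
                b -= 1
            if (diag, a) in seen:
                continue
            seen.add((diag, a))
            # extend right
            e1, e2 = i + k, j + k
            while e1 < len(s1) and e2 < len(r2) and s1[e1] == r2[e2]:
                e1 += 1
                e2 += 1
            length = e1 - a
            if length > min_run:
                start2 = len(s2) - (b + length)  # back to s2 sense coordinates
                runs.append((a, start2, length))
    runs.sort()
    return runs


def find_trans_pairs(
    transcripts: Sequence[TranscriptModel], min_run: int = 100
) -> list[NatPair]:
    """Pairs sharing a maximal reverse-complement run strictly > ``min_run``.

    Transcripts from non-overlapping genomic loci give ``trans`` pairs; when
    at least one transcript is unplaced the sequence criterion still applies
    and the pair is ``unclassified``.  Genomically overlapping transcripts
    are the cis criterion's business and are skipped here.
    """
    ts = sorted(transcripts, key=lambda t: t.transcript_id)
    pairs: list[NatPair] = []
    for i, a in enumerate(ts):
        for b in ts[i + 1 :]:
            if a.placed and b.placed and not _genomic_disjoint(a, b):
                continue
            runs = _antisense_runs(a.seq, b.seq, min_run)
            if not runs:
                continue
            pair_type = "trans" if (a.placed and b.placed) else "unclassified"
            regions = [
                OverlapRegion((s1, s1 + L), (s2, s2 + L), L) for s1, s2, L in runs
            ]
            pairs.append(NatPair(a.transcript_id, b.transcript_id, pair_type, regions))
    pairs.sort(key=lambda p: (p.t1, p.t2))
    return pairs


def duplex_paired_fraction(seq1: str, seq2: str) -> tuple[float, float]:
    """Fraction of bases in an intermolecular duplex and the hybrid MFE.

    Cofolds the two sequences and counts only pairs crossing the strand
    break, so unrelated sequences that merely fold on themselves score low.
    """
    a = seq1.upper().replace("T", "U")
    b = seq2.upper().replace("T", "U")
    fc = RNA.fold_compound(a + "&" + b)
    ss, mfe = fc.mfe()
    pt = RNA.ptable(ss)
    n1 = len(a)
    inter = sum(1 for i in range(1, n1 + 1) if pt[i] > n1)
    return 2.0 * inter / (len(a) + len(b)), float(mfe)


def validate_duplex(
    pair: NatPair,
    transcripts: dict[str, TranscriptModel],
    min_paired_fraction: float = 0.5,
) -> bool:
    """Hybridization check of the pair's overlap sequences.

    Valid iff the intermolecular paired fraction reaches the threshold and
    the hybrid energy is negative.  trans/unclassified overlaps are exact
    reverse complements by construction and are always valid.  A threshold
    of 0 accepts everything (degenerate configuration).
    """
    import warnings

    if min_paired_fraction <= 0:
        warnings.warn("min_paired_fraction <= 0: every duplex validates", stacklevel=2)
        pair.duplex_valid = True
        return True
    if pair.pair_type in ("trans", "unclassified"):
        pair.duplex_valid = True
        return True
    t1 = transcripts[pair.t1]
    t2 = transcripts[pair.t2]
    valid = False
    for ov in pair.overlaps:
        s1 = t1.seq[ov.t1_interval[0] : ov.t1_interval[1]]
        s2 = t2.seq[ov.t2_interval[0] : ov.t2_interval[1]]
        frac, mfe = duplex_paired_fraction(s1, s2)
        if frac >= min_paired_fraction and mfe < 0:
            valid = True
            break
    pair.duplex_valid = valid
    return valid


def classify_relationships(pairs: Sequence[NatPair]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Network relationships per pair-type cohort.

    Builds the pairing graph of each cohort; a pair is one-to-one when both
    endpoints have degree 1, one-to-many when exactly one endpoint has
    degree > 1, many-to-many when both do.  Returns (per-pair labels,
    per-cohort percentage summary); percentages within a cohort sum to 100.
    """
    rows = []
    for cohort in ("cis", "trans", "unclassified"):
        sub = [p for p in pairs if p.pair_type == cohort]
        if not sub:
            continue
        g = nx.Graph()
        g.add_edges_from((p.t1, p.t2) for p in sub)
        for p in sub:
            d1, d2 = g.degree(p.t1), g.degree(p.t2)
            if d1 == 1 and d2 == 1:
                rel = "one_to_one"
            elif d1 > 1 and d2 > 1:
                rel = "many_to_many"
            else:
                rel = "one_to_many"
            rows.append((p.t1, p.t2, cohort, rel))
    per_pair = pd.DataFrame(rows, columns=["t1", "t2", "pair_type", "relationship"])
    summaries = []
    for cohort, grp in per_pair.groupby("pair_type"):
        n = len(grp)
        for rel in ("one_to_one", "one_to_many", "many_to_many"):
            summaries.append((cohort, rel, 100.0 * (grp["relationship"] == rel).sum() / n))
    summary = pd.DataFrame(summaries, columns=["pair_type", "relationship", "pct"])
    return per_pair, summary


def _hit_regions(
    t: TranscriptModel, intervals: Sequence[tuple[int, int]], hits: Sequence[AlignmentHit]
) -> tuple[int, int]:
    """(overlap_count, nonoverlap_count) for hits on one transcript.

    A hit belongs to the region containing its placement midpoint.
    """
    ov = 0
    non = 0
    for h in hits:
        mid = (h.start + h.end) / 2
        if any(lo <= mid < hi for lo, hi in intervals):
            ov += h.count
        else:
            non += h.count
    return ov, non


def compute_density(
    hits: Sequence[AlignmentHit],
    pairs: Sequence[NatPair],
    transcripts: dict[str, TranscriptModel],
    min_reads_bias: int = 10,
    bias_threshold: float = 2.0,
) -> list[NatStats]:
    """Per-pair overlap and non-overlap sRNA densities, strand bias.

    ``hits`` are transcript-space placements (both strands).  Overlap density
    pools hits from both transcripts over the pooled overlap length (counted
    once — the two overlap intervals describe the same duplex region);
    non-overlap density covers the remainders of both transcripts.  Reads
    attributable to a transcript are the sense-strand overlap hits on that
    transcript; the bias fold is max/min with a pseudocount of 1 applied to
    both counts when the minimum is zero.
    """
    import warnings

    by_ref: dict[str, list[AlignmentHit]] = {}
    for h in hits:
        by_ref.setdefault(h.ref_id, []).append(h)

    out: list[NatStats] = []
    for pair in pairs:
        t1 = transcripts[pair.t1]
        t2 = transcripts[pair.t2]
        iv1 = [o.t1_interval for o in pair.overlaps]
        iv2 = [o.t2_interval for o in pair.overlaps]
        ov_len = sum(o.length for o in pair.overlaps)
        non_len = (len(t1) - ov_len) + (len(t2) - ov_len)
        ov1, non1 = _hit_regions(t1, iv1, by_ref.get(pair.t1, ()))
        ov2, non2 = _hit_regions(t2, iv2, by_ref.get(pair.t2, ()))
        if ov_len <= 0:
            warnings.warn(f"pair {pair.t1}-{pair.t2}: zero-length overlap, skipped")
            continue
        ov_density = (ov1 + ov2) / (ov_len / 1000.0)
        non_density = (non1 + non2) / (non_len / 1000.0) if non_len > 0 else 0.0
        c1 = sum(
            h.count
            for h in by_ref.get(pair.t1, ())
            if h.strand == "+" and any(lo <= (h.start + h.end) / 2 < hi for lo, hi in iv1)
        )
        c2 = sum(
            h.count
            for h in by_ref.get(pair.t2, ())
            if h.strand == "+" and any(lo <= (h.start + h.end) / 2 < hi for lo, hi in iv2)
        )
        fold, biased = strand_bias_counts(c1, c2, min_reads_bias, bias_threshold)
        out.append(
            NatStats(
                pair=pair,
                overlap_density=ov_density,
                nonoverlap_density=non_density,
                strand_counts=(c1, c2),
                bias_fold=fold,
                biased=biased,
            )
        )
    return out


def strand_bias_counts(
    c1: int, c2: int, min_reads: int = 10, threshold: float = 2.0
) -> tuple[float, bool]:
    """Fold bias between transcript-attributed counts.

    max/min convention; when the minimum is zero a pseudocount of 1 is added
    to both counts.  Biased iff fold >= threshold (inclusive) and the pair
    has at least ``min_reads`` attributed reads in total.
    """
    hi, lo = max(c1, c2), min(c1, c2)
    if lo == 0:
        fold = (hi + 1) / 1.0
    else:
        fold = hi / lo
    biased = fold >= threshold and (c1 + c2) >= min_reads
    return fold, biased


def enrichment_test(
    overlap_densities: Sequence[float], nonoverlap_densities: Sequence[float]
) -> tuple[float, str]:
    """Two-sided Wilcoxon rank-sum comparison of the two density cohorts.

    Exact null distribution for cohort sizes <= 25 without ties, normal
    approximation with tie correction otherwise.  Direction is 'enriched'
    when the overlap median exceeds the non-overlap median, 'reduced' when
    it is lower; identical cohorts give p = 1 and direction 'none'.
    """
    x = np.asarray(overlap_densities, dtype=float)
    y = np.asarray(nonoverlap_densities, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need at least 2 pairs per cohort")
    if np.all(x == y[0]) and np.all(y == y[0]):
        return 1.0, "none"
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (len(x) <= 25 and len(y) <= 25 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    direction = "enriched" if np.median(x) > np.median(y) else "reduced"
    if np.median(x) == np.median(y):
        direction = "enriched" if np.mean(x) > np.mean(y) else "reduced"
    return float(res.pvalue), direction


def pairs_to_frame(pairs: Sequence[NatPair]) -> pd.DataFrame:
    rows = []
    for p in pairs:
        for o in p.overlaps:
            rows.append(
                (p.t1, p.t2, p.pair_type, o.t1_interval[0], o.t1_interval[1],
                 o.t2_interval[0], o.t2_interval[1], o.length,
                 "" if p.duplex_valid is None else p.duplex_valid)
            )
    return pd.DataFrame(
        rows,
        columns=["t1", "t2", "pair_type", "t1_start", "t1_end",
                 "t2_start", "t2_end", "overlap_length", "duplex_valid"],
    )


def cohort_summary(
    pairs: Sequence[NatPair],
    stats_list: Sequence[NatStats],
    n_transcripts: int,
) -> pd.DataFrame:
    """Per-cohort summary: pair count, % of transcripts involved, median
    overlap length, relationship percentages, median densities, enrichment
    p-value/direction, % of pairs with >=2-fold strand bias."""
    _, rel_summary = classify_relationships(pairs)
    rows = []
    for cohort in ("cis", "trans", "unclassified"):
        sub = [p for p in pairs if p.pair_type == cohort]
        if not sub:
            continue
        st = [s for s in stats_list if s.pair.pair_type == cohort]
        tr = {p.t1 for p in sub} | {p.t2 for p in sub}
        med_len = float(np.median([o.length for p in sub for o in p.overlaps]))
        row = {
            "pair_type": cohort,
            "pairs": len(sub),
            "pct_transcripts": 100.0 * len(tr) / n_transcripts if n_transcripts else 0.0,
            "median_overlap_nt": med_len,
        }
        for rel in ("one_to_one", "one_to_many", "many_to_many"):
            sel = rel_summary[
                (rel_summary.pair_type == cohort) & (rel_summary.relationship == rel)
            ]["pct"]
            row[f"pct_{rel}"] = float(sel.iloc[0]) if len(sel) else 0.0
        if len(st) >= 2:
            ov = [s.overlap_density for s in st]
            non = [s.nonoverlap_density for s in st]
            p, direction = enrichment_test(ov, non)
            row["median_overlap_density"] = float(np.median(ov))
            row["median_nonoverlap_density"] = float(np.median(non))
            row["enrichment_p"] = p
            row["enrichment_direction"] = direction
            row["pct_biased"] = 100.0 * sum(s.biased for s in st) / len(st)
        rows.append(row)
    return pd.DataFrame(rows)
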
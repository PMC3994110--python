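"""Phased siRNA (phasiRNA / PHAS) cluster detection and initiator analysis.

RdRp-derived double-stranded RNA diced from a defined start yields siRNAs in
head-to-tail registers of the phase size (21 nt here).  Detection slides a
window of ``cycles`` phase periods along each reference; within a window the
distinct 5' positions of phase-sized tags are collapsed modulo the phase
size (minus-strand 5' ends shifted +2 for the 2-nt 3' overhang geometry of
the Dicer duplex), and the register occupying the most distinct cycles is
scored with a hypergeometric tail: the probability of at least k occupied
cycles in one register given n occupied slots among phase_size x cycles
positions.  Overlapping significant windows merge into maximal clusters
reporting their best window.

Initiator miRNAs are target sites whose predicted cleavage position falls in
(or drifts a few nucleotides off) a cluster's dominant register; plants'
canonical initiators are 22-nt, 5'-U miRNAs acting through a one-hit or
two-hit site model.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from scipy import stats

from srnaome.align import AlignmentHit
from srnaome.targets import TargetSite

ALPHA_TRANSCRIPT = 0.0034  # Bonferroni-adjusted defaults for the two modes
ALPHA_GENOME = 0.001


@dataclass
class PhasedCluster:
    ref_id: str
    start: int  # 0-based half-open
    end: int
    phase_size: int
    dominant_register: int  # 0 .. phase_size-1, absolute (ref coord mod phase)
    n_phased_positions: int  # distinct occupied cycles in the dominant register
    n_occupied_positions: int  # distinct occupied slots in the best window
    p_value: float
    significant: bool
    strandedness: float  # fraction of read counts on the plus strand


@dataclass(frozen=True)
class PhaseInitiator:
    cluster: PhasedCluster
    mirna_id: str
    cleavage_pos: int
    in_register: bool
    drift: int  # signed nt offset from the dominant register
    initiator_len: int
    five_prime_nt: str
    hit_model: str  # 'one_hit' | 'two_hit'
    degradome_supported: bool


def effective_position(hit: AlignmentHit, phase_size: int) -> int | None:
    """Register-collapsed 5' position of a phase-sized tag.

    Only tags of exactly ``phase_size`` nt participate.  Plus-strand tags
    use their start; minus-strand tags are shifted +2 so that the two
    strands of one Dicer duplex fall in the same register.
    """
    if len(hit.tag_seq) != phase_size:
        return None
    return hit.start if hit.strand == "+" else hit.start + 2


def phase_pvalue(k: int, n: int, phase_size: int, cycles: int) -> float:
    """Hypergeometric tail: P(>= k occupied cycles in one fixed register | n
    occupied slots among phase_size * cycles)."""
    N = phase_size * cycles
    return float(stats.hypergeom.sf(k - 1, N, cycles, n))


def register_corrected_pvalue(k: int, n: int, phase_size: int, cycles: int) -> float:
    """Window p-value with Bonferroni correction for register selection.

    The tail probability is computed for one fixed register, but the scored
    register is the *dominant* one among ``phase_size`` candidates; without
    the correction, diffuse read clouds (a dozen random 21-nt positions)
    reach nominal significance at a few percent per window.
    """
    return min(1.0, phase_size * phase_pvalue(k, n, phase_size, cycles))


def detect_phased_clusters(
    hits: Sequence[AlignmentHit],
    ref_lengths: dict[str, int],
    phase_size: int = 21,
    cycles: int = 9,
    alpha_adjusted: float = ALPHA_GENOME,
    min_distinct: int = 4,
) -> list[PhasedCluster]:
    """Scan for significantly phased windows and merge them into clusters.

    Windows of ``phase_size * cycles`` nt slide by one cycle; a window is
    scored when it holds at least ``min_distinct`` distinct effective
    positions.  Clusters merge overlapping significant windows and carry the
    best window's register and p-value.  Input hits may carry at most one
    mismatch; both strands contribute.
    """
    if phase_size < 15:
        raise ValueError(f"phase_size must be >= 15, got {phase_size}")
    window = phase_size * cycles

    by_ref: dict[str, list[AlignmentHit]] = {}
    for h in hits:
        by_ref.setdefault(h.ref_id, []).append(h)

    clusters: list[PhasedCluster] = []
    for ref_id in sorted(by_ref):
        ref_hits = by_ref[ref_id]
        pos_counts: dict[int, tuple[int, int]] = {}  # eff pos -> (+count, -count)
        for h in ref_hits:
            p = effective_position(h, phase_size)
            if p is None:
                continue
            plus, minus = pos_counts.get(p, (0, 0))
            if h.strand == "+":
                plus += h.count
            else:
                minus += h.count
            pos_counts[p] = (plus, minus)
        if not pos_counts:
            continue
        positions = sorted(pos_counts)
        ref_len = ref_lengths.get(ref_id, positions[-1] + window)

        sig_windows: list[tuple[int, int, int, float, int]] = []
        # candidate window starts: one per cycle across the occupied range
        w_lo = max(0, positions[0] - window + phase_size)
        w_hi = min(positions[-1], max(0, ref_len - window))
        start = w_lo
        while start <= w_hi:
            in_win = [p for p in positions if start <= p < start + window]
            if len(in_win) >= min_distinct:
                k, reg = _dominant_register(in_win, start, phase_size)
                p_val = register_corrected_pvalue(k, len(in_win), phase_size, cycles)
                if p_val < alpha_adjusted:
                    sig_windows.append((start, start + window, reg, p_val, k))
            start += phase_size
        clusters.extend(
            _merge_windows(sig_windows, ref_id, phase_size, pos_counts, alpha_adjusted)
        )
    clusters.sort(key=lambda c: (c.ref_id, c.start))
    return clusters


def _dominant_register(positions: Sequence[int], w_start: int, phase_size: int) -> tuple[int, int]:
    """(k, absolute register) with the most distinct occupied cycles."""
    cycles_by_reg: dict[int, set[int]] = {}
    for p in positions:
        rel = p - w_start
        cycles_by_reg.setdefault(rel % phase_size, set()).add(rel // phase_size)
    reg_rel, occupied = max(
        cycles_by_reg.items(), key=lambda kv: (len(kv[1]), -kv[0])
    )
    reg_abs = (w_start + reg_rel) % phase_size
    return len(occupied), reg_abs


def _merge_windows(
    windows: Sequence[tuple[int, int, int, float, int]],
    ref_id: str,
    phase_size: int,
    pos_counts: dict[int, tuple[int, int]],
    alpha: float,
) -> list[PhasedCluster]:
    if not windows:
        return []
    windows = sorted(windows)
    merged: list[list[tuple[int, int, int, float, int]]] = [[windows[0]]]
    for w in windows[1:]:
        if w[0] < merged[-1][-1][1]:  # overlaps the open cluster
            merged[-1].append(w)
        else:
            merged.append([w])
    out = []
    for group in merged:
        best = min(group, key=lambda w: (w[3], w[0]))
        c_start = min(w[0] for w in group)
        c_end = max(w[1] for w in group)
        in_cluster = [p for p in pos_counts if c_start <= p < c_end]
        plus = sum(pos_counts[p][0] for p in in_cluster)
        minus = sum(pos_counts[p][1] for p in in_cluster)
        n_occ = sum(1 for p in pos_counts if best[0] <= p < best[1])
        out.append(
            PhasedCluster(
                ref_id=ref_id,
                start=c_start,
                end=c_end,
                phase_size=phase_size,
                dominant_register=best[2],
                n_phased_positions=best[4],
                n_occupied_positions=n_occ,
                p_value=best[3],
                significant=best[3] < alpha,
                strandedness=plus / (plus + minus) if plus + minus else 0.0,
            )
        )
    return out


def correct_multiple_testing(
    clusters: Sequence[PhasedCluster],
    alpha_adjusted: float | None = None,
    alpha_family: float | None = None,
    n_tests: int | None = None,
    mode: str = "genome",
) -> list[PhasedCluster]:
    """Re-flag cluster significance under a Bonferroni-adjusted level.

    The level is ``alpha_adjusted`` when given, else ``alpha_family /
    n_tests``, else the mode default (0.001 genome, 0.0034 transcript).
    Significance is strict: raw p < adjusted alpha.
    """
    if alpha_adjusted is None:
        if alpha_family is not None:
            if not n_tests or n_tests < 1:
                raise ValueError("alpha_family requires n_tests >= 1")
            alpha_adjusted = alpha_family / n_tests
        else:
            alpha_adjusted = ALPHA_GENOME if mode == "genome" else ALPHA_TRANSCRIPT
    for c in clusters:
        c.significant = c.p_value < alpha_adjusted
    return list(clusters)


def signed_drift(cleavage_pos: int, register: int, phase_size: int) -> int:
    """Offset of a cleavage position from a register, in [-phase/2, phase/2)."""
    d = (cleavage_pos - register) % phase_size
    if d >= phase_size - phase_size // 2:
        d -= phase_size
    return d


def find_initiators(
    clusters: Sequence[PhasedCluster],
    target_sites: Sequence[TargetSite],
    degradome_supported: dict[tuple[str, int], bool] | None = None,
) -> list[PhaseInitiator]:
    """Match miRNA target sites to clusters as potential phase initiators.

    Every site on a cluster's reference within the cluster or up to one
    phase length away yields an initiator record.  The drift is the signed
    offset of the cleavage position from the dominant register; in-register
    means drift 0.  The same miRNA hitting a cluster at two or more sites is
    a two-hit initiator.  ``degradome_supported`` maps (transcript_id,
    cleavage_pos) to the validation flag.
    """
    degradome_supported = degradome_supported or {}
    by_ref: dict[str, list[TargetSite]] = {}
    for s in target_sites:
        by_ref.setdefault(s.transcript_id, []).append(s)

    out: list[PhaseInitiator] = []
    for cluster in clusters:
        sites = [
            s
            for s in by_ref.get(cluster.ref_id, ())
            if cluster.start - cluster.phase_size
            <= s.cleavage_pos
            < cluster.end + cluster.phase_size
        ]
        per_mirna: dict[str, int] = {}
        for s in sites:
            per_mirna[s.mirna_id] = per_mirna.get(s.mirna_id, 0) + 1
        for s in sites:
            mature_len = len(s.alignment[0])
            drift = signed_drift(s.cleavage_pos, cluster.dominant_register, cluster.phase_size)
            out.append(
                PhaseInitiator(
                    cluster=cluster,
                    mirna_id=s.mirna_id,
                    cleavage_pos=s.cleavage_pos,
                    in_register=drift == 0,
                    drift=drift,
                    initiator_len=mature_len,
                    five_prime_nt=s.alignment[0][0],
                    hit_model="two_hit" if per_mirna[s.mirna_id] >= 2 else "one_hit",
                    degradome_supported=degradome_supported.get(
                        (s.transcript_id, s.cleavage_pos), False
                    ),
                )
            )
    return out


def clusters_to_frame(clusters: Sequence[PhasedCluster]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (c.ref_id, c.start, c.end, c.phase_size, c.dominant_register,
             c.n_phased_positions, c.n_occupied_positions, c.p_value,
             c.significant, f"{c.strandedness:.4f}")
            for c in clusters
        ],
        columns=["ref_id", "start", "end", "phase_size", "dominant_register",
                 "n_phased", "n_occupied", "p_value", "significant", "strandedness"],
    )


def initiators_to_frame(initiators: Sequence[PhaseInitiator]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (i.cluster.ref_id, i.cluster.start, i.cluster.end, i.mirna_id,
             i.cleavage_pos, i.in_register, i.drift, i.initiator_len,
             i.five_prime_nt, i.hit_model, i.degradome_supported)
            for i in initiators
        ],
        columns=["ref_id", "cluster_start", "cluster_end", "mirna_id",
                 "cleavage_pos", "in_register", "drift", "initiator_len",
                 "five_prime_nt", "hit_model", "degradome_supported"],
    )


def write_clusters_bed(clusters: Sequence[PhasedCluster], path: str | Path) -> None:
    with open(path, "w") as out:
        for i, c in enumerate(clusters, 1):
            out.write(
                f"{c.ref_id}\t{c.start}\t{c.end}\tPHAS_{i}\t"
                f"{min(1000, int(-100 * _log10(c.p_value)))}\t+\n"
            )


def _log10(p: float) -> float:
    import math

    return math.log10(p) if p > 0 else -300.0
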
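"""Independent brute-force oracles used to check the package's operations.

Each function here is a deliberately naive reimplementation that shares no
code path with the package: exhaustive scans, dynamic programs, exact
enumerations.  Slow but obviously correct at small problem sizes.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

_RC = str.maketrans("ACGTN", "TGCAN")


def rc(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def brute_force_map(
    tags: list[tuple[str, int]],
    refs: dict[str, str],
    max_mm: int,
    both_strands: bool = True,
) -> set[tuple[str, str, int, str, int]]:
    """Every (tag, ref, start, strand, mismatches) by scanning ALL windows.

    No seeding or indexing: every window of every reference is compared
    against every query in full (vectorized over windows for speed; an N on
    either side always counts as a mismatch).
    """
    import numpy as np

    ref_arrays = {
        rid: np.frombuffer(ref.encode(), dtype=np.uint8) for rid, ref in refs.items()
    }
    n_code = ord("N")
    hits = set()
    for tag, _count in tags:
        queries = [(tag, "+")]
        if both_strands:
            queries.append((rc(tag), "-"))
        for q, strand in queries:
            qa = np.frombuffer(q.encode(), dtype=np.uint8)
            L = len(q)
            for rid, ra in ref_arrays.items():
                if L > len(ra):
                    continue
                windows = np.lib.stride_tricks.sliding_window_view(ra, L)
                mm = (
                    (windows != qa) | (windows == n_code) | (qa == n_code)
                ).sum(axis=1)
                for s in np.flatnonzero(mm <= max_mm):
                    hits.add((tag, rid, int(s), strand, int(mm[s])))
    return hits


def best_trim(seq: str, adapter: str, min_overlap: int, max_err: float) -> int | None:
    """All-offsets alignment: best adapter-prefix start in the read, or None."""
    best = None
    best_matches = -1
    for i in range(len(seq)):
        overlap = min(len(seq) - i, len(adapter))
        if overlap < min_overlap:
            continue
        mism = sum(1 for a, b in zip(seq[i : i + overlap], adapter) if a != b)
        if mism > max_err * overlap:
            continue
        matches = overlap - mism
        if matches > best_matches:
            best_matches = matches
            best = i
    return best


def nussinov_max_pairs(seq: str, min_loop: int = 3) -> int:
    """Pairing-maximization dynamic program (WC + GU pairs)."""
    seq = seq.upper().replace("T", "U")
    allowed = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}
    n = len(seq)
    dp = [[0] * n for _ in range(n)]
    for span in range(min_loop + 1, n):
        for i in range(n - span):
            j = i + span
            best = dp[i + 1][j]
            for k in range(i + min_loop + 1, j + 1):
                if (seq[i], seq[k]) in allowed:
                    left = dp[i + 1][k - 1]
                    right = dp[k + 1][j] if k + 1 <= j else 0
                    best = max(best, 1 + left + right)
            dp[i][j] = best
    return dp[0][n - 1]


def rescore_target(mature: str, window: str) -> float:
    """Position-by-position recomputation of the target penalty score."""
    m = mature.upper().replace("U", "T")
    t = rc(window.upper().replace("U", "T"))  # base facing mature position p at index p-1
    total = 0.0
    for p, (mb, tb_rc) in enumerate(zip(m, t), start=1):
        # tb_rc is the complement of the physical target base; undo it
        tb = {"A": "T", "T": "A", "G": "C", "C": "G"}[tb_rc]
        if {"A": "T", "T": "A", "G": "C", "C": "G"}[mb] == tb:
            pen = 0.0
        elif (mb, tb) in (("G", "T"), ("T", "G")):
            pen = 0.5
        else:
            pen = 1.0
        if 2 <= p <= 13:
            pen *= 2
        total += pen
    return total


def phase_tail_enumeration(k: int, n: int, phase_size: int, cycles: int) -> float:
    """Exhaustive placement enumeration for the phasing tail probability.

    All ways to occupy ``n`` of the ``phase_size * cycles`` window slots are
    equally likely; returns the fraction with at least ``k`` occupied slots
    in a fixed register (the register's slots are one per cycle).
    """
    N = phase_size * cycles
    register = set(range(0, N, phase_size))
    hits = 0
    total = 0
    for placement in combinations(range(N), n):
        total += 1
        if len(register.intersection(placement)) >= k:
            hits += 1
    assert total == comb(N, n)
    return hits / total


def ranksum_permutation_p(x: list[float], y: list[float]) -> float:
    """Exact two-sided rank-sum p by enumerating group assignments."""
    pooled = sorted(x + y)
    ranks = {}
    i = 0
    while i < len(pooled):
        j = i
        while j < len(pooled) and pooled[j] == pooled[i]:
            j += 1
        r = (i + j + 1) / 2  # midrank, 1-based
        ranks[pooled[i]] = r
        i = j
    # rank sum of x under all C(n, nx) assignments of pooled values
    obs = sum(ranks[v] for v in x)
    n = len(pooled)
    nx = len(x)
    vals = [ranks[v] for v in pooled]
    count_ge = 0
    count_le = 0
    total = 0
    for idx in combinations(range(n), nx):
        s = sum(vals[i] for i in idx)
        total += 1
        if s >= obs - 1e-9:
            count_ge += 1
        if s <= obs + 1e-9:
            count_le += 1
    return min(1.0, 2 * min(count_ge, count_le) / total)


def interval_union(intervals: list[tuple[int, int]], max_gap: int) -> list[tuple[int, int]]:
    """Sweep-line merge of intervals separated by <= max_gap."""
    out: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if out and s - out[-1][1] <= max_gap:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def antisense_runs_dp(s1: str, s2: str) -> list[tuple[int, int, int]]:
    """All maximal exact match runs between s1 and revcomp(s2) by full DP."""
    r2 = rc(s2)
    n, m = len(s1), len(r2)
    runs = []
    for diag in range(-(m - 1), n):
        i = max(0, diag)
        j = i - diag
        length = 0
        start_i = i
        while i <= n and j <= m:
            if i < n and j < m and s1[i] == r2[j]:
                if length == 0:
                    start_i = i
                length += 1
            else:
                if length > 0:
                    runs.append((start_i, len(s2) - (start_i - diag + length), length))
                length = 0
            i += 1
            j += 1
    return runs
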
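"""miRNA target prediction and degradome validation.

Complementarity is scored with the Allen-type penalty scheme used throughout
plant target prediction: reading the mature 5'->3' against the target site,
each position contributes 0 for a Watson-Crick match, 0.5 for a G:U wobble,
1 for a mismatch and 2 for a gap, with penalties doubled in the seed (mature
positions 2-13).  The sum is the "expectation"; sites at or below a cutoff
(default 3.0) are reported.  A site with a mismatch or gap at mature
positions 9-11 is predicted to act by translational inhibition, otherwise by
cleavage between the target bases opposite mature positions 10-11.

Cleavage sites are validated against degradome (PARE) tags: the 5' ends of
degradome reads mark uncapped cleavage products, so a supported site shows a
tag peak at the predicted cleavage position.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from srnaome.align import AlignmentHit, revcomp

SEED = (2, 13)  # mature positions with doubled penalties, 1-based inclusive
CENTRAL = (9, 11)  # mismatch/gap here -> translational inhibition

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass(frozen=True)
class TargetSite:
    mirna_id: str
    transcript_id: str
    t_start: int  # 0-based on the transcript (sense)
    expectation: float
    alignment: tuple[str, str, str]  # mature 5'->3', pairing symbols, site 3'->5'
    mode: str  # 'cleavage' | 'translational_inhibition'
    cleavage_pos: int  # transcript coordinate opposite mature position 10


@dataclass(frozen=True)
class DegradomeSupport:
    site: TargetSite
    tags_at_site: int
    tags_elsewhere_max: int
    supported: bool
    category: str  # 'peak_max' | 'above_median' | 'none'


def _position_penalty(m_base: str, t_base: str) -> tuple[float, str]:
    """Penalty and pairing symbol for one mature/target base pair.

    ``t_base`` is the transcript (sense) base physically opposite the mature
    base.  Match = WC complement; G:U wobble = mature G opposite target T or
    mature T opposite target G.
    """
    if _COMP.get(m_base) == t_base:
        return 0.0, "|"
    if (m_base, t_base) in (("G", "T"), ("T", "G")):
        return 0.5, "o"
    return 1.0, " "


def score_target(mature: str, window: str) -> tuple[float, tuple[str, str, str]]:
    """Expectation penalty of the mature against one candidate site window.

    ``window`` is the transcript site read sense 5'->3' and must have the
    mature's length (ungapped).  Mature position p (1-based, 5'->3') faces
    window base ``window[L - p]``.  Seed positions 2-13 carry doubled
    penalties.
    """
    mature = mature.upper().replace("U", "T")
    window = window.upper().replace("U", "T")
    if set(mature + window) - set("ACGT"):
        raise ValueError("score_target: non-nucleotide characters in input")
    if len(window) != len(mature):
        raise ValueError(
            f"ungapped scoring needs equal lengths; got {len(mature)} vs {len(window)}"
        )
    L = len(mature)
    total = 0.0
    symbols = []
    for p in range(1, L + 1):
        m_base = mature[p - 1]
        t_base = window[L - p]
        pen, sym = _position_penalty(m_base, t_base)
        if SEED[0] <= p <= SEED[1]:
            pen *= 2
        total += pen
        symbols.append(sym)
    alignment = (mature, "".join(symbols), window[::-1])
    return total, alignment


def _site_mode(alignment: tuple[str, str, str]) -> str:
    """Translational inhibition iff a mismatch occupies mature positions 9-11."""
    symbols = alignment[1]
    central = symbols[CENTRAL[0] - 1 : CENTRAL[1]]
    return "translational_inhibition" if " " in central else "cleavage"


def find_sites(
    mature: str,
    transcripts: dict[str, str],
    max_expectation: float = 3.0,
    mirna_id: str = "miRNA",
) -> list[TargetSite]:
    """Scan every transcript window for sites with expectation <= cutoff.

    The cleavage position is the transcript coordinate opposite mature
    position 10 (``t_start + L - 10``).
    """
    if max_expectation <= 0:
        raise ValueError("max_expectation must be > 0")
    mature = mature.upper().replace("U", "T")
    L = len(mature)
    sites: list[TargetSite] = []
    for tid in sorted(transcripts):
        seq = transcripts[tid].upper()
        for start in range(0, len(seq) - L + 1):
            window = seq[start : start + L]
            if "N" in window:
                continue
            exp, alignment = score_target(mature, window)
            if exp <= max_expectation:
                sites.append(
                    TargetSite(
                        mirna_id=mirna_id,
                        transcript_id=tid,
                        t_start=start,
                        expectation=exp,
                        alignment=alignment,
                        mode=_site_mode(alignment),
                        cleavage_pos=start + L - 10,
                    )
                )
    return sites


def validate_degradome(
    sites: Sequence[TargetSite],
    degradome_hits: Sequence[AlignmentHit],
    tolerance: int = 1,
    min_tags: int = 2,
    category_mode: str = "peak_max",
) -> list[DegradomeSupport]:
    """Check predicted cleavage sites against degradome tag 5' ends.

    Degradome hits must be sense-strand, 0-mismatch transcript placements;
    the 5' end of a hit is its start.  A site is supported iff the tag count
    within ``cleavage_pos +/- tolerance`` is at least ``min_tags`` and either
    equals the transcript's maximum position count (``peak_max``, the
    category-0-like rule) or is at least the median of nonzero position
    counts (``above_median``).
    """
    if category_mode not in ("peak_max", "above_median"):
        raise ValueError(f"unknown category_mode {category_mode!r}")
    ends: dict[str, dict[int, int]] = {}
    for h in degradome_hits:
        if h.strand != "+" or h.mismatches != 0:
            continue
        ends.setdefault(h.ref_id, {}).setdefault(h.start, 0)
        ends[h.ref_id][h.start] += h.count

    out: list[DegradomeSupport] = []
    for site in sites:
        pos_counts = ends.get(site.transcript_id, {})
        at_site = sum(
            c
            for p, c in pos_counts.items()
            if abs(p - site.cleavage_pos) <= tolerance
        )
        elsewhere = [
            c
            for p, c in pos_counts.items()
            if abs(p - site.cleavage_pos) > tolerance
        ]
        elsewhere_max = max(elsewhere, default=0)
        if at_site < min_tags or not pos_counts:
            supported, category = False, "none"
        elif category_mode == "peak_max":
            supported = at_site >= elsewhere_max
            category = "peak_max" if supported else "none"
        else:
            nonzero = sorted(pos_counts.values())
            med = float(np.median(nonzero)) if nonzero else 0.0
            supported = at_site >= med
            category = "above_median" if supported else "none"
        out.append(
            DegradomeSupport(
                site=site,
                tags_at_site=at_site,
                tags_elsewhere_max=elsewhere_max,
                supported=supported,
                category=category,
            )
        )
    return out


def sites_to_frame(
    supports: Iterable[DegradomeSupport] | Iterable[TargetSite],
) -> pd.DataFrame:
    rows = []
    for item in supports:
        if isinstance(item, DegradomeSupport):
            s = item.site
            rows.append(
                (s.mirna_id, s.transcript_id, s.t_start, s.expectation, s.mode,
                 s.cleavage_pos, item.tags_at_site, item.category, item.supported)
            )
        else:
            rows.append(
                (item.mirna_id, item.transcript_id, item.t_start, item.expectation,
                 item.mode, item.cleavage_pos, 0, "", False)
            )
    return pd.DataFrame(
        rows,
        columns=["mirna_id", "transcript_id", "t_start", "expectation", "mode",
                 "cleavage_pos", "degradome_tags", "degradome_category", "supported"],
    )
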
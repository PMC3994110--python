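"""End-to-end orchestration: reads -> classified small-RNA loci.

Runs preprocessing, mapping, known/novel miRNA analysis, target prediction
with degradome validation, NAT discovery and statistics, phasing analysis
and rasiRNA assignment under a single validated configuration, and emits
the summary tables (per-stage read accounting, size profile, NAT cohort
summary) plus per-module TSV/GFF3 outputs.  A run is fully reproducible
from (inputs, config); every output header records the config hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from srnaome import align, mirna, nat, phas, rasirna, sio, targets

log = logging.getLogger("srnaome")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, code: str, message: str):
        super().__init__(f"[{stage}/{code}] {message}")
        self.stage = stage
        self.code = code


@dataclass
class PipelineConfig:
    """All numeric thresholds of the analysis, range-checked at load."""

    adapter: str = "TGGAATTCTCGGGTGCCAAGG"
    min_phred: int = 20
    min_len: int = 17
    max_len: int = 26
    genome_max_mm: int = 1
    known_mirna_mm: int = 0
    hairpin_max: int = 150
    duplex_max_unpaired: int = 5
    dicer_fraction_min: float = 0.8
    min_mature_reads: int = 10
    cluster_max_gap: int = 100
    cis_min_overlap: int = 50
    trans_min_run: int = 100
    duplex_min_paired_fraction: float = 0.5
    bias_fold: float = 2.0
    bias_min_reads: int = 10
    phase_size: int = 21
    phase_cycles: int = 9
    phase_min_distinct: int = 4
    alpha_transcript: float = 0.0034
    alpha_genome: float = 0.001
    repeat_max_mm: int = 1
    target_max_expectation: float = 3.0
    degradome_tolerance: int = 1
    degradome_min_tags: int = 2
    seed: int = 1

    def __post_init__(self) -> None:
        checks = [
            (self.min_phred >= 0, "min_phred >= 0"),
            (0 < self.min_len <= self.max_len, "0 < min_len <= max_len"),
            (self.genome_max_mm in (0, 1), "genome_max_mm in {0,1}"),
            (self.known_mirna_mm == 0, "known_mirna_mm == 0"),
            (40 <= self.hairpin_max <= 300, "hairpin_max in [40,300]"),
            (self.duplex_max_unpaired >= 0, "duplex_max_unpaired >= 0"),
            (0 <= self.dicer_fraction_min <= 1, "dicer_fraction_min in [0,1]"),
            (self.min_mature_reads >= 1, "min_mature_reads >= 1"),
            (self.cis_min_overlap >= 1, "cis_min_overlap >= 1"),
            (self.trans_min_run >= 1, "trans_min_run >= 1"),
            (self.bias_fold >= 1, "bias_fold >= 1"),
            (self.phase_size >= 15, "phase_size >= 15"),
            (self.phase_cycles >= 3, "phase_cycles >= 3"),
            (0 < self.alpha_transcript < 1, "alpha_transcript in (0,1)"),
            (0 < self.alpha_genome < 1, "alpha_genome in (0,1)"),
            (self.repeat_max_mm in (0, 1), "repeat_max_mm in {0,1}"),
            (self.target_max_expectation > 0, "target_max_expectation > 0"),
        ]
        for ok, rule in checks:
            if not ok:
                raise ValueError(f"PipelineConfig: violated {rule}")

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @staticmethod
    def from_file(path: str | Path) -> "PipelineConfig":
        """Load key=value or JSON configuration."""
        text = Path(path).read_text()
        try:
            data = json.loads(text)
        except json.JSONDecodeError:
            data = {}
            for line in text.splitlines():
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                k, v = line.split("=", 1)
                data[k.strip()] = json.loads(v.strip()) if v.strip()[0] in "0123456789.-[{" else v.strip()
        return PipelineConfig(**data)


@dataclass
class PipelineInputs:
    """In-memory inputs; loaders in sio/align/synthetic_data fill this from files."""

    reads: Sequence[sio.ReadRecord]
    genome: dict[str, str]
    transcripts: Sequence[nat.TranscriptModel]
    species_matures: Sequence[mirna.MatureReference]
    plant_matures: Sequence[mirna.MatureReference]
    repeat_library: dict[str, str]
    degradome_reads: Sequence[sio.ReadRecord] = ()


@dataclass
class PipelineResult:
    config: PipelineConfig
    trim_report: sio.TrimReport
    filter_report: sio.FilterReport
    tags: list[sio.ReadTag]
    size_profile: pd.DataFrame
    genome_hits: list[align.AlignmentHit]
    known_matches: pd.DataFrame
    novel_loci: list[mirna.MirnaLocus]
    rejections: dict[str, int]
    target_supports: list[targets.DegradomeSupport]
    nat_pairs: list[nat.NatPair]
    nat_stats: list[nat.NatStats]
    nat_summary: pd.DataFrame
    phased_genome: list[phas.PhasedCluster]
    phased_transcript: list[phas.PhasedCluster]
    initiators: list[phas.PhaseInitiator]
    repeat_clusters: list[rasirna.RepeatCluster]
    repeat_empty: list[str]
    rasirna_sizes: pd.DataFrame
    stage_counts: pd.DataFrame


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                out = fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - re-raise with stage context
                raise PipelineError(name, "stage_failure", str(exc)) from exc
            return out
        return wrapped
    return deco


def run(config: PipelineConfig, inputs: PipelineInputs) -> PipelineResult:
    """Execute every stage; conservation of read counts is asserted between
    stages and logged as one structured line per stage."""
    cfg = config

    # --- sio ------------------------------------------------------------
    trimmed, trim_report = _run_trim(inputs.reads, cfg)
    kept, filter_report = _run_filter(trimmed, cfg)
    log.info("stage=preprocess in=%d trimmed=%d kept=%d", trim_report.total,
             trim_report.trimmed, filter_report.kept)
    if filter_report.total != len(trimmed):
        raise PipelineError("sio", "conservation", "filter report does not partition input")
    tags = sio.collapse(kept)
    if sum(t.count for t in tags) != len(kept):
        raise PipelineError("sio", "conservation", "collapse lost reads")
    profile = sio.size_profile(tags, cfg.min_len, cfg.max_len) if tags else pd.DataFrame()

    # --- align ----------------------------------------------------------
    genome_index = align.build_index(inputs.genome)
    genome_hits = align.map_tags(tags, genome_index, cfg.genome_max_mm, True)
    log.info("stage=map tags=%d genome_hits=%d", len(tags), len(genome_hits))

    # --- mirna ----------------------------------------------------------
    known = mirna.match_known(tags, inputs.species_matures)
    candidates = mirna.cluster_loci(genome_hits, cfg.cluster_max_gap)
    locus_cfg = mirna.LocusConfig(
        min_mature_reads=cfg.min_mature_reads,
        max_hairpin=cfg.hairpin_max,
        max_unpaired=cfg.duplex_max_unpaired,
        min_dicer_fraction=cfg.dicer_fraction_min,
    )
    novel, rejections = [], {}
    for cand in candidates:
        res = mirna.evaluate_mirna_locus(cand, inputs.genome, locus_cfg)
        if isinstance(res, mirna.MirnaLocus):
            mirna.classify_mature(res, inputs.species_matures, inputs.plant_matures)
            novel.append(res)
        else:
            rejections[res.reason] = rejections.get(res.reason, 0) + 1
    log.info("stage=mirna candidates=%d accepted=%d", len(candidates), len(novel))

    # --- targets (novel + species matures vs transcripts) ---------------
    tx_seqs = {t.transcript_id: t.seq for t in inputs.transcripts}
    matures_for_targets: list[tuple[str, str]] = [
        (m.mirna_id, m.seq) for m in inputs.species_matures
    ] + [(f"novel_{i+1}", l.mature_seq) for i, l in enumerate(novel)]
    all_sites: list[targets.TargetSite] = []
    for mid, seq in matures_for_targets:
        all_sites.extend(
            targets.find_sites(seq, tx_seqs, cfg.target_max_expectation, mirna_id=mid)
        )
    degradome_hits: list[align.AlignmentHit] = []
    if inputs.degradome_reads:
        deg_tags = sio.collapse(list(inputs.degradome_reads))
        tx_index = align.build_index(tx_seqs)
        degradome_hits = align.map_tags(deg_tags, tx_index, 0, report_both_strands=False)
    supports = targets.validate_degradome(
        all_sites, degradome_hits, cfg.degradome_tolerance, cfg.degradome_min_tags
    )
    log.info("stage=targets sites=%d supported=%d", len(all_sites),
             sum(s.supported for s in supports))

    # --- nat ------------------------------------------------------------
    tx_list = list(inputs.transcripts)
    tx_by_id = {t.transcript_id: t for t in tx_list}
    cis = nat.find_cis_pairs(tx_list, cfg.cis_min_overlap)
    trans = nat.find_trans_pairs(tx_list, cfg.trans_min_run)
    pairs = cis + trans
    for p in pairs:
        nat.validate_duplex(p, tx_by_id, cfg.duplex_min_paired_fraction)
    pairs = [p for p in pairs if p.duplex_valid]
    tx_index = align.build_index(tx_seqs)
    tx_hits = align.map_tags(tags, tx_index, 0, report_both_strands=True)
    nat_stats = nat.compute_density(tx_hits, pairs, tx_by_id, cfg.bias_min_reads, cfg.bias_fold)
    nat_summary = nat.cohort_summary(pairs, nat_stats, len(tx_list))
    log.info("stage=nat cis=%d trans=%d valid=%d", len(cis), len(trans), len(pairs))

    # --- phas (genome mode and transcript mode) --------------------------
    phased_g = phas.detect_phased_clusters(
        genome_hits, genome_index.lengths, cfg.phase_size, cfg.phase_cycles,
        cfg.alpha_genome, cfg.phase_min_distinct,
    )
    tx_hits_mm = align.map_tags(tags, tx_index, cfg.genome_max_mm, True)
    phased_t = phas.detect_phased_clusters(
        tx_hits_mm, tx_index.lengths, cfg.phase_size, cfg.phase_cycles,
        cfg.alpha_transcript, cfg.phase_min_distinct,
    )
    support_map = {
        (s.site.transcript_id, s.site.cleavage_pos): s.supported for s in supports
    }
    initiators = phas.find_initiators(
        [c for c in phased_t if c.significant], all_sites, support_map
    )
    log.info("stage=phas genome=%d transcript=%d initiators=%d",
             len(phased_g), len(phased_t), len(initiators))

    # --- rasirna ---------------------------------------------------------
    retained, removed = rasirna.filter_mirna_tags(tags, inputs.species_matures)
    repeat_clusters, repeat_empty = rasirna.assign_repeats(
        retained, inputs.repeat_library, cfg.repeat_max_mm
    )
    sizes = rasirna.summarize_sizes(repeat_clusters, cfg.min_len, cfg.max_len)
    log.info("stage=rasirna clusters=%d empty=%d", len(repeat_clusters), len(repeat_empty))

    stage_counts = _stage_table(
        trim_report, filter_report, tags, known, novel, nat_stats, phased_g,
        phased_t, repeat_clusters
    )

    return PipelineResult(
        config=cfg,
        trim_report=trim_report,
        filter_report=filter_report,
        tags=tags,
        size_profile=profile,
        genome_hits=genome_hits,
        known_matches=known,
        novel_loci=novel,
        rejections=rejections,
        target_supports=supports,
        nat_pairs=pairs,
        nat_stats=nat_stats,
        nat_summary=nat_summary,
        phased_genome=phased_g,
        phased_transcript=phased_t,
        initiators=initiators,
        repeat_clusters=repeat_clusters,
        repeat_empty=repeat_empty,
        rasirna_sizes=sizes,
        stage_counts=stage_counts,
    )


@_stage("sio.trim")
def _run_trim(reads, cfg):
    return sio.trim_adapter(list(reads), cfg.adapter)


@_stage("sio.filter")
def _run_filter(trimmed, cfg):
    return sio.filter_reads(trimmed, cfg.min_phred, cfg.min_len, cfg.max_len)


def _stage_table(trim_report, filter_report, tags, known, novel, nat_stats,
                 phased_g, phased_t, repeat_clusters) -> pd.DataFrame:
    """Per-stage unique/total read accounting (Table-1-style)."""
    known_unique = known["seq"].nunique() if not known.empty else 0
    known_total = (
        known.drop_duplicates("seq")["count"].sum() if not known.empty else 0
    )
    nat_reads = sum(s.strand_counts[0] + s.strand_counts[1] for s in nat_stats)
    rows = [
        ("adapter_trimmed", None, trim_report.trimmed),
        ("high_quality", None, filter_report.kept + filter_report.rejected_length),
        ("length_filtered", len(tags), filter_report.kept),
        ("known_mirna", known_unique, int(known_total)),
        ("novel_mirna_loci", len(novel), sum(l.mature_count for l in novel)),
        ("nat_sirna", None, int(nat_reads)),
        ("phased_clusters_genome", len([c for c in phased_g if c.significant]), None),
        ("phased_clusters_transcript", len([c for c in phased_t if c.significant]), None),
        ("rasirna", None, sum(c.total_count for c in repeat_clusters)),
    ]
    return pd.DataFrame(rows, columns=["stage", "unique", "total"])


def write_outputs(result: PipelineResult, out_dir: str | Path) -> None:
    """All per-module tables plus the run manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    header = f"# srnaome config_hash={result.config.hash()}\n"

    def _tsv(df: pd.DataFrame, name: str) -> None:
        with open(out / name, "w") as fh:
            fh.write(header)
            df.to_csv(fh, sep="\t", index=False)

    _tsv(result.stage_counts, "summary_stages.tsv")
    if not result.size_profile.empty:
        _tsv(result.size_profile, "size_profile.tsv")
    _tsv(result.known_matches, "known_mirna.tsv")
    _tsv(mirna.loci_to_frame(result.novel_loci), "novel_mirna.tsv")
    mirna.write_loci_gff3(result.novel_loci, out / "novel_mirna.gff3")
    _tsv(targets.sites_to_frame(result.target_supports), "targets.tsv")
    _tsv(nat.pairs_to_frame(result.nat_pairs), "nat_pairs.tsv")
    _tsv(result.nat_summary, "nat_summary.tsv")
    _tsv(phas.clusters_to_frame(result.phased_genome), "phas_genome.tsv")
    _tsv(phas.clusters_to_frame(result.phased_transcript), "phas_transcript.tsv")
    phas.write_clusters_bed(result.phased_genome, out / "phas_genome.bed")
    _tsv(phas.initiators_to_frame(result.initiators), "phas_initiators.tsv")
    _tsv(rasirna.clusters_to_frame(result.repeat_clusters), "rasirna.tsv")
    _tsv(result.rasirna_sizes, "rasirna_sizes.tsv")
    sio.write_tags_fasta(result.tags, out / "tags.fa")
    manifest = {
        "config_hash": result.config.hash(),
        "config": dataclasses.asdict(result.config),
        "outputs": sorted(p.name for p in out.iterdir()),
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=1))


def completed(config: PipelineConfig, out_dir: str | Path) -> bool:
    """True when ``out_dir`` holds a finished run for this exact config."""
    manifest = Path(out_dir) / "run_manifest.json"
    if not manifest.exists():
        return False
    try:
        data = json.loads(manifest.read_text())
    except json.JSONDecodeError:
        return False
    return data.get("config_hash") == config.hash()
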
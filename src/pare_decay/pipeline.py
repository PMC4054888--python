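"""End-to-end orchestration: io -> abundance -> classify -> enrich -> mirna -> endo.

A single declarative :class:`PipelineConfig` (YAML-loadable) names the
inputs and carries every numeric knob of every stage, all defaulting to the
thresholds the analysis convention fixes: signatures with count <= 5
dropped, inclusive +-1.5 log2 FC calls, >5-fold "obviously altered",
enrichment starred at P < 0.001, cleavage groups of < 6 members dropped,
motif E-value < 0.001.  Every stage logs its record count after filtering
so each exclusion is auditable, and the whole run is reproducible from the
config alone.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import abundance as ab
from . import decay_classifier as dc
from . import degradome_io as dio
from . import endo_cleavage as ec
from . import enrichment as en
from . import mirna_targets as mt

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]

logger = logging.getLogger("pare_decay")


@dataclass
class PipelineConfig:
    # inputs
    transcripts_fasta: str = ""
    annotation: str = ""
    signatures: str = ""
    counts: str = ""
    mirnas_fasta: str | None = None
    target_set_dir: str | None = None
    blocklist: str | None = None
    # library roles
    pare_control: str = "DW"
    pare_treated: str = "DC"
    rna_control: str = "RW"
    rna_treated: str = "RC"
    # knobs
    low_frequency_min: float = 5.0
    pseudocount: float = 1.0
    fc_threshold: float = 1.5
    fold_alteration: float = 5.0
    enrichment_alpha: float = 1e-3
    mirna_max_score: float = 4.5
    mirna_min_reads: float = 1.0
    prominence_min_count: float = 10.0
    prominence_min_fraction: float = 0.5
    prominence_min_ratio: float = 5.0
    mirna_exclusion_nt: int = 2
    flank_upstream: int = 10
    flank_downstream: int = 15
    min_group_size: int = 6
    motif_evalue_max: float = 1e-3
    motif_width_min: int = 6
    motif_width_max: int = 12
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config field(s): {', '.join(sorted(unknown))}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    def require(self, *fields: str) -> None:
        for name in fields:
            if not getattr(self, name):
                raise ValueError(f"missing required config field: {name}")


@dataclass
class PipelineResult:
    abundance_table: pd.DataFrame
    decay_records: pd.DataFrame
    type_counts: pd.Series
    fraction_altered_d: float
    enrichment: pd.DataFrame | None
    mirna_hits: list
    cleavage_sites: dict[str, list]
    cleavage_groups: list
    region_overall: dict[str, float]
    member_flanks: dict = field(default_factory=dict)  # (transcript, pos) -> flank seq
    outputs: dict[str, str] = field(default_factory=dict)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None) -> PipelineResult:
    """Run every stage in order and (optionally) write the report TSVs."""

    def stage(name):
        logger.info("stage %s", name)

    # -- io --------------------------------------------------------------
    try:
        stage("io")
        config.require("transcripts_fasta", "annotation", "signatures", "counts")
        sequences = dio.read_transcripts(config.transcripts_fasta)
        annotations = dio.read_annotation(config.annotation)
        signatures = dio.read_signatures(config.signatures)
        rna_counts = dio.read_counts(config.counts)
        block = (
            set(Path(config.blocklist).read_text().split()) if config.blocklist else set()
        )
        filtered: dict[str, dio.SignatureMatrix] = {}
        for lib in (config.pare_control, config.pare_treated):
            if lib not in signatures:
                raise ValueError(f"signature table has no library {lib!r}")
            m = dio.filter_blocklist(signatures[lib], block)
            m = dio.filter_low_frequency(m, config.low_frequency_min)
            logger.info(
                "  %s: %d signatures on %d transcripts after filters",
                lib, m.n_entries(), len(m.counts),
            )
            filtered[lib] = m
        for lib in (config.rna_control, config.rna_treated):
            if lib not in rna_counts:
                raise ValueError(f"counts table has no library {lib!r}")
    except StageError:
        raise
    except Exception as exc:
        raise StageError("io", exc) from exc

    # -- abundance --------------------------------------------------------
    try:
        stage("abundance")
        ref = filtered[config.pare_control]
        scaled_treated, factor = ab.normalize_library(filtered[config.pare_treated], ref)
        logger.info("  PARE scale factor (%s -> %s): %.4f",
                    config.pare_treated, config.pare_control, factor)
        norm = {config.pare_control: ref, config.pare_treated: scaled_treated}
        rna_treated_n, r_factor = ab.normalize_counts(
            rna_counts[config.rna_treated], rna_counts[config.rna_control]
        )
        table = ab.build_abundance_table(
            ab.transcript_abundance(ref),
            ab.transcript_abundance(scaled_treated),
            rna_counts[config.rna_control],
            rna_treated_n,
            pseudocount=config.pseudocount,
        )
        frac_altered = ab.fraction_altered(
            table["log2fc_d"], config.fold_alteration, allow_empty=True
        )
        logger.info("  %d genes on both platforms; %.1f%% altered >%g-fold (D)",
                    len(table), 100 * frac_altered, config.fold_alteration)
    except Exception as exc:
        raise StageError("abundance", exc) from exc

    # -- classify ---------------------------------------------------------
    try:
        stage("classify")
        records, type_counts = dc.classify_all(table, config.fc_threshold)
        logger.info("  type counts: %s", type_counts.to_dict())
    except Exception as exc:
        raise StageError("classify", exc) from exc

    # -- enrich -----------------------------------------------------------
    enrichment_table: pd.DataFrame | None = None
    try:
        if config.target_set_dir:
            stage("enrich")
            sets = [
                en.TargetSet.from_file(p)
                for p in sorted(Path(config.target_set_dir).glob("*.txt"))
            ]
            if sets:
                background = set(annotations)
                gene_lists = {
                    lib: {tid for tid, tot in m.transcript_totals().items() if tot > 0}
                    for lib, m in norm.items()
                }
                enrichment_table = en.batch_enrichment(
                    gene_lists, sets, background, alpha=config.enrichment_alpha
                )
                logger.info("  %d enrichment tests", len(enrichment_table))
    except Exception as exc:
        raise StageError("enrich", exc) from exc

    # -- mirna ------------------------------------------------------------
    hits: list[mt.TargetHit] = []
    try:
        if config.mirnas_fasta:
            stage("mirna")
            mirnas = dio.read_transcripts(config.mirnas_fasta)
            hits = mt.scan_targets(
                mirnas,
                sequences,
                norm,
                max_score=config.mirna_max_score,
                min_reads=config.mirna_min_reads,
            )
            logger.info("  %d degradome-supported target hits", len(hits))
    except Exception as exc:
        raise StageError("mirna", exc) from exc

    # -- endo -------------------------------------------------------------
    try:
        stage("endo")
        sites = {
            lib: ec.exclude_mirna_sites(
                ec.detect_prominent_sites(
                    m,
                    min_count=config.prominence_min_count,
                    min_fraction=config.prominence_min_fraction,
                    min_ratio=config.prominence_min_ratio,
                ),
                hits,
                window_nt=config.mirna_exclusion_nt,
            )
            for lib, m in norm.items()
        }
        for lib, s in sites.items():
            logger.info("  %s: %d prominent non-miRNA sites", lib, len(s))
        unique = {}
        for lib in (config.pare_control, config.pare_treated):
            for s in sites[lib]:
                unique.setdefault(s.key, s)
        flanks = ec.extract_flanks(
            unique.values(), sequences, config.flank_upstream, config.flank_downstream
        )
        groups = ec.discover_motif_groups(
            flanks,
            min_group_size=config.min_group_size,
            evalue_max=config.motif_evalue_max,
            widths=range(config.motif_width_min, config.motif_width_max + 1),
        )
        groups = ec.condition_specificity(
            groups,
            sites[config.pare_control],
            sites[config.pare_treated],
            control_label=f"{config.pare_control}_only",
            treated_label=f"{config.pare_treated}_only",
        )
        groups, region_overall = ec.annotate_regions(groups, annotations)
        logger.info("  %d cleavage groups survive", len(groups))
    except Exception as exc:
        raise StageError("endo", exc) from exc

    flank_seqs = {f.site.key: f.sequence for f in flanks}
    result = PipelineResult(
        abundance_table=table,
        decay_records=records,
        type_counts=type_counts,
        fraction_altered_d=frac_altered,
        enrichment=enrichment_table,
        mirna_hits=hits,
        cleavage_sites=sites,
        cleavage_groups=groups,
        region_overall=region_overall,
        member_flanks=flank_seqs,
    )
    if out_dir is not None:
        _write_report(result, config, Path(out_dir))
    return result


def _write_report(result: PipelineResult, config: PipelineConfig, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)

    def save(df: pd.DataFrame, name: str, **kw) -> None:
        path = out_dir / name
        df.to_csv(path, sep="\t", **kw)
        result.outputs[name] = str(path)

    save(result.abundance_table, "abundance.tsv", index_label="transcript_id")
    save(result.decay_records, "decay_types.tsv", index_label="transcript_id")
    save(result.type_counts.rename("n").to_frame(), "type_counts.tsv",
         index_label="decay_type")
    if result.enrichment is not None:
        save(result.enrichment, "enrichment.tsv", index=False)
    save(mt.hits_to_frame(result.mirna_hits,
                          (config.pare_control, config.pare_treated)),
         "mirna_hits.tsv", index=False)
    all_sites = [s for lib in sorted(result.cleavage_sites)
                 for s in result.cleavage_sites[lib]]
    save(ec.sites_to_frame(all_sites), "cleavage_sites.tsv", index=False)
    save(ec.groups_to_frame(result.cleavage_groups), "cleavage_groups.tsv", index=False)

    from .motif import write_meme_minimal

    write_meme_minimal(
        [g.motif for g in result.cleavage_groups],
        out_dir / "cleavage_motifs.meme",
        names=[g.group_id for g in result.cleavage_groups],
    )
    result.outputs["cleavage_motifs.meme"] = str(out_dir / "cleavage_motifs.meme")
    with open(out_dir / "cleavage_members.fasta", "w") as fh:
        for g in result.cleavage_groups:
            for s_ in g.members:
                flank = result.member_flanks.get(s_.key, "")
                fh.write(f">{g.group_id}|{s_.transcript_id}|{s_.position}\n{flank}\n")
    result.outputs["cleavage_members.fasta"] = str(out_dir / "cleavage_members.fasta")

    lines = [
        "pare-decay pipeline summary",
        f"genes on both platforms\t{len(result.abundance_table)}",
        f"fraction altered >{config.fold_alteration:g}-fold (D)\t"
        f"{result.fraction_altered_d:.4f}",
    ]
    for t, n in result.type_counts.items():
        lines.append(f"type {t}\t{n}")
    lines.append(f"miRNA target hits\t{len(result.mirna_hits)}")
    for lib in sorted(result.cleavage_sites):
        lines.append(f"prominent sites {lib}\t{len(result.cleavage_sites[lib])}")
    lines.append(f"cleavage groups\t{len(result.cleavage_groups)}")
    for r, f in result.region_overall.items():
        lines.append(f"cleavage fraction {r}\t{f:.4f}")
    path = out_dir / "summary.txt"
    path.write_text("\n".join(lines) + "\n")
    result.outputs["summary.txt"] = str(path)
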
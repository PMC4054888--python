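"""Ground-truth recovery evaluation on simulated degradomes.

These helpers run the standard analysis chain — low-frequency filtering,
population-size normalization, joint abundance table, decay-type
classification, degradome-guided miRNA target scan, and the endonucleolytic
cleavage pipeline — on an in-memory simulation and score the results
against the simulator's planted truth.  They are the package's own
validation surface: every number they return is computed by running the
analysis, never read from the truth directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import abundance as ab
from . import decay_classifier as dc
from . import degradome_io as dio
from . import endo_cleavage as ec
from . import mirna_targets as mt
from .synthetic_data import (
    GroundTruth,
    SimulationConfig,
    simulate_libraries,
    simulate_transcriptome,
)

__all__ = [
    "AnalysisRun",
    "run_standard_analysis",
    "classification_agreement",
    "mirna_recovery",
    "endo_recovery",
]


@dataclass
class AnalysisRun:
    """Everything the standard chain produced on one simulation."""

    annotations: dict
    sequences: dict
    truth: GroundTruth
    records: "object"  # decay records DataFrame
    type_counts: "object"
    mirna_hits: list
    sites: dict[str, list]
    groups: list
    region_overall: dict[str, float] = field(default_factory=dict)


def run_standard_analysis(
    config: SimulationConfig,
    low_frequency_min: float = 5.0,
    fc_threshold: float = 1.5,
    pseudocount: float = 1.0,
    scan_mirnas: bool = True,
    scan_endo: bool = True,
) -> AnalysisRun:
    """Simulate one dataset and run the full analysis chain on it."""
    annotations, sequences = simulate_transcriptome(config)
    pare, rnaseq, truth = simulate_libraries(config, annotations, sequences)

    filtered = {
        lib: dio.filter_low_frequency(m, low_frequency_min) for lib, m in pare.items()
    }
    norm_dc, _ = ab.normalize_library(filtered["DC"], filtered["DW"])
    norm = {"DW": filtered["DW"], "DC": norm_dc}
    rna_treated, _ = ab.normalize_counts(rnaseq["RC"], rnaseq["RW"])
    table = ab.build_abundance_table(
        ab.transcript_abundance(norm["DW"]),
        ab.transcript_abundance(norm["DC"]),
        rnaseq["RW"],
        rna_treated,
        pseudocount=pseudocount,
    )
    records, type_counts = dc.classify_all(table, fc_threshold)

    hits: list = []
    if scan_mirnas and truth.mirna_sequences:
        hits = mt.scan_targets(truth.mirna_sequences, sequences, norm)

    sites: dict[str, list] = {}
    groups: list = []
    region_overall: dict[str, float] = {}
    if scan_endo:
        sites = {
            lib: ec.exclude_mirna_sites(ec.detect_prominent_sites(m), hits)
            for lib, m in norm.items()
        }
        unique: dict = {}
        for lib in ("DW", "DC"):
            for s in sites[lib]:
                unique.setdefault(s.key, s)
        flanks = ec.extract_flanks(unique.values(), sequences)
        groups = ec.discover_motif_groups(flanks)
        groups = ec.condition_specificity(groups, sites["DW"], sites["DC"])
        groups, region_overall = ec.annotate_regions(groups, annotations)

    return AnalysisRun(
        annotations=annotations,
        sequences=sequences,
        truth=truth,
        records=records,
        type_counts=type_counts,
        mirna_hits=hits,
        sites=sites,
        groups=groups,
        region_overall=region_overall,
    )


def classification_agreement(run: AnalysisRun) -> tuple[float, bool]:
    """Label agreement with planted decay types, and exact per-type count match.

    Agreement is computed over the genes in the joint abundance table;
    planted 'null' corresponds to the classifier's UNCLASSIFIED outcome.
    """
    truth_types = {
        t: ("UNCLASSIFIED" if v == "null" else v)
        for t, v in run.truth.decay_type.items()
    }
    records = run.records
    if len(records) == 0:
        return 0.0, False
    agree = float(
        np.mean([records.loc[t, "decay_type"] == truth_types[t] for t in records.index])
    )
    import pandas as pd

    planted_counts = (
        pd.Series([truth_types[t] for t in records.index])
        .value_counts()
        .reindex(list(dc.DECAY_TYPES), fill_value=0)
    )
    counts_match = bool((run.type_counts == planted_counts).all())
    return agree, counts_match


def mirna_recovery(run: AnalysisRun) -> tuple[float, float]:
    """(recall, precision) of planted slicing events at the exact nucleotide."""
    planted = {
        (t.mirna_id, t.transcript_id, t.cleavage_position)
        for t in run.truth.mirna_targets
    }
    found = {
        (h.mirna_id, h.transcript_id, h.cleavage_position) for h in run.mirna_hits
    }
    if not planted:
        return float("nan"), float("nan")
    recall = len(planted & found) / len(planted)
    precision = len(planted & found) / len(found) if found else 0.0
    return recall, precision


def _hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        return max(len(a), len(b))
    return sum(x != y for x, y in zip(a, b))


def endo_recovery(run: AnalysisRun) -> dict:
    """Site- and group-level recovery of planted endonucleolytic cleavages."""
    truth_sites: dict[str, set] = {"DW": set(), "DC": set()}
    for e in run.truth.endo_sites:
        libs = ("DW", "DC") if e.condition == "both" else (e.condition,)
        for lib in libs:
            truth_sites[lib].add((e.transcript_id, e.cut_position))
    detected = {lib: {s.key for s in ss} for lib, ss in run.sites.items()}
    tp = sum(len(detected.get(lib, set()) & truth_sites[lib]) for lib in truth_sites)
    n_true = sum(len(v) for v in truth_sites.values())
    n_det = sum(len(v) for v in detected.values())
    recall = tp / n_true if n_true else float("nan")
    precision = tp / n_det if n_det else float("nan")

    # match each surviving group to the planted motif its members carry
    planted_by_motif: dict[str, dict] = {}
    for e in run.truth.endo_sites:
        d = planted_by_motif.setdefault(
            e.motif_id,
            {"consensus": e.consensus, "condition": e.condition, "sites": set()},
        )
        d["sites"].add((e.transcript_id, e.cut_position))
    group_matches = []
    for g in run.groups:
        member_keys = {s.key for s in g.members}
        best_id, best_overlap = None, 0
        for mid, d in planted_by_motif.items():
            overlap = len(member_keys & d["sites"])
            if overlap > best_overlap:
                best_id, best_overlap = mid, overlap
        if best_id is None:
            group_matches.append(
                {"group": g.group_id, "motif": None, "hamming": None, "label_ok": False}
            )
            continue
        d = planted_by_motif[best_id]
        expected_label = (
            "shared" if d["condition"] == "both" else f"{d['condition']}_only"
        )
        group_matches.append(
            {
                "group": g.group_id,
                "motif": best_id,
                "hamming": _hamming(g.consensus, d["consensus"]),
                "label_ok": g.condition_label == expected_label,
            }
        )
    return {
        "site_recall": recall,
        "site_precision": precision,
        "n_groups": len(run.groups),
        "group_matches": group_matches,
    }
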
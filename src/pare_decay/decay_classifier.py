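"""Decay-type classification from joint uncapped (D) and total (R) changes.

Each gene's response to treatment is summarized by two log2 fold changes:
D (uncapped transcript abundance, from PARE) and R (transcript abundance,
from RNA-Seq).  With an inclusive threshold t (default 1.5 log2 units) each
axis is called up (fc >= t), down (fc <= -t) or unchanged, and the pair of
calls yields one of four decay types:

=====  ==============================  =================================
type   direction pattern               reading
=====  ==============================  =================================
I      D and R change, same way        degradation tracks abundance
II     D changes, R unchanged          decay-buffered steady state
III    D and R change, opposite ways   decay drives the abundance change
IV     D unchanged, R changes          change without a decay signature
=====  ==============================  =================================

Genes with neither axis changed are reported as UNCLASSIFIED.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .degradome_io import TranscriptAnnotation
from .motif import Motif, find_motifs_scan

__all__ = [
    "DECAY_TYPES",
    "DecayRecord",
    "direction",
    "classify",
    "classify_all",
    "sequence_features_by_type",
    "find_utr_motifs",
]

DECAY_TYPES = ("I", "II", "III", "IV", "UNCLASSIFIED")

UP, DOWN, UNCHANGED = "up", "down", "unchanged"


@dataclass(frozen=True)
class DecayRecord:
    transcript_id: str
    log2fc_d: float
    log2fc_r: float
    decay_type: str
    d_direction: str
    r_direction: str


def direction(log2fc: float, threshold: float = 1.5) -> str:
    """Call an axis up/down/unchanged at an inclusive |log2 FC| threshold."""
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    if log2fc >= threshold:
        return UP
    if log2fc <= -threshold:
        return DOWN
    return UNCHANGED


def classify(log2fc_d: float, log2fc_r: float, threshold: float = 1.5) -> str:
    """Assign the decay type from the two fold changes (total function)."""
    d = direction(log2fc_d, threshold)
    r = direction(log2fc_r, threshold)
    if d == UNCHANGED and r == UNCHANGED:
        return "UNCLASSIFIED"
    if d == UNCHANGED:
        return "IV"
    if r == UNCHANGED:
        return "II"
    return "I" if d == r else "III"


def classify_all(
    table: pd.DataFrame, threshold: float = 1.5
) -> tuple[pd.DataFrame, pd.Series]:
    """Classify every row of an abundance table.

    Returns the records (one row per transcript, with directions and type)
    and the per-type counts over all five outcomes.
    """
    if len(table) == 0:
        records = pd.DataFrame(
            columns=["log2fc_d", "log2fc_r", "d_direction", "r_direction", "decay_type"]
        )
        counts = pd.Series(0, index=list(DECAY_TYPES), dtype=int)
        return records, counts
    d = table["log2fc_d"].to_numpy(float)
    r = table["log2fc_r"].to_numpy(float)
    d_dir = np.where(d >= threshold, UP, np.where(d <= -threshold, DOWN, UNCHANGED))
    r_dir = np.where(r >= threshold, UP, np.where(r <= -threshold, DOWN, UNCHANGED))
    d_ch = d_dir != UNCHANGED
    r_ch = r_dir != UNCHANGED
    types = np.where(
        ~d_ch & ~r_ch,
        "UNCLASSIFIED",
        np.where(
            ~d_ch,
            "IV",
            np.where(~r_ch, "II", np.where(d_dir == r_dir, "I", "III")),
        ),
    )
    records = pd.DataFrame(
        {
            "log2fc_d": d,
            "log2fc_r": r,
            "d_direction": d_dir,
            "r_direction": r_dir,
            "decay_type": types,
        },
        index=table.index,
    )
    counts = (
        records["decay_type"].value_counts().reindex(list(DECAY_TYPES), fill_value=0)
    )
    return records, counts


def _gc_fraction(seq: str) -> float:
    if not seq:
        return float("nan")
    return (seq.count("G") + seq.count("C")) / len(seq)


def sequence_features_by_type(
    records: pd.DataFrame,
    annotations: Mapping[str, TranscriptAnnotation],
    sequences: Mapping[str, str],
) -> pd.DataFrame:
    """Per-type summaries of mRNA length, UTR lengths, GC and intron counts."""
    rows = []
    for tid, rec in records.iterrows():
        ann = annotations.get(tid)
        if ann is None:
            continue
        rows.append(
            {
                "decay_type": rec["decay_type"],
                "length": ann.length,
                "utr5_length": ann.utr5_length,
                "utr3_length": ann.utr3_length,
                "gc": _gc_fraction(sequences.get(tid, "")),
                "n_introns": ann.n_introns,
                "intronless": ann.n_introns == 0,
            }
        )
    if not rows:
        return pd.DataFrame()
    df = pd.DataFrame(rows)
    return df.groupby("decay_type").agg(
        n=("length", "size"),
        mean_length=("length", "mean"),
        median_length=("length", "median"),
        mean_utr5=("utr5_length", "mean"),
        mean_utr3=("utr3_length", "mean"),
        mean_gc=("gc", "mean"),
        mean_introns=("n_introns", "mean"),
        fraction_intronless=("intronless", "mean"),
    )


def _region_seq(ann: TranscriptAnnotation, seq: str, region: str) -> str:
    if region == "utr5":
        return seq[: ann.cds_start - 1]
    if region == "utr3":
        return seq[ann.cds_end :]
    raise ValueError("region must be 'utr5' or 'utr3'")


def find_utr_motifs(
    records: pd.DataFrame,
    sequences: Mapping[str, str],
    annotations: Mapping[str, TranscriptAnnotation],
    region: str = "utr5",
    evalue_max: float = 1e-3,
    by_subgroup: bool = False,
    widths: Iterable[int] = range(6, 13),
    min_members: int = 4,
) -> dict[str, list[Motif]]:
    """Search for shared UTR motifs per decay type (or direction subgroup).

    Groups classified transcripts by decay type — or, with ``by_subgroup``,
    by the (D direction, R direction) pair — extracts the requested UTR from
    each, and runs the scanning motif engine.  Only motifs with engine
    E-value below ``evalue_max`` are returned.
    """
    out: dict[str, list[Motif]] = {}
    if len(records) == 0:
        return out
    if by_subgroup:
        keys = records.apply(
            lambda r: f"D{r['d_direction']}_R{r['r_direction']}", axis=1
        )
    else:
        keys = records["decay_type"]
    for key in sorted(keys.unique()):
        tids = records.index[keys == key]
        seqs = []
        for tid in tids:
            ann = annotations.get(tid)
            if ann is None or tid not in sequences:
                continue
            s = _region_seq(ann, sequences[tid], region)
            if s:
                seqs.append(s)
        if not seqs:
            out[key] = []
            continue
        out[key] = find_motifs_scan(
            seqs,
            widths=widths,
            min_members=min_members,
            evalue_max=evalue_max,
        )
    return out
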
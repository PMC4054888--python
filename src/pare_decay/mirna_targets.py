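"""Degradome-supported miRNA target detection and categorization.

Plant miRNA-guided slicing is near-perfectly complementary and cuts the
target between the bases paired to miRNA nucleotides 10 and 11 (counted
from the miRNA 5' end), leaving a 5'-phosphorylated 3' fragment whose first
nucleotide shows up as a PARE signature.  Candidate duplexes are scored with
Allen-style penalties — mismatch 1, G:U wobble 0.5, penalties doubled in the
seed-proximal core (miRNA positions 2-13), gapless — and a hit requires
degradome evidence at the predicted cut in at least one library.

Each supported site gets a degradome category per library (the "Ca" column
convention): 0 unique maximum on the transcript, 1 tied maximum, 2 above
the median of nonzero signatures, 3 at or below the median (but more than
one read), 4 a single read.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .degradome_io import SignatureMatrix
from .decay_classifier import direction
from .abundance import log2_fold_change

__all__ = [
    "MiRNA",
    "TargetHit",
    "align_mirna",
    "scan_targets",
    "categorize_hit",
    "compare_conditions",
]

_ALPHABET = "ACGU"
_INDEX = {c: i for i, c in enumerate(_ALPHABET)}
_COMPLEMENT = {0: 3, 3: 0, 1: 2, 2: 1}  # A-U, C-G
_CORE = (2, 13)  # miRNA positions (1-based, inclusive) with doubled penalties

MISMATCH_PENALTY = 1.0
WOBBLE_PENALTY = 0.5
CORE_WEIGHT = 2.0
SLICE_POSITION = 10  # target base paired to this miRNA position is the cut product's 5' nt


@dataclass(frozen=True)
class MiRNA:
    id: str
    sequence: str  # 5'->3', RNA alphabet

    def __post_init__(self) -> None:
        if not 19 <= len(self.sequence) <= 24:
            raise ValueError(f"{self.id}: miRNA length must be 19-24 nt")
        if not set(self.sequence) <= set(_ALPHABET):
            raise ValueError(f"{self.id}: miRNA sequence must be ACGU")


@dataclass
class TargetHit:
    mirna_id: str
    transcript_id: str
    window_start: int  # 1-based, inclusive
    window_end: int
    score: float
    cleavage_position: int  # 1-based transcript coordinate
    reads: dict[str, float] = field(default_factory=dict)  # per library
    categories: dict[str, int | None] = field(default_factory=dict)


def _encode(seq: str) -> np.ndarray:
    try:
        return np.fromiter((_INDEX[c] for c in seq), dtype=np.int8, count=len(seq))
    except KeyError as exc:
        raise ValueError(f"non-ACGU character in sequence: {exc}") from exc


def _penalty_table(mirna_seq: str) -> np.ndarray:
    """Per-window-position penalty lookup, shape (W, 4).

    ``table[k, t]`` is the penalty when the target window's k-th base
    (0-based, 5'->3') is nucleotide t; window position k pairs with miRNA
    position W-k (1-based from the miRNA 5' end).
    """
    w = len(mirna_seq)
    enc = _encode(mirna_seq)
    table = np.empty((w, 4))
    for k in range(w):
        i = w - k  # paired miRNA position, 1-based
        m = int(enc[i - 1])
        weight = CORE_WEIGHT if _CORE[0] <= i <= _CORE[1] else 1.0
        for t in range(4):
            if t == _COMPLEMENT[m]:
                pen = 0.0
            elif (m, t) in ((2, 3), (3, 2)):  # G:U wobble (G=2, U=3)
                pen = WOBBLE_PENALTY
            else:
                pen = MISMATCH_PENALTY
            table[k, t] = weight * pen
    return table


def align_mirna(mirna: MiRNA | str, window: str) -> float:
    """Penalty score of a gapless miRNA:target-window duplex (lower = better)."""
    seq = mirna.sequence if isinstance(mirna, MiRNA) else mirna
    if len(window) != len(seq):
        raise ValueError("window length must equal miRNA length (gapless mode)")
    table = _penalty_table(seq)
    enc = _encode(window)
    return float(table[np.arange(len(seq)), enc].sum())


def categorize_hit(profile: Mapping[int, float], site: int) -> int:
    """Degradome category (0-4) of a cleavage signature within its transcript."""
    if not profile:
        raise ValueError("empty signature profile")
    count = profile.get(site, 0.0)
    if count <= 0:
        raise ValueError(f"no signature at site {site}")
    nonzero = [c for c in profile.values() if c > 0]
    maximum = max(nonzero)
    if count == maximum:
        return 0 if sum(1 for c in nonzero if c == maximum) == 1 else 1
    if count > statistics.median(nonzero):
        return 2
    if count > 1:
        return 3
    return 4


def scan_targets(
    mirnas: Mapping[str, str] | Sequence[MiRNA],
    transcripts: Mapping[str, str],
    signatures: Mapping[str, SignatureMatrix],
    max_score: float = 4.5,
    min_reads: float = 1.0,
) -> list[TargetHit]:
    """Find degradome-supported miRNA target sites.

    Every gapless window with penalty <= ``max_score`` is a candidate; the
    predicted cleavage position is the transcript base paired to miRNA
    position 10, and the candidate becomes a hit only if at least one PARE
    library carries >= ``min_reads`` at exactly that position.
    """
    if not isinstance(mirnas, Mapping):
        mirnas = {m.id: m.sequence for m in mirnas}
    tables = {mid: _penalty_table(seq) for mid, seq in mirnas.items()}
    hits: list[TargetHit] = []
    encoded = {tid: _encode(seq) for tid, seq in transcripts.items()}
    for mid, seq in mirnas.items():
        w = len(seq)
        table = tables[mid]
        for tid, enc in encoded.items():
            n_win = len(enc) - w + 1
            if n_win <= 0:
                continue
            penalty = np.zeros(n_win)
            for k in range(w):
                penalty += table[k, enc[k : k + n_win]]
            for start0 in np.flatnonzero(penalty <= max_score):
                s = int(start0) + 1  # 1-based window start
                cut = s + w - SLICE_POSITION
                reads = {
                    lib: mat.counts.get(tid, {}).get(cut, 0.0)
                    for lib, mat in signatures.items()
                }
                if not any(c >= min_reads for c in reads.values()):
                    continue
                categories = {
                    lib: (
                        categorize_hit(signatures[lib].counts[tid], cut)
                        if reads[lib] > 0
                        else None
                    )
                    for lib in signatures
                }
                hits.append(
                    TargetHit(
                        mirna_id=mid,
                        transcript_id=tid,
                        window_start=s,
                        window_end=s + w - 1,
                        score=float(penalty[start0]),
                        cleavage_position=cut,
                        reads=reads,
                        categories=categories,
                    )
                )
    return hits


def hits_to_frame(hits: Sequence[TargetHit], libraries: Sequence[str] = ("DW", "DC")) -> pd.DataFrame:
    rows = []
    for h in hits:
        row = {
            "mirna": h.mirna_id,
            "transcript": h.transcript_id,
            "window_start": h.window_start,
            "window_end": h.window_end,
            "score": h.score,
            "cleavage_pos": h.cleavage_position,
        }
        for lib in libraries:
            row[f"reads_{lib}"] = h.reads.get(lib, 0.0)
            row[f"cat_{lib}"] = h.categories.get(lib)
        rows.append(row)
    return pd.DataFrame(rows)


def compare_conditions(
    hits: Sequence[TargetHit],
    abundance_table: pd.DataFrame,
    mirna_log2fc: Mapping[str, float],
    control_library: str = "DW",
    treated_library: str = "DC",
    threshold: float = 1.5,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Direction arrows for miRNA, target mRNA and degradation product.

    The degradation-product (De) arrow is the thresholded log2 fold change
    of the normalized PARE count at the cleavage site, treated over control;
    the mRNA arrow reuses the R fold change from the abundance table; the
    miRNA arrow comes from supplied expression fold changes.  All three use
    the same inclusive +-threshold convention.
    """
    rows = []
    for h in hits:
        mirna_fc = mirna_log2fc.get(h.mirna_id, 0.0)
        if h.transcript_id in abundance_table.index:
            mrna_dir = direction(
                float(abundance_table.loc[h.transcript_id, "log2fc_r"]), threshold
            )
        else:
            mrna_dir = "unchanged"
        de_fc = log2_fold_change(
            h.reads.get(treated_library, 0.0),
            h.reads.get(control_library, 0.0),
            pseudocount,
        )
        rows.append(
            {
                "mirna": h.mirna_id,
                "transcript": h.transcript_id,
                "cleavage_pos": h.cleavage_position,
                "mirna_change": direction(mirna_fc, threshold),
                "mrna_change": mrna_dir,
                "de_change": direction(de_fc, threshold),
            }
        )
    return pd.DataFrame(rows)
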
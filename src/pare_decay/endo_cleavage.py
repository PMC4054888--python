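"""Detection and grouping of prominent endonucleolytic cleavage sites.

Some transcripts carry a single dominant PARE spike not explained by any
miRNA: an endonucleolytic cut.  Prominence is operationalized as a triple
rule on the (filtered, normalized) signature matrix — an absolute count
floor, a minimum fraction of the transcript's total degradome signal, and a
minimum ratio to the runner-up position — with at most one site called per
transcript (exact ties for the maximum disqualify it).  Sites within a
small window of a miRNA-explained cleavage are excluded, fixed-length
flanks anchored at the cut are extracted, and shared motifs whose 5' end
coincides with the cut are discovered with the anchored motif engine.
Groups smaller than the minimum size are dropped, the survivors are
labelled by condition specificity (control-only / treated-only / shared),
and member sites are localized to 5'UTR / CDS / 3'UTR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .degradome_io import SignatureMatrix, TranscriptAnnotation
from .mirna_targets import TargetHit
from .motif import Motif, find_anchored_motifs

__all__ = [
    "CleavageSite",
    "AnchoredFlank",
    "CleavageGroup",
    "detect_prominent_sites",
    "exclude_mirna_sites",
    "extract_flanks",
    "discover_motif_groups",
    "condition_specificity",
    "annotate_regions",
]

REGIONS = ("utr5", "cds", "utr3")


@dataclass(frozen=True)
class CleavageSite:
    transcript_id: str
    position: int  # 1-based; 5' nt of the 3' cleavage fragment
    count: float
    transcript_total: float
    prominence_ratio: float  # count / second-highest positional count
    fraction_of_total: float
    library_id: str

    @property
    def key(self) -> tuple[str, int]:
        return (self.transcript_id, self.position)


@dataclass(frozen=True)
class AnchoredFlank:
    site: CleavageSite
    sequence: str  # fixed length; cut falls 5' of index `anchor_offset`
    anchor_offset: int


@dataclass
class CleavageGroup:
    group_id: str
    motif: Motif
    members: list[CleavageSite]
    condition_label: str | None = None  # control_only / treated_only / shared
    region_distribution: dict[str, float] = field(default_factory=dict)

    @property
    def consensus(self) -> str:
        return self.motif.consensus


def detect_prominent_sites(
    matrix: SignatureMatrix,
    min_count: float = 10.0,
    min_fraction: float = 0.5,
    min_ratio: float = 5.0,
) -> list[CleavageSite]:
    """Call at most one prominent cleavage site per transcript.

    A position qualifies iff its count is >= ``min_count``, carries at least
    ``min_fraction`` of the transcript's total signature mass, and is at
    least ``min_ratio`` times the second-highest position.  A transcript
    whose maximum is tied yields no site.
    """
    sites: list[CleavageSite] = []
    for tid, per_pos in matrix.counts.items():
        if not per_pos:
            continue
        counts = sorted(per_pos.values(), reverse=True)
        top = counts[0]
        if top <= 0:
            continue
        if len(counts) > 1 and counts[1] == top:
            continue  # tied maximum: no single prominent site
        runner_up = counts[1] if len(counts) > 1 else 0.0
        total = float(sum(counts))
        fraction = top / total
        ratio = top / runner_up if runner_up > 0 else float("inf")
        if top >= min_count and fraction >= min_fraction and ratio >= min_ratio:
            position = next(p for p, c in per_pos.items() if c == top)
            sites.append(
                CleavageSite(
                    transcript_id=tid,
                    position=position,
                    count=top,
                    transcript_total=total,
                    prominence_ratio=ratio,
                    fraction_of_total=fraction,
                    library_id=matrix.library_id,
                )
            )
    return sites


def exclude_mirna_sites(
    sites: Iterable[CleavageSite],
    hits: Iterable[TargetHit],
    window_nt: int = 2,
) -> list[CleavageSite]:
    """Drop sites within ``window_nt`` of any miRNA cleavage on that transcript."""
    by_transcript: dict[str, list[int]] = {}
    for h in hits:
        by_transcript.setdefault(h.transcript_id, []).append(h.cleavage_position)
    return [
        s
        for s in sites
        if not any(
            abs(s.position - p) <= window_nt
            for p in by_transcript.get(s.transcript_id, ())
        )
    ]


def extract_flanks(
    sites: Iterable[CleavageSite],
    sequences: Mapping[str, str],
    upstream: int = 10,
    downstream: int = 15,
) -> list[AnchoredFlank]:
    """Fixed-length windows around each cut, anchored so the motif can start
    at the cut.

    The window covers transcript positions ``[pos-upstream, pos+downstream]``
    inclusive; ``anchor_offset = upstream`` is the 0-based index of the cut
    position itself (the first nucleotide 3' of the cut).  Sites too close
    to a transcript end are dropped with a warning.
    """
    flanks: list[AnchoredFlank] = []
    dropped = 0
    for s in sites:
        seq = sequences.get(s.transcript_id)
        if seq is None:
            dropped += 1
            continue
        lo = s.position - upstream  # 1-based
        hi = s.position + downstream
        if lo < 1 or hi > len(seq):
            dropped += 1
            continue
        flanks.append(
            AnchoredFlank(
                site=s,
                sequence=seq[lo - 1 : hi],
                anchor_offset=upstream,
            )
        )
    if dropped:
        warnings.warn(
            f"{dropped} cleavage site(s) too close to a transcript end; dropped",
            stacklevel=2,
        )
    return flanks


def discover_motif_groups(
    flanks: Sequence[AnchoredFlank],
    min_group_size: int = 6,
    evalue_max: float = 1e-3,
    widths: Iterable[int] = range(6, 13),
) -> list[CleavageGroup]:
    """Group cleavage sites by a shared motif anchored at the cut.

    Fewer flanks than ``min_group_size`` yields an empty result.  Each flank
    joins at most one group; groups failing the size or E-value gate are not
    reported.
    """
    if len(flanks) < min_group_size:
        return []
    anchor = flanks[0].anchor_offset
    if any(f.anchor_offset != anchor for f in flanks):
        raise ValueError("all flanks must share one anchor offset")
    motifs = find_anchored_motifs(
        [f.sequence for f in flanks],
        anchor_offset=anchor,
        widths=widths,
        min_members=min_group_size,
        evalue_max=evalue_max,
    )
    return [
        CleavageGroup(
            group_id=f"EG{i+1}",
            motif=m,
            members=[flanks[j].site for j in m.members],
        )
        for i, m in enumerate(motifs)
    ]


def condition_specificity(
    groups: Iterable[CleavageGroup],
    sites_control: Iterable[CleavageSite],
    sites_treated: Iterable[CleavageSite],
    control_label: str = "DW_only",
    treated_label: str = "DC_only",
) -> list[CleavageGroup]:
    """Label each group by the condition(s) its member sites were detected in."""
    control_keys = {s.key for s in sites_control}
    treated_keys = {s.key for s in sites_treated}
    out = []
    for g in groups:
        keys = {s.key for s in g.members}
        in_control = keys & control_keys
        in_treated = keys & treated_keys
        if in_control and not in_treated:
            g.condition_label = control_label
        elif in_treated and not in_control:
            g.condition_label = treated_label
        else:
            g.condition_label = "shared"
        out.append(g)
    return out


def annotate_regions(
    groups: Iterable[CleavageGroup],
    annotations: Mapping[str, TranscriptAnnotation],
) -> tuple[list[CleavageGroup], dict[str, float]]:
    """Region distribution (5'UTR / CDS / 3'UTR) per group and overall."""
    overall = {r: 0 for r in REGIONS}
    n_total = 0
    out = []
    for g in groups:
        counts = {r: 0 for r in REGIONS}
        for s in g.members:
            ann = annotations.get(s.transcript_id)
            if ann is None:
                raise KeyError(f"no annotation for {s.transcript_id}")
            region = ann.region_of(s.position)
            counts[region] += 1
            overall[region] += 1
            n_total += 1
        n = len(g.members)
        g.region_distribution = {r: counts[r] / n for r in REGIONS} if n else {}
        out.append(g)
    overall_frac = (
        {r: overall[r] / n_total for r in REGIONS} if n_total else {r: 0.0 for r in REGIONS}
    )
    return out, overall_frac


def sites_to_frame(sites: Sequence[CleavageSite]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "library": s.library_id,
                "transcript": s.transcript_id,
                "position": s.position,
                "count": s.count,
                "fraction": s.fraction_of_total,
                "ratio": s.prominence_ratio,
            }
            for s in sites
        ]
    )


def groups_to_frame(groups: Sequence[CleavageGroup]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "group": g.group_id,
                "consensus": g.consensus,
                "n_members": len(g.members),
                "condition": g.condition_label,
                "evalue": g.motif.evalue,
                **{f"frac_{r}": g.region_distribution.get(r, np.nan) for r in REGIONS},
            }
            for g in groups
        ]
    )
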
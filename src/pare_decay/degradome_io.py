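"""Input/output and read-level processing for PARE degradome data.

A PARE library is held as a :class:`SignatureMatrix`: a sparse, per-library
map ``transcript -> (1-based position -> count)`` where the position is the
transcript coordinate of the 5'-phosphorylated first nucleotide of a 20-nt
degradome tag.  Counts may be fractional: tags mapping to several positions
are divided equally among them, and library normalization rescales counts.

All tabular formats are plain UTF-8, tab-delimited, with a header line:

* annotation TSV: ``transcript_id  length  cds_start  cds_end  n_introns``
  (1-based, inclusive CDS coordinates in transcript space)
* signature TSV:  ``library  transcript_id  position  count``
* counts TSV:     ``library  transcript_id  count``
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO

__all__ = [
    "TranscriptAnnotation",
    "SignatureMatrix",
    "TagPlacement",
    "read_transcripts",
    "write_transcripts",
    "read_annotation",
    "write_annotation",
    "read_signatures",
    "write_signatures",
    "read_counts",
    "write_counts",
    "read_tag_placements",
    "summarize_tags",
    "filter_low_frequency",
    "filter_blocklist",
]

ANNOTATION_COLUMNS = ["transcript_id", "length", "cds_start", "cds_end", "n_introns"]
SIGNATURE_COLUMNS = ["library", "transcript_id", "position", "count"]
COUNTS_COLUMNS = ["library", "transcript_id", "count"]


@dataclass(frozen=True)
class TranscriptAnnotation:
    """Transcript-space annotation of one mRNA model.

    Coordinates are 1-based and inclusive; the 5' UTR is ``[1, cds_start-1]``
    and the 3' UTR is ``[cds_end+1, length]``.
    """

    transcript_id: str
    length: int
    cds_start: int
    cds_end: int
    n_introns: int
    gene_id: str | None = None

    def __post_init__(self) -> None:
        if not (1 <= self.cds_start <= self.cds_end <= self.length):
            raise ValueError(
                f"{self.transcript_id}: CDS [{self.cds_start}, {self.cds_end}] "
                f"must satisfy 1 <= cds_start <= cds_end <= length ({self.length})"
            )
        if self.n_introns < 0:
            raise ValueError(f"{self.transcript_id}: n_introns must be >= 0")

    @property
    def utr5_length(self) -> int:
        return self.cds_start - 1

    @property
    def utr3_length(self) -> int:
        return self.length - self.cds_end

    def region_of(self, position: int) -> str:
        """Classify a transcript position as ``utr5`` / ``cds`` / ``utr3``.

        CDS boundaries are inclusive: a cut at ``cds_start`` or ``cds_end``
        is a CDS cut.
        """
        if not 1 <= position <= self.length:
            raise ValueError(
                f"position {position} outside [1, {self.length}] on {self.transcript_id}"
            )
        if position < self.cds_start:
            return "utr5"
        if position <= self.cds_end:
            return "cds"
        return "utr3"


@dataclass
class SignatureMatrix:
    """Per-library sparse matrix of PARE signature abundances."""

    library_id: str
    counts: dict[str, dict[int, float]] = field(default_factory=dict)

    @property
    def total_mapped(self) -> float:
        return float(
            sum(c for per_pos in self.counts.values() for c in per_pos.values())
        )

    def transcript_total(self, transcript_id: str) -> float:
        return float(sum(self.counts.get(transcript_id, {}).values()))

    def transcript_totals(self) -> dict[str, float]:
        return {tid: float(sum(p.values())) for tid, p in self.counts.items()}

    def add(self, transcript_id: str, position: int, count: float) -> None:
        if count < 0:
            raise ValueError("signature counts must be non-negative")
        per_pos = self.counts.setdefault(transcript_id, {})
        per_pos[position] = per_pos.get(position, 0.0) + float(count)

    def scaled(self, factor: float) -> "SignatureMatrix":
        out = SignatureMatrix(self.library_id)
        out.counts = {
            tid: {pos: c * factor for pos, c in per_pos.items()}
            for tid, per_pos in self.counts.items()
        }
        return out

    def n_entries(self) -> int:
        return sum(len(p) for p in self.counts.values())


@dataclass(frozen=True)
class TagPlacement:
    """One unique degradome tag and everywhere it maps."""

    tag_id: str
    placements: tuple[tuple[str, int], ...]
    read_count: float

    def __post_init__(self) -> None:
        if len(self.placements) < 1:
            raise ValueError(f"tag {self.tag_id}: at least one placement required")
        if self.read_count < 0:
            raise ValueError(f"tag {self.tag_id}: read_count must be >= 0")


# ---------------------------------------------------------------------------
# sequences


def _normalize_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def read_transcripts(path: str | Path) -> dict[str, str]:
    """Read a transcript (or miRNA) FASTA into ``{id: RNA sequence}``.

    Sequences are uppercased and DNA ``T`` is normalized to ``U``.  Duplicate
    ids and empty records are errors.
    """
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in sequences:
            raise ValueError(f"duplicate FASTA id: {record.id}")
        seq = _normalize_rna(str(record.seq))
        if not seq:
            raise ValueError(f"empty FASTA record: {record.id}")
        sequences[record.id] = seq
    return sequences


def write_transcripts(sequences: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for tid, seq in sequences.items():
            fh.write(f">{tid}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


# ---------------------------------------------------------------------------
# annotation


def _annotation_from_frame(df: pd.DataFrame) -> dict[str, TranscriptAnnotation]:
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"annotation table missing column(s): {', '.join(missing)}")
    out: dict[str, TranscriptAnnotation] = {}
    for row in df.itertuples(index=False):
        ann = TranscriptAnnotation(
            transcript_id=str(row.transcript_id),
            length=int(row.length),
            cds_start=int(row.cds_start),
            cds_end=int(row.cds_end),
            n_introns=int(row.n_introns),
            gene_id=str(row.gene_id) if "gene_id" in df.columns else None,
        )
        if ann.transcript_id in out:
            raise ValueError(f"duplicate transcript_id: {ann.transcript_id}")
        out[ann.transcript_id] = ann
    return out


def _read_annotation_gff3(path: Path) -> dict[str, TranscriptAnnotation]:
    """Project genome-space mRNA/exon/CDS features to transcript coordinates.

    Requires exon features for every mRNA; intron count is ``n_exons - 1``.
    Only forward projection along the mRNA's own exon chain is performed —
    genome alignment itself is out of scope.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    out: dict[str, TranscriptAnnotation] = {}
    for mrna in db.features_of_type("mRNA"):
        exons = sorted(db.children(mrna, featuretype="exon"), key=lambda f: f.start)
        cds = sorted(db.children(mrna, featuretype="CDS"), key=lambda f: f.start)
        if not exons:
            raise ValueError(
                f"GFF3 mRNA {mrna.id} has no exon features; transcript-space "
                "projection impossible — provide a TSV annotation instead"
            )
        if not cds:
            raise ValueError(f"GFF3 mRNA {mrna.id} has no CDS features")
        length = sum(e.end - e.start + 1 for e in exons)

        def genome_to_transcript(gpos: int) -> int:
            offset = 0
            if mrna.strand == "-":
                for e in sorted(exons, key=lambda f: -f.end):
                    if e.start <= gpos <= e.end:
                        return offset + (e.end - gpos) + 1
                    offset += e.end - e.start + 1
            else:
                for e in exons:
                    if e.start <= gpos <= e.end:
                        return offset + (gpos - e.start) + 1
                    offset += e.end - e.start + 1
            raise ValueError(f"CDS position {gpos} not inside exons of {mrna.id}")

        cds_g_start, cds_g_end = cds[0].start, cds[-1].end
        if mrna.strand == "-":
            t1 = genome_to_transcript(cds_g_end)
            t2 = genome_to_transcript(cds_g_start)
        else:
            t1 = genome_to_transcript(cds_g_start)
            t2 = genome_to_transcript(cds_g_end)
        gene = mrna.attributes.get("Parent", [None])[0]
        out[mrna.id] = TranscriptAnnotation(
            transcript_id=mrna.id,
            length=length,
            cds_start=min(t1, t2),
            cds_end=max(t1, t2),
            n_introns=len(exons) - 1,
            gene_id=gene,
        )
    return out


def read_annotation(path: str | Path) -> dict[str, TranscriptAnnotation]:
    """Read transcript annotation from TSV, or from GFF3 (.gff/.gff3)."""
    path = Path(path)
    if path.suffix.lower() in {".gff", ".gff3"}:
        return _read_annotation_gff3(path)
    df = pd.read_csv(path, sep="\t")
    return _annotation_from_frame(df)


def write_annotation(
    annotations: Mapping[str, TranscriptAnnotation], path: str | Path
) -> None:
    rows = [
        (a.transcript_id, a.length, a.cds_start, a.cds_end, a.n_introns)
        for a in annotations.values()
    ]
    pd.DataFrame(rows, columns=ANNOTATION_COLUMNS).to_csv(path, sep="\t", index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# signature / counts tables


def read_signatures(path: str | Path) -> dict[str, SignatureMatrix]:
    """Read a signature TSV into one :class:`SignatureMatrix` per library."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = [c for c in SIGNATURE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"signature table missing column(s): {', '.join(missing)}")
    out: dict[str, SignatureMatrix] = {}
    for row in df.itertuples(index=False):
        lib = out.setdefault(str(row.library), SignatureMatrix(str(row.library)))
        lib.add(str(row.transcript_id), int(row.position), float(row.count))
    return out


def write_signatures(
    matrices: Iterable[SignatureMatrix], path: str | Path
) -> None:
    rows = []
    for m in matrices:
        for tid in sorted(m.counts):
            for pos in sorted(m.counts[tid]):
                rows.append((m.library_id, tid, pos, m.counts[tid][pos]))
    pd.DataFrame(rows, columns=SIGNATURE_COLUMNS).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_counts(path: str | Path) -> dict[str, dict[str, float]]:
    """Read a per-transcript counts TSV into ``{library: {transcript: count}}``."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = [c for c in COUNTS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"counts table missing column(s): {', '.join(missing)}")
    out: dict[str, dict[str, float]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(str(row.library), {})[str(row.transcript_id)] = float(row.count)
    return out


def write_counts(counts: Mapping[str, Mapping[str, float]], path: str | Path) -> None:
    rows = [
        (lib, tid, c)
        for lib, per_t in counts.items()
        for tid, c in sorted(per_t.items())
    ]
    pd.DataFrame(rows, columns=COUNTS_COLUMNS).to_csv(path, sep="\t", index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# read-level processing


def read_tag_placements(path: str | Path) -> list[TagPlacement]:
    """Read raw tag placements from TSV.

    Columns ``tag_id  transcript_id  position  read_count``; a multimapped
    tag occupies one row per placement (read_count repeated identically).
    """
    df = pd.read_csv(path, sep="\t")
    needed = ["tag_id", "transcript_id", "position", "read_count"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(f"placement table missing column(s): {', '.join(missing)}")
    out = []
    for tag_id, group in df.groupby("tag_id", sort=True):
        counts = set(group["read_count"])
        if len(counts) > 1:
            raise ValueError(f"tag {tag_id}: inconsistent read_count across placements")
        out.append(
            TagPlacement(
                tag_id=str(tag_id),
                placements=tuple(
                    (str(r.transcript_id), int(r.position))
                    for r in group.itertuples(index=False)
                ),
                read_count=float(counts.pop()),
            )
        )
    return out


def summarize_tags(
    placements: Iterable[TagPlacement],
    library_id: str,
    known_transcripts: Iterable[str] | None = None,
) -> SignatureMatrix:
    """Summarize raw tag placements into a signature matrix.

    A tag with *k* placements contributes ``read_count / k`` at each placed
    position, so total mapped mass equals the sum of raw read counts
    regardless of mapping multiplicity.
    """
    known = set(known_transcripts) if known_transcripts is not None else None
    matrix = SignatureMatrix(library_id)
    for tag in placements:
        share = tag.read_count / len(tag.placements)
        for tid, pos in tag.placements:
            if known is not None and tid not in known:
                raise ValueError(
                    f"tag {tag.tag_id} placed on unknown transcript {tid}"
                )
            matrix.add(tid, pos, share)
    return matrix


def filter_low_frequency(
    matrix: SignatureMatrix, min_count: float = 5
) -> SignatureMatrix:
    """Drop low-frequency signatures: entries with count <= ``min_count``.

    The default reproduces the standard degradome practice of omitting reads
    with frequency <= 5 before any abundance comparison.
    """
    if min_count < 0:
        raise ValueError("min_count must be >= 0")
    out = SignatureMatrix(matrix.library_id)
    for tid, per_pos in matrix.counts.items():
        kept = {pos: c for pos, c in per_pos.items() if c > min_count}
        if kept:
            out.counts[tid] = kept
    return out


def filter_blocklist(
    matrix: SignatureMatrix, blocklist: Iterable[str]
) -> SignatureMatrix:
    """Remove transcripts on a blocklist (rRNA/tRNA/snRNA/snoRNA/repeat ids)."""
    block = set(blocklist)
    out = SignatureMatrix(matrix.library_id)
    out.counts = {
        tid: dict(per_pos)
        for tid, per_pos in matrix.counts.items()
        if tid not in block
    }
    return out
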
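"""Two-condition PARE / RNA-Seq simulator with planted ground truth.

The generator emulates the data shape of a cold-stress degradome study: two
PARE libraries (DW = control, DC = treated) holding per-position 5'-tag
counts, two RNA-Seq libraries (RW, RC) holding per-transcript counts, a
random transcriptome with UTR/CDS structure, and three kinds of planted
structure for downstream recovery testing:

* **decay types** — each transcript gets one of {I, II, III, IV, null};
  the type dictates which of the uncapped (D) and total (R) abundances
  change between conditions and whether they move together or apart, with
  a planted |log2 FC| magnitude and a random shared/opposed sign.
* **miRNA slicing** — perfectly complementary target windows written into
  CDS regions; a fraction ``peak_fraction`` of the transcript's PARE reads
  is placed at the base paired to miRNA position 10.
* **endonucleolytic motifs** — a consensus written into the sequence with
  the cut at the motif's 5'-most base, condition-specific or shared.

Counts are negative binomial around the condition means (``dispersion`` is
the NB overdispersion alpha: variance = mu + alpha*mu^2); ``dispersion = 0``
is the noiseless limit in which totals equal their means exactly (kept as
floats, so planted fold changes are exact on raw ratios).  Non-peak reads
scatter over a small set of positions with 5'-biased, rank-geometric
weights — enough positions to look like background, never enough mass at
one position to fake a prominent cleavage.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .degradome_io import (
    SignatureMatrix,
    TranscriptAnnotation,
    write_annotation,
    write_counts,
    write_signatures,
    write_transcripts,
)

__all__ = [
    "EndoMotifSpec",
    "SimulationConfig",
    "PlantedTarget",
    "PlantedEndoSite",
    "GroundTruth",
    "simulate_transcriptome",
    "simulate_libraries",
    "write_fixture",
]

_NT = np.frombuffer(b"ACGU", dtype=np.uint8)
_RNA_COMPLEMENT = str.maketrans("ACGU", "UGCA")

DECAY_TYPE_KEYS = ("I", "II", "III", "IV", "null")
# axis multipliers (d, r) relative to the drawn sign: same / one / opposite / other
_TYPE_AXES = {"I": (1, 1), "II": (1, 0), "III": (1, -1), "IV": (0, 1), "null": (0, 0)}

PARE_LIBRARIES = ("DW", "DC")
RNA_LIBRARIES = ("RW", "RC")

_CLASSIFICATION_THRESHOLD = 1.5  # inclusive |log2 FC| call used downstream


@dataclass(frozen=True)
class EndoMotifSpec:
    """One planted endonuclease motif: consensus, group size, condition."""

    consensus: str
    group_size: int
    condition: str  # "DW", "DC" or "both"

    def __post_init__(self) -> None:
        if not 6 <= len(self.consensus) <= 12:
            raise ValueError("endo_motifs: consensus width must be 6-12 nt")
        if set(self.consensus) - set("ACGU"):
            raise ValueError("endo_motifs: consensus must be ACGU")
        if self.group_size < 1:
            raise ValueError("endo_motifs: group_size must be >= 1")
        if self.condition not in ("DW", "DC", "both"):
            raise ValueError("endo_motifs: condition must be DW, DC or both")


@dataclass
class SimulationConfig:
    n_transcripts: int = 1000
    length_range: tuple[int, int] = (600, 2000)
    utr5_frac: float = 0.15
    utr3_frac: float = 0.25
    type_mixture: dict[str, float] = field(
        default_factory=lambda: {"I": 0.2, "II": 0.35, "III": 0.15, "IV": 0.2, "null": 0.1}
    )
    planted_log2fc: float = 2.5
    base_expression: float = 200.0
    base_uncapped: float = 200.0
    dispersion: float = 0.05
    n_mirnas: int = 5
    mirna_length: int = 21
    n_mirna_targets: int = 0
    endo_motifs: list[EndoMotifSpec] = field(default_factory=list)
    peak_fraction: float = 0.9
    background_positions: int = 20
    background_decay_rate: float = 0.15
    mean_introns: float = 3.0
    library_scale: dict[str, float] = field(
        default_factory=lambda: {"DW": 1.0, "DC": 1.0, "RW": 1.0, "RC": 1.0}
    )
    seed: int = 0

    def validate(self) -> None:
        if self.n_transcripts < 0:
            raise ValueError("invalid config field n_transcripts: must be >= 0")
        lo, hi = self.length_range
        if not (0 < lo <= hi):
            raise ValueError("invalid config field length_range: need 0 < min <= max")
        if not (0 <= self.utr5_frac and 0 <= self.utr3_frac):
            raise ValueError("invalid config field utr5_frac/utr3_frac: must be >= 0")
        if self.utr5_frac + self.utr3_frac >= 1:
            raise ValueError("invalid config field utr5_frac+utr3_frac: must sum to < 1")
        if set(self.type_mixture) != set(DECAY_TYPE_KEYS):
            raise ValueError(
                "invalid config field type_mixture: keys must be I, II, III, IV, null"
            )
        if any(v < 0 for v in self.type_mixture.values()) or abs(
            sum(self.type_mixture.values()) - 1.0
        ) > 1e-9:
            raise ValueError(
                "invalid config field type_mixture: proportions must be >= 0 and sum to 1"
            )
        if self.planted_log2fc <= _CLASSIFICATION_THRESHOLD:
            raise ValueError(
                "invalid config field planted_log2fc: must exceed the "
                f"classification threshold ({_CLASSIFICATION_THRESHOLD})"
            )
        for name in ("base_expression", "base_uncapped", "dispersion"):
            if getattr(self, name) < 0:
                raise ValueError(f"invalid config field {name}: must be >= 0")
        if not 19 <= self.mirna_length <= 24:
            raise ValueError("invalid config field mirna_length: must be 19-24")
        if self.n_mirnas < 0 or self.n_mirna_targets < 0:
            raise ValueError("invalid config field n_mirnas/n_mirna_targets: must be >= 0")
        if self.n_mirna_targets > 0 and self.n_mirnas == 0:
            raise ValueError("invalid config field n_mirnas: targets planted but no miRNAs")
        if not 0 <= self.peak_fraction <= 1:
            raise ValueError("invalid config field peak_fraction: must be in [0, 1]")
        if not 0 < self.background_decay_rate < 1:
            raise ValueError("invalid config field background_decay_rate: must be in (0,1)")
        if self.background_positions < 1:
            raise ValueError("invalid config field background_positions: must be >= 1")


@dataclass(frozen=True)
class PlantedTarget:
    mirna_id: str
    transcript_id: str
    window_start: int  # 1-based
    cleavage_position: int


@dataclass(frozen=True)
class PlantedEndoSite:
    motif_id: str
    transcript_id: str
    cut_position: int  # 5'-most base of the motif occurrence
    condition: str
    consensus: str


@dataclass
class GroundTruth:
    """Everything the simulator planted, for recovery testing."""

    decay_type: dict[str, str] = field(default_factory=dict)
    log2fc_d: dict[str, float] = field(default_factory=dict)
    log2fc_r: dict[str, float] = field(default_factory=dict)
    mirna_targets: list[PlantedTarget] = field(default_factory=list)
    endo_sites: list[PlantedEndoSite] = field(default_factory=list)
    library_scale: dict[str, float] = field(default_factory=dict)
    mirna_sequences: dict[str, str] = field(default_factory=dict)
    mirna_log2fc: dict[str, float] = field(default_factory=dict)


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return _NT[rng.integers(0, 4, size=length)].tobytes().decode("ascii")


def _balanced_up_counts(n_by_type: Mapping[str, int], fc: float) -> dict[str, int]:
    """How many genes of each changed type should go *up*.

    Population-size normalization only preserves planted per-gene fold
    changes when the total mass gained by up-genes matches the mass lost by
    down-genes, on each axis.  An up gene adds ``a = 2^fc - 1`` base units,
    a down gene removes ``d = 1 - 2^-fc``; balance therefore needs a small
    up fraction ``d / (a + d)`` of changed mass on each axis.  Type I moves
    D and R together and type III moves them apart, so the axes are coupled;
    a search over the type-I split finds a feasible allocation (or the
    least-imbalanced one when the mixture makes exact balance impossible).
    """
    a = 2.0**fc - 1.0
    d = 1.0 - 2.0 ** (-fc)
    p = d / (a + d)
    n1, n2, n3, n4 = (n_by_type.get(t, 0) for t in ("I", "II", "III", "IV"))
    target_d = p * (n1 + n2 + n3)  # D-axis up count
    target_r = p * (n1 + n3 + n4)  # R-axis up count
    best: tuple[float, dict[str, int]] | None = None
    for k1 in range(n1 + 1):
        # k3 counts type-III genes with D up (hence R down)
        lo = max(0.0, target_d - k1 - n2, n3 + k1 - target_r)
        hi = min(float(n3), target_d - k1, n4 + n3 + k1 - target_r)
        k3 = int(round(min(max((lo + hi) / 2.0, 0.0), n3)))
        k2 = int(round(min(max(target_d - k1 - k3, 0.0), n2)))
        k4 = int(round(min(max(target_r - k1 - n3 + k3, 0.0), n4)))
        viol = abs((k1 + k2 + k3) - target_d) + abs((k1 + n3 - k3 + k4) - target_r)
        if best is None or viol < best[0]:
            best = (viol, {"I": k1, "II": k2, "III": k3, "IV": k4})
        if viol < 1.0:
            break
    assert best is not None
    return best[1]


def simulate_transcriptome(
    config: SimulationConfig,
) -> tuple[dict[str, TranscriptAnnotation], dict[str, str]]:
    """Draw a random annotated transcriptome.

    UTR/CDS boundaries follow the configured fractions of each transcript's
    length; intron counts are Poisson with the configured mean; sequences
    are uniform random RNA (planted occurrences are written later, by
    :func:`simulate_libraries`).
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 0])
    annotations: dict[str, TranscriptAnnotation] = {}
    sequences: dict[str, str] = {}
    lo, hi = config.length_range
    width = len(str(max(config.n_transcripts, 1)))
    for i in range(config.n_transcripts):
        tid = f"t{i + 1:0{width}d}"
        length = int(rng.integers(lo, hi + 1))
        cds_start = int(round(config.utr5_frac * length)) + 1
        cds_end = length - int(round(config.utr3_frac * length))
        annotations[tid] = TranscriptAnnotation(
            transcript_id=tid,
            length=length,
            cds_start=cds_start,
            cds_end=cds_end,
            n_introns=int(rng.poisson(config.mean_introns)),
        )
        sequences[tid] = _random_sequence(rng, length)
    return annotations, sequences


def _draw_count(rng: np.random.Generator, mean: float, dispersion: float) -> float:
    if mean <= 0:
        return 0.0
    if dispersion == 0:
        return float(mean)  # noiseless limit: exact expectation
    n = 1.0 / dispersion
    return float(rng.negative_binomial(n, n / (n + mean)))


def _background_positions(
    rng: np.random.Generator, length: int, n_positions: int, exclude: int | None
) -> np.ndarray:
    candidates = np.arange(1, length + 1)
    if exclude is not None:
        candidates = candidates[candidates != exclude]
    n = min(n_positions, len(candidates))
    pos = rng.choice(candidates, size=n, replace=False)
    return np.sort(pos)


def _scatter(
    matrix: SignatureMatrix,
    rng: np.random.Generator,
    tid: str,
    length: int,
    total: float,
    peak_position: int | None,
    peak_fraction: float,
    n_bg: int,
    decay_rate: float,
) -> None:
    """Place a transcript's PARE mass: optional peak plus 5'-biased background."""
    if total <= 0:
        return
    peak = 0.0
    if peak_position is not None and peak_fraction > 0:
        peak = peak_fraction * total
        matrix.add(tid, peak_position, peak)
    remainder = total - peak
    if remainder <= 0:
        return
    positions = _background_positions(rng, length, n_bg, peak_position)
    if len(positions) == 0:  # degenerate single-base transcript
        matrix.add(tid, peak_position if peak_position is not None else 1, remainder)
        return
    weights = (1.0 - decay_rate) ** np.arange(len(positions))
    weights /= weights.sum()
    for pos, w in zip(positions, weights):
        matrix.add(tid, int(pos), remainder * float(w))


def simulate_libraries(
    config: SimulationConfig,
    annotations: Mapping[str, TranscriptAnnotation],
    sequences: dict[str, str],
) -> tuple[dict[str, SignatureMatrix], dict[str, dict[str, float]], GroundTruth]:
    """Draw the four libraries and plant all configured structure.

    Planted miRNA target windows and endonuclease motif occurrences
    overwrite ``sequences`` **in place** (each transcript hosts at most one
    planted event, so occurrences cannot collide).  Returns PARE signature
    matrices {DW, DC}, RNA-Seq counts {RW, RC}, and the ground truth.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 1])
    tids = list(annotations)
    truth = GroundTruth(library_scale=dict(config.library_scale))

    # --- decay types and planted fold changes ---------------------------------
    keys = list(config.type_mixture)
    probs = np.array([config.type_mixture[k] for k in keys])
    drawn = rng.choice(len(keys), size=len(tids), p=probs)
    fc = config.planted_log2fc
    by_type: dict[str, list[str]] = {k: [] for k in keys}
    for tid, k_idx in zip(tids, drawn):
        key = keys[int(k_idx)]
        truth.decay_type[tid] = key
        by_type[key].append(tid)
    # mass-balanced up/down allocation, so that population-size
    # normalization leaves planted fold changes intact
    up_counts = _balanced_up_counts(
        {t: len(by_type.get(t, [])) for t in ("I", "II", "III", "IV")}, fc
    )
    sign: dict[str, float] = {}
    for t in ("I", "II", "III", "IV"):
        members = by_type.get(t, [])
        order = rng.permutation(len(members))
        for rank, idx in enumerate(order):
            sign[members[int(idx)]] = 1.0 if rank < up_counts[t] else -1.0
    for tid in tids:
        key = truth.decay_type[tid]
        d_axis, r_axis = _TYPE_AXES[key]
        s = sign.get(tid, 0.0)
        truth.log2fc_d[tid] = d_axis * s * fc
        truth.log2fc_r[tid] = r_axis * s * fc

    # --- plant miRNAs and their slicing sites ---------------------------------
    mirnas = {
        f"mir{i + 1:03d}": _random_sequence(rng, config.mirna_length)
        for i in range(config.n_mirnas)
    }
    truth.mirna_sequences = mirnas
    truth.mirna_log2fc = {
        mid: float(rng.choice([-fc, 0.0, fc])) for mid in mirnas
    }
    used: set[str] = set()
    w = config.mirna_length
    if config.n_mirna_targets:
        eligible = [
            tid
            for tid in tids
            if annotations[tid].cds_end - annotations[tid].cds_start + 1 >= w
            and tid not in used
        ]
        if len(eligible) < config.n_mirna_targets:
            raise ValueError(
                "invalid config field n_mirna_targets: not enough transcripts "
                "with a CDS long enough for the miRNA window"
            )
        chosen = rng.choice(len(eligible), size=config.n_mirna_targets, replace=False)
        mirna_ids = list(mirnas)
        for j, idx in enumerate(chosen):
            tid = eligible[int(idx)]
            ann = annotations[tid]
            mid = mirna_ids[j % len(mirna_ids)]
            start = int(rng.integers(ann.cds_start, ann.cds_end - w + 2))
            site_seq = mirnas[mid].translate(_RNA_COMPLEMENT)[::-1]  # reverse complement
            seq = sequences[tid]
            sequences[tid] = seq[: start - 1] + site_seq + seq[start - 1 + w :]
            cut = start + w - 10  # base paired to miRNA position 10
            truth.mirna_targets.append(PlantedTarget(mid, tid, start, cut))
            used.add(tid)

    # --- plant endonuclease motifs --------------------------------------------
    region_weights = {"utr5": 0.05, "cds": 0.40, "utr3": 0.55}
    for m_idx, spec in enumerate(config.endo_motifs):
        motif_id = f"motif{m_idx + 1}"
        width = len(spec.consensus)
        flank_up, flank_down = 10, 15  # keep cuts extractable with default flanks
        free = [tid for tid in tids if tid not in used]
        rng.shuffle(free)
        planted = 0
        for tid in free:
            if planted == spec.group_size:
                break
            ann = annotations[tid]
            regions = {
                "utr5": (1, ann.cds_start - 1),
                "cds": (ann.cds_start, ann.cds_end),
                "utr3": (ann.cds_end + 1, ann.length),
            }
            names = list(region_weights)
            probs_r = np.array([region_weights[r] for r in names])
            # weighted region preference with fallback to any feasible region
            order = rng.choice(
                len(names), size=len(names), replace=False, p=probs_r / probs_r.sum()
            )
            placed = False
            for region in (names[int(o)] for o in order):
                lo_r, hi_r = regions[region]
                lo_c = max(lo_r, flank_up + 1)
                hi_c = min(hi_r, ann.length - max(width - 1, flank_down))
                if lo_c > hi_c:
                    continue
                cut = int(rng.integers(lo_c, hi_c + 1))
                seq = sequences[tid]
                sequences[tid] = (
                    seq[: cut - 1] + spec.consensus + seq[cut - 1 + width :]
                )
                truth.endo_sites.append(
                    PlantedEndoSite(motif_id, tid, cut, spec.condition, spec.consensus)
                )
                used.add(tid)
                planted += 1
                placed = True
                break
            if not placed:
                continue
        if planted < spec.group_size:
            raise ValueError(
                f"invalid config field endo_motifs: motif {spec.consensus!r} "
                f"needs {spec.group_size} host transcripts but only {planted} "
                "have an eligible region"
            )

    # --- draw counts ----------------------------------------------------------
    rnaseq: dict[str, dict[str, float]] = {lib: {} for lib in RNA_LIBRARIES}
    pare = {lib: SignatureMatrix(lib) for lib in PARE_LIBRARIES}
    peak_by_tid: dict[str, tuple[int, str]] = {}
    for t in truth.mirna_targets:
        peak_by_tid[t.transcript_id] = (t.cleavage_position, "both")
    for e in truth.endo_sites:
        peak_by_tid[e.transcript_id] = (e.cut_position, e.condition)

    scale = config.library_scale
    for tid in tids:
        ann = annotations[tid]
        r_means = {
            "RW": config.base_expression,
            "RC": config.base_expression * 2.0 ** truth.log2fc_r[tid],
        }
        for lib in RNA_LIBRARIES:
            rnaseq[lib][tid] = (
                _draw_count(rng, r_means[lib], config.dispersion) * scale.get(lib, 1.0)
            )
        d_means = {
            "DW": config.base_uncapped,
            "DC": config.base_uncapped * 2.0 ** truth.log2fc_d[tid],
        }
        for lib in PARE_LIBRARIES:
            total = _draw_count(rng, d_means[lib], config.dispersion) * scale.get(lib, 1.0)
            peak_position: int | None = None
            if tid in peak_by_tid:
                pos, cond = peak_by_tid[tid]
                if cond == "both" or cond == lib:
                    peak_position = pos
            _scatter(
                pare[lib],
                rng,
                tid,
                ann.length,
                total,
                peak_position,
                config.peak_fraction,
                config.background_positions,
                config.background_decay_rate,
            )
    return pare, rnaseq, truth


# ---------------------------------------------------------------------------
# fixture serialization


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_fixture(
    annotations: Mapping[str, TranscriptAnnotation],
    sequences: Mapping[str, str],
    pare: Mapping[str, SignatureMatrix],
    rnaseq: Mapping[str, Mapping[str, float]],
    truth: GroundTruth,
    directory: str | Path,
) -> dict[str, str]:
    """Write the whole simulation as plain-text files; returns {path: sha256}."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_transcripts(sequences, directory / "transcripts.fasta")
    write_transcripts(truth.mirna_sequences, directory / "mirnas.fasta")
    write_annotation(annotations, directory / "annotation.tsv")
    write_signatures(
        [pare[lib] for lib in sorted(pare)], directory / "signatures.tsv"
    )
    write_counts(rnaseq, directory / "counts.tsv")
    pd.DataFrame(
        [
            (tid, truth.decay_type[tid], truth.log2fc_d[tid], truth.log2fc_r[tid])
            for tid in sorted(truth.decay_type)
        ],
        columns=["transcript_id", "decay_type", "log2fc_d", "log2fc_r"],
    ).to_csv(directory / "truth_decay.tsv", sep="\t", index=False, float_format="%.17g")
    pd.DataFrame(
        [asdict(t) for t in truth.mirna_targets],
        columns=["mirna_id", "transcript_id", "window_start", "cleavage_position"],
    ).to_csv(directory / "truth_mirna.tsv", sep="\t", index=False)
    pd.DataFrame(
        [asdict(e) for e in truth.endo_sites],
        columns=["motif_id", "transcript_id", "cut_position", "condition", "consensus"],
    ).to_csv(directory / "truth_endo.tsv", sep="\t", index=False)
    pd.DataFrame(
        sorted(truth.library_scale.items()), columns=["library", "scale"]
    ).to_csv(directory / "truth_scale.tsv", sep="\t", index=False)

    names = [
        "transcripts.fasta",
        "mirnas.fasta",
        "annotation.tsv",
        "signatures.tsv",
        "counts.tsv",
        "truth_decay.tsv",
        "truth_mirna.tsv",
        "truth_endo.tsv",
        "truth_scale.tsv",
    ]
    manifest = {name: _sha256(directory / name) for name in names}
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
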
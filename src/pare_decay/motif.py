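"""Self-contained de novo motif discovery for RNA sequence sets.

Two modes share one greedy engine:

* **anchored** — every input sequence is a fixed-length flank around a
  cleavage site and the motif must start at a fixed offset (the first
  nucleotide 3' of the cut).  Used for endonucleolytic cleavage groups,
  where cuts fall at the 5' end of the shared motif.
* **scan** — variable-length sequences (e.g. UTRs); the motif may occur
  anywhere, at most once per sequence.

The engine seeds each motif with the most-enriched exact k-mer, collects
sequences within Hamming distance 1 of the seed, and refines a position
weight matrix (PWM) by iterating membership under a log-odds score
threshold against a uniform background.  Each sequence joins at most one
motif.  Significance is an E-value: the binomial tail probability of the
observed membership under the background match probability, Bonferroni
scaled by the 4^w possible seeds.  It is an internal calibration statistic
(comparable across runs of this engine, not numerically to MEME's E-value).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

__all__ = ["Motif", "find_anchored_motifs", "find_motifs_scan"]

ALPHABET = "ACGU"
_INDEX = {c: i for i, c in enumerate(ALPHABET)}

DEFAULT_WIDTHS = tuple(range(6, 13))


@dataclass
class Motif:
    """A discovered motif with its member sequences."""

    consensus: str
    pwm: np.ndarray  # shape (width, 4), rows sum to 1
    members: list[int]  # indices into the input sequence list
    offsets: list[int]  # 0-based motif start within each member
    evalue: float
    n_pool: int  # sequences available when this motif was found

    @property
    def width(self) -> int:
        return len(self.consensus)


def _encode(seq: str) -> np.ndarray:
    return np.fromiter((_INDEX[c] for c in seq), dtype=np.int8, count=len(seq))


def _pwm(kmers: Sequence[str], pseudocount: float = 0.25) -> np.ndarray:
    w = len(kmers[0])
    counts = np.full((w, 4), pseudocount)
    for k in kmers:
        for j, c in enumerate(k):
            counts[j, _INDEX[c]] += 1
    return counts / counts.sum(axis=1, keepdims=True)


def _consensus(pwm: np.ndarray) -> str:
    return "".join(ALPHABET[i] for i in pwm.argmax(axis=1))


def _log_odds(pwm: np.ndarray) -> np.ndarray:
    return np.log2(pwm / 0.25)


def _column_ic(pwm: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        h = -np.where(pwm > 0, pwm * np.log2(pwm), 0.0).sum(axis=1)
    return 2.0 - h


def _score_kmer(logodds: np.ndarray, kmer: str) -> float:
    return float(sum(logodds[j, _INDEX[c]] for j, c in enumerate(kmer)))


def _match_probability(logodds: np.ndarray, tau: float) -> float:
    """P(uniform random w-mer scores >= tau), by per-column convolution.

    The score distribution over the 4^w random w-mers factorizes across
    columns; convolve on a 0.01-bit grid.
    """
    res = 0.01
    lo = float(np.minimum(logodds.min(axis=1), 0).sum())
    hi = float(np.maximum(logodds.max(axis=1), 0).sum())
    n_bins = int(round((hi - lo) / res)) + 2
    dist = np.zeros(n_bins)
    dist[int(round(-lo / res))] = 1.0  # start at score 0
    for row in logodds:
        new = np.zeros(n_bins)
        for val in row:
            shift = int(round(val / res))
            if shift >= 0:
                new[shift:] += 0.25 * dist[: n_bins - shift]
            else:
                new[:shift] += 0.25 * dist[-shift:]
        dist = new
    start = int(round((tau - lo) / res)) - 1  # half-bin slack against rounding
    return float(dist[max(start, 0) :].sum())


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


@dataclass
class _Candidate:
    width: int
    members: list[int]
    offsets: list[int]
    pwm: np.ndarray
    evalue: float


def _refine_anchored(
    kmers: dict[int, str], seed: str, tau: float, max_iter: int = 8
) -> tuple[list[int], np.ndarray] | None:
    members = [i for i, k in kmers.items() if _hamming(k, seed) <= 1]
    if len(members) < 2:
        return None
    for _ in range(max_iter):
        pwm = _pwm([kmers[i] for i in members])
        logodds = _log_odds(pwm)
        new = [i for i, k in kmers.items() if _score_kmer(logodds, k) >= tau]
        if not new:
            return None
        if set(new) == set(members):
            return new, pwm
        members = new
    return members, _pwm([kmers[i] for i in members])


def _best_window(
    logodds: np.ndarray, seq: str
) -> tuple[float, int]:
    w = logodds.shape[0]
    best, best_off = -np.inf, -1
    enc = _encode(seq)
    for off in range(len(seq) - w + 1):
        s = float(logodds[np.arange(w), enc[off : off + w]].sum())
        if s > best:
            best, best_off = s, off
    return best, best_off


def _refine_scan(
    seqs: dict[int, str], seed: str, tau: float, max_iter: int = 8
) -> tuple[list[int], list[int], np.ndarray] | None:
    w = len(seed)
    members, offsets = [], []
    for i, s in seqs.items():
        for off in range(len(s) - w + 1):
            if _hamming(s[off : off + w], seed) <= 1:
                members.append(i)
                offsets.append(off)
                break
    if len(members) < 2:
        return None
    for _ in range(max_iter):
        pwm = _pwm([seqs[i][o : o + w] for i, o in zip(members, offsets)])
        logodds = _log_odds(pwm)
        new_m, new_o = [], []
        for i, s in seqs.items():
            if len(s) < w:
                continue
            score, off = _best_window(logodds, s)
            if score >= tau:
                new_m.append(i)
                new_o.append(off)
        if not new_m:
            return None
        if new_m == members and new_o == offsets:
            return members, offsets, pwm
        members, offsets = new_m, new_o
    return members, offsets, _pwm([seqs[i][o : o + w] for i, o in zip(members, offsets)])


def _candidate_evalue(
    pwm: np.ndarray, tau: float, n_pool: int, n_members: int, n_windows: float
) -> float:
    p_match = _match_probability(_log_odds(pwm), tau)
    p_seq = 1.0 - (1.0 - min(p_match, 1.0)) ** max(n_windows, 1.0)
    tail = float(stats.binom.sf(n_members - 1, n_pool, min(p_seq, 1.0)))
    return tail * (4.0 ** pwm.shape[0])


def _column_ic_from_chars(chars: Sequence[str], pseudocount: float = 0.25) -> float:
    counts = np.full(4, pseudocount)
    for c in chars:
        counts[_INDEX[c]] += 1
    p = counts / counts.sum()
    return float(2.0 + np.where(p > 0, p * np.log2(p), 0.0).sum())


def _greedy(
    build_candidates,
    n_total: int,
    min_members: int,
    evalue_max: float,
    max_motifs: int,
    extend=None,
) -> list[Motif]:
    unassigned = set(range(n_total))
    motifs: list[Motif] = []
    while unassigned and len(motifs) < max_motifs:
        candidates = build_candidates(unassigned)
        candidates = [c for c in candidates if len(c.members) >= min_members and c.evalue < evalue_max]
        if not candidates:
            break
        # the E-value picks the most background-improbable seed width; the
        # consensus is then grown over every adjacent conserved column, so
        # the reported motif is not truncated to the seed width
        best = min(candidates, key=lambda c: (c.evalue, -len(c.members), -c.width))
        if extend is not None:
            best = extend(best)
        motifs.append(
            Motif(
                consensus=_consensus(best.pwm),
                pwm=best.pwm,
                members=best.members,
                offsets=best.offsets,
                evalue=best.evalue,
                n_pool=len(unassigned),
            )
        )
        unassigned -= set(best.members)
    return motifs


def find_anchored_motifs(
    sequences: Sequence[str],
    anchor_offset: int,
    widths: Iterable[int] = DEFAULT_WIDTHS,
    min_members: int = 6,
    evalue_max: float = 1e-3,
    score_frac: float = 1.0,
    ic_min: float = 1.0,
    max_motifs: int = 20,
) -> list[Motif]:
    """Discover motifs starting at a fixed offset in equal-length flanks.

    ``score_frac`` sets the membership threshold at ``score_frac * width``
    bits of log-odds score; ``ic_min`` is the minimum per-column information
    content a reported motif must reach (prunes widths that overrun the
    conserved core into random flanking sequence).
    """
    widths = tuple(widths)

    def build(unassigned: set[int]) -> list[_Candidate]:
        out = []
        for w in widths:
            kmers = {
                i: sequences[i][anchor_offset : anchor_offset + w]
                for i in unassigned
                if len(sequences[i]) >= anchor_offset + w
            }
            kmers = {i: k for i, k in kmers.items() if set(k) <= set(ALPHABET)}
            if not kmers:
                continue
            seed = Counter(kmers.values()).most_common(1)[0][0]
            refined = _refine_anchored(kmers, seed, tau=score_frac * w)
            if refined is None:
                continue
            members, pwm = refined
            if _column_ic(pwm).min() < ic_min:
                continue
            ev = _candidate_evalue(pwm, score_frac * w, len(kmers), len(members), 1.0)
            out.append(_Candidate(w, sorted(members), [anchor_offset] * len(members), pwm, ev))
        return out

    max_width = max(widths)

    def extend(c: _Candidate) -> _Candidate:
        # grow 3' of the cut only: the motif's 5' end is pinned to the cut
        w = c.width
        while w < max_width:
            if any(len(sequences[i]) < anchor_offset + w + 1 for i in c.members):
                break
            col = [sequences[i][anchor_offset + w] for i in c.members]
            if _column_ic_from_chars(col) < ic_min:
                break
            w += 1
        if w != c.width:
            kmers = [sequences[i][anchor_offset : anchor_offset + w] for i in c.members]
            c = _Candidate(w, c.members, c.offsets, _pwm(kmers), c.evalue)
        return c

    return _greedy(build, len(sequences), min_members, evalue_max, max_motifs, extend)


def find_motifs_scan(
    sequences: Sequence[str],
    widths: Iterable[int] = DEFAULT_WIDTHS,
    min_members: int = 4,
    evalue_max: float = 1e-3,
    score_frac: float = 1.0,
    ic_min: float = 1.0,
    max_motifs: int = 20,
) -> list[Motif]:
    """Discover motifs occurring anywhere (at most once per sequence)."""
    widths = tuple(widths)
    clean = [
        s if set(s) <= set(ALPHABET) else "".join(c if c in _INDEX else "A" for c in s)
        for s in sequences
    ]

    def build(unassigned: set[int]) -> list[_Candidate]:
        out = []
        for w in widths:
            pool = {i: clean[i] for i in unassigned if len(clean[i]) >= w}
            if not pool:
                continue
            presence: Counter = Counter()
            for s in pool.values():
                presence.update({s[off : off + w] for off in range(len(s) - w + 1)})
            if not presence:
                continue
            seed = presence.most_common(1)[0][0]
            refined = _refine_scan(pool, seed, tau=score_frac * w)
            if refined is None:
                continue
            members, offsets, pwm = refined
            if _column_ic(pwm).min() < ic_min:
                continue
            mean_windows = float(np.mean([len(pool[i]) - w + 1 for i in pool]))
            ev = _candidate_evalue(pwm, score_frac * w, len(pool), len(members), mean_windows)
            out.append(_Candidate(w, members, offsets, pwm, ev))
        return out

    max_width = max(widths)

    def extend(c: _Candidate) -> _Candidate:
        w, offsets = c.width, list(c.offsets)
        while w < max_width:  # grow 5' while every member has a conserved column
            if any(o < 1 for o in offsets):
                break
            col = [clean[i][o - 1] for i, o in zip(c.members, offsets)]
            if _column_ic_from_chars(col) < ic_min:
                break
            offsets = [o - 1 for o in offsets]
            w += 1
        while w < max_width:  # grow 3' likewise
            if any(o + w + 1 > len(clean[i]) for i, o in zip(c.members, offsets)):
                break
            col = [clean[i][o + w] for i, o in zip(c.members, offsets)]
            if _column_ic_from_chars(col) < ic_min:
                break
            w += 1
        if w != c.width:
            kmers = [clean[i][o : o + w] for i, o in zip(c.members, offsets)]
            c = _Candidate(w, c.members, offsets, _pwm(kmers), c.evalue)
        return c

    return _greedy(build, len(clean), min_members, evalue_max, max_motifs, extend)


def write_meme_minimal(motifs: Iterable[Motif], path, names: Iterable[str] | None = None) -> None:
    """Write motifs in MEME minimal text format (position weight matrices)."""
    motifs = list(motifs)
    if names is None:
        names = [f"motif_{i+1}" for i in range(len(motifs))]
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGU\n\n")
        fh.write("Background letter frequencies\nA 0.25 C 0.25 G 0.25 U 0.25\n\n")
        for name, m in zip(names, motifs):
            fh.write(f"MOTIF {name} {m.consensus}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {m.width} "
                f"nsites= {len(m.members)} E= {m.evalue:.3e}\n"
            )
            for row in m.pwm:
                fh.write(" ".join(f"{p:.6f}" for p in row) + "\n")
            fh.write("\n")
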
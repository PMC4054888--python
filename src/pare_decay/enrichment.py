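"""Fisher's exact two-tailed set enrichment against a stated background.

Given a gene list (e.g. all genes represented in a PARE library), a named
target set (e.g. the substrates of a decay-pathway core component) and a
background universe, the 2x2 contingency table

    a = |list ∩ set|    b = |list \\ set|
    c = |set \\ list|    d = |background \\ (list ∪ set)|

is tested with the two-tailed Fisher-Irwin exact test: summing, over all
tables with the observed margins, the hypergeometric point probabilities
that do not exceed the observed table's (the point-probability method).
Enrichment is flagged significant at the conventional P < 0.001.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "TargetSet",
    "EnrichmentResult",
    "fisher_two_tailed",
    "set_enrichment",
    "batch_enrichment",
]


@dataclass(frozen=True)
class TargetSet:
    """A named pathway target set (e.g. TDT, PARN, UPF, RRP4)."""

    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"target set {self.name!r} is empty")

    @classmethod
    def from_file(cls, path, name: str | None = None) -> "TargetSet":
        """Load a plain-text target set, one gene id per line (filename = name)."""
        from pathlib import Path

        path = Path(path)
        genes = frozenset(
            line.strip() for line in path.read_text().splitlines() if line.strip()
        )
        return cls(name or path.stem, genes)


@dataclass(frozen=True)
class EnrichmentResult:
    set_name: str
    library: str
    a: int
    b: int
    c: int
    d: int
    p_two_tailed: float
    significant: bool


# Exact-integer evaluation is used while the hypergeometric support is small
# enough; products of math.comb integers give exact tie comparisons, so the
# two-tailed sum is correct to float output precision.  Very large supports
# fall back to log-gamma arithmetic.
_EXACT_SUPPORT_LIMIT = 10_000


def fisher_two_tailed(a: int, b: int, c: int, d: int) -> float:
    """Two-tailed Fisher exact P for the 2x2 table [[a, b], [c, d]].

    Point-probability (Fisher-Irwin) definition; returns a value in (0, 1].
    Degenerate tables (an all-zero margin pair, N = 0) are an error.
    """
    for x in (a, b, c, d):
        if not isinstance(x, (int,)) or isinstance(x, bool):
            raise TypeError("contingency counts must be integers")
        if x < 0:
            raise ValueError("contingency counts must be non-negative")
    n = a + b + c + d
    if n == 0:
        raise ValueError("degenerate table: all margins zero")
    r1, c1 = a + b, a + c
    k_min, k_max = max(0, r1 + c1 - n), min(r1, c1)
    support = range(k_min, k_max + 1)
    if len(support) <= _EXACT_SUPPORT_LIMIT:
        # exact: numerators share the denominator C(n, r1)
        nums = [math.comb(c1, k) * math.comb(n - c1, r1 - k) for k in support]
        obs = nums[a - k_min]
        total = sum(nums)
        tail = sum(x for x in nums if x <= obs)
        return tail / total
    # log-space fallback for huge supports
    def log_pmf(k: int) -> float:
        return (
            _lchoose(c1, k)
            + _lchoose(n - c1, r1 - k)
            - _lchoose(n, r1)
        )

    obs = log_pmf(a)
    eps = 1e-9
    total = 0.0
    for k in support:
        lp = log_pmf(k)
        if lp <= obs + eps:
            total += math.exp(lp)
    return min(total, 1.0)


def _lchoose(n: int, k: int) -> float:
    return math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)


def set_enrichment(
    gene_list: Iterable[str],
    target: TargetSet,
    background: Iterable[str],
    library: str = "",
    alpha: float = 1e-3,
) -> EnrichmentResult:
    """Test a gene list for enrichment in one target set.

    Genes outside the background (in either the list or the set) are dropped
    with a warning before building the contingency table.
    """
    bg = set(background)
    if not bg:
        raise ValueError("background is empty")
    genes = set(gene_list)
    stray = genes - bg
    if stray:
        warnings.warn(
            f"{len(stray)} gene(s) in the list are outside the background; dropped",
            stacklevel=2,
        )
        genes &= bg
    tset = set(target.genes)
    stray_t = tset - bg
    if stray_t:
        warnings.warn(
            f"{len(stray_t)} gene(s) in target set {target.name!r} are outside "
            "the background; dropped",
            stacklevel=2,
        )
        tset &= bg
    a = len(genes & tset)
    b = len(genes - tset)
    c = len(tset - genes)
    d = len(bg) - a - b - c
    p = fisher_two_tailed(a, b, c, d)
    return EnrichmentResult(
        set_name=target.name,
        library=library,
        a=a,
        b=b,
        c=c,
        d=d,
        p_two_tailed=p,
        significant=p < alpha,
    )


def batch_enrichment(
    gene_lists: Mapping[str, Iterable[str]],
    target_sets: Sequence[TargetSet],
    background: Iterable[str],
    alpha: float = 1e-3,
    bonferroni: bool = False,
) -> pd.DataFrame:
    """One enrichment test per (library gene list, target set) pair.

    Output is sorted by set name then library.  ``bonferroni`` optionally
    rescales the significance cutoff by the number of tests (off by default:
    raw two-tailed P values with a fixed star threshold are the convention
    this pipeline reports).
    """
    names = [t.name for t in target_sets]
    if len(set(names)) != len(names):
        raise ValueError("duplicate target set name")
    bg = set(background)
    cutoff = alpha / (len(gene_lists) * len(target_sets)) if bonferroni else alpha
    rows = []
    for tset in sorted(target_sets, key=lambda t: t.name):
        for lib in sorted(gene_lists):
            res = set_enrichment(gene_lists[lib], tset, bg, library=lib, alpha=cutoff)
            rows.append(res.__dict__)
    return pd.DataFrame(rows)
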
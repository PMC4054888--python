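"""Library normalization and uncapped/total abundance fold changes.

Two abundances are compared per gene: D, the uncapped transcript abundance
(sum of PARE signature counts on the transcript), and R, the transcript
abundance from RNA-Seq.  Libraries are normalized to a reference library by
total mapped population size, and change is measured as a pseudocounted
log2 fold change, treated over control.
"""

from __future__ import annotations

import math
from typing import Mapping

import numpy as np
import pandas as pd

from .degradome_io import SignatureMatrix

__all__ = [
    "normalize_library",
    "normalize_counts",
    "transcript_abundance",
    "log2_fold_change",
    "fraction_altered",
    "build_abundance_table",
]

ABUNDANCE_COLUMNS = [
    "d_control",
    "d_treated",
    "r_control",
    "r_treated",
    "log2fc_d",
    "log2fc_r",
]


def normalize_library(
    target: SignatureMatrix,
    reference: SignatureMatrix,
    reference_total: float | None = None,
    target_total: float | None = None,
) -> tuple[SignatureMatrix, float]:
    """Scale ``target`` so its total mapped population equals the reference's.

    Totals default to the transcriptome-mapped mass held in each matrix;
    pass ``reference_total`` / ``target_total`` to normalize by an external
    population size (e.g. genome-mapped reads) instead.

    Returns the scaled copy and the scale factor.
    """
    ref_total = reference.total_mapped if reference_total is None else reference_total
    tgt_total = target.total_mapped if target_total is None else target_total
    if ref_total <= 0:
        raise ValueError("reference total must be > 0")
    if tgt_total <= 0:
        raise ValueError("target library total is 0; cannot normalize")
    factor = ref_total / tgt_total
    return target.scaled(factor), factor


def normalize_counts(
    target: Mapping[str, float], reference: Mapping[str, float]
) -> tuple[dict[str, float], float]:
    """Same population-size normalization for per-transcript count dicts."""
    ref_total = float(sum(reference.values()))
    tgt_total = float(sum(target.values()))
    if ref_total <= 0:
        raise ValueError("reference total must be > 0")
    if tgt_total <= 0:
        raise ValueError("target library total is 0; cannot normalize")
    factor = ref_total / tgt_total
    return {tid: c * factor for tid, c in target.items()}, factor


def transcript_abundance(matrix: SignatureMatrix) -> dict[str, float]:
    """Sum positional signature counts into per-transcript uncapped abundance."""
    return matrix.transcript_totals()


def log2_fold_change(
    treated: float, control: float, pseudocount: float = 1.0
) -> float:
    """Pseudocounted log2 ratio, treated over control.

    ``(0, 0)`` maps to 0 and the result is finite for all non-negative inputs.
    """
    if treated < 0 or control < 0:
        raise ValueError("abundances must be non-negative")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    return math.log2((treated + pseudocount) / (control + pseudocount))


def fraction_altered(
    fold_changes, fold_threshold: float = 5.0, allow_empty: bool = False
) -> float:
    """Fraction of genes whose abundance changed more than ``fold_threshold``-fold.

    ``fold_changes`` are log2 values; an entry counts as altered when
    ``|log2fc| > log2(fold_threshold)``.
    """
    if fold_threshold <= 1:
        raise ValueError("fold_threshold must be > 1")
    fcs = np.asarray(list(fold_changes), dtype=float)
    if fcs.size == 0:
        if allow_empty:
            return 0.0
        raise ValueError("empty fold-change input")
    return float(np.mean(np.abs(fcs) > math.log2(fold_threshold)))


def build_abundance_table(
    pare_control: Mapping[str, float],
    pare_treated: Mapping[str, float],
    rna_control: Mapping[str, float],
    rna_treated: Mapping[str, float],
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Joint D/R abundance table over genes present on both platforms.

    A gene qualifies when it has nonzero abundance in at least one condition
    on the PARE side AND at least one condition on the RNA-Seq side (the
    "found in both libraries" rule).  Inputs should already be normalized.
    """
    pare_ids = {
        tid
        for tid in set(pare_control) | set(pare_treated)
        if pare_control.get(tid, 0.0) > 0 or pare_treated.get(tid, 0.0) > 0
    }
    rna_ids = {
        tid
        for tid in set(rna_control) | set(rna_treated)
        if rna_control.get(tid, 0.0) > 0 or rna_treated.get(tid, 0.0) > 0
    }
    shared = sorted(pare_ids & rna_ids)
    rows = []
    for tid in shared:
        dc, dt = pare_control.get(tid, 0.0), pare_treated.get(tid, 0.0)
        rc, rt = rna_control.get(tid, 0.0), rna_treated.get(tid, 0.0)
        rows.append(
            (
                dc,
                dt,
                rc,
                rt,
                log2_fold_change(dt, dc, pseudocount),
                log2_fold_change(rt, rc, pseudocount),
            )
        )
    return pd.DataFrame(rows, columns=ABUNDANCE_COLUMNS, index=pd.Index(shared, name="transcript_id"))
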
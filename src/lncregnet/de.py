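"""Differential-expression calling on FPKM matrices.

Fold changes are computed on condition means with a small pseudocount; calls
use the study thresholds q <= 0.05 and |log2FC| >= 1 (boundaries inclusive).
Upstream q-values (e.g. from Cuffdiff) are consumed as input; a Welch t-test
on log2 FPKM with Benjamini-Hochberg correction is available as a clearly
labelled stand-in when none are supplied.  The qPCR validation arithmetic
(2^-ddCt) lives here too.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation_io import ExpressionMatrix, GenomicInterval

__all__ = [
    "DEResult",
    "compute_log2fc",
    "call_de",
    "count_directions",
    "shared_loci",
    "count_distinct_loci",
    "welch_bh_stats",
    "ddct",
]

#: Pseudocount added to condition means before the log ratio (FPKM units).
DEFAULT_PSEUDOCOUNT = 0.01


@dataclass(frozen=True)
class DEResult:
    transcript_id: str
    log2fc: float
    qvalue: float
    direction: str  # up | down | none


def compute_log2fc(
    matrix: ExpressionMatrix,
    transcript_id: str,
    genotype: str,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    treated: str = "salt",
    control: str = "control",
) -> float:
    """log2((mean FPKM treated + eps) / (mean FPKM control + eps)) within a genotype."""
    x_treated = matrix.get(transcript_id, matrix.sample_names(genotype, treated))
    x_control = matrix.get(transcript_id, matrix.sample_names(genotype, control))
    return float(
        np.log2((x_treated.mean() + pseudocount) / (x_control.mean() + pseudocount))
    )


def call_de(
    log2fc: float,
    qvalue: float,
    min_abs_log2fc: float = 1.0,
    max_q: float = 0.05,
) -> str:
    """Direction call: up iff log2FC >= 1 and q <= 0.05; down iff <= -1; else none."""
    if not 0.0 <= qvalue <= 1.0:
        raise ValueError(f"qvalue must be in [0, 1], got {qvalue}")
    if qvalue <= max_q:
        if log2fc >= min_abs_log2fc:
            return "up"
        if log2fc <= -min_abs_log2fc:
            return "down"
    return "none"


def count_directions(results: Sequence[DEResult]) -> tuple[int, int]:
    """(n_up, n_down) over a list of DE results."""
    ups = sum(1 for r in results if r.direction == "up")
    downs = sum(1 for r in results if r.direction == "down")
    return ups, downs


def shared_loci(
    list_a: Sequence[GenomicInterval], list_b: Sequence[GenomicInterval]
) -> list[tuple[GenomicInterval, GenomicInterval]]:
    """All (a, b) pairs sharing >= 1 bp on the same chromosome."""
    return [(a, b) for a in list_a for b in list_b if a.overlaps(b)]


def count_distinct_loci(*interval_lists: Sequence[GenomicInterval]) -> int:
    """Number of distinct loci across lists, merging intervals that overlap."""
    intervals = sorted(
        (iv for lst in interval_lists for iv in lst),
        key=lambda iv: (iv.chrom, iv.start, iv.end),
    )
    count = 0
    cur_chrom, cur_end = None, -1
    for iv in intervals:
        if iv.chrom != cur_chrom or iv.start >= cur_end:
            count += 1
            cur_chrom, cur_end = iv.chrom, iv.end
        else:
            cur_end = max(cur_end, iv.end)
    return count


def welch_bh_stats(
    matrix: ExpressionMatrix,
    genotype: str,
    transcript_ids: Sequence[str] | None = None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    treated: str = "salt",
    control: str = "control",
) -> pd.DataFrame:
    """Stand-in significance when no upstream q-values exist.

    Welch t-test on log2(FPKM + eps) between conditions, Benjamini-Hochberg
    adjusted across transcripts.  Returns columns transcript_id, log2fc,
    pvalue, qvalue.  This is NOT the negative-binomial machinery of upstream
    count-based callers; it is a labelled approximation for FPKM-only input.
    """
    ids = list(transcript_ids) if transcript_ids is not None else matrix.transcript_ids
    s_treated = matrix.sample_names(genotype, treated)
    s_control = matrix.sample_names(genotype, control)
    rows = []
    for tid in ids:
        a = np.log2(matrix.get(tid, s_treated) + pseudocount)
        b = np.log2(matrix.get(tid, s_control) + pseudocount)
        if np.allclose(a.std(), 0) and np.allclose(b.std(), 0):
            p = 0.0 if not np.isclose(a.mean(), b.mean()) else 1.0
        else:
            p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
        rows.append(
            {
                "transcript_id": tid,
                "log2fc": compute_log2fc(matrix, tid, genotype, pseudocount, treated, control),
                "pvalue": p,
            }
        )
    df = pd.DataFrame(rows)
    df["qvalue"] = stats.false_discovery_control(df["pvalue"].to_numpy(), method="bh")
    return df


def ddct(
    ct_target_treated: float,
    ct_ref_treated: float,
    ct_target_control: float,
    ct_ref_control: float,
) -> float:
    """Relative qPCR expression 2^-ddCt.

    ddCt = (Ct_target,treated - Ct_ref,treated) - (Ct_target,control - Ct_ref,control).
    """
    for ct in (ct_target_treated, ct_ref_treated, ct_target_control, ct_ref_control):
        if not np.isfinite(ct):
            raise ValueError("Ct values must be finite")
    delta_delta = (ct_target_treated - ct_ref_treated) - (
        ct_target_control - ct_ref_control
    )
    return float(2.0 ** (-delta_delta))
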
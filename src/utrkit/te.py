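"""Per-transcript translation efficiency from paired Ribo-seq / RNA-seq counts.

Translation efficiency (TE) is the ratio of ribosome-footprint abundance to
mRNA abundance for a transcript:

    TE = RPF RPKM / RNA RPKM

with RPKM = reads per kilobase of transcript per million mapped reads.  TE is
scale-invariant: multiplying both library sizes by a constant leaves it
unchanged.  Transcripts with insufficient coverage in either assay are
filtered on raw counts (default >= 10 reads each) before TE is interpreted;
no pseudocounts enter TE itself — filtering removes the zero-denominator
cases instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import UtrkitError


@dataclass
class TranscriptQuant:
    """RNA/RPF counts, RPKMs and TE for one transcript.

    ``te`` is NaN when rna_rpkm == 0 (undefined, not zero and not infinity).
    """

    transcript_id: str
    length_nt: int
    rna_count: int
    rpf_count: int
    rna_rpkm: float = 0.0
    rpf_rpkm: float = 0.0
    te: float = math.nan


def rpkm(count: int, length_nt: int, total_mapped: int) -> float:
    """Reads per kilobase of transcript per million mapped reads."""
    if length_nt <= 0:
        raise UtrkitError(f"length_nt must be positive, got {length_nt}")
    if total_mapped <= 0:
        raise UtrkitError(f"total_mapped must be positive, got {total_mapped}")
    if count < 0:
        raise UtrkitError(f"count must be non-negative, got {count}")
    return count / (length_nt / 1e3) / (total_mapped / 1e6)


def translation_efficiency(rpf_rpkm: float, rna_rpkm: float) -> float:
    """RPF RPKM / RNA RPKM; NaN when the denominator is zero."""
    if rna_rpkm < 0 or rpf_rpkm < 0:
        raise UtrkitError("RPKMs must be non-negative")
    if rna_rpkm == 0:
        return math.nan
    return rpf_rpkm / rna_rpkm


def filter_coverage(
    quants: list[TranscriptQuant],
    min_rna_count: int = 10,
    min_rpf_count: int = 10,
) -> tuple[list[TranscriptQuant], dict[str, int]]:
    """Drop transcripts with insufficient RNA-seq or Ribo-seq coverage.

    Retains exactly the transcripts with ``rna_count >= min_rna_count`` and
    ``rpf_count >= min_rpf_count``.  Returns the surviving list plus a report
    ``{"n_in": ..., "n_out": ...}``.
    """
    if min_rna_count < 0 or min_rpf_count < 0:
        raise UtrkitError("coverage thresholds must be >= 0")
    kept = [
        q
        for q in quants
        if q.rna_count >= min_rna_count and q.rpf_count >= min_rpf_count
    ]
    return kept, {"n_in": len(quants), "n_out": len(kept)}


def quantify(
    rna_counts: pd.Series,
    rpf_counts: pd.Series,
    lengths: pd.Series,
    min_rna_count: int = 10,
    min_rpf_count: int = 10,
) -> pd.DataFrame:
    """Full TE quantification table for one cell type / tissue.

    Inputs are per-transcript RNA-seq counts, Ribo-seq (RPF) counts, and
    transcript lengths in nt, all indexed by transcript id.  Output columns:
    rna_count, rpf_count, rna_rpkm, rpf_rpkm, te, pass_filter.
    """
    idx = lengths.index
    if not (rna_counts.index.equals(idx) and rpf_counts.index.equals(idx)):
        rna_counts = rna_counts.reindex(idx)
        rpf_counts = rpf_counts.reindex(idx)
        if rna_counts.isna().any() or rpf_counts.isna().any():
            raise UtrkitError("count tables do not cover all transcripts")
    if (lengths <= 0).any():
        bad = idx[lengths <= 0][0]
        raise UtrkitError(f"non-positive length for transcript {bad!r}")
    rna_total = int(rna_counts.sum())
    rpf_total = int(rpf_counts.sum())
    if rna_total <= 0 or rpf_total <= 0:
        raise UtrkitError("each library must contain at least one read")
    kb = lengths.to_numpy(float) / 1e3
    rna_rpkm = rna_counts.to_numpy(float) / kb / (rna_total / 1e6)
    rpf_rpkm = rpf_counts.to_numpy(float) / kb / (rpf_total / 1e6)
    with np.errstate(divide="ignore", invalid="ignore"):
        te = np.where(rna_rpkm > 0, rpf_rpkm / rna_rpkm, np.nan)
    pass_filter = (rna_counts.to_numpy() >= min_rna_count) & (
        rpf_counts.to_numpy() >= min_rpf_count
    )
    return pd.DataFrame(
        {
            "rna_count": rna_counts.astype("int64"),
            "rpf_count": rpf_counts.astype("int64"),
            "rna_rpkm": rna_rpkm,
            "rpf_rpkm": rpf_rpkm,
            "te": te,
            "pass_filter": pass_filter,
        },
        index=idx,
    )
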
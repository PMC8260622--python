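"""Standardize 5' UTRs into 100-bp AUG-free library members.

A fixed diversity-region length of 100 bp is used throughout (the ceiling of
array-based oligo synthesis).  Longer natural UTRs contribute two variants
(their 5'-most and 3'-most 100 bp); shorter ones are padded at the 5' end
with repeats of the structure-free CAA motif, in two pad phases shifted by
one nucleotide.  Padding is placed at the 5' end so the native sequence stays
adjacent to the Kozak/CDS junction.  All ATG trinucleotides are removed by
random single-nucleotide substitution so the library introduces no upstream
start codons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .io import (
    FLANK_LEN,
    LIBRARY_UTR_LEN,
    UtrRecord,
    UtrkitError,
    VALID_BASES,
)

_BASES = "ACGT"
_CAA = "CAA"

#: cardinality of the two GA-designed library subsets
DESIGN_SET_SIZES = {"synthetic_high_te": 2388, "synthetic_test": 1198}


@dataclass
class PanelSpec:
    """Per-context natural-panel selection sizes.

    ``hek293t`` and ``pc3`` are (n_top, n_bottom) by TE; ``muscle_te`` is a
    top-n by TE; ``muscle_mrna`` is a top-n by mRNA expression level.
    """

    hek293t: tuple[int, int] = (1505, 937)
    pc3: tuple[int, int] = (1692, 756)
    muscle_te: int = 1831
    muscle_mrna: int = 1693

    def __post_init__(self) -> None:
        sizes = [*self.hek293t, *self.pc3, self.muscle_te, self.muscle_mrna]
        if any(n < 0 for n in sizes):
            raise UtrkitError("panel sizes must be >= 0")

    def total(self) -> int:
        return (
            sum(self.hek293t) + sum(self.pc3) + self.muscle_te + self.muscle_mrna
        )


DEFAULT_PANEL = PanelSpec()


def library_composition(
    panel: PanelSpec = DEFAULT_PANEL,
    design_sizes: Mapping[str, int] | None = None,
) -> dict[str, int]:
    """Counts of natural / synthetic / total library members."""
    if design_sizes is None:
        design_sizes = DESIGN_SET_SIZES
    natural = panel.total()
    synthetic = sum(design_sizes.values())
    return {
        "natural": natural,
        "synthetic": synthetic,
        "total": natural + synthetic,
    }


def _check_dna(seq: str, what: str = "sequence") -> str:
    seq = seq.upper()
    if not seq:
        raise UtrkitError(f"empty {what}")
    bad = set(seq) - VALID_BASES
    if bad:
        raise UtrkitError(f"{what} has invalid bases {sorted(bad)}")
    return seq


def caa_pad(length: int, phase: int = 0) -> str:
    """``length`` characters of the repeating CAA motif starting at ``phase``."""
    if length < 0:
        raise UtrkitError("pad length must be >= 0")
    reps = _CAA * (length // 3 + 2)
    return reps[phase : phase + length]


def standardize_utr(seq: str, target_len: int = LIBRARY_UTR_LEN) -> list[str]:
    """Return the 1-2 fixed-length variants of a raw 5' UTR.

    Exactly ``target_len`` long input -> [unchanged].  Longer -> the
    ``target_len`` prefix and suffix.  Shorter -> two 5'-CAA-padded versions
    whose pads are phase-shifted by one nucleotide.  Sequences shorter than
    3 nt are rejected as degenerate.
    """
    seq = _check_dna(seq)
    if target_len < 3:
        raise UtrkitError("target_len must be >= 3")
    if len(seq) < 3:
        raise UtrkitError(f"sequence too short to standardize ({len(seq)} nt)")
    n = len(seq)
    if n == target_len:
        return [seq]
    if n > target_len:
        return [seq[:target_len], seq[-target_len:]]
    pad = target_len - n
    return [caa_pad(pad, 0) + seq, caa_pad(pad, 1) + seq]


def count_atg(seq: str) -> int:
    """Number of (possibly overlapping) ATG occurrences."""
    count = 0
    start = seq.find("ATG")
    while start != -1:
        count += 1
        start = seq.find("ATG", start + 1)
    return count


def strip_augs(seq: str, rng: np.random.Generator) -> str:
    """Remove every ATG by randomly mutating one of its three nucleotides.

    Scans left to right; at each leftmost ATG occurrence a position in the
    triplet and a replacement base are drawn uniformly (9 single-substitution
    variants), and the draw is repeated until the candidate strictly reduces
    the total ATG count — substituting C at the T position always does, so
    the loop terminates.  Length is preserved; deterministic under a fixed
    rng state.
    """
    seq = _check_dna(seq)
    chars = list(seq)
    current = count_atg(seq)
    while current > 0:
        i = "".join(chars).find("ATG")
        while True:
            pos = i + int(rng.integers(3))
            old = chars[pos]
            alt = [b for b in _BASES if b != old]
            new = alt[int(rng.integers(3))]
            candidate = chars.copy()
            candidate[pos] = new
            cand_count = count_atg("".join(candidate))
            if cand_count < current:
                chars = candidate
                current = cand_count
                break
    return "".join(chars)


def select_natural_panels(
    te_tables: Mapping[str, pd.DataFrame],
    mrna_table: pd.DataFrame,
    spec: PanelSpec = DEFAULT_PANEL,
) -> pd.DataFrame:
    """Select the natural 5' UTR panels from quantified transcript tables.

    ``te_tables`` maps context ("HEK293T", "PC3", "muscle_te") to a table
    with columns ``transcript_id`` and ``te`` (already coverage-filtered);
    ``mrna_table`` has ``transcript_id`` and ``level`` for the muscle mRNA
    panel.  Per context the top-n by TE descending and (for HEK293T/PC3)
    bottom-n by TE ascending are taken, top and bottom disjoint; the
    muscle_mrna panel is top-n by expression level.  Ties break by
    lexicographic transcript_id for reproducibility.

    Returns a table with columns transcript_id, origin_context, panel
    ("top"/"bottom"), metric.
    """
    plan = {
        "HEK293T": spec.hek293t,
        "PC3": spec.pc3,
        "muscle_te": (spec.muscle_te, 0),
    }
    rows: list[pd.DataFrame] = []
    for context, (n_top, n_bottom) in plan.items():
        if context not in te_tables:
            raise UtrkitError(f"missing TE table for context {context!r}")
        table = te_tables[context]
        sub = _take_panel(table, "te", n_top, n_bottom, context)
        sub["origin_context"] = context
        rows.append(sub)
    mrna = mrna_table.rename(columns={"level": "te"})
    sub = _take_panel(mrna, "te", spec.muscle_mrna, 0, "muscle_mrna")
    sub["origin_context"] = "muscle_mrna"
    rows.append(sub)
    cols = ["transcript_id", "origin_context", "panel", "metric"]
    rows = [r for r in rows if len(r)]
    if not rows:
        return pd.DataFrame(columns=cols)
    return pd.concat(rows, ignore_index=True)[cols]


def _take_panel(
    table: pd.DataFrame, metric: str, n_top: int, n_bottom: int, context: str
) -> pd.DataFrame:
    if metric not in table.columns or "transcript_id" not in table.columns:
        raise UtrkitError(
            f"context {context!r}: table needs transcript_id and {metric!r}"
        )
    clean = table.dropna(subset=[metric])
    if n_top + n_bottom > len(clean):
        raise UtrkitError(
            f"context {context!r}: requested {n_top}+{n_bottom} panels but "
            f"only {len(clean)} transcripts available"
        )
    ordered = clean.sort_values(
        [metric, "transcript_id"], ascending=[False, True], kind="mergesort"
    )
    top = ordered.head(n_top)
    rest = ordered.iloc[n_top:]
    bottom = rest.sort_values(
        [metric, "transcript_id"], ascending=[True, True], kind="mergesort"
    ).head(n_bottom)
    frames = []
    for sub, panel in ((top, "top"), (bottom, "bottom")):
        if len(sub):
            frames.append(
                pd.DataFrame(
                    {
                        "transcript_id": sub["transcript_id"].to_numpy(),
                        "panel": panel,
                        "metric": sub[metric].to_numpy(),
                    }
                )
            )
    if not frames:
        return pd.DataFrame(columns=["transcript_id", "panel", "metric"])
    return pd.concat(frames, ignore_index=True)


def panels_to_records(
    panels: pd.DataFrame,
    utr_seqs: Mapping[str, str],
    rng: np.random.Generator,
    target_len: int = LIBRARY_UTR_LEN,
) -> list[UtrRecord]:
    """Standardize selected panel transcripts into library UtrRecords.

    Each transcript contributes its 1-2 standardized, AUG-free variants,
    suffixed ``.v0``/``.v1`` when there are two.
    """
    records: list[UtrRecord] = []
    for _, row in panels.iterrows():
        tid = row["transcript_id"]
        if tid not in utr_seqs:
            raise UtrkitError(f"no UTR sequence for transcript {tid!r}")
        variants = standardize_utr(utr_seqs[tid], target_len)
        for v, var in enumerate(variants):
            clean = strip_augs(var, rng)
            name = tid if len(variants) == 1 else f"{tid}.v{v}"
            records.append(
                UtrRecord(
                    id=name,
                    sequence=clean,
                    source="natural",
                    origin_context=row["origin_context"],
                    notes=f"panel={row['panel']}",
                )
            )
    return records


def build_oligo(utr: UtrRecord, left_flank: str, right_flank: str) -> str:
    """Assemble the 140-mer synthesis oligo: 20-nt flank + 100-nt UTR + 20-nt flank."""
    left = _check_dna(left_flank, "left flank")
    right = _check_dna(right_flank, "right flank")
    if len(left) != FLANK_LEN or len(right) != FLANK_LEN:
        raise UtrkitError("flanks must be exactly 20 nt")
    if len(utr.sequence) != LIBRARY_UTR_LEN:
        raise UtrkitError(
            f"oligo insert must be {LIBRARY_UTR_LEN} nt, got {len(utr.sequence)}"
        )
    return left + utr.sequence + right


def extract_insert(oligo: str, left_flank: str, right_flank: str) -> str:
    """Inverse of build_oligo: recover the 100-nt insert, checking both flanks."""
    oligo = _check_dna(oligo, "oligo")
    want = 2 * FLANK_LEN + LIBRARY_UTR_LEN
    if len(oligo) != want:
        raise UtrkitError(f"oligo must be {want} nt, got {len(oligo)}")
    if not oligo.startswith(left_flank.upper()):
        raise UtrkitError("oligo does not start with the left flank")
    if not oligo.endswith(right_flank.upper()):
        raise UtrkitError("oligo does not end with the right flank")
    return oligo[FLANK_LEN : FLANK_LEN + LIBRARY_UTR_LEN]


def combine_utrs(
    a: UtrRecord, b: UtrRecord, linker: str = "CAACAA"
) -> UtrRecord:
    """Join two standardized members head-to-tail with a linker (default CAACAA).

    Order-sensitive: combine(a, b) places ``a`` at the 5' end.  The default
    linker yields a 206-nt combinatorial member.
    """
    for rec in (a, b):
        if len(rec.sequence) != LIBRARY_UTR_LEN:
            raise UtrkitError(
                f"combine_utrs needs standardized {LIBRARY_UTR_LEN}-nt members;"
                f" {rec.id!r} is {len(rec.sequence)} nt"
            )
    if linker:
        linker = _check_dna(linker, "linker")
    return UtrRecord(
        id=f"{a.id}-{b.id}",
        sequence=a.sequence + linker + b.sequence,
        source="combinatorial",
        origin_context="designed",
        notes=f"combined={a.id}+{b.id}",
    )
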
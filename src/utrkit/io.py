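"""Readers and writers for the formats the toolkit touches.

Sequences are DNA over {A,C,G,T} and are normalized to uppercase on read.
Count tables are TSV with a header row of sample names and the UTR/transcript
id in the first column; counts are stored as 64-bit integers and normalized
counts live in separate float tables, never overwriting raw counts.  Any
interval coordinates emitted by this package are 0-based half-open.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

VALID_BASES = frozenset("ACGT")

UTR_SOURCES = ("natural", "synthetic_high_te", "synthetic_test", "combinatorial")
ORIGIN_CONTEXTS = ("HEK293T", "PC3", "muscle_te", "muscle_mrna", "designed")

#: standardized library members are exactly this long
LIBRARY_UTR_LEN = 100
#: combinatorial members: two 100-mers joined by the 6-nt CAACAA linker
COMBINATORIAL_UTR_LEN = 206
FLANK_LEN = 20


class UtrkitError(Exception):
    """Base class for toolkit errors."""


class ParseError(UtrkitError):
    """Malformed input file; message names the offending line."""


@dataclass
class UtrRecord:
    """One library member: a fixed-length, AUG-free 5' UTR sequence."""

    id: str
    sequence: str
    source: str = "natural"
    origin_context: str = "designed"
    notes: str = ""

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.id:
            raise UtrkitError("UtrRecord id must be non-empty")
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise UtrkitError(
                f"UtrRecord {self.id!r}: invalid bases {sorted(bad)}"
            )
        if self.source not in UTR_SOURCES:
            raise UtrkitError(
                f"UtrRecord {self.id!r}: unknown source {self.source!r}"
            )
        if self.origin_context not in ORIGIN_CONTEXTS:
            raise UtrkitError(
                f"UtrRecord {self.id!r}: unknown origin_context "
                f"{self.origin_context!r}"
            )

    def validate_library_standard(self) -> None:
        """Enforce the library invariants: fixed length and no ATG."""
        want = (
            COMBINATORIAL_UTR_LEN
            if self.source == "combinatorial"
            else LIBRARY_UTR_LEN
        )
        if len(self.sequence) != want:
            raise UtrkitError(
                f"UtrRecord {self.id!r}: length {len(self.sequence)} != {want}"
            )
        if "ATG" in self.sequence:
            raise UtrkitError(f"UtrRecord {self.id!r}: contains ATG")


@dataclass
class LibraryManifest:
    """A 5' UTR library plus the two 20-nt PCR-priming flanks.

    The synthesized oligo for a standard member is
    ``left_flank + sequence + right_flank`` (20 + 100 + 20 = 140 nt).
    """

    records: list[UtrRecord] = field(default_factory=list)
    left_flank: str = "GTTCAGAGTTCTACAGTCCG"
    right_flank: str = "GCCACCATGGTGAGCAAGGG"

    def __post_init__(self) -> None:
        self.left_flank = self.left_flank.upper()
        self.right_flank = self.right_flank.upper()
        for fl, name in ((self.left_flank, "left"), (self.right_flank, "right")):
            if len(fl) != FLANK_LEN or set(fl) - VALID_BASES:
                raise UtrkitError(f"{name} flank must be 20 nt of ACGT")
        ids = [r.id for r in self.records]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})[:5]
            raise UtrkitError(f"duplicate UtrRecord ids: {dupes}")

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def oligo_length(self, record: UtrRecord) -> int:
        return 2 * FLANK_LEN + len(record.sequence)


# ---------------------------------------------------------------------------
# FASTA
#
# Hand-written so parse errors can name the offending line number, which the
# error contract requires.

def read_fasta(path: str | Path | _io.TextIOBase) -> list[tuple[str, str]]:
    """Read a FASTA file into ordered (id, sequence) pairs.

    Sequences are uppercased.  Malformed headers or empty sequences raise
    :class:`ParseError` naming the line number.
    """
    close = False
    if isinstance(path, (str, Path)):
        handle = open(path)
        close = True
    else:
        handle = path
    records: list[tuple[str, str]] = []
    name: str | None = None
    chunks: list[str] = []
    header_line = 0
    try:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    if not chunks:
                        raise ParseError(
                            f"line {header_line}: record {name!r} has an "
                            "empty sequence"
                        )
                    records.append((name, "".join(chunks)))
                name = line[1:].split()[0] if len(line) > 1 else ""
                if not name:
                    raise ParseError(f"line {lineno}: empty FASTA header")
                header_line = lineno
                chunks = []
            else:
                if name is None:
                    raise ParseError(
                        f"line {lineno}: sequence before first FASTA header"
                    )
                chunks.append(line.upper())
        if name is not None:
            if not chunks:
                raise ParseError(
                    f"line {header_line}: record {name!r} has an empty sequence"
                )
            records.append((name, "".join(chunks)))
    finally:
        if close:
            handle.close()
    return records


def write_fasta(
    records: Iterable[tuple[str, str]], path: str | Path, width: int = 60
) -> None:
    """Write (id, sequence) pairs as FASTA; round-trips with read_fasta."""
    with open(path, "w") as fh:
        for name, seq in records:
            seq = seq.upper()
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# FASTQ (read-only; screen reads)

def read_fastq(path: str | Path) -> Iterator[tuple[str, str, str]]:
    """Yield (id, sequence, quality) tuples from a FASTQ file.

    Truncated records raise :class:`ParseError`.
    """
    try:
        with open(path) as fh:
            for title, seq, qual in FastqGeneralIterator(fh):
                yield title.split()[0], seq.upper(), qual
    except ValueError as exc:  # biopython signals truncation with ValueError
        raise ParseError(f"{path}: {exc}") from exc


def write_fastq(
    reads: Iterable[tuple[str, str, str]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        for name, seq, qual in reads:
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# Count tables

def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    """Read a UTR/transcript x sample integer count table.

    First column is the feature id; remaining columns are samples.  Missing
    cells and non-integer counts are errors, never silent zeros.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.has_duplicates:
        dupes = sorted(df.index[df.index.duplicated()].unique()[:5])
        raise ParseError(f"{path}: duplicate ids {dupes}")
    if df.isna().any().any():
        col = df.columns[df.isna().any()][0]
        raise ParseError(f"{path}: missing count in column {col!r}")
    out = {}
    for col in df.columns:
        try:
            vals = pd.to_numeric(df[col])
        except ValueError as exc:
            raise ParseError(f"{path}: non-integer count in {col!r}: {exc}")
        if not (vals == vals.round()).all():
            bad = df.index[vals != vals.round()][0]
            raise ParseError(
                f"{path}: non-integer count for {bad!r} in column {col!r}"
            )
        if (vals < 0).any():
            bad = df.index[vals < 0][0]
            raise ParseError(f"{path}: negative count for {bad!r} in {col!r}")
        out[col] = vals.astype("int64")
    res = pd.DataFrame(out, index=df.index)
    res.index.name = df.index.name or "id"
    return res


def write_counts_tsv(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t")


def write_table_tsv(table: pd.DataFrame, path: str | Path, float_format="%.6g"):
    """Write a float-valued result table (normalized counts, stats, ...)."""
    table.to_csv(path, sep="\t", float_format=float_format)


# ---------------------------------------------------------------------------
# Library manifest TSV

_MANIFEST_COLS = ["id", "source", "origin_context", "sequence", "notes"]


def write_manifest(manifest: LibraryManifest, path: str | Path) -> None:
    """Write a manifest TSV with flanks recorded as header comments."""
    with open(path, "w") as fh:
        fh.write(f"#left_flank={manifest.left_flank}\n")
        fh.write(f"#right_flank={manifest.right_flank}\n")
        fh.write("\t".join(_MANIFEST_COLS) + "\n")
        for r in manifest.records:
            fh.write(
                "\t".join(
                    [r.id, r.source, r.origin_context, r.sequence, r.notes]
                )
                + "\n"
            )


def read_manifest(path: str | Path) -> LibraryManifest:
    flanks = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, val = line[1:].strip().partition("=")
            flanks[key] = val
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh, sep="\t", dtype=str).fillna("")
    missing = [c for c in _MANIFEST_COLS[:-1] if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: manifest missing columns {missing}")
    records = [
        UtrRecord(
            id=row["id"],
            sequence=row["sequence"],
            source=row["source"],
            origin_context=row["origin_context"],
            notes=row.get("notes", ""),
        )
        for _, row in df.iterrows()
    ]
    kwargs = {}
    if "left_flank" in flanks:
        kwargs["left_flank"] = flanks["left_flank"]
    if "right_flank" in flanks:
        kwargs["right_flank"] = flanks["right_flank"]
    return LibraryManifest(records=records, **kwargs)
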
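"""Synthetic data with known ground truth for every toolkit stage.

Three generators emulate the toolkit's real inputs:

* :func:`simulate_transcriptome` — natural transcripts (random 5' UTRs of
  30-300 nt with uniform base composition plus an ATG-led CDS);
* :func:`simulate_ribo_rna` — paired RNA-seq / Ribo-seq count tables where
  true log2 TE is a planted linear function of k-mer frequencies plus
  Gaussian noise and counts are negative-binomial at a chosen depth;
* :func:`simulate_screen` — a FACS-bin sort-seq screen in which each cell
  carries one single-copy UTR (mirroring recombinase integration), cell
  fluorescence is lognormal around the UTR's true strength, cells are ranked
  into the top 2.5% / 2.5-5% / 5-10% bins (floor rounding; the unsorted bin
  is all cells), and reads are drawn multinomially from bin compositions.

All generators are pure functions of (parameters, seed); the returned truth
tables carry every planted quantity so recovery can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import LibraryManifest, UtrkitError, write_fastq
from .features import kmer_frequencies

_BASES = np.frombuffer(b"ACGT", dtype="S1")

BIN_FRACTIONS = (0.025, 0.025, 0.05)
SCREEN_BINS = ("top2.5", "top2.5_5", "top5_10", "unsorted")
#: screening guidance: keep >= 25 integrated cells per library member
MIN_COVERAGE_FOLD = 25


@dataclass
class SimTruth:
    """Ground truth planted by a simulator, serialized beside its dataset."""

    kind: str
    seed: int
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    params: dict = field(default_factory=dict)

    def write(self, prefix: str) -> None:
        for name, table in self.tables.items():
            table.to_csv(f"{prefix}.{name}.tsv", sep="\t")


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def simulate_transcriptome(
    n: int,
    utr_len_dist: tuple[int, int] = (30, 300),
    seed: int = 0,
    cds_len: int = 60,
) -> pd.DataFrame:
    """Random transcripts: uniform-composition 5' UTRs plus an ATG-led CDS.

    UTR lengths are uniform on [min, max]; the CDS starts with ATG and is at
    least 15 nt so the start-codon context is always available.  Columns:
    transcript_id, utr_seq, cds_seq, length_nt (UTR + CDS).
    """
    lo, hi = utr_len_dist
    if lo > hi:
        raise UtrkitError(f"utr_len_dist min {lo} > max {hi}")
    if n < 1:
        raise UtrkitError("n must be >= 1")
    if cds_len < 15:
        raise UtrkitError("cds_len must be >= 15")
    rng = np.random.default_rng(seed)
    width = len(str(n - 1))
    rows = []
    for i in range(n):
        ulen = int(rng.integers(lo, hi + 1))
        utr = _random_seq(rng, ulen)
        cds = "ATG" + _random_seq(rng, cds_len - 3)
        rows.append(
            {
                "transcript_id": f"tx{i:0{width}d}",
                "utr_seq": utr,
                "cds_seq": cds,
                "length_nt": ulen + cds_len,
            }
        )
    return pd.DataFrame(rows)


def default_te_weights(seed: int = 0, n_kmers: int = 8, scale: float = 36.0
                       ) -> dict[str, float]:
    """A planted k-mer weight map: random 3-mers with +-scale weights.

    A 3-mer frequency has SD ~ sqrt(p(1-p)/windows) ~ 0.01 across random
    UTRs (p = 1/64, ~165 windows), so ``n_kmers`` independent terms give the
    planted log2-TE signal an SD of ~ sqrt(n_kmers) * scale * 0.01 ~ 1 log2
    unit at the defaults — matching the few-fold TE spread of natural
    transcripts.
    """
    rng = np.random.default_rng(seed)
    from .features import kmer_words

    words = kmer_words(3)
    picks = rng.choice(len(words), size=n_kmers, replace=False)
    signs = rng.choice([-1.0, 1.0], size=n_kmers)
    return {words[int(i)]: float(s * scale) for i, s in zip(picks, signs)}


def planted_log2_te(utr: str, weights: dict[str, float]) -> float:
    """The noise-free planted signal: sum of weight x k-mer frequency."""
    ks = {len(w) for w in weights}
    freqs = kmer_frequencies(utr, ks)
    return sum(
        w * freqs[f"{len(kmer)}mer_{kmer}"] for kmer, w in weights.items()
    )


def _nb_counts(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float
) -> np.ndarray:
    """NB(mean, alpha) via gamma-Poisson; alpha=0 degenerates to Poisson."""
    if dispersion < 0:
        raise UtrkitError("dispersion must be >= 0")
    if dispersion == 0:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion)
    return rng.poisson(lam)


def simulate_ribo_rna(
    transcripts: pd.DataFrame,
    weights: dict[str, float] | None = None,
    noise_sd: float | None = None,
    snr: float = 2.0,
    depth: int = 1_000_000,
    dispersion: float = 0.1,
    mrna_sd: float = 1.0,
    seed: int = 0,
) -> tuple[pd.Series, pd.Series, SimTruth]:
    """Paired RNA-seq / Ribo-seq counts with planted TE.

    True log2 TE = sum(weights x k-mer frequencies of the UTR) +
    Normal(0, noise_sd); when ``noise_sd`` is None it is set to
    sd(signal)/snr over the cohort (default signal-to-noise 2:1).  mRNA
    levels are lognormal (sd ``mrna_sd`` in log2).  RNA counts are
    NB(mean proportional to mRNA x length x depth, dispersion); RPF counts
    are NB(mean proportional to mRNA x TE x length, dispersion) at the same
    depth.
    """
    if depth <= 0:
        raise UtrkitError("depth must be > 0")
    rng = np.random.default_rng(seed)
    if weights is None:
        weights = default_te_weights(seed)
    utrs = transcripts["utr_seq"].to_list()
    signal = np.array([planted_log2_te(u, weights) for u in utrs])
    signal = signal - signal.mean()
    if noise_sd is None:
        sd = float(signal.std())
        noise_sd = sd / snr if sd > 0 else 0.0
    log2_te = signal + rng.normal(0.0, noise_sd, size=len(utrs))
    te = np.exp2(log2_te)
    mrna = np.exp2(rng.normal(0.0, mrna_sd, size=len(utrs)))
    lengths = transcripts["length_nt"].to_numpy(float)

    rna_rate = mrna * lengths
    rna_mean = depth * rna_rate / rna_rate.sum()
    rpf_rate = mrna * te * lengths
    rpf_mean = depth * rpf_rate / rpf_rate.sum()
    idx = pd.Index(transcripts["transcript_id"], name="transcript_id")
    rna = pd.Series(_nb_counts(rng, rna_mean, dispersion), index=idx,
                    name="rna", dtype="int64")
    rpf = pd.Series(_nb_counts(rng, rpf_mean, dispersion), index=idx,
                    name="rpf", dtype="int64")
    truth = SimTruth(
        kind="ribo_rna",
        seed=seed,
        tables={
            "truth": pd.DataFrame(
                {"true_te": te, "true_log2_te": log2_te, "true_mrna": mrna,
                 "signal": signal},
                index=idx,
            ),
            "weights": pd.DataFrame(
                {"weight": pd.Series(weights)}
            ).rename_axis("kmer"),
        },
        params={
            "noise_sd": float(noise_sd),
            "snr": snr,
            "depth": depth,
            "dispersion": dispersion,
        },
    )
    return rna, rpf, truth


def simulate_screen(
    manifest: LibraryManifest,
    strengths: pd.Series,
    bin_fractions: tuple[float, float, float] = BIN_FRACTIONS,
    n_cells: int | None = None,
    depth: int = 200_000,
    replicates: int = 2,
    cell_noise_sd: float = 0.5,
    seed: int = 0,
    fastq_dir: str | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, SimTruth]:
    """Simulate a FACS-bin sort-seq screen of the library.

    Each of ``n_cells`` cells per replicate carries one uniformly drawn UTR
    (single-copy, as with recombinase integration).  ``n_cells`` models the
    sorted, post-expansion population — default 500 x library size, the
    scale at which simulated replicate correlations match the
    reproducibility of recombinase-mediated screens; founder coverage below
    25 x library still warns.  A cell's log fluorescence is
    Normal(log strength, cell_noise_sd).  Cells are ranked and the top
    fractions define the three top bins, with floor(fraction x n_cells)
    cells per bin (the unsorted bin is all cells).  ``depth`` reads per
    (bin, replicate) are drawn multinomially from the bin's cell
    composition.  Returns (counts, metadata, truth); when ``fastq_dir`` is
    set, flanked 140-nt reads are also written as one FASTQ per sample.
    """
    if sum(bin_fractions) > 1:
        raise UtrkitError("top bin fractions must sum to <= 1")
    if replicates < 1:
        raise UtrkitError("need >= 1 replicate")
    ids = manifest.ids
    if n_cells is None:
        n_cells = 500 * len(ids)
    strengths = strengths.reindex(ids)
    if strengths.isna().any():
        raise UtrkitError("strengths must cover every manifest id")
    if (strengths <= 0).any():
        raise UtrkitError("strengths must be positive")
    if n_cells < MIN_COVERAGE_FOLD * len(ids):
        import warnings

        warnings.warn(
            f"n_cells={n_cells} is below {MIN_COVERAGE_FOLD}-fold coverage "
            f"of the {len(ids)}-member library",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    log_strength = np.log(strengths.to_numpy(float))
    counts: dict[str, np.ndarray] = {}
    meta_rows = []
    reads_by_sample: dict[str, np.ndarray] = {}
    for rep in range(1, replicates + 1):
        cell_utr = rng.integers(len(ids), size=n_cells)
        fluor = rng.normal(log_strength[cell_utr], cell_noise_sd)
        order = np.argsort(-fluor, kind="stable")
        start = 0
        bins_cells = {}
        for frac, label in zip(bin_fractions, SCREEN_BINS[:3]):
            width = int(np.floor(frac * n_cells))
            bins_cells[label] = order[start : start + width]
            start += width
        bins_cells["unsorted"] = np.arange(n_cells)
        for label in SCREEN_BINS:
            comp = np.bincount(
                cell_utr[bins_cells[label]], minlength=len(ids)
            ).astype(float)
            if comp.sum() == 0:
                raise UtrkitError(f"bin {label!r} has no cells")
            sample = f"{label}_rep{rep}"
            counts[sample] = rng.multinomial(depth, comp / comp.sum())
            meta_rows.append(
                {"sample": sample, "bin": label, "replicate": f"rep{rep}"}
            )
            reads_by_sample[sample] = counts[sample]
    count_df = pd.DataFrame(counts, index=pd.Index(ids, name="utr_id")).astype(
        "int64"
    )
    metadata = pd.DataFrame(meta_rows).set_index("sample")
    if fastq_dir is not None:
        _write_screen_fastq(manifest, count_df, fastq_dir)
    truth = SimTruth(
        kind="screen",
        seed=seed,
        tables={
            "truth": pd.DataFrame(
                {"strength": strengths.to_numpy(float)},
                index=pd.Index(ids, name="utr_id"),
            )
        },
        params={
            "bin_fractions": list(bin_fractions),
            "n_cells": n_cells,
            "depth": depth,
            "replicates": replicates,
            "cell_noise_sd": cell_noise_sd,
        },
    )
    return count_df, metadata, truth


def _write_screen_fastq(
    manifest: LibraryManifest, counts: pd.DataFrame, fastq_dir: str
) -> None:
    """Expand per-sample counts into flanked 140-nt reads, one FASTQ each."""
    from pathlib import Path

    out = Path(fastq_dir)
    out.mkdir(parents=True, exist_ok=True)
    seq_by_id = {r.id: r.sequence for r in manifest.records}
    for sample in counts.columns:
        reads = []
        i = 0
        for utr_id, n in counts[sample].items():
            full = manifest.left_flank + seq_by_id[utr_id] + manifest.right_flank
            for _ in range(int(n)):
                reads.append((f"{sample}.{i}", full, "I" * len(full)))
                i += 1
        write_fastq(reads, out / f"{sample}.fastq")


def planted_screen_strengths(
    ids: list[str],
    n_enhanced: int = 50,
    fold: float = 2.0,
    seed: int = 0,
) -> tuple[pd.Series, list[str]]:
    """Baseline-1 strengths with ``n_enhanced`` members planted at ``fold``."""
    rng = np.random.default_rng(seed)
    strengths = pd.Series(1.0, index=pd.Index(ids, name="utr_id"))
    planted = sorted(
        rng.choice(len(ids), size=n_enhanced, replace=False).tolist()
    )
    planted_ids = [ids[i] for i in planted]
    strengths.loc[planted_ids] = fold
    return strengths, planted_ids
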
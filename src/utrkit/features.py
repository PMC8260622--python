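"""Sequence features for the surrogate expression model.

A 5' UTR plus the first 15 bp of the downstream CDS (the nucleotides
surrounding the start codon) is summarized as:

* k-mer frequencies for each configured k (default k in {1,2,3}, 84 words),
  normalized by window count so scale is length-invariant;
* a folding-energy proxy in kcal/mol (more negative = more predicted
  secondary structure);
* the UTR length in nt;
* the number of upstream AUGs and of complete upstream ORFs (AUG with an
  in-frame stop entirely inside the UTR).

The default folding engine is a self-contained Nussinov-style
maximum-base-pairing dynamic program (Watson-Crick + GU wobble, minimum
hairpin loop of 3 nt) scaled by -1 kcal/mol per pair, so the package needs no
external thermodynamic engine; any callable mapping an RNA string to a float
can be plugged in instead.
"""

from __future__ import annotations

import hashlib
import warnings
from itertools import product
from typing import Callable, Iterable, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .io import UtrkitError, VALID_BASES

_BASES = "ACGT"
MIN_HAIRPIN_LOOP = 3
CDS_CONTEXT_LEN = 15
#: strong Kozak + the first two EGFP codons; default CDS context for designed UTRs
DEFAULT_CDS_CONTEXT = "GCCACCATGGTGAGC"

_STOPS = ("TAA", "TAG", "TGA")

try:  # numba accelerates the O(n^3) DP; plain python fallback stays correct
    from numba import njit as _njit
except ImportError:  # pragma: no cover
    def _njit(*args, **kwargs):
        def wrap(fn):
            return fn

        return wrap if not (args and callable(args[0])) else args[0]


def kmer_words(k: int) -> list[str]:
    """All 4^k DNA words of length k in lexicographic order."""
    return ["".join(p) for p in product(_BASES, repeat=k)]


def kmer_frequencies(
    seq: str, k_set: Iterable[int] = (1, 2, 3)
) -> dict[str, float]:
    """Window-normalized k-mer frequencies with all 4^k words present.

    For each k, f_k(w) = count(w) / (len(seq) - k + 1); the frequencies of
    each k sum to 1 when len(seq) >= k, otherwise they are all zero (with a
    warning).
    """
    seq = seq.upper()
    bad = set(seq) - VALID_BASES
    if bad:
        raise UtrkitError(f"invalid bases {sorted(bad)}")
    out: dict[str, float] = {}
    for k in sorted(set(int(k) for k in k_set)):
        if k < 1:
            raise UtrkitError("k must be >= 1")
        words = kmer_words(k)
        n_windows = len(seq) - k + 1
        if n_windows < 1:
            warnings.warn(
                f"sequence shorter than k={k}; emitting zero frequencies",
                stacklevel=2,
            )
            out.update({f"{k}mer_{w}": 0.0 for w in words})
            continue
        counts = dict.fromkeys(words, 0)
        for i in range(n_windows):
            counts[seq[i : i + k]] += 1
        out.update(
            {f"{k}mer_{w}": counts[w] / n_windows for w in words}
        )
    return out


def count_uorfs(seq: str) -> tuple[int, int]:
    """(number of AUGs, number of AUGs with an in-frame stop inside seq).

    Overlapping AUGs are counted; a uORF requires a TAA/TAG/TGA codon in
    frame with the AUG and entirely within the sequence.
    """
    seq = seq.upper()
    n_uaug = 0
    n_uorf = 0
    start = seq.find("ATG")
    while start != -1:
        n_uaug += 1
        for pos in range(start + 3, len(seq) - 2, 3):
            if seq[pos : pos + 3] in _STOPS:
                n_uorf += 1
                break
        start = seq.find("ATG", start + 1)
    return n_uaug, n_uorf


# ---------------------------------------------------------------------------
# Folding energy

@_njit(cache=False)
def _nussinov_dp(codes: np.ndarray) -> int:  # pragma: no cover - numba path
    n = codes.shape[0]
    table = np.zeros((n, n), dtype=np.int32)
    for span in range(1, n):
        for i in range(0, n - span):
            j = i + span
            best = table[i + 1, j]
            if table[i, j - 1] > best:
                best = table[i, j - 1]
            if span > MIN_HAIRPIN_LOOP:
                s = codes[i] + codes[j]
                if s == 3 or s == 5:  # AU/UA, CG/GC (=3) and GU/UG (=5)
                    cand = table[i + 1, j - 1] + 1
                    if cand > best:
                        best = cand
            for k in range(i + 1, j):
                cand = table[i, k] + table[k + 1, j]
                if cand > best:
                    best = cand
            table[i, j] = best
    return int(table[0, n - 1])


_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}


def max_base_pairs(seq: str) -> int:
    """Maximum number of nested WC/GU pairs with hairpin loops >= 3 nt."""
    seq = seq.upper()
    if len(seq) < 2:
        return 0
    try:
        codes = np.array([_CODE[b] for b in seq], dtype=np.int8)
    except KeyError as exc:
        raise UtrkitError(f"invalid base {exc.args[0]!r}") from exc
    return _nussinov_dp(codes)


def folding_energy(seq: str, engine: str | Callable[[str], float] = "nussinov") -> float:
    """Folding-energy proxy in kcal/mol (always <= 0).

    ``engine="nussinov"`` (default) scores -1.0 kcal/mol per base pair of the
    maximum nested pairing.  A callable engine receives the RNA string
    (T already transcribed to U) and must return a float <= 0.
    """
    rna = seq.upper().replace("T", "U")
    if callable(engine):
        val = float(engine(rna))
        if val > 0:
            raise UtrkitError("external folding engine returned energy > 0")
        return val
    if engine in ("nussinov", "nussinov_default"):
        return -1.0 * max_base_pairs(seq)
    raise UtrkitError(f"unknown folding engine {engine!r}")


# ---------------------------------------------------------------------------
# Full feature vectors

def feature_names(k_set: Sequence[int] = (1, 2, 3)) -> list[str]:
    names: list[str] = []
    for k in sorted(set(int(k) for k in k_set)):
        names.extend(f"{k}mer_{w}" for w in kmer_words(k))
    names.extend(["mfe", "utr_length", "n_uaug", "n_uorf"])
    return names


def schema_hash(k_set: Sequence[int], engine: str | Callable) -> str:
    """Stable hash of the feature schema (names + folding engine)."""
    engine_tag = engine if isinstance(engine, str) else getattr(
        engine, "__name__", "callable"
    )
    payload = "|".join(feature_names(k_set)) + f"|engine={engine_tag}"
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def featurize(
    utr: str,
    cds_context: str = DEFAULT_CDS_CONTEXT,
    k_set: Sequence[int] = (1, 2, 3),
    engine: str | Callable[[str], float] = "nussinov",
) -> dict[str, float]:
    """Feature map for one UTR given its 15-bp CDS context.

    k-mers and folding energy are computed on the UTR + CDS-context
    concatenation (the region surrounding the start codon); UTR length and
    uORF counts are computed on the UTR alone.  Pure function: repeated calls
    are identical.
    """
    cds_context = cds_context.upper()
    if len(cds_context) != CDS_CONTEXT_LEN:
        raise UtrkitError(
            f"cds_context must be {CDS_CONTEXT_LEN} nt, got {len(cds_context)}"
        )
    utr = utr.upper()
    full = utr + cds_context
    feats = kmer_frequencies(full, k_set)
    feats["mfe"] = folding_energy(full, engine)
    feats["utr_length"] = float(len(utr))
    n_uaug, n_uorf = count_uorfs(utr)
    feats["n_uaug"] = float(n_uaug)
    feats["n_uorf"] = float(n_uorf)
    return feats


class UtrFeaturizer(TransformerMixin, BaseEstimator):
    """Transform 5' UTR sequences into the surrogate model's feature matrix.

    Parameters
    ----------
    k_set : tuple of int, default (1, 2, 3)
        k-mer sizes; 84 k-mer features at the default.
    engine : str or callable, default "nussinov"
        Folding engine; see :func:`folding_energy`.
    cds_context : str
        Default 15-bp CDS context used when X contains bare UTR strings.
        Entries of X may instead be (utr, cds_context) pairs.

    ``transform`` returns an (n_sequences, n_features) float array whose
    columns follow :meth:`get_feature_names_out`.
    """

    def __init__(
        self,
        k_set: tuple[int, ...] = (1, 2, 3),
        engine: str | Callable[[str], float] = "nussinov",
        cds_context: str = DEFAULT_CDS_CONTEXT,
    ):
        self.k_set = k_set
        self.engine = engine
        self.cds_context = cds_context

    def fit(self, X=None, y=None):
        self.feature_names_ = feature_names(self.k_set)
        self.schema_hash_ = schema_hash(self.k_set, self.engine)
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "feature_names_"):
            self.fit()
        rows = np.empty((len(X), len(self.feature_names_)), dtype=float)
        for i, item in enumerate(X):
            if isinstance(item, str):
                utr, cds = item, self.cds_context
            else:
                utr, cds = item
            feats = featurize(utr, cds, self.k_set, self.engine)
            rows[i] = [feats[name] for name in self.feature_names_]
        return rows

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        if not hasattr(self, "feature_names_"):
            self.fit()
        return np.asarray(self.feature_names_, dtype=object)
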
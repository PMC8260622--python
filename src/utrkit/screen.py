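"""Sort-seq screen analysis: counting, normalization, enrichment, hit calls.

Cells carrying single-copy integrations of a 5' UTR-GFP reporter are FACS
sorted into expression bins (top 0-2.5%, 2.5-5%, 5-10%, plus the unsorted
0-100% background) and the UTR inserts in each bin are sequenced.  Reads are
assigned by flank-anchored dictionary matching; counts are normalized with
median-of-ratios size factors; per-bin enrichment over the unsorted bin is
summarized as a log2 ratio and tested with a negative-binomial Wald test
across replicates; hits must clear a fold-change and an adjusted-p threshold
in all three top bins.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .io import LibraryManifest, UtrkitError

BIN_LABELS = ("top2.5", "top2.5_5", "top5_10", "unsorted")
TOP_BINS = ("top2.5", "top2.5_5", "top5_10")

_DISPERSION_FLOOR = 1e-8


# ---------------------------------------------------------------------------
# Read counting

def match_reads(
    reads: Iterable[tuple[str, str, str]],
    manifest: LibraryManifest,
    max_mismatch: int = 0,
) -> tuple[pd.Series, int]:
    """Count reads per library member by flank-anchored insert matching.

    The 20-nt left flank is located exactly in the read; the insert is the
    100 nt that follow and must be chased by the exact right flank.  Inserts
    are matched exactly against the manifest, or within ``max_mismatch``
    substitutions if that match is unique.  Every read lands in exactly one
    of {one UTR, unassigned}; assigned + unassigned == total reads.
    """
    if not manifest.records:
        raise UtrkitError("empty manifest")
    left, right = manifest.left_flank, manifest.right_flank
    insert_len = len(manifest.records[0].sequence)
    lookup = {r.sequence: r.id for r in manifest.records}
    seq_arr = None
    ids = manifest.ids
    counts = dict.fromkeys(ids, 0)
    unassigned = 0
    for _, read, _ in reads:
        pos = read.find(left)
        hit = None
        if pos != -1:
            start = pos + len(left)
            insert = read[start : start + insert_len]
            tail = read[start + insert_len : start + insert_len + len(right)]
            if len(insert) == insert_len and tail == right:
                hit = lookup.get(insert)
                if hit is None and max_mismatch > 0:
                    if seq_arr is None:
                        seq_arr = np.array(
                            [
                                np.frombuffer(r.sequence.encode(), dtype="S1")
                                for r in manifest.records
                            ]
                        )
                    query = np.frombuffer(insert.encode(), dtype="S1")
                    dists = (seq_arr != query).sum(axis=1)
                    close = np.nonzero(dists <= max_mismatch)[0]
                    if len(close) == 1:
                        hit = ids[int(close[0])]
        if hit is None:
            unassigned += 1
        else:
            counts[hit] += 1
    return pd.Series(counts, name="count", dtype="int64"), unassigned


# ---------------------------------------------------------------------------
# Normalization

def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (geometric-mean reference).

    The reference is the per-UTR geometric mean across samples, computed on
    UTRs with no zero count; each sample's factor is the median over those
    UTRs of count / reference.
    """
    mat = counts.to_numpy(dtype=float)
    nonzero = (mat > 0).all(axis=1)
    if not nonzero.any():
        raise UtrkitError(
            "no UTR has nonzero counts in every sample; consider adding a "
            "pseudocount"
        )
    sub = mat[nonzero]
    ref = np.exp(np.log(sub).mean(axis=1))  # per-UTR geometric mean
    factors = np.median(sub / ref[:, None], axis=0)
    return pd.Series(factors, index=counts.columns, name="size_factor")


def normalize_counts(
    counts: pd.DataFrame, factors: pd.Series | None = None
) -> pd.DataFrame:
    if factors is None:
        factors = size_factors(counts)
    return counts.div(factors, axis=1)


def _bin_samples(metadata: pd.DataFrame, bin_label: str) -> pd.Index:
    if bin_label not in set(metadata["bin"]):
        raise UtrkitError(f"bin {bin_label!r} not present in metadata")
    return metadata.index[metadata["bin"] == bin_label]


def log2_enrichment(
    norm: pd.DataFrame,
    metadata: pd.DataFrame,
    bin_label: str,
    reference_bin: str = "unsorted",
    pseudocount: float = 0.5,
) -> pd.Series:
    """Per-UTR log2((bin + pc)/(reference + pc)), averaged over replicates.

    Replicates are paired by the ``replicate`` metadata column.
    """
    if bin_label == reference_bin:
        raise UtrkitError("bin and reference_bin must differ")
    bin_samples = _bin_samples(metadata, bin_label)
    ref_samples = _bin_samples(metadata, reference_bin)
    ratios = []
    for rep in sorted(metadata.loc[bin_samples, "replicate"].unique()):
        b = bin_samples[metadata.loc[bin_samples, "replicate"] == rep]
        r = ref_samples[metadata.loc[ref_samples, "replicate"] == rep]
        if len(b) != 1 or len(r) != 1:
            raise UtrkitError(
                f"replicate {rep!r}: expected one sample per (bin, replicate)"
            )
        ratios.append(
            np.log2(norm[b[0]] + pseudocount)
            - np.log2(norm[r[0]] + pseudocount)
        )
    out = pd.concat(ratios, axis=1).mean(axis=1)
    out.name = f"log2fc_{bin_label}"
    return out


# ---------------------------------------------------------------------------
# Differential enrichment (negative-binomial Wald test)

def _mom_dispersion(
    mat: np.ndarray, factors: np.ndarray, groups: list[np.ndarray]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Method-of-moments NB dispersion components pooled across conditions.

    For each condition c with n_c >= 2 replicates, E[s2] = shot + alpha q^2
    with shot = q * mean(1/f).  Returns per-UTR (alpha_gene, num, den) where
    num = sum_c w_c (s2 - shot), den = sum_c w_c q^2 (w_c = n_c - 1) and
    alpha_gene = num/den, NaN when den is 0 or the estimate is <= 0.  The
    raw num/den pairs are kept un-truncated so the trend can average them
    without selection bias.
    """
    n_utr = mat.shape[0]
    num = np.zeros(n_utr)
    den = np.zeros(n_utr)
    for idx in groups:
        if len(idx) < 2:
            continue
        y = mat[:, idx] / factors[idx]
        q = y.mean(axis=1)
        s2 = y.var(axis=1, ddof=1)
        shot = q * np.mean(1.0 / factors[idx])
        w = len(idx) - 1
        num += w * (s2 - shot)
        den += w * q**2
    with np.errstate(invalid="ignore", divide="ignore"):
        alpha = np.where(den > 0, num / np.maximum(den, 1e-300), np.nan)
    alpha = np.where(alpha <= 0, np.nan, alpha)
    return alpha, num, den


def _trend_dispersion(
    base_mean: np.ndarray,
    num: np.ndarray,
    den: np.ndarray,
    min_bin: int = 25,
) -> np.ndarray:
    """Mean-dispersion trend from abundance-binned pooled moment estimates.

    Genes are grouped into base-mean quantile bins (>= ``min_bin`` genes
    each); the bin dispersion is the ratio of summed moment numerators to
    summed denominators (see :func:`_mom_dispersion`), which averages the
    heavy-tailed few-replicate estimates without the selection bias of
    discarding negatives.  The trend is interpolated linearly in
    (log mu, log alpha) and held flat outside the fitted range.
    """
    ok = (base_mean > 0) & (den > 0)
    if ok.sum() < 2 * min_bin:
        pooled = num[ok].sum() / den[ok].sum() if ok.any() else 0.1
        return np.full_like(base_mean, max(pooled, _DISPERSION_FLOOR))
    mu = base_mean[ok]
    order = np.argsort(mu, kind="stable")
    n_bins = max(min(ok.sum() // min_bin, 20), 2)
    centers = []
    levels = []
    for chunk in np.array_split(order, n_bins):
        alpha_bin = num[ok][chunk].sum() / den[ok][chunk].sum()
        centers.append(np.log(np.median(mu[chunk])))
        levels.append(np.log(max(alpha_bin, _DISPERSION_FLOOR)))
    centers = np.asarray(centers)
    levels = np.asarray(levels)
    uniq = np.concatenate([[True], np.diff(centers) > 0])
    with np.errstate(divide="ignore"):
        log_mu = np.log(np.maximum(base_mean, 1e-12))
    trend = np.exp(np.interp(log_mu, centers[uniq], levels[uniq]))
    return np.maximum(trend, _DISPERSION_FLOOR)


def _condition_dispersion(
    mat: np.ndarray,
    factors: np.ndarray,
    cols: np.ndarray,
    q: np.ndarray,
    shrink: bool,
) -> np.ndarray:
    """Per-UTR dispersion for one condition, optionally trend-shrunk."""
    alpha_gene, num, den = _mom_dispersion(mat, factors, [cols])
    if not shrink:
        return np.clip(
            np.where(np.isnan(alpha_gene), _DISPERSION_FLOOR, alpha_gene),
            _DISPERSION_FLOOR,
            None,
        )
    trend = _trend_dispersion(q, num, den)
    df = len(cols) - 1
    w = df / (df + 4.0)
    valid = ~np.isnan(alpha_gene)
    alpha = trend.copy()
    alpha[valid] = np.exp(
        w * np.log(alpha_gene[valid]) + (1 - w) * np.log(trend[valid])
    )
    return np.clip(alpha, _DISPERSION_FLOOR, None)


def nb_test(
    counts: pd.DataFrame,
    metadata: pd.DataFrame,
    bin_label: str,
    reference_bin: str = "unsorted",
    shrink: bool = True,
    adjust: bool = True,
) -> pd.DataFrame:
    """Negative-binomial Wald test of one bin against the unsorted background.

    Counts follow NB(mu = size_factor * q_condition, alpha_condition) with
    Var = mu + alpha mu^2.  q is estimated per condition from normalized
    counts; the dispersion is estimated per UTR and per condition by method
    of moments (floored at 1e-8) and, by default, shrunk in log space toward
    an abundance-binned mean-dispersion trend in proportion to its degrees
    of freedom — dispersion is deliberately not pooled across conditions,
    since sorting gates induce far larger biological (cell-sampling)
    variability in a narrow bin than in the unsorted background.  The
    condition log2 fold change is tested with a Wald z statistic.  UTRs with
    zero counts in all samples, or a zero condition mean, yield NA rows
    excluded from testing.  Requires >= 2 replicates per condition.

    Returns a table indexed by UTR with columns base_mean, log2fc, se, p,
    padj (padj only when ``adjust``).
    """
    bin_idx = _bin_samples(metadata, bin_label)
    ref_idx = _bin_samples(metadata, reference_bin)
    if len(bin_idx) < 2 or len(ref_idx) < 2:
        raise UtrkitError(
            "need >= 2 replicates per condition for a dispersion estimate"
        )
    samples = list(bin_idx) + list(ref_idx)
    mat = counts[samples].to_numpy(dtype=float)
    factors = size_factors(counts[samples]).to_numpy()
    nb = len(bin_idx)
    cols_a = np.arange(nb)
    cols_b = np.arange(nb, len(samples))

    norm = mat / factors
    q_a = norm[:, cols_a].mean(axis=1)
    q_b = norm[:, cols_b].mean(axis=1)
    base_mean = norm.mean(axis=1)

    alpha_a = _condition_dispersion(mat, factors, cols_a, q_a, shrink)
    alpha_b = _condition_dispersion(mat, factors, cols_b, q_b, shrink)

    testable = (mat.sum(axis=1) > 0) & (q_a > 0) & (q_b > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        log2fc = np.where(testable, np.log2(q_a / q_b), np.nan)
        var_log_a = (
            (1.0 / factors[cols_a] / np.maximum(q_a, 1e-300)[:, None]
             + alpha_a[:, None])
            .sum(axis=1)
            / len(cols_a) ** 2
        )
        var_log_b = (
            (1.0 / factors[cols_b] / np.maximum(q_b, 1e-300)[:, None]
             + alpha_b[:, None])
            .sum(axis=1)
            / len(cols_b) ** 2
        )
        se = np.sqrt(var_log_a + var_log_b) / np.log(2)
        z = log2fc / se
    p = np.where(testable, 2.0 * stats.norm.sf(np.abs(z)), np.nan)
    p = np.where(testable, np.clip(p, np.nextafter(0, 1), 1.0), np.nan)

    out = pd.DataFrame(
        {
            "base_mean": base_mean,
            "log2fc": log2fc,
            "se": np.where(testable, se, np.nan),
            "p": p,
        },
        index=counts.index,
    )
    if adjust:
        padj = np.full(len(out), np.nan)
        mask = ~np.isnan(p)
        if mask.any():
            padj[mask] = bh_adjust(p[mask])
        out["padj"] = padj
    return out


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, padj >= p)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p <= 0).any() or (p > 1).any():
        raise UtrkitError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Hit selection and summaries

def select_hits(
    results: Mapping[str, pd.DataFrame],
    min_fold: float = 1.5,
    alpha: float = 0.05,
    log2_line: float = 0.52,
) -> pd.DataFrame:
    """Call enhanced-expression hits from per-bin enrichment tables.

    A UTR is a hit iff log2fc >= log2(min_fold) AND padj < alpha in ALL
    bins supplied (the three top bins).  The ``log2_line`` diagnostic
    (log2 ratio above the line in all bins) is reported alongside, not used
    for the call.  Returns a table indexed by UTR with per-bin columns, the
    ``hit`` flag, ``above_line`` flag, and a human-readable rationale.
    """
    if not results:
        raise UtrkitError("no enrichment results supplied")
    bins = list(results)
    universe = results[bins[0]].index
    for b in bins[1:]:
        if not results[b].index.equals(universe):
            raise UtrkitError("bins cover different UTR universes")
    lfc_cut = np.log2(min_fold)
    table = pd.DataFrame(index=universe)
    hit = np.ones(len(universe), dtype=bool)
    above = np.ones(len(universe), dtype=bool)
    for b in bins:
        lfc = results[b]["log2fc"].to_numpy()
        padj = results[b]["padj"].to_numpy()
        table[f"log2fc_{b}"] = lfc
        table[f"padj_{b}"] = padj
        ok = ~np.isnan(lfc) & ~np.isnan(padj)
        hit &= ok & (lfc >= lfc_cut) & (padj < alpha)
        above &= ok & (lfc > log2_line)
    table["hit"] = hit
    table["above_line"] = above
    rationale = []
    for utr in universe:
        row = table.loc[utr]
        fails = [
            b
            for b in bins
            if not (
                row[f"log2fc_{b}"] >= lfc_cut and row[f"padj_{b}"] < alpha
            )
        ]
        rationale.append(
            "hit: fc>=%.2f & padj<%g in all bins" % (min_fold, alpha)
            if not fails
            else "fails in: " + ",".join(fails)
        )
    table["rationale"] = rationale
    return table


def replicate_correlation(
    norm: pd.DataFrame,
    metadata: pd.DataFrame,
    bin_label: str,
    pseudocount: float = 0.5,
) -> float:
    """Pearson r of log2 normalized counts between the bin's two replicates."""
    samples = _bin_samples(metadata, bin_label)
    if len(samples) != 2:
        raise UtrkitError(
            f"bin {bin_label!r}: expected exactly 2 replicates, got "
            f"{len(samples)}"
        )
    x = np.log2(norm[samples[0]].to_numpy(float) + pseudocount)
    y = np.log2(norm[samples[1]].to_numpy(float) + pseudocount)
    if np.std(x) == 0 or np.std(y) == 0:
        raise UtrkitError("zero-variance replicate vector")
    return float(stats.pearsonr(x, y).statistic)


def category_enrichment(
    hit_ids: Iterable[str], categories: Mapping[str, str], category: str
) -> float:
    """Percent fold-enrichment of a source category among hits.

    100 x (hit rate inside the category) / (hit rate outside).  NaN when a
    denominator is zero (undefined).  ``categories`` maps every library id
    to its source category.
    """
    hit_set = set(hit_ids)
    unknown = hit_set - set(categories)
    if unknown:
        raise UtrkitError(f"hits not in manifest: {sorted(unknown)[:5]}")
    in_cat = [u for u, c in categories.items() if c == category]
    out_cat = [u for u, c in categories.items() if c != category]
    if not in_cat or not out_cat:
        return float("nan")
    hits_in = sum(1 for u in in_cat if u in hit_set)
    hits_out = sum(1 for u in out_cat if u in hit_set)
    if hits_out == 0:
        return float("nan")
    return 100.0 * (hits_in / len(in_cat)) / (hits_out / len(out_cat))


class ScreenEnrichmentModel(BaseEstimator):
    """End-to-end screen analysis as one fit-shaped estimator.

    ``fit(counts, metadata)`` computes size factors, normalized counts,
    per-top-bin NB enrichment tables, replicate correlations, and hit calls.

    Fitted attributes: ``size_factors_``, ``normalized_``, ``results_``
    (bin -> table), ``hits_`` (full hit table), ``hit_ids_``,
    ``replicate_r_`` (bin -> Pearson r).
    """

    def __init__(
        self,
        min_fold: float = 1.5,
        alpha: float = 0.05,
        log2_line: float = 0.52,
        pseudocount: float = 0.5,
        reference_bin: str = "unsorted",
        shrink_dispersion: bool = True,
    ):
        self.min_fold = min_fold
        self.alpha = alpha
        self.log2_line = log2_line
        self.pseudocount = pseudocount
        self.reference_bin = reference_bin
        self.shrink_dispersion = shrink_dispersion

    def fit(self, X: pd.DataFrame, y: pd.DataFrame = None):
        counts, metadata = X, y
        if metadata is None:
            raise UtrkitError("fit needs sample metadata (bin, replicate)")
        self.size_factors_ = size_factors(counts)
        self.normalized_ = normalize_counts(counts, self.size_factors_)
        top_bins = [
            b
            for b in BIN_LABELS
            if b != self.reference_bin and b in set(metadata["bin"])
        ]
        self.results_ = {
            b: nb_test(
                counts,
                metadata,
                b,
                reference_bin=self.reference_bin,
                shrink=self.shrink_dispersion,
            )
            for b in top_bins
        }
        self.hits_ = select_hits(
            self.results_,
            min_fold=self.min_fold,
            alpha=self.alpha,
            log2_line=self.log2_line,
        )
        self.hit_ids_ = list(self.hits_.index[self.hits_["hit"]])
        self.replicate_r_ = {}
        for b in top_bins:
            try:
                self.replicate_r_[b] = replicate_correlation(
                    self.normalized_, metadata, b, self.pseudocount
                )
            except UtrkitError:
                self.replicate_r_[b] = float("nan")
        return self
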
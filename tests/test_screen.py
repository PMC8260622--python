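import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from utrkit.io import LibraryManifest, UtrkitError
from utrkit.screen import (
    bh_adjust,
    category_enrichment,
    log2_enrichment,
    match_reads,
    nb_test,
    normalize_counts,
    replicate_correlation,
    select_hits,
    size_factors,
)


def _meta(samples):
    rows = []
    for s in samples:
        bin_label, rep = s.rsplit("_", 1)
        rows.append({"sample": s, "bin": bin_label, "replicate": rep})
    return pd.DataFrame(rows).set_index("sample")


class TestMatchReads:
    def _reads(self, manifest, plan, mutate=None):
        reads = []
        i = 0
        for rec in manifest.records:
            n = plan.get(rec.id, 0)
            seq = manifest.left_flank + rec.sequence + manifest.right_flank
            for _ in range(n):
                reads.append((f"r{i}", seq, "I" * len(seq)))
                i += 1
        if mutate:
            reads = [mutate(r) for r in reads]
        return reads

    def test_constructed_multiplicities_recovered(self, small_manifest):
        ids = small_manifest.ids[:3]
        plan = dict(zip(ids, (50, 30, 20)))
        counts, unassigned = match_reads(
            self._reads(small_manifest, plan), small_manifest
        )
        assert unassigned == 0
        assert [counts[i] for i in ids] == [50, 30, 20]
        assert counts.sum() == 100  # conservation

    def test_corrupted_flank_goes_unassigned(self, small_manifest):
        rec = small_manifest.records[0]
        good = small_manifest.left_flank + rec.sequence + small_manifest.right_flank
        bad = "T" + good[1:] if good[0] != "T" else "A" + good[1:]
        counts, unassigned = match_reads(
            [("r0", bad, "I" * len(bad))], small_manifest
        )
        assert unassigned == 1 and counts.sum() == 0

    def test_one_mismatch_assigned_iff_unique(self):
        from utrkit.io import UtrRecord

        a = "A" * 99 + "C"
        b = "A" * 99 + "G"  # distance 2 from any 1-error read of a? no: 1
        far = "T" * 50 + "A" * 50
        man = LibraryManifest(records=[
            UtrRecord(id="a", sequence=a),
            UtrRecord(id="b", sequence=b),
            UtrRecord(id="far", sequence=far),
        ])
        # read with last base corrupted to T: distance 1 from BOTH a and b
        ambiguous = man.left_flank + "A" * 99 + "T" + man.right_flank
        counts, unassigned = match_reads(
            [("r", ambiguous, "I" * 140)], man, max_mismatch=1
        )
        assert unassigned == 1
        # read 1 substitution inside `far`: unique within distance 1
        errant = far[:10] + ("C" if far[10] != "C" else "G") + far[11:]
        read = man.left_flank + errant + man.right_flank
        counts, unassigned = match_reads(
            [("r", read, "I" * 140)], man, max_mismatch=1
        )
        assert unassigned == 0 and counts["far"] == 1

    def test_empty_manifest_rejected(self):
        with pytest.raises(UtrkitError, match="empty manifest"):
            match_reads([], LibraryManifest(records=[]))


def brute_force_size_factors(counts: pd.DataFrame) -> np.ndarray:
    """Independent median-of-ratios script."""
    rows = [r for _, r in counts.iterrows() if (r > 0).all()]
    factors = []
    for col in counts.columns:
        ratios = []
        for r in rows:
            gm = np.prod([float(v) for v in r]) ** (1.0 / len(r))
            ratios.append(r[col] / gm)
        factors.append(float(np.median(ratios)))
    return np.array(factors)


class TestSizeFactors:
    def test_identical_samples_give_unit_factors(self):
        counts = pd.DataFrame({"s1": [10, 20, 5], "s2": [10, 20, 5]})
        assert np.allclose(size_factors(counts), [1.0, 1.0])

    def test_three_fold_sample_hand_computed(self):
        counts = pd.DataFrame({"s1": [10, 20, 40], "s2": [30, 60, 120]})
        # reference = geometric mean; ratios are 1/sqrt(3) and sqrt(3)
        assert np.allclose(
            size_factors(counts), [1 / np.sqrt(3), np.sqrt(3)]
        )

    def test_homogeneity(self, rng):
        # the geometric-mean reference scales with the data, so jointly
        # scaling every sample leaves the (relative) factors unchanged and
        # normalized counts scale with the data
        counts = pd.DataFrame(rng.integers(1, 100, size=(30, 4)))
        f1 = size_factors(counts)
        f3 = size_factors(counts * 3)
        assert np.allclose(f3, f1)
        assert np.allclose(
            normalize_counts(counts * 3).to_numpy(),
            3 * normalize_counts(counts).to_numpy(),
        )

    def test_matches_brute_force_on_random_matrices(self, rng):
        for _ in range(100):
            counts = pd.DataFrame(
                rng.integers(0, 60, size=(int(rng.integers(5, 25)),
                                          int(rng.integers(2, 6))))
            )
            if not (counts.to_numpy() > 0).all(axis=1).any():
                counts.iloc[0] = 1  # guarantee a reference row
            assert np.allclose(
                size_factors(counts), brute_force_size_factors(counts)
            )

    def test_all_zero_rows_rejected(self):
        counts = pd.DataFrame({"s1": [0, 5], "s2": [3, 0]})
        with pytest.raises(UtrkitError, match="pseudocount"):
            size_factors(counts)


class TestLog2Enrichment:
    def test_equal_counts_give_zero(self):
        counts = pd.DataFrame(
            {"top2.5_rep1": [10, 20], "unsorted_rep1": [10, 20],
             "top2.5_rep2": [10, 20], "unsorted_rep2": [10, 20]}
        )
        out = log2_enrichment(counts.astype(float), _meta(counts.columns),
                              "top2.5")
        assert np.allclose(out, 0.0)

    def test_four_fold_with_vanishing_pseudocount(self):
        counts = pd.DataFrame(
            {"top2.5_rep1": [400.0], "unsorted_rep1": [100.0]}
        )
        out = log2_enrichment(counts, _meta(counts.columns), "top2.5",
                              pseudocount=1e-9)
        assert out.iloc[0] == pytest.approx(2.0)

    def test_matches_scripted_recomputation(self, rng):
        norm = pd.DataFrame(
            rng.uniform(0, 50, size=(20, 4)),
            columns=["top5_10_rep1", "top5_10_rep2",
                     "unsorted_rep1", "unsorted_rep2"],
        )
        out = log2_enrichment(norm, _meta(norm.columns), "top5_10",
                              pseudocount=0.5)
        expected = 0.5 * (
            np.log2((norm["top5_10_rep1"] + 0.5) / (norm["unsorted_rep1"] + 0.5))
            + np.log2((norm["top5_10_rep2"] + 0.5) / (norm["unsorted_rep2"] + 0.5))
        )
        assert np.allclose(out, expected)

    def test_same_bin_rejected(self):
        counts = pd.DataFrame({"unsorted_rep1": [1.0]})
        with pytest.raises(UtrkitError):
            log2_enrichment(counts, _meta(counts.columns), "unsorted")


class TestNbTest:
    def _simulated_counts(self, n_utr=400, planted=20, fold=4.0,
                          dispersion=0.01, depth=100_000, seed=0):
        rng = np.random.default_rng(seed)
        base = np.full(n_utr, depth / n_utr)
        enhanced = base.copy()
        enhanced[:planted] *= fold
        enhanced *= depth / enhanced.sum()

        def nb(mean):
            shape = 1.0 / dispersion
            return rng.poisson(rng.gamma(shape, mean * dispersion))

        counts = pd.DataFrame(
            {
                "top2.5_rep1": nb(enhanced),
                "top2.5_rep2": nb(enhanced),
                "unsorted_rep1": nb(base),
                "unsorted_rep2": nb(base),
            },
            index=[f"u{i}" for i in range(n_utr)],
        )
        return counts, _meta(counts.columns)

    def test_recovers_planted_four_fold_enrichment(self):
        counts, meta = self._simulated_counts()
        res = nb_test(counts, meta, "top2.5")
        planted = res.iloc[:20]
        # median-of-ratios normalization anchors on the unenhanced majority,
        # so the planted fold change is recovered at its true value
        assert abs(planted["log2fc"].mean() - 2.0) < 0.3
        assert (np.abs(planted["log2fc"] - 2.0) < 0.5).all()
        assert (planted["p"] < 0.01).all()

    def test_null_type_one_error_is_calibrated(self, screen_library):
        from utrkit.simulate import simulate_screen

        strengths = pd.Series(1.0, index=pd.Index(screen_library.ids,
                                                  name="utr_id"))
        counts, meta, _ = simulate_screen(
            screen_library, strengths, depth=200_000, seed=11
        )
        for b in ("top2.5", "top2.5_5", "top5_10"):
            res = nb_test(counts, meta, b)
            frac = float((res["p"] < 0.05).mean())
            assert 0.02 <= frac <= 0.09

    def test_all_zero_rows_yield_na_and_are_excluded(self):
        counts, meta = self._simulated_counts(n_utr=50, seed=3)
        counts.iloc[7] = 0
        res = nb_test(counts, meta, "top2.5")
        assert res.iloc[7][["log2fc", "se", "p", "padj"]].isna().all()
        assert res["p"].notna().sum() == 49

    def test_single_replicate_rejected(self):
        counts = pd.DataFrame(
            {"top2.5_rep1": [5, 6], "unsorted_rep1": [5, 6]}
        )
        with pytest.raises(UtrkitError, match="2 replicates"):
            nb_test(counts, _meta(counts.columns), "top2.5")


def brute_force_bh(p):
    """Step-up BH written independently: cummin of p_i * n / rank."""
    p = np.asarray(p, float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    scaled = p[order] * n / np.arange(1, n + 1)
    running = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(running, 1.0)
    return out


class TestBhAdjust:
    def test_hand_computed_examples(self):
        assert bh_adjust([0.03]) == pytest.approx([0.03])
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]),
                           [0.04, 0.04, 0.04, 0.04])
        assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        for bad in ([0.0, 0.5], [0.5, 1.5], [np.nan]):
            with pytest.raises(UtrkitError):
                bh_adjust(bad)

    @given(st.lists(st.floats(1e-9, 1.0), min_size=1, max_size=60),
           st.integers(0, 10**6))
    @settings(max_examples=100, deadline=None)
    def test_matches_independent_step_up(self, pvals, _seed):
        ours = bh_adjust(pvals)
        assert np.allclose(ours, brute_force_bh(pvals))
        assert (ours >= np.asarray(pvals) - 1e-12).all()  # padj >= p


class TestSelectHits:
    def _results(self, lfc, padj):
        bins = ("top2.5", "top2.5_5", "top5_10")
        idx = [f"u{i}" for i in range(len(lfc))]
        return {
            b: pd.DataFrame(
                {"log2fc": [r[i] for r in lfc], "padj": [r[i] for r in padj]},
                index=idx,
            )
            for i, b in enumerate(bins)
        }

    def test_joint_rule_over_three_bins(self):
        lfc = [
            (1.0, 1.0, 1.0),   # hit
            (2.0, 2.0, 0.2),   # fails fold in one bin
            (1.0, 1.0, 1.0),   # fails padj in one bin
            (0.9, 0.8, 0.7),   # hit
            (-1.0, 1.0, 1.0),  # depleted
        ]
        padj = [
            (0.01, 0.01, 0.01),
            (0.01, 0.01, 0.01),
            (0.01, 0.2, 0.01),
            (0.04, 0.04, 0.04),
            (0.01, 0.01, 0.01),
        ]
        table = select_hits(self._results(lfc, padj))
        assert list(table.index[table["hit"]]) == ["u0", "u3"]
        assert "fails in:" in table.loc["u1", "rationale"]
        # the 0.52 log2-ratio line is diagnostic, not part of the call
        assert bool(table.loc["u0", "above_line"]) is True
        assert bool(table.loc["u2", "above_line"]) is True

    def test_degenerate_thresholds_accept_all_positive(self):
        lfc = [(0.1, 0.2, 0.3), (1.0, 1.0, -0.1)]
        padj = [(0.99, 0.99, 0.99), (0.5, 0.5, 0.5)]
        table = select_hits(self._results(lfc, padj), min_fold=1.0, alpha=1.0)
        assert list(table.index[table["hit"]]) == ["u0"]

    def test_mismatched_universes_rejected(self):
        res = self._results([(1.0, 1.0, 1.0)], [(0.01, 0.01, 0.01)])
        res["top5_10"] = res["top5_10"].rename(index={"u0": "other"})
        with pytest.raises(UtrkitError, match="universe"):
            select_hits(res)


class TestReplicateCorrelation:
    def test_identical_and_scaled_replicates(self):
        norm = pd.DataFrame(
            {"top2.5_rep1": [1.0, 8.0, 64.0], "top2.5_rep2": [1.0, 8.0, 64.0]}
        )
        meta = _meta(norm.columns)
        assert replicate_correlation(norm, meta, "top2.5") == pytest.approx(1.0)
        norm["top2.5_rep2"] = norm["top2.5_rep1"] * 2
        r = replicate_correlation(norm, meta, "top2.5", pseudocount=0.0)
        assert r == pytest.approx(1.0)  # log shift invariance

    def test_independent_counts_are_uncorrelated(self, rng):
        norm = pd.DataFrame(
            {
                "top2.5_rep1": rng.integers(1, 1000, 1000).astype(float),
                "top2.5_rep2": rng.integers(1, 1000, 1000).astype(float),
            }
        )
        r = replicate_correlation(norm, _meta(norm.columns), "top2.5")
        assert abs(r) <= 0.1

    def test_zero_variance_rejected(self):
        norm = pd.DataFrame(
            {"top2.5_rep1": [5.0, 5.0], "top2.5_rep2": [1.0, 2.0]}
        )
        with pytest.raises(UtrkitError, match="variance"):
            replicate_correlation(norm, _meta(norm.columns), "top2.5")


class TestCategoryEnrichment:
    def test_equal_rates_are_100_percent(self):
        cats = {f"s{i}": "synthetic_high_te" for i in range(10)}
        cats.update({f"n{i}": "natural" for i in range(10)})
        hits = ["s0", "n0"]
        assert category_enrichment(hits, cats, "synthetic_high_te") == 100.0

    def test_matches_contingency_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(10, 60))
            cats = {
                f"u{i}": ("synthetic_high_te" if rng.random() < 0.3
                          else "natural")
                for i in range(n)
            }
            hits = [u for u in cats if rng.random() < 0.2]
            in_ids = [u for u, c in cats.items() if c == "synthetic_high_te"]
            out_ids = [u for u, c in cats.items() if c != "synthetic_high_te"]
            val = category_enrichment(hits, cats, "synthetic_high_te")
            if not in_ids or not out_ids or not any(u in hits for u in out_ids):
                assert np.isnan(val)
            else:
                rate_in = sum(u in hits for u in in_ids) / len(in_ids)
                rate_out = sum(u in hits for u in out_ids) / len(out_ids)
                assert val == pytest.approx(100 * rate_in / rate_out)

    def test_unknown_hit_rejected(self):
        with pytest.raises(UtrkitError, match="not in manifest"):
            category_enrichment(["ghost"], {"u": "natural"}, "natural")
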
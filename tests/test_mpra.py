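"""MPRA tag counting, normalization, artifact blackballing and allelic tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from varlocus import mpra
from varlocus import simulate as sim

CONST = "ACTGGCCGCT"


class TestCountTags:
    def _map(self):
        return {"AAAAACCCCCGGGGGTTTTT": ("v1", "ref")}

    def test_perfect_read_counted(self):
        reads = [CONST + "AAAAACCCCCGGGGGTTTTT"]
        counts = mpra.count_tags(reads, self._map(), CONST)
        assert counts.iloc[0] == 1

    def test_four_constant_mismatches_allowed_five_not(self):
        tag = "AAAAACCCCCGGGGGTTTTT"
        flip = {"A": "T", "C": "G", "G": "C", "T": "A"}
        cr4 = "".join(flip[c] if i < 4 else c for i, c in enumerate(CONST))
        cr5 = "".join(flip[c] if i < 5 else c for i, c in enumerate(CONST))
        counts = mpra.count_tags([cr4 + tag, cr5 + tag], self._map(), CONST)
        assert counts.iloc[0] == 1

    def test_tag_mismatch_discarded(self):
        reads = [CONST + "CAAAACCCCCGGGGGTTTTT"]
        counts = mpra.count_tags(reads, self._map(), CONST)
        assert counts.iloc[0] == 0

    def test_duplicate_tags_rejected(self):
        df = pd.DataFrame({"tag": ["A" * 20, "A" * 20]})
        with pytest.raises(ValueError, match="duplicate"):
            mpra.count_tags([], df, CONST)


class TestNormalization:
    def test_median_centered_log_ratios(self):
        table = pd.DataFrame({
            "tag": ["T1", "T2", "T3"],
            "dna": [40, 40, 40],
            "rna": [40, 80, 160],
            "gc": [50, 50, 50],
        })
        out = mpra.normalize_expression(table, "rna")
        expected = np.array([-np.log(2), 0.0, np.log(2)])
        # single GC bin: the GC step subtracts the (zero) mean
        assert np.allclose(out["expression"], expected - expected.mean() + 0.0)
        assert np.allclose(sorted(out["expression"]), sorted(expected - expected.mean()))

    def test_dna_threshold_boundary(self):
        table = pd.DataFrame({
            "tag": ["T1", "T2", "T3"],
            "dna": [29, 30, 100],
            "rna": [50, 50, 50],
            "gc": [50, 50, 50],
        })
        out = mpra.normalize_expression(table, "rna")
        assert out["kept"].tolist() == [False, True, True]
        assert out["reason"].iloc[0] == "low_dna"

    def test_rna_threshold_boundary(self):
        table = pd.DataFrame({
            "tag": ["T1", "T2"], "dna": [100, 100], "rna": [3, 4], "gc": [50, 50],
        })
        out = mpra.normalize_expression(table, "rna")
        assert out["kept"].tolist() == [False, True]

    def test_gc_bins_have_zero_mean(self):
        rng = np.random.default_rng(0)
        table = pd.DataFrame({
            "tag": [f"T{i}" for i in range(300)],
            "dna": rng.integers(30, 200, 300),
            "rna": rng.integers(4, 400, 300),
            "gc": rng.integers(30, 60, 300),
        })
        out = mpra.normalize_expression(table, "rna")
        kept = out[out["kept"]]
        means = kept.groupby("gc")["expression"].mean()
        assert np.allclose(means, 0.0, atol=1e-12)

    def test_gc_normalization_commutes_with_constant_shift(self):
        rng = np.random.default_rng(1)
        table = pd.DataFrame({
            "tag": [f"T{i}" for i in range(200)],
            "dna": rng.integers(30, 200, 200),
            "rna": rng.integers(4, 400, 200),
            "gc": rng.integers(30, 60, 200),
        })
        a = mpra.normalize_expression(table, "rna")
        shifted = table.copy()
        shifted["rna"] = (shifted["rna"] * np.e).round().astype(int)
        # multiplying RNA by e adds ~1 to every log ratio; centering removes it
        b = mpra.normalize_expression(shifted, "rna")
        both = a["kept"] & b["kept"]
        assert np.allclose(a.loc[both, "expression"], b.loc[both, "expression"],
                           atol=0.02)


class TestBlackball:
    def test_no_excess_no_removal(self):
        rng = np.random.default_rng(2)
        tags = ["".join(rng.choice(list("ACGT"), 20)) for _ in range(400)]
        expr = rng.normal(0, 0.01, 400)
        bad, mask = mpra.blackball_5mers(tags, expr)
        assert bad == set() and not mask.any()

    def test_universal_5mer_never_blackballed(self):
        rng = np.random.default_rng(3)
        tags = ["AAAAA" + "".join(rng.choice(list("CGT"), 15)) for _ in range(300)]
        expr = rng.normal(0, 0.3, 300)
        expr -= expr.mean()  # centered, as after normalization
        bad, _ = mpra.blackball_5mers(tags, expr)
        assert "AAAAA" not in bad

    def test_planted_artifact_detected_and_tags_removed(self):
        cfg = sim.SimConfig(seed=8)
        cfg.mpra.artifact_5mers = ("ACGCG",)
        tab = sim.simulate_mpra_counts(cfg, [f"v{i}" for i in range(40)], {})
        out, bad = mpra.tag_expression(tab, "rna1")
        assert "ACGCG" in bad
        # any extra flagged 5-mer must be substring-correlated with the artifact
        for b in bad:
            assert b == "ACGCG" or b[1:] == "ACGCG"[:4] or b[:4] == "ACGCG"[1:]
        removed = out[out["reason"] == "blackballed"]
        assert removed["tag"].str.contains("ACGCG").any()
        kept = out[out["kept"]]
        assert not kept["tag"].str.contains("ACGCG").any()


class TestAllelicTest:
    def test_identical_groups(self):
        t, p = mpra.test_allelic_activity([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        assert (t, p) == (0.0, 1.0)

    def test_textbook_pooled_t(self):
        t, p = mpra.test_allelic_activity([0, 1, 2], [1, 2, 3])
        assert t == pytest.approx(-1.2247, abs=1e-4)
        assert p == pytest.approx(0.2878, abs=1e-3)

    def test_matches_hand_rolled_oracle(self):
        # pooled-variance t computed from first principles
        rng = np.random.default_rng(4)
        for _ in range(1000):
            na, nb = rng.integers(2, 12, 2)
            a, b = rng.normal(size=na), rng.normal(1, 2, size=nb)
            t, p = mpra.test_allelic_activity(a, b)
            sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
            t_oracle = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
            p_oracle = 2 * stats.t.sf(abs(t_oracle), na + nb - 2)
            assert t == pytest.approx(t_oracle, abs=1e-10)
            assert p == pytest.approx(p_oracle, abs=1e-10)

    def test_too_few_tags_is_error(self):
        with pytest.raises(ValueError):
            mpra.test_allelic_activity([1.0], [1.0, 2.0])


class TestHitCalls:
    def _results(self, fdr_targets, signs):
        # craft p-values that survive single-variant BH untouched
        rows = []
        for rep, (p, s) in enumerate(zip(fdr_targets, signs), start=1):
            rows.append(("v", rep, s, p, True))
        return pd.DataFrame(rows, columns=["variant", "replicate", "t", "p",
                                           "tested"])

    def test_two_significant_consistent_is_hit(self):
        res = self._results([0.05, 0.08, 0.5], [1.0, 2.0, 0.5])
        out = mpra.call_mpra_hits(res)
        assert bool(out["hit"].iloc[0]) is True

    def test_inconsistent_directions_not_hit(self):
        res = self._results([0.05, 0.08], [1.0, -1.0])
        out = mpra.call_mpra_hits(res)
        assert bool(out["hit"].iloc[0]) is False

    def test_single_significant_replicate_not_hit(self):
        res = self._results([0.05, 0.2, 0.2], [1.0, 1.0, 1.0])
        out = mpra.call_mpra_hits(res)
        assert bool(out["hit"].iloc[0]) is False

    def test_variant_tested_once_flagged_untestable(self):
        res = self._results([0.01], [1.0])
        out = mpra.call_mpra_hits(res)
        assert bool(out["hit"].iloc[0]) is False
        assert out["n_tested"].iloc[0] == 1


class TestGoodTagRule:
    def test_80_tag_threshold(self):
        rng = np.random.default_rng(5)
        rows = []
        # v_ok: 40 + 40 tags; v_short: 40 + 39 tags
        for variant, n_alt in (("v_ok", 40), ("v_short", 39)):
            for allele, n in (("ref", 40), ("alt", n_alt)):
                for i in range(n):
                    tag = "".join(rng.choice(list("ACGT"), 20))
                    # low-noise counts: 5-mer means stay under the blackball
                    # threshold even with few tags per 5-mer
                    rows.append((tag, variant, allele, 50,
                                 100, rng.integers(95, 106)))
        tab = pd.DataFrame(rows, columns=["tag", "variant", "allele", "gc",
                                          "dna", "rna1"])
        tab["rna2"] = tab["rna1"]
        calls, tests = mpra.analyze_mpra(tab)
        tested = tests[tests["tested"]]
        assert set(tested["variant"]) == {"v_ok"}
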
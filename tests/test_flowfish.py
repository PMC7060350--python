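"""Guide specificity scoring and the sorted-bin screen statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from varlocus import flowfish as ff
from varlocus import simulate as sim


class TestOfftargetScore:
    @pytest.mark.parametrize("positions, expected", [
        ({0, 19}, 0.417 * 1.0 * 0.25),            # dbar = 19, weights 0 / 0.583
        ({0, 1}, 1.0 * (19.0 / 91.0) * 0.25),     # adjacent: dbar = 1
        ({2}, 0.986),                              # single mismatch, factor 1
    ])
    def test_hand_evaluations(self, positions, expected):
        assert ff.offtarget_hit_score(positions) == pytest.approx(expected, abs=1e-9)

    def test_requires_mismatch_in_range(self):
        with pytest.raises(ValueError):
            ff.offtarget_hit_score(set())
        with pytest.raises(ValueError):
            ff.offtarget_hit_score({20})

    def test_aggregate_specificity(self):
        assert ff.aggregate_guide_specificity([]) == 100.0
        assert ff.aggregate_guide_specificity([1.0]) == pytest.approx(50.0)
        # adding any hit strictly decreases specificity
        base = ff.aggregate_guide_specificity([0.3])
        assert ff.aggregate_guide_specificity([0.3, 0.01]) < base


class TestSelectGuides:
    def _tables(self, rows):
        guides = pd.DataFrame({"guide": ["g"], "sequence": ["ATGCATGCATGCATGCATGC"]})
        matches = pd.DataFrame(rows, columns=["guide", "position", "n_mismatches",
                                              "intended"])
        return guides, matches

    def test_four_perfect_matches_dropped(self):
        rows = [("g", 500, 0, True)] + [("g", 10_000 + i, 0, False) for i in range(4)]
        guides, matches = self._tables(rows)
        assert ff.select_guides(guides, matches, (0, 1000)).empty

    def test_on_locus_offtarget_dropped(self):
        rows = [("g", 500, 0, True), ("g", 900, 2, False)]
        guides, matches = self._tables(rows)
        assert ff.select_guides(guides, matches, (0, 1000)).empty

    def test_clean_guide_kept_and_g_prepended(self):
        rows = [("g", 500, 0, True), ("g", 99_000, 3, False)]
        guides, matches = self._tables(rows)
        out = ff.select_guides(guides, matches, (0, 1000))
        assert list(out["guide"]) == ["g"]
        assert out["sequence_synth"].iloc[0].startswith("G")
        assert len(out["sequence_synth"].iloc[0]) == 21

    def test_missing_intended_site_is_error(self):
        guides, matches = self._tables([("g", 5000, 0, True)])
        with pytest.raises(ValueError, match="intended"):
            ff.select_guides(guides, matches, (0, 1000))


class TestSortModel:
    def test_lowest_bin_interval(self):
        m = ff.fit_sort_model()
        assert m.bounds[0, 0] == pytest.approx(stats.norm.ppf(0.001), abs=1e-4)
        assert m.bounds[0, 0] == pytest.approx(-3.0902, abs=1e-3)
        assert m.bounds[0, 1] == pytest.approx(-1.2816, abs=1e-3)

    def test_symmetric_design_symmetric_bounds(self):
        m = ff.fit_sort_model()
        assert np.allclose(m.bounds, -m.bounds[::-1, ::-1])

    def test_zero_trim_gives_infinite_edge(self):
        m = ff.fit_sort_model(tail_trim=0.0)
        assert np.isneginf(m.bounds[0, 0]) and np.isposinf(m.bounds[5, 1])

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError):
            ff.fit_sort_model((0.2,) * 6)


class TestGuideEstimator:
    def test_null_profile_fixed_point(self):
        model = ff.fit_sort_model()
        counts = np.outer(np.ones(3), model.capture * 1e5)
        df = pd.DataFrame(counts, columns=ff.BIN_COLUMNS)
        fit = ff.estimate_guide_effects(df, model, refine=0, abundance_col=None)
        assert np.allclose(fit["mu_hat"], 0.0, atol=1e-6)

    def test_all_reads_lowest_bin_strictly_negative(self):
        model = ff.fit_sort_model()
        counts = np.zeros((1, 6))
        counts[0, 0] = 1e5
        df = pd.DataFrame(counts, columns=ff.BIN_COLUMNS)
        fit = ff.estimate_guide_effects(df, model, refine=0, abundance_col=None)
        assert fit["mu_hat"].iloc[0] < model.bounds[0, 1]

    def test_matches_scalar_optimizer_oracle(self):
        # grid fit vs an independent bounded Brent optimization per guide
        rng = np.random.default_rng(42)
        model = ff.fit_sort_model()
        counts = rng.integers(1, 2000, size=(100, 6)).astype(float)
        df = pd.DataFrame(counts, columns=ff.BIN_COLUMNS)
        fit = ff.estimate_guide_effects(df, model, refine=0, abundance_col=None,
                                        pseudocount_per_reads=np.inf)
        depth = counts.sum(axis=0)
        for i in range(len(counts)):
            oracle = ff.fit_single_guide(counts[i], model,
                                         weights=model.capture, depth=depth)
            assert abs(fit["mu_hat"].iloc[i] - oracle) <= 0.002

    def test_monotone_in_read_placement(self):
        # moving one read from a lower to a higher bin never decreases mu_hat
        model = ff.fit_sort_model()
        base = np.array([[300.0, 250, 200, 150, 100, 50]])
        moved = base.copy()
        moved[0, 0] -= 10
        moved[0, 5] += 10
        df = pd.DataFrame(np.vstack([base, moved]), columns=ff.BIN_COLUMNS)
        fit = ff.estimate_guide_effects(df, model, refine=0, abundance_col=None)
        assert fit["mu_hat"].iloc[1] >= fit["mu_hat"].iloc[0]

    def test_null_guides_centered_on_zero(self, default_cfg):
        elements = pd.DataFrame({"element": ["e"], "start": [0], "end": [1]})
        cfg = sim.SimConfig(seed=21)
        cfg.flowfish.n_nontargeting = 1500
        cfg.flowfish.guides_per_element = 50
        screens, model = sim.simulate_flowfish_screen(cfg, elements, {"e": 0.0})
        fit = ff.estimate_guide_effects(screens[0], model)
        nt = fit.loc[~fit["targeting"], "mu_hat"]
        assert abs(nt.mean()) < 0.05


class TestElementStats:
    def _guides(self, z_by_element, nt_z):
        rows = [(f"g{i}", el, True, z)
                for i, (el, z) in enumerate(
                    (el, z) for el, zs in z_by_element.items() for z in zs)]
        rows += [(f"nt{i}", None, False, z) for i, z in enumerate(nt_z)]
        return pd.DataFrame(rows, columns=["guide", "element", "targeting", "z"])

    def test_zero_z_gives_half_p(self):
        rng = np.random.default_rng(0)
        df = self._guides({"e": [0.0] * 4}, rng.normal(size=200))
        out = ff.element_stats(df, seed=0)
        assert out["sig_z"].iloc[0] == pytest.approx(0.0)
        assert out["p"].iloc[0] == pytest.approx(0.5)

    def test_single_guide_raw_stouffer_identity(self):
        rng = np.random.default_rng(1)
        df = self._guides({"e": [1.7]}, rng.normal(size=200))
        out = ff.element_stats(df, seed=0)
        assert out["raw_stouffer_z"].iloc[0] == pytest.approx(1.7)

    def test_nt_scale_converges_to_one_for_standard_normal(self):
        rng = np.random.default_rng(2)
        nt = rng.normal(size=5000)
        sd = ff._nt_stouffer_sd(nt, 5, np.random.default_rng(0))
        assert sd == pytest.approx(1.0, rel=0.05)

    def test_too_few_nontargeting_is_error(self):
        df = self._guides({"e": [0.0]}, [0.0] * 10)
        with pytest.raises(ValueError):
            ff.element_stats(df)


class TestElementCalls:
    def _rep(self, fdrs, effects):
        return pd.DataFrame({
            "element": [f"e{i}" for i in range(len(fdrs))],
            "fdr": fdrs, "effect_z": effects,
        })

    def test_both_replicates_below_sqrt_point1(self):
        reps = [self._rep([0.20], [-1.0]), self._rep([0.05], [-2.0])]
        out = ff.call_regulatory_elements(reps)
        assert bool(out["hit"].iloc[0]) is True  # 0.20 and 0.05 both < 0.3162

    def test_one_replicate_above_threshold(self):
        reps = [self._rep([0.35], [-1.0]), self._rep([0.01], [-2.0])]
        out = ff.call_regulatory_elements(reps)
        assert bool(out["hit"].iloc[0]) is False

    def test_opposite_directions_not_a_hit(self):
        reps = [self._rep([0.05], [-1.0]), self._rep([0.05], [+1.0])]
        out = ff.call_regulatory_elements(reps)
        assert bool(out["hit"].iloc[0]) is False

    def test_single_replicate_is_error(self):
        with pytest.raises(ValueError):
            ff.call_regulatory_elements([self._rep([0.05], [-1.0])])

    def test_promoter_control_picks_strongest_two(self):
        weak = pd.DataFrame({"element": ["promoter", "e0"],
                             "fdr": [0.5, 0.5], "effect_z": [-0.1, -0.2]})
        strong1 = pd.DataFrame({"element": ["promoter", "e0"],
                                "fdr": [0.01, 0.05], "effect_z": [-5.0, -1.0]})
        strong2 = pd.DataFrame({"element": ["promoter", "e0"],
                                "fdr": [0.01, 0.08], "effect_z": [-4.0, -1.0]})
        out = ff.call_regulatory_elements([weak, strong1, strong2])
        row = out[out["element"] == "e0"].iloc[0]
        assert bool(row["hit"]) is True  # weak replicate was discarded


class TestSnpFootprints:
    def test_inclusive_boundary_at_pad(self):
        elems = pd.DataFrame({"element": ["e"], "start": [1000], "end": [1100]})
        flags = ff.snp_hits_from_elements(elems, [1200, 1201], pad=100)
        assert flags.tolist() == [True, False]

    def test_planted_element_flags_only_causal(self, locus):
        truth = locus["truth"]
        panel = locus["panel"]
        causal_elems = locus["elements"][
            locus["elements"]["element"].str.startswith("elem")
        ]
        flags = ff.snp_hits_from_elements(causal_elems,
                                          panel.snps["pos"].to_numpy(), pad=100)
        flagged = {s for s, f in zip(panel.snp_ids, flags) if f}
        assert flagged == set(truth.causal_snps)


class TestOpposingAssays:
    def test_crispri_and_crispra_effects_have_opposite_sign(self):
        elements = pd.DataFrame({"element": ["e"], "start": [0], "end": [1]})
        cfg = sim.SimConfig(seed=31)
        cfg.flowfish.n_nontargeting = 1000
        cfg.flowfish.guides_per_element = 40
        down, model = sim.simulate_flowfish_screen(cfg, elements, {"e": -1.0})
        cfg2 = sim.SimConfig(seed=32)
        cfg2.flowfish.n_nontargeting = 1000
        cfg2.flowfish.guides_per_element = 40
        cfg2.flowfish.promoter_effect = +2.0
        up, _ = sim.simulate_flowfish_screen(cfg2, elements, {"e": +1.0})
        z_down = ff.guide_zscores(ff.estimate_guide_effects(down[0], model))
        z_up = ff.guide_zscores(ff.estimate_guide_effects(up[0], model))
        e_down = ff.element_stats(z_down, direction="down", seed=0)
        e_up = ff.element_stats(z_up, direction="up", seed=0)
        zd = e_down.set_index("element").loc["e", "effect_z"]
        zu = e_up.set_index("element").loc["e", "effect_z"]
        assert zd < 0 < zu
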
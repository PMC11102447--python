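"""Guide-effect models, FDR, efficacy threshold, deviations."""

import numpy as np
import pandas as pd
import pytest

from perturbmap import effects as fx


def lineage_table(per_seg_effect, baselines=None, noise_sd=0.01,
                  n_barcodes=3, seed=0):
    """CON + induced lineages for one gRNA with planted per-segregant
    effects."""
    rng = np.random.default_rng(seed)
    rows = []
    for i, (seg, eff) in enumerate(per_seg_effect.items()):
        b = 0.0 if baselines is None else baselines[seg]
        for ind in (0, 1):
            for k in range(n_barcodes):
                rows.append((seg, ind, b + ind * eff
                             + rng.normal(0, noise_sd)))
    df = pd.DataFrame(rows, columns=["segregant_id", "induced", "fitness"])
    df["guide_id"] = "g1"
    return df


class TestGuideModels:
    def test_identical_arms_give_null_result(self):
        # induced fitness literally equal to control fitness per lineage
        rng = np.random.default_rng(1)
        rows = []
        for i in range(40):
            for k in range(3):
                y = rng.normal(0, 0.01)
                rows.append((f"s{i}", 0, y))
                rows.append((f"s{i}", 1, y))
        df = pd.DataFrame(rows, columns=["segregant_id", "induced", "fitness"])
        res = fx.test_guide(df)
        assert abs(res.mean_effect) < 1e-6
        assert res.p_mean > 0.9

    @pytest.mark.parametrize("seed", range(10))
    def test_uniform_planted_effect_recovered_without_interaction(self, seed):
        eff = {f"s{i}": -0.1 for i in range(50)}
        res = fx.test_guide(lineage_table(eff, noise_sd=0.01, seed=seed))
        assert -0.12 < res.mean_effect < -0.08
        assert res.p_mean < 1e-6

    def test_uniform_effect_rarely_flags_interaction(self):
        flags = 0
        for seed in range(20):
            eff = {f"s{i}": -0.1 for i in range(50)}
            res = fx.test_guide(lineage_table(eff, noise_sd=0.01, seed=seed))
            flags += res.p_interaction < 0.05
        assert flags <= 2

    def test_heterogeneous_effects_flag_interaction(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            eff = {f"s{i}": rng.normal(-0.1, 0.05) for i in range(50)}
            res = fx.test_guide(lineage_table(eff, noise_sd=0.01, seed=seed))
            hits += res.p_interaction < 0.05
        assert hits >= 9

    def test_fixed_mode_matches_hand_arithmetic(self):
        eff = {"s1": -0.2, "s2": -0.1, "s3": -0.3}
        res = fx.test_guide(lineage_table(eff, noise_sd=0.0), mode="fixed")
        assert res.mean_effect == pytest.approx(-0.2, abs=1e-12)
        got = res.per_segregant_effect
        assert got["s2"] == pytest.approx(-0.1, abs=1e-12)

    def test_single_segregant_is_singular(self):
        res = fx.test_guide(lineage_table({"s1": -0.1}))
        assert res.singular


class TestFDR:
    def test_hand_bh_example(self):
        q = fx.adjust_fdr(pd.Series([0.01, 0.02, 0.03]))
        assert np.allclose(q, [0.03, 0.03, 0.03])

    def test_all_ones(self):
        assert (fx.adjust_fdr(pd.Series([1.0, 1.0, 1.0])) == 1.0).all()

    def test_single_p_passes_through(self):
        assert fx.adjust_fdr(pd.Series([0.04]))[0] == pytest.approx(0.04)

    def test_nans_passed_through(self):
        q = fx.adjust_fdr(pd.Series([0.01, np.nan, 0.5]))
        assert np.isnan(q[1]) and not np.isnan(q[0])


class TestEfficacyThreshold:
    def test_gaussian_null_cutoff_near_minus_three_sd(self):
        rng = np.random.default_rng(0)
        m = pd.Series(rng.normal(0, 0.01, 2000))
        null = fx.efficacy_threshold(m)
        assert null.cutoff == pytest.approx(-0.03, abs=0.004)
        assert (m < null.cutoff).mean() < 0.01

    def test_location_equivariance(self):
        rng = np.random.default_rng(1)
        m = pd.Series(rng.normal(0, 0.01, 500))
        a = fx.efficacy_threshold(m)
        b = fx.efficacy_threshold(m + 0.05)
        assert b.cutoff - a.cutoff == pytest.approx(0.05, abs=1e-12)

    def test_planted_cluster_separated_from_null(self):
        rng = np.random.default_rng(2)
        null_m = rng.normal(0, 0.01, 800)
        planted = np.full(200, -0.2) + rng.normal(0, 0.01, 200)
        m = pd.Series(np.concatenate([null_m, planted]))
        null = fx.efficacy_threshold(m)
        assert (planted < null.cutoff).all()
        assert (null_m < null.cutoff).mean() < 0.005

    def test_too_few_guides_rejected(self):
        with pytest.raises(ValueError):
            fx.efficacy_threshold(pd.Series([0.0] * 10))


class TestPolymorphicGuides:
    def test_window_overlap_boundaries(self):
        guides = pd.DataFrame({
            "guide_id": ["in", "edge", "out"],
            "chrom": ["chrI"] * 3,
            "pos": [100, 81, 79],
        })
        variants = pd.DataFrame({"chrom": ["chrI"], "pos": [100]})
        # 20-nt windows: [100,119] contains 100; [81,100] contains 100;
        # [79,98] does not
        flags = fx.flag_polymorphic_guides(guides, variants)
        assert flags.tolist() == [True, True, False]

    def test_simulator_planted_polymorphic_guides_all_flagged(
        self, guide_library, marker_map
    ):
        guides, _ = guide_library
        flags = fx.flag_polymorphic_guides(guides, marker_map)
        assert set(guides.loc[flags, "guide_id"]) >= set(
            guides.loc[guides["polymorphic"], "guide_id"])
        assert flags.sum() == guides["polymorphic"].sum()


class TestDeviations:
    def make_models(self, effs, n_min=0):
        models = {}
        for gid, eff in effs.items():
            models[gid] = fx.GuideEffectResult(
                gid, float(np.mean(list(eff.values()))), 0.001, 0.001,
                len(eff), True, per_segregant_effect=pd.Series(eff))
        return models

    def test_hand_toy_no_shrinkage(self):
        models = self.make_models(
            {"g1": {"s1": -0.2, "s2": -0.1, "s3": -0.3}})
        dev = fx.compute_deviations(models, ["g1"], min_segregants=3)
        assert np.allclose(sorted(dev["g1"]), [-0.1, 0.0, 0.1])

    def test_deviations_centred_to_zero(self):
        rng = np.random.default_rng(3)
        effs = {"g1": {f"s{i}": rng.normal(-0.1, 0.05) for i in range(50)}}
        dev = fx.compute_deviations(self.make_models(effs), ["g1"],
                                    min_segregants=35)
        assert abs(dev["g1"].mean()) < 1e-9

    def test_min_segregant_boundary_35(self):
        effs = {
            "g34": {f"s{i}": -0.1 + 0.001 * i for i in range(34)},
            "g35": {f"s{i}": -0.1 + 0.001 * i for i in range(35)},
        }
        dev = fx.compute_deviations(self.make_models(effs), ["g34", "g35"])
        assert "g34" not in dev.columns and "g35" in dev.columns

    def test_identical_effects_give_zero_deviations(self):
        models = self.make_models({"g1": {f"s{i}": -0.15 for i in range(40)}})
        dev = fx.compute_deviations(models, ["g1"], min_segregants=35)
        assert np.allclose(dev["g1"], 0.0)


class TestGeneSelection:
    def test_one_guide_per_gene_most_significant_interaction(self):
        res = pd.DataFrame({
            "background": [True, True, True],
            "q_interaction": [0.01, 0.001, 0.04],
        }, index=pd.Index(["gA1", "gA2", "gB1"], name="guide_id"))
        guides = pd.DataFrame({
            "guide_id": ["gA1", "gA2", "gB1"],
            "target_gene": ["GENEA", "GENEA", "GENEB"],
        })
        sel = fx.select_gene_guides(res, guides)
        chosen = dict(zip(sel["target_gene"], sel["guide_id"]))
        assert chosen == {"GENEA": "gA2", "GENEB": "gB1"}

    def test_mapped_locus_breaks_q_tie(self):
        res = pd.DataFrame({
            "background": [True, True],
            "q_interaction": [0.01, 0.01],
        }, index=pd.Index(["gA1", "gA2"], name="guide_id"))
        guides = pd.DataFrame({
            "guide_id": ["gA1", "gA2"],
            "target_gene": ["GENEA", "GENEA"],
        })
        sel = fx.select_gene_guides(res, guides, mapped_guides={"gA2"})
        assert sel["guide_id"].tolist() == ["gA2"]
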
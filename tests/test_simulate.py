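"""Generative model: cross, architecture, competition and chimeras."""

import numpy as np
import pandas as pd
import pytest

from perturbmap.genome import default_marker_map, genome_length
from perturbmap.sim import (
    ArchitectureConfig,
    ChimeraCoefficients,
    SimConfig,
    build_lineages,
    inject_chimeras,
    simulate_architecture,
    simulate_assay,
    simulate_cross,
    true_fitness,
    true_fitness_matrix,
)
from perturbmap.tables import COUNT_COLS


class TestCross:
    def test_genome_length_is_sum_of_chromosome_maxima(self, marker_map):
        per_chrom = marker_map.groupby("chrom")["pos"].max()
        assert genome_length(marker_map) == per_chrom.sum()

    def test_no_recombination_gives_single_blocks(self, marker_map):
        geno = simulate_cross(20, marker_map, 0.0, seed=0)
        for chrom, sub in marker_map.groupby("chrom"):
            block = geno[sub["marker"]]
            assert (block.nunique(axis=1) == 1).all()

    def test_free_recombination_decorrelates_adjacent_markers(self):
        mm = default_marker_map(n_chrom=1, markers_per_chrom=10)
        geno = simulate_cross(10_000, mm, 0.5, seed=1).to_numpy()
        for j in range(geno.shape[1] - 1):
            r = np.corrcoef(geno[:, j], geno[:, j + 1])[0, 1]
            assert abs(r) < 0.05

    def test_switch_rate_matches_recombination_fraction(self):
        mm = default_marker_map(n_chrom=1, markers_per_chrom=40)
        geno = simulate_cross(10_000, mm, 0.1, seed=2).to_numpy()
        rate = np.mean(geno[:, 1:] != geno[:, :-1])
        assert abs(rate - 0.1) < 0.01

    def test_deterministic_given_seed(self, marker_map):
        a = simulate_cross(30, marker_map, 0.12, seed=7)
        b = simulate_cross(30, marker_map, 0.12, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_invalid_recombination_fraction_rejected(self, marker_map):
        with pytest.raises(ValueError):
            simulate_cross(10, marker_map, 0.7, seed=0)


class TestArchitecture:
    def test_controls_have_no_effect_and_no_interactions(
        self, architecture, guide_library
    ):
        guides, _ = guide_library
        controls = guides.loc[guides["is_control"], "guide_id"]
        assert (architecture.guide_effect[controls] == 0).all()
        assert not architecture.interactions["guide_id"].isin(set(controls)).any()

    def test_efficacious_effects_are_negative(self, architecture):
        m = architecture.guide_effect
        assert (m[m != 0] < 0).all()

    def test_amplifying_beta_monotone_in_effect_size(self, architecture):
        amp = architecture.hubs.loc[
            architecture.hubs["style"] == "amplifying", "hub"
        ].iloc[0]
        sub = architecture.interactions[architecture.interactions["hub"] == amp]
        m = architecture.guide_effect[sub["guide_id"]].abs().to_numpy()
        beta = sub["beta"].to_numpy()
        order = np.argsort(m)
        assert (np.diff(beta[order]) >= 0).all()
        assert (beta > 0).all()

    def test_masking_induced_allele_effect_matches_closed_form(
        self, genotypes, guide_library, architecture
    ):
        guides, _ = guide_library
        hub = architecture.hubs[architecture.hubs["style"] == "masking"].iloc[0]
        a, r = hub["qtl_effect"], hub["attenuation"]
        eff = true_fitness_matrix(architecture, genotypes, induced=True)
        x = genotypes[hub["marker"]]
        members = architecture.interactions.loc[
            architecture.interactions["hub"] == hub["hub"], "guide_id"
        ]
        for gid in members:
            mg = abs(architecture.guide_effect[gid])
            expect = a * max(0.0, 1.0 - r * mg)
            # remove the epsilon noise: use the deterministic part
            w = eff[gid] - architecture.epsilon[gid]
            got = w[x == 1].mean() - w[x == 0].mean()
            # other loci shared between allele classes only via sampling noise
            assert got == pytest.approx(expect, abs=0.02)

    def test_zero_hubs_zero_qtl_gives_pure_residual_baseline(
        self, genotypes, guide_library
    ):
        guides, _ = guide_library
        arch = simulate_architecture(
            genotypes, guides,
            ArchitectureConfig(n_hubs=0, hub_styles=(), n_fitness_qtl=0,
                               baseline_resid_sd=0.0),
            seed=0,
        )
        assert (arch.baseline == 0).all()
        assert arch.interactions.empty

    def test_more_hubs_than_markers_rejected(self, guide_library):
        guides, _ = guide_library
        mm = default_marker_map(n_chrom=1, markers_per_chrom=2)
        geno = simulate_cross(10, mm, 0.1, seed=0)
        with pytest.raises(ValueError):
            simulate_architecture(
                geno, guides,
                ArchitectureConfig(n_hubs=3, hub_styles=("amplifying",) * 3),
                seed=0,
            )

    def test_true_fitness_hand_example(self, genotypes, guide_library):
        # b=0.05, m=-0.2, kappa=-0.5, one interaction beta=0.08 on a 3S
        # allele, eps=0: fitness = 0.05 - 0.2 - 0.025 + 0.08 = -0.095
        guides, _ = guide_library
        arch = simulate_architecture(
            genotypes, guides, ArchitectureConfig(kappa=-0.5), seed=1
        )
        seg = genotypes.index[0]
        gid = arch.active_guides()[0]
        marker = genotypes.columns[genotypes.loc[seg] == 1][0]
        arch.baseline.loc[seg] = 0.05
        arch.guide_effect.loc[gid] = -0.2
        arch.epsilon.loc[seg, gid] = 0.0
        arch.interactions = pd.DataFrame(
            [{"guide_id": gid, "marker": marker, "beta": 0.08, "hub": "hub1"}]
        )
        got = true_fitness(arch, genotypes, seg, gid, induced=True)
        assert got == pytest.approx(-0.095, abs=1e-12)

    def test_uninduced_fitness_is_baseline(self, genotypes, architecture):
        seg = genotypes.index[3]
        gid = architecture.active_guides()[2]
        got = true_fitness(architecture, genotypes, seg, gid, induced=False)
        assert got == architecture.baseline.loc[seg]

    def test_unknown_ids_raise(self, genotypes, architecture):
        with pytest.raises(KeyError):
            true_fitness(architecture, genotypes, "nope", "gRNA0001", True)
        with pytest.raises(KeyError):
            true_fitness(architecture, genotypes, genotypes.index[0], "nope", True)


class TestAssay:
    @pytest.fixture(scope="class")
    def lineages(self, segregant_barcodes, guide_library):
        _, gbc = guide_library
        return build_lineages(segregant_barcodes, gbc, SimConfig(seed=5))

    def test_t0_frequencies_sum_to_one(self, lineages):
        assert lineages["t0_abundance"].sum() == pytest.approx(1.0, abs=1e-12)

    def test_neutral_pool_expected_frequencies_constant(
        self, genotypes, guide_library, lineages
    ):
        guides, _ = guide_library
        arch = simulate_architecture(
            genotypes, guides,
            ArchitectureConfig(efficacious_fraction=0, n_hubs=0, hub_styles=(),
                               n_fitness_qtl=0, baseline_resid_sd=0),
            seed=0,
        )
        cfg = SimConfig(seed=5, sampling="expected", depth=10**6)
        counts, _ = simulate_assay(arch, genotypes, lineages, cfg, True, "A", 0)
        N = counts[COUNT_COLS].to_numpy()
        f = N / N.sum(axis=0)
        assert np.allclose(f, f[:, [0]], atol=1e-12)

    def test_two_lineage_logistic_frequency(self):
        # s = {0, 0.2}, equal T0: f2(10 gen) = e^2 / (1 + e^2) ~ 0.8808
        s = np.array([0.0, 0.2])
        f = np.array([0.5, 0.5])
        for dt in (2, 2, 2, 4):
            f = f * np.exp(s * dt)
            f /= f.sum()
        assert f[1] == pytest.approx(np.exp(2) / (1 + np.exp(2)), abs=1e-10)

    def test_multinomial_counts_conserve_depth(
        self, genotypes, architecture, lineages
    ):
        cfg = SimConfig(seed=6, depth=250_000)
        counts, _ = simulate_assay(architecture, genotypes, lineages, cfg,
                                   True, "A", 1)
        for col in COUNT_COLS:
            assert counts[col].sum() == 250_000

    def test_seed_determinism(self, genotypes, architecture, lineages):
        cfg = SimConfig(seed=6, depth=100_000)
        a, _ = simulate_assay(architecture, genotypes, lineages, cfg, True, "A", 2)
        b, _ = simulate_assay(architecture, genotypes, lineages, cfg, True, "A", 2)
        pd.testing.assert_frame_equal(a, b)

    def test_noiseless_log_ratio_linear_in_time(
        self, genotypes, architecture, lineages
    ):
        cfg = SimConfig(seed=6, sampling="expected", depth=10**7)
        counts, truth = simulate_assay(architecture, genotypes, lineages, cfg,
                                       True, "A", 3)
        gens = np.array(cfg.time_points)
        N = counts[COUNT_COLS].to_numpy()
        s = truth["true_fitness"].to_numpy()
        i, j = 0, len(N) // 2
        logratio = np.log(N[i] / N[j])
        slopes = np.diff(logratio) / np.diff(gens)
        assert np.allclose(slopes, s[i] - s[j], atol=1e-9)


class TestChimeras:
    @pytest.fixture(scope="class")
    def counts(self, genotypes, architecture, segregant_barcodes, guide_library):
        _, gbc = guide_library
        cfg = SimConfig(seed=7, depth=500_000)
        lineages = build_lineages(segregant_barcodes, gbc, cfg)
        counts, _ = simulate_assay(architecture, genotypes, lineages, cfg,
                                   True, "ATC1", 4)
        return counts

    def test_zero_coefficients_leave_counts_unchanged(self, counts):
        out, truth = inject_chimeras(counts, ChimeraCoefficients(0, 0, 0), 0)
        assert len(out) == len(counts)
        assert (out[COUNT_COLS].to_numpy() == counts[COUNT_COLS].to_numpy()).all()
        assert truth[COUNT_COLS].to_numpy().sum() == 0

    def test_intercept_only_poisson_mean(self, counts):
        c0 = 2e-6
        out, truth = inject_chimeras(counts, ChimeraCoefficients(c0, 0, 0), 1)
        depth = counts["n_t0"].sum()
        n_pairs = counts["segregant_bc"].nunique() * counts["guide_bc"].nunique()
        total = truth["n_t0"].sum()
        expect = n_pairs * depth * c0
        assert abs(total - expect) < 3 * np.sqrt(expect)

    def test_negative_coefficients_rejected(self):
        with pytest.raises(ValueError):
            ChimeraCoefficients(-1e-6, 0, 0)

    def test_default_chimeric_fraction_below_ten_percent(self, counts):
        out, truth = inject_chimeras(counts, ChimeraCoefficients(), 2)
        frac = truth[COUNT_COLS].to_numpy().sum() / out[COUNT_COLS].to_numpy().sum()
        assert 0 < frac < 0.10
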